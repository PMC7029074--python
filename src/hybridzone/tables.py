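"""Loaders for the packaged field-study tables.

Three small tables from the published contact-zone survey ship with the
package as plain TSV: the locality table (sampling sites and sizes), the
per-individual hybrid table (marker verdicts plus the three microsatellite
scores, 31 rows), and the six-class assignment-performance table computed on
simulated genotypes.  Score cells keep the printed notation — a bare number
for an individual outside the parental ranges, "p (0.072)" / "w (0.960)"
for one inside them, an em-dash for missing — and the loader parses them
into (verdict, score) pairs.
"""

from __future__ import annotations

import re
from importlib import resources

import numpy as np
import pandas as pd

from .io import _normalise_verdict

_SCORE = re.compile(r"^(?:(?P<tag>[pw])\s*\()?(?P<num>\d*\.\d+|\d+\.?\d*)\)?$")


def _data(name: str):
    return resources.files("hybridzone.data").joinpath(name)


def parse_score_cell(cell: str) -> tuple[str | None, float]:
    """Parse a printed score cell into (parental tag or None, score).

    "0.422" -> (None, 0.422); "p (0.072)" -> ("p", 0.072); "—" -> (None, nan).
    """
    cell = str(cell).strip()
    if cell in ("", "—", "-", "nan"):
        return None, float("nan")
    m = _SCORE.match(cell)
    if not m:
        raise ValueError(f"unparseable score cell {cell!r}")
    return m.group("tag"), float(m.group("num"))


def load_localities() -> pd.DataFrame:
    """Sampling localities: code, name, region, sample size n."""
    with resources.as_file(_data("localities.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"code": str})


def load_hybrid_table() -> pd.DataFrame:
    """The 31-row per-individual hybrid table.

    Returns one row per individual with normalised marker verdicts
    (COI/Pho/ITS1 in {P, W, PW, missing}), the parsed scores ``q_str`` and
    ``h`` (NaN when not genotyped), the parental tag printed next to each
    score (``str_tag`` / ``int_tag``), and the NewHybrids majority class
    (``nh``, None when missing).
    """
    with resources.as_file(_data("field_hybrids.tsv")) as p:
        raw = pd.read_csv(p, sep="\t", dtype=str)
    out = pd.DataFrame(
        {
            "locality_no": raw["locality_no"].astype(str),
            "locality": raw["locality"],
        }
    )
    for marker in ("COI", "Pho", "ITS1"):
        out[marker] = raw[marker].map(_normalise_verdict)
    str_parsed = raw["STR"].map(parse_score_cell)
    int_parsed = raw["INT"].map(parse_score_cell)
    out["str_tag"] = [t for t, _ in str_parsed]
    out["q_str"] = [v for _, v in str_parsed]
    out["int_tag"] = [t for t, _ in int_parsed]
    out["h"] = [v for _, v in int_parsed]
    out["nh"] = [
        None if c.strip() in ("—", "-", "") else c.strip() for c in raw["NH"]
    ]
    return out


def load_hybrid_frequencies() -> pd.DataFrame:
    """Printed per-locality hybrid frequencies f_H for the 8 hybrid sites."""
    with resources.as_file(_data("field_fh.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"locality_no": str})


def load_performance_table() -> pd.DataFrame:
    """Published six-class efficiency/accuracy/performance table."""
    with resources.as_file(_data("assignment_performance.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df.set_index("class")


#: parental score ranges calibrated on the published simulated dataset
#: (W-side convention: q for the wilkinsoni cluster, or the h-index).
PUBLISHED_RANGES = {
    "q_str": {"P": (0.0, 0.207), "W": (0.809, 1.0)},
    "h": {"P": (0.0, 0.183), "W": (0.838, 1.0)},
}

#: HgaI banding patterns of the two species' ITS-1 references (bp)
PUBLISHED_RFLP = {
    "P": (152, 131, 97, 70, 33, 17),
    "W": (232, 153, 66, 33, 17),
}
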