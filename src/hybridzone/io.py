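"""Readers and writers for the tabular and sequence formats the pipeline touches.

Genotypes are diploid codominant calls (microsatellite fragment sizes treated
as opaque labels), stored individual x locus with explicit missing-data
support.  Two table dialects are accepted: two columns per locus, or one
column per locus with slash-joined allele pairs.  Sequences travel as plain
FASTA via Biopython.  All sequence coordinates in this package are 0-based,
half-open.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = None  # sentinel for a missing allele call inside GenotypeMatrix

#: verdict vocabulary for per-marker species diagnoses
VERDICTS = ("P", "W", "PW", "missing")


class FormatError(ValueError):
    """Raised when an input file violates the expected table layout."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotypes with missing-data support.

    ``calls`` is an object array of shape (n_individuals, n_loci, 2) whose
    entries are allele labels (strings) or ``None`` for missing.  A call is
    either fully observed (two alleles) or fully missing.
    """

    individual_ids: list[str]
    locality_ids: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=object)
        n, L = len(self.individual_ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {L} loci"
            )
        if len(self.locality_ids) != n:
            raise ValueError("locality_ids length mismatch")
        half = (self.calls == None).sum(axis=2)  # noqa: E711 — elementwise
        if np.any(half == 1):
            raise ValueError("partial calls are not representable; mark fully missing")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def is_missing(self) -> np.ndarray:
        """Boolean (n, L) mask of missing calls."""
        return self.calls[:, :, 0] == None  # noqa: E711

    def subset(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {iid: i for i, iid in enumerate(self.individual_ids)}
        rows = [index[i] for i in ids]
        return GenotypeMatrix(
            [self.individual_ids[r] for r in rows],
            [self.locality_ids[r] for r in rows],
            list(self.loci),
            self.calls[rows],
        )

    def concat(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if self.loci != other.loci:
            raise ValueError("locus sets differ")
        return GenotypeMatrix(
            self.individual_ids + other.individual_ids,
            self.locality_ids + other.locality_ids,
            list(self.loci),
            np.concatenate([self.calls, other.calls], axis=0),
        )

    def encode(self) -> tuple[np.ndarray, list[list[str]]]:
        """Integer-code alleles per locus.

        Returns ``(codes, allele_lists)`` where ``codes`` is int array
        (n, L, 2) with -1 for missing and ``allele_lists[l]`` maps code ->
        allele label (sorted for determinism).
        """
        n, L = self.n_individuals, self.n_loci
        codes = np.full((n, L, 2), -1, dtype=np.int64)
        allele_lists: list[list[str]] = []
        for l in range(L):
            col = self.calls[:, l, :]
            alleles = sorted({a for a in col.ravel() if a is not None})
            lookup = {a: i for i, a in enumerate(alleles)}
            for i in range(n):
                a, b = col[i]
                if a is not None:
                    codes[i, l, 0] = lookup[a]
                    codes[i, l, 1] = lookup[b]
            allele_lists.append(alleles)
        return codes, allele_lists

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locality_ids == other.locality_ids
            and self.loci == other.loci
            and all(
                sorted(x for x in self.calls[i, l] if x is not None)
                == sorted(x for x in other.calls[i, l] if x is not None)
                for i in range(self.n_individuals)
                for l in range(self.n_loci)
            )
        )


@dataclass
class SequenceSet:
    """Named nucleotide sequences, optionally aligned and species-tagged."""

    ids: list[str]
    seqs: list[str]
    aligned: bool = False
    species: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs length mismatch")
        self.seqs = [s.upper() for s in self.seqs]
        bad = [i for i, s in zip(self.ids, self.seqs) if set(s) - set("ACGTN-")]
        if bad:
            raise ValueError(f"non-nucleotide characters in: {bad[:5]}")
        if self.aligned and len({len(s) for s in self.seqs}) > 1:
            raise ValueError("aligned set has unequal sequence lengths")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.seqs))


def read_genotypes(path: str | Path, missing_code: str = "0") -> GenotypeMatrix:
    """Read a genotype table, auto-detecting the locus-column dialect.

    The first two columns are individual id and locality.  Loci follow either
    as *pairs* of identically named columns or as single columns holding
    slash-joined allele pairs ("171/175").  A call equal to ``missing_code``
    (or ``missing_code/missing_code``) is missing; a single observed allele is
    demoted to fully missing with a warning.  Three or more alleles in one
    call is a format error.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if sample.count("\t") >= sample.count(",") else ","
        rows = list(csv.reader(fh, delimiter=delim))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    locus_cols = header[2:]
    paired = len(locus_cols) >= 2 and any(
        locus_cols[i] == locus_cols[i + 1] for i in range(0, len(locus_cols) - 1, 2)
    )
    if paired:
        if len(locus_cols) % 2:
            raise FormatError(f"{path}: odd number of allele columns")
        loci = locus_cols[0::2]
        if locus_cols[1::2] != loci:
            raise FormatError(f"{path}: locus column pairs do not match")
    else:
        loci = locus_cols

    ids, locs, calls = [], [], []
    for ridx, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        ids.append(row[0])
        locs.append(row[1])
        indiv = []
        for lidx, locus in enumerate(loci):
            if paired:
                raw = [row[2 + 2 * lidx].strip(), row[3 + 2 * lidx].strip()]
            else:
                cell = row[2 + lidx].strip()
                raw = cell.split("/") if cell else []
            raw = [a for a in raw if a != ""]
            alleles = [a for a in raw if a != missing_code]
            if len(raw) > 2:
                raise FormatError(
                    f"{path}: row {ridx}, locus {locus}: {len(raw)} alleles in one call"
                )
            if len(alleles) == 2:
                indiv.append(alleles)
            else:
                if len(alleles) == 1:
                    warnings.warn(
                        f"{path}: row {ridx}, locus {locus}: partial call "
                        "treated as missing",
                        stacklevel=2,
                    )
                indiv.append([MISSING, MISSING])
        calls.append(indiv)
    return GenotypeMatrix(ids, locs, list(loci), np.array(calls, dtype=object))


def write_genotypes(
    gm: GenotypeMatrix, path: str | Path, missing_code: str = "0"
) -> None:
    """Write a genotype table in the slash-joined dialect (round-trips)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "locality", *gm.loci])
        for i, (iid, loc) in enumerate(zip(gm.individual_ids, gm.locality_ids)):
            cells = []
            for l in range(gm.n_loci):
                a, b = gm.calls[i, l]
                if a is None:
                    cells.append(f"{missing_code}/{missing_code}")
                else:
                    cells.append(f"{a}/{b}")
            w.writerow([iid, loc, *cells])


def read_fasta(path: str | Path, aligned: bool = False) -> SequenceSet:
    """Read FASTA; ids must be unique, sequences are upper-cased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate sequence ids {dupes}")
    return SequenceSet(ids, [str(r.seq) for r in records], aligned=aligned)


def write_fasta(seqset: SequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(seqset.ids, seqset.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Per-individual per-marker diagnoses (P / W / PW / missing).

    Columns beyond ``id`` and ``locality`` are marker names; cells may use
    the compact field notation (p, w, "w,p", em-dash/blank for missing).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    markers = [c for c in df.columns if c not in ("id", "locality")]
    for m in markers:
        df[m] = df[m].map(_normalise_verdict)
    return df


def _normalise_verdict(cell: str) -> str:
    cell = cell.strip().lower()
    if cell in ("", "—", "-", "na", "missing"):
        return "missing"
    if cell in ("p",):
        return "P"
    if cell in ("w",):
        return "W"
    if cell in ("pw", "wp", "w,p", "p,w"):
        return "PW"
    raise FormatError(f"unrecognised marker verdict {cell!r}")


def read_locality_table(path: str | Path) -> pd.DataFrame:
    """Locality table: code, name, lat, lon, n (sample size)."""
    df = pd.read_csv(path, sep="\t", dtype={"code": str, "name": str})
    if not {"code", "name", "n"} <= set(df.columns):
        raise FormatError(f"{path}: locality table needs code, name, n columns")
    return df


def write_report(calls: Iterable, path: str | Path) -> None:
    """Write the per-individual hybrid report (one row per HybridCall).

    Columns mirror the field report layout: locality, the three sequence /
    RFLP marker verdicts, the three microsatellite scores (q for the
    wilkinsoni cluster, NewHybrids majority class, h-index) and the locality
    hybrid frequency.  Scores print to 3 decimals; the output is
    byte-deterministic for a fixed input.
    """
    cols = [
        "id", "locality", "COI", "Pho", "ITS1",
        "STR", "NH", "INT", "hybrid", "evidence", "f_H",
    ]
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for c in calls:
            w.writerow(
                [
                    c.individual_id,
                    c.locality,
                    c.markers.get("COI", "missing"),
                    c.markers.get("Pho", "missing"),
                    c.markers.get("ITS1", "missing"),
                    _fmt(c.q_str),
                    c.nh_class if c.nh_class is not None else "—",
                    _fmt(c.h),
                    "yes" if c.hybrid else "no",
                    ";".join(c.evidence),
                    _fmt(c.f_h),
                ]
            )


def _fmt(x) -> str:
    return "—" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.3f}"
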