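"""Simulation-calibrated thresholds and assignment-performance measures.

Parental score ranges (the observed [min, max] of an assignment score —
cluster membership q or hybrid index h, both on the W-side convention —
over simulated pure parents) turn a continuous score into a three-way
verdict: within the P range, within the W range, or outside both and hence
hybrid.  Per-class assignment quality uses the standard efficiency /
accuracy decomposition: efficiency is the fraction of a class' true members
assigned to it, accuracy the fraction of assignments to the class that are
correct, and overall performance their product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CLASSES


@dataclass
class CalibrationRanges:
    """Inclusive parental score ranges on the W-side score scale."""

    p_range: tuple[float, float]     # pure pityocampa (low scores)
    w_range: tuple[float, float]     # pure wilkinsoni (high scores)

    def __post_init__(self) -> None:
        for lo, hi in (self.p_range, self.w_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("ranges must satisfy 0 <= min <= max <= 1")
        if self.p_range[1] >= self.w_range[0]:
            raise ValueError(
                "parental ranges overlap: no hybrid is detectable "
                f"({self.p_range} vs {self.w_range})"
            )


def calibrate_parental_ranges(
    scores_p: np.ndarray | list[float], scores_w: np.ndarray | list[float]
) -> CalibrationRanges:
    """Observed [min, max] score range of each simulated parental class."""
    sp = np.asarray(scores_p, dtype=float)
    sw = np.asarray(scores_w, dtype=float)
    if sp.size == 0 or sw.size == 0:
        raise ValueError("need >= 1 simulated individual per parental class")
    return CalibrationRanges(
        p_range=(float(sp.min()), float(sp.max())),
        w_range=(float(sw.min()), float(sw.max())),
    )


def classify_by_threshold(score: float, ranges: CalibrationRanges) -> str:
    """Three-way verdict for one W-side score; range bounds are inclusive.

    Monotone in the score: parental_P below, hybrid between, parental_W
    above (scores below the P minimum or above the W maximum are more
    extreme than any simulated parent, not intermediate, and keep the
    parental verdict).
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if score <= ranges.p_range[1]:
        return "parental_P"
    if score >= ranges.w_range[0]:
        return "parental_W"
    return "hybrid"


def performance_metrics(
    true_labels, assigned_labels, classes: tuple[str, ...] = CLASSES
) -> pd.DataFrame:
    """Per-class efficiency, accuracy, performance and misassignment matrix.

    ``assigned_labels`` may contain ``"undetermined"``; those individuals
    count against efficiency but are excluded from the accuracy denominator
    and reported in the ``unassigned`` column.  Accuracy (and performance)
    is NaN for a class nothing was assigned to.
    """
    true = pd.Series(list(true_labels))
    assigned = pd.Series(list(assigned_labels))
    if len(true) != len(assigned):
        raise ValueError("label vectors differ in length")
    rows = []
    for cls in classes:
        mine = true == cls
        n_true = int(mine.sum())
        correct = int((mine & (assigned == cls)).sum())
        n_assigned = int((assigned == cls).sum())
        eff = correct / n_true if n_true else float("nan")
        acc = correct / n_assigned if n_assigned else float("nan")
        perf = eff * acc
        mis = {
            f"to_{z}": float((mine & (assigned == z)).sum()) / n_true
            if n_true
            else float("nan")
            for z in classes
        }
        unassigned = (
            float((mine & (assigned == "undetermined")).sum()) / n_true
            if n_true
            else float("nan")
        )
        rows.append(
            {
                "class": cls,
                "efficiency": eff,
                "accuracy": acc,
                "performance": perf,
                **mis,
                "unassigned": unassigned,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def overall_performance(efficiency: float, accuracy: float) -> float:
    """Overall assignment performance: efficiency x accuracy."""
    return efficiency * accuracy


def summarize_localities(calls, locality_table: pd.DataFrame) -> pd.DataFrame:
    """Per-locality hybrid frequency f_H and per-marker species composition.

    ``calls`` is an iterable of HybridCall; every call's locality must map
    to the locality table (keyed by name or code).  f_H = hybrids / sampled,
    with the sampled count taken from the locality table.
    """
    known = set(locality_table["name"]) | set(locality_table["code"].astype(str))
    n_by_loc = {}
    for _, r in locality_table.iterrows():
        n_by_loc[r["name"]] = int(r["n"])
        n_by_loc[str(r["code"])] = int(r["n"])
    buckets: dict[str, list] = {}
    for c in calls:
        if c.locality not in known:
            raise ValueError(f"unknown locality {c.locality!r}")
        buckets.setdefault(c.locality, []).append(c)
    rows = []
    for loc in sorted(buckets):
        group = buckets[loc]
        n_sampled = n_by_loc[loc]
        n_hyb = sum(bool(c.hybrid) for c in group)
        row = {
            "locality": loc,
            "n_sampled": n_sampled,
            "n_hybrids": n_hyb,
            "f_H": n_hyb / n_sampled,
        }
        for marker in ("COI", "Pho", "ITS1"):
            verdicts = [c.markers.get(marker, "missing") for c in group]
            for v in ("P", "W", "PW", "missing"):
                row[f"{marker}_{v}"] = verdicts.count(v)
        rows.append(row)
    return pd.DataFrame(rows)
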