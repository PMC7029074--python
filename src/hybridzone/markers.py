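"""Per-marker species diagnosis and sequence summaries.

Covers the sequence side of hybrid detection: p-distance and Kimura
2-parameter distances with pairwise deletion, within/between group means,
haplotype collapsing, a minimum-spanning haplotype network with a parsimony
connection limit, restriction-digest prediction (HgaI on ITS-1), nearest-
reference species diagnosis, and the two discordance criteria that flag an
individual as hybrid:

(a) both species' alleles co-occur at one nuclear marker, or
(b) two markers give opposite pure-species verdicts (mito-nuclear or
    nuclear-nuclear incongruence).
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import SequenceSet

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T"}

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class UndefinedDistance(UserWarning):
    """Emitted when a pairwise distance cannot be computed (returns NaN)."""


def _comparable_sites(seq1: str, seq2: str):
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a in _VALID and b in _VALID:
            yield a, b


def p_distance(seq1: str, seq2: str) -> float:
    """Proportion of differing sites, pairwise-deleting gaps and Ns.

    NaN (with an UndefinedDistance warning) when no site is comparable.
    """
    n = diff = 0
    for a, b in _comparable_sites(seq1, seq2):
        n += 1
        diff += a != b
    if n == 0:
        warnings.warn("no comparable sites", UndefinedDistance, stacklevel=2)
        return float("nan")
    return diff / n


def k2p_distance(seq1: str, seq2: str) -> float:
    """Kimura 2-parameter distance, d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).

    P and Q are the transition and transversion proportions over comparable
    sites.  Saturated pairs (log argument <= 0) give NaN with a warning.
    """
    n = ts = tv = 0
    for a, b in _comparable_sites(seq1, seq2):
        n += 1
        if a == b:
            continue
        if (a in PURINES) == (b in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        warnings.warn("no comparable sites", UndefinedDistance, stacklevel=2)
        return float("nan")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        warnings.warn("K2P saturated", UndefinedDistance, stacklevel=2)
        return float("nan")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def group_mean_distances(
    seqset: SequenceSet, grouping: dict[str, str], metric=k2p_distance
) -> pd.DataFrame:
    """Unweighted mean pairwise distance within and between groups.

    ``grouping`` maps sequence id -> group label.  Returns a symmetric
    group x group table; the diagonal holds within-group means (NaN for
    singleton groups, with a warning).
    """
    seqs = dict(seqset)
    groups = sorted(set(grouping.values()))
    members = {g: [i for i in seqset.ids if grouping.get(i) == g] for g in groups}
    for g in groups:
        if not members[g]:
            raise ValueError(f"group {g!r} has no sequences")
    table = pd.DataFrame(index=groups, columns=groups, dtype=float)
    for g1, g2 in itertools.combinations_with_replacement(groups, 2):
        if g1 == g2:
            pairs = list(itertools.combinations(members[g1], 2))
            if not pairs:
                warnings.warn(
                    f"singleton group {g1!r}: within-distance undefined",
                    UndefinedDistance,
                    stacklevel=2,
                )
                table.loc[g1, g1] = float("nan")
                continue
        else:
            pairs = [(a, b) for a in members[g1] for b in members[g2]]
        vals = [metric(seqs[a], seqs[b]) for a, b in pairs]
        table.loc[g1, g2] = table.loc[g2, g1] = float(np.mean(vals))
    return table


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with counts and member ids."""

    haplotypes: list[str]            # representative sequences
    ids: list[str]                   # haplotype labels (H1, H2, ...)
    counts: list[int]
    members: list[list[str]]
    tags: dict[str, str] = field(default_factory=dict)  # hap id -> species tag

    def __len__(self) -> int:
        return len(self.ids)


def collapse_haplotypes(seqset: SequenceSet, strict: bool = True) -> HaplotypeTable:
    """Collapse identical sequences of an aligned set into haplotypes.

    With ``strict=False`` sites where either sequence has N are ignored in
    the identity comparison (a sequence is merged into the first compatible
    haplotype); gaps always compare literally.
    """
    if not seqset.aligned and len({len(s) for s in seqset.seqs}) > 1:
        raise ValueError("sequences must be aligned")

    reps: list[str] = []
    members: list[list[str]] = []
    for sid, seq in seqset:
        hit = None
        for h, rep in enumerate(reps):
            if strict:
                same = seq == rep
            else:
                same = all(
                    a == b or a == "N" or b == "N" for a, b in zip(seq, rep)
                )
            if same:
                hit = h
                break
        if hit is None:
            reps.append(seq)
            members.append([sid])
        else:
            members[hit].append(sid)
    return HaplotypeTable(
        haplotypes=reps,
        ids=[f"H{i + 1}" for i in range(len(reps))],
        counts=[len(m) for m in members],
        members=members,
    )


def build_haplotype_network(
    table: HaplotypeTable, connection_limit: int = 10
) -> list[tuple[str, str, int]]:
    """Minimum-spanning network over haplotypes by absolute differences.

    All edges that belong to *some* minimum spanning tree are retained
    (Kruskal by weight class, adding every class edge that joins components
    distinct at the start of the class), so mutational-step ties appear as
    parallel paths.  Edges longer than ``connection_limit`` steps are then
    dropped, which may disconnect the network — the descriptive analogue of
    a statistical-parsimony connection limit.
    """
    n = len(table)
    edges = []
    for i, j in itertools.combinations(range(n), 2):
        steps = sum(
            a != b for a, b in zip(table.haplotypes[i], table.haplotypes[j])
        )
        edges.append((steps, i, j))
    edges.sort()

    uf = nx.utils.UnionFind(range(n))
    kept: list[tuple[str, str, int]] = []
    for _, class_edges in itertools.groupby(edges, key=lambda e: e[0]):
        batch = list(class_edges)
        joined = []
        for steps, i, j in batch:
            if uf[i] != uf[j]:
                kept.append((table.ids[i], table.ids[j], steps))
                joined.append((i, j))
        for i, j in joined:
            uf.union(i, j)
    return [(a, b, s) for a, b, s in kept if s <= connection_limit]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Type IIS enzyme cutting downstream of an asymmetric recognition site.

    ``cut_top`` is the top-strand cut distance past the site's 3' end;
    ``cut_bottom`` the bottom-strand distance, which for a bottom-strand
    site maps to a top-strand cut ``cut_bottom`` nt upstream of the site
    start.  HgaI is GACGC(5/10).
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int


HGAI = RestrictionEnzyme("HgaI", "GACGC", 5, 10)


def _find_all(seq: str, motif: str):
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return
        yield i
        start = i + 1


def predict_rflp(seq: str, enzyme: RestrictionEnzyme = HGAI) -> tuple[int, ...]:
    """Predicted fragment sizes of a complete digest, top-strand coordinates.

    Sites are found on both strands; cuts falling outside the sequence are
    dropped with a warning.  Fragments are returned sorted descending and
    always sum to the amplicon length.
    """
    seq = seq.upper()
    L = len(seq)
    rec = enzyme.recognition.upper()
    cuts = set()
    for i in _find_all(seq, rec):
        cuts.add(i + len(rec) + enzyme.cut_top)
    for j in _find_all(seq, revcomp(rec)):
        cuts.add(j - enzyme.cut_bottom)
    valid = sorted(c for c in cuts if 0 < c < L)
    dropped = len(cuts) - len(valid)
    if dropped:
        warnings.warn(
            f"{enzyme.name}: {dropped} cut(s) beyond sequence ends dropped",
            stacklevel=2,
        )
    bounds = [0, *valid, L]
    frags = [b - a for a, b in zip(bounds, bounds[1:])]
    return tuple(sorted(frags, reverse=True))


@dataclass
class ReferencePanel:
    """Per-species diagnosis anchors: reference sequences and RFLP patterns."""

    sequences: dict[str, dict[str, str]]         # marker -> {"P": seq, "W": seq}
    rflp_patterns: dict[str, tuple[int, ...]]    # {"P": sizes, "W": sizes}
    enzyme: RestrictionEnzyme = HGAI
    rflp_tolerance: int = 2

    def __post_init__(self) -> None:
        for marker, refs in self.sequences.items():
            if set(refs) != {"P", "W"}:
                raise ValueError(f"marker {marker}: need both species' references")
        if self.rflp_patterns and set(self.rflp_patterns) != {"P", "W"}:
            raise ValueError("RFLP panel needs both species' patterns")
        for sizes in self.rflp_patterns.values():
            if any(s <= 0 for s in sizes):
                raise ValueError("fragment sizes must be positive")


@dataclass
class MarkerDiagnosis:
    marker: str
    verdict: str                      # P / W / PW / missing
    evidence: dict = field(default_factory=dict)


def _nearest_species(seq: str, refs: dict[str, str]) -> str | None:
    dp = p_distance(seq, refs["P"])
    dw = p_distance(seq, refs["W"])
    if math.isnan(dp) or math.isnan(dw) or dp == dw:
        return None
    return "P" if dp < dw else "W"


def _match_pattern(
    observed: tuple[int, ...], reference: tuple[int, ...], tol: int
) -> bool:
    """Multiset match of band sizes within +/- tol bp (sorted greedy pairing)."""
    if len(observed) != len(reference):
        return False
    return all(
        abs(o - r) <= tol
        for o, r in zip(sorted(observed), sorted(reference))
    )


def _contains_bands(
    observed: tuple[int, ...], bands: tuple[int, ...], tol: int
) -> bool:
    pool = sorted(observed)
    for b in sorted(bands):
        hit = next((i for i, o in enumerate(pool) if abs(o - b) <= tol), None)
        if hit is None:
            return False
        pool.pop(hit)
    return True


def diagnose_marker(
    observed, marker: str, panel: ReferencePanel
) -> MarkerDiagnosis:
    """Diagnose one marker of one individual against the reference panel.

    For sequence markers ``observed`` is a list of allele sequences (one for
    a haploid/uniparental marker, two for a biparental one); each allele goes
    to the species whose reference is nearer by p-distance.  For the RFLP
    marker ``observed`` is a band-size multiset matched against each species'
    pattern, or against the composite of both (heterozygote).  Ambiguity is
    never resolved by guessing: equidistant alleles or unmatched patterns
    yield a ``missing`` verdict with the evidence recorded.
    """
    if marker in panel.sequences:
        if not observed:
            return MarkerDiagnosis(marker, "missing", {"reason": "no alleles"})
        species = []
        evidence = {}
        for k, allele in enumerate(observed):
            sp = _nearest_species(allele, panel.sequences[marker])
            evidence[f"allele{k}"] = sp
            if sp is None:
                return MarkerDiagnosis(marker, "missing", {"reason": "ambiguous", **evidence})
            species.append(sp)
        verdict = species[0] if len(set(species)) == 1 else "PW"
        return MarkerDiagnosis(marker, verdict, evidence)

    # RFLP pattern marker
    observed = tuple(observed)
    tol = panel.rflp_tolerance
    pats = panel.rflp_patterns
    if not observed:
        return MarkerDiagnosis(marker, "missing", {"reason": "no pattern"})
    hits = [sp for sp in ("P", "W") if _match_pattern(observed, pats[sp], tol)]
    if len(hits) == 1:
        return MarkerDiagnosis(marker, hits[0], {"matched": hits[0]})
    if len(hits) == 0:
        # composite pattern: both species' diagnostic (non-shared) bands present
        shared = _shared_bands(pats["P"], pats["W"], tol)
        uniq = {
            sp: _remove_bands(pats[sp], shared, tol) for sp in ("P", "W")
        }
        if all(_contains_bands(observed, uniq[sp], tol) for sp in ("P", "W")):
            return MarkerDiagnosis(marker, "PW", {"matched": "composite"})
    return MarkerDiagnosis(marker, "missing", {"reason": "ambiguous pattern"})


def _shared_bands(p1, p2, tol):
    pool = list(sorted(p2))
    shared = []
    for b in sorted(p1):
        hit = next((i for i, o in enumerate(pool) if abs(o - b) <= tol), None)
        if hit is not None:
            shared.append(b)
            pool.pop(hit)
    return tuple(shared)


def _remove_bands(pattern, bands, tol):
    pool = list(sorted(pattern))
    for b in bands:
        hit = next((i for i, o in enumerate(pool) if abs(o - b) <= tol), None)
        if hit is not None:
            pool.pop(hit)
    return tuple(pool)


MT_MARKERS = frozenset({"COI"})


@dataclass
class Discordance:
    """Outcome of the two hybrid criteria on one individual's marker row."""

    hybrid: bool | None               # None = undetermined (too few markers)
    criteria: list[tuple[str, tuple]] = field(default_factory=list)


def detect_discordance(
    verdicts: dict[str, str], mt_markers: frozenset[str] = MT_MARKERS
) -> Discordance:
    """Apply the two hybrid criteria to one individual's marker verdicts.

    Criterion (a): any *nuclear* marker shows both species' alleles (PW).
    Criterion (b): two non-missing markers give opposite pure verdicts
    (recorded as mt-nuc or nuc-nuc incongruence).  Fewer than two non-missing
    markers -> undetermined.  The check is order-invariant and symmetric in
    the species labels.
    """
    present = {m: v for m, v in verdicts.items() if v != "missing"}
    if len(present) < 2:
        return Discordance(hybrid=None)
    fired: list[tuple[str, tuple]] = []
    for m, v in sorted(present.items()):
        if v == "PW" and m not in mt_markers:
            fired.append(("a", (m,)))
    for m1, m2 in itertools.combinations(sorted(present), 2):
        v1, v2 = present[m1], present[m2]
        if {v1, v2} == {"P", "W"}:
            kind = "mt-nuc" if (m1 in mt_markers) != (m2 in mt_markers) else "nuc-nuc"
            fired.append(("b", (m1, m2, kind)))
    return Discordance(hybrid=bool(fired), criteria=fired)


def count_stop_codons(seq: str, frame: int = 0) -> int:
    """Quick pseudogene screen: in-frame stop codons in a coding fragment."""
    stops = {"TAA", "TAG", "TGA"}
    s = seq.upper().replace("-", "")
    return sum(
        1 for i in range(frame, len(s) - 2, 3) if s[i : i + 3] in stops
    )
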