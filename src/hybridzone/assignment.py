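"""Hybrid index and six-class ancestry assignment from codominant genotypes.

Two complementary per-individual summaries against a pair of parental
allele-frequency tables:

* the maximum-likelihood **hybrid index** h in [0, 1] (0 = pure pityocampa
  ancestry, 1 = pure wilkinsoni), maximising per allele copy the mixture
  (1-h) f_P(a) + h f_W(a) across loci;

* the **six genotype-frequency classes** (pure P, pure W, F1, F2, backcross
  to either parent).  Each class z fixes the probabilities theta_z that a
  locus' two gametes are both-P, one-of-each, or both-W; the per-locus
  genotype likelihood mixes Hardy-Weinberg terms over those origins and the
  class posterior q_NH follows by Bayes.  ``plugin`` mode treats the
  parental frequencies as known; ``mcmc`` mode resamples them jointly with
  the class assignments under Jeffreys-like Dirichlet(1/2) priors, the
  Bayesian treatment the class-assignment literature uses.

The six-class model cannot represent ancestry older than two generations;
later-generation backcrosses fold into the nearest representable class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .simulate import CLASSES

#: gamete-pair origin proportions (both-P, one-each, both-W) per class
ORIGIN_PROPS = {
    "P_pit": (1.0, 0.0, 0.0),
    "P_wil": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "Bkc_Pit": (0.5, 0.5, 0.0),
    "Bkc_Wil": (0.0, 0.5, 0.5),
}

FreqTable = list[dict[str, float]]     # per locus: allele -> frequency


def allele_frequencies(
    gm: GenotypeMatrix,
    ids: list[str] | None = None,
    smoothing: float = 0.5,
    allele_universe: list[set[str]] | None = None,
) -> FreqTable:
    """Smoothed allele frequencies of a reference pool.

    Counts alleles among ``ids`` (default: all individuals) and applies
    add-``smoothing`` (default add-half, Jeffreys) over the allele universe
    — by default every allele seen anywhere in ``gm``, so query alleles
    absent from one pool keep a small nonzero frequency instead of zeroing
    out downstream likelihoods.
    """
    sub = gm if ids is None else gm.subset(ids)
    if allele_universe is None:
        allele_universe = [
            {a for a in gm.calls[:, l, :].ravel() if a is not None}
            for l in range(gm.n_loci)
        ]
    out: FreqTable = []
    for l in range(gm.n_loci):
        universe = sorted(allele_universe[l])
        counts = {a: smoothing for a in universe}
        for pair in sub.calls[:, l, :]:
            for a in pair:
                if a is not None:
                    counts[a] = counts.get(a, smoothing) + 1.0
        tot = sum(counts.values())
        out.append({a: c / tot for a, c in counts.items()})
    return out


@dataclass
class HybridIndexEstimate:
    h: float
    loglik: float
    per_locus: list[float] = field(default_factory=list)
    loci_used: int = 0


def estimate_h(
    genotype: np.ndarray | list,
    freq_p: FreqTable,
    freq_w: FreqTable,
    tol: float = 1e-6,
) -> HybridIndexEstimate:
    """Maximum-likelihood hybrid index for one individual.

    ``genotype`` is the (L, 2) allele-label row; missing loci are skipped.
    The log-likelihood sum over allele copies of
    log((1-h) f_P(a) + h f_W(a)) is maximised by golden-section search on
    [0, 1] to ``tol``, with the boundary values checked explicitly so pure
    ancestries return exactly 0 or 1.  Returns NaN (flagged) when no locus
    is informative.
    """
    terms: list[tuple[int, float, float]] = []      # (locus, fP, fW) per copy
    for l, pair in enumerate(genotype):
        a1, a2 = pair
        if a1 is None:
            continue
        for a in (a1, a2):
            fp = freq_p[l].get(a)
            fw = freq_w[l].get(a)
            if fp is None or fw is None:
                continue
            terms.append((l, fp, fw))
    informative = [t for t in terms if not math.isclose(t[1], t[2])]
    if not informative:
        warnings.warn("no informative loci: h undefined", stacklevel=2)
        return HybridIndexEstimate(float("nan"), float("nan"))

    fp = np.array([t[1] for t in terms])
    fw = np.array([t[2] for t in terms])

    def ll(h: float) -> float:
        mix = (1.0 - h) * fp + h * fw
        if np.any(mix <= 0):
            return -np.inf
        return float(np.log(mix).sum())

    h_star = _golden_max(ll, 0.0, 1.0, tol)
    best = max((0.0, 1.0, h_star), key=ll)
    loci = sorted({t[0] for t in terms})
    per_locus = []
    for l in loci:
        idx = [i for i, t in enumerate(terms) if t[0] == l]
        mix = (1.0 - best) * fp[idx] + best * fw[idx]
        per_locus.append(float(np.log(mix).sum()))
    return HybridIndexEstimate(
        h=best, loglik=ll(best), per_locus=per_locus, loci_used=len(loci)
    )


def _golden_max(f, a: float, b: float, tol: float) -> float:
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def _encode(gm: GenotypeMatrix, freq_p: FreqTable, freq_w: FreqTable):
    """Pad frequency tables to arrays aligned with gm's integer coding."""
    codes, allele_lists = gm.encode()
    L = gm.n_loci
    Jmax = max((len(a) for a in allele_lists), default=1) or 1
    fP = np.zeros((L, Jmax))
    fW = np.zeros((L, Jmax))
    for l, alleles in enumerate(allele_lists):
        for j, a in enumerate(alleles):
            fP[l, j] = freq_p[l].get(a, 0.0)
            fW[l, j] = freq_w[l].get(a, 0.0)
    return codes, allele_lists, fP, fW


def _origin_likelihoods(codes, fP, fW):
    """Per-individual per-locus genotype likelihood under each gamete origin.

    Returns (gPP, gPW, gWW, valid); the one-of-each origin counts both
    allele orderings for heterozygotes.
    """
    a1, a2 = codes[:, :, 0], codes[:, :, 1]
    valid = a1 >= 0
    s1, s2 = np.where(valid, a1, 0), np.where(valid, a2, 0)
    lidx = np.broadcast_to(np.arange(codes.shape[1])[None, :], s1.shape)
    p1, p2 = fP[lidx, s1], fP[lidx, s2]
    w1, w2 = fW[lidx, s1], fW[lidx, s2]
    het = (a1 != a2) & valid
    gPP = np.where(het, 2.0 * p1 * p2, p1 * p1)
    gWW = np.where(het, 2.0 * w1 * w2, w1 * w1)
    gPW = np.where(het, p1 * w2 + p2 * w1, p1 * w1)
    return gPP, gPW, gWW, valid


def _class_logliks(codes, fP, fW) -> np.ndarray:
    gPP, gPW, gWW, valid = _origin_likelihoods(codes, fP, fW)
    out = np.zeros((codes.shape[0], len(CLASSES)))
    for zi, cls in enumerate(CLASSES):
        t0, t1, t2 = ORIGIN_PROPS[cls]
        per_locus = t0 * gPP + t1 * gPW + t2 * gWW
        with np.errstate(divide="ignore"):
            lg = np.where(valid, np.log(np.where(per_locus > 0, per_locus, 1.0)), 0.0)
            lg = np.where(valid & (per_locus == 0), -np.inf, lg)
        out[:, zi] = lg.sum(axis=1)
    return out


def classify_six(
    gm: GenotypeMatrix,
    freq_p: FreqTable,
    freq_w: FreqTable,
    prior: np.ndarray | None = None,
    mode: str = "plugin",
    ref_p: GenotypeMatrix | None = None,
    ref_w: GenotypeMatrix | None = None,
    sweeps: int = 500,
    burnin: int = 100,
    seed: int = 0,
    fix_mixing: bool = False,
) -> pd.DataFrame:
    """Posterior over the six genotype classes for every individual in gm.

    ``plugin`` treats (freq_p, freq_w) as fixed; ``mcmc`` runs a Gibbs
    sampler that jointly resamples classes, per-locus gamete origins and the
    parental allele frequencies (Dirichlet(1/2) priors, reference pools
    ``ref_p``/``ref_w`` contributing fixed-origin allele counts), with the
    class mixing proportions either resampled (Dirichlet(1/2)) or held
    uniform (``fix_mixing``).  Returns a DataFrame indexed by individual id
    with one column per class plus a ``majority`` column; an individual
    whose genotype is impossible under every class gets NaN posteriors and
    majority ``undetermined``.
    """
    if prior is None:
        prior = np.full(len(CLASSES), 1.0 / len(CLASSES))
    prior = np.asarray(prior, dtype=float)
    if mode == "plugin":
        codes, _, fP, fW = _encode(gm, freq_p, freq_w)
        loglik = _class_logliks(codes, fP, fW)
        with np.errstate(divide="ignore"):
            logpost = loglik + np.log(prior)[None, :]
        post = _normalise_rows(logpost)
    elif mode == "mcmc":
        post = _classify_mcmc(
            gm, freq_p, freq_w, ref_p, ref_w, sweeps, burnin, seed, fix_mixing
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    df = pd.DataFrame(post, index=gm.individual_ids, columns=list(CLASSES))
    df["majority"] = [majority_assignment(row) for _, row in df.iterrows()]
    return df


def _normalise_rows(logpost: np.ndarray) -> np.ndarray:
    out = np.empty_like(logpost)
    for i in range(logpost.shape[0]):
        row = logpost[i]
        m = row.max()
        if not np.isfinite(m):
            warnings.warn(
                f"individual {i}: genotype impossible under every class",
                stacklevel=3,
            )
            out[i] = np.nan
            continue
        w = np.exp(row - m)
        out[i] = w / w.sum()
    return out


def _classify_mcmc(
    gm, freq_p, freq_w, ref_p, ref_w, sweeps, burnin, seed, fix_mixing
):
    rng = np.random.default_rng(seed)
    codes, allele_lists, fP, fW = _encode(gm, freq_p, freq_w)
    n, L, _ = codes.shape
    Jmax = fP.shape[1]
    amask = fP > 0        # legal alleles carry smoothing mass > 0
    theta = np.array([ORIGIN_PROPS[c] for c in CLASSES])        # (6, 3)

    # fixed allele counts from the reference pools (origin known)
    base_p = np.full((L, Jmax), 0.5) * amask
    base_w = np.full((L, Jmax), 0.5) * amask
    for ref, base in ((ref_p, base_p), (ref_w, base_w)):
        if ref is None:
            continue
        rcodes, r_lists = ref.encode()
        for l in range(L):
            lookup = {a: j for j, a in enumerate(allele_lists[l])}
            remap = {j: lookup.get(a, -1) for j, a in enumerate(r_lists[l])}
            for pair in rcodes[:, l, :]:
                for c in pair:
                    if c >= 0 and remap[c] >= 0:
                        base[l, remap[c]] += 1.0

    a1, a2 = codes[:, :, 0], codes[:, :, 1]
    valid = a1 >= 0
    s1, s2 = np.where(valid, a1, 0), np.where(valid, a2, 0)
    lidx = np.broadcast_to(np.arange(L)[None, :], s1.shape)
    pi = np.full(len(CLASSES), 1.0 / len(CLASSES))
    post_sum = np.zeros((n, len(CLASSES)))
    kept = 0

    for sweep in range(burnin + sweeps):
        gPP, gPW, gWW, _ = _origin_likelihoods(codes, fP, fW)
        per_locus = np.stack([gPP, gPW, gWW], axis=-1)          # (n, L, 3)

        # z | f, pi
        lik = np.einsum("zo,nlo->nlz", theta, per_locus)
        with np.errstate(divide="ignore"):
            logl = np.where(valid[:, :, None], np.log(np.maximum(lik, 1e-300)), 0.0)
        logz = logl.sum(axis=1) + np.log(pi)[None, :]
        z = _sample_rows(logz, rng)

        # per-locus origin | z, f
        oprob = theta[z][:, None, :] * per_locus
        tot = oprob.sum(-1, keepdims=True)
        tot[tot == 0] = 1.0
        cdf = np.cumsum(oprob / tot, axis=-1)
        o = (rng.random((n, L))[:, :, None] > cdf).sum(-1)
        o = np.minimum(o, 2)

        # allele-species assignment -> frequency update
        cp = base_p.copy()
        cw = base_w.copy()
        het = (a1 != a2) & valid
        r1 = fP[lidx, s1] * fW[lidx, s2]
        r2 = fP[lidx, s2] * fW[lidx, s1]
        denom = r1 + r2
        denom[denom == 0] = 1.0
        first_to_p = rng.random((n, L)) < r1 / denom
        sel = valid & (o == 0)
        np.add.at(cp, (lidx[sel], s1[sel]), 1.0)
        np.add.at(cp, (lidx[sel], s2[sel]), 1.0)
        sel = valid & (o == 2)
        np.add.at(cw, (lidx[sel], s1[sel]), 1.0)
        np.add.at(cw, (lidx[sel], s2[sel]), 1.0)
        mixed = valid & (o == 1)
        hom = mixed & ~het                      # same allele to each species
        np.add.at(cp, (lidx[hom], s1[hom]), 1.0)
        np.add.at(cw, (lidx[hom], s1[hom]), 1.0)
        hp = mixed & het & first_to_p           # a1 from P gamete, a2 from W
        np.add.at(cp, (lidx[hp], s1[hp]), 1.0)
        np.add.at(cw, (lidx[hp], s2[hp]), 1.0)
        hw = mixed & het & ~first_to_p          # a2 from P gamete, a1 from W
        np.add.at(cp, (lidx[hw], s2[hw]), 1.0)
        np.add.at(cw, (lidx[hw], s1[hw]), 1.0)

        g = rng.gamma(np.where(amask, cp, 1.0))
        fP = np.where(amask, g, 0.0)
        fP /= fP.sum(1, keepdims=True)
        g = rng.gamma(np.where(amask, cw, 1.0))
        fW = np.where(amask, g, 0.0)
        fW /= fW.sum(1, keepdims=True)

        if not fix_mixing:
            counts = np.bincount(z, minlength=len(CLASSES))
            g = rng.gamma(0.5 + counts.astype(float))
            pi = g / g.sum()

        if sweep >= burnin:
            post_sum[np.arange(n), z] += 1.0
            kept += 1
    return post_sum / kept


def _sample_rows(logp: np.ndarray, rng) -> np.ndarray:
    m = logp.max(axis=1, keepdims=True)
    w = np.exp(logp - m)
    w /= w.sum(axis=1, keepdims=True)
    cdf = np.cumsum(w, axis=1)
    u = rng.random((logp.shape[0], 1))
    return np.minimum((u > cdf).sum(axis=1), logp.shape[1] - 1)


def majority_assignment(posterior) -> str:
    """Class attaining the highest posterior; exact ties are not broken.

    Accepts a mapping/Series over the six class names.  Returns the class
    name, or ``"undetermined"`` on an exact tie or all-NaN posterior.
    """
    vals = np.array([float(posterior[c]) for c in CLASSES])
    if np.all(np.isnan(vals)):
        return "undetermined"
    best = np.nanmax(vals)
    winners = [c for c, v in zip(CLASSES, vals) if v == best]
    if len(winners) != 1:
        return "undetermined"
    return winners[0]
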