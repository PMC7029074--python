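"""Bayesian admixture clustering of codominant genotypes.

A Gibbs sampler over the classic admixture model: each allele copy of
individual *i* has a latent cluster of origin Z, individual admixture
vectors q_i follow a symmetric Dirichlet(alpha) prior, and per-cluster
per-locus allele frequencies follow Dirichlet(lambda).  The sampler sweeps

    Z | q, P        (multinomial per allele copy)
    q | Z           (Dirichlet, alpha + origin counts)
    P | Z           (Dirichlet, lambda + allele counts)

optionally updating alpha by a Metropolis random walk (as the reference
implementations of this model do) and, in the correlated-frequencies mode,
per-cluster drift parameters F_k tying cluster frequencies to an ancestral
frequency vector.  Reported q is the posterior mean over post-burn-in
sweeps; the model evidence ln P(X|K) is estimated as mean(lnL) - var(lnL)/2.
Missing genotypes are skipped in every update.  Runs are bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix


@dataclass
class AdmixtureResult:
    q: pd.DataFrame                      # individuals x K, rows sum to 1
    cluster_freqs: list[pd.DataFrame]    # per locus: K x alleles posterior mean
    loglik_trace: np.ndarray
    ln_prob_data: float                  # mean(lnL) - var(lnL)/2, post-burnin
    K: int
    seed: int
    alpha_trace: np.ndarray | None = None


def fit_admixture(
    gm: GenotypeMatrix,
    K: int,
    burnin: int = 5_000,
    sweeps: int = 20_000,
    alpha: float = 1.0,
    lam: float = 1.0,
    seed: int = 0,
    infer_alpha: bool = False,
    model: str = "independent",
    thin: int = 1,
) -> AdmixtureResult:
    """Fit the admixture model with K clusters by Gibbs sampling.

    ``model`` is "independent" (Dirichlet(lambda) frequency prior, default)
    or "correlated" (F-model: cluster frequencies drift from a shared
    ancestral vector, drift F_k updated by Metropolis).  ``infer_alpha``
    switches on the Metropolis update of the admixture concentration;
    otherwise alpha stays fixed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    if model not in ("independent", "correlated"):
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)

    codes, allele_lists = gm.encode()
    keep = [l for l, al in enumerate(allele_lists) if len(al) > 0]
    if len(keep) < len(allele_lists):
        warnings.warn(
            f"dropping {len(allele_lists) - len(keep)} all-missing locus/loci",
            stacklevel=2,
        )
    codes = codes[:, keep, :]
    allele_lists = [allele_lists[l] for l in keep]
    loci = [gm.loci[l] for l in keep]

    n, L, _ = codes.shape
    J = np.array([len(a) for a in allele_lists])
    Jmax = int(J.max())
    valid = codes >= 0                                  # (n, L, 2)
    safe = np.where(valid, codes, 0)
    lgrid = np.broadcast_to(np.arange(L)[None, :, None], codes.shape)
    amask = np.arange(Jmax)[None, :] < J[:, None]       # (L, Jmax) legal alleles

    # ancestral frequencies for the correlated model: empirical + pseudocount
    anc = np.zeros((L, Jmax))
    np.add.at(anc, (lgrid[valid], safe[valid]), 1.0)
    anc = (anc + 0.5) * amask
    anc /= anc.sum(axis=1, keepdims=True)
    F = np.full(K, 0.1)

    q = rng.dirichlet(np.full(K, 1.0), size=n)
    P = np.where(amask[None], 1.0 / J[None, :, None], 0.0) * np.ones((K, L, 1))
    Z = rng.integers(0, K, size=codes.shape)

    total = burnin + sweeps
    ll_trace = np.empty(total)
    alpha_trace = np.empty(total) if infer_alpha else None
    q_sum = np.zeros((n, K))
    P_sum = np.zeros((K, L, Jmax))
    kept = 0

    for sweep in range(total):
        # Z | q, P
        lik = P[:, lgrid, safe]                          # (K, n, L, 2)
        probs = np.moveaxis(lik, 0, -1) * q[:, None, None, :]
        tot = probs.sum(axis=-1, keepdims=True)
        tot[tot == 0] = 1.0
        cdf = np.cumsum(probs / tot, axis=-1)
        u = rng.random(codes.shape)
        Z = (u[..., None] > cdf).sum(axis=-1)
        Z = np.minimum(Z, K - 1)

        # q | Z
        counts = np.zeros((n, K))
        for k in range(K):
            counts[:, k] = ((Z == k) & valid).sum(axis=(1, 2))
        g = rng.gamma(alpha + counts)
        q = g / g.sum(axis=1, keepdims=True)

        # P | Z
        acounts = np.zeros((K, L, Jmax))
        np.add.at(acounts, (Z[valid], lgrid[valid], safe[valid]), 1.0)
        if model == "independent":
            shape = lam + acounts
        else:
            shape = anc[None] * ((1.0 - F) / F)[:, None, None] + acounts
        g = rng.gamma(np.where(amask[None], shape, 1.0))
        g *= amask[None]
        P = g / g.sum(axis=2, keepdims=True)

        if model == "correlated":
            F = _update_drift(F, P, anc, amask, rng)
        if infer_alpha:
            alpha = _update_alpha(alpha, q, rng)
            alpha_trace[sweep] = alpha

        mix = (np.moveaxis(P[:, lgrid, safe], 0, -1) * q[:, None, None, :]).sum(-1)
        ll_trace[sweep] = np.log(mix[valid]).sum()

        if sweep >= burnin:
            q_sum += q
            P_sum += P
            kept += 1

    q_mean = q_sum / kept
    post = ll_trace[burnin:]
    ln_prob = float(post.mean() - post.var() / 2.0)
    q_df = pd.DataFrame(
        q_mean, index=gm.individual_ids, columns=[f"cluster{k}" for k in range(K)]
    )
    freqs = [
        pd.DataFrame(
            P_sum[:, l, : J[l]] / kept,
            index=[f"cluster{k}" for k in range(K)],
            columns=allele_lists[l],
        )
        for l in range(L)
    ]
    for f, locus in zip(freqs, loci):
        f.attrs["locus"] = locus
    return AdmixtureResult(
        q=q_df,
        cluster_freqs=freqs,
        loglik_trace=ll_trace,
        ln_prob_data=ln_prob,
        K=K,
        seed=seed,
        alpha_trace=alpha_trace,
    )


def _update_alpha(
    alpha: float,
    q: np.ndarray,
    rng: np.random.Generator,
    sd: float = 0.05,
    alpha_max: float = 10.0,
) -> float:
    """Metropolis step on the admixture concentration, uniform prior."""
    n, K = q.shape
    prop = alpha + rng.normal(0.0, sd)
    if prop <= 0 or prop > alpha_max:
        return alpha
    logq = np.log(q).sum()

    def logp(a: float) -> float:
        return n * (math.lgamma(K * a) - K * math.lgamma(a)) + (a - 1.0) * logq

    if math.log(rng.random()) < logp(prop) - logp(alpha):
        return prop
    return alpha


def _update_drift(F, P, anc, amask, rng, sd: float = 0.05):
    """Metropolis step on each cluster's drift parameter, uniform(0,1) prior."""
    K = F.shape[0]
    logP = np.where(amask[None] & (P > 0), np.log(np.where(P > 0, P, 1.0)), 0.0)
    for k in range(K):
        prop = F[k] + rng.normal(0.0, sd)
        if not 0.001 < prop < 0.999:
            continue

        def logdens(f: float) -> float:
            nu = anc * (1.0 - f) / f
            with np.errstate(invalid="ignore"):
                lg = math.lgamma
                out = 0.0
                for l in range(anc.shape[0]):
                    m = amask[l]
                    out += lg(nu[l, m].sum()) - sum(lg(v) for v in nu[l, m])
                    out += ((nu[l, m] - 1.0) * logP[k, l, m]).sum()
                return out

        if math.log(rng.random()) < logdens(prop) - logdens(F[k]):
            F[k] = prop
    return F


def align_runs(results: list[AdmixtureResult | pd.DataFrame]) -> pd.DataFrame:
    """Align cluster labels across replicate runs and average q.

    Label switching is resolved by permuting each run's columns to best
    match the first run (exhaustive over the K! permutations, K <= 6), then
    averaging element-wise — the greedy label-alignment strategy used to
    combine replicate clustering runs.
    """
    qs = [r.q if isinstance(r, AdmixtureResult) else r for r in results]
    if not qs:
        raise ValueError("no runs to align")
    ref = qs[0]
    K = ref.shape[1]
    if any(q.shape != ref.shape for q in qs):
        raise ValueError("runs have mismatched shapes")
    if any(list(q.index) != list(ref.index) for q in qs):
        raise ValueError("runs cover different individuals")
    if K > 6:
        raise ValueError("exhaustive alignment limited to K <= 6")
    acc = ref.to_numpy().copy()
    for q in qs[1:]:
        arr = q.to_numpy()
        best, best_err = None, np.inf
        for perm in itertools.permutations(range(K)):
            err = float(((arr[:, perm] - ref.to_numpy()) ** 2).sum())
            if err < best_err:
                best, best_err = perm, err
        acc += arr[:, best]
    out = acc / len(qs)
    return pd.DataFrame(out, index=ref.index, columns=ref.columns)


def evanno_delta_k(lnp_by_k: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno's second-order rate of change of ln P(X|K) across replicates.

    delta_K = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)); defined
    only for interior K of a contiguous K range and flagged NaN where the
    replicate spread is zero.
    """
    ks = sorted(lnp_by_k)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    means = {k: float(np.mean(lnp_by_k[k])) for k in ks}
    sds = {k: float(np.std(lnp_by_k[k], ddof=1)) for k in ks}
    if any(len(lnp_by_k[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicates per K")
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            dk = float("nan")
        elif sds[k] == 0:
            warnings.warn(f"sd=0 at K={k}: delta K undefined", stacklevel=2)
            dk = float("nan")
        else:
            dk = abs(means[k + 1] - 2.0 * means[k] + means[k - 1]) / sds[k]
        rows.append((k, means[k], sds[k], dk))
    return pd.DataFrame(rows, columns=["K", "mean_lnP", "sd_lnP", "delta_K"])


def orient_clusters(
    q: pd.DataFrame, p_ids: list[str], w_ids: list[str]
) -> pd.DataFrame:
    """Relabel a K=2 membership table so columns read (P, W).

    Cluster identity is arbitrary in any single run; known parental
    individuals anchor which cluster is the pityocampa one.  Returns a copy
    with columns ["P", "W"].  By reporting convention the single-number
    membership score is the W column (q for the wilkinsoni cluster).
    """
    if q.shape[1] != 2:
        raise ValueError("orientation requires K=2")
    c0, c1 = q.columns
    p_mean = q.loc[p_ids, c0].mean()
    w_mean = q.loc[w_ids, c0].mean()
    cols = [c0, c1] if p_mean >= w_mean else [c1, c0]
    out = q[cols].copy()
    out.columns = ["P", "W"]
    return out


def select_pure_reference(
    q: pd.DataFrame, threshold: float = 0.900
) -> dict[str, list[str]]:
    """Individuals whose maximum membership reaches the purity threshold.

    Returns, per cluster column, the ids assigned to that cluster's
    reference pool.  An empty pool for any cluster makes calibration
    impossible and raises.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    arr = q.to_numpy()
    best = arr.argmax(axis=1)
    pools: dict[str, list[str]] = {str(c): [] for c in q.columns}
    for i, iid in enumerate(q.index):
        if arr[i, best[i]] >= threshold:
            pools[str(q.columns[best[i]])].append(iid)
    empty = [c for c, ids in pools.items() if not ids]
    if empty:
        raise ValueError(f"no individuals reach q >= {threshold} for {empty}")
    return pools
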