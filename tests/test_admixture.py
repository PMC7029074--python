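import numpy as np
import pandas as pd
import pytest

from hybridzone.admixture import (
    align_runs,
    evanno_delta_k,
    fit_admixture,
    orient_clusters,
    select_pure_reference,
)
from hybridzone.simulate import simulate_hybrid_classes

FAST = dict(burnin=150, sweeps=400)


@pytest.fixture(scope="module")
def parents_and_f1(diagnostic_pops):
    pop_p, pop_w = diagnostic_pops
    return simulate_hybrid_classes(
        pop_p, pop_w, {"P_pit": 60, "P_wil": 60, "F1": 30}, seed=31
    )


class TestFit:
    def test_k1_membership_is_one(self, parents_and_f1):
        res = fit_admixture(parents_and_f1.genotypes, K=1, **FAST, seed=1)
        assert np.allclose(res.q.to_numpy(), 1.0)

    def test_q_rows_on_simplex(self, parents_and_f1):
        res = fit_admixture(parents_and_f1.genotypes, K=2, **FAST, seed=2)
        arr = res.q.to_numpy()
        assert np.all(arr >= 0) and np.all(arr <= 1)
        assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-9)

    def test_seeded_runs_bit_reproducible(self, parents_and_f1):
        a = fit_admixture(parents_and_f1.genotypes, K=2, **FAST, seed=3)
        b = fit_admixture(parents_and_f1.genotypes, K=2, **FAST, seed=3)
        assert np.array_equal(a.q.to_numpy(), b.q.to_numpy())
        assert np.array_equal(a.loglik_trace, b.loglik_trace)

    def test_cluster_freqs_sum_to_one(self, parents_and_f1):
        res = fit_admixture(parents_and_f1.genotypes, K=2, **FAST, seed=4)
        for f in res.cluster_freqs:
            assert np.allclose(f.to_numpy().sum(axis=1), 1.0, atol=1e-9)

    def test_all_missing_locus_dropped(self, parents_and_f1):
        gm = parents_and_f1.genotypes
        gm2 = gm.subset(gm.individual_ids[:20])
        gm2.calls[:, 0, :] = None
        with pytest.warns(UserWarning, match="all-missing"):
            res = fit_admixture(gm2, K=2, burnin=20, sweeps=40, seed=5)
        assert len(res.cluster_freqs) == gm.n_loci - 1

    def test_sweeps_validation(self, parents_and_f1):
        with pytest.raises(ValueError):
            fit_admixture(parents_and_f1.genotypes, K=2, sweeps=0)

    def test_correlated_model_runs_and_recovers(self, parents_and_f1):
        res = fit_admixture(
            parents_and_f1.genotypes, K=2, burnin=100, sweeps=250, seed=6,
            model="correlated", infer_alpha=True,
        )
        q = orient_clusters(
            res.q, parents_and_f1.ids_of("P_pit"), parents_and_f1.ids_of("P_wil")
        )
        assert q.loc[parents_and_f1.ids_of("P_pit"), "P"].min() > 0.9


class TestAlignment:
    def test_single_run_identity(self):
        q = pd.DataFrame([[0.7, 0.3], [0.2, 0.8]], index=["a", "b"])
        assert np.allclose(align_runs([q]).to_numpy(), q.to_numpy())

    def test_swapped_columns_realigned(self):
        q = pd.DataFrame([[0.7, 0.3], [0.2, 0.8]], index=["a", "b"])
        swapped = q.iloc[:, ::-1]
        swapped.columns = q.columns
        merged = align_runs([q, swapped])
        assert np.allclose(merged.to_numpy(), q.to_numpy())

    def test_k2_exhaustive_matches_two_permutation_oracle(self):
        rng = np.random.default_rng(9)
        ref = rng.dirichlet([1, 1], size=10)
        run = rng.dirichlet([1, 1], size=10)
        qs = [pd.DataFrame(ref), pd.DataFrame(run)]
        merged = align_runs(qs)
        errs = {
            perm: ((run[:, list(perm)] - ref) ** 2).sum() for perm in [(0, 1), (1, 0)]
        }
        best = min(errs, key=errs.get)
        expected = (ref + run[:, list(best)]) / 2
        assert np.allclose(merged.to_numpy(), expected)

    def test_mismatched_shapes_rejected(self):
        a = pd.DataFrame(np.ones((3, 2)) / 2)
        b = pd.DataFrame(np.ones((4, 2)) / 2)
        with pytest.raises(ValueError):
            align_runs([a, b])


class TestEvanno:
    def test_hand_computed_example(self):
        lnp = {1: [-200, -202], 2: [-120, -122], 3: [-118, -119]}
        table = evanno_delta_k(lnp).set_index("K")
        # |(-118.5) - 2(-121) + (-201)| / sd([-120,-122]) = 77.5 / 1.41421
        assert table.loc[2, "delta_K"] == pytest.approx(77.5 / np.sqrt(2), rel=1e-6)
        assert np.isnan(table.loc[1, "delta_K"])
        assert np.isnan(table.loc[3, "delta_K"])

    def test_flat_lnp_gives_zero(self):
        lnp = {1: [-10.0, -11.0], 2: [-10.0, -11.0], 3: [-10.0, -11.0]}
        table = evanno_delta_k(lnp).set_index("K")
        assert table.loc[2, "delta_K"] == 0.0

    def test_invariant_to_constant_shift(self):
        lnp = {1: [-200.0, -202.0], 2: [-120.0, -122.0], 3: [-118.0, -119.0]}
        shifted = {k: [v + 55.0 for v in vals] for k, vals in lnp.items()}
        a = evanno_delta_k(lnp)["delta_K"]
        b = evanno_delta_k(shifted)["delta_K"]
        assert np.allclose(a.dropna(), b.dropna())

    def test_zero_sd_flagged(self):
        lnp = {1: [-5.0, -5.0], 2: [-4.0, -4.0], 3: [-3.0, -3.0]}
        with pytest.warns(UserWarning, match="sd=0"):
            table = evanno_delta_k(lnp).set_index("K")
        assert np.isnan(table.loc[2, "delta_K"])

    def test_noncontiguous_k_rejected(self):
        with pytest.raises(ValueError):
            evanno_delta_k({1: [-1, -2], 3: [-1, -2]})


class TestReferenceSelection:
    def test_threshold_selects_two_of_three(self):
        q = pd.DataFrame(
            {"P": [0.95, 0.91, 0.85], "W": [0.05, 0.09, 0.15]},
            index=["a", "b", "c"],
        )
        # both clusters need a pool; add one W individual
        q.loc["d"] = [0.02, 0.98]
        pools = select_pure_reference(q, 0.900)
        assert pools["P"] == ["a", "b"]
        assert pools["W"] == ["d"]

    def test_threshold_one_keeps_exact_ones_only(self):
        q = pd.DataFrame({"P": [1.0, 0.999], "W": [0.0, 0.001]}, index=["a", "b"])
        q.loc["c"] = [0.0, 1.0]
        pools = select_pure_reference(q, 1.0)
        assert pools["P"] == ["a"] and pools["W"] == ["c"]

    def test_empty_pool_is_error(self):
        q = pd.DataFrame({"P": [0.6, 0.7], "W": [0.4, 0.3]}, index=["a", "b"])
        with pytest.raises(ValueError, match="no individuals"):
            select_pure_reference(q, 0.9)

    def test_invalid_threshold_rejected(self):
        q = pd.DataFrame({"P": [1.0], "W": [0.0]}, index=["a"])
        with pytest.raises(ValueError):
            select_pure_reference(q, 0.4)


def test_q_invariant_to_individual_order(parents_and_f1):
    gm = parents_and_f1.genotypes
    res = fit_admixture(gm, K=2, **FAST, seed=7, infer_alpha=True)
    perm = list(reversed(gm.individual_ids))
    res_p = fit_admixture(gm.subset(perm), K=2, **FAST, seed=7, infer_alpha=True)
    q1 = orient_clusters(res.q, parents_and_f1.ids_of("P_pit"), parents_and_f1.ids_of("P_wil"))
    q2 = orient_clusters(res_p.q, parents_and_f1.ids_of("P_pit"), parents_and_f1.ids_of("P_wil"))
    # same posterior up to MCMC noise, not bitwise (different sampling order)
    assert np.allclose(
        q1.loc[gm.individual_ids, "W"], q2.loc[gm.individual_ids, "W"], atol=0.05
    )
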