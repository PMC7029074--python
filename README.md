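# hybridzone

Detection and diagnosis of hybrids in a two-species contact zone from
multi-marker genetic data, built around the case of the two winter pine
processionary moths (*Thaumetopoea pityocampa* and *T. wilkinsoni*), which
meet and hybridize near the Turkish Straits.

Identifying hybrids between closely related taxa is unreliable with any
single method, so the pipeline combines three complementary ones, calibrated
against simulated genotypes of known ancestry:

* **Admixture clustering.** A Gibbs sampler over the admixture model: each
  allele copy has a latent cluster of origin *Z*, individual admixture
  vectors *q* ~ Dirichlet(α), cluster allele frequencies ~ Dirichlet(λ).
  The posterior-mean membership *q* of the *wilkinsoni* cluster is the first
  assignment score; the number of clusters is chosen from ln P(X|K) and the
  Evanno ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) across replicate runs.
* **Hybrid index.** The maximum-likelihood mixture weight
  h = argmax Σ log[(1−h)·f_P(a) + h·f_W(a)] over all allele copies,
  0 = pure *pityocampa*, 1 = pure *wilkinsoni*.
* **Six genotype-frequency classes.** Pure P, pure W, F1, F2 and the two
  backcrosses each fix the probabilities that a locus' two gametes are
  both-P, one-of-each, or both-W — (1,0,0), (0,0,1), (0,1,0), (¼,½,¼),
  (½,½,0), (0,½,½) — giving a per-class genotype likelihood and a Bayesian
  posterior q_NH; individuals take the majority (argmax) class.

Thresholds are never chosen by hand: simulated pure parents, F1, F2 and
backcross genotypes (gametes drawn from parental allele-frequency tables,
with F2/backcross gametes transmitted by explicitly simulated F1 parents)
define the parental [min, max] score ranges, and any field individual
scoring outside both ranges is non-parental, i.e. hybrid.  Per-class
assignment quality is measured as efficiency (true members correctly
assigned), accuracy (assignments that are correct) and overall performance
= efficiency × accuracy.

Independently of the microsatellite scores, sequence and RFLP markers
(mitochondrial COI, nuclear Pho, HgaI-digested ITS-1) are species-diagnosed
by nearest reference (p-distance) or band pattern, and an individual is
flagged hybrid when (a) a nuclear marker carries both species' alleles or
(b) two markers give opposite species verdicts (mito-nuclear or
nuclear-nuclear discordance).  The final call is the union over all
evidence.

## Worked example

```python
from hybridzone.simulate import generate_parental_populations, simulate_hybrid_classes
from hybridzone.admixture import fit_admixture, orient_clusters

pop_p, pop_w = generate_parental_populations(n_loci=12, divergence=1.0, seed=1)
ds = simulate_hybrid_classes(pop_p, pop_w, {"P_pit": 100, "P_wil": 100, "F1": 50}, seed=2)
res = fit_admixture(ds.genotypes, K=2, burnin=300, sweeps=900, seed=5, infer_alpha=True)
q = orient_clusters(res.q, ds.ids_of("P_pit"), ds.ids_of("P_wil"))
print(round(q.loc[ds.ids_of("P_pit"), "P"].min(), 3))   # 0.996
print(round(q.loc[ds.ids_of("F1"), "W"].mean(), 3))     # 0.501
```

Simulated pure parents recover membership ≥ 0.99 in their own cluster and
F1 hybrids sit at q ≈ 0.5, the behaviour the calibration relies on.

The numbered drivers under `analysis/` run the full study in order —
simulate the six classes, cluster and select K, compute h and the six-class
posteriors, calibrate thresholds and measure per-class performance, and
re-analyse the published 31-row field table:

```bash
python analysis/05_field_table_reanalysis.py
# hybrids by cluster-membership threshold (q): 11
# hybrids by hybrid-index threshold (h):       11
# hybrids by six-class majority assignment:    17
# dual-species Pho individuals (criterion a):  9
# dual-species ITS-1 individuals:              4
# hybrids under the union rule:                31
```

With the published parental ranges (q ≤ 0.207 / ≥ 0.809; h 0.000–0.183 /
0.838–1.000) the package's decision rules reproduce every printed tally and
per-locality hybrid frequency (e.g. Burhaniye f_H = 1.00, İzmir 0.56).

There is also a thin CLI (`hybridzone all|simulate|cluster`) over the same
library for running the synthetic-recipe pipeline from a shell.

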