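# Methods

## The problem

Two parapatric moth species meet in a narrow contact zone.  Most
individuals are clearly parental; the question is which of the remainder
are hybrids, of what kind (F1, F2, backcross), and in which direction
genes flow.  No single statistic answers this reliably, so the package
implements the combined strategy used in hybrid-zone surveys: three
microsatellite-based assignment methods calibrated on simulated genotypes
of known ancestry, plus species diagnosis of independent sequence/RFLP
markers and discordance rules, with a final union verdict.

## Admixture model

The clustering model is the standard admixture model for unlinked
codominant loci.  For individual *i*, allele copy *c* at locus *l*:

    Z_ilc | q_i            ~ Categorical(q_i)
    a_ilc | Z_ilc = k      ~ Categorical(p_kl)
    q_i                    ~ Dirichlet(alpha, ..., alpha)
    p_kl                   ~ Dirichlet(lambda, ..., lambda)

All three blocks have conjugate full conditionals and are updated by Gibbs
sampling; missing genotypes are skipped everywhere.  Reported q is the
posterior mean over post-burn-in sweeps, and the model evidence is the
standard harmonic approximation lnP(X|K) = mean(lnL) − var(lnL)/2.

Parameters and defaults:

* `lambda = 1.0` (flat frequency prior).  An optional correlated-frequency
  mode ties cluster frequencies to an empirical ancestral vector through
  per-cluster drift parameters F_k (Dirichlet(p_anc·(1−F)/F) prior, F_k
  updated by Metropolis).  The independent prior is the default because
  the package's validation is property-based parameter recovery, for which
  the simpler prior is sufficient and easier to reason about.
* `alpha = 1.0` fixed by default; `infer_alpha=True` adds the usual
  Metropolis random walk on a common alpha (uniform prior on (0, 10],
  normal proposal sd 0.05).  Alpha inference is used in the analysis
  drivers: on strongly differentiated data alpha equilibrates well below 1
  and pure parents then reach q ≥ 0.99, whereas a fixed alpha of 1
  shrinks a 24-copy parental posterior mean to ~25/26 ≈ 0.96.  This is the
  same reason reference implementations of the model infer alpha.
* MCMC lengths are configurable; the analysis drivers use 300 burn-in +
  900 kept sweeps, which on fully diagnostic 12-locus data gives Monte
  Carlo error well under the 0.05 tolerance the recovery checks use.
  (Production presets of 100k + 100k remain a config choice.)
* Label switching across replicate runs is resolved by exhaustive
  permutation alignment against the first run (K ≤ 6, so at most 720
  permutations), then element-wise averaging.  A K = 2 result is oriented
  into (P, W) columns using known parental individuals; single-number
  reports are the W-cluster membership.

Evanno's ΔK uses the population sd (ddof = 1) of lnP over replicates and
is undefined at the K-range ends and when sd = 0 (flagged NaN, never
silently patched).

## Hybrid index

h maximises the per-allele-copy mixture likelihood
Σ log[(1−h)·f_P(a) + h·f_W(a)].  The log-likelihood is concave in h, so a
golden-section search on [0, 1] (tolerance 1e-6) finds the optimum; the
endpoints are evaluated explicitly so pure ancestries return exactly 0 or
1.  Parental frequency tables use add-half (Jeffreys) smoothing over the
union allele set, so an allele absent from one reference pool has a small
positive frequency instead of zeroing the likelihood.  h is reported to 3
decimals.  With no informative locus (all f_P = f_W) the index is
undefined and flagged NaN.

## Six genotype classes

Class z fixes theta_z, the probability that a locus' gamete pair is
(both-P, one-each, both-W): pures (1,0,0)/(0,0,1), F1 (0,1,0), F2
(¼,½,¼), backcrosses (½,½,0)/(0,½,½).  Per locus,

    P(g | z) = sum_o theta_z(o) · P(g | o, f_P, f_W)

with Hardy–Weinberg terms per origin; the one-each origin counts both
orderings for heterozygotes (f_P(a1)f_W(a2) + f_P(a2)f_W(a1)), and the
homozygote one-each term is f_P(a)f_W(a).  Loci multiply; the posterior is
prior × likelihood, uniform prior by default.  Sanity anchor: an
individual heterozygous at two fully diagnostic loci has posterior
P(F1) = 1/(1+3·¼) = 4/7.

`plugin` mode fixes (f_P, f_W) at their smoothed estimates.  `mcmc` mode
Gibbs-samples class, per-locus gamete origins, allele-to-species
assignments and the frequencies themselves under Dirichlet(½)
(Jeffreys-like) priors, with reference-pool alleles contributing
fixed-origin counts; mixing proportions are either resampled
(Dirichlet(½)) or held uniform.  With reference pools of several hundred
individuals the two modes agree to within 0.05 posterior mass, which is
why the fast plugin mode is the pipeline default.  Majority assignment is
a strict argmax; exact ties return `undetermined` rather than a silent
tie-break.  The model cannot represent ancestry older than two
generations — a later-generation backcross will fold into the nearest
representable class.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* Two parental populations over 12 microsatellite loci, 4 alleles per
  locus by default.  `divergence` sets the fraction of loci with disjoint
  allele sets (⌈divergence·n_loci⌉ diagnostic loci); non-diagnostic loci
  share a Dirichlet(5) frequency base perturbed symmetrically
  (log-normal factor, sd 0.3).  Allele labels mimic fragment sizes.
* A maternally inherited haplotype pool per species (star-like: a
  reference plus satellites 1–2 substitutions away; species references
  ~10% divergent, the scale of the mitochondrial split between the two
  moths), a biparental nuclear sequence locus (~5% divergent), and the two
  species' published ITS-1 band patterns.
* Hybrid classes are pedigree-correct: F1 = one gamete from each parental
  frequency table; F2 = offspring of two independently simulated F1
  parents, each transmitting one of its two alleles per locus with
  probability ½; backcross = F1 × parental gamete.  Mendelian expectations
  therefore hold exactly (F2 segregates ¼:½:¼ at a diagnostic locus; a
  backcross to P is never homozygous for W alleles).
* The cross direction (and with it every hybrid's mitochondrial
  haplotype) is an explicit parameter, default P-mother — in the field
  data every discordant hybrid carried a *pityocampa* haplotype — because
  gamete-frequency simulation itself carries no information about
  uniparental markers.
* No linkage, no mutation, no selection, no null alleles; missing data
  only by an optional uniform per-call rate (default 0).  Passing tests on
  these data show the methods recover known ancestry under the model's own
  assumptions; they do not probe genotyping error, allele-size
  homoplasy, linked loci or deeper-generation ancestry in real data.

Problem sizes: the class simulator defaults to 1,000 individuals per class
(the calibration size of the original study design); the analysis drivers
and the test suite run 40–150 per class with 300 + 900 MCMC sweeps, sizes
chosen so the whole analysis re-runs in about a minute while keeping every
recovery margin far from its tolerance.

## Sequence markers and digest prediction

p-distance and Kimura-2-parameter distances use pairwise deletion of
gaps/Ns; K2P is −½·ln((1−2P−Q)·√(1−2Q)) and is flagged NaN on saturation.
Group mean distances are unweighted means over haplotype pairs (groups are
assigned to haplotypes, not individuals; `weight_by_count` would be the
alternative reading and the unweighted choice is surfaced deliberately).
The haplotype network is a minimum spanning network (all edges that occur
in some MST, so tied mutational paths stay as parallel edges) with a plain
integer connection limit standing in for the statistical-parsimony
connection criterion; the network is descriptive and nothing downstream
depends on it.

HgaI (GACGC(5/10)) digestion is predicted on both strands: a top-strand
site at *i* cuts the top strand at i+10 (0-based, half-open); a
bottom-strand site (GCGTC at *j* on the top strand) cuts 10 nt upstream of
*j*.  Complete digestion is assumed, out-of-range cuts are dropped with a
warning, and fragments always sum to the amplicon length.  The packaged
band patterns (152/131/97/70/33/17 and 232/153/66/33/17 bp) are matched
with ±2 bp tolerance; a pattern containing both species' non-shared
diagnostic bands is called dual-species (PW).  `make_rflp_reference`
builds synthetic amplicons with engineered site layouts reproducing those
band multisets; they are stand-ins for the deposited reference amplicons
and are labelled synthetic wherever used.

Species diagnosis of a sequence allele is by nearest reference under
p-distance; equidistant alleles are reported ambiguous, never guessed.

## Thresholds, union rule and degenerate inputs

Parental ranges are the inclusive [min, max] of the calibrated score over
simulated parents; hybrids are strictly outside both ranges.  This
convention is what makes a field score of 0.209 hybrid against a parental
maximum of 0.207 while 0.207 itself stays parental.  Overlapping parental
ranges are an error (no hybrid would be detectable), as is an empty
reference pool at the purity threshold (default q ≥ 0.900).  Efficiency ×
accuracy is the overall performance measure; undetermined assignments are
excluded from the accuracy denominator and reported separately.  The final
hybrid call is the union of criterion (a), criterion (b) and the three
score-based methods, with the triggering evidence recorded per individual.

Degenerate inputs throughout are flagged, not patched: zero comparable
sites, saturated distances, singleton groups, all-missing loci, impossible
genotypes and exact posterior ties each produce a NaN/undetermined result
plus a warning.

## Known limitations

* The six-class model and the simulator stop at second-generation
  ancestry; recurrent backcrossing is not representable.
* The admixture sampler uses a single common alpha and no location priors
  or linkage model.
* RFLP pattern matching treats band intensity as invisible (a shared band
  appears once in a composite pattern) and assumes complete digestion.
* The re-analysis of the published field table takes the printed scores as
  given; the underlying microsatellite genotypes are an external dataset,
  so the printed calibration ranges are inputs there, not recomputed.
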