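"""Known-ancestry synthetic data for calibrating hybrid detection.

Emulates the structure of the field data: two parental moth populations with
strongly differentiated multi-allelic microsatellite loci, a maternally
inherited mitochondrial haplotype pool, biparental nuclear sequence alleles,
and a species-specific restriction pattern.  Hybrid classes are built the
way simulation calibration tools build them — F1 gametes drawn from the
parental allele-frequency tables, F2 and backcross gametes transmitted by
explicitly simulated F1 parents — so Mendelian expectations (1/4 : 1/2 : 1/4
F2 segregation at a diagnostic locus, no W-homozygotes in a backcross to P)
hold exactly.  No linkage, no mutation, no selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .markers import HGAI, RestrictionEnzyme, predict_rflp
from .tables import PUBLISHED_RFLP

#: the six genotype classes
CLASSES = ("P_pit", "P_wil", "F1", "F2", "Bkc_Pit", "Bkc_Wil")

_NT = np.array(list("ACGT"))


@dataclass
class HaplotypePool:
    """Named sequence variants with sampling frequencies."""

    names: list[str]
    seqs: list[str]
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not np.isclose(self.freqs.sum(), 1.0, atol=1e-9):
            raise ValueError("haplotype frequencies must sum to 1")

    def draw(self, n: int, rng: np.random.Generator) -> list[int]:
        return list(rng.choice(len(self.names), size=n, p=self.freqs))


@dataclass
class ParentalPopulation:
    """One species' allele pools: microsatellites, mtDNA, nuclear sequence."""

    species_tag: str                          # "P" or "W"
    loci: list[str]
    allele_freqs: list[dict[str, float]]      # per locus: allele label -> freq
    mt_haplotypes: HaplotypePool
    nuclear_seq_alleles: HaplotypePool
    rflp_pattern: tuple[int, ...]

    def __post_init__(self) -> None:
        for l, freqs in enumerate(self.allele_freqs):
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"locus {self.loci[l]}: frequencies must sum to 1")

    def gamete(self, rng: np.random.Generator) -> list[str]:
        """One allele per locus, drawn from the population frequencies."""
        out = []
        for freqs in self.allele_freqs:
            alleles = list(freqs)
            out.append(alleles[_choice(rng, [freqs[a] for a in alleles])])
        return out


def _choice(rng: np.random.Generator, probs) -> int:
    return int(rng.choice(len(probs), p=np.asarray(probs) / np.sum(probs)))


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_NT, size=length))


def _mutate(seq: str, n_sites: int, rng: np.random.Generator) -> str:
    """Substitute exactly n_sites randomly chosen positions."""
    s = list(seq)
    for pos in rng.choice(len(s), size=n_sites, replace=False):
        s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
    return "".join(s)


def _haplotype_pool(
    ref: str, prefix: str, n_haps: int, rng: np.random.Generator
) -> HaplotypePool:
    """A star-like pool: the reference plus satellites 1-2 steps away."""
    seqs = [ref] + [
        _mutate(ref, int(rng.integers(1, 3)), rng) for _ in range(n_haps - 1)
    ]
    raw = rng.dirichlet(np.full(n_haps, 5.0))
    order = np.argsort(raw)[::-1]                   # commonest first
    return HaplotypePool(
        names=[f"{prefix}{i + 1}" for i in range(n_haps)],
        seqs=[seqs[i] for i in order],
        freqs=raw[order] / raw.sum(),
    )


def generate_parental_populations(
    n_loci: int = 12,
    alleles_per_locus: int = 4,
    divergence: float = 1.0,
    seed: int = 0,
    mt_length: int = 810,
    nuc_length: int = 660,
    species_seq_divergence: float = 0.10,
    n_haplotypes: int = 3,
) -> tuple[ParentalPopulation, ParentalPopulation]:
    """Two parental populations with a controlled fraction of diagnostic loci.

    ``divergence`` is the fraction of microsatellite loci whose allele sets
    are fully disjoint between the species (diagnostic loci); the remaining
    loci share one allele set with symmetrically perturbed frequencies.
    Allele labels mimic fragment sizes.  Deterministic under ``seed``.
    """
    if alleles_per_locus < 2:
        raise ValueError("alleles_per_locus must be >= 2")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_diag = int(np.ceil(divergence * n_loci))
    loci = [f"MS{l + 1:02d}" for l in range(n_loci)]

    freqs_p: list[dict[str, float]] = []
    freqs_w: list[dict[str, float]] = []
    for l in range(n_loci):
        base = 100 + 20 * l
        if l < n_diag:
            p_alleles = [str(base + 2 * a) for a in range(alleles_per_locus)]
            w_alleles = [
                str(base + 2 * alleles_per_locus + 2 * a)
                for a in range(alleles_per_locus)
            ]
            fp = rng.dirichlet(np.full(alleles_per_locus, 2.0))
            fw = rng.dirichlet(np.full(alleles_per_locus, 2.0))
            freqs_p.append(dict(zip(p_alleles, fp)))
            freqs_w.append(dict(zip(w_alleles, fw)))
        else:
            alleles = [str(base + 2 * a) for a in range(alleles_per_locus)]
            shared = rng.dirichlet(np.full(alleles_per_locus, 5.0))
            eps = rng.normal(0.0, 0.3, size=alleles_per_locus)
            fp = shared * np.exp(eps)
            fw = shared * np.exp(-eps)
            freqs_p.append(dict(zip(alleles, fp / fp.sum())))
            freqs_w.append(dict(zip(alleles, fw / fw.sum())))

    mt_anc = _random_seq(mt_length, rng)
    mt_w_ref = _mutate(mt_anc, max(1, int(species_seq_divergence * mt_length)), rng)
    nuc_anc = _random_seq(nuc_length, rng)
    nuc_w_ref = _mutate(
        nuc_anc, max(1, int(0.5 * species_seq_divergence * nuc_length)), rng
    )

    pop_p = ParentalPopulation(
        species_tag="P",
        loci=loci,
        allele_freqs=freqs_p,
        mt_haplotypes=_haplotype_pool(mt_anc, "mtP", n_haplotypes, rng),
        nuclear_seq_alleles=_haplotype_pool(nuc_anc, "nucP", n_haplotypes, rng),
        rflp_pattern=PUBLISHED_RFLP["P"],
    )
    pop_w = ParentalPopulation(
        species_tag="W",
        loci=loci,
        allele_freqs=freqs_w,
        mt_haplotypes=_haplotype_pool(mt_w_ref, "mtW", n_haplotypes, rng),
        nuclear_seq_alleles=_haplotype_pool(nuc_w_ref, "nucW", n_haplotypes, rng),
        rflp_pattern=PUBLISHED_RFLP["W"],
    )
    return pop_p, pop_w


@dataclass
class SimulatedDataset:
    """Genotypes plus sidecar tables for a batch of simulated individuals."""

    genotypes: GenotypeMatrix
    labels: pd.DataFrame          # id, class, maternal_species, seed
    mt: pd.DataFrame              # id, haplotype, species, sequence
    nuclear: pd.DataFrame         # id, allele1, allele2, seq1, seq2

    def ids_of(self, cls: str) -> list[str]:
        return list(self.labels.loc[self.labels["class"] == cls, "id"])


def sample_individuals(
    pop: ParentalPopulation, n: int, seed: int = 0, id_prefix: str | None = None
) -> SimulatedDataset:
    """Draw ``n`` Hardy-Weinberg individuals from one parental population."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    prefix = id_prefix or f"sim{pop.species_tag}"
    cls = "P_pit" if pop.species_tag == "P" else "P_wil"
    rows = []
    for _ in range(n):
        rows.append([pop.gamete(rng), pop.gamete(rng)])
    return _package(
        rows,
        classes=[cls] * n,
        mothers=[pop.species_tag] * n,
        mt_pools={pop.species_tag: pop.mt_haplotypes},
        nuc_draws=[(pop.nuclear_seq_alleles, pop.nuclear_seq_alleles)] * n,
        loci=pop.loci,
        prefix=prefix,
        rng=rng,
        seed=seed,
    )


def _transmit(genotype: list[list[str]], rng: np.random.Generator) -> list[str]:
    """One gamete from a diploid parent: per locus, either allele w.p. 1/2."""
    return [pair[int(rng.integers(2))] for pair in zip(*genotype)]


def simulate_hybrid_classes(
    pop_p: ParentalPopulation,
    pop_w: ParentalPopulation,
    n_per_class: int | dict[str, int] = 1000,
    direction: str = "P-mother",
    seed: int = 0,
    missing_rate: float = 0.0,
    id_prefix: str = "sim",
) -> SimulatedDataset:
    """Simulate the six genotype classes with pedigree-correct segregation.

    ``n_per_class`` may be one integer for all classes or a per-class dict.
    ``direction`` fixes the maternal species of interspecific crosses
    ("P-mother", "W-mother", or "random"), and with it the mitochondrial
    haplotype every hybrid carries.  F2 individuals are offspring of two
    independently simulated F1 parents; backcrosses cross an F1 with a
    parental-population gamete.
    """
    if direction not in ("P-mother", "W-mother", "random"):
        raise ValueError(f"unknown direction {direction!r}")
    if pop_p.loci != pop_w.loci:
        raise ValueError("parental populations must share the locus panel")
    counts = (
        {c: int(n_per_class) for c in CLASSES}
        if isinstance(n_per_class, int)
        else {c: int(n_per_class.get(c, 0)) for c in CLASSES}
    )
    rng = np.random.default_rng(seed)
    pops = {"P": pop_p, "W": pop_w}

    def hybrid_mother() -> str:
        if direction == "random":
            return "PW"[int(rng.integers(2))]
        return "P" if direction == "P-mother" else "W"

    rows, classes, mothers, nuc_draws = [], [], [], []
    for cls in CLASSES:
        for _ in range(counts[cls]):
            if cls == "P_pit":
                geno = [pop_p.gamete(rng), pop_p.gamete(rng)]
                mom = "P"
                nuc = (pop_p.nuclear_seq_alleles, pop_p.nuclear_seq_alleles)
            elif cls == "P_wil":
                geno = [pop_w.gamete(rng), pop_w.gamete(rng)]
                mom = "W"
                nuc = (pop_w.nuclear_seq_alleles, pop_w.nuclear_seq_alleles)
            elif cls == "F1":
                geno = [pop_p.gamete(rng), pop_w.gamete(rng)]
                mom = hybrid_mother()
                nuc = (pop_p.nuclear_seq_alleles, pop_w.nuclear_seq_alleles)
            elif cls == "F2":
                f1a = [pop_p.gamete(rng), pop_w.gamete(rng)]
                f1b = [pop_p.gamete(rng), pop_w.gamete(rng)]
                geno = [_transmit(f1a, rng), _transmit(f1b, rng)]
                mom = hybrid_mother()
                pools = (pop_p.nuclear_seq_alleles, pop_w.nuclear_seq_alleles)
                nuc = (pools[int(rng.integers(2))], pools[int(rng.integers(2))])
            else:  # backcrosses
                back = pop_p if cls == "Bkc_Pit" else pop_w
                f1 = [pop_p.gamete(rng), pop_w.gamete(rng)]
                geno = [_transmit(f1, rng), back.gamete(rng)]
                mom = hybrid_mother()
                pools = (pop_p.nuclear_seq_alleles, pop_w.nuclear_seq_alleles)
                nuc = (pools[int(rng.integers(2))], back.nuclear_seq_alleles)
            rows.append(geno)
            classes.append(cls)
            mothers.append(mom)
            nuc_draws.append(nuc)

    ds = _package(
        rows,
        classes=classes,
        mothers=mothers,
        mt_pools={"P": pop_p.mt_haplotypes, "W": pop_w.mt_haplotypes},
        nuc_draws=nuc_draws,
        loci=pop_p.loci,
        prefix=id_prefix,
        rng=rng,
        seed=seed,
    )
    if missing_rate > 0:
        mask = rng.random(ds.genotypes.calls.shape[:2]) < missing_rate
        ds.genotypes.calls[mask] = None
    return ds


def _package(rows, classes, mothers, mt_pools, nuc_draws, loci, prefix, rng, seed):
    n = len(rows)
    ids = [f"{prefix}_{classes[i]}_{i:05d}" for i in range(n)]
    calls = np.empty((n, len(loci), 2), dtype=object)
    for i, (g1, g2) in enumerate(rows):
        for l in range(len(loci)):
            calls[i, l, 0] = g1[l]
            calls[i, l, 1] = g2[l]
    gm = GenotypeMatrix(ids, list(classes), list(loci), calls)
    mt_rows = []
    for i, mom in enumerate(mothers):
        pool = mt_pools[mom]
        h = pool.draw(1, rng)[0]
        mt_rows.append((ids[i], pool.names[h], mom, pool.seqs[h]))
    nuc_rows = []
    for i, (pool1, pool2) in enumerate(nuc_draws):
        a1 = pool1.draw(1, rng)[0]
        a2 = pool2.draw(1, rng)[0]
        nuc_rows.append(
            (ids[i], pool1.names[a1], pool2.names[a2], pool1.seqs[a1], pool2.seqs[a2])
        )
    labels = pd.DataFrame(
        {"id": ids, "class": classes, "maternal_species": mothers, "seed": seed}
    )
    mt = pd.DataFrame(mt_rows, columns=["id", "haplotype", "species", "sequence"])
    nuclear = pd.DataFrame(
        nuc_rows, columns=["id", "allele1", "allele2", "seq1", "seq2"]
    )
    return SimulatedDataset(gm, labels, mt, nuclear)


def make_rflp_reference(
    fragments: tuple[int, ...],
    enzyme: RestrictionEnzyme = HGAI,
    seed: int = 0,
) -> str:
    """Synthetic amplicon whose complete digest yields the given fragments.

    Builds a random background free of recognition sites, then plants one
    top-strand site upstream of each internal cut so the digest produces
    exactly the requested fragment sizes, in the given order along the
    sequence.  Used as a stand-in reference when the deposited amplicon
    sequences are not at hand; the band multiset — the diagnostic datum —
    is reproduced exactly.  Every fragment must be > ``cut_top`` +
    site length so the planted site fits inside the preceding fragment.
    """
    rec = enzyme.recognition.upper()
    site_span = len(rec) + enzyme.cut_top
    if any(f <= site_span for f in fragments):
        raise ValueError(f"all fragments must exceed {site_span} bp")
    total = sum(fragments)
    cuts = np.cumsum(fragments)[:-1]
    from .markers import revcomp

    bad = (rec, revcomp(rec))
    for attempt in range(100):
        rng = np.random.default_rng((seed + attempt * 7919) % 2**31)
        seq = list(_random_seq(total, rng))
        for c in cuts:
            seq[c - site_span : c - enzyme.cut_top] = list(rec)
        s = _scrub(seq, cuts, enzyme, rng)
        if s is not None and tuple(sorted(predict_rflp(s, enzyme), reverse=True)) == tuple(
            sorted(fragments, reverse=True)
        ):
            return s
    raise RuntimeError("could not build a clean amplicon; try another seed")


def _scrub(seq: list[str], cuts, enzyme: RestrictionEnzyme, rng) -> str | None:
    """Remove accidental recognition sites without touching the planted ones."""
    from .markers import revcomp

    rec = enzyme.recognition.upper()
    site_span = len(rec) + enzyme.cut_top
    planted = set()
    for c in cuts:
        planted.update(range(c - site_span, c - enzyme.cut_top))
    for _ in range(200):
        s = "".join(seq)
        hits = []
        for motif in (rec, revcomp(rec)):
            start = 0
            while True:
                i = s.find(motif, start)
                if i < 0:
                    break
                if not set(range(i, i + len(motif))) <= planted:
                    hits.append((i, len(motif)))
                start = i + 1
        if not hits:
            return s
        for i, m in hits:
            free = [p for p in range(i, i + m) if p not in planted]
            if not free:
                return None
            p = free[int(rng.integers(len(free)))]
            seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
    return None
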