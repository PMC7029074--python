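#!/usr/bin/env python
"""Per-individual hybrid index and six-class posteriors on the simulated set.

Builds smoothed parental allele-frequency tables from the simulated pure
parents, estimates the maximum-likelihood hybrid index h for every
individual and the posterior over the six genotype classes (plug-in mode),
and writes both tables.
"""

import argparse
from pathlib import Path

import pandas as pd

from hybridzone.assignment import allele_frequencies, classify_six, estimate_h
from hybridzone.simulate import generate_parental_populations, simulate_hybrid_classes


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-per-class", type=int, default=150)
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    pop_p, pop_w = generate_parental_populations(divergence=1.0, seed=args.seed)
    ds = simulate_hybrid_classes(
        pop_p, pop_w, args.n_per_class, direction="P-mother", seed=args.seed + 1
    )
    gm = ds.genotypes
    freq_p = allele_frequencies(gm, ds.ids_of("P_pit"))
    freq_w = allele_frequencies(gm, ds.ids_of("P_wil"))

    h = pd.Series(
        {iid: estimate_h(gm.calls[i], freq_p, freq_w).h
         for i, iid in enumerate(gm.individual_ids)},
        name="h",
    )
    h.rename_axis("id").to_frame().to_csv(
        args.out_dir / "h_index.tsv", sep="\t", float_format="%.3f"
    )
    nh = classify_six(gm, freq_p, freq_w, mode="plugin")
    nh.rename_axis("id").to_csv(
        args.out_dir / "six_class_posteriors.tsv", sep="\t", float_format="%.4f"
    )

    truth = ds.labels.set_index("id")["class"]
    print("mean h by true class:")
    print(h.groupby(truth).mean().round(3).to_string())
    agree = (nh["majority"] == truth.loc[nh.index]).mean()
    print(f"six-class majority assignment matches truth for {agree:.1%} "
          "of simulated individuals")
    print(f"outputs in {args.out_dir}")


if __name__ == "__main__":
    main()
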