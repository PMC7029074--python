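"""End-to-end orchestration: simulate, diagnose, cluster, calibrate, combine.

The full analysis mirrors the field workflow: admixture clustering first
delimits the two parental clusters; simulated known-ancestry genotypes
calibrate the parental score ranges for the cluster membership q and the
hybrid index h; a six-class genotype-frequency model assigns each
individual to pure / F1 / F2 / backcross; and sequence-marker discordance
(mito-nuclear or nuclear-nuclear) contributes the marker criteria.  The
final per-individual verdict is the union over all evidence sources.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import fit_admixture, orient_clusters
from .assignment import allele_frequencies, classify_six, estimate_h
from .calibration import (
    CalibrationRanges,
    calibrate_parental_ranges,
    classify_by_threshold,
    performance_metrics,
    summarize_localities,
)
from .io import GenotypeMatrix, write_genotypes, write_report
from .markers import ReferencePanel, detect_discordance, diagnose_marker, predict_rflp
from .simulate import (
    CLASSES,
    generate_parental_populations,
    make_rflp_reference,
    simulate_hybrid_classes,
)

HYBRID_CLASSES = ("F1", "F2", "Bkc_Pit", "Bkc_Wil")


@dataclass
class HybridCall:
    """Combined per-individual verdict with the evidence that triggered it."""

    individual_id: str
    locality: str
    markers: dict[str, str] = dc_field(default_factory=dict)
    q_str: float | None = None
    h: float | None = None
    nh_class: str | None = None
    verdicts: dict[str, str] = dc_field(default_factory=dict)
    hybrid: bool = False
    evidence: list[str] = dc_field(default_factory=list)
    f_h: float | None = None


def combine_evidence(
    discordance,
    str_verdict: str | None,
    int_verdict: str | None,
    nh_class: str | None,
) -> tuple[bool, list[str]]:
    """Union rule over all evidence sources.

    An individual is hybrid if marker criterion (a) or (b) fired, or any of
    the three microsatellite methods calls it non-parental.
    """
    evidence: list[str] = []
    if discordance is not None and discordance.hybrid:
        for crit, detail in discordance.criteria:
            evidence.append(f"criterion_{crit}:{','.join(map(str, detail))}")
    if str_verdict == "hybrid":
        evidence.append("STR:outside_parental_ranges")
    if int_verdict == "hybrid":
        evidence.append("INT:outside_parental_ranges")
    if nh_class in HYBRID_CLASSES:
        evidence.append(f"NH:{nh_class}")
    return bool(evidence), evidence


DEFAULT_CONFIG = {
    "seed": 0,
    "n_loci": 12,
    "alleles_per_locus": 4,
    "divergence": 1.0,
    "direction": "P-mother",
    "n_sim_per_class": 150,        # calibration set, per class
    "n_field_per_class": {         # synthetic field sample, per class
        "P_pit": 30, "P_wil": 30, "F1": 5, "F2": 5, "Bkc_Pit": 5, "Bkc_Wil": 5,
    },
    "missing_rate": 0.0,
    "K": 2,
    "burnin": 300,
    "sweeps": 900,
    "infer_alpha": True,
    "threshold": 0.900,
    "nh_mode": "plugin",
    "include_sim_in_nh": True,
    "out_dir": "results/pipeline",
}


def run_pipeline(config: dict | None = None) -> dict:
    """Run every stage on a synthetic recipe and write the report bundle.

    Returns a dict with the in-memory artefacts (calls, ranges, performance
    table, locality summary, manifest).  Outputs under ``out_dir``:
    ``report.tsv`` (per-individual), ``performance.tsv`` (six-class quality
    on the calibration set), ``ranges.tsv``, ``localities.tsv``,
    ``genotypes_field.tsv`` and ``manifest.json``.  Bit-reproducible for a
    fixed config.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # --- stage 1: synthetic populations and datasets -----------------------
    pop_p, pop_w = generate_parental_populations(
        n_loci=cfg["n_loci"],
        alleles_per_locus=cfg["alleles_per_locus"],
        divergence=cfg["divergence"],
        seed=seed,
    )
    sim = simulate_hybrid_classes(
        pop_p, pop_w, cfg["n_sim_per_class"], cfg["direction"], seed=seed + 1,
        id_prefix="sim",
    )
    fld = simulate_hybrid_classes(
        pop_p,
        pop_w,
        dict(cfg["n_field_per_class"]),
        cfg["direction"],
        seed=seed + 2,
        missing_rate=cfg["missing_rate"],
        id_prefix="field",
    )
    field_ids = list(fld.genotypes.individual_ids)
    write_genotypes(fld.genotypes, out_dir / "genotypes_field.tsv")

    # --- stage 2: sequence / RFLP marker diagnosis -------------------------
    panel = ReferencePanel(
        sequences={
            "COI": {"P": pop_p.mt_haplotypes.seqs[0], "W": pop_w.mt_haplotypes.seqs[0]},
            "Pho": {
                "P": pop_p.nuclear_seq_alleles.seqs[0],
                "W": pop_w.nuclear_seq_alleles.seqs[0],
            },
        },
        rflp_patterns={"P": pop_p.rflp_pattern, "W": pop_w.rflp_pattern},
    )
    mt_seq = dict(zip(fld.mt["id"], fld.mt["sequence"]))
    nuc_seqs = {
        r["id"]: (r["seq1"], r["seq2"]) for _, r in fld.nuclear.iterrows()
    }
    its_pattern = _simulate_its_patterns(fld.labels, panel, rng)
    marker_rows = {}
    for iid in field_ids:
        coi = diagnose_marker([mt_seq[iid]], "COI", panel)
        pho = diagnose_marker(list(nuc_seqs[iid]), "Pho", panel)
        its = diagnose_marker(its_pattern[iid], "ITS1", panel)
        marker_rows[iid] = {"COI": coi.verdict, "Pho": pho.verdict, "ITS1": its.verdict}

    # --- stage 3: admixture clustering on field + simulated ----------------
    joint = fld.genotypes.concat(sim.genotypes)
    adm = fit_admixture(
        joint,
        K=cfg["K"],
        burnin=cfg["burnin"],
        sweeps=cfg["sweeps"],
        seed=seed + 3,
        infer_alpha=cfg["infer_alpha"],
    )
    q = orient_clusters(adm.q, sim.ids_of("P_pit"), sim.ids_of("P_wil"))
    q_w = q["W"]

    # --- stage 4: calibration from the simulated classes -------------------
    str_ranges = calibrate_parental_ranges(
        q_w.loc[sim.ids_of("P_pit")], q_w.loc[sim.ids_of("P_wil")]
    )
    freq_p = allele_frequencies(joint, sim.ids_of("P_pit"))
    freq_w = allele_frequencies(joint, sim.ids_of("P_wil"))
    h_all = {
        iid: estimate_h(joint.calls[i], freq_p, freq_w).h
        for i, iid in enumerate(joint.individual_ids)
    }
    h_ser = pd.Series(h_all)
    int_ranges = calibrate_parental_ranges(
        h_ser.loc[sim.ids_of("P_pit")], h_ser.loc[sim.ids_of("P_wil")]
    )

    # --- stage 5: six-class assignment -------------------------------------
    nh_input = joint if cfg["include_sim_in_nh"] else fld.genotypes
    nh = classify_six(
        nh_input,
        freq_p,
        freq_w,
        mode=cfg["nh_mode"],
        ref_p=sim.genotypes.subset(sim.ids_of("P_pit")),
        ref_w=sim.genotypes.subset(sim.ids_of("P_wil")),
        seed=seed + 4,
    )

    # --- stage 6: per-individual verdicts and union rule --------------------
    calls = []
    for iid in field_ids:
        disc = detect_discordance(marker_rows[iid])
        sv = classify_by_threshold(float(q_w[iid]), str_ranges)
        hv = h_all[iid]
        iv = classify_by_threshold(float(hv), int_ranges) if np.isfinite(hv) else None
        nh_cls = nh.loc[iid, "majority"]
        hyb, ev = combine_evidence(disc, sv, iv, nh_cls)
        calls.append(
            HybridCall(
                individual_id=iid,
                locality=fld.genotypes.locality_ids[field_ids.index(iid)],
                markers=marker_rows[iid],
                q_str=float(q_w[iid]),
                h=float(hv) if np.isfinite(hv) else None,
                nh_class=None if nh_cls == "undetermined" else nh_cls,
                verdicts={"STR": sv, "INT": iv or "missing", "NH": nh_cls},
                hybrid=hyb,
                evidence=ev,
            )
        )

    # --- stage 7: reports ---------------------------------------------------
    loc_table = pd.DataFrame(
        {
            "code": list(CLASSES),
            "name": list(CLASSES),
            "n": [int(cfg["n_field_per_class"].get(c, 0)) for c in CLASSES],
        }
    )
    loc_table = loc_table[loc_table["n"] > 0]
    localities = summarize_localities(calls, loc_table)
    fh_by_loc = dict(zip(localities["locality"], localities["f_H"]))
    for c in calls:
        c.f_h = fh_by_loc.get(c.locality)

    perf = performance_metrics(
        sim.labels["class"], nh.loc[sim.labels["id"], "majority"]
    )
    write_report(calls, out_dir / "report.tsv")
    perf.to_csv(out_dir / "performance.tsv", sep="\t", float_format="%.3f")
    localities.to_csv(out_dir / "localities.tsv", sep="\t", index=False,
                      float_format="%.3f")
    ranges_df = pd.DataFrame(
        [
            ("q_str", *str_ranges.p_range, *str_ranges.w_range),
            ("h", *int_ranges.p_range, *int_ranges.w_range),
        ],
        columns=["score", "P_min", "P_max", "W_min", "W_max"],
    )
    ranges_df.to_csv(out_dir / "ranges.tsv", sep="\t", index=False,
                     float_format="%.3f")
    manifest = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "config": {k: v for k, v in cfg.items()},
        "n_field": len(field_ids),
        "n_sim": sim.genotypes.n_individuals,
        "n_hybrid_calls": int(sum(c.hybrid for c in calls)),
        "ln_prob_data": adm.ln_prob_data,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "calls": calls,
        "str_ranges": str_ranges,
        "int_ranges": int_ranges,
        "performance": perf,
        "localities": localities,
        "q": q,
        "h": h_ser,
        "nh": nh,
        "manifest": manifest,
    }


def _simulate_its_patterns(labels: pd.DataFrame, panel: ReferencePanel, rng):
    """Mendelian ITS-1 band patterns per individual from the class pedigree.

    Each gamete's species origin follows the class' origin proportions; the
    observed pattern is one species' band set for a homospecific pair and
    the composite band set for a heterospecific pair.
    """
    composite = _composite_pattern(
        panel.rflp_patterns["P"], panel.rflp_patterns["W"], panel.rflp_tolerance
    )
    out = {}
    for _, row in labels.iterrows():
        cls = row["class"]
        if cls == "P_pit":
            origins = ("P", "P")
        elif cls == "P_wil":
            origins = ("W", "W")
        elif cls == "F1":
            origins = ("P", "W")
        elif cls == "F2":
            origins = tuple("PW"[int(rng.integers(2))] for _ in range(2))
        elif cls == "Bkc_Pit":
            origins = ("PW"[int(rng.integers(2))], "P")
        else:
            origins = ("PW"[int(rng.integers(2))], "W")
        if origins[0] == origins[1]:
            out[row["id"]] = panel.rflp_patterns[origins[0]]
        else:
            out[row["id"]] = composite
    return out


def _composite_pattern(pat_p, pat_w, tol):
    """Bands of a heterozygote digest: union, shared bands appearing once."""
    from .markers import _remove_bands, _shared_bands

    shared = _shared_bands(pat_p, pat_w, tol)
    unique_w = _remove_bands(pat_w, shared, tol)
    return tuple(sorted((*pat_p, *unique_w), reverse=True))
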