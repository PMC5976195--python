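"""End-to-end orchestration: simulate -> design panel -> validate -> assign.

One seed drives the whole run; identical configuration and seed give a
byte-identical JSON report. Stage artifacts (catalog VCF/FASTA, genotype
and metadata TSVs, Genepop export, assay FASTA, the filter report and the
run report) are written under the configured output directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats_io, popgen_stats, replicate_qc
from .assignment import SexPanel, SpeciesTable, assign_sex, assign_species, match_individuals
from .formats_io import GenotypeMatrix
from .panel_design import FilterCriteria, run_filter_cascade
from .replicate_qc import ErrorModel, ReplicateDesign
from .synthetic_data import SimConfig, generate_catalog, generate_marker_profiles, generate_replicate_run


@dataclass
class PipelineConfig:
    """Everything a full run needs, thresholds included."""

    sim: SimConfig
    criteria: FilterCriteria
    error_model: ErrorModel = field(default_factory=lambda: ErrorModel(0.002, 0.001, 0.01))
    outdir: Path = Path("panelforge_run")
    seed: int = 0
    n_deep_replicates: int = 10
    n_deep_samples: int = 2
    n_duplicate_samples: int = 12
    n_ntc: int = 3
    callrate_threshold: float = 0.75
    relatedness_threshold: float = 0.35
    pi_bound: float = 0.01
    hwe_alpha: float = 0.05
    ld_alpha: float = 0.01
    ld_permutations: int = 199
    marker_failure_rate: float = 0.0


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return (and write) the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # stage 1: simulate the catalog -------------------------------------
    sim = dataclasses.replace(config.sim, seed=config.seed)
    catalog, truth = generate_catalog(sim)
    formats_io.write_catalog(catalog, out / "catalog.vcf", out / "catalog.fasta")
    formats_io.write_sample_meta(catalog.meta, out / "samples.tsv")
    formats_io.write_genotype_table(catalog.genotypes, out / "genotypes.tsv")

    # stage 2: filtering cascade ----------------------------------------
    report = run_filter_cascade(catalog, config.criteria)
    panel = report.selected
    (out / "filter_report.json").write_text(json.dumps(_jsonable(report.to_dict()), indent=2))
    if panel:
        formats_io.export_assay_sequences(
            catalog, panel, out / "assays.fasta", min_flank=config.criteria.min_flank
        )
    panel_matrix = catalog.genotypes.subset(snps=panel)

    # stage 3: replicate validation run ---------------------------------
    sources = panel_matrix.samples
    plan = [(s, config.n_deep_replicates) for s in sources[: config.n_deep_samples]]
    plan += [(s, 2) for s in sources[config.n_deep_samples : config.n_deep_samples + config.n_duplicate_samples]]
    design = ReplicateDesign.build(plan)
    ntc_ids = [f"NTC{i + 1}" for i in range(config.n_ntc)]
    run = generate_replicate_run(
        panel_matrix,
        config.error_model,
        design,
        seed=int(rng.integers(0, 2**31 - 1)),
        alleles={sid: truth.snp_alleles[sid] for sid in panel},
        ntc_ids=ntc_ids,
    )
    combined = GenotypeMatrix(
        pd.concat([panel_matrix.df, run.matrix.df]), validate=False
    )
    formats_io.write_genotype_table(combined, out / "validation_genotypes.tsv")

    # stage 4: call-rate filtering, error rate, NTC checks --------------
    filtered, removed_samples, removed_snps = replicate_qc.apply_callrate_filter(
        combined, config.callrate_threshold
    )
    usable_groups = [
        g for g in design.groups if all(r in set(filtered.samples) for r in g.replicate_ids)
    ]
    error_report = replicate_qc.replicate_error_rate(
        filtered.subset(samples=[r for g in usable_groups for r in g.replicate_ids]),
        ReplicateDesign(groups=usable_groups),
    )
    ntc_present = [n for n in ntc_ids if n in set(filtered.samples)]
    ntc_pass = replicate_qc.ntc_check(filtered, ntc_present) if ntc_present else {}

    # stage 5: population statistics on pruned originals ----------------
    originals = [s for s in filtered.samples if s in set(panel_matrix.samples)]
    stats_matrix = filtered.subset(samples=originals)
    panel_snps = stats_matrix.snp_ids
    r_matrix = popgen_stats.pairwise_relatedness(stats_matrix, "lynch_ritland")
    retained = popgen_stats.prune_related(r_matrix, config.relatedness_threshold)
    pruned = stats_matrix.subset(samples=retained)

    freqs = {sid: popgen_stats.allele_frequencies(pruned, sid) for sid in panel_snps}
    snp_rows = []
    for sid in panel_snps:
        ho, he = popgen_stats.heterozygosity(pruned, sid)
        col = pruned.column(sid)
        called = col[col != formats_io.MISSING]
        het = (called.str[0] != called.str[1]).sum()
        hom = called.str[0] == called.str[1]
        alleles = pruned.observed_alleles(sid)
        n_aa = int((called == alleles[0] * 2).sum()) if alleles else 0
        n_bb = int((called == alleles[-1] * 2).sum()) if len(alleles) > 1 else 0
        p_hwe = popgen_stats.hwe_exact_test(n_aa, int(het), n_bb) if alleles else float("nan")
        snp_rows.append(
            {"snp_id": sid, "maf": freqs[sid].maf, "ho": ho, "he": he, "hwe_p": p_hwe}
        )
    snp_stats = pd.DataFrame(snp_rows).set_index("snp_id") if snp_rows else pd.DataFrame()
    if len(snp_stats):
        snp_stats.to_csv(out / "panel_stats.tsv", sep="\t")

    ld_flagged = 0
    ld_tested = 0
    for i, a in enumerate(panel_snps):
        for b in panel_snps[i + 1 :]:
            p = popgen_stats.ld_probability_test(
                pruned, a, b, config.ld_permutations, seed=int(rng.integers(0, 2**31 - 1))
            )
            if not np.isnan(p):
                ld_tested += 1
                if p < config.ld_alpha:
                    ld_flagged += 1

    populations = dict(zip(catalog.meta["sample_id"], catalog.meta["population"]))
    theta = (
        popgen_stats.fst_wc(pruned, populations)
        if len({populations[s] for s in pruned.samples}) > 1 and panel_snps
        else float("nan")
    )

    freq_list = [freqs[sid] for sid in panel_snps]
    pi_curve = popgen_stats.cumulative_pi_curve(freq_list, "unrelated") if freq_list else np.array([])
    pi_sib_curve = popgen_stats.cumulative_pi_curve(freq_list, "sibs") if freq_list else np.array([])

    # stage 6: assignments ----------------------------------------------
    sex_profiles, mito_profiles = generate_marker_profiles(
        truth.true_sex,
        truth.true_species,
        failure_rate=config.marker_failure_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    sample_rates, _ = replicate_qc.call_rates(stats_matrix) if originals else (pd.Series(dtype=float), None)
    sex_calls = {
        s: assign_sex(sex_profiles.loc[s].to_dict(), float(sample_rates.get(s, 0.0)))
        for s in originals
    }
    species_calls = {}
    for s in originals:
        compatible, nearest = assign_species(mito_profiles.loc[s].to_dict())
        species_calls[s] = {"compatible": sorted(compatible), "nearest": nearest[:2]}
    clusters, pair_table = match_individuals(filtered.subset(
        samples=[s for s in filtered.samples if s not in set(ntc_ids)]
    ))

    report_dict = {
        "seed": config.seed,
        "cascade": report.to_dict(),
        "panel_size": len(panel_snps),
        "removed_samples": removed_samples,
        "removed_snps": removed_snps,
        "error_report": {
            "overall": error_report.overall,
            "group_means": error_report.group_means,
            "classification": error_report.classification,
        },
        "ntc_pass": ntc_pass,
        "n_retained_after_pruning": len(retained),
        "panel_stats": {
            "mean_maf": float(snp_stats["maf"].mean()) if len(snp_stats) else None,
            "mean_ho": float(snp_stats["ho"].mean()) if len(snp_stats) else None,
            "mean_he": float(snp_stats["he"].mean()) if len(snp_stats) else None,
            "n_hwe_deviating": int((snp_stats["hwe_p"] < config.hwe_alpha).sum()) if len(snp_stats) else 0,
            "ld_pairs_tested": ld_tested,
            "ld_pairs_flagged": ld_flagged,
            "theta": theta,
        },
        "pi_curve": pi_curve,
        "pi_sibs_curve": pi_sib_curve,
        "pi_bound_met_at": int(np.argmax(pi_curve < config.pi_bound) + 1) if len(pi_curve) and (pi_curve < config.pi_bound).any() else None,
        "sex_calls": sex_calls,
        "species_calls": species_calls,
        "recapture_clusters": [sorted(c) for c in clusters],
        "n_recapture_pairs": int(len(pair_table)),
    }
    report_json = json.dumps(_jsonable(report_dict), indent=2, sort_keys=True)
    (out / "run_report.json").write_text(report_json)
    return json.loads(report_json)
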