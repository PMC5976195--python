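"""Ground-truth recovery and bookkeeping of the simulators."""

import numpy as np
import pandas as pd
import pytest

from panelforge.formats_io import MISSING
from panelforge.popgen_stats import LocusFreqs, allele_frequencies, fst_wc, relatedness
from panelforge.replicate_qc import ErrorModel, ReplicateDesign
from panelforge.synthetic_data import (
    SimConfig,
    calibrated_error_model,
    expected_het_fraction,
    generate_catalog,
    generate_marker_profiles,
    generate_pedigree_genotypes,
    generate_replicate_run,
)


def test_empty_catalog():
    catalog, truth = generate_catalog(SimConfig(n_loci=0, n_individuals=8, seed=0))
    assert catalog.loci == {} and catalog.snps == []
    assert truth.ancestral_freqs == {}


def test_config_validation():
    with pytest.raises(ValueError, match="special-locus"):
        SimConfig(n_loci=10, frac_monomorphic=0.6, frac_multi_snp_loci=0.6)
    with pytest.raises(ValueError, match="maf_spectrum"):
        SimConfig(n_loci=10, maf_spectrum=(0.0, 0.6))
    with pytest.raises(ValueError, match="locus_length"):
        SimConfig(n_loci=10, locus_length=50)


def test_seed_determinism():
    cfg = SimConfig(n_loci=30, n_individuals=10, missing_rate=0.1, n_linked_pairs=2,
                    frac_multi_snp_loci=0.1, seed=99)
    c1, t1 = generate_catalog(cfg)
    c2, t2 = generate_catalog(cfg)
    assert c1.loci == c2.loci
    pd.testing.assert_frame_equal(c1.genotypes.df, c2.genotypes.df)
    pd.testing.assert_frame_equal(t1.pop_freqs, t2.pop_freqs)


def test_allele_frequency_recovery_within_binomial_error():
    cfg = SimConfig(n_loci=40, n_individuals=300, target_fst=0.05, missing_rate=0.0, seed=5)
    catalog, truth = generate_catalog(cfg)
    pops = dict(zip(catalog.meta["sample_id"], catalog.meta["population"]))
    for sid in catalog.genotypes.snp_ids[:15]:
        ref, alt = truth.snp_alleles[sid]
        for pop in ("pop1", "pop2"):
            members = [s for s, p in pops.items() if p == pop]
            dos = catalog.genotypes.subset(samples=members).dosage(sid, alt)
            n = 2 * dos.notna().sum()
            p_true = truth.pop_freqs.at[sid, pop]
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(dos.mean() / 2 - p_true) < 5 * se + 1e-9


@pytest.mark.parametrize("target", [0.0, 0.08])
def test_fst_recovery_over_seeds(target):
    thetas = []
    for seed in range(20):
        cfg = SimConfig(n_loci=200, n_individuals=200, target_fst=target,
                        missing_rate=0.0, seed=seed)
        catalog, _ = generate_catalog(cfg)
        pops = dict(zip(catalog.meta["sample_id"], catalog.meta["population"]))
        thetas.append(fst_wc(catalog.genotypes, pops))
    assert abs(np.mean(thetas) - target) < 0.02


def test_linked_pairs_and_special_loci_present():
    cfg = SimConfig(n_loci=60, n_individuals=40, frac_multi_snp_loci=0.1,
                    frac_monomorphic=0.1, n_linked_pairs=4, maf_spectrum=(0.2, 0.5), seed=3)
    catalog, truth = generate_catalog(cfg)
    assert len(truth.linked_pairs) == 4
    multi = [l for l in catalog.loci if len(catalog.snps_on_locus(l)) > 1]
    assert len(multi) == 6
    mono = [l for l in catalog.loci if not catalog.snps_on_locus(l)]
    assert len(mono) == 6
    # linked copies correlate strongly with their sources
    from panelforge.popgen_stats import ld_r2
    for src, copy in truth.linked_pairs:
        assert ld_r2(catalog.genotypes, src, copy) > 0.7


# --- pedigrees -------------------------------------------------------------

# allele frequencies spread over the panel's working range
_P = [0.25 + 0.05 * (i % 11) for i in range(500)]
FREQS = {f"s{i}": ("A", "C", p) for i, p in enumerate(_P)}
REF_FREQS = {f"s{i}": LocusFreqs(f"s{i}", ("A", "C"), (1 - p, p), 100) for i, p in enumerate(_P)}


def test_fixed_cross_is_deterministic():
    freqs = {"s0": ("A", "C", 0.0)}  # alt absent: founders AA
    m = generate_pedigree_genotypes(freqs, {"kid": ("p1", "p2")}, seed=0)
    assert set(m.df["s0"]) == {"AA"}


def test_pedigree_cycle_raises():
    with pytest.raises(ValueError, match="cycle"):
        generate_pedigree_genotypes(FREQS, {"a": ("b", None), "b": ("a", None)}, seed=0)


def test_parent_offspring_relatedness_near_half():
    vals = []
    for seed in range(20):
        m = generate_pedigree_genotypes(FREQS, {"child": ("mum", None)}, seed=seed)
        vals.append(relatedness(m, ("mum", "child"), "lynch_ritland", REF_FREQS).r)
    assert abs(np.mean(vals) - 0.5) < 0.05


def test_twins_related_but_not_identical():
    vals, identical = [], []
    for seed in range(20):
        m = generate_pedigree_genotypes(FREQS, {"c1": ("mum", "dad"), "c2": ("mum", "dad")}, seed=seed)
        vals.append(relatedness(m, ("c1", "c2"), "lynch_ritland", REF_FREQS).r)
        identical.append((m.df.loc["c1"] == m.df.loc["c2"]).all())
    assert abs(np.mean(vals) - 0.5) < 0.05
    assert not any(identical)


# --- replicate runs --------------------------------------------------------

def _source(seed=0, n=14, n_loci=20):
    cfg = SimConfig(n_loci=n_loci, n_individuals=n, n_populations=1, target_fst=0.0,
                    maf_spectrum=(0.25, 0.5), missing_rate=0.0, seed=seed)
    return generate_catalog(cfg)


def test_zero_error_model_copies_sources():
    catalog, truth = _source()
    design = ReplicateDesign.default_plan(catalog.genotypes.samples)
    run = generate_replicate_run(catalog.genotypes, ErrorModel(), design, seed=1,
                                 alleles=truth.snp_alleles)
    assert run.events == []
    for g in design.groups:
        for rid in g.replicate_ids:
            assert (run.matrix.df.loc[rid] == catalog.genotypes.df.loc[g.source_id]).all()


def test_forced_dropout_makes_every_het_homozygous():
    catalog, truth = _source(seed=2)
    design = ReplicateDesign.build([(catalog.genotypes.samples[0], 5)])
    run = generate_replicate_run(catalog.genotypes, ErrorModel(dropout_rate=1.0), design,
                                 seed=3, alleles=truth.snp_alleles)
    src = catalog.genotypes.df.loc[design.groups[0].source_id]
    for rid in design.groups[0].replicate_ids:
        rep = run.matrix.df.loc[rid]
        for sid in catalog.genotypes.snp_ids:
            if src[sid][0] != src[sid][1]:
                assert rep[sid][0] == rep[sid][1]
                assert rep[sid][0] in src[sid]


def test_error_event_bookkeeping_is_exact():
    catalog, truth = _source(seed=4)
    design = ReplicateDesign.default_plan(catalog.genotypes.samples)
    run = generate_replicate_run(
        catalog.genotypes, ErrorModel(0.05, 0.05, 0.03), design, seed=5,
        alleles=truth.snp_alleles, ntc_ids=["NTC1"],
    )
    n_discordant = 0
    for g in design.groups:
        src = catalog.genotypes.df.loc[g.source_id]
        for rid in g.replicate_ids:
            rep = run.matrix.df.loc[rid]
            n_discordant += int(((rep != src) & (rep != MISSING) & (src != MISSING)).sum())
    non_missing_events = [e for e in run.events if e[2] in ("dropout", "dropin")]
    assert n_discordant == len(non_missing_events)
    missing_events = [e for e in run.events if e[2] == "missing"]
    emitted_missing = sum(
        int(((run.matrix.df.loc[rid] == MISSING) & (catalog.genotypes.df.loc[g.source_id] != MISSING)).sum())
        for g in design.groups for rid in g.replicate_ids
    )
    assert emitted_missing == len(missing_events)
    assert (run.matrix.df.loc["NTC1"] == MISSING).all()  # clean controls by default


def test_rate_validation():
    with pytest.raises(ValueError):
        ErrorModel(dropout_rate=0.9, missing_rate=0.2)


def test_calibrated_error_model_marginal_rate():
    em = calibrated_error_model(0.002, (0.25, 0.5))
    h = expected_het_fraction((0.25, 0.5))
    marginal = h * em.dropout_rate + (1 - h) * em.dropin_rate
    assert marginal == pytest.approx(0.002, rel=1e-12)
    assert h * em.dropout_rate == pytest.approx(2 * (1 - h) * em.dropin_rate, rel=1e-12)


# --- marker profiles -------------------------------------------------------

def test_marker_profiles_follow_truth():
    sex_df, mito_df = generate_marker_profiles(
        {"m1": "male", "f1": "female"}, {"m1": "moose", "f1": "roe deer"},
        failure_rate=0.0, seed=0,
    )
    assert (sex_df.loc["m1"] == "positive").all()
    assert (sex_df.loc["f1"] == "negative").all()
    assert list(mito_df.loc["m1"]) == ["C", "C", "C", "T", "G"]
    assert mito_df.loc["f1", "Aa_mt_1"] in {"A", "C"}  # ambiguous cell drawn uniformly
    with pytest.raises(ValueError, match="unknown species"):
        generate_marker_profiles({"x": "male"}, {"x": "muntjac"})
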