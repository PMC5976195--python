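"""Validation statistics against enumeration oracles and sampling theory."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from panelforge.formats_io import GenotypeMatrix
from panelforge.popgen_stats import (
    LocusFreqs,
    allele_frequencies,
    cumulative_pi_curve,
    fst_wc,
    heterozygosity,
    hwe_exact_test,
    ld_probability_test,
    ld_r2,
    pairwise_relatedness,
    pi_sibs,
    pi_unrelated,
    prune_related,
    relatedness,
)

from conftest import hwe_column, make_matrix


# --- frequencies and heterozygosity ---------------------------------------

def test_allele_frequencies_direct_counts():
    m = make_matrix({"snp": ["AA", "AA", "AC"]})
    fr = allele_frequencies(m, "snp")
    assert fr.alleles == ("A", "C")
    assert fr.freqs[1] == pytest.approx(1 / 6)
    assert fr.maf == pytest.approx(1 / 6)

    m = make_matrix({"snp": ["AC", "AC", "AC"]})
    assert allele_frequencies(m, "snp").freqs == (0.5, 0.5)

    m = make_matrix({"snp": ["AA", "NN", "AC", "NN"]})
    fr = allele_frequencies(m, "snp")
    assert fr.n_called == 2 and fr.freqs[1] == pytest.approx(0.25)

    with pytest.raises(ValueError, match="no called"):
        allele_frequencies(make_matrix({"snp": ["NN", "NN"]}), "snp")


def test_heterozygosity_limits(rng):
    m = make_matrix({"snp": ["AC", "AC", "AA", "CC"]})
    ho, he = heterozygosity(m, "snp")
    assert he == pytest.approx(0.5)  # He maximal at p = 0.5
    assert ho == pytest.approx(0.5)
    m = make_matrix({"snp": ["AA", "AA", "CC"]})
    assert heterozygosity(m, "snp")[0] == 0.0

    # HWE sampling: mean Ho over seeds ~ 2pq at p = 0.3
    hos = []
    for _ in range(20):
        m = make_matrix({"snp": hwe_column(rng, 100, 0.3)})
        hos.append(heterozygosity(m, "snp")[0])
    assert abs(np.mean(hos) - 0.42) < 0.03


def test_heterozygosity_unbiased_flag():
    m = make_matrix({"snp": ["AC", "AA", "CC", "AC"]})
    _, he = heterozygosity(m, "snp")
    _, he_u = heterozygosity(m, "snp", unbiased=True)
    assert he_u == pytest.approx(he * 8 / 7)


# --- Hardy-Weinberg exact test ---------------------------------------------

def _hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact-integer enumeration of the conditional HWE null."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    configs = []
    for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        aa = (n_a - h) // 2
        bb = n - h - aa
        if aa < 0 or bb < 0:
            continue
        w = Fraction(math.factorial(n), math.factorial(aa) * math.factorial(h) * math.factorial(bb)) * 2**h
        configs.append((h, w))
    total = sum(w for _, w in configs)
    probs = {h: Fraction(w, total) for h, w in configs}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs)


def test_hwe_perfect_proportions_give_p_one():
    assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)


def test_hwe_extreme_het_deficit():
    assert hwe_exact_test(50, 0, 50) < 1e-6


def test_hwe_matches_enumeration_oracle_for_small_n():
    for n in range(1, 11):
        for n_aa in range(n + 1):
            for n_ab in range(n - n_aa + 1):
                n_bb = n - n_aa - n_ab
                got = hwe_exact_test(n_aa, n_ab, n_bb)
                want = float(_hwe_oracle(n_aa, n_ab, n_bb))
                assert got == pytest.approx(want, abs=1e-10), (n_aa, n_ab, n_bb)


def test_hwe_input_validation():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 0, 1)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


# --- linkage disequilibrium -------------------------------------------------

def test_ld_r2_identical_columns(rng):
    col = hwe_column(rng, 50, 0.4)
    m = make_matrix({"a": col, "b": list(col)})
    assert ld_r2(m, "a", "b") == pytest.approx(1.0)


def test_ld_r2_independent_columns(rng):
    m = make_matrix({"a": hwe_column(rng, 1000, 0.4), "b": hwe_column(rng, 1000, 0.4)})
    assert ld_r2(m, "a", "b") < 0.01


def test_ld_r2_flip_model(rng):
    """Copy with 10% re-draws: corr = 0.9, so r^2 ~ 0.81."""
    p, e, n = 0.5, 0.10, 4000
    dos = rng.binomial(2, p, size=n)
    redraw = rng.random(n) < e
    dos_b = np.where(redraw, rng.binomial(2, p, size=n), dos)
    genos = ["AA", "AC", "CC"]
    m = make_matrix({"a": [genos[d] for d in dos], "b": [genos[d] for d in dos_b]})
    assert ld_r2(m, "a", "b") == pytest.approx((1 - e) ** 2, abs=0.03)


def test_ld_r2_undefined_for_monomorphic():
    m = make_matrix({"a": ["AA", "AA", "AA"], "b": ["GT", "GG", "TT"]})
    assert np.isnan(ld_r2(m, "a", "b"))


def test_ld_permutation_test_perfect_pair(rng):
    col = hwe_column(rng, 40, 0.5)
    m = make_matrix({"a": col, "b": list(col)})
    assert ld_probability_test(m, "a", "b", n_perm=99, seed=0) == pytest.approx(1 / 100)
    with pytest.raises(ValueError):
        ld_probability_test(m, "a", "b", n_perm=0, seed=0)


def test_ld_permutation_type_one_error_calibrated(rng):
    hits = 0
    n_rep = 500
    for i in range(n_rep):
        m = make_matrix({"a": hwe_column(rng, 50, 0.4), "b": hwe_column(rng, 50, 0.4)})
        if ld_probability_test(m, "a", "b", n_perm=399, seed=i) < 0.05:
            hits += 1
    assert abs(hits / n_rep - 0.05) < 0.03


# --- F_st -------------------------------------------------------------------

def test_fst_identical_populations(rng):
    cols = {f"s{i}": hwe_column(rng, 30, 0.3) for i in range(20)}
    df = pd.DataFrame(cols, index=[f"a{i}" for i in range(30)], dtype=object)
    dup = df.copy()
    dup.index = [f"b{i}" for i in range(30)]
    m = GenotypeMatrix(pd.concat([df, dup]))
    pops = {s: s[0] for s in m.samples}
    # theta is unbiased around 0; for finite samples the estimate sits
    # slightly negative when the two groups are copies of each other
    assert abs(fst_wc(m, pops)) < 0.05


def test_fst_fixed_differences():
    m = make_matrix(
        {"s1": ["AA"] * 10 + ["CC"] * 10, "s2": ["GG"] * 10 + ["TT"] * 10},
        samples=[f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)],
    )
    pops = {s: s[0] for s in m.samples}
    assert fst_wc(m, pops) == pytest.approx(1.0)


def test_fst_requires_two_populations():
    m = make_matrix({"s1": ["AA", "AC"]})
    with pytest.raises(ValueError):
        fst_wc(m, {"s1": "p", "s2": "p"})


# --- probability of identity ------------------------------------------------

def _pi_unrelated_oracle(p: float) -> float:
    """Sum over genotype pairs of squared HWE probabilities."""
    probs = [p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]
    return sum(g * g for g in probs)


def _pi_sibs_oracle(p: float) -> float:
    """Full enumeration: two offspring of random HWE parents match."""
    freqs = [p, 1 - p]
    geno_p = {(i, j): (2 - (i == j)) * freqs[i] * freqs[j] for i in range(2) for j in range(i, 2)}

    def offspring_dist(mum, dad):
        dist = {}
        for a in mum:
            for b in dad:
                g = tuple(sorted((a, b)))
                dist[g] = dist.get(g, 0.0) + 0.25
        return dist

    total = 0.0
    for mum, pm in geno_p.items():
        for dad, pd_ in geno_p.items():
            dist = offspring_dist(mum, dad)
            total += pm * pd_ * sum(v * v for v in dist.values())
    return total


@pytest.mark.parametrize("p", [0.05 * k for k in range(1, 11)])
def test_pi_formulas_match_enumeration(p):
    assert pi_unrelated([p, 1 - p]) == pytest.approx(_pi_unrelated_oracle(p), abs=1e-12)
    assert pi_sibs([p, 1 - p]) == pytest.approx(_pi_sibs_oracle(p), abs=1e-12)
    assert pi_sibs([p, 1 - p]) >= pi_unrelated([p, 1 - p])


def test_pi_closed_form_examples():
    assert pi_unrelated([0.5, 0.5]) == pytest.approx(0.375)
    assert pi_unrelated([0.8, 0.2]) == pytest.approx(0.5136)
    assert pi_unrelated([1.0, 0.0]) == 1.0
    assert pi_sibs([0.5, 0.5]) == pytest.approx(0.59375)
    assert pi_sibs([1.0, 0.0]) == 1.0


def test_cumulative_pi_curve_products_and_ordering():
    five = [[0.5, 0.5]] * 5
    curve = cumulative_pi_curve(five, "unrelated")
    assert curve[-1] == pytest.approx(0.375**5)
    assert curve[-1] < 0.01
    ten = [[0.5, 0.5]] * 10
    assert cumulative_pi_curve(ten, "sibs")[-1] == pytest.approx(0.59375**10)
    # most informative (lowest PI) first; monomorphic locus leaves product unchanged
    mixed = [[1.0, 0.0], [0.5, 0.5]]
    curve = cumulative_pi_curve(mixed, "unrelated")
    assert curve[0] == pytest.approx(0.375) and curve[1] == pytest.approx(0.375)
    assert np.all(np.diff(cumulative_pi_curve([[0.3, 0.7]] * 6, "unrelated")) <= 0)
    assert list(cumulative_pi_curve([[1.0, 0.0]], "unrelated")) == [1.0]


# --- relatedness ------------------------------------------------------------

def test_lr_self_comparison_near_one(rng):
    ref = {f"s{i}": LocusFreqs(f"s{i}", ("A", "C"), (0.7, 0.3), 100) for i in range(300)}
    cols = {sid: hwe_column(rng, 2, 0.3) for sid in ref}
    m = make_matrix(cols, samples=["x", "y"])
    m.df.loc["y"] = m.df.loc["x"]  # identical multilocus genotypes
    res = relatedness(m, ("x", "y"), "lynch_ritland", ref)
    assert res.r == pytest.approx(1.0, abs=0.15)


def test_relatedness_requires_informative_loci():
    m = make_matrix({"s0": ["AA", "AA"]}, samples=["x", "y"])
    ref = {"s0": LocusFreqs("s0", ("A",), (1.0,), 10)}
    with pytest.raises(ValueError, match="no informative loci"):
        relatedness(m, ("x", "y"), "lynch_ritland", ref)


def test_unrelated_dyads_center_on_zero(rng):
    ref = {f"s{i}": LocusFreqs(f"s{i}", ("A", "C"), (0.6, 0.4), 100) for i in range(500)}
    vals = []
    for _ in range(50):
        cols = {sid: hwe_column(rng, 2, 0.4) for sid in ref}
        m = make_matrix(cols, samples=["x", "y"])
        for est in ("lynch_ritland", "ritland"):
            vals.append(relatedness(m, ("x", "y"), est, ref).r)
    assert abs(np.mean(vals)) < 0.03


# --- related-pair pruning ---------------------------------------------------

def _r_matrix(samples, flagged_pairs):
    df = pd.DataFrame(0.0, index=samples, columns=samples)
    for a, b in flagged_pairs:
        df.at[a, b] = df.at[b, a] = 0.6
    return df


def test_prune_disjoint_pairs_drops_one_each():
    samples = [f"i{k:02d}" for k in range(59)]
    pairs = [(samples[2 * k], samples[2 * k + 1]) for k in range(9)]
    retained = prune_related(_r_matrix(samples, pairs), threshold=0.35)
    assert len(retained) == 50
    for a, b in pairs:
        assert (a in retained) != (b in retained)


def test_prune_identity_when_no_pairs():
    samples = ["a", "b", "c"]
    assert prune_related(_r_matrix(samples, []), 0.35) == samples


def test_prune_triangle_minimal_removal():
    samples = ["a", "b", "c", "d"]
    triangle = [("a", "b"), ("b", "c"), ("a", "c")]
    retained = prune_related(_r_matrix(samples, triangle), 0.35)
    assert len([s for s in retained if s in {"a", "b", "c"}]) == 1
    assert "d" in retained
    # brute force: minimal removal leaving no flagged pair is 2
    best = min(
        3 - len(keep)
        for r in range(4)
        for keep in itertools.combinations(["a", "b", "c"], r)
        if not any(a in keep and b in keep for a, b in triangle)
    )
    assert best == 2 and len(retained) == len(samples) - best
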