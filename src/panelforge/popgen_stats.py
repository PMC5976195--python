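"""Population-genetic statistics for panel validation.

Implements the statistics used to validate an individual-identification
SNP panel: allele frequencies and heterozygosity, the exact test of
Hardy-Weinberg equilibrium, linkage disequilibrium as squared dosage
correlation with a permutation probability test, the Weir & Cockerham
(1984) theta estimator of F_st, probability of identity for unrelated
individuals and for full siblings, pairwise relatedness by the Lynch &
Ritland (1999) and Ritland (1996) moment estimators, and greedy pruning of
related pairs above a relatedness threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .formats_io import MISSING, GenotypeMatrix

__all__ = [
    "LocusFreqs",
    "RelatednessResult",
    "allele_frequencies",
    "heterozygosity",
    "hwe_exact_test",
    "ld_r2",
    "ld_probability_test",
    "fst_wc",
    "pi_unrelated",
    "pi_sibs",
    "cumulative_pi_curve",
    "relatedness",
    "pairwise_relatedness",
    "prune_related",
]


@dataclass(frozen=True)
class LocusFreqs:
    """Allele frequencies at one locus (alleles in alphabetical order)."""

    locus_id: str
    alleles: tuple[str, ...]
    freqs: tuple[float, ...]
    n_called: int

    def __post_init__(self) -> None:
        if abs(sum(self.freqs) - 1.0) > 1e-12:
            raise ValueError(f"{self.locus_id}: frequencies sum to {sum(self.freqs)}")

    @property
    def maf(self) -> float:
        """Minor allele frequency (0 for a monomorphic locus)."""
        if len(self.freqs) < 2:
            return 0.0
        return min(self.freqs)

    def freq_of(self, allele: str) -> float:
        try:
            return self.freqs[self.alleles.index(allele)]
        except ValueError:
            return 0.0


@dataclass(frozen=True)
class RelatednessResult:
    pair: tuple[str, str]
    estimator: str
    r: float
    n_loci: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", tuple(sorted(self.pair)))


# ---------------------------------------------------------------------------
# frequencies and heterozygosity
# ---------------------------------------------------------------------------

def allele_frequencies(matrix: GenotypeMatrix, snp_id: str) -> LocusFreqs:
    """Allele frequencies over non-missing calls at one SNP."""
    counts: dict[str, int] = {}
    n_called = 0
    for cell in matrix.column(snp_id):
        if cell == MISSING:
            continue
        n_called += 1
        for a in cell:
            counts[a] = counts.get(a, 0) + 1
    if n_called == 0:
        raise ValueError(f"{snp_id}: no called genotypes")
    alleles = tuple(sorted(counts))
    total = 2 * n_called
    return LocusFreqs(snp_id, alleles, tuple(counts[a] / total for a in alleles), n_called)


def heterozygosity(matrix: GenotypeMatrix, snp_id: str, unbiased: bool = False) -> tuple[float, float]:
    """Observed and expected heterozygosity at one SNP.

    He is the gene-diversity form ``1 - sum(p_i^2)``; with ``unbiased`` the
    small-sample correction ``2n / (2n - 1)`` is applied.
    """
    fr = allele_frequencies(matrix, snp_id)
    col = matrix.column(snp_id)
    called = col[col != MISSING]
    ho = float((called.str[0] != called.str[1]).mean())
    he = 1.0 - sum(p * p for p in fr.freqs)
    if unbiased:
        he *= (2 * fr.n_called) / (2 * fr.n_called - 1)
    return ho, he


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact HWE test on biallelic genotype counts.

    Conditions on the observed allele counts: P(n_AB | n, n_A) is the
    hypergeometric-style null, and the p-value sums the probabilities of
    every heterozygote count no more probable than the observed one.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    # heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    n_homr = (rare - hets) // 2
    n_homc = n - hets - n_homr
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(n_homr + 1)
        - gammaln(n_homc + 1)
        + hets * math.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    probs /= probs.sum()  # guard against rounding drift
    p_obs = probs[np.nonzero(hets == n_ab)[0][0]]
    return float(probs[probs <= p_obs * (1.0 + 1e-9)].sum())


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def _paired_dosages(matrix: GenotypeMatrix, snp_a: str, snp_b: str) -> tuple[np.ndarray, np.ndarray]:
    da = matrix.dosage(snp_a, matrix.observed_alleles(snp_a)[0]).to_numpy()
    db = matrix.dosage(snp_b, matrix.observed_alleles(snp_b)[0]).to_numpy()
    keep = ~(np.isnan(da) | np.isnan(db))
    if keep.sum() < 2:
        raise ValueError(f"{snp_a}/{snp_b}: fewer than 2 samples called at both SNPs")
    return da[keep], db[keep]


def ld_r2(matrix: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of genotype dosages, pairwise-complete.

    Returns ``nan`` when either SNP has zero dosage variance among the
    jointly called samples (r^2 undefined).
    """
    da, db = _paired_dosages(matrix, snp_a, snp_b)
    if da.std() == 0.0 or db.std() == 0.0:
        return float("nan")
    r = np.corrcoef(da, db)[0, 1]
    return float(r * r)


def ld_probability_test(
    matrix: GenotypeMatrix, snp_a: str, snp_b: str, n_perm: int, seed: int
) -> float:
    """Permutation probability test of LD between two SNPs.

    Permutes one dosage vector over the jointly called samples and reports
    the plus-one-corrected proportion of permutations with |r| at least the
    observed |r|.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    da, db = _paired_dosages(matrix, snp_a, snp_b)
    if da.std() == 0.0 or db.std() == 0.0:
        return float("nan")
    r_obs = abs(np.corrcoef(da, db)[0, 1])
    rng = np.random.default_rng(seed)
    za = (da - da.mean()) / da.std()
    zb = (db - db.mean()) / db.std()
    n = len(da)
    perms = np.stack([rng.permutation(zb) for _ in range(n_perm)])
    r_perm = np.abs(perms @ za) / n
    exceed = int((r_perm >= r_obs - 1e-12).sum())
    return (exceed + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# F_st (Weir & Cockerham 1984 theta)
# ---------------------------------------------------------------------------

def fst_wc(matrix: GenotypeMatrix, populations: Mapping[str, str]) -> float:
    """Multi-locus Weir-Cockerham theta over the matrix's SNPs.

    ``populations`` maps sample id to population label; samples absent from
    the mapping are ignored. Per locus the among-population (a), among-
    individual (b) and within-individual (c) variance components are
    accumulated and theta = sum(a) / sum(a + b + c). Loci with fewer than
    two populations called are skipped.
    """
    pops = sorted(set(populations[s] for s in matrix.samples if s in populations))
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    sample_pop = {s: populations[s] for s in matrix.samples if s in populations}

    sum_a = sum_b = sum_c = 0.0
    used = 0
    for sid in matrix.snp_ids:
        alleles = matrix.observed_alleles(sid)
        if not alleles:
            continue
        dos = matrix.dosage(sid, alleles[0])
        het = matrix.het_mask(sid)
        n_i, p_i, h_i = [], [], []
        for pop in pops:
            members = [s for s, p in sample_pop.items() if p == pop]
            d = dos[members].dropna()
            if len(d) == 0:
                continue
            n_i.append(len(d))
            p_i.append(d.mean() / 2.0)
            h_i.append(het[d.index].mean())
        r = len(n_i)
        if r < 2:
            continue
        n_i = np.asarray(n_i, dtype=float)
        p_i = np.asarray(p_i, dtype=float)
        h_i = np.asarray(h_i, dtype=float)
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        sum_a += a
        sum_b += b
        sum_c += c
        used += 1
    if used == 0:
        raise ValueError("no locus informative for F_st")
    denom = sum_a + sum_b + sum_c
    if denom == 0.0:
        return 0.0
    return float(sum_a / denom)


# ---------------------------------------------------------------------------
# probability of identity
# ---------------------------------------------------------------------------

def _freq_array(freqs: "LocusFreqs | Sequence[float]") -> np.ndarray:
    p = np.asarray(freqs.freqs if isinstance(freqs, LocusFreqs) else freqs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("allele frequencies must sum to 1")
    return p


def pi_unrelated(freqs: "LocusFreqs | Sequence[float]") -> float:
    """Per-locus probability that two unrelated individuals match.

    PI = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2 (Paetkau-Strobeck form).
    """
    p = _freq_array(freqs)
    s = 0.0
    for i in range(len(p)):
        s += p[i] ** 4
        for j in range(i + 1, len(p)):
            s += (2.0 * p[i] * p[j]) ** 2
    return float(s)


def pi_sibs(freqs: "LocusFreqs | Sequence[float]") -> float:
    """Per-locus probability that two full siblings match.

    PI_sibs = 0.25 + 0.5*sum(p^2) + 0.5*(sum(p^2))^2 - 0.25*sum(p^4)
    (Waits et al. form, the conservative bound for first-order relatives).
    """
    p = _freq_array(freqs)
    s2 = float((p**2).sum())
    s4 = float((p**4).sum())
    return 0.25 + 0.5 * s2 + 0.5 * s2 * s2 - 0.25 * s4


def cumulative_pi_curve(
    freq_list: Sequence["LocusFreqs | Sequence[float]"], mode: str = "unrelated"
) -> np.ndarray:
    """Cumulative multilocus PI, most informative locus first.

    Loci are ordered by ascending per-locus PI of the chosen mode
    (``"unrelated"`` or ``"sibs"``) and the running product returned.
    """
    if len(freq_list) < 1:
        raise ValueError("need at least one locus")
    fn = {"unrelated": pi_unrelated, "sibs": pi_sibs}[mode]
    per_locus = sorted(fn(f) for f in freq_list)
    return np.cumprod(per_locus)


# ---------------------------------------------------------------------------
# pairwise relatedness
# ---------------------------------------------------------------------------

def _lr_directional(ref: str, prob: str, p: Mapping[str, float]) -> tuple[float, float] | None:
    """One Lynch-Ritland directional term: (weight * r, weight).

    ``ref`` and ``prob`` are canonical genotype cells; ``p`` maps allele to
    reference frequency.
    """
    a, b = ref[0], ref[1]
    c, d = prob[0], prob[1]
    pa, pb = p.get(a, 0.0), p.get(b, 0.0)
    if pa <= 0.0 or pb <= 0.0:
        return None
    sab = 1.0 if a == b else 0.0
    num = (
        pa * ((1.0 if b == c else 0.0) + (1.0 if b == d else 0.0))
        + pb * ((1.0 if a == c else 0.0) + (1.0 if a == d else 0.0))
        - 4.0 * pa * pb
    )
    den = (1.0 + sab) * (pa + pb) - 4.0 * pa * pb
    if den == 0.0:
        return None
    weight = den / (2.0 * pa * pb)
    # weight * (num / den) = num / (2 pa pb)
    return num / (2.0 * pa * pb), weight


def _ritland_locus(ref: str, prob: str, p: Mapping[str, float]) -> float | None:
    """Ritland (1996) per-locus estimate for a biallelic locus."""
    alleles = [a for a, f in p.items() if f > 0.0]
    if len(alleles) < 2:
        return None
    total = 0.0
    for a in alleles:
        sx = (ref.count(a)) / 2.0
        sy = (prob.count(a)) / 2.0
        total += sx * sy / p[a]
    n_alleles = len(alleles)
    return (2.0 / (n_alleles - 1)) * (total - 1.0)


def relatedness(
    matrix: GenotypeMatrix,
    pair: tuple[str, str],
    estimator: str = "lynch_ritland",
    reference_freqs: Mapping[str, LocusFreqs] | None = None,
) -> RelatednessResult:
    """Pairwise relatedness r for one sample pair.

    ``lynch_ritland``: the Lynch & Ritland (1999) regression estimator,
    locus-weighted by its information weight and symmetrized by averaging
    the two reference/proband directions. ``ritland``: the Ritland (1996)
    estimator, loci equally weighted (biallelic). Monomorphic reference
    loci and loci missing in either sample are skipped.
    """
    if estimator not in {"lynch_ritland", "ritland"}:
        raise ValueError(f"unknown estimator {estimator!r}")
    x, y = pair
    if reference_freqs is None:
        reference_freqs = {sid: allele_frequencies(matrix, sid) for sid in matrix.snp_ids}

    n_loci = 0
    if estimator == "lynch_ritland":
        num_xy = den_xy = num_yx = den_yx = 0.0
        for sid in matrix.snp_ids:
            fr = reference_freqs.get(sid)
            if fr is None or fr.maf <= 0.0:
                continue
            gx, gy = matrix.call(x, sid), matrix.call(y, sid)
            if gx == MISSING or gy == MISSING:
                continue
            p = dict(zip(fr.alleles, fr.freqs))
            t_xy = _lr_directional(gx, gy, p)
            t_yx = _lr_directional(gy, gx, p)
            if t_xy is None or t_yx is None:
                continue
            num_xy += t_xy[0]
            den_xy += t_xy[1]
            num_yx += t_yx[0]
            den_yx += t_yx[1]
            n_loci += 1
        if n_loci == 0 or den_xy == 0.0 or den_yx == 0.0:
            raise ValueError(f"no informative loci for pair {pair}")
        r = 0.5 * (num_xy / den_xy + num_yx / den_yx)
    else:
        values = []
        for sid in matrix.snp_ids:
            fr = reference_freqs.get(sid)
            if fr is None or fr.maf <= 0.0:
                continue
            gx, gy = matrix.call(x, sid), matrix.call(y, sid)
            if gx == MISSING or gy == MISSING:
                continue
            v = _ritland_locus(gx, gy, dict(zip(fr.alleles, fr.freqs)))
            if v is not None:
                values.append(v)
        if not values:
            raise ValueError(f"no informative loci for pair {pair}")
        n_loci = len(values)
        r = float(np.mean(values))
    return RelatednessResult(pair=(x, y), estimator=estimator, r=float(r), n_loci=n_loci)


def pairwise_relatedness(
    matrix: GenotypeMatrix,
    estimator: str = "lynch_ritland",
    reference_freqs: Mapping[str, LocusFreqs] | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise r over all sample pairs (NaN diagonal)."""
    if reference_freqs is None:
        reference_freqs = {sid: allele_frequencies(matrix, sid) for sid in matrix.snp_ids}
    samples = matrix.samples
    out = pd.DataFrame(np.nan, index=samples, columns=samples)
    for i, x in enumerate(samples):
        for y in samples[i + 1 :]:
            res = relatedness(matrix, (x, y), estimator, reference_freqs)
            out.at[x, y] = res.r
            out.at[y, x] = res.r
    return out


def prune_related(r_matrix: pd.DataFrame, threshold: float = 0.35) -> list[str]:
    """Retain a subset of samples with no pairwise r above ``threshold``.

    Greedy: repeatedly drop the individual involved in the most
    above-threshold pairs (ties broken by lexicographically smallest id)
    until none remain; an isolated flagged pair loses exactly one member.
    Returns the retained sample ids in the matrix's order.
    """
    if not r_matrix.index.equals(r_matrix.columns):
        raise ValueError("relatedness matrix must be square with matching labels")
    flagged = {
        frozenset((a, b))
        for i, a in enumerate(r_matrix.index)
        for b in r_matrix.columns[i + 1 :]
        if pd.notna(r_matrix.at[a, b]) and r_matrix.at[a, b] > threshold
    }
    removed: set[str] = set()
    while True:
        active = [p for p in flagged if not (p & removed)]
        if not active:
            break
        degree: dict[str, int] = {}
        for p in active:
            for s in p:
                degree[s] = degree.get(s, 0) + 1
        worst = max(degree.values())
        victim = min(s for s, d in degree.items() if d == worst)
        removed.add(victim)
    return [s for s in r_matrix.index if s not in removed]
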