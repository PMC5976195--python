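"""Replicate-based genotyping quality control.

Call-rate filtering, the replicate mismatch-ratio error estimator with
dropout/drop-in classification, no-template-control checks and
platform-vs-catalog concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class ReplicateGroup:
    source_id: str
    replicate_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.replicate_ids) < 2:
            raise ValueError(f"group {self.source_id}: need >= 2 replicates")


@dataclass
class ReplicateDesign:
    """Mapping of replicate genotyping runs to their source samples."""

    groups: list[ReplicateGroup]

    @classmethod
    def build(cls, plan: Sequence[tuple[str, int]], suffix: str = "rep") -> "ReplicateDesign":
        """Build a design from (source id, replicate count) pairs.

        Replicate ids are ``{source}_{suffix}{k}``. The default validation
        layout is two deeply replicated samples (10 runs each) plus twelve
        duplicated samples.
        """
        groups = [
            ReplicateGroup(src, tuple(f"{src}_{suffix}{k + 1}" for k in range(n)))
            for src, n in plan
        ]
        return cls(groups=groups)

    @classmethod
    def default_plan(cls, sample_ids: Sequence[str]) -> "ReplicateDesign":
        """2 samples x 10 replicates + 12 samples x 2 replicates."""
        if len(sample_ids) < 14:
            raise ValueError("default replicate plan needs >= 14 source samples")
        plan = [(sample_ids[0], 10), (sample_ids[1], 10)]
        plan += [(s, 2) for s in sample_ids[2:14]]
        return cls.build(plan)

    @property
    def replicate_ids(self) -> list[str]:
        return [rid for g in self.groups for rid in g.replicate_ids]


@dataclass(frozen=True)
class ErrorModel:
    """Per-genotype perturbation rates for a replicate genotyping run."""

    dropout_rate: float = 0.0  # heterozygote emitted as one homozygote
    dropin_rate: float = 0.0  # homozygote emitted as heterozygote
    missing_rate: float = 0.0
    ntc_contamination_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "dropin_rate", "missing_rate", "ntc_contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.missing_rate + self.dropout_rate > 1.0 or self.missing_rate + self.dropin_rate > 1.0:
            raise ValueError("per-genotype perturbation rates sum above 1")


@dataclass
class ErrorReport:
    """Replicate mismatch-ratio error rates with mismatch classification."""

    per_locus: pd.Series  # index snp_id, mismatches / amplified calls
    overall: float  # unweighted mean over loci
    group_means: dict[str, float]  # keyed by replicate-count class, e.g. "10x", "2x"
    classification: dict[str, int]  # dropout / dropin / other counts


def call_rates(matrix: GenotypeMatrix) -> tuple[pd.Series, pd.Series]:
    """Fraction of non-missing calls per sample and per SNP."""
    if matrix.df.size == 0:
        raise ValueError("empty genotype matrix")
    called = ~matrix.is_missing()
    return called.mean(axis=1), called.mean(axis=0)


def apply_callrate_filter(
    matrix: GenotypeMatrix, threshold: float = 0.75
) -> tuple[GenotypeMatrix, list[str], list[str]]:
    """Drop SNPs, then samples, with call rate strictly below ``threshold``.

    SNP columns are judged first; sample rates are recomputed on the
    surviving columns. A rate exactly at the threshold is retained.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    _, snp_rates = call_rates(matrix)
    removed_snps = [sid for sid in matrix.snp_ids if snp_rates[sid] < threshold]
    kept_snps = [sid for sid in matrix.snp_ids if sid not in set(removed_snps)]
    trimmed = matrix.subset(snps=kept_snps)
    if trimmed.df.shape[1] == 0:
        return trimmed, [], removed_snps
    sample_rates, _ = call_rates(trimmed)
    removed_samples = [s for s in trimmed.samples if sample_rates[s] < threshold]
    kept = trimmed.subset(samples=[s for s in trimmed.samples if s not in set(removed_samples)])
    return kept, removed_samples, removed_snps


def classify_mismatch(consensus: str, replicate: str) -> str:
    """Classify one replicate call against the group consensus.

    het -> hom is ``dropout``; hom -> het is ``dropin``; hom -> the other
    homozygote is ``other``; a missing replicate is ``missing``.
    """
    if replicate == MISSING:
        return "missing"
    cons_het = consensus[0] != consensus[1]
    rep_het = replicate[0] != replicate[1]
    if cons_het and not rep_het:
        return "dropout"
    if not cons_het and rep_het:
        return "dropin"
    return "other"


def replicate_error_rate(matrix: GenotypeMatrix, design: ReplicateDesign) -> ErrorReport:
    """Replicate mismatch-ratio error estimate.

    Per locus and group, the consensus is the plurality call among
    amplified replicates and the mismatch count is the number of amplified
    replicates deviating from it (for a disagreeing duplicate pair, one of
    the two calls counts as mismatching). The per-locus rate pools
    mismatches and amplified calls over groups; the overall rate is the
    unweighted mean over loci. Group means are also reported separately by
    replicate-count class.
    """
    snp_ids = matrix.snp_ids
    mismatches = pd.Series(0.0, index=snp_ids)
    amplified = pd.Series(0.0, index=snp_ids)
    by_class: dict[str, list[float]] = {}
    classification = {"dropout": 0, "dropin": 0, "other": 0}

    class_mm: dict[str, pd.Series] = {}
    class_amp: dict[str, pd.Series] = {}

    any_usable = {g.source_id: False for g in design.groups}
    for group in design.groups:
        klass = f"{len(group.replicate_ids)}x"
        class_mm.setdefault(klass, pd.Series(0.0, index=snp_ids))
        class_amp.setdefault(klass, pd.Series(0.0, index=snp_ids))
        missing_rows = set(group.replicate_ids) - set(matrix.samples)
        if missing_rows:
            raise ValueError(f"replicates absent from matrix: {sorted(missing_rows)}")
        sub = matrix.df.loc[list(group.replicate_ids)]
        for sid in snp_ids:
            calls = [c for c in sub[sid] if c != MISSING]
            if len(calls) < 2:
                continue
            any_usable[group.source_id] = True
            counts = pd.Series(calls).value_counts()
            modal = int(counts.iloc[0])
            n_amp = len(calls)
            mm = n_amp - modal
            mismatches[sid] += mm
            amplified[sid] += n_amp
            class_mm[klass][sid] += mm
            class_amp[klass][sid] += n_amp
            if mm:
                # classification needs an unambiguous consensus
                if len(counts) == 1 or counts.iloc[0] > counts.iloc[1]:
                    consensus = counts.index[0]
                    for c in calls:
                        if c != consensus:
                            classification[classify_mismatch(consensus, c)] += 1

    if not all(any_usable.values()):
        bad = sorted(s for s, ok in any_usable.items() if not ok)
        raise ValueError(f"groups with <2 amplified replicates at every locus: {bad}")

    with np.errstate(invalid="ignore"):
        per_locus = (mismatches / amplified).fillna(0.0)
    overall = float(per_locus.mean()) if len(per_locus) else 0.0
    group_means = {}
    for klass in class_amp:
        with np.errstate(invalid="ignore"):
            rates = (class_mm[klass] / class_amp[klass]).fillna(0.0)
        group_means[klass] = float(rates.mean())
    return ErrorReport(
        per_locus=per_locus, overall=overall, group_means=group_means, classification=classification
    )


def ntc_check(matrix: GenotypeMatrix, ntc_ids: Iterable[str], max_calls: int = 0) -> dict[str, bool]:
    """Pass/fail per no-template control: fail when called loci exceed ``max_calls``."""
    result = {}
    for nid in ntc_ids:
        if nid not in set(matrix.samples):
            raise ValueError(f"NTC {nid} not in matrix")
        n_called = int((matrix.df.loc[nid] != MISSING).sum())
        result[nid] = n_called <= max_calls
    return result


def concordance(platform: GenotypeMatrix, catalog_calls: GenotypeMatrix) -> tuple[pd.Series, int]:
    """Per-SNP agreement between platform and catalog calls, plus het gain.

    Compares cells called in both tables over the shared samples and SNPs;
    the het-gain count is the number of cells homozygous in the catalog but
    heterozygous on the platform (the expected direction of disagreement).
    """
    samples = [s for s in platform.samples if s in set(catalog_calls.samples)]
    snps = [sid for sid in platform.snp_ids if sid in set(catalog_calls.snp_ids)]
    if not samples or not snps:
        raise ValueError("no shared samples/SNPs between platform and catalog")
    a = platform.df.loc[samples, snps]
    b = catalog_calls.df.loc[samples, snps]
    both = (a != MISSING) & (b != MISSING)
    agree = (a == b) & both
    with np.errstate(invalid="ignore"):
        per_snp = (agree.sum(axis=0) / both.sum(axis=0)).astype(float)
    plat_het = a.apply(lambda col: col.str[0] != col.str[1])
    cat_hom = b.apply(lambda col: col.str[0] == col.str[1])
    het_gain = int((both & plat_het & cat_hom).to_numpy().sum())
    return per_snp, het_gain
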