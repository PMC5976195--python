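"""Candidate-SNP filtering cascade and least-linked panel selection.

The cascade narrows a de novo SNP catalog to an assay-ready panel in the
order: polymorphic stacks -> joint quality criteria (one SNP per locus,
all three genotype classes observed, completeness, presence in every
sampling location, MAF above threshold) -> least-linked selection down to
the target panel size -> assay flank check (invariant flanking sequence on
both sides of the SNP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import MISSING, GenotypeMatrix, SnpCatalog, SnpRecord
from .popgen_stats import allele_frequencies, hwe_exact_test, ld_r2

CRITERIA_ORDER = [
    "single_snp_locus",
    "genotype_classes",
    "min_individuals",
    "all_locations",
    "maf",
    "flank",
]


@dataclass
class FilterCriteria:
    """Thresholds of the candidate-SNP quality cascade."""

    min_flank: int = 40
    require_all_genotype_classes: bool = True
    min_individuals: int = 24
    min_individuals_total: int = 34
    require_all_locations: bool = True
    min_maf: float = 0.2
    n_target: int = 140
    hwe_alpha: float | None = None  # HWE belongs to validation, off by default

    def __post_init__(self) -> None:
        if self.min_individuals > self.min_individuals_total:
            raise ValueError("min_individuals exceeds min_individuals_total")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")


@dataclass
class FilterReport:
    """Ordered cascade stages with survivor counts and per-criterion verdicts."""

    stages: list[tuple[str, int, list[str]]]
    verdicts: pd.DataFrame  # index snp_id, columns CRITERIA_ORDER, bool
    max_r2_selected: float | None = None

    def counts(self) -> list[tuple[str, int]]:
        return [(name, n) for name, n, _ in self.stages]

    @property
    def selected(self) -> list[str]:
        return list(self.stages[-1][2])

    def to_dict(self) -> dict:
        return {
            "stages": [{"name": n, "survivors": c, "snp_ids": ids} for n, c, ids in self.stages],
            "max_r2_selected": self.max_r2_selected,
            "verdicts": {
                sid: {c: bool(v) for c, v in row.items()}
                for sid, row in self.verdicts.iterrows()
            },
        }


def _flank_ok(snp: SnpRecord, catalog: SnpCatalog, min_flank: int) -> bool:
    length = len(catalog.loci[snp.locus_id])
    if snp.position < min_flank or length - snp.position - 1 < min_flank:
        return False
    for other in catalog.snps_on_locus(snp.locus_id):
        if other.snp_id != snp.snp_id and abs(other.position - snp.position) <= min_flank:
            return False
    return True


def snp_quality_predicates(
    snp: SnpRecord,
    catalog: SnpCatalog,
    criteria: FilterCriteria,
    locations: Mapping[str, str] | None = None,
) -> dict[str, bool]:
    """Per-criterion verdicts for one SNP.

    ``locations`` maps sample id to location group; when absent, the
    catalog's metadata supplies it and, failing that, the location
    criterion passes vacuously. MAF is pooled over all non-missing calls.
    """
    matrix = catalog.genotypes
    sid = snp.snp_id
    col = matrix.column(sid)
    called = col[col != MISSING]
    n_called = len(called)

    verdicts: dict[str, bool] = {}
    verdicts["single_snp_locus"] = len(catalog.snps_on_locus(snp.locus_id)) == 1

    hom_ref = (called == snp.ref_allele * 2).sum()
    het = (called == "".join(sorted(snp.alleles))).sum()
    hom_alt = (called == snp.alt_allele * 2).sum()
    if criteria.require_all_genotype_classes:
        verdicts["genotype_classes"] = bool(hom_ref > 0 and het > 0 and hom_alt > 0)
    else:
        verdicts["genotype_classes"] = True

    verdicts["min_individuals"] = n_called >= criteria.min_individuals

    if criteria.require_all_locations:
        if locations is None and catalog.meta is not None:
            meta = catalog.meta
            originals = meta[(~meta["is_ntc"]) & (meta["replicate_source"] == "")]
            locations = dict(zip(originals["sample_id"], originals["location"]))
        if locations:
            all_locs = set(locations.values())
            called_locs = {locations[s] for s in called.index if s in locations}
            verdicts["all_locations"] = called_locs == all_locs
        else:
            verdicts["all_locations"] = True
    else:
        verdicts["all_locations"] = True

    if n_called > 0:
        maf = allele_frequencies(matrix, sid).maf
        verdicts["maf"] = maf > criteria.min_maf
    else:
        verdicts["maf"] = False

    verdicts["flank"] = _flank_ok(snp, catalog, criteria.min_flank)

    if criteria.hwe_alpha is not None and n_called > 0:
        verdicts["hwe"] = hwe_exact_test(int(hom_ref), int(het), int(hom_alt)) >= criteria.hwe_alpha

    return verdicts


def _r2_matrix(matrix: GenotypeMatrix, candidates: Sequence[str]) -> pd.DataFrame:
    """Pairwise r^2 among candidates; undefined pairs scored 0."""
    k = len(candidates)
    out = pd.DataFrame(0.0, index=list(candidates), columns=list(candidates))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                r2 = ld_r2(matrix, candidates[i], candidates[j])
            except ValueError:
                r2 = float("nan")
            if np.isnan(r2):
                r2 = 0.0
            out.iat[i, j] = r2
            out.iat[j, i] = r2
    return out


def ld_rank_select(
    matrix: GenotypeMatrix, candidates: Sequence[str], n_target: int
) -> tuple[list[str], float]:
    """Select the ``n_target`` least-linked candidates.

    Each SNP's linkage score is its maximum pairwise r^2 against the
    current candidate set; the highest-scoring SNP is removed (ties broken
    by lower MAF, then lexicographically smaller id) until ``n_target``
    remain. Returns the selection (input order) and the maximum pairwise
    r^2 within it.
    """
    candidates = list(candidates)
    if n_target > len(candidates):
        raise ValueError(f"n_target {n_target} exceeds {len(candidates)} candidates")
    r2 = _r2_matrix(matrix, candidates)
    maf = {sid: allele_frequencies(matrix, sid).maf for sid in candidates}
    alive = list(candidates)
    while len(alive) > n_target:
        sub = r2.loc[alive, alive]
        scores = sub.max(axis=1)
        worst = scores.max()
        tied = sorted(scores.index[scores >= worst - 1e-15], key=lambda s: (maf[s], s))
        alive.remove(tied[0])
    max_r2 = float(r2.loc[alive, alive].to_numpy().max()) if len(alive) > 1 else 0.0
    selected = [sid for sid in candidates if sid in set(alive)]
    return selected, max_r2


def run_filter_cascade(
    catalog: SnpCatalog,
    criteria: FilterCriteria,
    locations: Mapping[str, str] | None = None,
) -> FilterReport:
    """Run the full cascade and report survivor counts per stage.

    Stage order: ``candidate_snps`` (all SNPs on polymorphic loci) ->
    ``quality_criteria`` (all predicates except the assay flank rule,
    jointly) -> ``least_linked`` (selection down to ``n_target`` when more
    survive) -> ``assay_flank`` (the flank-invariance rule, applied last as
    in assay design).
    """
    all_snps = [s.snp_id for s in catalog.snps]
    verdict_rows = {}
    for snp in catalog.snps:
        verdict_rows[snp.snp_id] = snp_quality_predicates(snp, catalog, criteria, locations)
    verdicts = (
        pd.DataFrame.from_dict(verdict_rows, orient="index")
        if verdict_rows
        else pd.DataFrame(columns=CRITERIA_ORDER)
    )

    stages: list[tuple[str, int, list[str]]] = [("candidate_snps", len(all_snps), all_snps)]

    quality_cols = [c for c in verdicts.columns if c != "flank"]
    survivors = [
        sid for sid in all_snps if len(verdicts) and bool(verdicts.loc[sid, quality_cols].all())
    ]
    stages.append(("quality_criteria", len(survivors), survivors))

    max_r2 = None
    if survivors and len(survivors) > criteria.n_target:
        selected, max_r2 = ld_rank_select(catalog.genotypes, survivors, criteria.n_target)
    else:
        selected = list(survivors)
        if len(selected) > 1:
            selected, max_r2 = ld_rank_select(catalog.genotypes, selected, len(selected))
    stages.append(("least_linked", len(selected), selected))

    final = [sid for sid in selected if bool(verdicts.at[sid, "flank"])] if selected else []
    stages.append(("assay_flank", len(final), final))

    return FilterReport(stages=stages, verdicts=verdicts, max_r2_selected=max_r2)
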