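"""Synthetic inputs with known ground truth for the whole pipeline.

Emulates a de novo reduced-representation catalog: loci with one or more
SNPs, two (or more) populations whose allele frequencies follow the
Balding-Nichols construction at a target F_st, a minor-allele-frequency
spectrum wide enough to exercise the MAF filter, linked SNP pairs,
monomorphic stacks, per-genotype missingness, Mendelian pedigrees,
replicate genotyping runs with dropout/drop-in/missing perturbations, and
Y-marker / mitochondrial assignment profiles. Every generator is fully
determined by its seed.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assignment import FAILED, NEGATIVE, POSITIVE, SexPanel, SpeciesTable
from .formats_io import MISSING, GenotypeMatrix, SnpCatalog, SnpRecord, canonical_call
from .replicate_qc import ErrorModel, ReplicateDesign

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic catalog.

    ``target_fst`` is the Balding-Nichols differentiation parameter
    (default 0.08, the observed north-south split in the motivating
    system); ``maf_spectrum`` is the (low, high) range of the uniform
    ancestral minor-allele frequency. ``n_individuals`` is the total count
    split evenly over populations.
    """

    n_loci: int
    n_individuals: int = 34
    locus_length: int = 150
    n_populations: int = 2
    target_fst: float = 0.08
    maf_spectrum: tuple[float, float] = (0.02, 0.5)
    frac_multi_snp_loci: float = 0.0
    frac_monomorphic: float = 0.0
    n_linked_pairs: int = 0
    linkage_copy_error: float = 0.02
    missing_rate: float = 0.0
    locations_per_population: int = 7
    min_flank: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_fst", "frac_multi_snp_loci", "frac_monomorphic",
                     "linkage_copy_error", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.target_fst >= 1.0:
            raise ValueError("target_fst must be below 1")
        lo, hi = self.maf_spectrum
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_spectrum must satisfy 0 < low <= high <= 0.5")
        if self.locus_length < 2 * self.min_flank + 1:
            raise ValueError("locus_length too short for plantable SNPs")
        n_special = (
            round(self.frac_multi_snp_loci * self.n_loci)
            + round(self.frac_monomorphic * self.n_loci)
            + 2 * self.n_linked_pairs
        )
        if n_special > self.n_loci:
            raise ValueError("special-locus fractions exceed the catalog size")


@dataclass
class TruthSet:
    """Ground truth behind a synthetic catalog or replicate run."""

    ancestral_freqs: dict[str, float]  # snp_id -> ancestral alt-allele frequency
    pop_freqs: pd.DataFrame  # index snp_id, columns population, alt-allele freq
    true_genotypes: GenotypeMatrix  # pre-missingness calls
    pedigree: dict[str, tuple[str | None, str | None]]
    error_events: list[tuple[str, str, str]]  # (sample, snp, type)
    true_sex: dict[str, str]
    true_species: dict[str, str]
    linked_pairs: list[tuple[str, str]] = field(default_factory=list)
    snp_alleles: dict[str, tuple[str, str]] = field(default_factory=dict)


def _random_locus(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(BASES, size=length))


def _balding_nichols(rng: np.random.Generator, p_anc: float, fst: float, k: int) -> np.ndarray:
    """Per-population allele frequencies: Beta with mean p and var p(1-p)F."""
    if fst == 0.0:
        return np.full(k, p_anc)
    c = (1.0 - fst) / fst
    return rng.beta(p_anc * c, (1.0 - p_anc) * c, size=k)


def _dosage_to_call(dos: int, ref: str, alt: str) -> str:
    if dos == 0:
        return canonical_call(ref, ref)
    if dos == 1:
        return canonical_call(ref, alt)
    return canonical_call(alt, alt)


def generate_catalog(config: SimConfig) -> tuple[SnpCatalog, TruthSet]:
    """Simulate a stack catalog with genotypes and full ground truth.

    Ancestral minor-allele frequencies are uniform on ``maf_spectrum``;
    population frequencies follow Balding-Nichols at ``target_fst``;
    genotypes are Hardy-Weinberg within population. Linked pairs copy a
    source SNP's genotype column, redrawing each genotype with probability
    ``linkage_copy_error``; multi-SNP loci carry a second SNP inside the
    flank window; monomorphic loci carry no SNP record. Missingness is
    applied uniformly at ``missing_rate`` after truth is recorded.
    """
    rng = np.random.default_rng(config.seed)

    # -- samples, populations, locations --------------------------------
    per_pop = [config.n_individuals // config.n_populations] * config.n_populations
    for i in range(config.n_individuals % config.n_populations):
        per_pop[i] += 1
    samples, pops, locations, sexes = [], [], [], []
    for k, n in enumerate(per_pop):
        pop = f"pop{k + 1}"
        for i in range(n):
            samples.append(f"{pop}_ind{i + 1:03d}")
            pops.append(pop)
            loc = i * config.locations_per_population // max(n, 1)
            locations.append(f"{pop}_loc{min(loc, config.locations_per_population - 1) + 1}")
            sexes.append("F" if i % 2 == 0 else "M")
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "sex": sexes,
            "location": locations,
            "population": pops,
            "replicate_source": "",
            "is_ntc": False,
        }
    )
    pop_of = dict(zip(samples, pops))

    n_mono = round(config.frac_monomorphic * config.n_loci)
    n_multi = round(config.frac_multi_snp_loci * config.n_loci)
    n_copy = config.n_linked_pairs
    n_plain = config.n_loci - n_mono - n_multi - n_copy
    if n_plain < n_copy:
        raise ValueError("not enough ordinary loci to serve as linked-pair sources")

    loci: dict[str, str] = {}
    snps: list[SnpRecord] = []
    calls: dict[str, list[str]] = {}
    truth_calls: dict[str, list[str]] = {}
    anc: dict[str, float] = {}
    pop_freq_rows: dict[str, list[float]] = {}
    snp_alleles: dict[str, tuple[str, str]] = {}
    linked_pairs: list[tuple[str, str]] = []

    pop_labels = [f"pop{k + 1}" for k in range(config.n_populations)]
    pop_index = np.array([pop_labels.index(p) for p in pops])

    def plant_snp(locus_seq: list[str], position: int, snp_id: str, locus_id: str,
                  p_pop: np.ndarray, ref: str, alt: str) -> np.ndarray:
        locus_seq[position] = ref
        snps.append(SnpRecord(snp_id, locus_id, position, ref, alt))
        dosages = rng.binomial(2, p_pop[pop_index])
        truth = [_dosage_to_call(int(d), ref, alt) for d in dosages]
        truth_calls[snp_id] = truth
        calls[snp_id] = list(truth)
        anc[snp_id] = np.nan  # set by caller
        pop_freq_rows[snp_id] = list(p_pop)
        snp_alleles[snp_id] = (ref, alt)
        return dosages

    def draw_alleles() -> tuple[str, str]:
        ref, alt = rng.choice(BASES, size=2, replace=False)
        return str(ref), str(alt)

    def draw_freqs() -> tuple[float, np.ndarray]:
        lo, hi = config.maf_spectrum
        p_anc = float(rng.uniform(lo, hi))
        p_pop = np.clip(
            _balding_nichols(rng, p_anc, config.target_fst, config.n_populations), 1e-6, 1 - 1e-6
        )
        return p_anc, p_pop

    locus_counter = 0
    plain_source_dosages: list[tuple[str, np.ndarray, np.ndarray]] = []  # (snp_id, dosages, p_pop)

    def new_locus() -> tuple[str, list[str]]:
        nonlocal locus_counter
        locus_counter += 1
        lid = f"locus_{locus_counter:05d}"
        return lid, _random_locus(rng, config.locus_length)

    # ordinary single-SNP loci
    for i in range(n_plain):
        lid, seq = new_locus()
        pos = int(rng.integers(config.min_flank, config.locus_length - config.min_flank))
        ref, alt = draw_alleles()
        p_anc, p_pop = draw_freqs()
        sid = f"snp_{locus_counter:05d}"
        dosages = plant_snp(seq, pos, sid, lid, p_pop, ref, alt)
        anc[sid] = p_anc
        loci[lid] = "".join(seq)
        plain_source_dosages.append((sid, dosages, p_pop))

    # linked copies of the first n_copy ordinary SNPs
    for k in range(n_copy):
        src_id, src_dos, src_p = plain_source_dosages[k]
        lid, seq = new_locus()
        pos = int(rng.integers(config.min_flank, config.locus_length - config.min_flank))
        ref, alt = draw_alleles()
        sid = f"snp_{locus_counter:05d}"
        seq[pos] = ref
        snps.append(SnpRecord(sid, lid, pos, ref, alt))
        redraw = rng.random(len(src_dos)) < config.linkage_copy_error
        fresh = rng.binomial(2, src_p[pop_index])
        dosages = np.where(redraw, fresh, src_dos)
        truth = [_dosage_to_call(int(d), ref, alt) for d in dosages]
        truth_calls[sid] = truth
        calls[sid] = list(truth)
        anc[sid] = anc[src_id]
        pop_freq_rows[sid] = list(src_p)
        snp_alleles[sid] = (ref, alt)
        loci[lid] = "".join(seq)
        linked_pairs.append((src_id, sid))

    # multi-SNP loci: second SNP inside the flank window of the first
    for i in range(n_multi):
        lid, seq = new_locus()
        pos1 = int(rng.integers(config.min_flank, config.locus_length - config.min_flank - 2))
        offset = int(rng.integers(1, min(config.min_flank, config.locus_length - config.min_flank - pos1)))
        pos2 = pos1 + offset
        for j, pos in enumerate((pos1, pos2)):
            ref, alt = draw_alleles()
            p_anc, p_pop = draw_freqs()
            sid = f"snp_{locus_counter:05d}" + ("" if j == 0 else "b")
            plant_snp(seq, pos, sid, lid, p_pop, ref, alt)
            anc[sid] = p_anc
        loci[lid] = "".join(seq)

    # monomorphic stacks: no SNP record
    for i in range(n_mono):
        lid, seq = new_locus()
        loci[lid] = "".join(seq)

    # missingness
    snp_ids = [s.snp_id for s in snps]
    if config.missing_rate > 0.0:
        for sid in snp_ids:
            mask = rng.random(len(samples)) < config.missing_rate
            col = calls[sid]
            for i in np.nonzero(mask)[0]:
                col[i] = MISSING

    gdf = pd.DataFrame(calls, index=samples, dtype=object) if snp_ids else pd.DataFrame(index=samples)
    tdf = pd.DataFrame(truth_calls, index=samples, dtype=object) if snp_ids else pd.DataFrame(index=samples)
    catalog = SnpCatalog(
        loci=loci, snps=snps, genotypes=GenotypeMatrix(gdf, validate=False), meta=meta
    )
    truth = TruthSet(
        ancestral_freqs=anc,
        pop_freqs=pd.DataFrame(pop_freq_rows, index=pop_labels).T if snp_ids else pd.DataFrame(),
        true_genotypes=GenotypeMatrix(tdf, validate=False),
        pedigree={},
        error_events=[],
        true_sex={s: ("female" if x == "F" else "male") for s, x in zip(samples, sexes)},
        true_species={s: "moose" for s in samples},
        linked_pairs=linked_pairs,
        snp_alleles=snp_alleles,
    )
    return catalog, truth


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

def generate_pedigree_genotypes(
    freqs: Mapping[str, tuple[str, str, float]],
    pedigree: Mapping[str, tuple[str | None, str | None]],
    seed: int,
) -> GenotypeMatrix:
    """Mendelian genotypes for a pedigree.

    ``freqs`` maps snp id to (ref, alt, alt frequency); ``pedigree`` maps
    each individual to its (parent1, parent2), either of which may be
    ``None``. Founders (and unspecified parents' gametes) are drawn from
    the population frequencies under Hardy-Weinberg; each offspring
    receives one uniformly chosen allele per specified parent. Raises on a
    pedigree cycle.
    """
    rng = np.random.default_rng(seed)
    members: set[str] = set(pedigree)
    for p1, p2 in pedigree.values():
        members.update(x for x in (p1, p2) if x is not None)

    ts = graphlib.TopologicalSorter()
    for child in sorted(members):
        parents = pedigree.get(child, (None, None))
        ts.add(child, *[p for p in parents if p is not None])
    try:
        order = list(ts.static_order())
    except graphlib.CycleError as exc:
        raise ValueError("cycle in pedigree") from exc

    snp_ids = list(freqs)
    # allele pairs stored as alt-dosage contributions per haplotype
    haplos: dict[str, dict[str, tuple[int, int]]] = {}
    for ind in order:
        parents = pedigree.get(ind, (None, None))
        geno: dict[str, tuple[int, int]] = {}
        for sid in snp_ids:
            _, _, p_alt = freqs[sid]
            alleles = []
            for parent in parents:
                if parent is None:
                    alleles.append(int(rng.random() < p_alt))
                else:
                    pa = haplos[parent][sid]
                    alleles.append(pa[int(rng.integers(0, 2))])
            geno[sid] = (alleles[0], alleles[1])
        haplos[ind] = geno

    rows = {}
    for ind in sorted(members):
        cells = []
        for sid in snp_ids:
            ref, alt, _ = freqs[sid]
            a1, a2 = haplos[ind][sid]
            cells.append(canonical_call(alt if a1 else ref, alt if a2 else ref))
        rows[ind] = cells
    df = pd.DataFrame.from_dict(rows, orient="index", columns=snp_ids)
    return GenotypeMatrix(df.astype(object), validate=False)


# ---------------------------------------------------------------------------
# replicate runs
# ---------------------------------------------------------------------------

@dataclass
class ReplicateRun:
    matrix: GenotypeMatrix
    events: list[tuple[str, str, str]]  # (replicate id, snp id, event type)


def generate_replicate_run(
    truth: GenotypeMatrix,
    error_model: ErrorModel,
    design: ReplicateDesign,
    seed: int,
    alleles: Mapping[str, tuple[str, str]] | None = None,
    ntc_ids: Sequence[str] = (),
) -> ReplicateRun:
    """Emit replicate rows of the source samples with injected errors.

    Each replicate cell is the source call perturbed independently:
    missing with ``missing_rate``; a heterozygote collapses to one of its
    homozygotes (allele uniform) with ``dropout_rate``; a homozygote gains
    the locus's other allele with ``dropin_rate``. NTC rows are all-missing
    apart from contamination events. Every non-missing logged event
    corresponds to exactly one discordant cell against truth.
    """
    rng = np.random.default_rng(seed)
    snp_ids = truth.snp_ids
    if alleles is None:
        alleles = {sid: tuple(truth.observed_alleles(sid))[:2] for sid in snp_ids}

    events: list[tuple[str, str, str]] = []
    rows: dict[str, list[str]] = {}
    for group in design.groups:
        if group.source_id not in set(truth.samples):
            raise ValueError(f"design references unknown sample {group.source_id}")
        source = truth.df.loc[group.source_id]
        for rid in group.replicate_ids:
            cells = []
            for sid in snp_ids:
                cell = source[sid]
                if cell == MISSING:
                    cells.append(MISSING)
                    continue
                u = rng.random()
                if u < error_model.missing_rate:
                    cells.append(MISSING)
                    events.append((rid, sid, "missing"))
                    continue
                het = cell[0] != cell[1]
                if het and u < error_model.missing_rate + error_model.dropout_rate:
                    kept = cell[int(rng.integers(0, 2))]
                    cells.append(canonical_call(kept, kept))
                    events.append((rid, sid, "dropout"))
                elif not het and u < error_model.missing_rate + error_model.dropin_rate:
                    pair = alleles.get(sid, ())
                    other = [a for a in pair if a != cell[0]]
                    if not other:
                        cells.append(cell)  # locus effectively monomorphic
                        continue
                    cells.append(canonical_call(cell[0], other[0]))
                    events.append((rid, sid, "dropin"))
                else:
                    cells.append(cell)
            rows[rid] = cells

    for nid in ntc_ids:
        cells = []
        for sid in snp_ids:
            if rng.random() < error_model.ntc_contamination_rate:
                ref, alt = alleles.get(sid, ("A", "C"))
                dos = int(rng.integers(0, 3))
                cells.append(_dosage_to_call(dos, ref, alt))
                events.append((nid, sid, "contamination"))
            else:
                cells.append(MISSING)
        rows[nid] = cells

    df = pd.DataFrame.from_dict(rows, orient="index", columns=snp_ids)
    return ReplicateRun(matrix=GenotypeMatrix(df.astype(object), validate=False), events=events)


def expected_het_fraction(maf_spectrum: tuple[float, float]) -> float:
    """Expected Hardy-Weinberg heterozygote fraction, MAF uniform on (lo, hi)."""
    lo, hi = maf_spectrum
    mean_p = (lo + hi) / 2.0
    mean_p2 = (hi - lo) ** 2 / 12.0 + mean_p**2
    return 2.0 * (mean_p - mean_p2)


def calibrated_error_model(
    overall_rate: float,
    maf_spectrum: tuple[float, float] = (0.25, 0.5),
    dropout_share: float = 2.0 / 3.0,
    missing_rate: float = 0.0,
) -> ErrorModel:
    """Error model whose marginal per-genotype error equals ``overall_rate``.

    Dropout applies only to heterozygotes and drop-in only to homozygotes,
    so the conditional rates are scaled by the expected genotype-class
    fractions under the MAF spectrum; ``dropout_share`` is the expected
    fraction of errors that are dropouts (2/3 by default).
    """
    h = expected_het_fraction(maf_spectrum)
    return ErrorModel(
        dropout_rate=dropout_share * overall_rate / h,
        dropin_rate=(1.0 - dropout_share) * overall_rate / (1.0 - h),
        missing_rate=missing_rate,
    )


# ---------------------------------------------------------------------------
# assignment profiles
# ---------------------------------------------------------------------------

def generate_marker_profiles(
    true_sex: Mapping[str, str],
    true_species: Mapping[str, str],
    sex_panel: SexPanel | None = None,
    species_table: SpeciesTable | None = None,
    failure_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Y-marker amplification and mitochondrial haplotype profiles.

    Males amplify the male haplotype with independent per-marker failures
    at ``failure_rate``; females never amplify. Species profiles draw one
    allele per marker from the species' allele set (uniform over an
    ambiguous cell, e.g. the roe deer A/C polymorphism).
    """
    sex_panel = sex_panel or SexPanel.default()
    species_table = species_table or SpeciesTable.default()
    rng = np.random.default_rng(seed)

    sex_rows = {}
    for sample, sex in true_sex.items():
        if sex == "male":
            sex_rows[sample] = [
                FAILED if rng.random() < failure_rate else POSITIVE for _ in sex_panel.markers
            ]
        else:
            sex_rows[sample] = [NEGATIVE] * len(sex_panel.markers)
    sex_df = pd.DataFrame.from_dict(sex_rows, orient="index", columns=list(sex_panel.markers))

    mito_rows = {}
    for sample, sp in true_species.items():
        if sp not in species_table.alleles:
            raise ValueError(f"unknown species label {sp!r} for sample {sample}")
        row = []
        for allele_set in species_table.alleles[sp]:
            choices = sorted(allele_set)
            row.append(choices[int(rng.integers(0, len(choices)))])
        mito_rows[sample] = row
    mito_df = pd.DataFrame.from_dict(mito_rows, orient="index", columns=list(species_table.markers))
    return sex_df, mito_df
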