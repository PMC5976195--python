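"""Sex determination, sympatric-species diagnosis and individual matching.

Sex is called from Y-chromosome presence markers: males carry a fixed
five-marker haplotype, females show no amplification, and a sample must
amplify at least three of the five markers to be called male. Species are
diagnosed against a mitochondrial allele table for five sympatric deer
species (moose, roe deer, red deer, fallow deer, reindeer); ambiguity is
reported explicitly, never silently resolved. Individual recaptures are
found by single-linkage clustering of near-identical multilocus genotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .formats_io import MISSING, GenotypeMatrix

POSITIVE, NEGATIVE, FAILED = "positive", "negative", "failed"


@dataclass(frozen=True)
class SexPanel:
    """Y-chromosome presence markers with the expected male haplotype."""

    markers: tuple[str, ...]
    male_haplotype: tuple[str, ...]
    min_positive: int = 3
    enabled: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.male_haplotype):
            raise ValueError("marker and haplotype lengths differ")
        if not self.enabled:
            object.__setattr__(self, "enabled", tuple(True for _ in self.markers))
        if len(self.enabled) != len(self.markers):
            raise ValueError("enabled flags must match marker count")

    @classmethod
    def default(cls) -> "SexPanel":
        """The packaged five-marker Y panel."""
        with resources.files("panelforge.data").joinpath("sex_panel.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
        return cls(
            markers=tuple(df["marker"]),
            male_haplotype=tuple(df["male_allele"]),
            enabled=tuple(df["enabled"].astype(str).str.lower() == "true"),
        )

    @property
    def active_markers(self) -> tuple[str, ...]:
        return tuple(m for m, e in zip(self.markers, self.enabled) if e)


@dataclass(frozen=True)
class SpeciesTable:
    """Per-species allele sets at the mitochondrial diagnostic markers."""

    species: tuple[str, ...]
    markers: tuple[str, ...]
    alleles: Mapping[str, tuple[frozenset[str], ...]]  # species -> per-marker allele sets

    def __post_init__(self) -> None:
        for sp in self.species:
            sets = self.alleles[sp]
            if len(sets) != len(self.markers):
                raise ValueError(f"{sp}: allele sets do not match marker count")
            for s in sets:
                if not s or not s <= set("ACGT"):
                    raise ValueError(f"{sp}: invalid allele set {s}")

    @classmethod
    def default(cls) -> "SpeciesTable":
        """The packaged five-species diagnostic table."""
        with resources.files("panelforge.data").joinpath("species_table.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
        markers = tuple(df.columns[1:])
        alleles = {
            row["species"]: tuple(frozenset(str(row[m]).split("/")) for m in markers)
            for _, row in df.iterrows()
        }
        return cls(species=tuple(df["species"]), markers=markers, alleles=alleles)


def assign_sex(
    y_profile: Mapping[str, str],
    autosomal_callrate: float,
    panel: SexPanel | None = None,
    callrate_threshold: float = 0.75,
) -> str:
    """Call sex from a Y-marker amplification profile.

    ``y_profile`` maps marker id to ``positive``/``negative``/``failed``.
    At least ``min_positive`` positives -> male; zero positives with an
    adequate autosomal call rate -> female; some but too few positives ->
    ambiguous; zero positives on a failing sample -> no_call.
    """
    panel = panel or SexPanel.default()
    missing = [m for m in panel.active_markers if m not in y_profile]
    if missing:
        raise ValueError(f"profile lacks markers: {missing}")
    positives = sum(1 for m in panel.active_markers if y_profile[m] == POSITIVE)
    if positives >= panel.min_positive:
        return "male"
    if positives == 0:
        return "female" if autosomal_callrate >= callrate_threshold else "no_call"
    return "ambiguous"


def assign_species(
    mito_profile: Mapping[str, str | None],
    table: SpeciesTable | None = None,
) -> tuple[set[str], list[tuple[str, int]]]:
    """Diagnose species from a mitochondrial marker profile.

    A species is compatible when every called allele belongs to its allele
    set; all compatible species are returned as a set. When none is
    compatible, the second element ranks species by mismatch count
    (nearest first) so novel haplotypes are flagged rather than
    force-assigned; it is empty otherwise.
    """
    table = table or SpeciesTable.default()
    called = {
        m: a for m, a in mito_profile.items() if m in table.markers and a not in (None, "", "N")
    }
    if not called:
        raise ValueError("no called species markers in profile")
    compatible: set[str] = set()
    mismatches: list[tuple[str, int]] = []
    for sp in table.species:
        sets = dict(zip(table.markers, table.alleles[sp]))
        mm = sum(1 for m, a in called.items() if a not in sets[m])
        if mm == 0:
            compatible.add(sp)
        mismatches.append((sp, mm))
    nearest = sorted(mismatches, key=lambda t: (t[1], t[0])) if not compatible else []
    return compatible, nearest


def species_difference_matrix(
    table: SpeciesTable | None = None,
) -> dict[tuple[str, str], tuple[int, int]]:
    """Pairwise (min, max) allele differences between species.

    For each marker the minimum difference is 0 when the two allele sets
    intersect (an allele choice can agree) and the maximum is 1 unless both
    sets are the same single allele; sums over markers give the per-pair
    range, matching brute-force enumeration over ambiguous-cell choices.
    """
    table = table or SpeciesTable.default()
    out: dict[tuple[str, str], tuple[int, int]] = {}
    for sp1 in table.species:
        for sp2 in table.species:
            lo = hi = 0
            for s1, s2 in zip(table.alleles[sp1], table.alleles[sp2]):
                if not (s1 & s2):
                    lo += 1
                if not (len(s1) == 1 and s1 == s2):
                    hi += 1
            out[(sp1, sp2)] = (lo, hi)
    return out


def match_individuals(
    matrix: GenotypeMatrix,
    max_mismatch: int = 2,
    min_overlap: int = 10,
) -> tuple[list[set[str]], pd.DataFrame]:
    """Cluster samples into putative individuals (recaptures).

    Two samples are linked when their genotypes disagree at no more than
    ``max_mismatch`` loci over at least ``min_overlap`` jointly called
    loci; clusters are the single-linkage (connected) components. Returns
    the clusters (sorted, deterministic) and a table of per-pair mismatch
    and overlap counts for the linked pairs.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    samples = matrix.samples
    df = matrix.df
    parent = {s: s for s in samples}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    rows = []
    arr = df.to_numpy(dtype=object)
    miss = df.eq(MISSING).to_numpy()
    for i, a in enumerate(samples):
        for j in range(i + 1, len(samples)):
            both = ~(miss[i] | miss[j])
            overlap = int(both.sum())
            if overlap < min_overlap:
                continue
            mism = int((arr[i][both] != arr[j][both]).sum())
            if mism <= max_mismatch:
                rows.append({"sample_a": a, "sample_b": samples[j], "mismatches": mism, "overlap": overlap})
                ra, rb = find(a), find(samples[j])
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[str, set[str]] = {}
    for s in samples:
        clusters.setdefault(find(s), set()).add(s)
    ordered = sorted(clusters.values(), key=lambda c: sorted(c)[0])
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "mismatches", "overlap"])
    return ordered, pairs
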