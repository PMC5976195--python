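"""Readers and writers for the formats the panel pipeline touches.

The central in-memory objects live here: a :class:`SnpCatalog` (de novo
loci with consensus sequences, SNP records and per-sample genotype calls,
standing in for a stack catalog), and a :class:`GenotypeMatrix` (samples x
SNPs diploid calls with explicit missingness).

Conventions used throughout the package:

* internal SNP positions are 0-based offsets within their locus; VCF POS is
  1-based and converted on read/write;
* a genotype cell is a two-character string of alphabetically ordered
  alleles (``"AC"``, never ``"CA"``); missing is ``"NN"``;
* alleles are single bases from ``{A, C, G, T}``;
* alphabetical allele order is the single canonical order everywhere
  (Genepop codes, genotype cells, assay brackets use ref first).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")
MISSING = "NN"

META_COLUMNS = ["sample_id", "sex", "location", "population", "replicate_source", "is_ntc"]


def canonical_call(allele1: str, allele2: str) -> str:
    """Return the two alleles as a canonical (alphabetically ordered) cell."""
    if allele1 not in VALID_BASES or allele2 not in VALID_BASES:
        raise ValueError(f"invalid alleles for a call: {allele1!r}/{allele2!r}")
    return "".join(sorted((allele1, allele2)))


@dataclass(frozen=True)
class SnpRecord:
    """A single biallelic SNP on a de novo locus."""

    snp_id: str
    locus_id: str
    position: int  # 0-based offset within the locus consensus
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(f"{self.snp_id}: alleles must be single bases from ACGT")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")
        if self.position < 0:
            raise ValueError(f"{self.snp_id}: negative position")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref_allele, self.alt_allele)

    def valid_cells(self) -> frozenset[str]:
        r, a = self.ref_allele, self.alt_allele
        return frozenset({canonical_call(r, r), canonical_call(r, a), canonical_call(a, a), MISSING})


class GenotypeMatrix:
    """Samples x SNPs matrix of diploid calls.

    Wraps a pandas DataFrame whose index is sample ids, columns SNP ids and
    cells canonical two-character calls (``"NN"`` for missing). Missing is a
    distinct state, never an allele.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if validate and df.size:
            values = df.to_numpy(dtype=object).ravel()
            for v in values:
                if not (isinstance(v, str) and len(v) == 2):
                    raise ValueError(f"genotype cell must be a 2-character string, got {v!r}")
                if v != MISSING and (v[0] not in VALID_BASES or v[1] not in VALID_BASES):
                    raise ValueError(f"invalid genotype cell {v!r}")
                if v != MISSING and (v[0], v[1]) != tuple(sorted(v)):
                    raise ValueError(f"genotype cell {v!r} is not in canonical allele order")
        self.df = df.copy()
        self.df.index.name = "sample_id"

    # -- basic accessors -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def call(self, sample: str, snp_id: str) -> str:
        return self.df.at[sample, snp_id]

    def is_missing(self) -> pd.DataFrame:
        return self.df == MISSING

    def column(self, snp_id: str) -> pd.Series:
        return self.df[snp_id]

    def observed_alleles(self, snp_id: str) -> list[str]:
        """Alphabetical list of alleles observed at a SNP (missing excluded)."""
        alleles: set[str] = set()
        for cell in self.df[snp_id]:
            if cell != MISSING:
                alleles.update(cell)
        return sorted(alleles)

    def dosage(self, snp_id: str, allele: str) -> pd.Series:
        """Copies of ``allele`` per sample (0/1/2), NaN where missing."""
        col = self.df[snp_id]
        dos = col.str.count(allele).astype(float)
        dos[col == MISSING] = np.nan
        return dos

    def het_mask(self, snp_id: str) -> pd.Series:
        """Boolean heterozygote indicator per sample; NaN-safe (missing False)."""
        col = self.df[snp_id]
        return (col != MISSING) & (col.str[0] != col.str[1])

    def subset(self, samples: Sequence[str] | None = None, snps: Sequence[str] | None = None) -> "GenotypeMatrix":
        df = self.df
        if samples is not None:
            df = df.loc[list(samples)]
        if snps is not None:
            df = df[list(snps)]
        return GenotypeMatrix(df, validate=False)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenotypeMatrix) and self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.shape[0]} samples x {self.shape[1]} SNPs)"


@dataclass
class SnpCatalog:
    """De novo locus catalog: consensus sequences, SNP records, genotypes.

    ``loci`` maps locus id to its consensus sequence (insertion order is the
    catalog order); ``meta`` is an optional sample-metadata table with the
    columns in :data:`META_COLUMNS`.
    """

    loci: dict[str, str]
    snps: list[SnpRecord]
    genotypes: GenotypeMatrix
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        snp_ids = set()
        for snp in self.snps:
            if snp.snp_id in snp_ids:
                raise ValueError(f"duplicate SNP id {snp.snp_id}")
            snp_ids.add(snp.snp_id)
            if snp.locus_id not in self.loci:
                raise ValueError(f"{snp.snp_id}: unknown locus {snp.locus_id}")
            if snp.position >= len(self.loci[snp.locus_id]):
                raise ValueError(f"{snp.snp_id}: position beyond locus length")
        if set(self.genotypes.snp_ids) - snp_ids:
            raise ValueError("genotype matrix contains SNPs absent from the catalog")
        by_id = {s.snp_id: s for s in self.snps}
        for sid in self.genotypes.snp_ids:
            allowed = by_id[sid].valid_cells()
            bad = set(self.genotypes.df[sid].unique()) - allowed
            if bad:
                raise ValueError(f"{sid}: genotype calls {sorted(bad)} use alleles outside ref/alt")

    @property
    def snp_by_id(self) -> dict[str, SnpRecord]:
        return {s.snp_id: s for s in self.snps}

    def snps_on_locus(self, locus_id: str) -> list[SnpRecord]:
        return [s for s in self.snps if s.locus_id == locus_id]


# ---------------------------------------------------------------------------
# catalog <-> VCF + FASTA
# ---------------------------------------------------------------------------

def write_catalog(catalog: SnpCatalog, vcf_path: str | Path, fasta_path: str | Path) -> tuple[Path, Path]:
    """Write a catalog as VCFv4.2 (GT-only FORMAT) + 60-column FASTA."""
    vcf_path, fasta_path = Path(vcf_path), Path(fasta_path)

    records = [SeqRecord(Seq(seq), id=locus_id, description="") for locus_id, seq in catalog.loci.items()]
    SeqIO.write(records, str(fasta_path), "fasta")

    header = pysam.VariantHeader()
    for locus_id, seq in catalog.loci.items():
        header.contigs.add(locus_id, length=len(seq))
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = catalog.genotypes.samples
    for s in samples:
        header.add_sample(s)

    order = {locus_id: i for i, locus_id in enumerate(catalog.loci)}
    snps = sorted(catalog.snps, key=lambda s: (order[s.locus_id], s.position))
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vf:
        for snp in snps:
            rec = vf.new_record(
                contig=snp.locus_id,
                start=snp.position,  # pysam start is 0-based; POS is written 1-based
                alleles=(snp.ref_allele, snp.alt_allele),
                id=snp.snp_id,
            )
            if snp.snp_id in set(catalog.genotypes.snp_ids):
                code = {
                    canonical_call(snp.ref_allele, snp.ref_allele): (0, 0),
                    canonical_call(snp.ref_allele, snp.alt_allele): (0, 1),
                    canonical_call(snp.alt_allele, snp.alt_allele): (1, 1),
                }
                for s in samples:
                    cell = catalog.genotypes.call(s, snp.snp_id)
                    rec.samples[s]["GT"] = (None, None) if cell == MISSING else code[cell]
            else:
                for s in samples:
                    rec.samples[s]["GT"] = (None, None)
            vf.write(rec)
    return vcf_path, fasta_path


def read_catalog(
    vcf_path: str | Path,
    fasta_path: str | Path,
    meta_path: str | Path | None = None,
) -> SnpCatalog:
    """Load a catalog from VCF + locus FASTA (+ optional sample metadata TSV)."""
    loci = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}

    snps: list[SnpRecord] = []
    calls: dict[str, dict[str, str]] = {}
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.chrom not in loci:
                raise ValueError(f"VCF CHROM {rec.chrom} has no FASTA entry")
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"record {rec.id or rec.chrom}:{rec.pos} is not biallelic")
            snp = SnpRecord(
                snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                locus_id=rec.chrom,
                position=rec.pos - 1,
                ref_allele=rec.ref.upper(),
                alt_allele=rec.alts[0].upper(),
            )
            snps.append(snp)
            col: dict[str, str] = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(i is None for i in gt) or len(gt) != 2:
                    col[s] = MISSING
                else:
                    try:
                        pair = tuple(snp.alleles[i] for i in gt)
                    except IndexError as exc:  # allele index beyond ref/alt
                        raise ValueError(f"{snp.snp_id}: malformed GT {gt} for sample {s}") from exc
                    col[s] = canonical_call(*pair)
            calls[snp.snp_id] = col

    df = pd.DataFrame(calls, index=samples) if samples else pd.DataFrame(
        {sid: pd.Series(dtype=object) for sid in calls}
    )
    matrix = GenotypeMatrix(df.astype(object) if df.size else df, validate=False)
    meta = read_sample_meta(meta_path) if meta_path is not None else None
    return SnpCatalog(loci=loci, snps=snps, genotypes=matrix, meta=meta)


# ---------------------------------------------------------------------------
# genotype table and sample metadata TSVs
# ---------------------------------------------------------------------------

def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.df.to_csv(path, sep="\t")
    return path


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    return GenotypeMatrix(df.astype(object))


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    meta.loc[:, META_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False)
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file lacks columns: {sorted(missing)}")
    meta["is_ntc"] = meta["is_ntc"].astype(str).str.lower().isin({"true", "1", "yes"})
    known = set(meta["sample_id"])
    bad = meta.loc[(meta["replicate_source"] != "") & ~meta["replicate_source"].isin(known)]
    if len(bad):
        raise ValueError(f"replicate_source names unknown samples: {sorted(bad['replicate_source'])}")
    return meta


# ---------------------------------------------------------------------------
# Genepop export
# ---------------------------------------------------------------------------

def write_genepop(
    matrix: GenotypeMatrix,
    populations: Mapping[str, str],
    path: str | Path,
    title: str = "panelforge export",
) -> Path:
    """Write the matrix in Genepop format (2-digit allele codes).

    Allele codes 01/02 follow alphabetical allele order per locus; a missing
    call is ``0000``. One ``Pop`` block per population, populations in
    sorted label order and samples in matrix order within each.
    """
    codes: dict[str, dict[str, str]] = {}
    for sid in matrix.snp_ids:
        alleles = matrix.observed_alleles(sid)
        if len(alleles) > 2:
            raise ValueError(f"{sid}: more than 2 alleles, Genepop export is biallelic-only")
        codes[sid] = {a: f"{i + 1:02d}" for i, a in enumerate(alleles)}

    lines = [title]
    lines.extend(matrix.snp_ids)
    for pop in sorted(set(populations[s] for s in matrix.samples if s in populations)):
        lines.append("Pop")
        for s in matrix.samples:
            if populations.get(s) != pop:
                continue
            fields = []
            for sid in matrix.snp_ids:
                cell = matrix.call(s, sid)
                if cell == MISSING:
                    fields.append("0000")
                else:
                    fields.append(codes[sid][cell[0]] + codes[sid][cell[1]])
            lines.append(f"{s} ,  " + " ".join(fields))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# assay-sequence export
# ---------------------------------------------------------------------------

def assay_sequence(catalog: SnpCatalog, snp_id: str, min_flank: int = 40) -> str:
    """Assay string for one SNP: flank, ``[ref/alt]``, flank.

    Exactly ``min_flank`` invariant consensus bases are emitted on each side.
    Raises if the SNP sits closer than ``min_flank`` to a locus edge or if
    another SNP falls inside the flank window.
    """
    snp = catalog.snp_by_id[snp_id]
    seq = catalog.loci[snp.locus_id]
    left_len = snp.position
    right_len = len(seq) - snp.position - 1
    if left_len < min_flank or right_len < min_flank:
        raise ValueError(
            f"{snp_id}: flank too short ({left_len} bp left, {right_len} bp right, need {min_flank})"
        )
    for other in catalog.snps_on_locus(snp.locus_id):
        if other.snp_id != snp_id and abs(other.position - snp.position) <= min_flank:
            raise ValueError(f"{snp_id}: SNP {other.snp_id} within the {min_flank} bp flank window")
    left = seq[snp.position - min_flank : snp.position]
    right = seq[snp.position + 1 : snp.position + 1 + min_flank]
    return f"{left}[{snp.ref_allele}/{snp.alt_allele}]{right}"


def export_assay_sequences(
    catalog: SnpCatalog,
    selected_snp_ids: Iterable[str],
    path: str | Path,
    min_flank: int = 40,
) -> Path:
    """Write a FASTA-like assay file, one bracketed record per selected SNP."""
    lines = []
    for sid in selected_snp_ids:
        lines.append(f">{sid}")
        lines.append(assay_sequence(catalog, sid, min_flank=min_flank))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
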