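import numpy as np
import pandas as pd
import pytest

from panelforge.formats_io import GenotypeMatrix, SnpCatalog, SnpRecord


def make_matrix(columns: dict[str, list[str]], samples: list[str] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from snp_id -> list-of-cells columns."""
    n = len(next(iter(columns.values())))
    samples = samples or [f"s{i + 1}" for i in range(n)]
    return GenotypeMatrix(pd.DataFrame(columns, index=samples, dtype=object))


def hwe_column(rng: np.random.Generator, n: int, p_alt: float, ref: str = "A", alt: str = "C") -> list[str]:
    """n Hardy-Weinberg calls at alt frequency p_alt."""
    genos = ["".join(sorted((ref, ref))), "".join(sorted((ref, alt))), "".join(sorted((alt, alt)))]
    return [genos[d] for d in rng.binomial(2, p_alt, size=n)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_catalog() -> SnpCatalog:
    """Three loci: one clean SNP, one flank-violating pair, one monomorphic."""
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))

    def seq(length, plant: dict[int, str]):
        s = list(rng.choice(bases, size=length))
        for pos, base in plant.items():
            s[pos] = base
        return "".join(s)

    loci = {
        "locA": seq(150, {75: "A"}),
        "locB": seq(150, {60: "G", 70: "T"}),
        "locC": seq(150, {}),
    }
    snps = [
        SnpRecord("snpA", "locA", 75, "A", "C"),
        SnpRecord("snpB1", "locB", 60, "G", "A"),
        SnpRecord("snpB2", "locB", 70, "T", "C"),
    ]
    samples = [f"s{i + 1}" for i in range(6)]
    df = pd.DataFrame(
        {
            "snpA": ["AA", "AC", "CC", "AC", "AA", "NN"],
            "snpB1": ["GG", "AG", "GG", "NN", "AA", "AG"],
            "snpB2": ["TT", "CT", "TT", "CC", "TT", "CT"],
        },
        index=samples,
        dtype=object,
    )
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "sex": ["F", "M"] * 3,
            "location": ["L1", "L1", "L2", "L2", "L3", "L3"],
            "population": ["pop1"] * 3 + ["pop2"] * 3,
            "replicate_source": [""] * 6,
            "is_ntc": [False] * 6,
        }
    )
    return SnpCatalog(loci=loci, snps=snps, genotypes=GenotypeMatrix(df), meta=meta)
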