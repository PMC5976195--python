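"""In-silico reduced-representation library design calculator.

Plans a restriction-enzyme digest from three inputs: the enzyme's IUPAC
recognition motif, the genome's GC content and its size. Cut sites are
modeled as a Poisson process along the genome, so fragment lengths are
exponential with mean 1/p_cut; the mass of genomic sequence carried by
fragments inside a size-selection window follows in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class DesignSummary:
    """Digest planning summary for one enzyme/genome combination."""

    motif: str
    gc_content: float
    genome_size: float
    cut_site_probability: float
    expected_fragment_length: float  # bp, = 1 / cut_site_probability
    expected_cut_count: float
    window: tuple[float, float]
    fraction_genome_in_window: float
    expected_breadth: float
    read_depth_target: float


def cut_site_probability(motif: str, gc_content: float) -> float:
    """Per-bp probability that a recognition motif starts at a position.

    Bases are independent with p(G) = p(C) = gc/2 and p(A) = p(T) =
    (1-gc)/2; an IUPAC degenerate code contributes the sum of its bases'
    probabilities.
    """
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must be in (0, 1)")
    base_p = {
        "G": gc_content / 2.0,
        "C": gc_content / 2.0,
        "A": (1.0 - gc_content) / 2.0,
        "T": (1.0 - gc_content) / 2.0,
    }
    prob = 1.0
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in motif {motif!r}")
        prob *= sum(base_p[b] for b in IUPAC[ch])
    return prob


def fraction_in_window(mean_fragment: float, lo: float, hi: float) -> float:
    """Fraction of genomic base mass on fragments with length in (lo, hi).

    Fragment lengths are exponential with mean mu; base-mass (length-
    biased) weighting gives
    ``[(lo + mu) e^(-lo/mu) - (hi + mu) e^(-hi/mu)] / mu``.
    ``hi`` may be ``math.inf``.
    """
    if lo < 0 or hi <= lo:
        raise ValueError("need 0 <= lo < hi")
    mu = mean_fragment
    upper = 0.0 if math.isinf(hi) else (hi + mu) * math.exp(-hi / mu)
    return ((lo + mu) * math.exp(-lo / mu) - upper) / mu


def digestion_summary(
    genome_size: float,
    gc_content: float,
    motif: str,
    window: tuple[float, float] = (300.0, 500.0),
    read_depth: float = 20.0,
) -> DesignSummary:
    """Plan a digest: cut count, fragment size, size-window breadth.

    The expected breadth of coverage is the window's base-mass fraction
    (every selected fragment is assumed sequenced; read-length effects are
    not modeled), with the read-depth target recorded alongside.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window min must be below window max")
    p = cut_site_probability(motif, gc_content)
    mu = 1.0 / p
    frac = fraction_in_window(mu, lo, hi)
    return DesignSummary(
        motif=motif.upper(),
        gc_content=gc_content,
        genome_size=genome_size,
        cut_site_probability=p,
        expected_fragment_length=mu,
        expected_cut_count=genome_size * p,
        window=(lo, hi),
        fraction_genome_in_window=frac,
        expected_breadth=frac,
        read_depth_target=read_depth,
    )
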