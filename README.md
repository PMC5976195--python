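# panelforge

Design and validation of SNP panels for individual identification in wild
populations, modeled on a moose (*Alces alces*) monitoring panel built
from reduced-representation sequencing.

Wildlife monitoring by genotyping needs a small marker panel that (a)
distinguishes every individual, including close relatives, (b) has a
measured, low genotyping error rate, and (c) carries auxiliary markers for
sex and for separating sympatric species in non-invasive samples.
`panelforge` implements that workflow end to end on a de novo variant
catalog:

1. **Digest planning** — Poisson/exponential arithmetic for a restriction
   digest (cut-site probability from GC content, expected fragment size,
   size-window breadth).
2. **Catalog simulation** — a Balding–Nichols two-population catalog with
   known ground truth (allele frequencies, pedigrees, linked pairs,
   injected genotyping errors), so every downstream stage is testable
   without any data download.
3. **Panel design** — the candidate-SNP filtering cascade (one SNP per
   locus, all three genotype classes, completeness ≥ 24/34, presence in
   all sampling locations, MAF > 0.2) followed by greedy least-linked
   selection on pairwise r² and a 40 bp invariant-flank assay check.
4. **Validation** — call-rate filtering (75%), replicate-based error
   rates with dropout/drop-in classification, exact Hardy–Weinberg tests,
   permutation LD tests, Weir–Cockerham F_st, heterozygosity, probability
   of identity:

       PI      = Σ p_i⁴ + Σ_{i<j} (2 p_i p_j)²
       PI_sibs = 0.25 + 0.5 Σp² + 0.5 (Σp²)² − 0.25 Σp⁴

   Lynch–Ritland and Ritland relatedness, and pruning of related pairs
   (r > 0.35).
5. **Assignment** — 3-of-5 Y-marker sex determination, five-species
   mitochondrial diagnostics (with explicit ambiguity reporting), and
   single-linkage recapture matching.

## Worked example

```
$ panelforge plan-digest --motif YGGCCR --gc 0.45 --genome-size 3e9 --window 300:500
{
  "cut_site_probability": 0.0006407226562500001,
  "expected_fragment_length": 1560.737692424935,
  "expected_cut_count": 1922167.9687500005,
  "fraction_genome_in_window": 0.02529868244410175,
  ...
}
```

Eae I (`YGGCCR`) on a 3 Gb genome at GC 0.45 cuts every ~1561 bp
(~1.92 million sites); a 300–500 bp size selection carries ~2.5% of the
genome, the expected breadth of coverage.

```
$ panelforge run-all --outdir demo --seed 3 --n-loci 400 --n-target 30
{
  "panel_size": 30,
  "error_overall": 0.0033503649635036497,
  "theta": 0.0676...
}
```

This simulates a 400-locus catalog for 34 individuals in two populations
(F_st 0.08), filters it down to a 30-SNP panel, runs a replicate
validation round (2 samples × 10 replicates + 12 × 2, plus three
no-template controls), and reports the recovered error rate (here 0.0034
against injected dropout/drop-in rates of 0.004/0.002), the
between-population θ, per-SNP statistics, PI/PI-sibs curves and
sex/species/recapture assignments in `demo/run_report.json`. Identical
`--seed` gives a byte-identical report.

In Python:

```python
from panelforge.popgen_stats import cumulative_pi_curve

curve = cumulative_pi_curve([[0.5, 0.5]] * 5, mode="unrelated")
print(curve[-1])        # 0.007415771484375 — five ideal loci resolve
                        # unrelated individuals below the 0.01 bound
```

See `docs/methods.md` for the models, defaults and their rationale.

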