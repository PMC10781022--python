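# finemapvi

Fine-mapping of GWAS loci from summary statistics, with optional
functional-annotation priors.

Genome-wide association studies report per-variant z-scores, but linkage
disequilibrium (LD) makes marginal association a poor guide to causality:
a locus may contain hundreds of correlated variants and several causal
ones.  `finemapvi` infers which variants are causal using only summary
statistics (z, N) and an LD matrix, for statistical geneticists who have
GWAS output and a matched LD panel but no individual-level data.

## Model

The trait is modelled as a sum of K single-effect components,

y ~ N(X S β, τ_y⁻¹ I),  s_k ~ Multinomial(1, π̃),  β_k ~ N(0, τ_β⁻¹),

where each one-hot s_k selects the variant carrying the k-th effect.
A paired mean-field variational algorithm fits the model from the
summary-level sufficient statistics (XᵀX ≈ N·R, Xᵀy ≈ z√N) with no
matrix inversion, so rank-deficient LD is fine.  Precisions τ_β, τ_y are
derived from a local-heritability estimate ĥ² = (zᵀR⁺z − p)/(N − p).
Outputs are variant-level posterior inclusion probabilities
PIP_g = 1 − Π_k(1 − γ_kg), and ρ-level credible sets reported only for
effect groups whose *attainable coverage* (posterior mass in LD r² ≥ 0.25
with the top variant) reaches ρ — diffuse groups are never reported.

Binary functional annotations enter through a softmax prior
π̃_g ∝ exp(A_gᵀw); enrichment weights w are estimated jointly from the
fine-mapping posteriors themselves (exp(w) is an annotation's
fold-enrichment among causal variants), screened by a G-test on
PIP-weighted soft counts (default p < 1e-5), and fed back as the prior
for a second pass.  A sliding-window driver (3-Mb windows, 1-Mb step,
central-1-Mb retention) scales the same machinery genome-wide.

A synthetic-data module simulates the whole pipeline offline —
LD-structured genotypes, annotation-enriched causal variants, a trait
with exact heritability, univariate GWAS — so every claim in the test
suite is checked against known ground truth.

## Worked example

`examples/02_functional_priors.py` simulates 12 loci of 200 variants for
25,000 individuals with 5 causal variants each, sampled preferentially
(log-odds W = 2) from 5 of 10 binary annotations, then estimates
enrichment jointly from the pooled posteriors and re-fine-maps:

```
joint enrichment estimates from pooled signal PIPs (G-test screens relevance):
 * anno0_enriched     w=+1.65 (fold  5.22)  p=3.51e-13
 * anno1_enriched     w=+1.78 (fold  5.91)  p=4.06e-12
 * anno2_enriched     w=+2.20 (fold  8.98)  p=2.20e-14
 * anno3_enriched     w=+1.05 (fold  2.85)  p=2.89e-09
 * anno4_enriched     w=+1.44 (fold  4.24)  p=1.22e-09
   anno5_null         w=+0.24 (fold  1.27)  p=9.60e-05
   ...
AUPRC ranking variants by PIP against true causal status (mean over the 12 loci):
  statistics only     : 0.675
  with informed prior : 0.919
```

All five truly enriched annotations pass the screen with weights near the
simulated log-odds 2 (folds ≈ 3–9× versus the simulated e² ≈ 7.4×); the
null annotations do not.  Feeding the estimated prior back raises the
area under the precision-recall curve for causal-variant ranking from
0.675 to 0.919.  `examples/01_finemap_locus.py` shows the single-locus
workflow (credible sets covering the true causal variants),
`03_genome_scan.py` the sliding-window scan, and `04_files_and_cli.py`
the file-based round trip.

## Command line

```sh
finemapvi simulate --g 200 --n 25000 --K 5 --W 2 --seed 1 --out locus
finemapvi finemap  --ss locus.ss.tsv --ld locus.ld.txt --anno locus.anno.tsv --out fm
finemapvi scan     --ss chrom.ss.tsv --ld chrom.ld.txt --chrom-length 5000000 --out gw
finemapvi evaluate --pip fm.pip.tsv --cs fm.cs.tsv --truth locus.truth.tsv
```

Summary statistics are whitespace-separated TSV with a header
(`SNP CHR POS A1 A2` plus `Z`+`N` or `BETA`+`SE`+`N`); LD is a plain-text
square matrix; annotations are a TSV of 0/1 indicators keyed by SNP.

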