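# polyratio

Analysis of miRNA target regulation from comparative light/heavy polysome
profiling, for transcriptome researchers studying translational control.

## The problem

miRNAs moderately inhibit translation of their target mRNAs, yet those
targets remain polysome-associated. Comparative polysome profiling of a
wild-type (WT) human cell line and its isogenic DICER1-knockout mutant
(MT, deficient in mature miRNA production) resolves the paradox: targeted
mRNAs are enriched in translationally less-active *light* polysomes (2–9
ribosomes) relative to more-active *heavy* polysomes (≥10 ribosomes).
Detecting this requires controlling for ORF length, because a longer open
reading frame accommodates more ribosomes and depresses the light/heavy
ratio regardless of miRNA regulation — and miRNA-targeted mRNAs tend to
have longer ORFs.

`polyratio` implements that analysis as a tested, reusable pipeline over
four RNA-seq count libraries (WT light, WT heavy, MT light, MT heavy):

1. **Raw ratios** — per gene, `r_WT = log2(WT_L / WT_H)` and
   `r_MT = log2(MT_L / MT_H)` on pseudocounted counts-per-million, after
   an expression filter.
2. **ORF-length adjustment** — LOESS (tricube-weighted local quadratic,
   span 0.75, implemented from scratch and verified against a per-point
   weighted-least-squares oracle) of each ratio on log2 ORF length; the
   **residual** is the adjusted ratio, with the fit's R² reported.
3. **Double adjustment** — `adj_WT − adj_MT`, cancelling
   miRNA-independent regulation shared by the isogenic lines.
4. **Statistics** — targeted (>50 conserved miRNA-family 3′-UTR sites) vs
   untargeted (no site) comparisons (Welch t, variance-ratio F), an
   empirical null from 1000 random same-size gene samples, per-site-count
   trend summaries with a linearity measure, and mean-ORF-length-by-site-
   count profiles.
5. **Enrichment** — standardized mean-rank gene-set scores of the
   double-adjusted ratio against GMT collections, with permutation
   p-values.
6. **Synthetic data** — a calibrated generator (log-normal ORFs,
   geometric exponential-tail site counts optionally coupled to ORF
   length, a planted per-unit-log2(sites+1) WT ratio shift β, separate
   WT/MT noise, negative-binomial counts) whose defaults define the
   study conditions under which every guarantee is tested.

The core statistic in field notation: with LOESS fit
`f̂(x) = argmin_local Σ w_i (r_i − P_d(x_i))²` (tricube `w`, degree
`d = 2`), the adjusted ratio is `a_i = r_i − f̂(log2 L_i)` and the double-
adjusted ratio `Δ_i = a_i^WT − a_i^MT`, regressed and ranked against
`log2(s_i + 1)` where `s_i` counts distinct conserved miRNA families in
the 3′-UTR.

## Worked example

```python
from polyratio import SimulationConfig, run_full_analysis

res = run_full_analysis(SimulationConfig(seed=7), run_enrichment=False)
lin = res.trend_linearity
print(len(res.ratios), res.ratios.attrs["r2_wt"], res.ratios.attrs["r2_mt"])
print(res.comparison_raw.t_pvalue, res.comparison_adj.t_pvalue)
print(res.null.observed_mean, res.null.max_sample_mean)
print(lin.slope, lin.pearson_r)
```

prints (formatted):

```
genes analyzed: 11886
LOESS R^2 (WT, MT): 0.235  0.722
raw  WT ratio,  >50 sites vs no site: diff=0.622  Welch p=2.92e-08
adj. WT ratio,  >50 sites vs no site: diff=2.042  Welch p=5.88e-38
sampling null: observed=1.352  max of 1000 sample means=0.348  p=0.0010
double-adjusted trend: slope=0.380  r=0.979
```

Reading: ORF length explains less ratio variance in WT than in the
miRNA-deficient mutant (R² 0.235 vs 0.722) because miRNA activity is an
extra determinant in WT only; removing the ORF trend widens the
targeted-vs-untargeted separation by thirty orders of magnitude in p; the
targeted-group mean (1.352) towers over the best of 1000 random same-size
samples (0.348); and the double-adjusted ratio rises near-linearly with
log2(site count + 1) (r = 0.979; the slope 0.38 sits below the planted
β = 0.5 because site count and ORF length are coupled under the default
conditions, so the ORF adjustment absorbs part of the miRNA signal — with
the coupling disabled the slope recovers β within ±0.1).

The same pipeline is scriptable from the shell:

```sh
polyratio all --seed 7 --out-dir runs/demo          # synthetic end-to-end
polyratio ratios --htseq WT_L.tsv WT_H.tsv MT_L.tsv MT_H.tsv \
    --genes genes.tsv --out-dir runs/real           # real count tables
polyratio adjust --ratios runs/real/ratios.tsv --out-dir runs/real
polyratio enrich --ratios runs/real/ratios_adjusted.tsv \
    --gmt kegg.gmt --seed 1 --out-dir runs/real
```

Each stage writes TSV/JSON artifacts plus a provenance record (config,
seeds, versions, input checksums).

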