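# gbsdiv

Genetic diversity analysis of highly incomplete, unordered SNP genotype
data — and an assessment harness for how badly missingness and genotype
imputation bias it.

Genotyping-by-sequencing (GBS) panels routinely arrive with 50–90% of
genotype calls missing, and for non-model species the markers are not
ordered along a reference, so haplotype-based imputation is off the table.
`gbsdiv` is for population geneticists and genebank curators who must
decide, before analysing such a panel, whether to analyse the missing data
as-is or to impute — and what that choice does to their estimates.

The package provides:

* **missing-aware estimators** — per-locus allele frequencies
  p = (2N₁ + N₂)/2n from observed cells only; Ho = N₂/n;
  He = 1 − p² − (1−p)²; F = (He − Ho)/He; and one-level AMOVA
  Φst = Vₐ/(Vₐ + V_w) on squared allele-count distances with an
  L/L_valid rescaling for missing loci;
* **three map-independent imputers** — random-forest regression (RF),
  probabilistic PCA fitted by EM (PP), and NIPALS PCA whose regressions
  skip missing cells (NI) — all binned to genotypes by the rule
  estimate ≤ 1.5 → 1, ≤ 2.5 → 2, else 3;
* **tree inference** — simple-matching-coefficient distances,
  neighbor-joining with deterministic tie handling, and unrooted quartet
  comparison for topology accuracy;
* **a simulation harness** — mask the panel at missing levels
  m = 0.1 … 0.9, subsample lines × markers, impute, re-estimate, and
  tabulate means, SDs, relative biases, topology accuracy, and cell-level
  imputation accuracy split by the original genotype class;
* **a synthetic panel generator** — Balding–Nichols group differentiation,
  an inbreeding F-model, and three empirical minor-allele-frequency
  regimes, so the whole pipeline is testable with no external data.

## Worked example

Simulate a selfing four-group panel, estimate its diversity, then assess
what 30% and 70% random missingness do with and without PP imputation:

```sh
gbsdiv simulate --n-groups 4 --lines-per-group 30 --n-markers 800 \
    --fst-target 0.03 --f-is 0.98 --seed 7 --out-prefix panel
gbsdiv stats --input panel_genotypes.tsv --groups panel_groups.tsv --out-prefix panel
# ho=0.00701, he=0.358, f=0.9799, n_loci_used=800, phi_st=0.03006
gbsdiv assess --input panel_genotypes.tsv --groups panel_groups.tsv \
    --levels 0.3,0.7 --runs 5 --lines 60 --markers 300 \
    --methods NONE,PP --seed 1 --out-dir out
```

`out/summary.csv` (selected columns):

```
 level   method  he_mean  phi_st_mean  topo_accuracy  acc_m_mean  bias_he_mean
   0.3     NONE   0.3519       0.0282           60.0         NaN       -0.4545
   0.3 ORIGINAL   0.3535       0.0267            NaN         NaN        0.0000
   0.3       PP   0.3415       0.0258           60.0     41.9314       -3.4184
   0.7     NONE   0.3400       0.0361           60.0         NaN       -4.1492
   0.7 ORIGINAL   0.3547       0.0320            NaN         NaN        0.0000
   0.7       PP   0.3271       0.0364           20.0     44.0688       -7.7601
```

Reading it: the simulated panel is highly inbred (Ho ≈ 0.7%, F ≈ 0.98)
with weak four-group structure (Φst ≈ 3%).  Without imputation (`NONE`),
He drifts down as missingness grows (−0.5% at m = 0.3, −4.1% at m = 0.7 —
the small-sample bias of p̂), while Φst stays within noise of the
original-data value; quartet topology accuracy degrades.  PP imputation
recovers ~42–44% of masked genotypes on this structure-poor panel, and its
estimates are *more* biased than simply tolerating the missing cells —
the central practical warning this package operationalizes.

The same operations are importable (`gbsdiv.run_assessment`,
`gbsdiv.het_stats`, `gbsdiv.amova_phi`, …); the CLI is a thin wrapper.
Genotype matrices are TSVs with a `line_id` column and 1/2/3/NA cells
(`gbsdiv.vcf_to_matrix` imports biallelic VCF); groups are two-column
TSVs.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end assessment from scratch: it generates
the default synthetic world, runs the reduced sweep (missing levels
0.1/0.5/0.9, unimputed and PP-imputed paths, 10 runs), writes the summary
table beside the JSON output, and emits the results JSON.
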