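# tapa — trans-ancestry pathway analysis of GWAS summary statistics

`tapa` tests whether a pathway (gene set) is associated with a trait
by combining GWAS **summary statistics from multiple ancestry groups**
— European, East Asian, African, … — without individual-level study
data. It addresses the self-contained null hypothesis: *no SNP
assigned to the pathway is associated with the outcome in any of the
populations.* Per-ancestry LD is taken from reference genotype panels
(e.g. 1000 Genomes subsets). The intended users are statistical
geneticists running gene-set analyses on published multi-ancestry
GWAS.

## The statistics

The core engine is the **adaptive rank truncated product (ARTP)**: for
component p-values p₍₁₎ ≤ … ≤ p₍q₎ (SNPs in a gene, then genes in a
pathway) and candidate truncation points c₁ < … < c_K it forms
w_k = −Σ_{i≤c_k} log p₍ᵢ₎, converts each w_k to an empirical p-value
ξ_k against M null replicates of the z-score vector drawn from
N(0, V⁽ˡ⁾) — V⁽ˡ⁾ estimated from the ancestry-l reference panel — and
calibrates the minP statistic T = min_k ξ_k against the same
replicates. The replicate-level p-values are reused across the
SNP → gene → pathway hierarchy, so one pool of M draws calibrates
everything.

Cross-ancestry evidence is merged at three levels:

* **SNP-centric** — per-SNP statistics across the L studies:
  inverse-variance-weighted z (SNP-IVW), max |z| (SNP-max), or the
  weighted Fisher combination with gamma shapes proportional to
  effective sample size (SNP-wFisher);
* **gene-centric** — per-ancestry ARTP gene p-values combined by
  weighted Fisher (Gene-wFisher) or minimum (Gene-minP);
* **pathway-centric** — per-ancestry ARTP pathway p-values combined by
  weighted Fisher (Path-joint), alongside the single-ancestry results
  (Path-EUR, …);

plus the **ACAT-IVW-wFisher** composite, an equal-weight Cauchy
combination of the SNP-IVW and Gene-wFisher pathway p-values that is
robust to their dependence.

A multi-ancestry GWAS **simulator** (`tapa.simulate`) generates the
five-population case-control (or continuous-outcome) study design the
methods assume — population-specific allele frequencies and LD,
reference panels, per-SNP regression summaries — and drives the
packaged Type I error and power studies.

## Worked example

Simulate a small null fixture and analyze it:

```bash
tapa simulate --profile null --seed 3 --scale 0.05 -o fixture/
tapa run -c fixture/config.yaml --m-replicates 1000 --seed 5 -o results/
```

`results/pathway_results.tsv` then contains one row per method
(tab-separated; long selected_genes lists truncated here):

```
pathway            method            p_value              J   best_threshold  selected_genes
SYNTHETIC_PATHWAY  SNP-IVW           0.3196803196803197   20  6               G010;G019;G001;G007;G016;G005
SYNTHETIC_PATHWAY  SNP-max           0.6093906093906094   20  9               G019;G008;G012;...
SYNTHETIC_PATHWAY  SNP-wFisher       0.25074925074925075  20  1               G019
SYNTHETIC_PATHWAY  Path-AFR          0.23376623376623376  20  2               G019;G012
SYNTHETIC_PATHWAY  Path-AMR          0.7952047952047953   20  1               G013
SYNTHETIC_PATHWAY  Path-EAS          0.7162837162837162   20  2               G010;G017
SYNTHETIC_PATHWAY  Path-EUR          0.2867132867132867   20  3               G000;G008;G007
SYNTHETIC_PATHWAY  Path-SAS          0.2627372627372627   20  4               G007;G012;G004;G019
SYNTHETIC_PATHWAY  Path-joint        0.5325465614048621   20
SYNTHETIC_PATHWAY  Gene-wFisher      0.3626373626373626   20  6               G019;G007;G008;G000;G012;G010
SYNTHETIC_PATHWAY  Gene-minP         0.4885114885114885   20  9               G019;G000;G007;...
SYNTHETIC_PATHWAY  ACAT-IVW-wFisher  0.3403665361744834   20
```

Reading the row for SNP-IVW: the pathway p-value is 0.32 on the
resampling grid (M + 1 = 1001 values, hence 320/1001), J = 20 genes
carried analyzable SNPs, and the minP statistic was attained at
gene-level truncation d = 6 — the 6 genes with the smallest
trans-ancestry gene p-values (listed in `selected_genes`) drive
whatever signal there is. Under this null simulation all methods are,
correctly, far from significance. `gene_pvalues.json` holds the per-gene p-values;
`manifest.json` records the seed, M, and the Bonferroni threshold
0.05/(number of pathways analyzed).

The simulation studies are exposed the same way:

```bash
tapa calibrate --n-datasets 1000 -o study/   # Type I error table
tapa power --setting common --beta 0.12 -o study/
```

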