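# hybridqg

Quantitative genetics of immortalized-F2 hybrid populations derived from
biparental doubled-haploid (DH) panels: simulation with known ground truth,
marker QC and hybrid-genotype inference, relationship kernels, GCA/SCA
variance decomposition, kinship-corrected QTL scans (including a full
two-locus epistasis scan with permutation thresholds), and multi-kernel
genomic prediction with the estimation/test cross-validation scheme used in
hybrid breeding studies.

## Modules

| module | contents |
| --- | --- |
| `hybridqg.simdata` | DH meiosis simulator (Haldane map function), crossing designs, multi-environment trait simulation with per-class G×E, calibration to target variance components, independent-validation scenario |
| `hybridqg.genotype` | hybrid genotype inference from inbred parents, MAF/missingness filters, perfect-LD deduplication, F∞-metric design matrices, minimal VCF reader |
| `hybridqg.kernels` | Rogers-distance kinship, shrinkage additive/dominance relationship matrices, Gaussian kernel |
| `hybridqg.phenostat` | outlier screening, adjusted entry means (within/across environments), one-step GCA/SCA REML model, broad-sense heritability |
| `hybridqg.gwas` | P3D/exact single-marker additive+dominance scans, Bonferroni–Holm, 2D epistasis scan, permutation thresholds, sequential explained variance, QTL-based cross-validated accuracy |
| `hybridqg.predict` | multi-kernel GBLUP (REML), prediction of untested hybrids, cross-validation over A / A+D / A+D+E models, independent validation, Bayesian variance partition (Gibbs) |
| `hybridqg.pipeline` | end-to-end orchestration from one YAML config with a reproducibility manifest |

## CLI

```bash
hybridqg template > run.yaml          # config template with all defaults
hybridqg run --config run.yaml       # simulate -> QC -> means -> scan -> predict
hybridqg simulate --out-dir sim/ --seed 7
hybridqg qc --geno sim/geno.tsv --maf 0.05 --miss 0.05 --dedup \
            --out filtered.tsv --report qc.json
hybridqg kernels --geno filtered.tsv --out-dir K/
hybridqg adjust --pheno sim/pheno.tsv --across --out means.tsv
hybridqg varcomp --pheno sim/pheno.tsv --pedigree sim/crosses.tsv \
                 --geno sim/geno.tsv --out vc.json
hybridqg scan --means means_within.tsv --geno filtered.tsv \
              --kinship K/kinship.tsv --alpha 0.1 --out scan.tsv
hybridqg cv --means means.tsv --geno filtered.tsv --h2 0.47 --out cv.json
```

All tabular artifacts are plain TSV; genotype files carry a `#group` header
line labeling individuals as `inbred` or `hybrid`.

## Conventions

* Genotype codes: −1 / 0 / +1 (homozygote, heterozygote, homozygote), `NA`
  missing. Inbred rows never contain heterozygotes; hybrid codes are the
  parental mean.
* F∞ metric: additive design = code, dominance design = heterozygote
  indicator.
* GCA components are reported on the hybrid scale (both parental
  contributions summed), so `sigma2_genotype = sigma2_gca + sigma2_sca`
  for the hybrid population.
* Every stochastic routine takes an explicit seed; a single master seed is
  split into named per-stage streams, so toggling one pipeline stage never
  shifts another stage's randomness.
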