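# aisnp

Evaluation of ancestry-informative SNP (AISNP) panels and continental
ancestry inference from unlinked biallelic genotypes.

The package covers the full analysis chain for a small forensic ancestry
panel:

- **genotype_io** — VCF / TSV genotype matrices, population manifests,
  allele-frequency tables, one-vs-rest pooling.
- **synthetic_data** — Balding–Nichols population simulator: drifted
  allele frequencies, HWE genotypes, Dirichlet-admixed cohorts and NGS
  allele-depth tables, all reproducible from one seed.
- **coverage_qc** — depth of coverage (DOC), allele coverage ratio (ACR)
  over heterozygous calls, detection/interpretation threshold flags.
- **divergence_metrics** — per-locus δ (one-vs-rest allele-frequency
  difference), Nei Gst (with an optional Weir–Cockerham comparison) and
  Rosenberg's informativeness-for-assignment (In).
- **locus_stats** — exact Hardy–Weinberg test with Bonferroni threshold,
  MAF / Ho / He, two-locus EM haplotype frequencies and LD r², forensic
  parameters (MP, PD, PIC, PE) with panel-level CPD / CPE.
- **ancestry_classifier** — naive-Bayes assignment with HWE genotype
  likelihoods, Laplace-smoothed training frequencies, deterministic
  leave-one-out cross-validation (confusion matrices) and external-cohort
  classification.
- **population_structure** — Nei DA distances, multi-locus pairwise Fst,
  neighbor-joining trees with newick output, population- and
  individual-level PCA.
- **admixture_model** — unsupervised maximum-likelihood admixture (Q / F)
  fitted by monotone EM with a ΔLL < 1e-4 termination rule, best-of-seeds
  over K ranges.

## CLI

All analyses are exposed through the `aisnp` command; outputs are plain
TSV / VCF / newick / `.Q` / `.P` files.

```sh
# generate a synthetic 4-source + admixed-cohort dataset
aisnp simulate --out-dir data/sim --seed 1 --n-loci 30 --n-per-pop 100

# divergence, locus and forensic statistics + text summary
aisnp evaluate-panel --genotypes data/sim/genotypes.tsv \
    --manifest data/sim/manifest.tsv --depths data/sim/depths.tsv \
    --out-dir results/eval

# leave-one-out confusion matrix (optionally classify an extra cohort)
aisnp classify --genotypes data/sim/genotypes.tsv \
    --manifest data/sim/manifest.tsv --out-dir results/cls

# DA / Fst matrices, NJ tree, PCA scores, admixture Q/F for K=2..6
aisnp structure --genotypes data/sim/genotypes.tsv \
    --manifest data/sim/manifest.tsv --k-min 2 --k-max 6 \
    --seed 1 --out-dir results/structure
```

`aisnp simulate` also accepts a YAML config (`--config`) describing
populations (label, super-label, size, drift), admixed cohorts
(Dirichlet α) and the depth model; see `aisnp simulate --help`.

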