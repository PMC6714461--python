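# nilqtl

QTL mapping toolkit for nearly-isogenic backcrossed yeast lineages. It
implements the full analysis path used to dissect stuck wine fermentation in
a backcross population:

- **`nilqtl.core_io`** — strict readers/writers for every table the pipeline
  touches: genotype matrices (segregant × marker calls over `{B, G, NA}`),
  SNP tables (single-sample VCF 4.x subset or TSV), marker panels, phenotype
  tables, CO₂ curves (CSV), and linkage-scan results. All coordinates are
  1-based inclusive; the BED export is the only 0-based surface.
- **`nilqtl.simulate`** — synthetic data with the statistical structure the
  analysis assumes: parental SNP sets with a configurable shared fraction,
  Haldane-map meiosis yielding fully homozygous diploid segregants, recurrent
  backcross programs with phenotypic selection, additive QTL phenotypes,
  logistic CO₂ curves, and noisy tiling-array prediction tables.
- **`nilqtl.kinetics`** — loess-style (tricube local quadratic) curve
  smoothing and kinetic trait extraction (CO2max, lag phase, T35/T50/T70
  against an expected maximum of 125 g/L, rate between T50 and T70), plus
  broad-sense heritability and Bonferroni-corrected Pearson trait
  correlations.
- **`nilqtl.markers`** — marker-panel construction: z-score signal
  segmentation into SNP predictions, sequencing-SNP quality filtering
  (QUAL ≥ 30, GQ ≥ 20, homozygous), window matching of predictions against
  sequencing with FDR reporting, parental-origin assignment, occurrence
  counting in extreme segregants, introgressed-region clustering, and
  read-per-kb deletion flagging.
- **`nilqtl.linkage`** — Mendelian segregation QC (1:1 χ²), the per-marker
  two-sided Wilcoxon–Mann–Whitney scan (exact for small tie-free samples,
  tie/continuity-corrected normal approximation otherwise), genome-wide
  max-statistic permutation thresholds at the 5%/10% levels, Type-II ANOVA
  variance decomposition for one or two loci, extreme-segregant selection,
  and sequential-cross design (fixing mapped QTLs to expose minor ones).
- **`nilqtl.effects`** — c.-notation CDS variants (substitution, deletion,
  insertion with 3′-rule normalization), translation, and protein-consequence
  classification (synonymous / missense / nonsense / frameshift / no-stop)
  with HGVS-style `p.` notation, e.g. `p.Ser77fsTer95`, `p.Tyr372*`.
- **`nilqtl.pipeline`** — end-to-end orchestration
  (simulate → kinetics → validate → scan → annotate) with a seeded,
  checksum-based reproducibility manifest and stage resumption.

## Command line

```bash
nilqtl run --out out/                      # full demo pipeline (seeded)
nilqtl simulate --seed 42 --out out/       # population only
nilqtl kinetics --curves curves/ --expected-max 125 --out traits.tsv
nilqtl validate-markers --predictions p.tsv --wgs-b b.vcf --wgs-g g.vcf \
    --window 20 --out validated
nilqtl scan --genotypes g.tsv --phenotypes p.tsv --trait RS \
    --n-perm 1000 --seed 7 --out scan.tsv
nilqtl annotate --cds cds.fasta --variant "c.229_230delTC"
```

The demo pipeline simulates 77 fully homozygous segregants from a 4×
backcross with two selected QTLs, extracts kinetic traits from simulated CO₂
curves, reconciles simulated tiling predictions against parental SNP sets,
runs the permutation-thresholded linkage scan, and annotates a demo variant,
writing a `manifest.json` with per-stage checksums. Re-running with the same
config and seed reproduces byte-identical outputs.

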