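# sweepscan

Selective-sweep scanning on phased three-population haplotype data
(two domesticated breeds plus a wild outgroup):

- **PBS scan** — Hudson-style F<sub>ST</sub> (`1 − π_w/π_t`) per population
  pair in sliding windows of 200 SNPs (step 50), transformed by
  `T = −ln(1 − F_ST)` and combined into per-population branch lengths
  `PBS_1 = (T_12 + T_13 − T_23)/2`.
- **iHS scan** — EHH decay from each core SNP (breed MAF > 0.2, derived
  allele polarized as the minor-or-absent allele in the outgroup),
  trapezoid-integrated to iHH with truncation at EHH < 0.05; raw score
  `ln(iHH_A/iHH_D)` standardized to mean 0 / variance 1 within
  derived-allele-frequency classes.
- **H statistic** — number of distinct haplotypes in bins of 30 sites
  variable within a population.
- **Gene outliers** — signals mapped to genes with a 1 kb flank, strongest
  signal per gene, top-1% calling anchored to the full annotated-gene
  universe (19,990 genes → 200 candidates).
- **QTL enrichment** — overlap of outlier genes with QTL-candidate genes
  (QTL < 5 cM, de-duplicated; four categories), tested by uniform gene-set
  resampling (hypergeometric null) with Bonferroni correction over
  subcategories.
- **Synthetic data** — a structured-coalescent simulator (no recombination,
  infinite sites) and a forward Wright–Fisher simulator (recombination,
  finite sites, migration, optional complete/partial sweeps) sharing one
  two-split / two-bottleneck demography, plus toy gene/QTL tracks and
  ground-truth records.

## Command line

```bash
# simulate a forward replicate with a planted sweep
sweepscan simulate forward --model model.yaml --sweeps sweeps.yaml \
    --seed 1 --region-length 300000 --out-prefix sim

# scans
sweepscan pbs-scan --haps sim.haps.txt --window 200 --step 50 --out pbs.tsv
sweepscan ihs-scan --haps sim.haps.txt --breed breed1 --out ihs.tsv
sweepscan h-stat   --haps sim.haps.txt --population breed1 --out h.tsv

# enrichment from explicit tables
sweepscan qtl-enrich --outliers outliers.txt --genes genes.bed \
    --qtl qtl.tsv -B 100000 --seed 1 --out enrich.tsv

# everything from one YAML config into a run directory
sweepscan run-all --config config.yaml --out-dir run/
```

Input formats: phased VCF 4.x (GT with `|`), an internal one-line-header
haplotype text format, BED-like gene tables (0-based half-open) and
tab-separated QTL tables (`chrom  start  stop  category  subcategory
size_cm`). All in-memory coordinates are 0-based half-open.

## Layout

```
src/sweepscan/
  io.py        haplotype substrate + VCF/BED/TSV/haplotype-text IO
  simulate.py  coalescent + forward Wright-Fisher generators
  core.py      pi, MAF, outgroup polarization, H statistic
  pbs.py       Hudson F_ST, divergence-time transform, PBS window scan
  ihs.py       EHH, iHH, iHS, per-frequency-class standardization
  genes.py     signal->gene assignment, ranking, top-1% outliers
  qtl.py       QTL candidate genes, resampling enrichment
  presets.py   canned desk-scale validation scenarios
  cli.py       click-based pipeline
```
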