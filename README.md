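# sweepscan

Selective-sweep scans on phased haplotype panels: haplotype-based (iHS,
nSL) and SFS-based (composite likelihood ratio, Tajima's D, Fay & Wu's H,
heterozygosity) sweep statistics, 40-kb-style window tracks with
genome-wide empirical p-values and candidate-region calling, LD-decay
profiling with ascertainment comparisons, two-population F_ST scans, a
mixed-model (EMMAX-style) GWAS, and a permutation test for overlap between
GWAS hits and selection-candidate windows.

A forward Wright–Fisher simulator (neutral and conditioned hard sweeps,
array-like SNP ascertainment, polygenic-plus-QTL phenotypes) provides
ground-truth data, so the entire pipeline is exercised end-to-end without
any external download.

## Test

```bash
python -m pytest -q tests/
```

The suite covers per-module unit tests, property tests (EHH monotonicity,
allele-label symmetry, fold invariance, window tiling, region calling
invariants), calibration against coalescent expectations, and
`tests/test_acceptance.py` with sweep-localization power tests on
conditioned hard sweeps (25 replicates; roughly 10 minutes of simulation).
One acceptance test validates window/region counts against the source
study's supplementary genome-wide score CSVs and fails with an explanatory
message when those files are absent (they are journal downloads and cannot
be redistributed or fetched offline); place them at
`data/supplementary/dataset_s1.csv` / `dataset_s2.csv` to run it.

## CLI

```bash
# simulate a conditioned hard sweep and write VCF + ancestral TSV + truth
sweepscan simulate --mode sweep --n 200 --sample-hap 86 --len 200000 \
    --mu 1.25e-6 --rho 1e-6 --s 0.1 --end-freq 1.0 --seed 1 --out-prefix sweep

# ingest + polarize a phased VCF
sweepscan ingest --vcf in.vcf --ancestral anc.tsv --out panel.vcf

# per-site standardized iHS / nSL scores
sweepscan ihs --vcf sweep.vcf --ancestral sweep.ancestral.tsv --out ihs.tsv
sweepscan nsl --vcf sweep.vcf --ancestral sweep.ancestral.tsv --out nsl.tsv

# windowed SFS statistics and CLR scan
sweepscan sfsstats --vcf sweep.vcf --ancestral sweep.ancestral.tsv \
    --grid 40000 --stats tajd,faywuh,zhet --out sfs.tsv
sweepscan clr --vcf sweep.vcf --ancestral sweep.ancestral.tsv \
    --grid 40000 --out clr.tsv

# empirical p-values + top-percentile candidate regions
sweepscan regions --track track.tsv --percentile 0.99 --out regions.bed

# LD decay, F_ST, GWAS, overlap test
sweepscan ld --vcf panel.vcf --max-dist 250000 --out ld.tsv
sweepscan fst --pop1 a.vcf --pop2 b.vcf --k 3 --top 0.001 --out fst.tsv
sweepscan gwas --vcf panel.vcf --pheno pheno.tsv --out gwas.tsv
sweepscan overlap --gwas gwas.tsv --track track.tsv --n-perm 10000 \
    --seed 1 --out overlap.json
```

Conventions: internal coordinates are 0-based half-open (VCF positions are
converted on read/write); window grids are anchored at coordinate 0 per
chromosome; empirical p-values are rank/N with ties sharing the maximal
rank; code 1 always denotes the derived allele after polarization.

## Layout

| module | contents |
|---|---|
| `sweepscan.core_data` | `HaplotypePanel`, site tables, VCF/BED/GFF3/track I/O, polarization, window grids, interval overlap |
| `sweepscan.synthetic_data` | forward Wright–Fisher simulator, ascertainment, phenotype generator |
| `sweepscan.sfs_stats` | SFS construction, Tajima's D, Fay & Wu's H, windowed (Z)heterozygosity |
| `sweepscan.haplotype_stats` | EHH curves, iHH integration, iHS, nSL, DAF-bin standardization |
| `sweepscan.clr_scan` | background SFS, sweep-transformed spectra, CLR grid scan |
| `sweepscan.window_scan` | window aggregation, empirical p-values, region calling, variance coherence check |
| `sweepscan.ld_fst` | r², LD-decay curves and comparisons, two-population F_ST |
| `sweepscan.gwas_overlap` | GRM, EMMAX-style mixed-model scan, variance explained, overlap permutation test |
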