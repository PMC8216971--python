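# provscan

Environmental association analysis (EAA) for common-garden provenance trials.
The package implements a complete, tested workflow for detecting
climate-adaptive SNPs in a multi-provenance genomic study:

1. **QC filter cascade** (`provscan.qc`) — minor-allele-frequency and call-rate
   site filters, an exact Hardy–Weinberg test, windowed composite-LD pruning,
   PLINK-style method-of-moments IBD kinship, per-sample heterozygosity-deficit
   filtering, and a seeded neutral SNP subset.
2. **Climate PCA and dendroclimatic traits** (`provscan.phenoclimate`) —
   correlation-matrix PCA of a provenance × climate-variable table into
   standardized environmental PCs; ring-width detrending with a smoothing
   spline (50% frequency response at a configurable wavelength), Tukey-biweight
   provenance chronologies, bootstrapped response functions, and the
   provenance-level response-coefficient cline against climate PCs.
3. **Four genome scans** —
   * `provscan.scan_fst`: Weir–Cockerham FST with a calibrated
     hierarchical-island (Balding–Nichols) null joint distribution of
     heterozygosity and FST;
   * `provscan.scan_lfmm`: latent factor mixed model (Y = XBᵀ + W + E) with
     deterministic alternating estimation, genomic-inflation recalibration and
     Bonferroni/BH adjustment;
   * `provscan.scan_bayesenv`: covariance-controlled allele-frequency/
     environment Bayes factors (closed-form conjugate, with Spearman backup)
     and a beta-binomial three-model F-model comparison yielding q-values.
4. **Consensus outliers** (`provscan.consensus`) — per-method shortlists at the
   standard thresholds, pairwise/triple Venn structure, the capped consensus
   rule, allele-frequency/climate correlations, and eigenvector discrimination
   of consensus vs random neutral SNPs.
5. **Ancestry and RDA** (`provscan.ancestry_rda`) — sparse nonnegative
   matrix-factorization ancestry coefficients with masked cross-entropy model
   choice, and redundancy analysis partitioning genotype variance among
   climate, geography and ancestry with permutation tests.
6. **Synthetic data** (`provscan.simulate`) — hierarchical-island genotype,
   climate and ring-width generators with planted adaptive loci, related
   pairs, inbred samples and full ground truth for recovery tests.

`provscan.pipeline` orchestrates everything from one config with cached,
byte-reproducible CSV outputs and a machine-readable run report.

## Test

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests for the documented
invariants, and `tests/test_acceptance.py` with the acceptance criteria
(arithmetic targets, oracle equivalences, statistical calibration, and
planted-signal recovery).

## CLI

```bash
# generate a synthetic dataset (VCF + CSVs + ground truth)
provscan simulate --out data/ --seed 1

# full pipeline
provscan run --vcf data/genotypes.vcf --provenances data/provenances.csv \
    --climate data/climate.csv --rings data/rings.csv \
    --site-climate data/site_climate.csv --out run/ --seed 1

# or stage by stage (each command runs the pipeline up to that stage,
# reusing cached intermediates in the run directory)
provscan qc --config config.yaml
provscan scan --config config.yaml
provscan consensus --config config.yaml
provscan rda --config config.yaml
```

Input schemas: VCF v4.2 with GT genotypes; `provenances.csv`
(id,lat,lon,elev[,n_samples]); `climate.csv` (provenance,var1..varK);
`rings.csv` (tree,provenance,year,earlywood,latewood,total);
`site_climate.csv` (year,month,variable,value).

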