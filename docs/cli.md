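# Command-line interface

All subcommands take one YAML run configuration:

```
vcqtl simulate   cfg.yaml   # write synthetic pedigree/map/genotypes/phenotypes (+ truth sidecar)
vcqtl validate   cfg.yaml   # cross-check inputs; Mendelian screen; exit 1 on violations
vcqtl ibd        cfg.yaml   # estimate the IBD store on the scan grid (cached ibd_store.npz)
vcqtl thresholds cfg.yaml   # chromosome-wise empirical thresholds (thresholds.tsv)
vcqtl scan       cfg.yaml   # per-trait LRT scans, carrier contrasts, summary table
vcqtl report     cfg.yaml   # SVG LRT-profile figures from scan outputs
```

Stages are cacheable and resumable: the IBD store and threshold table are
computed once per map/design and reused across traits.  Every tabular
output starts with a comment line embedding the configuration hash and
master seed, so two runs with equal configuration and seed are
byte-identical.

## Configuration schema

```yaml
seed: 1                      # master seed for every stage
outdir: out/                 # output directory
preset: reference            # simulate only: reference | threshold | tiny

pedigree: out/pedigree.tsv   # id  sire  dam  sex  generation  line ("0" = unknown parent)
map: out/map.tsv             # chromosome  marker  position_cM (Haldane, sex-averaged)
genotypes: out/genotypes.tsv # id then two columns per marker (allele1, allele2), 0 = missing
phenotypes: out/phenotypes.csv  # CSV with header; 'id' column required

grid_step: 4                 # scan-grid spacing, cM
ibd:
  iterations: 20000          # MCMC sweeps per linkage group
  burn_in: 2000
  thinning: 10
mendel:
  policy: blank              # blank | report: what to do with inconsistent genotypes

thresholds:
  profile: desk              # desk (500 null replicates) | full (5000)
  n_reps: 500                # overrides the profile count
  h2: 0.3                    # heritability of the simulated polygenic null

groups: ["1", "6", "15"]     # linkage groups to analyse (default: all)

traits:                      # one model per trait
  - trait: ph45
    factors: [batch, sex]    # fixed-effect factor columns
    covariates: []           # covariate columns
    litter: litter           # litter-id column, or omit for no litter effect
    exclude_carriers_of: [mut_recessive]   # run the carrier contrast at these loci
```
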