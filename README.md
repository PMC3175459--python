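# vcqtl

Variance-component QTL linkage mapping for outbred two-line F2 intercrosses
— the classical livestock design in which two production lines (e.g. a
Pietrain-type sire line and a synthetic dam line) are crossed to produce
~1,000 phenotyped F2 animals, genotyped for microsatellite markers across
all autosomes.

The package is for quantitative geneticists who want the full two-step
analysis as reusable, tested code:

1. **IBD step.** At every scan position `p` (default every 4 cM), estimate
   the identity-by-descent relationship matrix `G(p)` from pedigree and
   multi-allelic marker data by MCMC over segregation indicators.  Founder
   gametes are treated as mutually non-IBD, regardless of parental line.
2. **Variance-component step.** For each trait, fit by AI-REML the
   polygenic mixed model H0: `y = Xb + u_a + (u_c) + e`,
   `u_a ~ N(0, σ²_a A)`, and at each position the QTL model H1 that adds
   `u_q ~ N(0, σ²_q G(p))`.  The detection statistic is
   `LRT(p) = 2(logL_H1 − logL_H0)`; only the per-chromosome maximum is
   tested; `σ²_q / Σσ²` is the variance fraction attributed to the QTL;
   a −1 LOD drop (`ln 10`) gives an approximate 95% support interval; BLUP
   solutions of the mixed-model equations give per-individual predicted QTL
   genotypic effects.

Significance uses simulation-based empirical thresholds: phenotypes are
simulated under a polygenic-only null (`h² = 0.3`) on the same IBD matrices
and pedigree, and chromosome-wise quantiles of the max-LRT are mapped to
genome-wise levels by the Šidák rule for 18 autosomes (5% genome-wise ↔
0.285% chromosome-wise); χ²(2 df) quantiles (1%: 9.21) are the theoretical
upper-bound reference.

A first-class gene-dropping simulator reproduces the study design —
including low-frequency major-effect mutations with recessive or dominant
action (RYR1- and PRKAG3-like positive controls) — so the
carrier-inclusion/exclusion contrast can be exercised without any external
data: scanning with all animals detects a rare causative mutation as a
highly significant QTL; excluding its carriers abolishes the signal, while
an independent linked QTL survives exclusion.

## Worked example

Simulate a 320-animal F2 population with a dominant mutation at founder-line
frequency 0.03 (16 cM) affecting a glycolytic-potential-like trait, compute
the IBD store, empirical thresholds, and the carrier contrast:

```python
import numpy as np
import vcqtl as v
from vcqtl.ibd import IbdRunConfig
from vcqtl.scan import QtlScan, carrier_contrast
from vcqtl.thresholds import NullScanDesign, null_max_lrt_distribution, chromosome_thresholds

mut = v.MutationSpec(name="mut_dominant", group="1", position_cm=16.0,
                     line_frequency={"DAM": 0.03}, action="dominant",
                     effects={"glyc_p": 55.0})
trait = v.TraitSimSpec(name="glyc_p", mean=159.4, sigma2_a=0.30 * 24.8**2,
                       sigma2_e=0.70 * 24.8**2, batch_sd=0.05**0.5 * 24.8)
design = v.SimulationDesign(n_f0_sires=6, n_f0_dams=10, n_f1_boars=6, n_f1_sows=18,
                            sows_per_boar=(3, 3), litters_per_sow=(2, 2), n_f2=320,
                            n_groups=1, markers_per_group=(5,), marker_spacing_cm=15.0,
                            mutations=[mut], traits=[trait])
gmap = v.make_map(design)
ped = v.make_pedigree(design, seed=7)
geno, truth = v.drop_genomes(ped, gmap, design, seed=8, require_segregating=True)
phen = v.simulate_traits(ped, truth, design.traits, seed=9, design=design)
f2 = ped.ids_of_generation("F2")
store = v.compute_ibd_store(ped, geno, gmap, f2,
                            IbdRunConfig(iterations=5000, burn_in=500, thinning=10, seed=10),
                            extra_positions={"1": [16.0]})
A = v.additive_matrix(ped)
nd = NullScanDesign(ids=f2, X=np.ones((len(f2), 1)), amatrix=A, store=store, group="1")
null = null_max_lrt_distribution(nd, ped, n_reps=200, seed=11)
print("empirical thresholds:", chromosome_thresholds(null, levels=(0.05, 0.01)))
sc = QtlScan(ped, gmap, phen, A, store, genotypes=geno)
spec = v.TraitModelSpec(trait="glyc_p", factors=("batch", "sex"))
cc = carrier_contrast(sc, spec, "1", "mut_dominant")
inc, exc = cc.include, cc.exclude
print(f"all animals:      max LRT {inc.max_lrt:.1f} at {inc.max_position:.0f} cM, "
      f"95% CI ({inc.support[0]:.0f}-{inc.support[1]:.0f}), "
      f"QTL variance {100 * inc.qtl_fraction[inc.max_index]:.1f}%")
print(f"carriers removed: max LRT {np.nanmax(exc.lrt):.1f}")
```

Output:

```
empirical thresholds: {0.05: 4.63, 0.01: 7.21}
all animals:      max LRT 7.6 at 16 cM, 95% CI (16-20), QTL variance 14.3%
carriers removed: max LRT 0.2
```

Reading this: under the null, a max LRT above 4.63 (7.21) is exceeded on
this chromosome only 5% (1%) of the time — both are below the χ²(2 df)
quantiles, the theoretical upper bound.  With all 320 animals the scan
finds a QTL (LRT 7.6, above the 1% chromosome-wise threshold) whose maximum
sits at the true mutation position (16 cM), attributing ~14% of phenotypic
variance to the locus; the 11 true mutation carriers drive it — their mean
predicted QTL genotypic effect is +19.4 μmol/g against −1.3 for wild-type
animals — and removing them flattens the profile (max LRT 0.2).

The same pipeline is scriptable from the shell via the `vcqtl` CLI
(`simulate`, `validate`, `ibd`, `thresholds`, `scan`, `report`) driven by a
YAML run configuration; `report` renders the per-chromosome LRT profile
figures with overlaid include/exclude-carrier curves.

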