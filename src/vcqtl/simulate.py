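"""Gene-dropping simulator of a two-line F2 intercross study design.

Emulates the structure of a pig-style intercross: ~16 F0 sires of one line
and ~25 F0 dams of another produce 18 F1 boars and 72 F1 sows; each boar is
mated to a group of one to four full-sib sows (never his own sibs) for one
to three litters each, yielding ~1,000 phenotyped F2.  Marker genomes are
dropped through the pedigree under the Haldane model (no crossover
interference); low-frequency major-effect causal mutations (recessive or
dominant) can be planted in one founder line; traits combine batch, sex,
covariate, litter, polygenic, QTL and residual terms.  Everything is
deterministic given the seed, and the latent descent record (the "truth")
is returned for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _descent
from .core import GeneticMap, GenotypeTable, LinkageGroup, Pedigree, PhenotypeTable
from .ibd import haldane
from .pedigree import additive_matrix

import pandas as pd


@dataclass(frozen=True)
class MutationSpec:
    """A biallelic causal locus planted in the founders.

    ``line_frequency`` maps founder-line label -> mutant allele frequency;
    the realised founder carrier count is max(1, round(2 n p)) so the
    mutation is guaranteed to segregate, as in a study that conditions on
    observed segregating mutations.  Allele 1 is wild-type, allele 2 mutant.
    """

    name: str
    group: str
    position_cm: float
    line_frequency: dict = field(default_factory=dict)
    action: str = "additive"  # recessive | dominant | additive
    effects: dict = field(default_factory=dict)  # trait -> effect size, trait units

    def __post_init__(self):
        for p in self.line_frequency.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mutation {self.name}: frequency {p} outside [0,1]")
        if self.action not in ("recessive", "dominant", "additive"):
            raise ValueError(f"mutation {self.name}: unknown action {self.action!r}")

    def genotype_effects(self, trait: str) -> tuple[float, float, float]:
        """Trait effect per mutant-allele count (0, 1, 2)."""
        e = self.effects.get(trait, 0.0)
        if self.action == "recessive":
            return (0.0, 0.0, e)
        if self.action == "dominant":
            return (0.0, e, e)
        return (0.0, 0.5 * e, e)


@dataclass(frozen=True)
class TraitSimSpec:
    """Variance-component structure of one simulated trait.

    Variances are in squared trait units; ``covariate`` is (name, mean, sd,
    slope); ``n_records`` optionally thins phenotyped F2 to mimic per-trait
    record counts."""

    name: str
    mean: float = 0.0
    sigma2_a: float = 0.3
    sigma2_e: float = 0.7
    sigma2_litter: float = 0.0
    batch_sd: float = 0.0
    sex_effects: dict = field(default_factory=dict)
    covariate: tuple | None = None
    n_records: int | None = None

    def __post_init__(self):
        for v in (self.sigma2_a, self.sigma2_e, self.sigma2_litter):
            if v < 0:
                raise ValueError(f"trait {self.name}: negative variance")
        tot = self.sigma2_a + self.sigma2_e + self.sigma2_litter
        if tot <= 0 or not 0.0 <= self.sigma2_a / tot < 1.0:
            raise ValueError(f"trait {self.name}: implied h2 outside [0,1)")


@dataclass
class SimulationDesign:
    """Counts, map shape, causal loci and trait models of one simulated study."""

    n_f0_sires: int = 16
    n_f0_dams: int = 25
    n_f1_boars: int = 18
    n_f1_sows: int = 72
    sows_per_boar: tuple[int, int] = (1, 4)
    litters_per_sow: tuple[int, int] = (1, 3)
    n_f2: int = 1000
    sire_line: str = "SIRE"
    dam_line: str = "DAM"
    n_groups: int = 18
    markers_per_group: tuple[int, ...] | None = None  # default: 170 split over groups
    marker_spacing_cm: float = 17.0
    n_alleles: int = 4
    line_allele_profiles: dict = field(default_factory=dict)  # line -> frequency vector
    mutations: list[MutationSpec] = field(default_factory=list)
    traits: list[TraitSimSpec] = field(default_factory=list)
    n_batches: int = 32
    missing_rate: float = 0.0

    def __post_init__(self):
        for v in (self.n_f0_sires, self.n_f0_dams, self.n_f1_boars, self.n_f1_sows, self.n_f2):
            if v <= 0:
                raise ValueError("design counts must be positive")
        if self.markers_per_group is None:
            base, extra = divmod(170, self.n_groups)
            self.markers_per_group = tuple(
                base + (1 if g < extra else 0) for g in range(self.n_groups)
            )
        if not self.line_allele_profiles:
            # distinct line profiles give realistic partial informativeness
            k = self.n_alleles
            up = np.arange(1, k + 1, dtype=float)
            self.line_allele_profiles = {
                self.sire_line: (up / up.sum()).tolist(),
                self.dam_line: (up[::-1] / up.sum()).tolist(),
            }
        for line, prof in self.line_allele_profiles.items():
            if abs(sum(prof) - 1.0) > 1e-9:
                raise ValueError(f"line {line}: allele frequencies must sum to 1")


def reference_design() -> SimulationDesign:
    """The frozen default design mirroring the study: 16x25 F0, 18x72 F1,
    ~1,000 F2, 18 autosomes carrying 170 markers at 17 cM average spacing,
    a recessive mutation at frequency 0.08 in the sire line (group 6, 74 cM,
    large early-pH effect) and a dominant mutation at frequency 0.03 in the
    dam line (group 15, large glycolytic-potential effect)."""
    glyc = TraitSimSpec(
        name="glycolytic_potential",
        mean=159.4,
        sigma2_a=0.30 * 24.8**2,
        sigma2_e=0.65 * 24.8**2,
        batch_sd=0.05**0.5 * 24.8,
        sex_effects={"female": 0.0, "castrate": 5.0},
    )
    ph45 = TraitSimSpec(
        name="ph45",
        mean=6.55,
        sigma2_a=0.30 * 0.18**2,
        sigma2_e=0.65 * 0.18**2,
        batch_sd=0.05**0.5 * 0.18,
    )
    ryr1_like = MutationSpec(
        name="mut_recessive",
        group="6",
        position_cm=74.0,
        line_frequency={"SIRE": 0.08},
        action="recessive",
        effects={"ph45": -0.45},
    )
    prkag3_like = MutationSpec(
        name="mut_dominant",
        group="15",
        position_cm=40.0,
        line_frequency={"DAM": 0.03},
        action="dominant",
        effects={"glycolytic_potential": 50.0},
    )
    return SimulationDesign(mutations=[ryr1_like, prkag3_like], traits=[glyc, ph45])


def half_sib_threshold_design(
    n_f2: int = 305, group_length_markers: int = 8, marker_spacing_cm: float = 17.0
) -> SimulationDesign:
    """Reduced subset design used for null-threshold simulation: ~305 F2 in 4
    paternal half-sib families on one multi-marker linkage group."""
    return SimulationDesign(
        n_f0_sires=4,
        n_f0_dams=8,
        n_f1_boars=4,
        n_f1_sows=16,
        sows_per_boar=(4, 4),
        litters_per_sow=(2, 3),
        n_f2=n_f2,
        n_groups=1,
        markers_per_group=(group_length_markers,),
        marker_spacing_cm=marker_spacing_cm,
    )


def make_map(design: SimulationDesign) -> GeneticMap:
    """Evenly spaced marker map; declared causal loci are inserted as extra
    biallelic loci at their stated positions."""
    groups = []
    for g in range(design.n_groups):
        name = str(g + 1)
        nm = design.markers_per_group[g]
        pos = [round(k * design.marker_spacing_cm, 6) for k in range(nm)]
        markers = [f"M{name}_{k + 1}" for k in range(nm)]
        for mut in design.mutations:
            if mut.group == name:
                if mut.position_cm in pos:
                    raise ValueError(f"mutation {mut.name} coincides with a marker position")
                markers.append(mut.name)
                pos.append(float(mut.position_cm))
        order = np.argsort(pos)
        groups.append(LinkageGroup(name, [markers[i] for i in order], np.array(pos)[order]))
    return GeneticMap(groups)


def make_pedigree(design: SimulationDesign, seed: int = 0) -> Pedigree:
    """Three-generation pedigree honouring the mating structure.

    F1 boars are never mated to their own full sibs; each boar's mates are
    full sibs of one another; F1 of both sexes may share F0 parents.  Litter
    ids of F2 individuals are attached as ``pedigree.litter_of``.  Raises if
    the design cannot avoid boar-sib matings."""
    rng = np.random.default_rng(seed)
    if design.n_f0_dams < 2:
        raise ValueError("need at least two F0 dams to avoid boar-sib matings")
    records = []
    sires = [f"S{i + 1}" for i in range(design.n_f0_sires)]
    dams = [f"D{i + 1}" for i in range(design.n_f0_dams)]
    for s in sires:
        records.append((s, None, None, "male", "F0", design.sire_line))
    for d in dams:
        records.append((d, None, None, "female", "F0", design.dam_line))
    # one couple per dam; sires cycle so families share F0 fathers
    order = rng.permutation(design.n_f0_sires)
    couples = [(sires[order[i % design.n_f0_sires]], dams[i]) for i in range(design.n_f0_dams)]

    lo, hi = design.sows_per_boar
    sizes = rng.integers(lo, hi + 1, size=design.n_f1_boars)
    while sizes.sum() != design.n_f1_sows:
        j = rng.integers(design.n_f1_boars)
        if sizes.sum() < design.n_f1_sows and sizes[j] < hi:
            sizes[j] += 1
        elif sizes.sum() > design.n_f1_sows and sizes[j] > lo:
            sizes[j] -= 1
    group_couples = rng.choice(len(couples), size=design.n_f1_boars, replace=design.n_f1_boars > len(couples))
    boars, sow_groups = [], []
    sow_count = 0
    for b in range(design.n_f1_boars):
        gc = int(group_couples[b])
        others = [c for c in range(len(couples)) if c != gc]
        bc = int(rng.choice(others))
        boar = f"B{b + 1}"
        records.append((boar, couples[bc][0], couples[bc][1], "male", "F1", None))
        boars.append(boar)
        group = []
        for _ in range(int(sizes[b])):
            sow_count += 1
            sow = f"W{sow_count}"
            records.append((sow, couples[gc][0], couples[gc][1], "female", "F1", None))
            group.append(sow)
        sow_groups.append(group)

    matings = []
    for boar, group in zip(boars, sow_groups):
        for sow in group:
            for parity in range(int(rng.integers(design.litters_per_sow[0], design.litters_per_sow[1] + 1))):
                matings.append((boar, sow, parity))
    n_litters = len(matings)
    base, extra = divmod(design.n_f2, n_litters)
    litter_sizes = np.full(n_litters, base)
    litter_sizes[rng.choice(n_litters, size=extra, replace=False)] += 1
    litter_of = {}
    f2 = 0
    for k, ((boar, sow, parity), sz) in enumerate(zip(matings, litter_sizes)):
        for _ in range(int(sz)):
            f2 += 1
            iid = f"F{f2}"
            sex = "female" if rng.random() < 0.5 else "castrate"
            records.append((iid, boar, sow, sex, "F2", None))
            litter_of[iid] = f"L{k + 1}"
    ped = Pedigree(records)
    ped.litter_of = litter_of
    return ped


@dataclass
class Truth:
    """Latent descent record: oracle-only sidecar, never an analysis input.

    Per group: segregation indicators (n_loci, n_meioses), founder-slot
    allele arrays (n_slots, n_loci) and locus names/positions; plus per-
    mutation mutant-allele counts per individual."""

    indicators: dict
    founder_alleles: dict
    loci: dict  # group -> (names, positions)
    causal_counts: dict  # mutation name -> (n,) int array, pedigree order

    def slots(self, pedigree: Pedigree, group: str, locus_index: int):
        """Founder-slot pair (fp, fm) per individual at one locus."""
        fp = np.zeros(pedigree.n, dtype=np.int64)
        fm = np.zeros(pedigree.n, dtype=np.int64)
        _descent.slots_at(
            np.ascontiguousarray(pedigree.sire_idx),
            np.ascontiguousarray(pedigree.dam_idx),
            np.ascontiguousarray(pedigree.founder_ord),
            np.ascontiguousarray(pedigree.nonfounder_ord),
            np.ascontiguousarray(self.indicators[group][locus_index]),
            fp,
            fm,
        )
        return fp, fm

    def save(self, path) -> None:
        arrays = {}
        for g, S in self.indicators.items():
            arrays[f"S@{g}"] = S
            arrays[f"FA@{g}"] = self.founder_alleles[g]
            arrays[f"POS@{g}"] = self.loci[g][1]
        for mname, counts in self.causal_counts.items():
            arrays[f"CC@{mname}"] = counts
        np.savez_compressed(path, **arrays)


def _founder_line_slots(pedigree: Pedigree, line: str) -> np.ndarray:
    slots = []
    for i in range(pedigree.n):
        if pedigree.is_founder[i] and pedigree.line[i] == line:
            f = pedigree.founder_ord[i]
            slots.extend([2 * f, 2 * f + 1])
    return np.array(slots, dtype=np.int64)


def drop_genomes(
    pedigree: Pedigree,
    gmap: GeneticMap,
    design: SimulationDesign,
    seed: int = 0,
    require_segregating: bool = False,
    max_redraws: int = 200,
) -> tuple[GenotypeTable, Truth]:
    """Drop founder gametes through the pedigree under the Haldane model.

    Founder marker alleles are drawn from line-specific frequency profiles;
    mutation loci get a fixed mutant-copy count planted in the target line's
    founder slots.  With ``require_segregating`` the whole drop is redrawn
    until every declared mutation reaches an F2 allele frequency within
    [0.5, 2] times its transmission expectation (half the founder-line
    frequency) — emulating a study that analyses mutations it observed
    segregating.  Returns observed genotypes (optionally thinned by the
    design's missingness rate) plus the latent truth."""
    if require_segregating and design.mutations:
        f2_idx = pedigree.indices(pedigree.ids_of_generation("F2"))
        for k in range(max_redraws):
            geno, truth = drop_genomes(pedigree, gmap, design, seed=seed + 7919 * k)
            ok = True
            for mut in design.mutations:
                target = 0.5 * max(mut.line_frequency.values(), default=0.0)
                if target <= 0:
                    continue
                freq = truth.causal_counts[mut.name][f2_idx].sum() / (2 * len(f2_idx))
                if not 0.5 * target <= freq <= 2.0 * target:
                    ok = False
            if ok:
                return geno, truth
        raise RuntimeError("could not realise segregating mutations; design too small")
    rng = np.random.default_rng(seed)
    n_slots = 2 * pedigree.n_founders
    n_mei = pedigree.n_meioses
    sire = np.ascontiguousarray(pedigree.sire_idx)
    dam = np.ascontiguousarray(pedigree.dam_idx)
    fo = np.ascontiguousarray(pedigree.founder_ord)
    nf = np.ascontiguousarray(pedigree.nonfounder_ord)
    founder_line_of_slot = np.empty(n_slots, dtype=object)
    for i in range(pedigree.n):
        if pedigree.is_founder[i]:
            f = pedigree.founder_ord[i]
            founder_line_of_slot[2 * f] = pedigree.line[i]
            founder_line_of_slot[2 * f + 1] = pedigree.line[i]

    mutation_names = {m.name for m in design.mutations}
    indicators, founder_alleles, loci = {}, {}, {}
    all_markers: list[str] = []
    geno_cols: list[np.ndarray] = []
    fp = np.zeros(pedigree.n, dtype=np.int64)
    fm = np.zeros(pedigree.n, dtype=np.int64)
    causal_counts: dict[str, np.ndarray] = {}
    for g in gmap.groups:
        L = len(g.markers)
        fa = np.zeros((n_slots, L), dtype=np.int32)
        for l, mname in enumerate(g.markers):
            if mname in mutation_names:
                mut = next(m for m in design.mutations if m.name == mname)
                fa[:, l] = 1
                for line, p in mut.line_frequency.items():
                    if p <= 0:
                        continue
                    line_slots = _founder_line_slots(pedigree, line)
                    # line_slots already counts two gametes per founder
                    n_copies = min(max(1, round(len(line_slots) * p)), len(line_slots))
                    chosen = rng.choice(line_slots, size=n_copies, replace=False)
                    fa[chosen, l] = 2
            else:
                for line, prof in design.line_allele_profiles.items():
                    line_slots = _founder_line_slots(pedigree, line)
                    fa[line_slots, l] = rng.choice(
                        np.arange(1, len(prof) + 1), size=len(line_slots), p=prof
                    )
        # Haldane Markov chain over loci, per meiosis
        S = np.zeros((L, n_mei), dtype=np.uint8)
        S[0] = rng.integers(0, 2, size=n_mei)
        r = haldane(np.diff(g.positions))
        for l in range(1, L):
            switch = rng.random(n_mei) < r[l - 1]
            S[l] = np.where(switch, 1 - S[l - 1], S[l - 1])
        indicators[g.name] = S
        founder_alleles[g.name] = fa
        loci[g.name] = (list(g.markers), np.array(g.positions))
        for l, mname in enumerate(g.markers):
            _descent.slots_at(sire, dam, fo, nf, np.ascontiguousarray(S[l]), fp, fm)
            a1 = fa[fp, l]
            a2 = fa[fm, l]
            if mname in mutation_names:
                causal_counts[mname] = ((a1 == 2).astype(np.int64) + (a2 == 2)).astype(np.int64)
            col = np.stack([a1, a2], axis=1)
            if design.missing_rate > 0:
                miss = rng.random(pedigree.n) < design.missing_rate
                col[miss] = 0
            geno_cols.append(col)
            all_markers.append(mname)
    data = np.stack(geno_cols, axis=1)
    genotypes = GenotypeTable(pedigree.ids, all_markers, data)
    truth = Truth(indicators, founder_alleles, loci, causal_counts)
    return genotypes, truth


def simulate_traits(
    pedigree: Pedigree,
    truth: Truth,
    trait_specs: list[TraitSimSpec],
    seed: int = 0,
    design: SimulationDesign | None = None,
    mutations: list[MutationSpec] | None = None,
) -> PhenotypeTable:
    """Phenotypes y = mean + batch + sex + covariate + litter + polygenic + QTL + residual.

    The polygenic term follows the pedigree recursion against the A-matrix;
    QTL contributions come from the truth's causal genotype counts; records
    are optionally thinned per trait to the requested record count."""
    rng = np.random.default_rng(seed)
    muts = mutations if mutations is not None else (design.mutations if design else [])
    n_batches = design.n_batches if design else 32
    f2_ids = pedigree.ids_of_generation("F2")
    f2_idx = pedigree.indices(f2_ids)
    n2 = len(f2_ids)
    Fcoef = np.diag(additive_matrix(pedigree).values) - 1.0
    litter_of = getattr(pedigree, "litter_of", {})
    litters = [litter_of.get(i, "L0") for i in f2_ids]
    batches = [f"B{(k * n_batches) // n2 + 1}" for k in range(n2)]
    sexes = [pedigree.sex[i] for i in f2_idx]

    cols = {"id": f2_ids, "batch": batches, "sex": sexes, "litter": litters}
    cov_cache: dict[str, np.ndarray] = {}
    for spec in trait_specs:
        s2a = spec.sigma2_a
        bv = np.zeros(pedigree.n)
        for i in range(pedigree.n):
            si, di = pedigree.sire_idx[i], pedigree.dam_idx[i]
            if si < 0 and di < 0:
                bv[i] = rng.normal(0.0, np.sqrt(s2a))
            else:
                fbar = 0.5 * (Fcoef[si] + Fcoef[di])
                bv[i] = 0.5 * (bv[si] + bv[di]) + rng.normal(
                    0.0, np.sqrt(max(0.5 * s2a * (1.0 - fbar), 0.0))
                )
        y = np.full(n2, spec.mean) + bv[f2_idx]
        if spec.batch_sd > 0:
            beff = {f"B{b + 1}": rng.normal(0.0, spec.batch_sd) for b in range(n_batches)}
            y += np.array([beff[b] for b in batches])
        if spec.sex_effects:
            y += np.array([spec.sex_effects.get(s, 0.0) for s in sexes])
        if spec.covariate is not None:
            cname, cmean, csd, slope = spec.covariate
            if cname not in cov_cache:
                cov_cache[cname] = rng.normal(cmean, csd, size=n2)
            y += slope * (cov_cache[cname] - cmean)
        if spec.sigma2_litter > 0:
            uniq = sorted(set(litters))
            leff = {l: rng.normal(0.0, np.sqrt(spec.sigma2_litter)) for l in uniq}
            y += np.array([leff[l] for l in litters])
        for mut in muts:
            if spec.name in mut.effects and mut.name in truth.causal_counts:
                eff = mut.genotype_effects(spec.name)
                counts = truth.causal_counts[mut.name][f2_idx]
                y += np.array([eff[c] for c in counts])
        y += rng.normal(0.0, np.sqrt(spec.sigma2_e), size=n2)
        if spec.n_records is not None and spec.n_records < n2:
            drop = rng.choice(n2, size=n2 - spec.n_records, replace=False)
            y = y.astype(float)
            y[drop] = np.nan
        cols[spec.name] = y
    for cname, vals in cov_cache.items():
        cols[cname] = vals
    return PhenotypeTable(pd.DataFrame(cols))
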