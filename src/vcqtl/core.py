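"""Shared data model for variance-component QTL mapping in a three-generation intercross.

The pipeline operates on four tabular inputs — a pedigree, a sex-averaged
genetic map (Haldane cM), a multi-allelic marker genotype table and a
phenotype table with factors/covariates — plus per-trait model
specifications.  Everything downstream (A-matrix, IBD sampling, REML scans)
consumes the classes defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEXES = ("male", "female", "castrate")
GENERATIONS = ("F0", "F1", "F2")

MISSING_ALLELE = 0


@dataclass(frozen=True)
class Violation:
    """One validation problem; validation reports, it never throws."""

    kind: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.message}"


class Pedigree:
    """Directed acyclic three-generation pedigree.

    Records are (id, sire, dam, sex, generation, line); parents of founders
    are unknown (``None``), founders carry a line label.  Storage is
    topological (parents before offspring), which fixes matrix row order for
    the whole run.
    """

    def __init__(self, records: Iterable[tuple], strict: bool = True):
        recs = list(records)
        self.ids: list[str] = [str(r[0]) for r in recs]
        self.index: dict[str, int] = {}
        for i, iid in enumerate(self.ids):
            if strict and iid in self.index:
                raise ValueError(f"duplicate id {iid!r}")
            self.index.setdefault(iid, i)
        n = len(recs)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        self.sex: list[str] = []
        self.generation: list[str] = []
        self.line: list[str | None] = []
        for i, (iid, sire, dam, sex, gen, *rest) in enumerate(recs):
            line = rest[0] if rest else None
            for which, parent, arr in (("sire", sire, self.sire_idx), ("dam", dam, self.dam_idx)):
                if parent in (None, "0", 0, ""):
                    continue
                j = self.index.get(str(parent), -1)
                if j < 0 or j >= i:
                    if strict:
                        raise ValueError(
                            f"{which} {parent!r} of {iid!r} missing or out of topological order"
                        )
                    j = -1
                arr[i] = j
            if strict:
                if sex not in SEXES:
                    raise ValueError(f"bad sex {sex!r} for {iid!r}")
                if gen not in GENERATIONS:
                    raise ValueError(f"bad generation {gen!r} for {iid!r}")
                if gen == "F0" and (self.sire_idx[i] >= 0 or self.dam_idx[i] >= 0):
                    raise ValueError(f"F0 individual {iid!r} has a known parent")
                if gen != "F0" and (self.sire_idx[i] < 0 or self.dam_idx[i] < 0):
                    raise ValueError(f"{gen} individual {iid!r} must have both parents known")
            self.sex.append(sex)
            self.generation.append(gen)
            self.line.append(line)
        self.n = n
        self.is_founder = (self.sire_idx < 0) & (self.dam_idx < 0)
        # founder ordinals and non-founder (meiosis) ordinals
        self.founder_ord = np.full(n, -1, dtype=np.int64)
        self.founder_ord[self.is_founder] = np.arange(int(self.is_founder.sum()))
        self.nonfounder_ord = np.full(n, -1, dtype=np.int64)
        self.nonfounder_ord[~self.is_founder] = np.arange(int((~self.is_founder).sum()))
        self.n_founders = int(self.is_founder.sum())
        self.n_meioses = 2 * (n - self.n_founders)

    # -- meiosis convention: non-founder ordinal k owns meioses 2k (paternal
    #    gamete, from the sire) and 2k+1 (maternal gamete, from the dam).

    def indices(self, ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.index[str(i)] for i in ids], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"unknown individual id {e.args[0]!r}") from None

    def ids_of_generation(self, gen: str) -> list[str]:
        return [i for i, g in zip(self.ids, self.generation) if g == gen]

    def to_frame(self) -> pd.DataFrame:
        sire = ["0" if s < 0 else self.ids[s] for s in self.sire_idx]
        dam = ["0" if d < 0 else self.ids[d] for d in self.dam_idx]
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": sire,
                "dam": dam,
                "sex": self.sex,
                "generation": self.generation,
                "line": [l if l is not None else "-" for l in self.line],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, strict: bool = True) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype=str)
        recs = [
            (
                r.id,
                None if r.sire == "0" else r.sire,
                None if r.dam == "0" else r.dam,
                r.sex,
                r.generation,
                None if r.line in ("-", None) else r.line,
            )
            for r in df.itertuples()
        ]
        return cls(recs, strict=strict)


@dataclass
class LinkageGroup:
    name: str
    markers: list[str]
    positions: np.ndarray  # Haldane cM, strictly increasing

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)

    @property
    def length(self) -> float:
        return float(self.positions[-1])


class GeneticMap:
    """Ordered linkage groups with marker positions in Haldane cM.

    ``grid`` returns scan positions every ``step`` cM from 0 to the last
    marker inclusive, optionally augmented with extra positions (e.g. the
    exact location of a declared causal locus).
    """

    def __init__(self, groups: Sequence[LinkageGroup], step: float = 4.0, strict: bool = True):
        self.groups = list(groups)
        self.step = float(step)
        self._by_name = {g.name: g for g in self.groups}
        if strict:
            for g in self.groups:
                if len(g.positions) != len(g.markers):
                    raise ValueError(f"group {g.name}: marker/position length mismatch")
                if len(g.positions) and g.positions[0] < 0:
                    raise ValueError(f"group {g.name}: first position negative")
                if np.any(np.diff(g.positions) <= 0):
                    raise ValueError(f"group {g.name}: positions not strictly increasing")

    def group(self, name: str) -> LinkageGroup:
        return self._by_name[name]

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    def grid(self, name: str, extra: Sequence[float] = (), step: float | None = None) -> np.ndarray:
        g = self.group(name)
        last = g.length
        pos = np.arange(0.0, last + 1e-9, step if step is not None else self.step)
        pos = np.union1d(np.round(pos, 6), np.round([last, *extra], 6))
        return pos[(pos >= 0) & (pos <= last + 1e-9)]

    @property
    def marker_names(self) -> list[str]:
        return [m for g in self.groups for m in g.markers]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g.name, m, p) for g in self.groups for m, p in zip(g.markers, g.positions)
        ]
        return pd.DataFrame(rows, columns=["chromosome", "marker", "position_cM"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, step: float = 4.0, strict: bool = True) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        groups = []
        for name, sub in df.groupby("chromosome", sort=False):
            groups.append(
                LinkageGroup(str(name), [str(m) for m in sub["marker"]], sub["position_cM"].to_numpy())
            )
        return cls(groups, step=step, strict=strict)


class GenotypeTable:
    """Unordered allele pairs of positive integer labels; 0 = missing.

    ``data`` has shape (n_individuals, n_markers, 2); allele labels are
    marker-local (microsatellite bin numbers).
    """

    def __init__(self, ids: Sequence[str], markers: Sequence[str], data: np.ndarray):
        self.ids = [str(i) for i in ids]
        self.markers = list(markers)
        self.data = np.asarray(data, dtype=np.int32)
        if self.data.shape != (len(self.ids), len(self.markers), 2):
            raise ValueError("genotype data shape mismatch")
        self._id_index = {i: k for k, i in enumerate(self.ids)}
        self._marker_index = {m: k for k, m in enumerate(self.markers)}

    def marker_column(self, marker: str) -> np.ndarray:
        return self.data[:, self._marker_index[marker], :]

    def alleles(self, marker: str) -> list[int]:
        col = self.marker_column(marker)
        return sorted(int(a) for a in np.unique(col) if a != MISSING_ALLELE)

    def get(self, iid: str, marker: str) -> tuple[int, int]:
        g = self.data[self._id_index[str(iid)], self._marker_index[marker]]
        return int(g[0]), int(g[1])

    def has_individual(self, iid: str) -> bool:
        return str(iid) in self._id_index

    def aligned_to(self, ped: Pedigree, markers: Sequence[str]) -> np.ndarray:
        """(n_ped, len(markers), 2) array in pedigree order; absent rows missing."""
        out = np.zeros((ped.n, len(markers), 2), dtype=np.int32)
        mk = [self._marker_index[m] for m in markers]
        for i, iid in enumerate(ped.ids):
            k = self._id_index.get(iid)
            if k is not None:
                out[i] = self.data[k][mk]
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = {"id": self.ids}
        for j, m in enumerate(self.markers):
            cols[f"{m}_1"] = self.data[:, j, 0]
            cols[f"{m}_2"] = self.data[:, j, 1]
        return pd.DataFrame(cols)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t")
        markers = [c[:-2] for c in df.columns[1:] if c.endswith("_1")]
        data = np.zeros((len(df), len(markers), 2), dtype=np.int32)
        for j, m in enumerate(markers):
            data[:, j, 0] = df[f"{m}_1"]
            data[:, j, 1] = df[f"{m}_2"]
        return cls(df["id"].astype(str).tolist(), markers, data)


@dataclass
class PhenotypeTable:
    """Per-F2 trait values plus factor/covariate/litter columns.

    ``data`` must contain an ``id`` column; missing trait values are NaN and
    drop a record only for models of that trait.
    """

    data: pd.DataFrame

    def __post_init__(self):
        if "id" not in self.data.columns:
            raise ValueError("phenotype table needs an 'id' column")
        self.data = self.data.copy()
        self.data["id"] = self.data["id"].astype(str)

    @property
    def ids(self) -> list[str]:
        return self.data["id"].tolist()

    def restrict_to(self, keep_ids: Iterable[str]) -> "PhenotypeTable":
        keep = set(str(i) for i in keep_ids)
        return PhenotypeTable(self.data[self.data["id"].isin(keep)].reset_index(drop=True))

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class TraitModelSpec:
    """Which fixed effects/covariates/random litter term a trait's model uses."""

    trait: str
    factors: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    litter: str | None = None
    exclude_carriers_of: tuple[str, ...] = ()

    def check_against(self, phen: PhenotypeTable) -> list[Violation]:
        out = []
        cols = set(phen.data.columns)
        for c in (self.trait, *self.factors, *self.covariates, *((self.litter,) if self.litter else ())):
            if c not in cols:
                out.append(Violation("missing-column", f"model for {self.trait!r} references absent column {c!r}"))
        return out


@dataclass
class RelationshipMatrix:
    """Symmetric individual×individual relationship matrix on the additive scale.

    ``role`` is ``pedigree-additive`` (numerator relationship A) or
    ``ibd-at-position`` (marker-conditional IBD matrix G(p)); diagonal lies
    in [1, 2] (1 + inbreeding / own-gamete IBD probability).
    """

    ids: tuple[str, ...]
    values: np.ndarray
    role: str = "pedigree-additive"
    position: tuple[str, float] | None = None

    def __post_init__(self):
        self.ids = tuple(str(i) for i in self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape mismatch")

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([pos[str(i)] for i in ids], dtype=np.int64)
        return RelationshipMatrix(tuple(str(i) for i in ids), self.values[np.ix_(idx, idx)], self.role, self.position)

    def check(self, jitter: float = 1e-8) -> list[Violation]:
        out = []
        v = self.values
        if not np.allclose(v, v.T, atol=1e-10):
            out.append(Violation("asymmetric", f"{self.role} matrix not symmetric"))
        d = np.diag(v)
        if np.any(d < 1 - 1e-9) or np.any(d > 2 + 1e-9):
            out.append(Violation("diagonal-range", "diagonal outside [1, 2]"))
        off = v[~np.eye(len(d), dtype=bool)]
        if off.size and (off.min() < -1e-9 or off.max() > 2 + 1e-9):
            out.append(Violation("offdiagonal-range", "off-diagonal outside [0, 2]"))
        w = np.linalg.eigvalsh(v)
        if w.min() < -jitter * max(1.0, w.max()):
            out.append(Violation("not-psd", f"minimum eigenvalue {w.min():.3g}"))
        return out


def validate_inputs(
    pedigree: Pedigree,
    gmap: GeneticMap,
    genotypes: GenotypeTable,
    phenotypes: PhenotypeTable,
    model_specs: Sequence[TraitModelSpec] = (),
) -> list[Violation]:
    """Cross-check the four parsed inputs; returns all violations, throws nothing.

    Idempotent and side-effect free: an empty report means the inputs are
    mutually consistent.
    """
    out: list[Violation] = []
    # pedigree-internal problems (when parsed with strict=False)
    for i, iid in enumerate(pedigree.ids):
        gen = pedigree.generation[i]
        if gen not in GENERATIONS:
            out.append(Violation("bad-generation", f"{iid}: generation {gen!r}"))
        if gen == "F0" and (pedigree.sire_idx[i] >= 0 or pedigree.dam_idx[i] >= 0):
            out.append(Violation("founder-with-parent", f"F0 individual {iid} has a recorded parent"))
        if gen in ("F1", "F2") and (pedigree.sire_idx[i] < 0 or pedigree.dam_idx[i] < 0):
            out.append(Violation("unknown-parent", f"{gen} individual {iid} has an unknown parent"))
    seen: set[str] = set()
    for iid in pedigree.ids:
        if iid in seen:
            out.append(Violation("duplicate-id", f"id {iid} occurs more than once"))
        seen.add(iid)
    # map
    for g in gmap.groups:
        if len(g.positions) and g.positions[0] < 0:
            out.append(Violation("negative-position", f"group {g.name} starts below 0 cM"))
        bad = np.nonzero(np.diff(g.positions) <= 0)[0]
        for b in bad:
            out.append(
                Violation(
                    "non-increasing-position",
                    f"group {g.name}: {g.markers[b + 1]} at {g.positions[b + 1]} cM does not follow {g.markers[b]}",
                )
            )
    # genotypes
    for iid in genotypes.ids:
        if iid not in pedigree.index:
            out.append(Violation("orphan-genotype", f"genotyped individual {iid} absent from pedigree"))
    known = set(gmap.marker_names)
    for m in genotypes.markers:
        if m not in known:
            out.append(Violation("unmapped-marker", f"marker {m} not on the genetic map"))
    # phenotypes
    for iid in phenotypes.ids:
        k = pedigree.index.get(iid)
        if k is None:
            out.append(Violation("orphan-phenotype", f"phenotyped individual {iid} absent from pedigree"))
        elif pedigree.generation[k] != "F2":
            out.append(Violation("non-f2-phenotype", f"{iid} is {pedigree.generation[k]} but carries phenotypes"))
    for spec in model_specs:
        out.extend(spec.check_against(phenotypes))
        for c in (*spec.factors, *spec.covariates):
            if c in phenotypes.data.columns and phenotypes.data[c].isna().any():
                nmiss = int(phenotypes.data[c].isna().sum())
                out.append(
                    Violation(
                        "missing-covariate",
                        f"column {c!r} used by {spec.trait!r} has {nmiss} missing values (records dropped per model)",
                    )
                )
    return out


def exclude_carriers(
    pedigree: Pedigree,
    genotypes: GenotypeTable,
    phenotypes: PhenotypeTable,
    locus: str,
) -> PhenotypeTable:
    """Phenotypes restricted to F2 individuals homozygous wild-type at ``locus``.

    The wild-type allele is the more frequent of the locus' two allele
    labels (ties broken toward the smaller label).  Pedigree and genotypes
    are untouched, so IBD matrices remain computable on the full marker
    pedigree and can be subset afterwards.
    """
    if locus not in genotypes.markers:
        raise KeyError(f"unknown locus {locus!r}")
    alleles = genotypes.alleles(locus)
    if len(alleles) > 2:
        raise ValueError(f"locus {locus!r} has {len(alleles)} alleles; expected 2 (wild-type, mutant)")
    col = genotypes.marker_column(locus)
    if len(alleles) == 1:
        wild = alleles[0]
    else:
        counts = {a: int(np.sum(col == a)) for a in alleles}
        wild = min(alleles, key=lambda a: (-counts[a], a))
    keep = []
    for iid in phenotypes.ids:
        if not genotypes.has_individual(iid):
            continue
        a, b = genotypes.get(iid, locus)
        if a == wild and b == wild:
            keep.append(iid)
    return phenotypes.restrict_to(keep)
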