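"""Per-chromosome LRT profiles, support intervals and predicted QTL effects.

For a trait model the polygenic H0 is fitted once; the QTL H1 (polygenic +
IBD term at the position) is refitted at every grid position, warm-started
from its neighbour.  Only the per-chromosome maximum is tested against
thresholds; the -1 LOD (ln 10 drop) support interval around the maximum
approximates a 95% confidence interval for QTL position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneticMap, GenotypeTable, PhenotypeTable, Pedigree, RelationshipMatrix, TraitModelSpec, exclude_carriers
from .ibd import IbdStore
from .varcomp import (
    ModelData,
    RemlWorkspace,
    VarianceComponentFit,
    build_model_data,
    fit_reml,
    litter_kernel,
    lrt,
    total_variance_check,
    variance_explained,
)

LOD_DROP = math.log(10.0)


@dataclass
class ScanResult:
    """LRT profile over one linkage group for one trait model."""

    group: str
    trait: str
    positions: np.ndarray
    lrt: np.ndarray  # NaN where the H1 fit failed
    sigma2_q: np.ndarray
    qtl_fraction: np.ndarray
    h1_loglik: np.ndarray
    h0_fit: VarianceComponentFit | None = None
    h1_at_max: VarianceComponentFit | None = None
    qtl_effects: pd.Series | None = None
    flanking_markers: tuple[str | None, str | None] = (None, None)
    flags: list[tuple[float, str]] = field(default_factory=list)

    @property
    def max_index(self) -> int | None:
        if np.all(np.isnan(self.lrt)):
            return None
        return int(np.nanargmax(np.where(np.isnan(self.lrt), -np.inf, self.lrt)))

    @property
    def max_position(self) -> float | None:
        i = self.max_index
        return None if i is None else float(self.positions[i])

    @property
    def max_lrt(self) -> float | None:
        i = self.max_index
        return None if i is None else float(self.lrt[i])

    @property
    def support(self) -> tuple[float, float] | None:
        if self.max_index is None:
            return None
        return support_interval(self.positions, self.h1_loglik)

    def to_frame(self) -> pd.DataFrame:
        flagged = {p for p, _ in self.flags}
        return pd.DataFrame(
            {
                "group": self.group,
                "position_cM": self.positions,
                "lrt": self.lrt,
                "sigma2_qtl": self.sigma2_q,
                "qtl_fraction": self.qtl_fraction,
                "flags": [";".join(f for p2, f in self.flags if p2 == p) for p in self.positions],
            }
        )

    def summary_row(self) -> dict:
        ci = self.support
        return {
            "trait": self.trait,
            "group": self.group,
            "max_cM": self.max_position,
            "ci_low_cM": None if ci is None else ci[0],
            "ci_high_cM": None if ci is None else ci[1],
            "max_lrt": self.max_lrt,
            "qtl_pct": None if self.max_index is None else 100.0 * float(self.qtl_fraction[self.max_index]),
            "flank_left": self.flanking_markers[0],
            "flank_right": self.flanking_markers[1],
        }


def support_interval(positions: np.ndarray, loglik: np.ndarray, drop: float = LOD_DROP) -> tuple[float, float]:
    """Contiguous grid run around the maximum with log-likelihood >= max - drop.

    The run is forced contiguous through the maximum; NaN (failed) positions
    terminate it.  Ties in the maximum break toward the smaller cM."""
    ll = np.asarray(loglik, dtype=float)
    if np.all(np.isnan(ll)):
        raise ValueError("profile has no finite values")
    imax = int(np.nanargmax(np.where(np.isnan(ll), -np.inf, ll)))
    cut = ll[imax] - drop
    lo = imax
    while lo > 0 and np.isfinite(ll[lo - 1]) and ll[lo - 1] >= cut:
        lo -= 1
    hi = imax
    while hi < len(ll) - 1 and np.isfinite(ll[hi + 1]) and ll[hi + 1] >= cut:
        hi += 1
    return float(positions[lo]), float(positions[hi])


def predict_qtl_effects(fit: VarianceComponentFit, component: str = "qtl") -> pd.Series:
    """Per-individual predicted QTL genotypic effects, in trait units.

    BLUP solutions of the mixed-model equations for the position-specific
    IBD term (the individual-level sum of the two gametic contributions);
    all zero when sigma2_q is estimated at the boundary."""
    if component in fit.blup:
        u = fit.blup[component]
    else:
        u = np.zeros(fit.n_records)
    return pd.Series(u, index=fit.ids, name=component)


def _flanking_markers(gmap: GeneticMap, group: str, position: float) -> tuple[str | None, str | None]:
    g = gmap.group(group)
    left = [m for m, p in zip(g.markers, g.positions) if p <= position + 1e-9]
    right = [m for m, p in zip(g.markers, g.positions) if p >= position - 1e-9]
    return (left[-1] if left else None, right[0] if right else None)


class QtlScan:
    """Scan driver binding phenotypes, pedigree A-matrix and an IBD store.

    H0 is fitted once per trait model and reused across positions and
    groups; fits at individual positions run without effect solutions, and
    the H1 at the maximum is refitted with solutions for effect prediction.
    """

    def __init__(
        self,
        pedigree: Pedigree,
        gmap: GeneticMap,
        phenotypes: PhenotypeTable,
        amatrix: RelationshipMatrix,
        ibd_store: IbdStore,
        genotypes: GenotypeTable | None = None,
        max_iter: int = 200,
    ):
        self.pedigree = pedigree
        self.gmap = gmap
        self.phenotypes = phenotypes
        self.amatrix = amatrix
        self.store = ibd_store
        self.genotypes = genotypes
        self.max_iter = max_iter
        self._h0_cache: dict = {}

    def _model(self, spec: TraitModelSpec, phen: PhenotypeTable) -> ModelData:
        return build_model_data(phen, spec)

    def _kernels_for(self, spec: TraitModelSpec, data: ModelData):
        kernels = {"polygenic": self.amatrix.subset(data.ids).values}
        if spec.litter is not None and data.litter_codes is not None:
            kernels["litter"] = litter_kernel(data.litter_codes)
        return kernels

    def h0_fit(self, spec: TraitModelSpec, phen: PhenotypeTable | None = None, key=None):
        cache_key = (spec, key)
        if cache_key in self._h0_cache:
            return self._h0_cache[cache_key]
        data = self._model(spec, phen if phen is not None else self.phenotypes)
        ws = RemlWorkspace(data.X, data.columns)
        kernels = self._kernels_for(spec, data)
        fit = fit_reml(
            data.y, data.X, kernels, columns=data.columns, ids=data.ids,
            workspace=ws, max_iter=self.max_iter,
        )
        self._h0_cache[cache_key] = (data, ws, kernels, fit)
        return self._h0_cache[cache_key]

    def scan_chromosome(
        self,
        spec: TraitModelSpec,
        group: str,
        phen: PhenotypeTable | None = None,
        key=None,
    ) -> ScanResult:
        """LRT profile over the group's grid; failed positions are flagged.

        Degenerate responses (zero variance) yield an all-flagged result."""
        phen_tbl = phen if phen is not None else self.phenotypes
        positions = self.store.positions(group)
        try:
            data, ws, kernels, h0 = self.h0_fit(spec, phen_tbl, key=key)
        except ValueError as e:
            res = ScanResult(
                group=group, trait=spec.trait, positions=positions,
                lrt=np.full(len(positions), np.nan),
                sigma2_q=np.full(len(positions), np.nan),
                qtl_fraction=np.full(len(positions), np.nan),
                h1_loglik=np.full(len(positions), np.nan),
            )
            res.flags = [(float(p), f"non-informative: {e}") for p in positions]
            return res

        # subset index into the store's id order, fixed once per scan
        store_pos = {i: k for k, i in enumerate(self.store.ids)}
        idx = np.array([store_pos[i] for i in data.ids], dtype=np.int64)
        n = len(positions)
        lrt_prof = np.full(n, np.nan)
        s2q = np.full(n, np.nan)
        frac = np.full(n, np.nan)
        h1_ll = np.full(n, np.nan)
        flags: list[tuple[float, str]] = []
        start = dict(h0.raw_components)
        start["qtl"] = 1e-6 * float(np.var(data.y))
        fits: list[VarianceComponentFit | None] = [None] * n
        for j, p in enumerate(positions):
            G = self.store._entries[(group, round(float(p), 6))][np.ix_(idx, idx)]
            kern = dict(kernels)
            kern["qtl"] = G
            try:
                fit = fit_reml(
                    data.y, data.X, kern, columns=data.columns, ids=data.ids,
                    workspace=ws, kernel_keys={k: (k, key) for k in kernels},
                    start=start, max_iter=self.max_iter, want_effects=False,
                )
            except (ValueError, np.linalg.LinAlgError) as e:
                flags.append((float(p), f"fit-failed: {e}"))
                continue
            if not fit.converged:
                flags.append((float(p), "non-convergence"))
                continue
            fits[j] = fit
            lrt_prof[j] = lrt(h0, fit)
            s2q[j] = fit.components["qtl"]
            frac[j] = variance_explained(fit)["qtl"]
            h1_ll[j] = fit.loglik
            dev, bad = total_variance_check(h0, fit)
            if bad:
                flags.append((float(p), f"variance-inflation:{dev:+.1f}%"))
            start = dict(fit.raw_components)  # warm start the neighbour
        result = ScanResult(
            group=group, trait=spec.trait, positions=positions, lrt=lrt_prof,
            sigma2_q=s2q, qtl_fraction=frac, h1_loglik=h1_ll, h0_fit=h0, flags=flags,
        )
        i = result.max_index
        if i is not None:
            p = float(positions[i])
            G = self.store._entries[(group, round(p, 6))][np.ix_(idx, idx)]
            kern = dict(kernels)
            kern["qtl"] = G
            h1max = fit_reml(
                data.y, data.X, kern, columns=data.columns, ids=data.ids,
                workspace=ws, kernel_keys={k: (k, key) for k in kernels},
                start=dict(fits[i].raw_components) if fits[i] else None,
                max_iter=self.max_iter, want_effects=True,
            )
            result.h1_at_max = h1max
            result.qtl_effects = predict_qtl_effects(h1max)
            result.flanking_markers = _flanking_markers(self.gmap, group, p)
        return result


@dataclass
class CarrierContrast:
    """Paired scans including vs excluding carriers of a causal mutation."""

    locus: str
    locus_position: float
    include: ScanResult
    exclude: ScanResult
    lrt_at_locus_include: float
    lrt_at_locus_exclude: float


def carrier_contrast(
    scanner: QtlScan,
    spec: TraitModelSpec,
    group: str,
    causal_locus: str,
) -> CarrierContrast:
    """Run the scan twice: all animals, then animals homozygous wild-type at
    ``causal_locus``; report both profiles and the LRT at the locus' grid
    position (nearest grid point)."""
    if scanner.genotypes is None:
        raise ValueError("carrier_contrast needs genotypes on the scanner")
    g = scanner.gmap.group(group)
    locus_pos = float(g.positions[g.markers.index(causal_locus)])
    include = scanner.scan_chromosome(spec, group, key="include")
    phen_ex = exclude_carriers(scanner.pedigree, scanner.genotypes, scanner.phenotypes, causal_locus)
    exclude = scanner.scan_chromosome(spec, group, phen=phen_ex, key=("exclude", causal_locus))

    def lrt_at(res: ScanResult) -> float:
        j = int(np.argmin(np.abs(res.positions - locus_pos)))
        return float(res.lrt[j])

    return CarrierContrast(
        locus=causal_locus,
        locus_position=locus_pos,
        include=include,
        exclude=exclude,
        lrt_at_locus_include=lrt_at(include),
        lrt_at_locus_exclude=lrt_at(exclude),
    )
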