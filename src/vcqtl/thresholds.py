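"""Empirical significance thresholds from polygenic-only null simulations.

Chromosome-wise thresholds are quantiles of the per-chromosome maximum LRT
over phenotypes simulated with additive polygenic variation only (h2 = 0.3),
scanned against the *same* IBD matrices and pedigree as the real analysis.
Genome-wise levels map to chromosome-wise levels through the Sidak form for
independent scanning of 18 autosomes; the chi-square with 2 degrees of
freedom is the theoretical upper-bound reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Pedigree, RelationshipMatrix
from .ibd import IbdStore
from .varcomp import RemlWorkspace, _chol_lower, _inv_from_chol, fit_reml, lrt

DEFAULT_LEVELS = (0.05, 0.01, 0.00285, 0.00058)


def simulate_null_phenotype(
    pedigree: Pedigree,
    amatrix: RelationshipMatrix,
    h2: float = 0.3,
    seed: int = 0,
    ids: list[str] | None = None,
    sigma_p: float = 1.0,
    return_breeding_values: bool = False,
):
    """Phenotypes carrying polygenic additive variation only.

    Breeding values follow the pedigree recursion (founders N(0, sigma_a^2);
    offspring = parent mean + Mendelian sampling N(0, sigma_a^2/2 * (1 -
    (F_s+F_d)/2))), giving covariance sigma_a^2 A exactly; residuals are
    i.i.d. so that sigma_a^2/(sigma_a^2+sigma_e^2) = h2.  Deterministic
    given seed; returns values for ``ids`` (default: all F2)."""
    rng = np.random.default_rng(seed)
    s2a = h2 * sigma_p**2
    s2e = (1.0 - h2) * sigma_p**2
    apos = {i: k for k, i in enumerate(amatrix.ids)}
    F = np.zeros(pedigree.n)
    for i, iid in enumerate(pedigree.ids):
        k = apos.get(iid)
        if k is not None:
            F[i] = amatrix.values[k, k] - 1.0
    bv = np.zeros(pedigree.n)
    for i in range(pedigree.n):
        si, di = pedigree.sire_idx[i], pedigree.dam_idx[i]
        if si < 0 and di < 0:
            bv[i] = rng.normal(0.0, np.sqrt(s2a))
        else:
            mean = 0.5 * (bv[si] if si >= 0 else 0.0) + 0.5 * (bv[di] if di >= 0 else 0.0)
            fbar = 0.5 * ((F[si] if si >= 0 else 0.0) + (F[di] if di >= 0 else 0.0))
            bv[i] = mean + rng.normal(0.0, np.sqrt(max(0.5 * s2a * (1.0 - fbar), 0.0)))
    if ids is None:
        ids = pedigree.ids_of_generation("F2")
    idx = pedigree.indices(ids)
    y = bv[idx] + rng.normal(0.0, np.sqrt(s2e), size=len(idx)) if s2e > 0 else bv[idx]
    out = pd.Series(y, index=[str(i) for i in ids], name="null_phenotype")
    if return_breeding_values:
        return out, pd.Series(bv, index=pedigree.ids, name="breeding_value")
    return out


@dataclass
class NullScanDesign:
    """Fixed design reused across null replicates (records, X, A, IBD grid)."""

    ids: list[str]
    X: np.ndarray
    amatrix: RelationshipMatrix
    store: IbdStore
    group: str
    h2: float = 0.3


def null_max_lrt_distribution(
    design: NullScanDesign,
    pedigree: Pedigree,
    n_reps: int,
    seed: int = 0,
    max_iter: int = 100,
) -> np.ndarray:
    """Per-replicate maximum LRT over the group's grid under the polygenic null.

    The IBD store is computed once outside and reused for every replicate
    (the same marker genotypes and pedigree underlie all simulated phenotype
    sets).  Replicates with a non-convergent H0 are discarded."""
    ids = design.ids
    ws = RemlWorkspace(design.X)
    A = design.amatrix.subset(ids).values
    store_pos = {i: k for k, i in enumerate(design.store.ids)}
    idx = np.array([store_pos[i] for i in ids], dtype=np.int64)
    positions = design.store.positions(design.group)
    Gs = [
        design.store._entries[(design.group, round(float(p), 6))][np.ix_(idx, idx)]
        for p in positions
    ]
    kernel_keys_h0 = {"polygenic": "A"}
    Astar = ws.project_kernel(A, "A")
    Gstars = [ws.project_kernel(G, ("G", j)) for j, G in enumerate(Gs)]
    m = Astar.shape[0]
    out = []
    h0_start = None
    for rep in range(n_reps):
        y = simulate_null_phenotype(
            pedigree, design.amatrix, h2=design.h2, seed=seed + rep, ids=ids
        ).to_numpy()
        try:
            h0 = fit_reml(
                y, design.X, {"polygenic": A}, workspace=ws, ids=ids,
                kernel_keys=kernel_keys_h0, start=h0_start, max_iter=max_iter,
                want_effects=False,
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not h0.converged:
            continue
        h0_start = dict(h0.raw_components)
        # KKT screen at the H0 optimum: a non-positive score for sigma2_q at
        # the zero boundary means the H1 optimum is the H0 fit (LRT = 0)
        th = h0.raw_components
        V0 = th["polygenic"] * Astar + th["residual"] * np.eye(m)
        c0 = _chol_lower(V0)
        V0inv = _inv_from_chol(c0) if c0 is not None else None
        ystar = ws.project_y(y)
        alpha0 = V0inv @ ystar if V0inv is not None else None
        best = 0.0
        start = dict(h0.raw_components)
        start["qtl"] = 1e-6 * float(np.var(y))
        for j, G in enumerate(Gs):
            if alpha0 is not None:
                Gstar = Gstars[j]
                score_q = 0.5 * (alpha0 @ (Gstar @ alpha0) - float(np.sum(V0inv * Gstar)))
                if score_q <= 0.0:
                    continue
            try:
                h1 = fit_reml(
                    y, design.X, {"polygenic": A, "qtl": G}, workspace=ws, ids=ids,
                    kernel_keys={"polygenic": "A", "qtl": ("G", j)}, start=start,
                    max_iter=max_iter, want_effects=False,
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            if h1.converged:
                best = max(best, lrt(h0, h1))
                start = dict(h1.raw_components)
        out.append(best)
    return np.array(out)


def chromosome_thresholds(sample: np.ndarray, levels=DEFAULT_LEVELS) -> dict[float, float]:
    """Empirical upper-tail quantiles by the nearest-rank convention.

    The threshold at level a is the sample value of rank floor((1-a)n)+1
    (ascending, 1-based): the smallest value strictly exceeded by fewer than
    a fraction a of the sample."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError(f"sample of {n} max-LRT values is too small (need >= 100)")
    out = {}
    for a in levels:
        rank = int(np.floor((1.0 - a) * n)) + 1
        rank = min(rank, n)
        out[a] = float(x[rank - 1])
    return out


def quantile_mc_error(sample: np.ndarray, level: float) -> float:
    """Approximate Monte-Carlo standard error of an empirical upper quantile
    (binomial variance through a kernel density estimate of the local slope)."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    q = 1.0 - level
    se_p = np.sqrt(q * (1 - q) / n)
    lo = max(int(np.floor((q - se_p) * n)) - 1, 0)
    hi = min(int(np.ceil((q + se_p) * n)), n - 1)
    if hi <= lo:
        return 0.0
    return float((x[hi] - x[lo]) / 2.0)


def genomewise_to_chromosomewise(alpha: float, n_chromosomes: int = 18) -> float:
    """Chromosome-wise level for a genome-wise alpha over independent scans.

    Sidak form 1 - (1-a)^(1/n): 5% genome-wise over 18 autosomes maps to a
    0.285% chromosome-wise level."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return 1.0 - (1.0 - alpha) ** (1.0 / n_chromosomes)


def chi2_reference(level: float, df: int = 2) -> float:
    """Upper-tail chi-square quantile, the theoretical upper-bound threshold
    for a genome-scan interval test (df=2, 1% -> 9.21)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    return float(stats.chi2.isf(level, df))


@dataclass
class ThresholdTable:
    """Per-group empirical thresholds with replicate counts and chi2 reference."""

    h2: float
    levels: tuple[float, ...] = DEFAULT_LEVELS
    rows: dict[str, dict] = field(default_factory=dict)

    def add_group(self, group: str, sample: np.ndarray) -> None:
        th = chromosome_thresholds(sample, self.levels)
        self.rows[group] = {
            "n_reps": len(sample),
            **{f"q{a:g}": th[a] for a in self.levels},
            **{f"mc_se{a:g}": quantile_mc_error(sample, a) for a in self.levels},
        }

    def threshold(self, group: str, level: float) -> float:
        return self.rows[group][f"q{level:g}"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.rows, orient="index")
        df.index.name = "group"
        for a in self.levels:
            df[f"chi2_2df_q{a:g}"] = chi2_reference(a)
        df["h2"] = self.h2
        return df

    def significance_tier(self, group: str, max_lrt: float) -> str:
        """Annotate a scan maximum: genome-wise 5%/1% (via Sidak-mapped
        chromosome-wise levels), else chromosome-wise suggestive tiers."""
        labels = [
            (0.00058, "significant-1%-genomewise"),
            (0.00285, "significant-5%-genomewise"),
            (0.01, "suggestive-1%-chromosomewise"),
            (0.05, "suggestive-5%-chromosomewise"),
        ]
        for level, label in labels:
            if level in self.levels and max_lrt >= self.threshold(group, level):
                return label
        return "not-significant"
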