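"""AI-REML estimation of mixed models with polygenic, positional-QTL and litter components.

Model: y = Xb + sum_i u_i + e, u_i ~ N(0, sigma_i^2 K_i), e ~ N(0, sigma_e^2 I),
with K_i the pedigree A-matrix, a position-specific IBD matrix, or a
litter-block matrix.  Estimation maximizes the REML log-likelihood
-(1/2)[log|V| + log|X'V^-1 X| + y'Py] over non-negative components by
average-information updates with EM-style fallback steps and step halving,
after projecting onto error contrasts (an orthonormal basis of the null
space of X'), which turns REML into plain ML on the projected data.  The
standard REML log-likelihood is recovered through the identity
log|V| + log|X'V^-1 X| = log|X'X| + log|T'VT|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .core import PhenotypeTable, RelationshipMatrix, TraitModelSpec


@dataclass
class ModelData:
    """Response, full-rank fixed design and record ids for one trait model."""

    ids: list[str]
    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    litter_codes: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)


def build_model_data(phen: PhenotypeTable, spec: TraitModelSpec, min_level_count: int = 2) -> ModelData:
    """Per-model missing-data removal and fixed-design construction.

    Records missing the trait, any factor level or any covariate are dropped
    for this model only.  Factor levels with fewer than ``min_level_count``
    records are merged into the preceding level in run order (noted, not
    silent).  Returns an intercept + treatment-coded design.
    """
    df = phen.data
    cols = [spec.trait, *spec.factors, *spec.covariates]
    if spec.litter:
        cols.append(spec.litter)
    sub = df[["id", *cols]].dropna(subset=[spec.trait, *spec.factors, *spec.covariates])
    notes: list[str] = []
    n_drop = len(df) - len(sub)
    if n_drop:
        notes.append(f"dropped {n_drop} records with missing response/factor/covariate")
    parts = [np.ones((len(sub), 1))]
    names = ["intercept"]
    for f in spec.factors:
        levels = list(pd.unique(sub[f]))
        counts = sub[f].value_counts()
        merged = {}
        kept_levels = []
        for lv in levels:
            if counts[lv] < min_level_count and kept_levels:
                merged[lv] = kept_levels[-1]
                notes.append(f"factor {f!r}: level {lv!r} ({counts[lv]} records) merged into {kept_levels[-1]!r}")
            else:
                kept_levels.append(lv)
        vals = sub[f].map(lambda v: merged.get(v, v))
        for lv in kept_levels[1:]:
            parts.append((vals == lv).to_numpy(dtype=float)[:, None])
            names.append(f"{f}={lv}")
    for c in spec.covariates:
        parts.append(sub[c].to_numpy(dtype=float)[:, None])
        names.append(c)
    X = np.hstack(parts)
    litter = None
    if spec.litter:
        codes = pd.Categorical(sub[spec.litter]).codes.astype(np.int64)
        litter = codes
    return ModelData(
        ids=sub["id"].astype(str).tolist(),
        y=sub[spec.trait].to_numpy(dtype=float),
        X=X,
        columns=names,
        litter_codes=litter,
        notes=notes,
    )


def litter_kernel(codes: np.ndarray) -> np.ndarray:
    """Block matrix: 1 within a common litter, 0 elsewhere (identity over litters)."""
    return (codes[:, None] == codes[None, :]).astype(float)


class RankDeficientDesign(ValueError):
    pass


class RemlWorkspace:
    """Caches the error-contrast projection for one fixed design X.

    Reused across scan positions and phenotype replicates: T (orthonormal
    null-space basis of X'), log|X'X| and the projected kernels T'KT.
    """

    def __init__(self, X: np.ndarray, columns: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        Q, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        rank = int(np.sum(diag > tol))
        if rank < p:
            bad = sorted(piv[rank:])
            names = [columns[j] if columns else f"col{j}" for j in bad]
            raise RankDeficientDesign(f"fixed design is rank deficient; confounded columns: {names}")
        Qf, _ = linalg.qr(X, mode="full")
        self.X = X
        self._columns = list(columns) if columns is not None else None
        self.n, self.p = n, p
        self.T = Qf[:, p:]
        _, self.logdet_xtx = np.linalg.slogdet(X.T @ X)
        self._proj_cache: dict = {}

    def project_y(self, y: np.ndarray) -> np.ndarray:
        return self.T.T @ y

    def project_kernel(self, K: np.ndarray, key=None) -> np.ndarray:
        if key is not None and key in self._proj_cache:
            return self._proj_cache[key]
        Ks = self.T.T @ K @ self.T
        if key is not None:
            self._proj_cache[key] = Ks
        return Ks


@dataclass
class VarianceComponentFit:
    """REML solution: components, log-likelihood, solutions, AI matrix."""

    components: dict[str, float]  # boundary estimates reported as 0
    loglik: float
    converged: bool
    n_iter: int
    n_records: int
    ids: list[str]
    ai_matrix: pd.DataFrame | None = None
    ai_inverse: pd.DataFrame | None = None
    fixed_effects: pd.Series | None = None
    blup: dict[str, np.ndarray] = field(default_factory=dict)
    raw_components: dict[str, float] = field(default_factory=dict)
    at_boundary: dict[str, bool] = field(default_factory=dict)

    @property
    def total_variance(self) -> float:
        return float(sum(self.components.values()))

    def summary(self) -> str:
        lines = [
            f"records: {self.n_records}  iterations: {self.n_iter}  converged: {self.converged}",
            f"REML log-likelihood: {self.loglik:.6f}",
        ]
        for k, v in self.components.items():
            tag = " (boundary)" if self.at_boundary.get(k) else ""
            lines.append(f"  sigma2[{k}] = {v:.6g}{tag}")
        if self.fixed_effects is not None:
            lines.append("fixed effects:")
            for k, v in self.fixed_effects.items():
                lines.append(f"  {k} = {v:.6g}")
        return "\n".join(lines)


def _chol_logdet(V: np.ndarray):
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return (c, low), logdet


def _chol_lower(V: np.ndarray):
    """LAPACK Cholesky (lower) or None if not positive definite."""
    c, info = linalg.lapack.dpotrf(V, lower=1, overwrite_a=0)
    return c if info == 0 else None


def _inv_from_chol(c: np.ndarray):
    inv, info = linalg.lapack.dpotri(c.copy(), lower=1)
    if info != 0:
        return None
    return inv + np.tril(inv, -1).T


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    kernels: dict[str, np.ndarray | None],
    *,
    columns: list[str] | None = None,
    ids: list[str] | None = None,
    workspace: RemlWorkspace | None = None,
    kernel_keys: dict[str, object] | None = None,
    start: dict[str, float] | None = None,
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
    want_effects: bool = True,
    min_records: int = 30,
) -> VarianceComponentFit:
    """Maximize the REML log-likelihood over non-negative variance components.

    ``kernels`` maps component name -> covariance structure matrix; the
    value ``None`` denotes the identity (used for the residual, which is
    always appended as ``'residual'`` if absent).  Components are floored at
    1e-8 x sample variance during iteration; estimates at the floor are
    reported as 0 with the boundary flag set.  Convergence requires relative
    log-likelihood change < tol_loglik and relative parameter change <
    tol_param; non-convergence after ``max_iter`` is flagged, not thrown.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < min_records:
        raise ValueError(f"only {n} records after missing-data removal; need >= {min_records}")
    names = list(kernels)
    if "residual" not in kernels:
        names = names + ["residual"]
        kernels = {**kernels, "residual": None}
    ws = workspace if workspace is not None else RemlWorkspace(X, columns)
    ystar = ws.project_y(y)
    m = len(ystar)
    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("response has zero variance")
    floor = 1e-8 * vary
    kernel_keys = kernel_keys or {}
    Ks: list[np.ndarray | None] = []
    for name in names:
        K = kernels[name]
        Ks.append(None if K is None else ws.project_kernel(np.asarray(K, dtype=float), kernel_keys.get(name)))

    k = len(names)
    theta = np.empty(k)
    if start:
        for i, name in enumerate(names):
            theta[i] = max(float(start.get(name, vary / k)), floor)
    else:
        theta[:] = vary / k
    theta = np.maximum(theta, floor)

    def build_V(th):
        V = np.zeros((m, m))
        for i, K in enumerate(Ks):
            if K is None:
                V[np.diag_indices(m)] += th[i]
            else:
                V += th[i] * K
        return V

    def evaluate(th):
        """(loglik, chol factor) for a candidate; (-inf, None) if V not PD.

        The line search needs only log|V| and the quadratic form, so the
        explicit inverse is deferred to the accepted step."""
        c = _chol_lower(build_V(th))
        if c is None:
            return -np.inf, None
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        z, info = linalg.lapack.dtrtrs(c, ystar, lower=1)
        if info != 0:
            return -np.inf, None
        return -0.5 * (logdet + float(z @ z)), c

    ll, cfac = evaluate(theta)
    if not np.isfinite(ll):
        raise ValueError("initial variance parameters give a singular covariance")
    converged = False
    it = 0
    AI = np.zeros((k, k))
    for it in range(1, max_iter + 1):
        Vinv = _inv_from_chol(cfac)
        if Vinv is None:
            break
        alpha = Vinv @ ystar
        Kalpha = np.empty((m, k))
        traces = np.empty(k)
        for i, K in enumerate(Ks):
            if K is None:
                Kalpha[:, i] = alpha
                traces[i] = np.trace(Vinv)
            else:
                Kalpha[:, i] = K @ alpha
                traces[i] = float(np.sum(Vinv * K))
        score = 0.5 * (Kalpha.T @ alpha - traces)  # dl/dtheta_i
        AI = 0.5 * (Kalpha.T @ (Vinv @ Kalpha))

        at_floor = theta <= floor * 1.0001
        frozen = at_floor & (score <= 0.0)
        free = ~frozen
        if not np.any(free):
            converged = True
            break
        delta = np.zeros(k)
        Af = AI[np.ix_(free, free)]
        try:
            delta[free] = np.linalg.solve(Af + 1e-12 * np.eye(int(free.sum())), score[free])
        except np.linalg.LinAlgError:
            delta[free] = score[free] / np.maximum(np.diag(Af), 1e-12)

        new_theta = None
        new_ll = -np.inf
        new_cfac = None
        step = 1.0
        for _half in range(12):
            # projected AI step: components may land exactly on the floor
            cand = np.maximum(theta + step * delta, floor)
            if np.any(cand != theta):
                cand_ll, cand_cfac = evaluate(cand)
                if cand_ll >= ll - 1e-10:
                    new_theta, new_ll, new_cfac = cand, cand_ll, cand_cfac
                    break
            step *= 0.5
        if new_theta is None:
            # EM-style fallback: multiplicative fixed-point update, ascent
            # enforced by geometric interpolation toward the current point
            ratio = np.ones(k)
            ratio[free] = (Kalpha.T @ alpha)[free] / np.maximum(traces[free], 1e-300)
            ratio = np.clip(ratio, 1e-4, 1e4)
            frac = 1.0
            for _half in range(12):
                cand = np.maximum(theta * ratio**frac, floor)
                cand_ll, cand_cfac = evaluate(cand)
                if cand_ll >= ll - 1e-10:
                    new_theta, new_ll, new_cfac = cand, cand_ll, cand_cfac
                    break
                frac *= 0.5
        if new_theta is None:
            converged = True  # no ascent direction improves: stationary
            break
        rel_param = np.max(
            np.abs(new_theta - theta)[free] / np.maximum(np.abs(theta), floor * 10)[free]
        )
        rel_ll = abs(new_ll - ll) / max(abs(ll), 1.0)
        theta, ll, cfac = new_theta, new_ll, new_cfac
        if rel_ll < tol_loglik and rel_param < tol_param:
            converged = True
            break

    loglik = ll - 0.5 * ws.logdet_xtx
    at_boundary = {name: bool(theta[i] <= floor * 1.0001) for i, name in enumerate(names)}
    reported = {
        name: (0.0 if at_boundary[name] else float(theta[i])) for i, name in enumerate(names)
    }
    ai_df = pd.DataFrame(AI, index=names, columns=names)
    try:
        ai_inv = pd.DataFrame(np.linalg.inv(AI), index=names, columns=names)
    except np.linalg.LinAlgError:
        ai_inv = None

    fit = VarianceComponentFit(
        components=reported,
        loglik=float(loglik),
        converged=converged,
        n_iter=it,
        n_records=n,
        ids=list(ids) if ids is not None else [str(i) for i in range(n)],
        ai_matrix=ai_df,
        ai_inverse=ai_inv,
        raw_components={name: float(theta[i]) for i, name in enumerate(names)},
        at_boundary=at_boundary,
    )
    if want_effects:
        _solve_effects(fit, y, ws, names, kernels, theta)
    return fit


def _solve_effects(fit, y, ws, names, kernels, theta):
    """Fixed-effect GLS solutions and BLUP random-effect predictions at the optimum."""
    n = len(y)
    V = np.zeros((n, n))
    for i, name in enumerate(names):
        K = kernels[name]
        if K is None:
            V[np.diag_indices(n)] += theta[i]
        else:
            V += theta[i] * np.asarray(K, dtype=float)
    cf, _ = _chol_logdet(V)
    X = ws.X
    ViX = linalg.cho_solve(cf, X, check_finite=False)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, ViX.T @ y)
    resid = y - X @ beta
    Vir = linalg.cho_solve(cf, resid, check_finite=False)
    cols = getattr(ws, "_columns", None) or [f"b{j}" for j in range(X.shape[1])]
    fit.fixed_effects = pd.Series(beta, index=cols[: len(beta)])
    for i, name in enumerate(names):
        K = kernels[name]
        if K is None:
            continue
        fit.blup[name] = theta[i] * (np.asarray(K, dtype=float) @ Vir)


def lrt(h0: VarianceComponentFit, h1: VarianceComponentFit) -> float:
    """Likelihood-ratio statistic 2(logL_H1 - logL_H0), floored at 0.

    Requires both fits converged on the same records with the same fixed
    design (same record ids is checked)."""
    if h0.ids != h1.ids:
        raise ValueError("H0 and H1 fits use different record sets")
    return max(0.0, 2.0 * (h1.loglik - h0.loglik))


def variance_explained(fit: VarianceComponentFit) -> dict[str, float]:
    """Each component over the sum of all estimated components."""
    total = fit.total_variance
    if total <= 0:
        return {k: 0.0 for k in fit.components}
    return {k: v / total for k, v in fit.components.items()}


def sampling_error_ratio(fit: VarianceComponentFit, component: str) -> float:
    """Component estimate over its AI sampling error.

    The sampling error is sqrt of the corresponding diagonal element of the
    inverse average-information matrix; boundary components return 0;
    a singular AI matrix makes the ratio undefined (NaN)."""
    if fit.at_boundary.get(component):
        return 0.0
    if fit.ai_inverse is None:
        return float("nan")
    var = float(fit.ai_inverse.loc[component, component])
    if var <= 0:
        return float("nan")
    return fit.components[component] / np.sqrt(var)


def total_variance_check(
    h0: VarianceComponentFit, h1: VarianceComponentFit, limit: float = 2.0
) -> tuple[float, bool]:
    """Percent deviation of H1 total variance from H0 total; flag beyond ``limit``%.

    A large inflation indicates an unstable QTL fit (the variance the QTL
    model adds is not redistributed from the polygenic/residual terms)."""
    t0, t1 = h0.total_variance, h1.total_variance
    dev = 100.0 * (t1 - t0) / t0
    return dev, abs(dev) > limit
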