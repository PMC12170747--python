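"""Geographically and temporally weighted regression, single- and multiscale.

GTWR estimates locally varying coefficients β_k(u_i, v_i, t_i) by solving a
weighted least-squares problem at every observation, with weights from a
separable Gaussian kernel in space and time:

    w_ij = exp(-d_s(i,j)² / bws²) · exp(-(t_i - t_j)² / bt²)

where bws is a fixed spatial bandwidth in meters and bt a temporal bandwidth
in years.  The multiscale variant (MGTWR) gives every covariate — including
the intercept, treated as variable 0 with x ≡ 1 — its own (bws_k, bt_k),
estimated by backfitting: terms f_k = β_k ⊙ x_k are initialized from a GTWR
fit and then iteratively refit one at a time against partial residuals, each
with a freshly selected bandwidth pair, until the relative change in the
residual sum of squares (SOC_RSS) drops to 1e-5 or a sweep cap is reached.

Bandwidths are selected by nested golden-section search on the log scale,
minimizing the corrected Akaike criterion

    AICc = 2n ln σ̂ + n ln 2π + n (n + ν) / (n - 2 - ν)

with ν the trace of the hat matrix and σ̂² = RSS/n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "ScalingRecord",
    "BandwidthSet",
    "STWRFit",
    "SingularFitError",
    "UndefinedAICcError",
    "standardize",
    "st_kernel_weights",
    "local_wls",
    "gtwr_fit",
    "aicc",
    "search_bandwidth",
    "mgtwr_fit",
    "soc_rss",
    "coefficient_summary",
    "compare_models",
]

MAX_SWEEPS = 50
SOC_TOL = 1e-5
_RIDGE = 1e-8
_GOLDEN_ITERS = 16


class SingularFitError(np.linalg.LinAlgError):
    """Locally weighted design matrix is rank-deficient."""


class UndefinedAICcError(ValueError):
    """Hat-matrix trace too large for the AICc correction term."""


@dataclass
class PanelDataset:
    """Space-time panel: one row per (location, epoch) observation.

    Wraps a DataFrame with columns ``id, u, v, t, y`` plus covariates; ``u``
    and ``v`` are projected meters, ``t`` epoch years.
    """

    data: pd.DataFrame
    covariates: list[str]
    standardized: bool = False
    scaling: "ScalingRecord | None" = None

    def __post_init__(self):
        required = ["u", "v", "t", "y"] + self.covariates
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        if self.data[required].isna().any().any():
            raise ValueError("panel contains missing values")
        if len(self.data) < len(self.covariates) + 2:
            raise ValueError("panel needs at least K+2 observations")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def coords(self) -> np.ndarray:
        return self.data[["u", "v"]].to_numpy(dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.data["t"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy(dtype=float)

    def X(self, intercept: bool = True) -> np.ndarray:
        x = self.data[self.covariates].to_numpy(dtype=float)
        if intercept:
            x = np.column_stack([np.ones(self.n), x])
        return x

    def variable_names(self, intercept: bool = True) -> list[str]:
        return (["intercept"] if intercept else []) + list(self.covariates)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PanelDataset":
        df = pd.read_csv(path)
        covs = [c for c in df.columns if c not in ("id", "u", "v", "t", "y")]
        return cls(df, covariates=covs)


@dataclass
class ScalingRecord:
    """Means/sds used to z-score y and the covariates; supports inversion."""

    means: dict[str, float]
    sds: dict[str, float]

    def unstandardize_coef(self, name: str, beta_std: np.ndarray) -> np.ndarray:
        """Raw-scale slope for one covariate from its standardized slope."""
        return beta_std * self.sds["y"] / self.sds[name]


@dataclass
class BandwidthSet:
    """Per-variable spatial (m) and temporal (yr) bandwidths."""

    bws: dict[str, float]
    bt: dict[str, float]

    def __post_init__(self):
        for d in (self.bws, self.bt):
            for k, v in d.items():
                if v <= 0:
                    raise ValueError(f"bandwidth for {k} must be positive")

    @classmethod
    def uniform(cls, names: Sequence[str], bws: float, bt: float) -> "BandwidthSet":
        return cls({k: bws for k in names}, {k: bt for k in names})


@dataclass
class STWRFit:
    """Fitted locally weighted regression: coefficients and diagnostics."""

    model: str
    coefficients: pd.DataFrame  # n × variables
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    tss: float
    r2: float
    aicc: float
    hat_trace: float
    bandwidths: BandwidthSet
    converged: bool = True
    n_sweeps: int = 0
    terms: pd.DataFrame | None = None  # additive terms f_k (MGTWR)
    panel_fingerprint: tuple = ()


def standardize(panel: PanelDataset) -> PanelDataset:
    """Z-score y and every covariate over the pooled panel (all epochs)."""
    if panel.standardized:
        return panel
    df = panel.data.copy()
    means, sds = {}, {}
    for col in ["y"] + panel.covariates:
        mu = float(df[col].mean())
        sd = float(df[col].std(ddof=0))
        if sd == 0:
            raise ValueError(f"zero-variance column: {col}")
        df[col] = (df[col] - mu) / sd
        means[col], sds[col] = mu, sd
    return PanelDataset(
        df, panel.covariates, standardized=True, scaling=ScalingRecord(means, sds)
    )


def _sq_dist_matrices(panel: PanelDataset) -> tuple[np.ndarray, np.ndarray]:
    uv = panel.coords
    t = panel.times
    du = uv[:, 0][:, None] - uv[:, 0][None, :]
    dv = uv[:, 1][:, None] - uv[:, 1][None, :]
    return du**2 + dv**2, (t[:, None] - t[None, :]) ** 2

def _kernel_matrix(ds2: np.ndarray, dt2: np.ndarray, bws: float, bt: float) -> np.ndarray:
    return np.exp(-ds2 / bws**2 - dt2 / bt**2)


def st_kernel_weights(panel: PanelDataset, i: int, bws: float, bt: float) -> np.ndarray:
    """Kernel weights of every observation relative to observation i."""
    if bws <= 0 or bt <= 0:
        raise ValueError("bandwidths must be positive")
    uv = panel.coords
    ds2 = ((uv - uv[i]) ** 2).sum(axis=1)
    dt2 = (panel.times - panel.times[i]) ** 2
    return np.exp(-ds2 / bws**2 - dt2 / bt**2)


def local_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, i: int | None = None):
    """Weighted least squares at one focal point.

    Returns ``(beta, h_ii)`` where ``h_ii`` is the focal diagonal element of
    the hat matrix (``None`` when no focal index is given).  Raises
    :class:`SingularFitError` on a rank-deficient weighted design.
    """
    xtw = X.T * w
    a = xtw @ X
    b = xtw @ y
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularFitError("weighted design is singular or near-singular")
    beta = np.linalg.solve(a, b)
    h_ii = None
    if i is not None:
        h_ii = float(X[i] @ np.linalg.solve(a, X[i] * w[i]))
    return beta, h_ii


def aicc(n: int, rss: float, hat_trace: float) -> float:
    """Corrected AIC for a locally weighted fit with effective df = hat trace."""
    if hat_trace >= n - 2:
        raise UndefinedAICcError(f"hat trace {hat_trace:.2f} >= n-2 = {n - 2}")
    sigma = math.sqrt(max(rss, 1e-300) / n)
    return 2 * n * math.log(sigma) + n * math.log(2 * math.pi) + n * (n + hat_trace) / (
        n - 2 - hat_trace
    )


def _gtwr_core(
    X: np.ndarray,
    y: np.ndarray,
    kern: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Vectorized per-observation WLS: betas (n×p), fitted, hat trace."""
    n, p = X.shape
    # A[i] = X^T W_i X,  b[i] = X^T W_i y
    a = np.einsum("ij,jk,jl->ikl", kern, X, X, optimize=True)
    b = np.einsum("ij,jk,j->ik", kern, X, y, optimize=True)
    a += _RIDGE * np.trace(a, axis1=1, axis2=2)[:, None, None] * np.eye(p)[None]
    try:
        betas = np.linalg.solve(a, b[..., None])[..., 0]
        ainv_x = np.linalg.solve(a, X[..., None])[..., 0]  # A_i^{-1} x_i
    except np.linalg.LinAlgError as exc:
        raise SingularFitError(str(exc)) from exc
    fitted = (betas * X).sum(axis=1)
    # h_ii = x_i^T A_i^{-1} x_i w_ii ; kernel diagonal is 1
    hat = (X * ainv_x).sum(axis=1) * np.diag(kern)
    return betas, fitted, float(hat.sum())


def gtwr_fit(panel: PanelDataset, bws: float, bt: float) -> STWRFit:
    """GTWR with a single shared spatial/temporal bandwidth pair."""
    X = panel.X()
    y = panel.y
    ds2, dt2 = _sq_dist_matrices(panel)
    kern = _kernel_matrix(ds2, dt2, bws, bt)
    betas, fitted, hat = _gtwr_core(X, y, kern)
    resid = y - fitted
    rss = float((resid**2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    names = panel.variable_names()
    try:
        crit = aicc(panel.n, rss, hat)
    except UndefinedAICcError:
        crit = math.inf
    return STWRFit(
        model="GTWR",
        coefficients=pd.DataFrame(betas, columns=names),
        fitted=fitted,
        residuals=resid,
        rss=rss,
        tss=tss,
        r2=1.0 - rss / tss,
        aicc=crit,
        hat_trace=hat,
        bandwidths=BandwidthSet.uniform(names, bws, bt),
        panel_fingerprint=(panel.n, float(y.sum())),
    )


def soc_rss(rss_new: float, rss_old: float) -> float:
    """Relative RSS change between backfitting sweeps; 0 when RSS hits zero."""
    if rss_new == 0:
        return 0.0
    return abs(rss_new - rss_old) / rss_new


def _golden_min(f: Callable[[float], float], lo: float, hi: float, iters: int = _GOLDEN_ITERS):
    """Golden-section minimization on [lo, hi] (log-scale handled by caller)."""
    invphi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        # near-ties keep the right (larger-bandwidth) interval: a flat
        # objective means the data carry no information at that scale, and
        # the smoother, more global fit is the right default
        tol = 1e-9 * (abs(fd) + 1.0)
        if fc < fd - tol:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    if fc < fd - 1e-9 * (abs(fd) + 1.0):
        return c, fc
    return d, fd


def _default_bounds(panel: PanelDataset) -> tuple[tuple[float, float], tuple[float, float]]:
    uv = panel.coords
    extent = max(np.ptp(uv[:, 0]), np.ptp(uv[:, 1]), 1.0)
    # lower spatial bound: the data spacing (smallest nonzero neighbor
    # distance, e.g. the sampling-grid step), so local fits cannot collapse
    # into per-point interpolation; floor at a small fraction of the extent
    from scipy.spatial import cKDTree

    tree = cKDTree(uv)
    k = min(len(uv), 8)
    dists, _ = tree.query(uv, k=k)
    positive = dists[:, 1:][dists[:, 1:] > 0]
    d_min = float(positive.min()) if positive.size else extent / 50.0
    s_lo, s_hi = max(extent / 50.0, d_min), 10.0 * extent
    trange = float(np.ptp(panel.times))
    t_lo, t_hi = 0.1, 10.0 * max(trange, 1.0)
    return (s_lo, s_hi), (t_lo, t_hi)


def search_bandwidth(
    panel: PanelDataset,
    objective: Callable[[float, float], float] | None = None,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """Select (bws, bt) minimizing AICc by nested golden-section on log scale.

    The outer search runs over the spatial bandwidth, the inner over the
    temporal one.  ``objective(bws, bt)`` defaults to the AICc of a full
    GTWR fit; MGTWR passes per-term objectives.  Deterministic given bounds.
    """
    if bounds is None:
        bounds = _default_bounds(panel)
    (s_lo, s_hi), (t_lo, t_hi) = bounds

    if objective is None:
        X = panel.X()
        y = panel.y
        ds2, dt2 = _sq_dist_matrices(panel)

        def objective(bws: float, bt: float) -> float:
            kern = _kernel_matrix(ds2, dt2, bws, bt)
            try:
                _, fitted, hat = _gtwr_core(X, y, kern)
                return aicc(panel.n, float(((y - fitted) ** 2).sum()), hat)
            except (SingularFitError, UndefinedAICcError):
                return math.inf

    def outer(log_bws: float) -> float:
        bws = math.exp(log_bws)
        _, val = _golden_min(lambda lt: objective(bws, math.exp(lt)), math.log(t_lo), math.log(t_hi))
        return val

    best_ls, best_val = _golden_min(outer, math.log(s_lo), math.log(s_hi))
    if not math.isfinite(best_val):
        raise ValueError("no valid bandwidth in the search range")
    bws = math.exp(best_ls)
    log_bt, _ = _golden_min(
        lambda lt: objective(bws, math.exp(lt)), math.log(t_lo), math.log(t_hi)
    )
    return bws, math.exp(log_bt)


def _term_fit(
    x: np.ndarray, e: np.ndarray, kern: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Local single-regressor fit of partial residual e on covariate x.

    β_i = Σ_j w_ij x_j e_j / Σ_j w_ij x_j²; returns (β, f = β⊙x, hat trace).
    """
    num = kern @ (x * e)
    den = kern @ (x * x)
    den = den + _RIDGE * den.mean()
    beta = num / den
    hat = float((np.diag(kern) * x * x / den).sum())
    return beta, beta * x, hat


def mgtwr_fit(
    panel: PanelDataset,
    init: STWRFit | None = None,
    max_sweeps: int = MAX_SWEEPS,
    tol: float = SOC_TOL,
    init_bandwidths: tuple[float, float] | None = None,
    max_search_sweeps: int = 10,
) -> STWRFit:
    """Multiscale GTWR by backfitting with per-variable bandwidth selection.

    Additive terms f_k = β_k ⊙ x_k (intercept included as x ≡ 1) are
    initialized from a GTWR fit, then refit one variable at a time against
    partial residuals, each with its own (bws_k, bt_k) chosen by AICc.
    Stops when SOC_RSS ≤ ``tol`` or after ``max_sweeps`` sweeps (then the
    fit is flagged unconverged rather than raising).
    """
    X = panel.X()
    y = panel.y
    n, p = X.shape
    names = panel.variable_names()
    ds2, dt2 = _sq_dist_matrices(panel)
    bounds = _default_bounds(panel)
    (s_lo, s_hi), (t_lo, t_hi) = bounds

    if init is None:
        if init_bandwidths is None:
            init_bandwidths = search_bandwidth(panel, bounds=bounds)
        init = gtwr_fit(panel, *init_bandwidths)
    betas = init.coefficients[names].to_numpy(dtype=float).copy()
    terms = betas * X
    bw_s = {k: init.bandwidths.bws[k] for k in names}
    bw_t = {k: init.bandwidths.bt[k] for k in names}
    hats = {k: init.hat_trace / p for k in names}

    rss_old = float(((y - terms.sum(axis=1)) ** 2).sum())
    converged = False
    sweeps = 0
    search_active = True
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        any_adopted = False
        for k in range(p):
            e_k = y - terms.sum(axis=1) + terms[:, k]
            x_k = X[:, k]

            def term_objective(bws: float, bt: float) -> float:
                kern = _kernel_matrix(ds2, dt2, bws, bt)
                _, f_k, hat = _term_fit(x_k, e_k, kern)
                try:
                    return aicc(n, float(((e_k - f_k) ** 2).sum()), hat)
                except UndefinedAICcError:
                    return math.inf

            bws_k, bt_k = bw_s[names[k]], bw_t[names[k]]
            if search_active:
                if sweep == 0:
                    k_bounds = bounds
                else:
                    # warm start: window around the previous sweep's bandwidths
                    k_bounds = (
                        (max(s_lo, bws_k / 8), min(s_hi, bws_k * 8)),
                        (max(t_lo, bt_k / 8), min(t_hi, bt_k * 8)),
                    )
                cand_s, cand_t = search_bandwidth(
                    panel, objective=term_objective, bounds=k_bounds
                )
                # hysteresis: adopt the candidate only if it clearly improves
                # the term criterion, so near-equivalent bandwidths cannot
                # set up a limit cycle across sweeps
                val_prev = term_objective(bws_k, bt_k) if sweep > 0 else math.inf
                val_cand = term_objective(cand_s, cand_t)
                improved = math.isinf(val_prev) or (
                    val_cand < val_prev - 1e-6 * (abs(val_prev) + 1.0)
                )
                if improved:
                    bws_k, bt_k = cand_s, cand_t
                    any_adopted = True
            kern = _kernel_matrix(ds2, dt2, bws_k, bt_k)
            beta_k, f_k, hat_k = _term_fit(x_k, e_k, kern)
            betas[:, k] = beta_k
            terms[:, k] = f_k
            bw_s[names[k]], bw_t[names[k]] = bws_k, bt_k
            hats[names[k]] = hat_k
        if search_active and (not any_adopted or sweeps >= max_search_sweeps):
            # bandwidths stable (or the refinement budget is spent): plain
            # backfitting with frozen smoothers from here, which descends
            # monotonically and lets SOC_RSS reach the criterion
            search_active = False
        rss_new = float(((y - terms.sum(axis=1)) ** 2).sum())
        if soc_rss(rss_new, rss_old) <= tol:
            rss_old = rss_new
            converged = True
            break
        rss_old = rss_new

    fitted = terms.sum(axis=1)
    resid = y - fitted
    rss = float((resid**2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    # effective df of the additive fit: sum of per-term smoother traces
    hat_total = float(sum(hats.values()))
    try:
        crit = aicc(n, rss, hat_total)
    except UndefinedAICcError:
        crit = math.inf
    return STWRFit(
        model="MGTWR",
        coefficients=pd.DataFrame(betas, columns=names),
        fitted=fitted,
        residuals=resid,
        rss=rss,
        tss=tss,
        r2=1.0 - rss / tss,
        aicc=crit,
        hat_trace=hat_total,
        bandwidths=BandwidthSet(bws=bw_s, bt=bw_t),
        converged=converged,
        n_sweeps=sweeps,
        terms=pd.DataFrame(terms, columns=names),
        panel_fingerprint=(panel.n, float(y.sum())),
    )


def coefficient_summary(fit: STWRFit) -> pd.DataFrame:
    """Per-variable bandwidths and min/median/max of local coefficients."""
    rows = []
    for name in fit.coefficients.columns:
        col = fit.coefficients[name]
        rows.append(
            {
                "variable": name,
                "bws": fit.bandwidths.bws[name],
                "bt": fit.bandwidths.bt[name],
                "beta_min": float(col.min()),
                "beta_med": float(col.median()),
                "beta_max": float(col.max()),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def compare_models(fits: Sequence[STWRFit]) -> pd.DataFrame:
    """Side-by-side R² / AICc / RSS diagnostics for fits on one panel."""
    fps = {fit.panel_fingerprint for fit in fits}
    if len(fps) > 1:
        raise ValueError("fits were made on different panels")
    rows = [
        {"model": fit.model, "R2": fit.r2, "AICc": fit.aicc, "RSS": fit.rss} for fit in fits
    ]
    return pd.DataFrame(rows).set_index("model")
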