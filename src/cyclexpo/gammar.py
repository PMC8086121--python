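"""Generalized additive mixed models with moving-average residuals (GAMMAR).

The exposure model for each response (noise L_Aeq, NO2, inhaled NO2) is

    y_t = X_t beta + f_time(clock_t) + f_space(x_t, y_t)
          + b_day(t) + b_participant(t) + r_t,
    r_t = e_t + theta_1 e_{t-1} + theta_2 e_{t-2} + theta_3 e_{t-3},

with fixed effects X (road-type time shares relative to residential streets,
speed, grade, intersections, and — for the NO2 and inhalation responses —
humidity and wind), centred penalized spline smooths for time-of-day and 2D
space, crossed random intercepts for day and participant, and an MA(3)
residual process of heavy-tailed (Student-t) innovations that resets at trip
boundaries.

Estimation is iterated two-stage feasible GLS:

1. variance components for the crossed random intercepts from a linear mixed
   model (REML) ignoring the MA term;
2. MA(3) coefficients by conditional least squares on per-trip ordered
   conditional residuals;
3. the design is whitened with the implied per-trip MA covariance (plus
   robustness weights for the Student-t likelihood, IRLS with fixed df) and
   the fixed/smooth coefficients refit by GLS, with random-intercept BLUPs
   from the same solve;

steps 2-3 iterate to a 1e-4 relative-change tolerance. Smoothing of the
spline blocks is ridge-type with the penalty weight chosen by GCV at the
first (OLS) stage. Uncertainty intervals are Wald; they are labelled as such
in the coefficient table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.interpolate import BSpline
from scipy.optimize import least_squares
from scipy.signal import lfilter
from scipy.stats import kurtosis

from .segmentation import TripSegment, segments_to_frame
from .synthetic import ROAD_CONTRASTS

logger = logging.getLogger(__name__)

_COVARIATE_COLUMNS = {
    "humidity": "humidity_pct",
    "wind": "wind_kmh",
    "intersections": "intersections",
    "speed": "speed_kmh",
    "slope": "slope_pct",
    **{t: f"share_{t}" for t in ROAD_CONTRASTS},
}

_RESPONSE_COLUMNS = {
    "noise_db": "laeq_1min",
    "no2_ugm3": "no2_ugm3",
    "inhaled_ug": "inhaled_ug",
}

#: Fixed-effect lists per response. The noise model has no weather terms.
DEFAULT_FIXED = {
    "noise_db": ("intersections", "speed", "slope") + ROAD_CONTRASTS,
    "no2_ugm3": ("humidity", "wind", "intersections", "speed", "slope") + ROAD_CONTRASTS,
    "inhaled_ug": ("humidity", "wind", "intersections", "speed", "slope") + ROAD_CONTRASTS,
}


@dataclass
class ModelSpec:
    """Specification of one exposure model."""

    response: str
    fixed: tuple[str, ...] | None = None
    spline_time: int = 8
    spline_space: int = 30
    ma_order: int = 3
    likelihood: str = "student"
    student_df: float = 4.0
    include_random: bool = True
    smooth_lambda: float | str = "gcv"

    def __post_init__(self) -> None:
        if self.response not in _RESPONSE_COLUMNS:
            raise ValueError(f"unknown response {self.response!r}")
        if self.likelihood not in ("student", "gaussian"):
            raise ValueError("likelihood must be 'student' or 'gaussian'")
        if self.fixed is None:
            self.fixed = DEFAULT_FIXED[self.response]
        if self.response == "noise_db" and any(
            p in self.fixed for p in ("humidity", "wind")
        ):
            raise ValueError("the noise model excludes humidity and wind")


# ---------------------------------------------------------------------------
# Spline bases
# ---------------------------------------------------------------------------


class TimeSplineBasis:
    """Cubic B-spline basis for minutes-since-08:00, column-centred over the
    training observations; the first basis column is dropped so the centred
    basis is not collinear with the intercept."""

    def __init__(self, x: np.ndarray, df: int):
        x = np.asarray(x, dtype=float)
        self.lo, self.hi = float(x.min()), float(x.max())
        if self.hi <= self.lo:
            self.hi = self.lo + 1.0
        n_interior = max(df - 4, 0)
        qs = np.linspace(0, 100, n_interior + 2)[1:-1]
        interior = np.percentile(x, qs) if n_interior else np.array([])
        self.knots = np.r_[[self.lo] * 4, interior, [self.hi] * 4]
        self.means = np.zeros(self._raw(x).shape[1] - 1)
        self.means = self._raw(x)[:, 1:].mean(axis=0)

    def _raw(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(xc, self.knots, 3).toarray()

    def transform(self, x) -> np.ndarray:
        return self._raw(np.atleast_1d(x))[:, 1:] - self.means

    @property
    def n_cols(self) -> int:
        return len(self.means)


class SpaceRBFBasis:
    """Thin-plate-type radial basis for planar coordinates.

    Knots sit on a regular grid over the training bounding box; the basis is
    phi(r) = r^2 log r (r scaled by the domain diameter) plus centred linear
    x/y terms, all column-centred over the training observations.
    """

    def __init__(self, xy: np.ndarray, k: int):
        xy = np.asarray(xy, dtype=float)
        self.x0, self.y0 = xy[:, 0].min(), xy[:, 1].min()
        self.x1, self.y1 = xy[:, 0].max(), xy[:, 1].max()
        self.scale = max(self.x1 - self.x0, self.y1 - self.y0, 1.0)
        m = max(int(np.ceil(np.sqrt(max(k - 2, 1)))), 2)
        gx = np.linspace(self.x0, self.x1, m)
        gy = np.linspace(self.y0, self.y1, m)
        self.knots = np.array([(a, b) for a in gx for b in gy])
        self.means = np.zeros(self.knots.shape[0] + 2)
        self.means = self._raw(xy).mean(axis=0)

    def _raw(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        d = np.linalg.norm(xy[:, None, :] - self.knots[None, :, :], axis=2) / self.scale
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(d > 0, d**2 * np.log(d), 0.0)
        lin = (xy - [(self.x0 + self.x1) / 2, (self.y0 + self.y1) / 2]) / self.scale
        return np.hstack([phi, lin])

    def transform(self, xy) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return self._raw(xy) - self.means

    def in_support(self, xy) -> bool:
        x, y = float(xy[0]), float(xy[1])
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    @property
    def n_cols(self) -> int:
        return len(self.means)


# ---------------------------------------------------------------------------
# Design bundle
# ---------------------------------------------------------------------------


@dataclass
class DesignBundle:
    """Everything the estimator needs, with observation order preserved
    within trips for the MA structure."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    smooth_mask: np.ndarray  # True for penalized (spline) columns
    time_basis: TimeSplineBasis | None
    space_basis: SpaceRBFBasis | None
    time_cols: slice | None
    space_cols: slice | None
    Zd: np.ndarray | None
    Zp: np.ndarray | None
    day_levels: list[str]
    participant_levels: list[str]
    trip_slices: list[tuple[int, int]]
    spec: ModelSpec
    frame: pd.DataFrame


def build_design(segments: Sequence[TripSegment], spec: ModelSpec) -> DesignBundle:
    """Assemble the fixed-effect matrix, centred spline bases and random- and
    MA-structure indices from one-minute segments.

    Residential street is the omitted road-type reference; the noise model's
    design contains no humidity/wind columns. Raises ``KeyError`` naming any
    missing covariate.
    """
    df = segments_to_frame(segments)
    # stable trip order: keep encounter order, sort within trip by index
    order = {t: i for i, t in enumerate(dict.fromkeys(df["trip_id"]))}
    df = df.sort_values(
        ["trip_id", "segment_index"], key=lambda s: s.map(order) if s.name == "trip_id" else s
    ).reset_index(drop=True)

    y = df[_RESPONSE_COLUMNS[spec.response]].to_numpy(dtype=float)
    cols, names = [np.ones(len(df))], ["intercept"]
    for pred in spec.fixed:
        col = _COVARIATE_COLUMNS.get(pred)
        if col is None or col not in df.columns:
            raise KeyError(f"missing covariate {pred!r}")
        cols.append(df[col].to_numpy(dtype=float))
        names.append(pred)
    n_fixed = len(names)

    time_basis = space_basis = None
    time_cols = space_cols = None
    if spec.spline_time:
        time_basis = TimeSplineBasis(df["clock_min"].to_numpy(), df=spec.spline_time)
        B = time_basis.transform(df["clock_min"].to_numpy())
        time_cols = slice(len(names), len(names) + B.shape[1])
        cols.append(B.T)
        names += [f"s_time_{j}" for j in range(B.shape[1])]
    if spec.spline_space:
        xy = df[["mid_x", "mid_y"]].to_numpy()
        space_basis = SpaceRBFBasis(xy, k=spec.spline_space)
        S = space_basis.transform(xy)
        space_cols = slice(len(names), len(names) + S.shape[1])
        cols.append(S.T)
        names += [f"s_space_{j}" for j in range(S.shape[1])]

    X = np.vstack([c if c.ndim > 1 else c[None, :] for c in cols]).T
    smooth_mask = np.zeros(X.shape[1], dtype=bool)
    smooth_mask[n_fixed:] = True

    Zd = Zp = None
    day_levels: list[str] = []
    part_levels: list[str] = []
    if spec.include_random:
        days = df["day"].astype(str)
        day_levels = sorted(days.unique())
        if len(day_levels) > 1:
            Zd = (days.to_numpy()[:, None] == np.array(day_levels)[None, :]).astype(float)
        else:
            day_levels = []
        parts = df["participant"].astype(str)
        part_levels = sorted(parts.unique())
        if len(part_levels) > 1:
            Zp = (parts.to_numpy()[:, None] == np.array(part_levels)[None, :]).astype(float)
        else:
            part_levels = []

    trip_slices = []
    start = 0
    for _, grp in df.groupby("trip_id", sort=False):
        trip_slices.append((start, start + len(grp)))
        start += len(grp)

    return DesignBundle(
        y=y,
        X=X,
        columns=names,
        smooth_mask=smooth_mask,
        time_basis=time_basis,
        space_basis=space_basis,
        time_cols=time_cols,
        space_cols=space_cols,
        Zd=Zd,
        Zp=Zp,
        day_levels=day_levels,
        participant_levels=part_levels,
        trip_slices=trip_slices,
        spec=spec,
        frame=df,
    )


# ---------------------------------------------------------------------------
# Fitted model
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """Estimates, 95% Wald intervals and diagnostics for one GAMMAR fit."""

    spec: ModelSpec
    estimates: dict[str, tuple[float, float, float]]
    ma_coefs: list[tuple[float, float, float]]
    random_intercepts: dict[str, dict[str, tuple[float, float, float]]]
    r2_marginal: float
    r2_conditional: float
    resid_acf: tuple[float, float, float]
    converged: bool
    interval_kind: str = "wald"
    # internals used by predict/diagnostics
    _design: DesignBundle = field(repr=False, default=None)
    _beta: np.ndarray = field(repr=False, default=None)
    _sigma2: float = field(repr=False, default=0.0)
    _theta: np.ndarray = field(repr=False, default=None)
    _vcomp: dict = field(repr=False, default_factory=dict)
    _innovations: np.ndarray = field(repr=False, default=None)

    def smooth_time(self, clock_min):
        d = self._design
        if d.time_basis is None:
            return np.zeros(np.shape(np.atleast_1d(clock_min)))
        return d.time_basis.transform(clock_min) @ self._beta[d.time_cols]

    def smooth_space(self, x, y):
        d = self._design
        if d.space_basis is None:
            return np.zeros(np.shape(np.atleast_1d(x)))
        xy = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        return d.space_basis.transform(xy) @ self._beta[d.space_cols]


def _ma_autocov(theta: np.ndarray, n: int) -> np.ndarray:
    """First column of the unit-innovation MA covariance (length min(n, q+1))."""
    th = np.r_[1.0, theta]
    q = len(th) - 1
    gam = np.zeros(min(n, q + 1))
    for k in range(len(gam)):
        gam[k] = np.sum(th[: len(th) - k] * th[k:])
    return gam


def _trip_chol(theta: np.ndarray, n: int) -> np.ndarray:
    """Cholesky factor of the n x n unit-innovation MA covariance."""
    gam = _ma_autocov(theta, n)
    col = np.zeros(n)
    col[: len(gam)] = gam
    return np.linalg.cholesky(sla.toeplitz(col))


def _cls_ma(
    residuals: np.ndarray,
    trip_slices: Sequence[tuple[int, int]],
    order: int,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """MA(order) conditional least squares on per-trip ordered residuals.

    Innovations are reconstructed per trip with pre-sample values set to 0
    (the process resets at trip boundaries). Returns (theta, innovations).
    """

    def innov(theta: np.ndarray, slices=trip_slices) -> np.ndarray:
        a = np.r_[1.0, theta]
        return np.concatenate([lfilter([1.0], a, residuals[s:e]) for s, e in slices])

    if order == 0:
        return np.zeros(0), residuals.copy()
    res = least_squares(
        innov,
        x0=np.zeros(order) if x0 is None else np.clip(x0, -0.9, 0.9),
        bounds=(-0.98, 0.98),
        xtol=1e-10,
        ftol=1e-10,
    )
    return res.x, innov(res.x)


def _cls_ma_se(
    residuals: np.ndarray,
    trip_slices: Sequence[tuple[int, int]],
    theta: np.ndarray,
) -> np.ndarray:
    """Delete-one-trip jackknife standard errors for the MA coefficients.

    The jackknife captures variance the curvature-based (Hessian) SE misses —
    in particular noise inherited from estimating the mean structure — and
    needs no distributional assumption on the heavy-tailed innovations. Falls
    back to the Gauss-Newton SE when there are too few trips to jackknife.
    """
    order = len(theta)
    m = len(trip_slices)
    if m >= 4:
        loo = []
        for j in range(m):
            slices = [s for i, s in enumerate(trip_slices) if i != j]
            th_j, _ = _cls_ma(residuals, slices, order, x0=theta)
            loo.append(th_j)
        loo = np.array(loo)
        return np.sqrt((m - 1) / m * np.sum((loo - loo.mean(axis=0)) ** 2, axis=0))
    # Gauss-Newton fallback

    def innov(th: np.ndarray) -> np.ndarray:
        a = np.r_[1.0, th]
        return np.concatenate([lfilter([1.0], a, residuals[s:e]) for s, e in trip_slices])

    res = least_squares(innov, x0=theta, bounds=(-0.98, 0.98))
    e = innov(res.x)
    s2 = float(e @ e) / max(len(e) - order, 1)
    try:
        return np.sqrt(np.diag(s2 * np.linalg.inv(res.jac.T @ res.jac)))
    except np.linalg.LinAlgError:
        return np.full(order, np.nan)


def _variance_components(design: DesignBundle) -> dict:
    """Day/participant variance components via REML (linear mixed model with
    crossed variance components, ignoring the MA term). Falls back to
    moment-based estimates if the REML fit does not converge."""
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import VCSpec

    out = {"day": 0.0, "participant": 0.0, "sigma_e2": 1.0, "method": "reml"}
    mats, names, colnames = [], [], []
    if design.Zd is not None:
        mats.append([design.Zd])
        names.append("day")
        colnames.append([design.day_levels])
    if design.Zp is not None:
        mats.append([design.Zp])
        names.append("participant")
        colnames.append([design.participant_levels])
    resid = design.y - design.X @ np.linalg.lstsq(design.X, design.y, rcond=None)[0]
    out["sigma_e2"] = float(np.var(resid))
    if not mats:
        return out
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vcs = VCSpec(names, colnames, mats)
        groups = np.zeros(len(design.y))
        model = sm.MixedLM(design.y, design.X, groups=groups, exog_vc=vcs)
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = model.fit(reml=True, method=method, maxiter=300)
            except Exception:
                continue
            if cand.converged:
                fit = cand
                break
            fit = fit or cand
    if fit is not None and fit.converged:
        for i, nm in enumerate(names):
            out[nm] = float(fit.vcomp[i])
        out["sigma_e2"] = float(fit.scale)
    else:
        # moment (ANOVA-type) estimates: deterministic, no iteration involved
        logger.info("REML did not converge; using moment variance components")
        out["method"] = "moments"
        for nm, Z in (("day", design.Zd), ("participant", design.Zp)):
            if Z is None:
                continue
            counts = Z.sum(axis=0)
            means = (Z.T @ resid) / counts
            v = float(np.var(means, ddof=1) - out["sigma_e2"] * np.mean(1.0 / counts))
            out[nm] = max(v, 0.0)
    return out


def _gcv_lambda(design: DesignBundle) -> float:
    """Ridge weight for the spline blocks by generalized cross-validation on
    the first-stage penalized OLS."""
    spec = design.spec
    if not design.smooth_mask.any():
        return 0.0
    if spec.smooth_lambda != "gcv":
        return float(spec.smooth_lambda)
    X, y = design.X, design.y
    n = len(y)
    XtX = X.T @ X
    Xty = X.T @ y
    pen = np.diag(design.smooth_mask.astype(float))
    best = (np.inf, 0.0)
    for lam in (0.0, 0.01, 0.1, 1.0, 10.0, 100.0):
        try:
            A = np.linalg.solve(XtX + lam * pen, np.eye(X.shape[1]))
        except np.linalg.LinAlgError:
            continue
        beta = A @ Xty
        rss = float(np.sum((y - X @ beta) ** 2))
        edf = float(np.trace(A @ XtX))
        if n - edf <= 1:
            continue
        gcv = n * rss / (n - edf) ** 2
        if gcv < best[0]:
            best = (gcv, lam)
    return best[1]


def fit_gammar(design: DesignBundle, spec: ModelSpec | None = None) -> FittedModel:
    """Fit a GAMMAR by iterated two-stage feasible GLS (see module docstring).

    Raises ``ValueError`` when there are fewer than 10 observations per
    coefficient. Non-convergence after the maximum number of iterations is
    reported honestly through ``converged=False``.
    """
    spec = spec or design.spec
    X, y = design.X, design.y
    n, p = X.shape
    if n < 10 * p:
        raise ValueError(f"need >= {10 * p} observations for {p} coefficients, got {n}")

    lam = _gcv_lambda(design)
    pen = lam * np.diag(design.smooth_mask.astype(float))

    vc = _variance_components(design) if (design.Zd is not None or design.Zp is not None) else {
        "day": 0.0,
        "participant": 0.0,
        "sigma_e2": float(np.var(y)) or 1.0,
        "method": "none",
    }
    Z_parts, g_diag = [], []
    if design.Zd is not None:
        Z_parts.append(design.Zd)
        g_diag += [max(vc["day"], 1e-8)] * design.Zd.shape[1]
    if design.Zp is not None:
        Z_parts.append(design.Zp)
        g_diag += [max(vc["participant"], 1e-8)] * design.Zp.shape[1]
    Z = np.hstack(Z_parts) if Z_parts else np.zeros((n, 0))
    g_diag = np.asarray(g_diag)

    def gls_solve(Xw, yw, Zw, rows=None):
        """Penalized GLS solve via Woodbury on (optionally subset) whitened data.

        Returns (beta, b_hat, XtVX, v0_inv applied to residual closure)."""
        if rows is not None:
            Xw, yw = Xw[rows], yw[rows]
            Zw = Zw[rows] if Zw.size else Zw
        if Zw.size:
            M = np.diag(sigma2 / g_diag) + Zw.T @ Zw
            Minv_Zt = np.linalg.solve(M, Zw.T)

            def v0i(mat):
                return mat - Zw @ (Minv_Zt @ mat)
        else:

            def v0i(mat):
                return mat

        XtVX_ = Xw.T @ v0i(Xw)
        XtVy_ = Xw.T @ v0i(yw)
        beta_ = np.linalg.solve(XtVX_ + pen / max(sigma2, 1e-12), XtVy_)
        b_ = (g_diag / sigma2) * (Zw.T @ v0i(yw - Xw @ beta_)) if Zw.size else np.zeros(0)
        return beta_, b_, XtVX_, v0i

    nu = spec.student_df
    robust = spec.likelihood == "student"
    theta = np.zeros(spec.ma_order)
    sigma2 = vc["sigma_e2"]
    beta = np.linalg.solve(X.T @ X + pen, X.T @ y)
    w = np.ones(n)
    innov = y - X @ beta
    converged = False

    for it in range(20):
        # --- whiten with the current MA covariance and robustness weights ---
        if spec.ma_order:
            Xs = np.empty_like(X)
            ys = np.empty_like(y)
            Zs = np.empty_like(Z) if Z.size else Z
            for s, e in design.trip_slices:
                L = _trip_chol(theta, e - s)
                Xs[s:e] = sla.solve_triangular(L, X[s:e], lower=True)
                ys[s:e] = sla.solve_triangular(L, y[s:e], lower=True)
                if Z.size:
                    Zs[s:e] = sla.solve_triangular(L, Z[s:e], lower=True)
        else:
            Xs, ys, Zs = X.copy(), y.copy(), Z.copy()
        if robust:
            sw = np.sqrt(w)
            Xs *= sw[:, None]
            ys *= sw
            if Z.size:
                Zs = Zs * sw[:, None]

        # --- GLS via Woodbury: V0 = I + Zs (G/sigma2) Zs' -------------------
        beta_new, b_hat, XtVX, v0_inv = gls_solve(Xs, ys, Zs)

        # --- conditional residuals in observation order, MA re-estimation ---
        r_c = y - X @ beta_new - (Z @ b_hat if Z.size else 0.0)
        if spec.ma_order:
            theta_new, innov = _cls_ma(r_c, design.trip_slices, spec.ma_order, x0=theta)
        else:
            theta_new, innov = theta, r_c
        if robust:
            s2_rob = float(np.sum(w * innov**2) / n)
            w = (nu + 1.0) / (nu + innov**2 / max(s2_rob, 1e-12))
            sigma2_new = float(np.sum(w * innov**2) / n)
        else:
            sigma2_new = float(innov @ innov / max(n - p, 1))

        db = np.max(np.abs(beta_new - beta)) / (1.0 + np.max(np.abs(beta_new)))
        dt = np.max(np.abs(theta_new - theta)) if spec.ma_order else 0.0
        beta, theta, sigma2 = beta_new, theta_new, sigma2_new
        if db < 1e-4 and dt < 1e-4:
            converged = True
            break

    theta_se = (
        _cls_ma_se(y - X @ beta - (Z @ b_hat if Z.size else 0.0), design.trip_slices, theta)
        if spec.ma_order
        else np.zeros(0)
    )

    # Fixed-effect covariance: delete-one-trip jackknife around the final
    # whitened GLS solve, with a t(m-1) critical value. The jackknife stays
    # honest when residual dependence is imperfectly captured by the MA(3)
    # term (e.g. block-constant weather within trips) and avoids the
    # downward bias of plain cluster sandwiches with few clusters.
    m_trips = len(design.trip_slices)
    if m_trips >= 4:
        keep = np.ones(n, dtype=bool)
        loo_betas = []
        for s, e in design.trip_slices:
            keep[s:e] = False
            bj, _, _, _ = gls_solve(Xs, ys, Zs, rows=keep)
            loo_betas.append(bj)
            keep[s:e] = True
        loo = np.array(loo_betas)
        dev = loo - loo.mean(axis=0)
        cov_beta = (m_trips - 1) / m_trips * dev.T @ dev
        from scipy.stats import t as t_dist

        zq = float(t_dist.ppf(0.975, m_trips - 1))
    else:
        cov_beta = sigma2 * np.linalg.inv(XtVX + pen / max(sigma2, 1e-12))
        zq = 1.959963984540054
    if robust:
        # Student-ML asymptotics: the IRLS solve conditions on the robustness
        # weights, which hides the (nu+3)/(nu+1) variance contribution of the
        # heavy-tailed likelihood; restore it explicitly.
        cov_beta = cov_beta * (nu + 3.0) / (nu + 1.0)
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    estimates = {
        name: (float(beta[i]), float(beta[i] - zq * se[i]), float(beta[i] + zq * se[i]))
        for i, name in enumerate(design.columns)
        if not design.smooth_mask[i]
    }

    # BLUPs and their uncertainty
    random_intercepts: dict[str, dict[str, tuple[float, float, float]]] = {}
    if Z.size:
        # diag of G - G Z' V^-1 Z G with V = sigma2 * V0
        GZt = g_diag[:, None] * Zs.T
        mid = GZt @ v0_inv(GZt.T) / sigma2
        post_var = np.clip(g_diag - np.diag(mid), 0.0, None)
        b_se = np.sqrt(post_var)
        k = 0
        for nm, levels in (("day", design.day_levels), ("participant", design.participant_levels)):
            if not levels:
                continue
            random_intercepts[nm] = {
                lev: (
                    float(b_hat[k + j]),
                    float(b_hat[k + j] - zq * b_se[k + j]),
                    float(b_hat[k + j] + zq * b_se[k + j]),
                )
                for j, lev in enumerate(levels)
            }
            k += len(levels)

    ma_out = [
        (float(theta[i]), float(theta[i] - zq * theta_se[i]), float(theta[i] + zq * theta_se[i]))
        for i in range(spec.ma_order)
    ]

    # Explained-variance summaries (variance-partition R2): fitted marginal
    # part = fixed + smooths; random part = BLUP contributions; residual =
    # conditional residual variance.
    fit_m = X @ beta
    var_f = float(np.var(fit_m))
    var_re = float(np.var(Z @ b_hat)) if Z.size else 0.0
    var_res = float(np.var(y - fit_m - (Z @ b_hat if Z.size else 0.0)))
    denom = var_f + var_re + var_res
    r2_m = var_f / denom if denom > 0 else np.nan
    r2_c = (var_f + var_re) / denom if denom > 0 else np.nan

    acf = _innovation_acf(innov, design.trip_slices, lags=3)

    model = FittedModel(
        spec=spec,
        estimates=estimates,
        ma_coefs=ma_out,
        random_intercepts=random_intercepts,
        r2_marginal=r2_m,
        r2_conditional=r2_c,
        resid_acf=tuple(acf),
        converged=converged,
        _design=design,
        _beta=beta,
        _sigma2=sigma2,
        _theta=theta,
        _vcomp=vc,
        _innovations=innov,
    )
    if not model.converged:
        logger.warning(
            "fit_gammar did not converge (beta change %.2e, theta change %.2e)", db, dt
        )
    return model


def _innovation_acf(
    innov: np.ndarray, trip_slices: Sequence[tuple[int, int]], lags: int = 3
) -> list[float]:
    out = []
    for k in range(1, lags + 1):
        num = den = 0.0
        for s, e in trip_slices:
            g = innov[s:e]
            if len(g) <= k:
                continue
            a, b = g[:-k], g[k:]
            if a.std() == 0 or b.std() == 0:
                continue
            w = len(g) - k
            num += w * float(np.corrcoef(a, b)[0, 1])
            den += w
        out.append(num / den if den else np.nan)
    return out


# ---------------------------------------------------------------------------
# Prediction, R2, diagnostics
# ---------------------------------------------------------------------------


def predict_exposure(
    model: FittedModel,
    covariates: Mapping[str, float],
    xy: tuple[float, float],
    clock_min: float,
    include_random: bool = False,
    participant: str | None = None,
    day: str | None = None,
) -> float:
    """Predicted response level at given covariates, location and clock time.

    The linear predictor sums the intercept, fixed effects, and the centred
    smooths evaluated at ``xy`` and ``clock_min``; random intercepts enter
    only when ``include_random`` is set (the default excludes them, as
    prediction for a generic rider should). A location outside the fitted
    spatial support triggers an extrapolation warning.
    """
    if not model.converged:
        raise ValueError("model did not converge; refusing to predict")
    d = model._design
    val = 0.0
    for i, name in enumerate(d.columns):
        if d.smooth_mask[i]:
            continue
        if name == "intercept":
            val += model._beta[i]
        else:
            val += model._beta[i] * float(covariates.get(name, 0.0))
    val += float(np.asarray(model.smooth_time(clock_min)).ravel()[0]) if d.time_basis else 0.0
    if d.space_basis is not None:
        if not d.space_basis.in_support(xy):
            warnings.warn("location outside fitted spatial support: extrapolating")
        val += float(np.asarray(model.smooth_space(xy[0], xy[1])).ravel()[0])
    if include_random:
        for nm, lev in (("day", day), ("participant", participant)):
            if lev is not None and nm in model.random_intercepts:
                val += model.random_intercepts[nm][lev][0]
    return float(val)


def bayes_r2(model: FittedModel, kind: str = "marginal") -> float:
    """Variance-partition R2: marginal uses fixed+smooth fitted values only;
    conditional adds the random-intercept contributions."""
    if kind == "marginal":
        r2 = model.r2_marginal
    elif kind == "conditional":
        r2 = model.r2_conditional
    else:
        raise ValueError("kind must be 'marginal' or 'conditional'")
    if not np.isfinite(r2):
        raise ValueError("degenerate fit: R2 undefined")
    return r2


def residual_diagnostics(model: FittedModel) -> dict:
    """Whitened-innovation ACF at lags 1-3 and heavy-tail summaries.

    On a well-specified fit the whitened innovations should show no temporal
    dependency (|ACF| < 0.1) and tail weight consistent with the Student
    likelihood.
    """
    e = model._innovations
    sd = e.std()
    return {
        "acf": model.resid_acf,
        "excess_kurtosis": float(kurtosis(e, fisher=True, bias=False)),
        "prop_beyond_3sd": float(np.mean(np.abs(e) > 3 * sd)),
        "converged": model.converged,
    }


def coefficient_table(models: Mapping[str, FittedModel]) -> pd.DataFrame:
    """Coefficient table across responses (term, estimate, lower95, upper95),
    mirroring the usual exposure-model report layout."""
    rows = []
    for resp, m in models.items():
        for term, (est, lo, hi) in m.estimates.items():
            rows.append({"response": resp, "term": term, "estimate": est, "lower95": lo, "upper95": hi, "kind": m.interval_kind})
        for i, (est, lo, hi) in enumerate(m.ma_coefs, start=1):
            rows.append({"response": resp, "term": f"MA[{i}]", "estimate": est, "lower95": lo, "upper95": hi, "kind": m.interval_kind})
        for nm, levels in m.random_intercepts.items():
            for lev, (est, lo, hi) in levels.items():
                rows.append({"response": resp, "term": f"{nm}:{lev}", "estimate": est, "lower95": lo, "upper95": hi, "kind": "blup"})
        rows.append({"response": resp, "term": "R2_marginal", "estimate": m.r2_marginal, "lower95": np.nan, "upper95": np.nan, "kind": ""})
        rows.append({"response": resp, "term": "R2_conditional", "estimate": m.r2_conditional, "lower95": np.nan, "upper95": np.nan, "kind": ""})
    return pd.DataFrame(rows)
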