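"""Penalized additive regression (a small Gaussian GAM engine).

Smooth terms are cubic B-spline bases with second-order difference
penalties; 2-D surfaces are tensor products with one penalty per margin;
random intercepts are ridge-penalized factor dummies.  Smoothing parameters
are chosen by restricted maximum likelihood (generalized cross-validation
is kept as an alternative criterion), and an optional second penalty on
each smooth's penalty null space allows a term to be shrunk entirely out of
the model (double-penalty selection).

The estimator follows scikit-learn conventions: ``fit(X, y)`` with a
pandas DataFrame of covariates, fitted attributes with trailing
underscores, ``predict`` with optional standard errors, and
``get_params``/``set_params`` for composition with sklearn tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["Smooth", "Smooth2D", "RandomIntercept", "Linear", "PenalizedGAM"]


# ---------------------------------------------------------------------------
# basis construction
# ---------------------------------------------------------------------------


def _bspline_knots(x: np.ndarray, k: int) -> np.ndarray:
    """Augmented knot vector giving k cubic B-spline basis functions.

    Interior knots are equidistant: the second-order difference penalty
    then has exactly the linear functions in its null space (the P-spline
    construction requires equal spacing).
    """
    if k < 4:
        raise ValueError("need k >= 4 for a cubic basis")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        hi = lo + 1.0
    h = (hi - lo) / (k - 3)
    return lo + h * (np.arange(k + 4) - 3.0)


def _bspline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    xc = np.clip(x, knots[3], knots[-4])  # constant-knot clamp outside range
    return BSpline.design_matrix(xc, knots, 3).toarray()


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


def _cyclic_design(x: np.ndarray, k: int, period: float) -> np.ndarray:
    """k cyclic cubic B-spline basis functions on [0, period)."""
    u = np.linspace(0.0, period, k + 1)
    t = np.concatenate([u[-4:-1] - period, u, u[1:4] + period])
    xm = np.mod(x, period)
    b = BSpline.design_matrix(xm, t, 3).toarray()  # k + 3 columns
    b[:, :3] += b[:, k : k + 3]
    return b[:, :k]


def _cyclic_penalty(k: int) -> np.ndarray:
    d = np.zeros((k, k))
    for i in range(k):
        d[i, i] += 1.0
        d[i, (i + 1) % k] += -2.0
        d[i, (i + 2) % k] += 1.0
    return d.T @ d


def _absorb_sum_to_zero(X: np.ndarray, penalties: list[np.ndarray]):
    """Reparameterize so the column-mean (constant) direction is removed."""
    c = X.mean(axis=0)
    nrm = np.linalg.norm(c)
    if nrm < 1e-12:
        return X, penalties, np.eye(X.shape[1])
    q, _ = np.linalg.qr(c[:, None] / nrm, mode="complete")
    Z = q[:, 1:]
    return X @ Z, [Z.T @ S @ Z for S in penalties], Z


def _normalize(S: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(S)
    return S / nrm if nrm > 0 else S


# ---------------------------------------------------------------------------
# term definitions
# ---------------------------------------------------------------------------


@dataclass
class Smooth:
    """Penalized 1-D smooth f(var); optionally cyclic or varying-coefficient.

    by : name of a numeric column multiplying the smooth row-wise (a
        varying-coefficient term), or of a categorical column giving one
        smooth copy per level (a by-factor smooth with a shared penalty).
    """

    var: str
    k: int = 8
    cyclic: bool = False
    period: float | None = None
    by: str | None = None

    @property
    def label(self) -> str:
        return f"s({self.var})" if self.by is None else f"s({self.var},by={self.by})"

    def build(self, df: pd.DataFrame) -> "_Built":
        x = df[self.var].to_numpy(dtype=float)
        if self.cyclic:
            period = self.period if self.period is not None else float(np.ptp(x)) or 1.0
            state = {"period": period}
            B = _cyclic_design(x, self.k, period)
            pens = [_cyclic_penalty(self.k)]
        else:
            knots = _bspline_knots(x, self.k)
            state = {"knots": knots}
            B = _bspline_design(x, knots)
            pens = [_difference_penalty(self.k)]
        by_levels = None
        if self.by is not None and not pd.api.types.is_numeric_dtype(df[self.by]):
            by_levels = sorted(df[self.by].astype(str).unique())
            state["by_levels"] = by_levels
        B, pens, Z = _absorb_sum_to_zero(B, pens)
        state["Z"] = Z
        if self.by is not None:
            if by_levels is None:  # varying coefficient
                B = B * df[self.by].to_numpy(dtype=float)[:, None]
            else:
                blocks = []
                lv = df[self.by].astype(str).to_numpy()
                for level in by_levels:
                    blocks.append(B * (lv == level)[:, None])
                B = np.hstack(blocks)
                m = len(by_levels)
                pens = [np.kron(np.eye(m), pens[0])]
        rng = (float(np.min(x)), float(np.max(x)))
        return _Built(self, B, [_normalize(S) for S in pens], state, {self.var: rng})

    def design(self, df: pd.DataFrame, state: dict) -> np.ndarray:
        x = df[self.var].to_numpy(dtype=float)
        if self.cyclic:
            B = _cyclic_design(x, self.k, state["period"])
        else:
            B = _bspline_design(x, state["knots"])
        B = B @ state["Z"]
        if self.by is not None:
            if "by_levels" in state:
                lv = df[self.by].astype(str).to_numpy()
                B = np.hstack([B * (lv == level)[:, None] for level in state["by_levels"]])
            else:
                B = B * df[self.by].to_numpy(dtype=float)[:, None]
        return B


@dataclass
class Smooth2D:
    """Tensor-product surface f(xvar, yvar) with one penalty per margin."""

    xvar: str
    yvar: str
    k: int = 30  # total basis dimension budget

    @property
    def label(self) -> str:
        return f"s({self.xvar},{self.yvar})"

    @property
    def _km(self) -> int:
        return max(4, int(np.floor(np.sqrt(self.k))))

    def build(self, df: pd.DataFrame) -> "_Built":
        km = self._km
        x = df[self.xvar].to_numpy(dtype=float)
        y = df[self.yvar].to_numpy(dtype=float)
        kx = _bspline_knots(x, km)
        ky = _bspline_knots(y, km)
        Bx = _bspline_design(x, kx)
        By = _bspline_design(y, ky)
        B = np.einsum("ij,ik->ijk", Bx, By).reshape(len(x), km * km)
        P = _difference_penalty(km)
        pens = [np.kron(P, np.eye(km)), np.kron(np.eye(km), P)]
        B, pens, Z = _absorb_sum_to_zero(B, pens)
        state = {"kx": kx, "ky": ky, "Z": Z}
        ranges = {
            self.xvar: (float(np.min(x)), float(np.max(x))),
            self.yvar: (float(np.min(y)), float(np.max(y))),
        }
        return _Built(self, B, [_normalize(S) for S in pens], state, ranges)

    def design(self, df: pd.DataFrame, state: dict) -> np.ndarray:
        Bx = _bspline_design(df[self.xvar].to_numpy(dtype=float), state["kx"])
        By = _bspline_design(df[self.yvar].to_numpy(dtype=float), state["ky"])
        km = Bx.shape[1]
        B = np.einsum("ij,ik->ijk", Bx, By).reshape(len(df), km * km)
        return B @ state["Z"]


@dataclass
class RandomIntercept:
    """Ridge-penalized intercept per level of a factor (a random effect)."""

    var: str

    @property
    def label(self) -> str:
        return f"re({self.var})"

    def build(self, df: pd.DataFrame) -> "_Built":
        levels = sorted(df[self.var].astype(str).unique())
        state = {"levels": levels}
        return _Built(self, self.design(df, state), [np.eye(len(levels)) / np.sqrt(len(levels))], state, {})

    def design(self, df: pd.DataFrame, state: dict) -> np.ndarray:
        lv = df[self.var].astype(str).to_numpy()
        # unseen levels get all-zero rows: the population level
        return np.column_stack([(lv == level).astype(float) for level in state["levels"]])


@dataclass
class Linear:
    """A single centered linear column (unpenalized unless select=True)."""

    var: str

    @property
    def label(self) -> str:
        return self.var

    def build(self, df: pd.DataFrame) -> "_Built":
        x = df[self.var].to_numpy(dtype=float)
        mu = float(x.mean())
        state = {"centre": mu}
        rng = (float(np.min(x)), float(np.max(x)))
        return _Built(self, (x - mu)[:, None], [], state, {self.var: rng})

    def design(self, df: pd.DataFrame, state: dict) -> np.ndarray:
        return (df[self.var].to_numpy(dtype=float) - state["centre"])[:, None]


@dataclass
class _Built:
    term: object
    X: np.ndarray
    penalties: list[np.ndarray]
    state: dict
    ranges: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class PenalizedGAM(RegressorMixin, BaseEstimator):
    """Gaussian additive model with GCV-selected penalized spline terms.

    Parameters
    ----------
    terms : sequence of Smooth / Smooth2D / RandomIntercept / Linear.
    select : add a null-space shrinkage penalty per smooth so that terms
        can be removed entirely (double-penalty variable selection).
    ar_rho : AR(1) residual correlation used to pre-whiten y and the design
        within each series before fitting (0 disables).
    series : column naming the series for AR(1) pre-whitening; rows must be
        time-ordered within each series.
    gamma : GCV effective-dof inflation (>1 smooths more; GCV only).
    method : smoothing-parameter criterion, "REML" (default) or "GCV".
    """

    def __init__(self, terms=(), select: bool = False, ar_rho: float = 0.0,
                 series: str | None = None, gamma: float = 1.0, method: str = "REML"):
        self.terms = terms
        self.select = select
        self.ar_rho = ar_rho
        self.series = series
        self.gamma = gamma
        self.method = method

    # -- internal ----------------------------------------------------------

    def _assemble(self, df: pd.DataFrame):
        built = [t.build(df) for t in self.terms]
        blocks = [np.ones((len(df), 1))] + [b.X for b in built]
        X = np.hstack(blocks)
        slices, pos = [], 1
        for b in built:
            slices.append(slice(pos, pos + b.X.shape[1]))
            pos += b.X.shape[1]
        pens = []  # (term index, coefficient slice, small penalty block)
        for i, (b, sl) in enumerate(zip(built, slices)):
            for S in b.penalties:
                pens.append((i, sl, S))
            if self.select:
                extra = None
                if b.penalties:
                    Ssum = sum(b.penalties)
                    w, V = np.linalg.eigh(Ssum)
                    null = V[:, w < 1e-8 * max(w.max(), 1e-300)]
                    if null.shape[1]:
                        extra = null @ null.T
                elif isinstance(b.term, Linear):
                    extra = np.eye(1)
                if extra is not None:
                    pens.append((i, sl, _normalize(extra)))
        return built, X, slices, pens

    def _whiten(self, X: np.ndarray, y: np.ndarray, df: pd.DataFrame):
        rho = float(self.ar_rho)
        if rho == 0.0:
            return X, y
        Xw, yw = X.copy(), y.copy()
        if self.series is not None:
            groups = df.groupby(self.series, sort=False).indices.values()
        else:
            groups = [np.arange(len(y))]
        c = np.sqrt(1.0 - rho**2)
        for idx in groups:
            idx = np.asarray(idx)
            Xw[idx[1:]] -= rho * X[idx[:-1]]
            yw[idx[1:]] -= rho * y[idx[:-1]]
            Xw[idx[0]] *= c
            yw[idx[0]] *= c
        return Xw, yw

    # -- API ----------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y):
        df = X
        if not isinstance(df, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame of covariates")
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or len(y) != len(df):
            raise ValueError("y must be 1-D and aligned with X")
        self.built_, Xm, self.slices_, pens = self._assemble(df)
        Xw, yw = self._whiten(Xm, y, df)
        n, p = Xw.shape
        XtX = Xw.T @ Xw
        Xty = Xw.T @ yw

        def add_penalties(loglam):
            lam = 10.0**loglam
            M = XtX.copy()
            for lm, (_, sl, S) in zip(lam, pens):
                M[sl, sl] += lm * S
            M[np.diag_indices_from(M)] += 1e-10
            return M

        def solve(loglam):
            M = add_penalties(loglam)
            try:
                beta = np.linalg.solve(M, Xty)
                H = np.linalg.solve(M, XtX)
            except np.linalg.LinAlgError:
                return None
            return beta, H, M

        tss = float(np.sum((yw - yw.mean()) ** 2))
        rss_floor = 1e-9 * max(tss, 1e-30)  # keeps the score well-defined at RSS ~ 0

        def gcv(loglam):
            out = solve(loglam)
            if out is None:
                return 1e30
            beta, H, _ = out
            rss = float(np.sum((yw - Xw @ beta) ** 2))
            edf = float(np.trace(H))
            denom = n - self.gamma * edf
            if denom <= 1.0:
                return 1e30
            return float(np.log(n * (rss + rss_floor)) - 2.0 * np.log(denom))

        # group penalty indices by owning term for the log|S|_+ blocks
        term_pen: dict[int, list[int]] = {}
        for j, (i, _, _) in enumerate(pens):
            term_pen.setdefault(i, []).append(j)
        block_rank: dict[int, int] = {}
        for i, idxs in term_pen.items():
            Ssum = sum(pens[j][2] for j in idxs)
            w = np.linalg.eigvalsh(Ssum)
            block_rank[i] = int(np.sum(w > 1e-9 * max(w.max(), 1e-300)))
        r_total = sum(block_rank.values())
        m0 = p - r_total  # unpenalized coefficient-space dimension

        def reml(loglam):
            out = solve(loglam)
            if out is None:
                return 1e30
            beta, _, M = out
            lam = 10.0**loglam
            pen_quad = 0.0
            log_s_plus = 0.0
            for i, idxs in term_pen.items():
                sl = pens[idxs[0]][1]
                Ssum = sum(10.0 ** loglam[j] * pens[j][2] for j in idxs)
                pen_quad += float(beta[sl] @ Ssum @ beta[sl])
                w = np.sort(np.linalg.eigvalsh(Ssum))[::-1][: block_rank[i]]
                log_s_plus += float(np.sum(np.log(np.maximum(w, 1e-300))))
            rss = float(np.sum((yw - Xw @ beta) ** 2))
            q_hat = rss + pen_quad
            # floor keeps the profiled scale away from rounding noise when a
            # noise-free fit drives the residuals to ~0
            sig2 = max(q_hat / max(n - m0, 1.0),
                       1e-9 * tss / max(n - m0, 1.0) if tss > 0 else 1e-300)
            sign, logdet_m = np.linalg.slogdet(M)
            if sign <= 0:
                return 1e30
            # -2 log restricted likelihood, sigma^2 profiled out
            return float(
                (n - m0) * np.log(2.0 * np.pi * sig2)
                + q_hat / sig2
                + logdet_m
                - log_s_plus
            )

        objective = reml if self.method == "REML" else gcv

        def lbfgs(x0):
            # wide fd step: the objective is O(n log sigma^2), so tiny steps
            # drown the gradient in rounding noise
            return minimize(objective, x0, method="L-BFGS-B",
                            bounds=[(-8.0, 10.0)] * len(pens),
                            options={"maxiter": 300, "eps": 1e-5, "ftol": 1e-12})

        def polish(x):
            # coordinate-wise grid refinement: the objective has long flat
            # plateaus in individual log-lambdas where gradient descent stalls
            best = objective(x)
            # wide jumps included: plateaus can span many decades
            steps = np.array([-8.0, -5.0, -3.0, -2.0, -1.0, -0.5,
                              0.5, 1.0, 2.0, 3.0, 5.0, 8.0])
            for _ in range(3):
                improved = False
                for j in range(len(x)):
                    cand = np.clip(np.concatenate([x[j] + steps, [-4.0, -2.0, 0.0, 2.0, 4.0]]),
                                   -8.0, 10.0)
                    vals = []
                    for c in cand:
                        xx = x.copy()
                        xx[j] = c
                        vals.append(objective(xx))
                    k = int(np.argmin(vals))
                    if vals[k] < best - 1e-9:
                        x = x.copy()
                        x[j] = cand[k]
                        best = vals[k]
                        improved = True
                if not improved:
                    break
            return x

        if pens:
            res = lbfgs(np.zeros(len(pens)))
            loglam = polish(res.x)
            res2 = lbfgs(loglam)
            if objective(res2.x) < objective(loglam):
                loglam = res2.x
        else:
            loglam = np.zeros(0)
        beta, H, M = solve(loglam)
        self.coef_ = beta
        self.lambda_ = 10.0**loglam
        self.edf_ = float(np.trace(H))
        self.edf_by_term_ = {}
        dH = np.diag(H)
        for b, sl in zip(self.built_, self.slices_):
            self.edf_by_term_[b.term.label] = float(np.sum(dH[sl]))
        rss_w = float(np.sum((yw - Xw @ beta) ** 2))
        self.scale_ = rss_w / max(n - self.edf_, 1.0)
        self.cov_ = np.linalg.inv(M) @ XtX @ np.linalg.inv(M).T * self.scale_
        # Bayesian posterior covariance, used for prediction intervals
        self.vb_ = np.linalg.inv(M) * self.scale_
        self.fitted_values_ = Xm @ beta
        self.residuals_ = y - self.fitted_values_
        tss = float(np.sum((y - y.mean()) ** 2))
        rss = float(np.sum(self.residuals_**2))
        self.deviance_explained_ = 1.0 - rss / tss if tss > 0 else 0.0
        self.adj_r2_ = 1.0 - (rss / max(n - self.edf_ - 1, 1.0)) / (tss / max(n - 1, 1))
        sig2 = rss_w / n
        self.aic_ = n * np.log(2.0 * np.pi * max(sig2, 1e-300)) + n + 2.0 * (self.edf_ + 1.0)
        self.n_obs_ = n
        self.gcv_ = gcv(loglam)
        return self

    def predict(self, X: pd.DataFrame, return_se: bool = False,
                return_extrapolation: bool = False):
        check_is_fitted(self, "coef_")
        blocks = [np.ones((len(X), 1))]
        extrap = np.zeros(len(X), dtype=bool)
        for b in self.built_:
            blocks.append(b.term.design(X, b.state))
            for var, (lo, hi) in b.ranges.items():
                v = X[var].to_numpy(dtype=float)
                extrap |= (v < lo) | (v > hi)
        Xm = np.hstack(blocks)
        mu = Xm @ self.coef_
        out = [mu]
        if return_se:
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xm, self.vb_, Xm), 0.0))
            out.append(se)
        if return_extrapolation:
            out.append(extrap)
        return out[0] if len(out) == 1 else tuple(out)

    def partial_effect(self, label: str, X: pd.DataFrame) -> np.ndarray:
        """Centred contribution of one term at the rows of ``X``."""
        check_is_fitted(self, "coef_")
        for b, sl in zip(self.built_, self.slices_):
            if b.term.label == label:
                return b.term.design(X, b.state) @ self.coef_[sl]
        raise KeyError(f"no term labelled {label!r}")

    def summary(self) -> pd.DataFrame:
        check_is_fitted(self, "coef_")
        return pd.DataFrame(
            {"term": list(self.edf_by_term_), "edf": list(self.edf_by_term_.values())}
        )
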