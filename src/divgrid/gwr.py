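"""Geographically weighted regression with golden-section AICc bandwidths.

``GWR`` fits, at every calibration location i, a weighted least-squares
regression of the response on [1, x] with Gaussian kernel weights
w_ij = exp(−0.5 (d_ij / b)²), where d_ij is the distance between locations
and b the (fixed, distance-metric) bandwidth.  The bandwidth is selected by
golden-section search minimizing the corrected Akaike criterion

    AICc = 2n ln σ̂ + n ln 2π + n (n + tr(S)) / (n − 2 − tr(S)),

with σ̂² = RSS/n and tr(S) the trace of the hat matrix (effective number of
parameters).  ``MGWR`` relaxes the single-scale assumption: each term
(intercept, slope) receives its own bandwidth via backfitting on partial
residuals; with all bandwidths equal, MGWR is by definition ordinary GWR at
that bandwidth and is solved jointly.

``run_model_suite`` fits the six pairwise congruence models between
diversity (FD~TD, PD~TD, FD~PD) and endemism (WE~FE, WE~PE, FE~PE)
surfaces and classifies residual signs: a positive residual marks cells
where the response exceeds the value expected from the predictor, a
negative one where it falls short.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidConfigError,
    SearchFailureError,
)

__all__ = [
    "GWR",
    "MGWR",
    "GWRResults",
    "aicc",
    "golden_section_minimize",
    "golden_section_bandwidth",
    "run_model_suite",
    "classify_residuals",
    "MODEL_PAIRS",
]

#: the six pairwise congruence models, (response, predictor)
MODEL_PAIRS = (
    ("FD", "TD"),
    ("PD", "TD"),
    ("FD", "PD"),
    ("WE", "FE"),
    ("WE", "PE"),
    ("FE", "PE"),
)


# ---------------------------------------------------------------------------
# results


@dataclass
class GWRResults:
    """Local estimates and diagnostics of one (M)GWR fit."""

    model_name: str
    coords: np.ndarray            # (n, 2)
    bandwidth: float | tuple[float, ...]
    params: np.ndarray            # (n, 2): local intercept, local slope
    fittedvalues: np.ndarray      # (n,)
    resid: np.ndarray             # observed − fitted, exactly
    local_r2: np.ndarray          # (n,), in [0, 1] where defined
    tr_S: float                   # effective parameters, trace of hat matrix
    degenerate: np.ndarray        # (n,) bool: singular local design flag
    endog: np.ndarray
    exog: np.ndarray
    converged: bool = True
    n_iter: int = 0

    @property
    def nobs(self) -> int:
        return len(self.endog)

    @property
    def rss(self) -> float:
        return float(np.sum(self.resid**2))

    @property
    def aicc(self) -> float:
        return aicc(self.rss, self.nobs, self.tr_S)

    def summary(self) -> str:
        bw = self.bandwidth
        bw_str = (f"{bw:.4g}" if np.isscalar(bw)
                  else ", ".join(f"{b:.4g}" for b in bw))
        lines = [
            f"{'':=>60}".replace("=", "="),
            f"Geographically weighted regression: {self.model_name}",
            f"{'-' * 60}",
            f"{'No. observations:':<28}{self.nobs:>12d}",
            f"{'Bandwidth:':<28}{bw_str:>12}",
            f"{'Effective parameters tr(S):':<28}{self.tr_S:>12.3f}",
            f"{'Residual sum of squares:':<28}{self.rss:>12.4g}",
            f"{'AICc:':<28}{self.aicc:>12.4f}",
            f"{'Local R2 (min/median/max):':<28}"
            f"{np.nanmin(self.local_r2):>8.3f}"
            f"{np.nanmedian(self.local_r2):>8.3f}"
            f"{np.nanmax(self.local_r2):>8.3f}",
            f"{'Converged:':<28}{str(self.converged):>12}",
            f"{'-' * 60}",
        ]
        return "\n".join(lines)

    def plot(self, what: str = "resid", ax=None):
        """Scatter the residual (or local R²) surface at the fit's coords."""
        import matplotlib.pyplot as plt

        values = {"resid": self.resid, "local_r2": self.local_r2,
                  "fitted": self.fittedvalues}[what]
        if ax is None:
            _, ax = plt.subplots()
        sc = ax.scatter(self.coords[:, 0], self.coords[:, 1], c=values,
                        cmap="RdBu_r", s=25)
        ax.set_title(f"{self.model_name}: {what}")
        ax.figure.colorbar(sc, ax=ax)
        return ax


# ---------------------------------------------------------------------------
# criteria


def aicc(rss: float, n: int, tr_s: float) -> float:
    """Corrected AIC for a GWR fit with hat-matrix trace ``tr_s``."""
    if tr_s >= n - 2:
        raise InvalidConfigError(
            f"AICc undefined: tr(S)={tr_s:.3f} >= n-2={n - 2}"
        )
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    return float(
        n * math.log(sigma2) + n * math.log(2 * math.pi)
        + n * (n + tr_s) / (n - 2 - tr_s)
    )


def golden_section_minimize(
    f, lo: float, hi: float, rel_tol: float = 1e-3, max_iter: int = 200
) -> tuple[float, float]:
    """Golden-section search for the minimum of ``f`` on [lo, hi].

    ``f`` may return +inf for inadmissible points.  Terminates when the
    interval shrinks below ``rel_tol`` relative to its midpoint.  Returns
    (argmin, f(argmin)); raises if no admissible point was found.
    """
    if not (0 < lo < hi):
        raise InvalidConfigError("need 0 < lo < hi for the search interval")
    invphi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    cache: dict[float, float] = {}

    def ev(x: float) -> float:
        if x not in cache:
            cache[x] = f(x)
        return cache[x]

    for _ in range(max_iter):
        if (b - a) < rel_tol * max(abs(a + b) / 2, 1e-12):
            break
        if ev(c) <= ev(d):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    candidates = [x for x in list(cache) + [lo, hi] if lo <= x <= hi]
    finite = [(ev(x), x) for x in candidates if math.isfinite(ev(x))]
    if not finite:
        raise SearchFailureError("objective undefined on entire interval")
    fbest, xbest = min(finite)
    return xbest, fbest


# ---------------------------------------------------------------------------
# models


class GWR:
    """Geographically weighted regression of ``endog`` on one predictor.

    Parameters
    ----------
    endog, exog : 1-D arrays of the response and single predictor.
    coords : (n, 2) array of planar location coordinates.
    kernel : only "gaussian" is implemented (fixed distance bandwidth).
    """

    def __init__(self, endog, exog, coords, kernel: str = "gaussian"):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float).ravel()
        self.coords = np.asarray(coords, dtype=float)
        if kernel != "gaussian":
            raise InvalidConfigError(f"unsupported kernel {kernel!r}")
        self.kernel = kernel
        n = len(self.endog)
        if n < 3:
            raise InsufficientDataError("need at least 3 locations")
        if self.exog.shape != (n,) or self.coords.shape != (n, 2):
            raise ValueError("endog, exog and coords have inconsistent shapes")
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        self._d2 = np.sum(diff**2, axis=-1)
        self.model_name = "y~x"

    # -- kernel and default search interval --------------------------------

    def weights(self, bandwidth: float) -> np.ndarray:
        if bandwidth <= 0:
            raise InvalidConfigError("bandwidth must be > 0")
        return np.exp(-0.5 * self._d2 / bandwidth**2)

    def default_interval(self) -> tuple[float, float]:
        d = np.sqrt(self._d2)
        nz = d[d > 0]
        if nz.size == 0:
            raise DegenerateDesignError("all locations coincide")
        lo = float(nz.min())
        span = self.coords.max(axis=0) - self.coords.min(axis=0)
        hi = float(np.hypot(*span))
        if hi <= lo:
            hi = lo * 10
        return lo, hi

    # -- fitting -----------------------------------------------------------

    def fit(self, bandwidth: float | None = None,
            bw_interval: tuple[float, float] | None = None) -> GWRResults:
        """Fit at a fixed bandwidth, or select one by golden-section AICc."""
        if bandwidth is None:
            bandwidth = self.select_bandwidth(bw_interval)
        return self._fit_at(bandwidth)

    def select_bandwidth(
        self, interval: tuple[float, float] | None = None,
        rel_tol: float = 1e-3,
    ) -> float:
        if interval is None:
            interval = self.default_interval()
        lo, hi = interval
        if not (lo < hi):
            raise InvalidConfigError("bandwidth interval must satisfy lo < hi")

        def objective(b: float) -> float:
            try:
                return self._fit_at(b).aicc
            except (InvalidConfigError, FloatingPointError):
                return math.inf

        b, _ = golden_section_minimize(objective, lo, hi, rel_tol=rel_tol)
        return b

    def _fit_at(self, bandwidth: float) -> GWRResults:
        y, x = self.endog, self.exog
        n = len(y)
        W = self.weights(bandwidth)  # (n, n), row i = weights for location i
        # closed-form 2x2 local WLS at every location simultaneously
        s0 = W.sum(axis=1)
        sx = W @ x
        sxx = W @ (x * x)
        sy = W @ y
        sxy = W @ (x * y)
        det = s0 * sxx - sx**2
        scale = np.maximum(s0 * np.maximum(sxx, 0), 1e-300)
        degenerate = det <= 1e-12 * scale
        det_safe = np.where(degenerate, 1.0, det)
        slope = np.where(degenerate, 0.0, (s0 * sxy - sx * sy) / det_safe)
        intercept = np.where(degenerate, sy / np.maximum(s0, 1e-300),
                             (sxx * sy - sx * sxy) / det_safe)
        params = np.column_stack([intercept, slope])
        fitted = intercept + slope * x
        resid = y - fitted
        # hat diagonal: S_ii = w_ii * [1, x_i] A_i^{-1} [1, x_i]^T
        wii = np.diag(W)
        quad = np.where(
            degenerate,
            wii / np.maximum(s0, 1e-300),
            wii * (sxx - 2 * x * sx + x * x * s0) / det_safe,
        )
        tr_S = float(np.sum(quad))
        # geographically weighted local R^2 at each location
        yhat_ji = intercept[:, None] + slope[:, None] * x[None, :]
        rss_i = np.sum(W * (y[None, :] - yhat_ji) ** 2, axis=1)
        ybar_i = sy / np.maximum(s0, 1e-300)
        tss_i = np.sum(W * (y[None, :] - ybar_i[:, None]) ** 2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            local_r2 = np.where(tss_i > 0, 1.0 - rss_i / tss_i, np.nan)
        local_r2 = np.clip(local_r2, 0.0, 1.0)
        return GWRResults(
            model_name=self.model_name,
            coords=self.coords,
            bandwidth=float(bandwidth),
            params=params,
            fittedvalues=fitted,
            resid=resid,
            local_r2=local_r2,
            tr_S=tr_S,
            degenerate=degenerate,
            endog=y,
            exog=x,
        )


def golden_section_bandwidth(
    endog, exog, coords,
    interval: tuple[float, float] | None = None,
    rel_tol: float = 1e-3,
) -> float:
    """Functional wrapper: AICc-optimal Gaussian bandwidth for a GWR."""
    return GWR(endog, exog, coords).select_bandwidth(interval,
                                                     rel_tol=rel_tol)


class MGWR(GWR):
    """Multiscale GWR: one bandwidth per model term via backfitting.

    The additive model y = f0(u) + f1(u)·x is initialized from the ordinary
    GWR fit at its AICc-optimal single bandwidth; the terms are then
    iteratively re-fitted on partial residuals, each with its own
    golden-section AICc bandwidth, until the change in fitted values
    (SOC-RSS) falls below ``soc_tol``.
    """

    def __init__(self, endog, exog, coords, kernel: str = "gaussian",
                 soc_tol: float = 1e-5, max_iter: int = 200):
        super().__init__(endog, exog, coords, kernel=kernel)
        if np.ptp(self.exog) == 0:
            raise DegenerateDesignError("predictor has zero variance")
        self.soc_tol = soc_tol
        self.max_iter = max_iter

    def fit(self, bandwidths: tuple[float, float] | None = None,
            bw_interval: tuple[float, float] | None = None) -> GWRResults:
        if bandwidths is not None:
            b0, b1 = bandwidths
            if b0 == b1:
                # equal scales: MGWR is by definition ordinary GWR
                res = self._fit_at(b0)
                res.bandwidth = (float(b0), float(b1))
                res.model_name = self.model_name
                return res
            return self._backfit(fixed=(b0, b1), bw_interval=bw_interval)
        return self._backfit(fixed=None, bw_interval=bw_interval)

    def _term_smooth(self, e: np.ndarray, term: int, bandwidth: float
                     ) -> tuple[np.ndarray, np.ndarray, float]:
        """Local single-column WLS of partial residual ``e`` on one term.

        term 0: intercept column (1); term 1: the predictor column (x).
        Returns (fitted contribution, local coefficient, tr of the term's
        smoother)."""
        W = self.weights(bandwidth)
        if term == 0:
            s = W.sum(axis=1)
            coef = (W @ e) / np.maximum(s, 1e-300)
            contrib = coef
            tr = float(np.sum(np.diag(W) / np.maximum(s, 1e-300)))
        else:
            x = self.exog
            sxx = W @ (x * x)
            coef = (W @ (x * e)) / np.maximum(sxx, 1e-300)
            contrib = coef * x
            tr = float(np.sum(np.diag(W) * x * x / np.maximum(sxx, 1e-300)))
        return contrib, coef, tr

    def _select_term_bandwidth(self, e: np.ndarray, term: int,
                               interval: tuple[float, float]) -> float:
        n = len(e)

        def objective(b: float) -> float:
            contrib, _, tr = self._term_smooth(e, term, b)
            rss = float(np.sum((e - contrib) ** 2))
            try:
                return aicc(rss, n, tr)
            except InvalidConfigError:
                return math.inf

        b, _ = golden_section_minimize(objective, *interval)
        return b

    def _backfit(self, fixed: tuple[float, float] | None,
                 bw_interval: tuple[float, float] | None) -> GWRResults:
        y, x = self.endog, self.exog
        interval = bw_interval or self.default_interval()
        # initialize from single-bandwidth GWR
        init_bw = self.select_bandwidth(interval)
        init = self._fit_at(init_bw)
        f = [init.params[:, 0].copy(), init.params[:, 1] * x]
        coefs = [init.params[:, 0].copy(), init.params[:, 1].copy()]
        bws = [init_bw, init_bw]
        trs = [init.tr_S / 2, init.tr_S / 2]
        yhat = f[0] + f[1]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            for term in (0, 1):
                e = y - f[1 - term]
                if fixed is not None:
                    bws[term] = fixed[term]
                else:
                    bws[term] = self._select_term_bandwidth(e, term, interval)
                contrib, coef, tr = self._term_smooth(e, term, bws[term])
                f[term] = contrib
                coefs[term] = coef
                trs[term] = tr
            new_yhat = f[0] + f[1]
            denom = float(np.sum(new_yhat**2))
            soc = math.sqrt(
                float(np.sum((new_yhat - yhat) ** 2))
                / max(denom, 1e-300)
            )
            yhat = new_yhat
            if soc < self.soc_tol:
                converged = True
                break
        resid = y - yhat
        tr_S = float(sum(trs))
        # local R2 from the term-0 kernel (the intercept scale)
        W = self.weights(bws[0])
        s0 = W.sum(axis=1)
        ybar_i = (W @ y) / np.maximum(s0, 1e-300)
        yhat_ji = coefs[0][:, None] + coefs[1][:, None] * x[None, :]
        rss_i = np.sum(W * (y[None, :] - yhat_ji) ** 2, axis=1)
        tss_i = np.sum(W * (y[None, :] - ybar_i[:, None]) ** 2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            local_r2 = np.where(tss_i > 0, 1.0 - rss_i / tss_i, np.nan)
        local_r2 = np.clip(local_r2, 0.0, 1.0)
        return GWRResults(
            model_name=self.model_name,
            coords=self.coords,
            bandwidth=(float(bws[0]), float(bws[1])),
            params=np.column_stack(coefs),
            fittedvalues=yhat,
            resid=resid,
            local_r2=local_r2,
            tr_S=tr_S,
            degenerate=np.zeros(len(y), dtype=bool),
            endog=y,
            exog=x,
            converged=converged,
            n_iter=it,
        )


# ---------------------------------------------------------------------------
# the six-model congruence suite


def classify_residuals(resid: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Sign labels per cell: 'positive' (response above expectation),
    'negative' (below), 'neutral' (within ±eps)."""
    labels = np.full(resid.shape, "neutral", dtype=object)
    labels[resid > eps] = "positive"
    labels[resid < -eps] = "negative"
    return labels


def run_model_suite(
    surfaces,
    mode: str = "gwr",
    eps: float = 0.0,
    bw_interval: tuple[float, float] | None = None,
    models: tuple[tuple[str, str], ...] = MODEL_PAIRS,
) -> dict[str, dict]:
    """Fit the six pairwise congruence models on cell centroids.

    ``surfaces`` is a :class:`divgrid.surfaces.SurfaceSet`.  Cells missing
    either variable of a pair are excluded (interpolated cells are
    included).  Returns, per model name like "FD~TD", a dict with the
    results object, the used flat cell indices, and residual sign labels.
    """
    from .surfaces import SurfaceSet  # noqa: F401  (documented contract)

    centroids = surfaces.grid.centroids()
    out: dict[str, dict] = {}
    for response, predictor in models:
        y = surfaces.values[response]
        x = surfaces.values[predictor]
        usable = np.isfinite(y) & np.isfinite(x)
        if usable.sum() < 10:
            raise InsufficientDataError(
                f"model {response}~{predictor}: only {int(usable.sum())} "
                "usable cells (need >= 10)"
            )
        cls = MGWR if mode == "mgwr" else GWR
        model = cls(y[usable], x[usable], centroids[usable])
        model.model_name = f"{response}~{predictor}"
        result = model.fit(bw_interval=bw_interval)
        out[model.model_name] = {
            "result": result,
            "cells": np.flatnonzero(usable),
            "signs": classify_residuals(result.resid, eps=eps),
        }
    return out
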