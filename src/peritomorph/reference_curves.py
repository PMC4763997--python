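"""LMS (lambda–mu–sigma) age-reference centile curves.

The LMS method summarizes how a positive, possibly skewed measurement
changes with age by three smooth curves: the Box–Cox power L(t) that makes
the distribution normal at each age, the median M(t), and the coefficient of
variation S(t).  A measurement ``y`` at age ``t`` maps to a z-score

    z = ((y / M)^L − 1) / (L · S)        for L ≠ 0,
    z = ln(y / M) / S                    for L = 0,

and the α-centile curve is the inverse transform ``M (1 + L S z_α)^{1/L}``
(``M e^{S z_α}`` for L = 0).  The three curves are modeled as low-rank
smooths (orthogonal-polynomial bases with the conventional
degrees-of-freedom defaults L:2, M:4, S:3) of log-transformed age,
``t = log(age + 0.25)``, which concentrates resolution on the steep changes
of infancy.  Coefficients are estimated by maximizing the Box–Cox–Cole–Green
likelihood with a quasi-Newton optimizer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy import optimize, stats

__all__ = ["LMSConfig", "LMSModel", "fit_lms", "lms_zscore", "lms_percentile"]

_L_EPS = 1e-7  # |L| below this uses the log (L = 0) branch

#: Conventional report centiles (the method does not prescribe a set).
REPORT_CENTILES = (0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97)


@dataclass(frozen=True)
class LMSConfig:
    """Smoothing configuration: df = equivalent degrees of freedom per curve."""

    df_l: int = 2
    df_m: int = 4
    df_s: int = 3
    age_offset: float = 0.25     # years added before the log transform
    max_iter: int = 500

    def __post_init__(self):
        if min(self.df_l, self.df_m, self.df_s) < 1:
            raise ValueError("each curve needs at least 1 degree of freedom")


def _age_transform(age, offset):
    age = np.asarray(age, dtype=float)
    if np.any(age + offset <= 0):
        raise ValueError(f"age must exceed {-offset} years")
    return np.log(age + offset)


def _basis(t, df, t_lo, t_hi):
    """Orthogonal (Legendre) polynomial basis with df columns on [t_lo, t_hi]."""
    span = max(t_hi - t_lo, 1e-12)
    x = 2.0 * (np.asarray(t, float) - t_lo) / span - 1.0
    return legendre.legvander(x, df - 1)


@dataclass
class LMSModel:
    """Fitted age-varying Box–Cox power / median / CV curves.

    ``coef`` concatenates the basis coefficients of L, log M and log S.
    Curves are evaluable on the full age domain of the fit; evaluation
    outside ``age_range`` extrapolates the polynomial smooth with a warning.
    """

    coef: np.ndarray
    config: LMSConfig
    t_range: tuple[float, float]
    age_range: tuple[float, float]
    n: int
    loglik: float = np.nan
    converged: bool = True

    def _split(self):
        c = self.config
        a = self.coef
        return a[: c.df_l], a[c.df_l : c.df_l + c.df_m], a[c.df_l + c.df_m :]

    def curves(self, age):
        """Evaluate (L, M, S) at the given age(s) in years."""
        age_arr = np.atleast_1d(np.asarray(age, dtype=float))
        if np.any(age_arr < self.age_range[0] - 1e-12) or np.any(
            age_arr > self.age_range[1] + 1e-12
        ):
            warnings.warn(
                f"age outside the fitted range {self.age_range}; extrapolating",
                stacklevel=2,
            )
        t = _age_transform(age_arr, self.config.age_offset)
        cl, cm, cs = self._split()
        L = _basis(t, self.config.df_l, *self.t_range) @ cl
        M = np.exp(_basis(t, self.config.df_m, *self.t_range) @ cm)
        S = np.exp(_basis(t, self.config.df_s, *self.t_range) @ cs)
        if np.isscalar(age) or np.asarray(age).ndim == 0:
            return float(L[0]), float(M[0]), float(S[0])
        return L, M, S

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "coef": self.coef.tolist(),
            "config": {
                "df_l": self.config.df_l,
                "df_m": self.config.df_m,
                "df_s": self.config.df_s,
                "age_offset": self.config.age_offset,
                "max_iter": self.config.max_iter,
            },
            "t_range": list(self.t_range),
            "age_range": list(self.age_range),
            "n": self.n,
            "loglik": self.loglik,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LMSModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            coef=np.asarray(payload["coef"], dtype=float),
            config=LMSConfig(**payload["config"]),
            t_range=tuple(payload["t_range"]),
            age_range=tuple(payload["age_range"]),
            n=int(payload["n"]),
            loglik=float(payload["loglik"]),
            converged=bool(payload["converged"]),
        )


def _zscore_core(y, L, M, S):
    y, L, M, S = np.broadcast_arrays(
        np.asarray(y, float), np.asarray(L, float),
        np.asarray(M, float), np.asarray(S, float),
    )
    ratio = y / M
    z = np.empty_like(ratio)
    small = np.abs(L) < _L_EPS
    with np.errstate(invalid="ignore"):
        z[small] = np.log(ratio[small]) / S[small]
        Ln = L[~small]
        z[~small] = (ratio[~small] ** Ln - 1.0) / (Ln * S[~small])
    return z


def fit_lms(values, ages, config: LMSConfig | None = None) -> LMSModel:
    """Fit L(t), M(t), S(t) to (value, age) pairs by maximum likelihood.

    Requires at least 30 strictly positive values.  The Box–Cox–Cole–Green
    log-likelihood is maximized over the basis coefficients with L-BFGS-B,
    started from L = 1 and L = 0 initializations (the better optimum wins).
    Non-convergence raises with optimizer diagnostics.
    """
    if config is None:
        config = LMSConfig()
    y = np.asarray(values, dtype=float)
    age = np.asarray(ages, dtype=float)
    if y.shape != age.shape or y.ndim != 1:
        raise ValueError("values and ages must be matching 1-D arrays")
    keep = np.isfinite(y) & np.isfinite(age)
    y, age = y[keep], age[keep]
    if len(y) < 30:
        raise ValueError(f"need at least 30 (value, age) pairs, got {len(y)}")
    if np.any(y <= 0):
        raise ValueError("values must be strictly positive for the Box-Cox transform")
    if np.ptp(y) == 0:
        raise ValueError("degenerate constant values: zero variance")

    t = _age_transform(age, config.age_offset)
    t_range = (float(t.min()), float(t.max()))
    B_l = _basis(t, config.df_l, *t_range)
    B_m = _basis(t, config.df_m, *t_range)
    B_s = _basis(t, config.df_s, *t_range)
    log_y = np.log(y)
    n_l, n_m, n_s = config.df_l, config.df_m, config.df_s

    def nll(theta):
        L = B_l @ theta[:n_l]
        log_M = B_m @ theta[n_l : n_l + n_m]
        log_S = B_s @ theta[n_l + n_m :]
        if np.any(log_S > 5) or np.any(np.abs(log_M) > 50) or np.any(np.abs(L) > 20):
            return 1e12
        S = np.exp(log_S)
        z = _zscore_core(y, L, np.exp(log_M), S)
        if not np.all(np.isfinite(z)):
            return 1e12
        # ln f(y) = ln φ(z) + (L−1) ln y − L ln M − ln S
        ll = -0.5 * z**2 + (L - 1.0) * log_y - L * log_M - log_S
        return -float(ll.sum())

    # initialization: median curve from a least-squares fit of log y
    cm0, *_ = np.linalg.lstsq(B_m, log_y, rcond=None)
    resid = log_y - B_m @ cm0
    s0 = max(float(resid.std()), 1e-3)
    cs0 = np.zeros(n_s)
    cs0[0] = np.log(s0)

    best = None
    for l_init in (1.0, 0.0):
        cl0 = np.zeros(n_l)
        cl0[0] = l_init
        theta0 = np.concatenate([cl0, cm0, cs0])
        res = optimize.minimize(
            nll, theta0, method="L-BFGS-B",
            options={"maxiter": config.max_iter, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(f"LMS fit did not converge: {best.message}")
    if not best.success:
        warnings.warn(f"LMS optimizer stopped early: {best.message}", stacklevel=2)
    return LMSModel(
        coef=np.asarray(best.x, dtype=float),
        config=config,
        t_range=t_range,
        age_range=(float(age.min()), float(age.max())),
        n=len(y),
        loglik=-float(best.fun),
        converged=bool(best.success),
    )


def lms_zscore(model: LMSModel, age, value):
    """Age-standardized z-score of a measurement under the fitted model."""
    value_arr = np.atleast_1d(np.asarray(value, dtype=float))
    if np.any(value_arr <= 0):
        raise ValueError("value must be > 0")
    L, M, S = model.curves(age)
    z = _zscore_core(value_arr, L, M, S)
    return float(z[0]) if np.isscalar(value) or np.asarray(value).ndim == 0 else z


def lms_percentile(model: LMSModel, age, alpha):
    """Value at the α-centile (α in (0, 1)) for the given age."""
    alpha_arr = np.atleast_1d(np.asarray(alpha, dtype=float))
    if np.any((alpha_arr <= 0) | (alpha_arr >= 1)):
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.ppf(alpha_arr)
    L, M, S = model.curves(age)
    L, M, S, z = np.broadcast_arrays(
        np.asarray(L, float), np.asarray(M, float), np.asarray(S, float), z
    )
    out = np.empty_like(z)
    small = np.abs(L) < _L_EPS
    out[small] = M[small] * np.exp(S[small] * z[small])
    base = 1.0 + L[~small] * S[~small] * z[~small]
    if np.any(base <= 0):
        warnings.warn("centile outside the Box-Cox support; returning NaN", stacklevel=2)
    with np.errstate(invalid="ignore"):
        out[~small] = M[~small] * np.where(base > 0, base, np.nan) ** (1.0 / L[~small])
    scalar = (np.isscalar(alpha) or np.asarray(alpha).ndim == 0) and (
        np.isscalar(age) or np.asarray(age).ndim == 0
    )
    return float(out.ravel()[0]) if scalar else out


def centile_table(model: LMSModel, ages, centiles=REPORT_CENTILES):
    """Centile values on an age grid, one column per centile."""
    import pandas as pd

    ages = np.asarray(ages, dtype=float)
    data = {"age": ages}
    for a in centiles:
        data[f"P{round(a * 100):02d}"] = [lms_percentile(model, g, a) for g in ages]
    return pd.DataFrame(data)
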