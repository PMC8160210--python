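"""Initial-rate rate laws and nested-model selection for PNP kinetics.

Three steady-state models cover the observed behaviour:

* Michaelis-Menten for nucleoside substrates,

      v0 = Vmax1 * c0 / (c0 + Km1)

* a two-site allosteric law for phosphate as variable substrate, in
  which occupation of one active site of a dimer changes the kinetic
  constants of its neighbour (Km2 = a*Km1, Vmax2 = b*Vmax1),

      v0 = (2 Vmax1 c0 / Km1 + 2 Vmax2 c0^2 / Km2^2)
           / (1 + 2 c0 / Km1 + c0^2 / (a Km1^2))

* competitive inhibition (formycin A vs the nucleoside substrate),

      v0 = Vmax1 * c0 / (c0 + Km1 * (1 + ci / Ki))

The allosteric law is implemented exactly in the quoted form; note its
numerator uses ``Km2**2`` while the denominator's quadratic term uses
``a * Km1**2 = Km1 * Km2``, which only agree when a = 1.  The
``eq2_variant="consistent"`` flag switches the numerator's quadratic
term to ``2 Vmax2 c0^2 / (Km1 * Km2)``, the algebraically self-consistent
two-site form.  Both variants reduce to Michaelis-Menten with doubled
Vmax when a = b = 1.

Model choice between nested fits uses the extra-sum-of-squares F test at
the 95% confidence level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, InvalidInputError

__all__ = [
    "KineticParams",
    "KineticDataset",
    "KineticFit",
    "mm_rate",
    "allosteric_rate",
    "competitive_rate",
    "fit_kinetics",
    "select_kinetic_model",
]

ModelName = Literal["mm", "allosteric", "competitive"]

_MODEL_PARAMS = {
    "mm": ("vmax1", "km1"),
    "allosteric": ("vmax1", "km1", "a", "b"),
    "competitive": ("vmax1", "km1", "ki"),
}


@dataclass
class KineticParams:
    """Rate-law parameters; units: vmax1 U/mg, km1 and ki uM, a and b
    dimensionless."""

    model: ModelName
    vmax1: float
    km1: float
    a: Optional[float] = None
    b: Optional[float] = None
    ki: Optional[float] = None
    eq2_variant: Literal["printed", "consistent"] = "printed"

    def __post_init__(self) -> None:
        if self.model not in _MODEL_PARAMS:
            raise InvalidInputError(f"unknown model {self.model!r}")
        if not (self.vmax1 > 0 and self.km1 > 0):
            raise InvalidInputError("vmax1 and km1 must be > 0")
        for name in _MODEL_PARAMS[self.model]:
            v = getattr(self, name)
            if v is None or not v > 0:
                raise InvalidInputError(
                    f"model {self.model!r} requires {name} > 0, got {v}"
                )

    def rate(self, c0, ci=0.0):
        if self.model == "mm":
            return mm_rate(self, c0)
        if self.model == "allosteric":
            return allosteric_rate(self, c0)
        return competitive_rate(self, c0, ci)


@dataclass
class KineticDataset:
    """Initial-rate measurements: substrate concentration c0 (uM), rate
    v0 (U/mg), optional inhibitor concentration ci (uM) per point."""

    c0: np.ndarray
    v0: np.ndarray
    ci: Optional[np.ndarray] = None
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.c0 = np.asarray(self.c0, dtype=float)
        self.v0 = np.asarray(self.v0, dtype=float)
        if self.c0.shape != self.v0.shape or self.c0.ndim != 1:
            raise InvalidInputError("c0 and v0 must be equal-length vectors")
        if np.any(self.c0 <= 0):
            raise InvalidInputError("c0 must be > 0")
        if np.any(self.v0 < 0):
            raise InvalidInputError("v0 must be >= 0")
        if self.ci is not None:
            self.ci = np.asarray(self.ci, dtype=float)
            if self.ci.shape != self.c0.shape or np.any(self.ci < 0):
                raise InvalidInputError("ci must match c0 and be >= 0")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.c0.shape or np.any(self.weights <= 0):
                raise InvalidInputError("weights must match c0 and be > 0")

    @property
    def n(self) -> int:
        return self.c0.size

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KineticDataset":
        ci = df["ci_uM"].to_numpy() if "ci_uM" in df.columns else None
        return cls(
            c0=df["c0_uM"].to_numpy(), v0=df["v0_U_per_mg"].to_numpy(), ci=ci
        )


@dataclass
class KineticFit:
    """Result of a nonlinear least-squares kinetic fit."""

    params: KineticParams
    sd: dict
    ssr: float
    n_obs: int
    n_params: int
    residuals: np.ndarray
    cov: np.ndarray


def mm_rate(p: KineticParams, c0) -> np.ndarray | float:
    c0 = np.asarray(c0, dtype=float)
    _check_conc(c0)
    v = p.vmax1 * c0 / (c0 + p.km1)
    return _as_input(v, c0)


def allosteric_rate(p: KineticParams, c0) -> np.ndarray | float:
    c0 = np.asarray(c0, dtype=float)
    _check_conc(c0)
    km2 = p.a * p.km1
    vmax2 = p.b * p.vmax1
    if p.eq2_variant == "printed":
        quad_num = 2.0 * vmax2 * c0**2 / km2**2
    elif p.eq2_variant == "consistent":
        quad_num = 2.0 * vmax2 * c0**2 / (p.km1 * km2)
    else:
        raise InvalidInputError(f"unknown eq2_variant {p.eq2_variant!r}")
    num = 2.0 * p.vmax1 * c0 / p.km1 + quad_num
    den = 1.0 + 2.0 * c0 / p.km1 + c0**2 / (p.a * p.km1**2)
    return _as_input(num / den, c0)


def competitive_rate(p: KineticParams, c0, ci) -> np.ndarray | float:
    c0 = np.asarray(c0, dtype=float)
    ci = np.asarray(ci, dtype=float)
    _check_conc(c0)
    if np.any(ci < 0):
        raise InvalidInputError("ci must be >= 0")
    v = p.vmax1 * c0 / (c0 + p.km1 * (1.0 + ci / p.ki))
    return _as_input(v, np.broadcast_arrays(c0, ci)[0])


def _check_conc(c0: np.ndarray) -> None:
    if np.any(c0 < 0):
        raise InvalidInputError("c0 must be >= 0")


def _as_input(v: np.ndarray, like: np.ndarray):
    return float(v) if np.ndim(like) == 0 else v


def _predict(model: ModelName, theta: np.ndarray, data: KineticDataset,
             eq2_variant: str) -> np.ndarray:
    names = _MODEL_PARAMS[model]
    # positivity via log params; clip so excursions of the optimiser
    # cannot overflow the rate laws
    kwargs = dict(zip(names, np.exp(np.clip(theta, -40.0, 40.0))))
    p = KineticParams(model=model, eq2_variant=eq2_variant, **kwargs)
    ci = data.ci if data.ci is not None else np.zeros_like(data.c0)
    return p.rate(data.c0, ci)


def fit_kinetics(
    data: KineticDataset,
    model: ModelName,
    eq2_variant: str = "printed",
    n_starts: int = 5,
    seed: int = 0,
) -> KineticFit:
    """Weighted nonlinear least squares for one rate law.

    Parameters are optimised in log space to enforce positivity.  The
    default start is Vmax = max(v0), Km = c0 at half-max, a = b = 1,
    Ki = median(positive ci); four further log-perturbed starts (seeded)
    guard against local minima.  For the competitive model a single
    (Vmax, Km, Ki) triple is shared across all inhibitor series — the
    global fit.  Standard deviations come from the Gauss-Newton
    covariance at the optimum.
    """
    names = _MODEL_PARAMS[model]
    k = len(names)
    if data.n < k + 2:
        raise InvalidInputError(
            f"need >= {k + 2} points to fit {model!r}, got {data.n}"
        )
    if model == "competitive" and data.ci is None:
        raise InvalidInputError("competitive model requires ci per point")

    w = 1.0 / data.weights if data.weights is not None else np.ones(data.n)

    start: dict[str, float] = {
        "vmax1": float(np.max(data.v0)) or 1.0,
        "km1": float(
            np.interp(0.5 * np.max(data.v0), np.sort(data.v0),
                      data.c0[np.argsort(data.v0)])
        )
        or float(np.median(data.c0)),
        "a": 1.0,
        "b": 1.0,
    }
    if data.ci is not None and np.any(data.ci > 0):
        start["ki"] = float(np.median(data.ci[data.ci > 0]))
    else:
        start["ki"] = float(np.median(data.c0))
    theta0 = np.log([max(start[n], 1e-12) for n in names])

    rng = np.random.default_rng(seed)
    starts = [theta0] + [
        theta0 + rng.normal(scale=0.5, size=k) for _ in range(n_starts - 1)
    ]
    if model == "allosteric":
        # the (a, b) surface has collapsed-b local minima; probe a grid of
        # cooperativity magnitudes deterministically
        ia = names.index("a")
        for a0 in (10.0, 100.0, 1000.0):
            t = theta0.copy()
            t[ia] = np.log(a0)
            starts.append(t)

    def resid(theta: np.ndarray) -> np.ndarray:
        return w * (data.v0 - _predict(model, theta, data, eq2_variant))

    best = None
    diag = []
    for i, t0 in enumerate(starts):
        try:
            sol = optimize.least_squares(resid, t0, method="lm", max_nfev=5000)
        except Exception as e:  # keep trying other starts
            diag.append(f"start {i}: {e}")
            continue
        diag.append(f"start {i}: cost={sol.cost:.6g} status={sol.status}")
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("all kinetic fit starts failed:\n" + "\n".join(diag))

    # short simplex polish: LM stops early in the flat (a, b) valleys of
    # the allosteric law, which would bias nested F tests
    def _ssr_of(theta: np.ndarray) -> float:
        r = resid(theta)
        return float(r @ r)

    f_best = float(2 * best.cost)
    nm = optimize.minimize(
        _ssr_of, best.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": max(1e-10 * f_best, 1e-16),
                 "maxfev": 400},
    )
    if nm.fun < f_best:
        # LM restart from the simplex point can only go further down
        sol = optimize.least_squares(resid, nm.x, method="lm", max_nfev=400)
        if 2 * sol.cost < f_best:
            best = sol

    ssr = float(2 * best.cost)
    dof = max(data.n - k, 1)
    s2 = ssr / dof
    JTJ = best.jac.T @ best.jac
    cov_log = s2 * np.linalg.pinv(JTJ)
    est = np.exp(np.clip(best.x, -40.0, 40.0))
    # delta method: sd(p) = p * sd(log p)
    sd = {n: float(est[i] * np.sqrt(cov_log[i, i])) for i, n in enumerate(names)}
    params = KineticParams(
        model=model, eq2_variant=eq2_variant, **dict(zip(names, est))
    )
    return KineticFit(
        params=params,
        sd=sd,
        ssr=ssr,
        n_obs=data.n,
        n_params=k,
        residuals=-best.fun,
        cov=cov_log,
    )


def select_kinetic_model(
    fit_simple: KineticFit, fit_complex: KineticFit, alpha: float = 0.05
) -> dict:
    """Extra-sum-of-squares F test between nested fits on the same data.

    F = [(SSR_s - SSR_c)/(k_c - k_s)] / [SSR_c/(n - k_c)]; the complex
    model is adopted only if the SSR decrease is significant at the
    given level (default 95% confidence).
    """
    if fit_simple.n_obs != fit_complex.n_obs:
        raise InvalidInputError("fits must be on the same data")
    df1 = fit_complex.n_params - fit_simple.n_params
    df2 = fit_complex.n_obs - fit_complex.n_params
    if df1 <= 0 or df2 <= 0:
        raise InvalidInputError(
            "models must be nested (k_complex > k_simple) with df > 0"
        )
    if fit_complex.ssr == 0:
        return {"F": np.inf, "p": 0.0, "choose_complex": True,
                "df1": df1, "df2": df2}
    F = ((fit_simple.ssr - fit_complex.ssr) / df1) / (fit_complex.ssr / df2)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df1, df2))
    return {"F": float(F), "p": p, "choose_complex": p < alpha,
            "df1": df1, "df2": df2}
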