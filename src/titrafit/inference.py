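"""Global multi-curve fitting and model discrimination.

A titration series (five to eight curves measured on one protein-ligand
system, possibly across modalities or instrument settings) is fitted
globally: the stepwise dissociation constants are shared by every curve
while each curve carries its own species-response coefficients.  Because
the predicted signal is *linear* in the responses, they are profiled out
exactly at every step (variable projection): the optimiser only ever
sees the 1-3 shared log10 K_d's, which makes the global fit fast and
immune to response-parameter local minima.

Model choice follows a forward ladder: start from the one-site model and
move to the next more complex model only when the Wald-Wolfowitz runs
test on the residuals signals systematic lack of fit (too few sign
runs).  Akaike weights (small-sample corrected) are computed across all
fitted models as a second, independent criterion; when the two disagree
both verdicts are reported.

Confidence intervals at the 3-sigma level (alpha = 0.0027) come from
profile likelihood; a bound that falls outside the tested ligand range
is reported *open*, censored at the nearest tested concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .binding import BindingScheme, solve_free_ligand, species_concentrations
from .errors import FitError, InvalidInputError
from .signals import ITCExperiment, TitrationCurve

__all__ = [
    "RunsTestResult",
    "FitResult",
    "ModelComparison",
    "runs_test",
    "aic_and_weights",
    "global_fit",
    "global_fit_itc",
    "profile_ci_3sigma",
    "discriminate",
]

ALPHA_3SIGMA = 0.0027  # two-sided tail mass of +-3 sigma


# --------------------------------------------------------------------------
# Wald-Wolfowitz runs test
# --------------------------------------------------------------------------

@dataclass
class RunsTestResult:
    n_pos: int
    n_neg: int
    runs_observed: int
    runs_expected: float
    variance: float
    p_two_sided: float
    p_one_sided: float  # tail in the observed direction
    direction: Literal["below", "above", "degenerate"]
    exact: bool


def _exact_runs_pmf(n1: int, n2: int) -> np.ndarray:
    """P(R = r) for r = 0..n1+n2 under random arrangement of n1 + n2 signs."""
    n = n1 + n2
    total = math.comb(n, n1)
    pmf = np.zeros(n + 1)
    for r in range(2, n + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k - 1)
        else:
            k = (r - 1) // 2
            ways = math.comb(n1 - 1, k) * math.comb(n2 - 1, k - 1) + math.comb(
                n1 - 1, k - 1
            ) * math.comb(n2 - 1, k)
        pmf[r] = ways / total
    return pmf


def runs_test(residuals: Sequence[float], drop_zeros: bool = True) -> RunsTestResult:
    """Wald-Wolfowitz runs test on the sign sequence of residuals.

    Too few runs (clustered signs) indicates systematic lack of fit; too
    many indicates anti-correlation.  Exact enumeration of the runs
    distribution is used for n1 + n2 <= 20, the normal approximation
    above.  One-sided tail probabilities carry a continuity correction
    (conservative, used for directional calls); the two-sided p uses the
    mid-p convention (the observed value counted half), which is the
    better-calibrated choice for a discrete statistic.  Residuals that
    are exactly zero are dropped (stated convention).
    """
    r = np.asarray(list(residuals), dtype=float)
    if drop_zeros:
        r = r[r != 0.0]
    if r.size < 8:
        raise InvalidInputError(
            f"runs test needs >= 8 nonzero residuals, got {r.size}"
        )
    signs = r > 0
    n1 = int(np.count_nonzero(signs))
    n2 = int(signs.size - n1)
    if n1 == 0 or n2 == 0:
        return RunsTestResult(
            n_pos=n1, n_neg=n2, runs_observed=1, runs_expected=1.0,
            variance=0.0, p_two_sided=float("nan"), p_one_sided=float("nan"),
            direction="degenerate", exact=True,
        )
    runs = int(1 + np.count_nonzero(signs[1:] != signs[:-1]))
    n = n1 + n2
    expected = 2.0 * n1 * n2 / n + 1.0
    variance = (
        2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    )
    direction = "below" if runs < expected else "above"

    if n <= 20:
        pmf = _exact_runs_pmf(n1, n2)
        p_below = float(pmf[: runs + 1].sum())
        p_above = float(pmf[runs:].sum())
        # mid-p: count the observed value half, the calibrated convention
        # for a discrete statistic
        pb_mid = float(pmf[:runs].sum() + 0.5 * pmf[runs])
        pa_mid = float(pmf[runs + 1 :].sum() + 0.5 * pmf[runs])
        exact = True
    else:
        sd = math.sqrt(variance)
        z = (runs - expected) / sd
        p_below = float(stats.norm.cdf((runs - expected + 0.5) / sd))
        p_above = float(stats.norm.sf((runs - expected - 0.5) / sd))
        pb_mid = float(stats.norm.cdf(z))
        pa_mid = float(stats.norm.sf(z))
        exact = False
    p_one = p_below if direction == "below" else p_above
    p_two = min(1.0, 2.0 * min(pb_mid, pa_mid))
    return RunsTestResult(
        n_pos=n1, n_neg=n2, runs_observed=runs, runs_expected=expected,
        variance=variance, p_two_sided=p_two, p_one_sided=p_one,
        direction=direction, exact=exact,
    )


# --------------------------------------------------------------------------
# Fit result containers
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a global binding fit.

    ``params`` maps names to estimates: ``log10_kd1`` ... plus per-curve
    responses ``r{curve}_{species}`` (and ITC enthalpies/dilution heats
    for calorimetric fits).  ``ci3`` holds per-K_d 3-sigma intervals on
    the concentration scale as ``(lo, hi, lo_open, hi_open)``.
    """

    model_label: str
    n_sites: int
    params: dict
    sd: dict
    ci3: dict
    ssr: float
    n_obs: int
    n_params: int
    residuals: list
    aic: float
    aicc: float
    runs: dict
    identifiable: bool
    scheme: BindingScheme
    converged: bool = True
    # retained so profiling can re-optimise; not part of the reported state
    _data: object = field(default=None, repr=False)
    _weights: object = field(default=None, repr=False)
    _modality_tag: str = field(default="optical", repr=False)

    @property
    def kd(self) -> tuple[float, ...]:
        return self.scheme.kd

    def kd_sd(self) -> dict:
        """SDs of the K_d's on the concentration scale (delta method
        from the log10 parameterisation)."""
        out = {}
        ln10 = math.log(10.0)
        for i in range(1, self.n_sites + 1):
            kd = 10.0 ** self.params[f"log10_kd{i}"]
            out[f"kd{i}"] = kd * ln10 * self.sd[f"log10_kd{i}"]
        return out


@dataclass
class ModelComparison:
    fits: list
    table: pd.DataFrame
    ladder_choice: int
    aic_choice: int
    final_choice: int
    conflict: bool
    ladder_trace: list


def _ls_aic(ssr: float, n: int, k_model: int) -> tuple[float, float]:
    """Least-squares AIC and AICc; K counts model parameters plus the
    error variance."""
    K = k_model + 1
    ssr = max(ssr, 1e-300)
    aic = n * math.log(ssr / n) + 2 * K
    denom = n - K - 1
    aicc = aic + (2 * K * (K + 1) / denom if denom > 0 else float("inf"))
    return aic, aicc


def aic_and_weights(
    fits: Sequence[FitResult], variant: Literal["aicc", "aic"] = "aicc"
) -> pd.DataFrame:
    """Akaike criterion table with evidence weights.

    All fits must be on the same observations.  Weights are
    ``exp(-delta_i/2)`` normalised to sum to one.
    """
    ns = {f.n_obs for f in fits}
    if len(ns) != 1:
        raise InvalidInputError(
            f"fits are on different data (n_obs = {sorted(ns)})"
        )
    vals = np.array([f.aicc if variant == "aicc" else f.aic for f in fits])
    delta = vals - vals.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    return pd.DataFrame(
        {
            "model": [f.model_label for f in fits],
            variant: vals,
            "delta": delta,
            "weight": w,
        }
    ).set_index("model")


# --------------------------------------------------------------------------
# Global fit of optical / MST titration curves (variable projection)
# --------------------------------------------------------------------------

_SPECIES_NAMES = ("P", "PL", "PLL", "PLLL")


def _design_matrix(
    curve: TitrationCurve, scheme: BindingScheme
) -> np.ndarray:
    """Species design matrix: concentrations for optical modalities,
    fractions for MST (labelled protein fixed)."""
    L = solve_free_ligand(scheme, curve.p_total, curve.l_total)
    conc = species_concentrations(scheme, curve.p_total, L)
    X = conc[:, : scheme.n_steps + 1]
    if curve.modality == "mst":
        X = X / curve.p_total
    return X


def _design_matrices(
    curves: Sequence[TitrationCurve], scheme: BindingScheme
) -> list:
    """Design matrices for all curves, batching the mass-balance solves
    of curves that share a protein concentration into one vectorised
    call."""
    groups: dict[float, list[int]] = {}
    for i, c in enumerate(curves):
        groups.setdefault(c.p_total, []).append(i)
    out: list = [None] * len(curves)
    for p_total, idx in groups.items():
        l_cat = np.concatenate([curves[i].l_total for i in idx])
        L = solve_free_ligand(scheme, p_total, l_cat)
        conc = species_concentrations(scheme, p_total, L)
        off = 0
        for i in idx:
            n = curves[i].n_points
            X = conc[off : off + n, : scheme.n_steps + 1]
            if curves[i].modality == "mst":
                X = X / p_total
            out[i] = X
            off += n
    return out


def _theta_to_scheme(theta: np.ndarray) -> BindingScheme:
    """theta = (log10 kd1, log10 kd2/kd1, log10 kd3/kd2), increments >= 0."""
    log_kd = np.cumsum(theta)
    return BindingScheme(kd=tuple(10.0 ** log_kd))


def _polish_theta(resid, theta: np.ndarray, n_sites: int) -> np.ndarray:
    """Nelder-Mead polish of the projected objective.

    Gauss-Newton steps crawl along the curved K_d valleys these
    objectives have; a short simplex descent from the best least-squares
    point reliably reaches the valley floor.  The K_d ordering is kept
    by optimising |increment|, smooth at any interior optimum."""

    def fold(t: np.ndarray) -> np.ndarray:
        out = t.copy()
        if n_sites > 1:
            out[1:] = np.abs(out[1:])
        return out

    def obj(t: np.ndarray) -> float:
        r = resid(fold(t))
        return float(r @ r)

    r0 = resid(theta)
    f0 = float(r0 @ r0)
    sol = optimize.minimize(
        obj, theta, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": max(1e-9 * f0, 1e-16),
                 "maxiter": 500, "maxfev": 700},
    )
    cand = fold(sol.x)
    return cand if sol.fun < f0 else theta


def _projected_residuals(
    theta: np.ndarray,
    curves: Sequence[TitrationCurve],
    weights: Sequence[np.ndarray],
) -> tuple[np.ndarray, list]:
    scheme = _theta_to_scheme(theta)
    res = []
    coefs = []
    designs = _design_matrices(curves, scheme)
    for curve, w, X in zip(curves, weights, designs):
        Xw = X * w[:, None]
        yw = curve.signal * w
        c, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        coefs.append(c)
        res.append(yw - Xw @ c)
    return np.concatenate(res), coefs


def _default_starts(
    curves: Sequence[TitrationCurve], n_sites: int, n_starts: int, seed: int
) -> list:
    """Deterministic quantile-based start plus seeded log-perturbed ones,
    spanning the tested ligand range."""
    l_all = np.concatenate([c.l_total for c in curves])
    l_pos = l_all[l_all > 0]
    lo, hi = math.log10(l_pos.min()), math.log10(l_pos.max())
    qs = np.linspace(lo + 0.15 * (hi - lo), hi - 0.15 * (hi - lo), n_sites)
    base = np.concatenate([[qs[0]], np.diff(qs)]) if n_sites > 1 else qs[:1]
    starts = [base]
    rng = np.random.default_rng(seed)
    for _ in range(n_starts - 1):
        t = base.copy()
        t[0] += rng.normal(scale=0.8)
        if n_sites > 1:
            t[1:] = np.abs(t[1:] * rng.lognormal(sigma=0.5, size=n_sites - 1))
        starts.append(t)
    return starts


def _wald_ci3(
    log_kd: np.ndarray, sd_log_kd: np.ndarray, l_min: float, l_max: float
) -> dict:
    ci3 = {}
    for i, (m, s) in enumerate(zip(log_kd, sd_log_kd), start=1):
        lo = 10.0 ** (m - 3 * s) if np.isfinite(s) else 0.0
        hi = 10.0 ** (m + 3 * s) if np.isfinite(s) else float("inf")
        lo_open = lo < l_min
        hi_open = hi > l_max
        ci3[f"kd{i}"] = (
            max(lo, l_min) if lo_open else lo,
            min(hi, l_max) if hi_open else hi,
            lo_open,
            hi_open,
        )
    return ci3


def _finite_diff_jac(fun, x0: np.ndarray, f0: np.ndarray, rel: float = 1e-6):
    J = np.empty((f0.size, x0.size))
    for j in range(x0.size):
        h = rel * max(abs(x0[j]), 1e-3)
        xp = x0.copy()
        xp[j] += h
        xm = x0.copy()
        xm[j] -= h
        J[:, j] = (fun(xp) - fun(xm)) / (2 * h)
    return J


def _covariance_report(resid_full, phi_hat, n_obs, n_sites, y_norm=None):
    """Gauss-Newton covariance of (theta, linear coefs) at the optimum,
    with identifiability screening of near-null directions.

    Columns of the Jacobian are normalised before the eigen screen so
    that parameters of wildly different natural scales (log10 K_d vs
    kcal-scale dilution heats) do not masquerade as degeneracies.  A
    column is *dead* (parameter absent from the observable, e.g. the
    gauge degeneracy of an all-flat curve) when its norm vanishes both
    relative to the other columns and relative to the scale of the
    observations themselves."""
    f0 = resid_full(phi_hat)
    J = _finite_diff_jac(resid_full, phi_hat, f0)
    k = phi_hat.size
    dof = max(n_obs - k, 1)
    s2 = float(f0 @ f0) / dof
    col_norm = np.linalg.norm(J, axis=0)
    # the data-scale floor sits above finite-difference rounding noise
    # (~eps * |y| / h) yet orders of magnitude below any column that
    # actually moves the prediction
    floor = col_norm.max() * 1e-14
    if y_norm is not None:
        floor = max(floor, 1e-9 * y_norm)
    dead = col_norm <= floor
    scale = np.where(dead, 1.0, col_norm)
    Jn = J / scale
    JTJ = Jn.T @ Jn
    evals, evecs = np.linalg.eigh(JTJ)
    tol = max(evals.max(), 1e-300) * 1e-12
    identifiable = bool(evals.min() > tol) and not dead.any()
    inv_evals = np.where(evals > tol, 1.0 / np.maximum(evals, 1e-300), 0.0)
    cov_n = (evecs * inv_evals) @ evecs.T
    cov = s2 * cov_n / np.outer(scale, scale)
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if not identifiable:
        null_mask = dead.copy()
        if evals.min() <= tol:
            null_mask |= (np.abs(evecs[:, evals <= tol]) > 1e-6).any(axis=1)
        sd = np.where(null_mask, np.inf, sd)
    return cov, sd, identifiable


def global_fit(
    curves: Sequence[TitrationCurve],
    n_sites: int,
    seed: int = 0,
    n_starts: int = 10,
    theta0: Optional[np.ndarray] = None,
) -> FitResult:
    """Global weighted least-squares fit of a sequential binding model.

    The log10 K_d's are shared across curves (with the ordering
    K_d1 <= K_d2 <= K_d3 enforced by an increment parameterisation to
    remove label switching); per-curve responses are profiled out
    exactly.  The instrumental offset of each curve is absorbed into the
    free-protein response — for a fixed-protein titration the two are
    not separately identifiable.  Deterministic given ``seed``.
    """
    if n_sites not in (1, 2, 3):
        raise InvalidInputError("n_sites must be 1, 2 or 3")
    curves = list(curves)
    if not curves:
        raise InvalidInputError("no curves supplied")
    weights = [
        1.0 / c.weights if c.weights is not None else np.ones(c.n_points)
        for c in curves
    ]
    n_obs = sum(c.n_points for c in curves)
    n_lin = len(curves) * (n_sites + 1)
    n_params = n_sites + n_lin
    if n_obs <= n_params:
        raise InvalidInputError(
            f"{n_obs} observations cannot constrain {n_params} parameters"
        )

    def resid(theta: np.ndarray) -> np.ndarray:
        return _projected_residuals(theta, curves, weights)[0]

    lb = np.full(n_sites, -np.inf)
    ub = np.full(n_sites, np.inf)
    if n_sites > 1:
        lb[1:] = 0.0  # increments: enforce kd ordering

    starts = (
        [np.asarray(theta0, dtype=float)]
        if theta0 is not None
        else _default_starts(curves, n_sites, n_starts, seed)
    )
    best = None
    diag = []
    n_at_best = 0
    for i, t0 in enumerate(starts):
        t0 = np.clip(t0, lb + 1e-12, None)
        try:
            sol = optimize.least_squares(
                resid, t0, bounds=(lb, ub), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=400,
            )
        except Exception as e:
            diag.append(f"start {i}: {e}")
            continue
        diag.append(f"start {i}: cost={sol.cost:.8g} status={sol.status}")
        if sol.status > 0:
            if best is None or sol.cost < best.cost * (1 - 1e-9):
                best = sol
                n_at_best = 1
            elif sol.cost <= best.cost * (1 + 1e-6):
                n_at_best += 1
        # two independent starts agreeing on the optimum is strong
        # evidence against a missed basin; stop probing
        if n_at_best >= 2 and i >= 2:
            break
    if best is None:
        raise FitError(
            "global fit failed from every start:\n" + "\n".join(diag)
        )

    theta_hat = _polish_theta(resid, best.x, n_sites)
    scheme = _theta_to_scheme(theta_hat)
    resid_hat, coefs = _projected_residuals(theta_hat, curves, weights)
    ssr = float(resid_hat @ resid_hat)

    # full-parameter covariance in the direct (log10 kd, responses) basis
    def resid_full(phi: np.ndarray) -> np.ndarray:
        log_kd = phi[:n_sites]
        sch = BindingScheme(kd=tuple(10.0 ** np.sort(log_kd)))
        out = []
        pos = n_sites
        designs = _design_matrices(curves, sch)
        for curve, w, X in zip(curves, weights, designs):
            c = phi[pos : pos + n_sites + 1]
            pos += n_sites + 1
            out.append(w * (curve.signal - X @ c))
        return np.concatenate(out)

    phi_hat = np.concatenate([np.cumsum(theta_hat)] + coefs)
    y_norm = float(np.linalg.norm(
        np.concatenate([c.signal * w for c, w in zip(curves, weights)])
    ))
    cov, sd_all, identifiable = _covariance_report(
        resid_full, phi_hat, n_obs, n_sites, y_norm=y_norm
    )

    aic, aicc = _ls_aic(ssr, n_obs, n_params)

    params: dict = {}
    sd: dict = {}
    log_kd = np.cumsum(theta_hat)
    for i in range(n_sites):
        params[f"log10_kd{i+1}"] = float(log_kd[i])
        sd[f"log10_kd{i+1}"] = float(sd_all[i])
    pos = n_sites
    for ci_, c in enumerate(coefs):
        for s_i, v in enumerate(c):
            params[f"r{ci_}_{_SPECIES_NAMES[s_i]}"] = float(v)
            sd[f"r{ci_}_{_SPECIES_NAMES[s_i]}"] = float(sd_all[pos])
            pos += 1

    l_all = np.concatenate([c.l_total for c in curves])
    l_pos = l_all[l_all > 0]
    ci3 = _wald_ci3(
        log_kd, sd_all[:n_sites], float(l_pos.min()), float(l_pos.max())
    )

    res_list = []
    offset = 0
    resid_vec = resid_hat
    for c in curves:
        res_list.append(resid_vec[offset : offset + c.n_points])
        offset += c.n_points
    runs = {
        i: _safe_runs(r) for i, r in enumerate(res_list)
    }
    runs["pooled"] = _safe_runs(resid_vec)

    return FitResult(
        model_label=f"{n_sites}-site",
        n_sites=n_sites,
        params=params,
        sd=sd,
        ci3=ci3,
        ssr=ssr,
        n_obs=n_obs,
        n_params=n_params,
        residuals=res_list,
        aic=aic,
        aicc=aicc,
        runs=runs,
        identifiable=identifiable,
        scheme=scheme,
        _data=curves,
        _weights=weights,
        _modality_tag="optical",
    )


def _safe_runs(residuals: np.ndarray):
    try:
        return runs_test(residuals)
    except InvalidInputError:
        return None


# --------------------------------------------------------------------------
# Global fit of ITC injection series
# --------------------------------------------------------------------------

from .signals import cell_trajectory, itc_step_design as _itc_design


def global_fit_itc(
    experiments: Sequence[ITCExperiment],
    heats: Sequence[np.ndarray],
    n_sites: int,
    seed: int = 0,
    n_starts: int = 10,
    theta0: Optional[np.ndarray] = None,
    weights: Optional[Sequence[np.ndarray]] = None,
) -> FitResult:
    """Global fit of per-injection heats across calorimetric experiments.

    The K_d's and per-step enthalpies are shared across experiments;
    each experiment carries its own constant dilution heat.  Enthalpies
    and dilution heats enter linearly and are profiled out exactly, so
    the optimiser again sees only the log10 K_d's.
    """
    if n_sites not in (1, 2, 3):
        raise InvalidInputError("n_sites must be 1, 2 or 3")
    experiments = list(experiments)
    heats = [np.asarray(h, dtype=float) for h in heats]
    if len(experiments) != len(heats) or not experiments:
        raise InvalidInputError("need one heat series per experiment")
    for e, h in zip(experiments, heats):
        if h.size != e.n_injections:
            raise InvalidInputError("heat series length != injection count")
    if weights is None:
        w_list = [np.ones(h.size) for h in heats]
    else:
        w_list = [1.0 / np.asarray(w, dtype=float) for w in weights]
    n_obs = sum(h.size for h in heats)
    n_exp = len(experiments)
    n_lin = n_sites + n_exp  # shared dH + per-experiment q_dilution
    n_params = n_sites + n_lin

    # cell trajectories depend only on geometry: precompute once and
    # batch the speciation solves of all experiments per evaluation
    trajs = [cell_trajectory(e) for e in experiments]
    p_cat = np.concatenate([t[0] for t in trajs])
    l_cat = np.concatenate([t[1] for t in trajs])

    def A_of_scheme(scheme: BindingScheme) -> np.ndarray:
        L = solve_free_ligand(scheme, p_cat, l_cat)
        conc = species_concentrations(scheme, p_cat, L)
        B_all = np.cumsum(conc[:, 1 : n_sites + 1][:, ::-1], axis=1)[:, ::-1]
        rows = []
        off = 0
        for j, (e, (p, l, f)) in enumerate(zip(experiments, trajs)):
            n = p.size
            B = B_all[off : off + n]
            off += n
            B_prev = np.vstack([np.zeros(n_sites), B[:-1]])
            block = np.zeros((n, n_lin))
            block[:, :n_sites] = e.cell_volume * (B - f[:, None] * B_prev) * 1e-12
            block[:, n_sites + j] = 1.0
            rows.append(block)
        return np.vstack(rows)

    def build(theta: np.ndarray):
        return A_of_scheme(_theta_to_scheme(theta))

    y = np.concatenate(heats)
    w = np.concatenate(w_list)
    # heats are O(1e-7) kcal; rescale so the optimiser's relative
    # tolerances act on O(1) residuals
    y_scale = float(np.abs(y * w).max()) or 1.0

    def resid(theta: np.ndarray) -> np.ndarray:
        A = build(theta) * w[:, None]
        c, *_ = np.linalg.lstsq(A, y * w, rcond=None)
        return (y * w - A @ c) / y_scale

    lb = np.full(n_sites, -np.inf)
    ub = np.full(n_sites, np.inf)
    if n_sites > 1:
        lb[1:] = 0.0

    if theta0 is not None:
        starts = [np.asarray(theta0, dtype=float)]
    else:
        # span the ligand range the cells actually explore
        lo = math.log10(max(l_cat.min(), 1e-9))
        hi = math.log10(l_cat.max()) + 0.5
        qs = np.linspace(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo), n_sites)
        base = np.concatenate([[qs[0]], np.diff(qs)]) if n_sites > 1 else qs[:1]
        rng = np.random.default_rng(seed)
        starts = [base] + [
            base + np.concatenate([[rng.normal(scale=0.8)],
                                   np.abs(rng.normal(scale=0.5, size=n_sites - 1))])
            for _ in range(n_starts - 1)
        ]

    best, diag = None, []
    n_at_best = 0
    for i, t0 in enumerate(starts):
        t0 = np.clip(t0, lb + 1e-12, None)
        try:
            sol = optimize.least_squares(
                resid, t0, bounds=(lb, ub), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=250,
            )
        except Exception as e:
            diag.append(f"start {i}: {e}")
            continue
        diag.append(f"start {i}: cost={sol.cost:.8g} status={sol.status}")
        if sol.status >= 0:
            if best is None or sol.cost < best.cost * (1 - 1e-9) - 1e-300:
                best = sol
                n_at_best = 1
            elif sol.cost <= best.cost * (1 + 1e-6):
                n_at_best += 1
        if n_at_best >= 2 and i >= 2:
            break
    if best is None:
        raise FitError("ITC global fit failed:\n" + "\n".join(diag))

    theta_hat = _polish_theta(resid, best.x, n_sites)
    scheme = _theta_to_scheme(theta_hat)
    A = build(theta_hat) * w[:, None]
    coef, *_ = np.linalg.lstsq(A, y * w, rcond=None)

    def resid_full(phi: np.ndarray) -> np.ndarray:
        sch = BindingScheme(kd=tuple(10.0 ** np.sort(phi[:n_sites])))
        return w * (y - A_of_scheme(sch) @ phi[n_sites:])

    phi_hat = np.concatenate([np.cumsum(theta_hat), coef])
    cov, sd_all, identifiable = _covariance_report(
        resid_full, phi_hat, n_obs, n_sites,
        y_norm=float(np.linalg.norm(y * w)),
    )
    r_hat = resid(theta_hat)
    ssr = float(r_hat @ r_hat) * y_scale**2
    aic, aicc = _ls_aic(ssr, n_obs, n_params)

    params: dict = {}
    sd: dict = {}
    log_kd = np.cumsum(theta_hat)
    for i in range(n_sites):
        params[f"log10_kd{i+1}"] = float(log_kd[i])
        sd[f"log10_kd{i+1}"] = float(sd_all[i])
    for i in range(n_sites):
        params[f"dH{i+1}"] = float(coef[i])
        sd[f"dH{i+1}"] = float(sd_all[n_sites + i])
    for j in range(n_exp):
        params[f"q_dil{j}"] = float(coef[n_sites + j])
        sd[f"q_dil{j}"] = float(sd_all[2 * n_sites + j])

    # ligand range actually explored in the cells
    l_ranges = [cell_trajectory(e)[1] for e in experiments]
    l_min = min(float(l[0]) for l in l_ranges)
    l_max = max(float(l[-1]) for l in l_ranges)
    ci3 = _wald_ci3(log_kd, sd_all[:n_sites], l_min, l_max)

    resid_vec = resid(theta_hat)
    res_list = []
    off = 0
    for h in heats:
        res_list.append(resid_vec[off : off + h.size])
        off += h.size
    runs = {i: _safe_runs(r) for i, r in enumerate(res_list)}
    runs["pooled"] = _safe_runs(resid_vec)

    return FitResult(
        model_label=f"{n_sites}-site",
        n_sites=n_sites,
        params=params,
        sd=sd,
        ci3=ci3,
        ssr=ssr,
        n_obs=n_obs,
        n_params=n_params,
        residuals=res_list,
        aic=aic,
        aicc=aicc,
        runs=runs,
        identifiable=identifiable,
        scheme=scheme,
        _data=(experiments, heats, w_list),
        _modality_tag="itc",
    )


# --------------------------------------------------------------------------
# Profile-likelihood 3-sigma intervals
# --------------------------------------------------------------------------

def _ssr_with_fixed_kd(
    fit: FitResult, which: int, log_kd_fixed: float
) -> float:
    """Minimum SSR with log10 K_d(which) clamped, all other parameters
    (remaining K_d's via re-optimisation, responses via projection)
    free."""
    n_sites = fit.n_sites
    free_idx = [i for i in range(n_sites) if i != which]
    log_kd_hat = [fit.params[f"log10_kd{i+1}"] for i in range(n_sites)]

    if fit._modality_tag == "itc":
        experiments, heats, w_list = fit._data
        y = np.concatenate(heats)
        w = np.concatenate(w_list)
        n_exp = len(experiments)
        n_lin = n_sites + n_exp

        def ssr_of(free_vals: np.ndarray) -> float:
            log_kd = np.empty(n_sites)
            log_kd[which] = log_kd_fixed
            log_kd[free_idx] = free_vals
            sch = BindingScheme(kd=tuple(10.0 ** np.sort(log_kd)))
            rows = []
            for j, e in enumerate(experiments):
                D = _itc_design(e, sch)
                block = np.zeros((D.shape[0], n_lin))
                block[:, :n_sites] = D
                block[:, n_sites + j] = 1.0
                rows.append(block)
            A = np.vstack(rows) * w[:, None]
            c, *_ = np.linalg.lstsq(A, y * w, rcond=None)
            r = y * w - A @ c
            return float(r @ r)

    else:
        curves, weights = fit._data, fit._weights

        def ssr_of(free_vals: np.ndarray) -> float:
            log_kd = np.empty(n_sites)
            log_kd[which] = log_kd_fixed
            log_kd[free_idx] = free_vals
            sch = BindingScheme(kd=tuple(10.0 ** np.sort(log_kd)))
            r, _ = _projected_residuals(
                np.concatenate([[math.log10(sch.kd[0])],
                                np.diff(np.log10(sch.kd))])
                if n_sites > 1 else np.asarray([math.log10(sch.kd[0])]),
                curves, weights,
            )
            return float(r @ r)

    if not free_idx:
        return ssr_of(np.empty(0))
    x0 = np.asarray([log_kd_hat[i] for i in free_idx])
    sol = optimize.minimize(
        ssr_of, x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400},
    )
    return float(min(sol.fun, ssr_of(x0)))


def profile_ci_3sigma(
    fit: FitResult,
    param: str,
    step_log10: float = 0.08,
    max_decades: float = 6.0,
) -> tuple[float, float, bool, bool]:
    """Profile-likelihood interval at the 3-sigma level for one K_d.

    The target log10 K_d is stepped outward from the estimate on a log
    grid, re-optimising every other parameter at each step; the interval
    boundary is where the SSR crosses
    ``SSR_min * (1 + F(alpha*; 1, n-k) / (n-k))`` with alpha* = 0.0027.
    A crossing that falls outside the tested ligand range is reported
    open, censored at the nearest tested concentration.  Returns
    ``(lo, hi, lo_open, hi_open)`` on the concentration scale (uM).
    """
    if not param.startswith("kd"):
        raise InvalidInputError("param must be 'kd1', 'kd2' or 'kd3'")
    which = int(param[2:]) - 1
    if which not in range(fit.n_sites):
        raise InvalidInputError(f"{param} not in a {fit.n_sites}-site fit")
    n, k = fit.n_obs, fit.n_params
    if n - k <= 0:
        raise InvalidInputError("no residual degrees of freedom")
    f_crit = stats.f.isf(ALPHA_3SIGMA, 1, n - k)
    thr = fit.ssr * (1.0 + f_crit / (n - k))
    mle = fit.params[f"log10_kd{which+1}"]

    # censoring values: the tested ligand range
    l_min = l_max = None
    if fit._modality_tag == "optical":
        l_all = np.concatenate([c.l_total for c in fit._data])
        l_pos = l_all[l_all > 0]
        l_min, l_max = math.log10(l_pos.min()), math.log10(l_pos.max())
    elif fit._modality_tag == "itc":
        trajs = [cell_trajectory(e)[1] for e in fit._data[0]]
        l_min = math.log10(min(float(t[0]) for t in trajs))
        l_max = math.log10(max(float(t[-1]) for t in trajs))

    def walk(direction: int) -> tuple[float, bool]:
        prev_ssr = fit.ssr
        prev_x = mle
        n_steps = int(max_decades / step_log10)
        for s in range(1, n_steps + 1):
            x = mle + direction * s * step_log10
            ssr = _ssr_with_fixed_kd(fit, which, x)
            if ssr >= thr:
                # linear interpolation of the crossing in log10 space
                frac = (thr - prev_ssr) / max(ssr - prev_ssr, 1e-300)
                x_cross = prev_x + (x - prev_x) * frac
                bound = 10.0 ** x_cross
                if direction < 0 and l_min is not None and x_cross < l_min:
                    return 10.0 ** l_min, True
                if direction > 0 and l_max is not None and x_cross > l_max:
                    return 10.0 ** l_max, True
                return bound, False
            prev_ssr, prev_x = ssr, x
        # never crossed: flat likelihood -> open at the censoring value
        cens = l_min if direction < 0 else l_max
        if cens is not None:
            return 10.0 ** cens, True
        return 10.0 ** prev_x, True

    lo, lo_open = walk(-1)
    hi, hi_open = walk(+1)
    return lo, hi, lo_open, hi_open


# --------------------------------------------------------------------------
# Discrimination ladder
# --------------------------------------------------------------------------

def discriminate(
    curves: Sequence[TitrationCurve],
    max_sites: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
    aic_variant: Literal["aicc", "aic"] = "aicc",
) -> ModelComparison:
    """Forward model ladder with runs-test escalation and Akaike check.

    Fits the one-site model first; moves to the next more complex model
    only when the pooled residual runs test shows significantly *fewer*
    runs than expected (two-sided p < alpha with the count below
    expectation) — the signature of systematic misfit.  Complex fits are
    warm-started from the simpler fit's constants so nested SSRs are
    monotone.  AICc weights over all fitted models provide the second
    verdict; disagreements are reported, with the ladder verdict kept as
    the headline call and the Akaike winner flagged.
    """
    fits: list[FitResult] = []
    trace = []
    chosen = None
    for n_sites in range(1, max_sites + 1):
        if fits:
            prev = fits[-1]
            prev_log = [prev.params[f"log10_kd{i+1}"] for i in range(prev.n_sites)]
            # warm start: append a new weakest site one decade up
            new_log = prev_log + [prev_log[-1] + 1.0]
            t0 = np.concatenate([[new_log[0]], np.diff(new_log)])
            fit = global_fit(curves, n_sites, seed=seed, theta0=t0)
            if fit.ssr > prev.ssr * (1 + 1e-6):
                # warm start failed to do at least as well as the nested
                # simpler model: fall back to the full multistart
                cold = global_fit(curves, n_sites, seed=seed)
                if cold.ssr < fit.ssr:
                    fit = cold
        else:
            fit = global_fit(curves, n_sites, seed=seed)
        fits.append(fit)
        rt = fit.runs["pooled"]
        reject = (
            rt is not None
            and rt.direction == "below"
            and rt.p_two_sided < alpha
        )
        trace.append(
            {
                "n_sites": n_sites,
                "ssr": fit.ssr,
                "runs_p": None if rt is None else rt.p_two_sided,
                "runs_direction": None if rt is None else rt.direction,
                "escalate": bool(reject),
            }
        )
        if not reject:
            chosen = n_sites
            break
        chosen = n_sites  # provisional: ladder exhausted
    table = aic_and_weights(fits, variant=aic_variant)
    aic_choice = fits[int(np.argmax(table["weight"].to_numpy()))].n_sites
    conflict = aic_choice != chosen
    return ModelComparison(
        fits=fits,
        table=table,
        ladder_choice=chosen,
        aic_choice=aic_choice,
        final_choice=chosen,
        conflict=conflict,
        ladder_trace=trace,
    )
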