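"""Observation models mapping speciation to measured titration signals.

Each modality reports a linear combination of species concentrations:

* fluorescence / CD — molar responses, signal per uM of species, times
  the species concentration, plus an instrumental offset;
* MST — the labelled-protein concentration is fixed, so normalised
  thermophoresis responds to species *fractions* rather than
  concentrations;
* ITC — per-injection heats from the change in ligand bound at each
  step, with the standard perfusion-cell displacement bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .binding import (
    MAX_STEPS,
    BindingScheme,
    solve_free_ligand,
    species_concentrations,
)
from .errors import InvalidInputError

__all__ = [
    "TitrationCurve",
    "ResponseSet",
    "ITCExperiment",
    "optical_signal",
    "mst_signal",
    "itc_injection_heats",
]

MODALITIES = ("fluorescence", "cd", "mst", "itc")


@dataclass
class TitrationCurve:
    """One measured or simulated titration series.

    ``l_total`` must be non-decreasing and the curve must have at least
    4 points.  ``p_total`` is on the binding-unit basis (uM).
    ``weights`` are per-point standard deviations (same units as
    ``signal``); None means unweighted.
    """

    modality: str
    l_total: np.ndarray  # uM, non-decreasing
    signal: np.ndarray
    p_total: float
    metadata: dict = field(default_factory=dict)
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise InvalidInputError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        self.l_total = np.asarray(self.l_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.l_total.shape != self.signal.shape:
            raise InvalidInputError("l_total and signal must have equal length")
        if self.l_total.size < 4:
            raise InvalidInputError("a titration curve needs >= 4 points")
        if np.any(np.diff(self.l_total) < 0):
            raise InvalidInputError("l_total must be non-decreasing")
        if np.any(self.l_total < 0):
            raise InvalidInputError("l_total must be >= 0")
        if not self.p_total > 0:
            raise InvalidInputError("p_total must be > 0")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.signal.shape:
                raise InvalidInputError("weights must match signal length")
            if np.any(self.weights <= 0):
                raise InvalidInputError("weights (per-point sigma) must be > 0")

    @property
    def n_points(self) -> int:
        return self.l_total.size


@dataclass
class ResponseSet:
    """Per-curve species response coefficients.

    ``r`` holds one coefficient per species P, PL, PLL, PLLL (signal
    units per uM of species for optical modalities; signal units per
    unit species *fraction* for MST).  Coefficients beyond the scheme's
    step count are ignored.  ``offset`` is an additive instrumental
    baseline; note that for a fixed-protein titration the species
    concentrations sum to ``p_total``, so a constant offset is not
    separately identifiable from a common shift of all ``r`` (the gauge
    freedom handled in :mod:`titrafit.inference`).
    """

    r: np.ndarray
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 1 or self.r.size > MAX_STEPS:
            raise InvalidInputError(
                f"r must be a vector of <= {MAX_STEPS} coefficients"
            )
        if not np.all(np.isfinite(self.r)) or not np.isfinite(self.offset):
            raise InvalidInputError("responses must be finite")

    def padded(self) -> np.ndarray:
        out = np.zeros(MAX_STEPS)
        out[: self.r.size] = self.r
        return out


@dataclass
class ITCExperiment:
    """Geometry and thermodynamics of one calorimetric titration.

    ``dH`` holds the molar enthalpy of each binding step (kcal/mol of
    step-i complex formed); ``q_dilution`` is a constant per-injection
    blank heat (kcal).  ``cell_protein`` is on the binding-unit basis.
    """

    cell_volume: float  # uL
    injection_volumes: np.ndarray  # uL
    syringe_ligand: float  # uM
    cell_protein: float  # uM, binding units
    dH: np.ndarray  # kcal/mol per step
    q_dilution: float = 0.0  # kcal per injection

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        self.dH = np.asarray(self.dH, dtype=float)
        if self.cell_volume <= 0 or np.any(self.injection_volumes <= 0):
            raise InvalidInputError("volumes must be > 0")
        if np.any(self.injection_volumes >= self.cell_volume):
            raise InvalidInputError(
                "injection volume must be smaller than the cell volume"
            )
        if self.syringe_ligand < 0 or self.cell_protein < 0:
            raise InvalidInputError("concentrations must be >= 0")

    @property
    def n_injections(self) -> int:
        return self.injection_volumes.size


def optical_signal(
    scheme: BindingScheme,
    responses: ResponseSet,
    p_total: float,
    l_totals: np.ndarray,
) -> np.ndarray:
    """Predicted optical signal: ``offset + sum_s r_s * [species_s]``.

    Used for fluorescence and CD alike; the curve shape carries the
    imprint of every binding step whose response differs from its
    neighbours', which is why curves with mixed-sign responses can show
    more than one extremum.
    """
    l_totals = np.asarray(l_totals, dtype=float)
    L = solve_free_ligand(scheme, p_total, l_totals)
    conc = species_concentrations(scheme, p_total, L)
    return responses.offset + conc @ responses.padded()


def mst_signal(
    scheme: BindingScheme,
    responses: ResponseSet,
    p_total: float,
    l_totals: np.ndarray,
) -> np.ndarray:
    """Predicted normalised thermophoresis: responses weight species
    *fractions* (the labelled-protein concentration is constant across
    the titration, so only the distribution over states matters)."""
    l_totals = np.asarray(l_totals, dtype=float)
    L = solve_free_ligand(scheme, p_total, l_totals)
    frac = species_concentrations(scheme, p_total, L) / p_total
    return responses.offset + frac @ responses.padded()


def cell_trajectory(
    exp: ITCExperiment, displacement_correction: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-injection cell composition of a perfusion calorimeter.

    For injection n of volume v_n into a cell of active volume V0, a
    fraction ``f_n = 1 - v_n/V0`` of the prior contents is retained (the
    overflow leaves the active volume) and syringe ligand is added.
    Returns ``(p, l, f)``: protein and total-ligand concentrations (uM)
    after each injection, and the retained fractions.  These depend only
    on the geometry, never on the binding scheme.
    """
    V0 = exp.cell_volume
    n_inj = exp.n_injections
    p = np.empty(n_inj)
    l = np.empty(n_inj)
    f = (
        1.0 - exp.injection_volumes / V0
        if displacement_correction
        else np.ones(n_inj)
    )
    p_cur, l_cur = exp.cell_protein, 0.0
    for n, v in enumerate(exp.injection_volumes):
        p_cur = p_cur * f[n]
        l_cur = l_cur * f[n] + exp.syringe_ligand * v / V0
        p[n], l[n] = p_cur, l_cur
    return p, l, f


def itc_step_design(
    exp: ITCExperiment,
    scheme: BindingScheme,
    displacement_correction: bool = True,
) -> np.ndarray:
    """Per-injection, per-step heat design matrix D (kcal per kcal/mol).

    ``D[n, i-1] = V0 * ([B_i]_n - f_n [B_i]_{n-1}) * 1e-12`` where
    ``[B_i] = [PL_>=i]`` is the concentration of ligand bound at step i,
    so that predicted heats are ``D @ dH + q_dilution`` — linear in the
    enthalpies, which the global ITC fit exploits.
    """
    p, l, f = cell_trajectory(exp, displacement_correction)
    L = solve_free_ligand(scheme, p, l)
    conc = species_concentrations(scheme, p, L)
    n = scheme.n_steps
    # [B_i] = reverse cumulative sum over ligation states
    B = np.cumsum(conc[:, 1 : n + 1][:, ::-1], axis=1)[:, ::-1]
    B_prev = np.vstack([np.zeros(n), B[:-1]])
    return exp.cell_volume * (B - f[:, None] * B_prev) * 1e-12


def itc_injection_heats(
    exp: ITCExperiment,
    scheme: BindingScheme,
    displacement_correction: bool = True,
) -> np.ndarray:
    """Per-injection heats (kcal) for a sequential-binding scheme.

    ``q_n = V0 * sum_i dH_i * ([B_i]_n - f_n [B_i]_{n-1}) + q_dilution``
    with the perfusion-displacement bookkeeping of
    :func:`cell_trajectory`.  With ``displacement_correction=False`` the
    retained fraction is 1 and the heats telescope exactly to the total
    binding enthalpy.
    """
    if scheme.n_steps != exp.dH.size:
        raise InvalidInputError(
            f"dH has {exp.dH.size} entries but the scheme has "
            f"{scheme.n_steps} steps"
        )
    D = itc_step_design(exp, scheme, displacement_correction)
    return D @ exp.dH + exp.q_dilution
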