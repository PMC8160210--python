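"""Exact equilibrium speciation for sequential ligand-binding schemes.

A protein P (expressed on a *binding-unit* basis, see :func:`binding_units`)
binds up to three ligand molecules L in consecutive steps::

    P   + L  <=>  PL      K_d1
    PL  + L  <=>  PLL     K_d2
    PLL + L  <=>  PLLL    K_d3

where ``K_di`` are stepwise *macroscopic* dissociation constants (uM).
The partition function over ligation states (the binding polynomial) is

    Q(L) = 1 + sum_i beta_i L**i,    beta_i = prod_{j<=i} 1/K_dj,

and species fractions are its individual terms divided by ``Q``.  Because
protein and ligand concentrations are comparable in the regimes of
interest (uM protein, uM-range K_d1), free ligand is obtained by solving
the full ligand mass balance rather than assuming free == total
(ligand-depletion regime).

All concentrations are in uM internally; unit conversion happens at the
I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, InvalidInputError, UnidentifiableError

MAX_STEPS = 4  # species vector is padded to P, PL, PLL, PLLL

__all__ = [
    "BindingScheme",
    "SpeciesState",
    "binding_polynomial",
    "solve_speciation",
    "statistical_scheme",
    "saturation_fraction",
    "binding_units",
]


@dataclass(frozen=True)
class BindingScheme:
    """A 1-, 2- or 3-step sequential binding model.

    Parameters
    ----------
    kd
        Ordered stepwise macroscopic dissociation constants
        ``(K_d1, ..., K_dn)`` in uM.  All must be strictly positive.
    """

    kd: tuple[float, ...]

    def __post_init__(self) -> None:
        kd = tuple(float(k) for k in self.kd)
        if len(kd) not in (1, 2, 3):
            raise InvalidInputError(
                f"scheme must have 1-3 steps, got {len(kd)}"
            )
        if any(not np.isfinite(k) or k <= 0 for k in kd):
            raise InvalidInputError(f"all K_d must be finite and > 0, got {kd}")
        object.__setattr__(self, "kd", kd)

    @property
    def n_steps(self) -> int:
        return len(self.kd)

    @property
    def beta(self) -> np.ndarray:
        """Cumulative association constants ``beta_i = prod_j 1/K_dj``
        for i = 1..n (uM**-i)."""
        return np.cumprod(1.0 / np.asarray(self.kd))


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium composition at a single titration point.

    ``species`` holds concentrations of P, PL, PLL, PLLL (uM); entries
    beyond the scheme's step count are zero.
    """

    free_ligand: float
    species: np.ndarray  # length MAX_STEPS, uM
    p_total: float
    l_total: float

    @property
    def bound_ligand(self) -> float:
        """Total ligand sequestered in complexes, ``sum_i i*[PL_i]`` (uM)."""
        return float(np.dot(np.arange(MAX_STEPS), self.species))


def binding_polynomial(
    scheme: BindingScheme, free_ligand: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the binding polynomial and its bound-ligand moment.

    Returns ``(Q, bound_moment)`` with ``Q = 1 + sum beta_i L**i`` and
    ``bound_moment = sum i * beta_i L**i`` so that the average number of
    ligands bound per binding unit is ``bound_moment / Q``.

    Accepts a scalar or array of free-ligand concentrations (uM).
    """
    L = np.asarray(free_ligand, dtype=float)
    if np.any(L < 0):
        raise InvalidInputError("free_ligand must be >= 0")
    beta = scheme.beta
    powers = np.arange(1, scheme.n_steps + 1)
    # terms[i-1] = beta_i * L**i, broadcast over L
    terms = beta * L[..., None] ** powers
    Q = 1.0 + terms.sum(axis=-1)
    bound_moment = (powers * terms).sum(axis=-1)
    if np.isscalar(free_ligand) or np.ndim(free_ligand) == 0:
        return float(Q), float(bound_moment)
    return Q, bound_moment


def _free_ligand_array(
    scheme: BindingScheme,
    p_total: float | np.ndarray,
    l_total: np.ndarray,
    rtol: float = 1e-14,
    max_iter: int = 200,
) -> np.ndarray:
    """Vectorised bracketed solve of the ligand mass balance.

    The residual g(L) = L + p_total * BM(L)/Q(L) - l_total is strictly
    increasing in L (BM/Q is the mean ligation number, itself
    non-decreasing), with g(0) <= 0 and g(l_total) >= 0, so bisection on
    [0, l_total] is globally convergent.  Bisection halves the bracket
    each step; max_iter = 200 takes the interval far below any float64
    relative tolerance.
    """
    lo = np.zeros_like(l_total)
    hi = l_total.copy()
    beta = scheme.beta
    powers = np.arange(1, scheme.n_steps + 1)

    def g(L: np.ndarray) -> np.ndarray:
        terms = beta * L[..., None] ** powers
        Q = 1.0 + terms.sum(axis=-1)
        bm = (powers * terms).sum(axis=-1)
        return L + p_total * bm / Q - l_total

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        hi = np.where(gm >= 0, mid, hi)
        lo = np.where(gm < 0, mid, lo)
        # interval below both absolute floor and relative tolerance
        if np.all(hi - lo <= rtol * np.maximum(hi, 1e-300)):
            break
    L = 0.5 * (lo + hi)
    resid = np.abs(g(L))
    scale = np.maximum(l_total, 1.0)
    if np.any(resid > 1e-9 * scale):
        worst = int(np.argmax(resid / scale))
        raise ConvergenceError(
            "ligand mass-balance solve did not converge: "
            f"residual {resid[worst]:.3e} at l_total={l_total[worst]:.6g} uM, "
            f"p_total={np.max(p_total):.6g} uM, kd={scheme.kd}"
        )
    return L


def solve_free_ligand(
    scheme: BindingScheme, p_total: float | np.ndarray, l_total: np.ndarray
) -> np.ndarray:
    """Free-ligand concentrations for an array of total-ligand values (uM).

    Vectorised workhorse used by the signal models; :func:`solve_speciation`
    wraps it for a single point with full species bookkeeping.
    ``p_total`` may be a scalar or an array broadcastable against
    ``l_total`` (e.g. the per-injection protein trajectory of a
    perfusion ITC cell).
    """
    l_total = np.asarray(l_total, dtype=float)
    p_total = np.asarray(p_total, dtype=float)
    if np.any(p_total < 0) or np.any(l_total < 0):
        raise InvalidInputError("p_total and l_total must be >= 0")
    if np.all(p_total == 0):
        return l_total.copy()
    return _free_ligand_array(scheme, p_total, l_total)


def species_concentrations(
    scheme: BindingScheme, p_total: float | np.ndarray, free_ligand: np.ndarray
) -> np.ndarray:
    """Concentrations of P, PL, PLL, PLLL (uM) given free ligand.

    Returns an array of shape ``free_ligand.shape + (MAX_STEPS,)``.
    """
    L = np.asarray(free_ligand, dtype=float)
    p = np.broadcast_to(np.asarray(p_total, dtype=float), L.shape)
    beta = scheme.beta
    powers = np.arange(1, scheme.n_steps + 1)
    terms = beta * L[..., None] ** powers
    Q = 1.0 + terms.sum(axis=-1)
    out = np.zeros(L.shape + (MAX_STEPS,))
    out[..., 0] = p / Q
    out[..., 1 : scheme.n_steps + 1] = p[..., None] * terms / Q[..., None]
    return out


def solve_speciation(
    scheme: BindingScheme, p_total: float, l_total: float
) -> SpeciesState:
    """Solve the coupled mass balances at one titration point.

    Finds the unique free-ligand root of
    ``L + p_total * BM(L)/Q(L) = l_total`` on ``[0, l_total]`` and returns
    the full species breakdown.  Raises :class:`ConvergenceError` (never
    silently) if the bracketed solve fails.
    """
    if p_total < 0 or l_total < 0:
        raise InvalidInputError("p_total and l_total must be >= 0")
    L = float(solve_free_ligand(scheme, p_total, np.asarray([l_total]))[0])
    species = species_concentrations(scheme, p_total, np.asarray(L))
    return SpeciesState(
        free_ligand=L,
        species=species,
        p_total=float(p_total),
        l_total=float(l_total),
    )


def statistical_scheme(n_sites: int, k_micro: float) -> BindingScheme:
    """Stepwise constants for ``n`` identical, independent sites.

    Site counting alone fixes the ratios between consecutive stepwise
    macroscopic constants: ``K_di = k_micro * i / (n - i + 1)``.  For two
    sites this gives ``K_d2 = 4 K_d1``; for three sites
    ``K_d2 = 3 K_d1`` and ``K_d3 = 9 K_d1``.  Deviations from these
    ratios in fitted constants are the operational signature of site
    non-equivalence or cooperativity.
    """
    if n_sites not in (1, 2, 3):
        raise InvalidInputError(f"n_sites must be in {{1,2,3}}, got {n_sites}")
    if not (np.isfinite(k_micro) and k_micro > 0):
        raise InvalidInputError("k_micro must be finite and > 0")
    kd = tuple(
        k_micro * i / (n_sites - i + 1) for i in range(1, n_sites + 1)
    )
    return BindingScheme(kd=kd)


def saturation_fraction(scheme: BindingScheme, state: SpeciesState) -> float:
    """Fraction of binding sites occupied, in [0, 1].

    Defined as ``sum_i i*[PL_i] / (n_steps * p_total)``.  Undefined at
    zero protein (raises :class:`UnidentifiableError`).
    """
    if state.p_total == 0:
        raise UnidentifiableError(
            "saturation fraction is undefined at p_total = 0"
        )
    return state.bound_ligand / (scheme.n_steps * state.p_total)


def binding_units(monomer_uM: float, units_per_site_group: float = 2.0) -> float:
    """Convert a monomer concentration to the binding-unit basis.

    The hexamer carries non-equivalent site classes; the schemes here
    count one site per step on a *binding unit* of
    ``units_per_site_group`` monomers.  The default of 2 corresponds to
    one site per dimer (the dimer-level bookkeeping used for both the
    2-site model on a dimer and the 3-site model on a hexamer of three
    dimers).  The divisor is deliberately configurable because the
    monomer-to-site-group conversion is a modelling choice, not a
    measured quantity; changing it rescales fitted responses but not the
    dissociation constants.
    """
    if monomer_uM < 0:
        raise InvalidInputError("monomer concentration must be >= 0")
    if units_per_site_group <= 0:
        raise InvalidInputError("units_per_site_group must be > 0")
    return monomer_uM / units_per_site_group
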