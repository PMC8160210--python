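"""Pre-fit signal corrections for raw titration data.

Fluorimetric titrations of the tryptophan-bearing mutant drift slowly in
time (photo-quenching that the ligand itself suppresses) and are quenched
at high ionic strength; near-UV CD spectra are smoothed and cross-sected
at the wavelengths of largest change; MST titrations over very wide
ligand ranges are recorded in two overlapping concentration ranges that
must be stitched.  Everything here is deterministic arithmetic on the
observed series — no model fitting beyond ordinary least squares.

Correction order matters: the time drift is additive on the raw signal
while the ionic-strength quench is multiplicative, so drift correction
must be applied to both the titration and the quench-reference series
*before* dividing one by the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

from .errors import ExtrapolationError, InvalidInputError, UnidentifiableError
from .signals import TitrationCurve

__all__ = [
    "DriftRecord",
    "IonicStrengthModel",
    "Spectrum",
    "StitchReport",
    "fit_drift_slopes",
    "drift_correct",
    "phosphate_ionic_strength",
    "ionic_strength_correct",
    "sg_smooth",
    "differential_and_select",
    "stitch_ranges",
]


@dataclass
class DriftRecord:
    """Per-titration-point linear drift slopes.

    ``slopes[m]`` is the fitted signal change per inter-point interval at
    titration point m; ``interval`` is the time between consecutive
    titration points in minutes (1 min in the reference protocol).
    """

    slopes: np.ndarray  # signal units per interval
    interval: float = 1.0  # min

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        if not np.all(np.isfinite(self.slopes)):
            raise InvalidInputError("drift slopes must be finite")
        if self.interval <= 0:
            raise InvalidInputError("interval must be > 0")


@dataclass
class IonicStrengthModel:
    """Reference fluorescence-vs-ionic-strength curve from a NaCl titration.

    ``normalization_I`` (mM) is the ionic strength at which the
    interpolated reference is scaled to 1, so that the titration point
    measured at that ionic strength is left untouched by the correction.
    """

    I_mM: np.ndarray
    F: np.ndarray
    normalization_I: float | None = None

    def __post_init__(self) -> None:
        self.I_mM = np.asarray(self.I_mM, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.I_mM.ndim != 1 or self.I_mM.size < 2:
            raise InvalidInputError("reference needs >= 2 points")
        if np.any(np.diff(self.I_mM) <= 0):
            raise InvalidInputError("reference I must be strictly increasing")
        if np.any(self.F <= 0):
            raise InvalidInputError("reference F must be > 0")

    def interpolator(self) -> PchipInterpolator:
        # monotone piecewise cubic: no overshoot between reference points
        return PchipInterpolator(self.I_mM, self.F, extrapolate=False)


@dataclass
class Spectrum:
    """A spectrum on a uniform, strictly increasing wavelength grid."""

    wavelength_nm: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.wavelength_nm.shape != self.value.shape:
            raise InvalidInputError("grid and values must have equal length")
        steps = np.diff(self.wavelength_nm)
        if self.wavelength_nm.size < 2 or np.any(steps <= 0):
            raise InvalidInputError("wavelength grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise InvalidInputError("wavelength grid must be uniform")

    @property
    def step(self) -> float:
        return float(self.wavelength_nm[1] - self.wavelength_nm[0])


@dataclass
class StitchReport:
    scale: float
    offset: float
    rms_mismatch: float
    n_overlap: int


def fit_drift_slopes(
    time_series: Sequence[np.ndarray], interval: float = 1.0
) -> DriftRecord:
    """OLS slope of signal vs time at each titration point.

    ``time_series[m]`` is an (n_samples, 2) array of (t_min, F) pairs
    recorded while sitting at titration point m.  Slopes are rescaled
    from per-minute to per-interval units.
    """
    slopes = []
    for m, ts in enumerate(time_series):
        ts = np.asarray(ts, dtype=float)
        if ts.ndim != 2 or ts.shape[1] != 2 or ts.shape[0] < 2:
            raise InvalidInputError(
                f"point {m}: need >= 2 (t, F) samples for a linear fit"
            )
        slope_per_min = np.polyfit(ts[:, 0], ts[:, 1], 1)[0]
        slopes.append(slope_per_min * interval)
    return DriftRecord(slopes=np.asarray(slopes), interval=interval)


def drift_correct(
    F: np.ndarray, drift: DriftRecord, sign: int = +1
) -> np.ndarray:
    """Undo accumulated linear time drift: ``F_n + sign * sum_{m<=n} a_m``.

    The default ``sign=+1`` applies the correction exactly as the
    additive-slope bookkeeping is written; because quenching slopes are
    negative, subtracting the accumulated loss (restoring the signal)
    corresponds to ``sign=-1`` when slopes are recorded as raw decay
    rates.  The choice is a stated convention, pinned per dataset by the
    round-trip identity with the simulator.
    """
    F = np.asarray(F, dtype=float)
    if sign not in (+1, -1):
        raise InvalidInputError("sign must be +1 or -1")
    if F.size != drift.slopes.size:
        raise InvalidInputError(
            f"signal has {F.size} points but drift record has "
            f"{drift.slopes.size} slopes"
        )
    return F + sign * np.cumsum(drift.slopes)


def phosphate_ionic_strength(
    c_phosphate_mM: float | np.ndarray,
    pH: float,
    pKa: float = 7.2,
    background_I_mM: float = 0.0,
) -> float | np.ndarray:
    """Ionic strength (mM) contributed by a phosphate buffer at given pH.

    Around neutral pH phosphate partitions between the mono- (charge -1)
    and di-anion (charge -2); the dibasic fraction is
    ``f2 = 1 / (1 + 10**(pKa - pH))``.  With monovalent counterions at
    electroneutrality, ``I = 1/2 sum c_i z_i**2`` reduces to

        I = c * (1 + 2*f2)

    which is linear in the phosphate concentration at fixed pH.
    ``background_I_mM`` (e.g. a Tris buffer's constant contribution) is
    simply added.
    """
    c = np.asarray(c_phosphate_mM, dtype=float)
    if np.any(c < 0):
        raise InvalidInputError("phosphate concentration must be >= 0")
    f2 = 1.0 / (1.0 + 10.0 ** (pKa - pH))
    I = c * (1.0 + 2.0 * f2) + background_I_mM
    if np.ndim(c_phosphate_mM) == 0:
        return float(I)
    return I


def ionic_strength_correct(
    F_obs: np.ndarray,
    model: IonicStrengthModel,
    I_of_point: np.ndarray,
) -> np.ndarray:
    """Divide out the ionic-strength quench: ``F_bind = F_obs / F_hat(I)``.

    The reference curve is interpolated with a monotone piecewise cubic
    and normalised to 1 at ``model.normalization_I`` (default: the ionic
    strength of the first titration point), so the first point is
    correction-neutral.  Points outside the measured reference range
    raise :class:`ExtrapolationError`.
    """
    F_obs = np.asarray(F_obs, dtype=float)
    I = np.asarray(I_of_point, dtype=float)
    if F_obs.shape != I.shape:
        raise InvalidInputError("F_obs and I_of_point must have equal length")
    norm_I = model.normalization_I if model.normalization_I is not None else I[0]
    lo, hi = model.I_mM[0], model.I_mM[-1]
    out_of_range = (I < lo) | (I > hi)
    if norm_I < lo or norm_I > hi or np.any(out_of_range):
        bad = I[out_of_range] if np.any(out_of_range) else np.asarray([norm_I])
        raise ExtrapolationError(
            f"ionic strength {bad[:3]} mM outside reference range "
            f"[{lo}, {hi}] mM; refusing to extrapolate"
        )
    f = model.interpolator()
    F_hat = f(I) / f(norm_I)
    return F_obs / F_hat


def sg_smooth(spec: Spectrum, poly_order: int = 4, window: int = 11) -> Spectrum:
    """Savitzky-Golay smoothing (local polynomial least squares).

    Defaults follow the near-UV CD protocol: 4th-degree polynomial,
    11-point window.  Endpoints are handled by polynomial fits on
    one-sided windows (scipy's ``mode='interp'``).  Polynomials of
    degree <= ``poly_order`` pass through unchanged.
    """
    if window % 2 == 0 or window <= poly_order:
        raise InvalidInputError("window must be odd and > poly_order")
    if spec.value.size < window:
        raise InvalidInputError(
            f"spectrum has {spec.value.size} points, shorter than the "
            f"{window}-point window"
        )
    smoothed = savgol_filter(
        spec.value, window_length=window, polyorder=poly_order, mode="interp"
    )
    return Spectrum(wavelength_nm=spec.wavelength_nm.copy(), value=smoothed)


def differential_and_select(
    spec_complex: Spectrum,
    spec_apo: Spectrum,
    k: int,
    min_spacing_nm: float | None = None,
) -> tuple[Spectrum, np.ndarray]:
    """Difference spectrum and the k wavelengths of largest |change|.

    Cross-secting titration spectra at these wavelengths yields the
    titration curves with the best signal-to-noise.  Selected
    wavelengths are local maxima of |diff| kept at least one smoothing
    window (default 11 grid steps) apart so near-duplicate picks on the
    same band are suppressed.
    """
    if not np.array_equal(spec_complex.wavelength_nm, spec_apo.wavelength_nm):
        raise InvalidInputError("spectra must share an identical grid")
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    diff = spec_complex.value - spec_apo.value
    diff_spec = Spectrum(
        wavelength_nm=spec_complex.wavelength_nm.copy(), value=diff
    )
    if not np.any(np.abs(diff) > 0):
        raise UnidentifiableError(
            "difference spectrum is identically zero; no wavelength carries "
            "a binding signal"
        )
    if min_spacing_nm is None:
        min_spacing_nm = 11 * diff_spec.step
    order = np.argsort(np.abs(diff))[::-1]
    picks: list[int] = []
    wl = spec_complex.wavelength_nm
    for idx in order:
        if len(picks) == k:
            break
        if all(abs(wl[idx] - wl[p]) >= min_spacing_nm for p in picks):
            picks.append(int(idx))
    return diff_spec, wl[np.asarray(picks, dtype=int)]


def stitch_ranges(
    curve_low: TitrationCurve,
    curve_high: TitrationCurve,
    n_overlap_min: int = 3,
    rtol: float = 1e-6,
) -> tuple[TitrationCurve, StitchReport]:
    """Merge two concentration ranges of one titration into a single curve.

    The high-range curve is mapped onto the low-range signal scale by a
    least-squares affine transform (scale + offset) estimated on the
    shared ligand concentrations; affine rather than scale-only because
    instrument baselines differ between runs.  Overlap points are
    averaged after alignment, the union sorted by ligand concentration.
    """
    if curve_low.modality != curve_high.modality:
        raise InvalidInputError("cannot stitch curves of different modalities")
    lo_l, hi_l = curve_low.l_total, curve_high.l_total
    # match overlapping ligand concentrations within relative tolerance
    pairs = [
        (i, j)
        for i, li in enumerate(lo_l)
        for j, lj in enumerate(hi_l)
        if abs(li - lj) <= rtol * max(li, lj, 1e-12)
    ]
    if len(pairs) < n_overlap_min:
        raise InvalidInputError(
            f"only {len(pairs)} overlapping points; >= {n_overlap_min} required"
        )
    ii = np.asarray([p[0] for p in pairs])
    jj = np.asarray([p[1] for p in pairs])
    y_lo = curve_low.signal[ii]
    y_hi = curve_high.signal[jj]
    A = np.column_stack([y_hi, np.ones_like(y_hi)])
    (scale, offset), *_ = np.linalg.lstsq(A, y_lo, rcond=None)
    aligned_hi = scale * curve_high.signal + offset
    rms = float(np.sqrt(np.mean((scale * y_hi + offset - y_lo) ** 2)))

    l_all = np.concatenate([lo_l, hi_l])
    s_all = np.concatenate([curve_low.signal, aligned_hi])
    order = np.argsort(l_all, kind="stable")
    l_sorted, s_sorted = l_all[order], s_all[order]
    # average duplicates (the aligned overlap points)
    l_out: list[float] = []
    s_out: list[float] = []
    for l, s in zip(l_sorted, s_sorted):
        if l_out and abs(l - l_out[-1]) <= rtol * max(l, l_out[-1], 1e-12):
            s_out[-1] = 0.5 * (s_out[-1] + s)
        else:
            l_out.append(float(l))
            s_out.append(float(s))
    merged = TitrationCurve(
        modality=curve_low.modality,
        l_total=np.asarray(l_out),
        signal=np.asarray(s_out),
        p_total=curve_low.p_total,
        metadata={**curve_low.metadata, "stitched": True},
    )
    report = StitchReport(
        scale=float(scale),
        offset=float(offset),
        rms_mismatch=rms,
        n_overlap=len(pairs),
    )
    return merged, report
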