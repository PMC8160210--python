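"""CSV readers/writers, configuration schema and report rendering.

The single tabular dialect is RFC-4180 CSV, UTF-8, dot decimal.  Units
and curve-level metadata travel in ``#``-prefixed header comment lines,
e.g. ``# units: uM``.  Internal concentration unit is uM throughout;
conversion happens here and only here.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .errors import InvalidInputError, SchemaError
from .inference import FitResult, ModelComparison
from .signals import MODALITIES, TitrationCurve

__all__ = [
    "AnalysisConfig",
    "read_titration_csv",
    "write_titration_csv",
    "read_itc_csv",
    "read_kinetics_csv",
    "write_report",
    "format_interval",
    "assembly_mass_kda",
    "file_sha256",
]

_UNIT_TO_UM = {"uM": 1.0, "nM": 1e-3, "mM": 1e3, "M": 1e6}


class AnalysisConfig(BaseModel):
    """Validated analysis options; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    modality: str = "fluorescence"
    units: str = "uM"
    units_per_site_group: float = 2.0
    n_sites: int = 3
    max_sites: int = 3
    seed: int = 0
    aic_variant: str = "aicc"
    eq2_variant: str = "printed"
    drift_sign: int = 1
    apply_drift_correction: bool = True
    apply_ionic_correction: bool = True
    report_format: str = "text"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load and validate a YAML configuration file; unknown keys are
        rejected by the schema."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        return cls(**data)


def _parse_header_comments(path: Path) -> dict:
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
    return meta


def _read_table(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except Exception as e:
        raise SchemaError(f"{path}: cannot parse CSV ({e})") from e


def read_titration_csv(
    path: str | Path,
    modality: Optional[str] = None,
    p_total: Optional[float] = None,
) -> TitrationCurve:
    """Read one titration curve.

    Required columns: ``l_total_uM`` (or ``l_total`` with a
    ``# units: <u>`` header line) and ``signal``.  ``p_total`` and
    ``modality`` may come from header comments (``# p_total_uM: 0.5``,
    ``# modality: fluorescence``) or be passed explicitly (arguments
    win).  Malformed rows are reported with their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    meta = _parse_header_comments(path)
    df = _read_table(path)
    unit = meta.get("units", "uM")
    if unit not in _UNIT_TO_UM:
        raise SchemaError(f"{path}: unknown unit {unit!r}")
    lcol = "l_total_uM" if "l_total_uM" in df.columns else "l_total"
    if lcol not in df.columns or "signal" not in df.columns:
        raise SchemaError(
            f"{path}: required columns l_total_uM (or l_total) and signal; "
            f"found {list(df.columns)}"
        )
    scale = 1.0 if lcol == "l_total_uM" else _UNIT_TO_UM[unit]
    l_total = df[lcol].to_numpy(dtype=float) * scale
    signal = df["signal"].to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(l_total) | (l_total < 0))[0]
    if bad.size:
        # +2: one for the header row, one for 1-based numbering
        n_comments = sum(
            1 for line in open(path, encoding="utf-8") if line.startswith("#")
        )
        rows = [int(b) + n_comments + 2 for b in bad[:5]]
        raise SchemaError(
            f"{path}: negative or non-finite l_total at line(s) {rows}"
        )
    if np.any(np.diff(l_total) < 0):
        raise SchemaError(f"{path}: l_total must be non-decreasing")
    modality = modality or meta.get("modality")
    if modality not in MODALITIES:
        raise SchemaError(
            f"{path}: modality {modality!r} missing or invalid; pass one of "
            f"{MODALITIES}"
        )
    if p_total is None:
        if "p_total_uM" not in meta:
            raise SchemaError(
                f"{path}: p_total not given (argument or '# p_total_uM:' "
                "header line)"
            )
        p_total = float(meta["p_total_uM"])
    return TitrationCurve(
        modality=modality, l_total=l_total, signal=signal,
        p_total=float(p_total), metadata=dict(meta),
    )


def write_titration_csv(curve: TitrationCurve, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# units: uM\n")
        fh.write(f"# modality: {curve.modality}\n")
        fh.write(f"# p_total_uM: {curve.p_total!r}\n")
        pd.DataFrame(
            {"l_total_uM": curve.l_total, "signal": curve.signal}
        ).to_csv(fh, index=False)


def read_itc_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read per-injection volumes (uL) and heats (kcal).

    Columns: ``injection_index``, ``injection_volume_uL`` and either
    ``heat_kcal`` or ``heat_ucal``.
    """
    path = Path(path)
    df = _read_table(path)
    need = {"injection_index", "injection_volume_uL"}
    if not need.issubset(df.columns):
        raise SchemaError(f"{path}: required columns {sorted(need)}")
    if "heat_kcal" in df.columns:
        heats = df["heat_kcal"].to_numpy(dtype=float)
    elif "heat_ucal" in df.columns:
        heats = df["heat_ucal"].to_numpy(dtype=float) * 1e-9
    else:
        raise SchemaError(f"{path}: need a heat_kcal or heat_ucal column")
    return df["injection_volume_uL"].to_numpy(dtype=float), heats


def read_kinetics_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_table(path)
    if "c0_uM" not in df.columns or "v0_U_per_mg" not in df.columns:
        raise SchemaError(
            f"{path}: required columns c0_uM, v0_U_per_mg (optional ci_uM)"
        )
    return df


def format_interval(
    lo: float, hi: float, lo_open: bool, hi_open: bool, unit: str = "uM"
) -> str:
    """Render a confidence interval, marking open bounds with '<'/'>'.

    A lower bound below the smallest tested ligand concentration is not
    experimentally constrained; it is rendered as e.g. ``(< 0.07–2.12) uM``
    with the censoring concentration after the '<'.
    """
    lo_s = f"< {lo:.3g}" if lo_open else f"{lo:.3g}"
    hi_s = f"> {hi:.3g}" if hi_open else f"{hi:.3g}"
    return f"({lo_s}–{hi_s}) {unit}"


def _fit_block(fit: FitResult) -> list[str]:
    lines = [f"model: {fit.model_label}   SSR = {fit.ssr:.6g}   "
             f"AICc = {fit.aicc:.4f}   n = {fit.n_obs}"]
    kd_sd = fit.kd_sd()
    for i in range(1, fit.n_sites + 1):
        kd = 10.0 ** fit.params[f"log10_kd{i}"]
        sd = kd_sd[f"kd{i}"]
        lo, hi, lo_o, hi_o = fit.ci3[f"kd{i}"]
        lines.append(
            f"  K_d{i} = ({kd:.3g} ± {sd:.2g}) uM   "
            f"3σ CI {format_interval(lo, hi, lo_o, hi_o)}"
        )
    rt = fit.runs.get("pooled")
    if rt is not None:
        lines.append(
            f"  runs test: R = {rt.runs_observed} (expected "
            f"{rt.runs_expected:.1f}), p = {rt.p_two_sided:.3g}, "
            f"{rt.direction} expected"
        )
    if not fit.identifiable:
        lines.append("  WARNING: fit is not identifiable (flat directions)")
    return lines


def write_report(
    results: Sequence[FitResult] | ModelComparison,
    path_text: Optional[str | Path] = None,
    path_json: Optional[str | Path] = None,
) -> str:
    """Human-readable fit report plus a JSON twin for machines."""
    if isinstance(results, ModelComparison):
        fits = results.fits
        extra = [
            "",
            f"ladder choice: {results.ladder_choice}-site   "
            f"Akaike choice: {results.aic_choice}-site"
            + ("   (criteria disagree)" if results.conflict else ""),
            results.table.to_string(),
        ]
    else:
        fits = list(results)
        extra = []
    lines: list[str] = []
    for f in fits:
        lines.extend(_fit_block(f))
        lines.append("")
    lines.extend(extra)
    text = "\n".join(lines).rstrip() + "\n" if (lines or extra) else ""

    payload = []
    for f in fits:
        kd_sd = f.kd_sd()
        payload.append(
            {
                "model": f.model_label,
                "n_sites": f.n_sites,
                "ssr": f.ssr,
                "aic": f.aic,
                "aicc": f.aicc,
                "n_obs": f.n_obs,
                "identifiable": f.identifiable,
                "kd_uM": {
                    f"kd{i}": 10.0 ** f.params[f"log10_kd{i}"]
                    for i in range(1, f.n_sites + 1)
                },
                "kd_sd_uM": kd_sd,
                "ci3_uM": {
                    k: {"lo": v[0], "hi": v[1], "lo_open": v[2],
                        "hi_open": v[3]}
                    for k, v in f.ci3.items()
                },
            }
        )
    if path_text is not None:
        Path(path_text).write_text(text, encoding="utf-8")
    if path_json is not None:
        Path(path_json).write_text(
            json.dumps(payload, indent=2, default=_jsonify), encoding="utf-8"
        )
    return text


def _jsonify(obj):
    """Coerce numpy scalars to built-ins for the JSON twin."""
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def assembly_mass_kda(monomer_kda: float, n_subunits: int) -> float:
    """Molecular mass of an oligomeric assembly, rounded to 0.1 kDa for
    display (e.g. six 25.970 kDa monomers -> 155.8 kDa)."""
    if n_subunits < 1:
        raise InvalidInputError("n_subunits must be >= 1")
    if monomer_kda <= 0:
        raise InvalidInputError("monomer mass must be > 0")
    return round(monomer_kda * n_subunits, 1)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
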