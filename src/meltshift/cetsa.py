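"""CETSA densitometry analysis: apparent melting curves, Tm50, in-situ dTm.

A cellular thermal shift assay heats intact cells across a temperature
gradient, immunoblots the remaining soluble target and quantifies band
intensity by densitometry.  Plotting relative band intensity against
temperature gives the apparent melting curve; Tm50 is the temperature at
which 50% of the protein is denatured.  Ligand binding shifts Tm50 upward
(stabilization) or downward, and the treated-minus-vehicle difference is
the in-situ melting-point shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .curves import FitSettings, MeltingCurve, fit_unfolding

__all__ = [
    "DensitometryCurve",
    "normalize_bands",
    "apparent_tm50",
    "cetsa_delta_tm",
    "analyze_cetsa_table",
    "Tm50Undefined",
]


class Tm50Undefined(ValueError):
    """The series never crosses 50% relative intensity."""


@dataclass(frozen=True)
class DensitometryCurve:
    """Band intensities versus temperature for one target in one condition."""

    target_name: str
    condition: str  # treated | vehicle
    temperatures: np.ndarray
    intensities: np.ndarray
    replicate: int = 1

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "intensities", y)
        if len(t) < 4:
            raise ValueError("a densitometry series needs at least 4 temperatures")
        if len(t) != len(y):
            raise ValueError("temperatures and intensities must have equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("band intensities must be >= 0")


def normalize_bands(curve: DensitometryCurve) -> np.ndarray:
    """Relative band intensities: each band divided by the lowest-temperature
    band.  Raises if the reference band is zero."""
    ref = curve.intensities[0]
    if ref <= 0:
        raise ValueError(
            f"reference band at {curve.temperatures[0]} degC is zero; cannot normalize"
        )
    return curve.intensities / ref


def _interpolate_tm50(temps: np.ndarray, rel: np.ndarray) -> float:
    """Linear interpolation at the first adjacent pair bracketing 0.5."""
    for i in range(len(temps) - 1):
        y0, y1 = rel[i], rel[i + 1]
        if (y0 - 0.5) == 0.0:
            return float(temps[i])
        if (y0 - 0.5) * (y1 - 0.5) < 0 or y1 == 0.5:
            frac = (y0 - 0.5) / (y0 - y1)
            return float(temps[i] + frac * (temps[i + 1] - temps[i]))
    raise Tm50Undefined("no_crossing")


def apparent_tm50(curve: DensitometryCurve, method: str = "auto") -> float:
    """Apparent melting point (Tm50) of one densitometry series.

    method="fit" fits the three-parameter unfolding model and returns its
    melting point (needs >= 5 points); method="interpolate" linearly
    interpolates between the first adjacent pair of points bracketing 0.5
    relative intensity; "auto" fits when >= 5 points are available, else
    interpolates.  Raises :class:`Tm50Undefined` (reason "no_crossing")
    when the series never reaches 50%.
    """
    rel = normalize_bands(curve)
    temps = curve.temperatures
    if method == "auto":
        method = "fit" if len(temps) >= 5 else "interpolate"
    if method == "interpolate":
        return _interpolate_tm50(temps, rel)
    if method != "fit":
        raise ValueError(f"unknown Tm50 method {method!r}")
    points = pd.DataFrame(
        {"temperature_c": temps, "relative_abundance": rel, "replicate": curve.replicate}
    )
    mc = MeltingCurve(curve.target_name, curve.condition, points, float(temps[0]))
    fit = fit_unfolding(mc, FitSettings(min_points=5))
    if not fit.converged or fit.tm is None:
        # fall back to direct interpolation of the observed series
        return _interpolate_tm50(temps, rel)
    return fit.tm


def _as_list(curves) -> list[DensitometryCurve]:
    return [curves] if isinstance(curves, DensitometryCurve) else list(curves)


def cetsa_delta_tm(
    control,
    treated,
    method: str = "auto",
) -> dict:
    """In-situ melting-point shift from CETSA curves.

    ``control`` and ``treated`` may each be a single
    :class:`DensitometryCurve` or a list of replicate curves.  Per-condition
    Tm50 is the mean of replicate Tm50 values; ``delta_tm`` is treated minus
    control.  With >= 3 replicate pairs a paired two-sided Student's t-test
    on replicate Tm50 differences supplies a p-value.

    Returns a dict with ``tm_control, tm_treated, delta_tm, p_value,
    n_replicates``.
    """
    ctrl = _as_list(control)
    trt = _as_list(treated)
    try:
        tms_c = [apparent_tm50(c, method) for c in ctrl]
        tms_t = [apparent_tm50(c, method) for c in trt]
    except Tm50Undefined as err:
        raise Tm50Undefined(f"Tm50 undefined for one condition: {err}") from err

    tm_control = float(np.mean(tms_c))
    tm_treated = float(np.mean(tms_t))
    n_pairs = min(len(tms_c), len(tms_t))
    p_value = None
    if n_pairs >= 3:
        diffs = np.asarray(tms_t[:n_pairs]) - np.asarray(tms_c[:n_pairs])
        if np.std(diffs, ddof=1) > 0:
            _, p_value = stats.ttest_rel(tms_t[:n_pairs], tms_c[:n_pairs])
            p_value = float(p_value)
        else:
            p_value = 0.0 if diffs.mean() != 0 else 1.0
    return {
        "tm_control": tm_control,
        "tm_treated": tm_treated,
        "delta_tm": tm_treated - tm_control,
        "p_value": p_value,
        "n_replicates": n_pairs,
    }


def analyze_cetsa_table(df: pd.DataFrame, method: str = "auto") -> pd.DataFrame:
    """Run :func:`cetsa_delta_tm` for every target in a densitometry table.

    Expects columns ``target_name, condition, replicate, temperature_c,
    band_intensity`` with conditions ``vehicle`` and ``treated``.
    """
    rows = []
    for target, grp in df.groupby("target_name", sort=True):
        curves = {"vehicle": [], "treated": []}
        for (cond, rep), sub in grp.groupby(["condition", "replicate"], sort=True):
            sub = sub.sort_values("temperature_c")
            curves[cond].append(
                DensitometryCurve(
                    target_name=str(target),
                    condition=str(cond),
                    temperatures=sub["temperature_c"].to_numpy(dtype=float),
                    intensities=sub["band_intensity"].to_numpy(dtype=float),
                    replicate=int(rep),
                )
            )
        res = cetsa_delta_tm(curves["vehicle"], curves["treated"], method)
        res["target_name"] = str(target)
        rows.append(res)
    cols = ["target_name", "tm_control", "tm_treated", "delta_tm", "p_value", "n_replicates"]
    return pd.DataFrame(rows)[cols]
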