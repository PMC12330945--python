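"""Normalization of abundance series and nonlinear fitting of melting curves.

A raw label-free quantification (LFQ) series for one protein/condition is
turned into a fraction-folded curve by dividing each replicate's intensities
by that replicate's intensity at the lowest available temperature (the
non-denaturing reference, where essentially all protein is still folded and
soluble).  The three-parameter unfolding model is then fitted to all
replicate points of a condition jointly by bounded nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .model import fraction_folded, melting_point

__all__ = [
    "MeltingCurve",
    "UnfoldingFit",
    "FitSettings",
    "QcThresholds",
    "normalize_to_reference",
    "fit_unfolding",
    "qc_filter",
]


@dataclass(frozen=True)
class MeltingCurve:
    """Fraction-folded observations for one protein in one condition.

    ``points`` is a DataFrame with columns ``temperature_c``,
    ``relative_abundance`` and ``replicate``; each replicate is normalized so
    its value at ``reference_temperature`` is exactly 1.
    """

    protein_id: str
    condition: str
    points: pd.DataFrame
    reference_temperature: float

    @property
    def n_temperatures(self) -> int:
        return int(self.points["temperature_c"].nunique())


@dataclass(frozen=True)
class UnfoldingFit:
    """Fitted unfolding parameters and diagnostics for one curve.

    ``tm`` is ``None`` when the melting point is undefined (plateau
    ``p >= 0.5``) or the fit did not converge.  ``r_squared`` is NaN for
    degenerate (e.g. flat) curves.
    """

    protein_id: str
    condition: str
    a: float
    b: float
    p: float
    tm: float | None
    r_squared: float
    rmse: float
    n_points: int
    converged: bool
    reason: str | None = None


@dataclass
class FitSettings:
    """Tunables of the nonlinear least-squares melting-curve fit."""

    min_points: int = 5          # distinct temperatures required
    a_bounds: tuple[float, float] = (-10.0, -1e-3)
    b_pad: float = 10.0          # b searched in [T_min - pad, T_max + pad]
    p_bounds: tuple[float, float] = (0.0, 1.0 - 1e-9)
    max_nfev: int = 2000


@dataclass
class QcThresholds:
    """Acceptance thresholds for a control/treated fit pair."""

    r2_min: float = 0.8
    plateau_max: float = 0.4
    tm_window_pad: float = 5.0   # Tm must lie within [T_min - pad, T_max + pad]


def normalize_to_reference(
    raw: pd.DataFrame,
    protein_id: str,
    condition: str,
) -> tuple[MeltingCurve | None, str | None]:
    """Convert raw intensities into relative (fraction-folded) abundances.

    ``raw`` holds columns ``temperature_c``, ``intensity``, ``replicate`` for
    a single protein/condition.  Each replicate is divided by its own
    intensity at the lowest temperature at which it was observed; replicates
    whose reference intensity is zero or missing are excluded.

    Returns ``(curve, None)`` on success, or ``(None, "no_reference")``
    when no replicate has a usable reference.  Already-normalized input
    (reference value 1) passes through unchanged, so the operation is
    idempotent.
    """
    if raw.empty:
        return None, "no_reference"
    ref_temp = float(raw["temperature_c"].min())
    refs = (
        raw.loc[raw["temperature_c"] == ref_temp]
        .set_index("replicate")["intensity"]
    )
    refs = refs[refs > 0]
    if refs.empty:
        return None, "no_reference"
    sub = raw.loc[raw["replicate"].isin(refs.index)].sort_values(
        ["replicate", "temperature_c"], kind="mergesort"
    )
    points = pd.DataFrame(
        {
            "temperature_c": sub["temperature_c"].to_numpy(dtype=float),
            "relative_abundance": sub["intensity"].to_numpy(dtype=float)
            / sub["replicate"].map(refs).to_numpy(dtype=float),
            "replicate": sub["replicate"].to_numpy(),
        }
    )
    return MeltingCurve(protein_id, condition, points, ref_temp), None


def _initial_guess(T: np.ndarray, y: np.ndarray, settings: FitSettings):
    """Heuristic start values: plateau from the curve floor, inflection from
    the temperature nearest the half-height, slope from a local two-point
    difference around it."""
    p0 = float(np.clip(y.min(), 0.0, 0.3))
    # group by temperature for a mean profile
    order = np.argsort(T)
    Ts, idx = np.unique(T[order], return_index=True)
    means = np.array([y[T == t].mean() for t in Ts])
    half = (1.0 + p0) / 2.0
    k = int(np.argmin(np.abs(means - half)))
    b0 = float(Ts[k])
    lo = max(k - 1, 0)
    hi = min(k + 1, len(Ts) - 1)
    if hi > lo and Ts[hi] != Ts[lo]:
        slope = (means[hi] - means[lo]) / (Ts[hi] - Ts[lo])
    else:
        slope = -0.1
    # near the midpoint df/dT = a*(1-p)/4
    a0 = 4.0 * slope / max(1.0 - p0, 1e-6)
    a0 = float(np.clip(a0, settings.a_bounds[0], settings.a_bounds[1]))
    return a0, b0, p0


def fit_unfolding(curve: MeltingCurve, settings: FitSettings | None = None) -> UnfoldingFit:
    """Fit the unfolding model to one melting curve by bounded least squares.

    All replicate points are pooled into a single fit of the self-normalized
    model f(T)/f(T_ref) — the quantity the reference-anchored normalization
    actually observes.  Requires at least
    ``settings.min_points`` distinct temperatures; otherwise the fit is
    skipped with reason ``"insufficient_points"``.  On non-convergence a
    3x3 multi-start grid of perturbed (a0, b0) start values is tried before
    reporting ``converged=False``.
    """
    settings = settings or FitSettings()
    T = curve.points["temperature_c"].to_numpy(dtype=float)
    y = curve.points["relative_abundance"].to_numpy(dtype=float)
    n_temps = len(np.unique(T))
    if n_temps < settings.min_points:
        return UnfoldingFit(
            curve.protein_id, curve.condition,
            np.nan, np.nan, np.nan, None, np.nan, np.nan, len(T),
            converged=False, reason="insufficient_points",
        )
    if np.allclose(y, y[0]):
        # flat series carries no melting signal; r^2 is undefined
        return UnfoldingFit(
            curve.protein_id, curve.condition,
            np.nan, np.nan, np.nan, None, np.nan, np.nan, len(T),
            converged=False, reason="no_melting_signal",
        )

    lo = [settings.a_bounds[0], T.min() - settings.b_pad, settings.p_bounds[0]]
    hi = [settings.a_bounds[1], T.max() + settings.b_pad, settings.p_bounds[1]]
    a0, b0, p0 = _initial_guess(T, y, settings)

    # the data are normalized by the reference-temperature observation, so
    # the observed curve is f(T)/f(T_ref); fitting the same self-normalized
    # model removes the bias from melting that starts before the reference
    ref_T = curve.reference_temperature

    def model(T_, a_, b_, p_):
        return fraction_folded(T_, a_, b_, p_) / fraction_folded(ref_T, a_, b_, p_)

    Tall = np.append(T, ref_T)  # last entry evaluates the reference factor

    def _resid(theta):
        a_, b_, p_ = theta
        u = expit(a_ * (Tall - b_))
        f = (1.0 - p_) * u + p_
        return f[:-1] / f[-1] - y

    def _jac(theta):
        a_, b_, p_ = theta
        u = expit(a_ * (Tall - b_))
        f = (1.0 - p_) * u + p_
        w = (1.0 - p_) * u * (1.0 - u)
        dfa = w * (Tall - b_)
        dfb = -a_ * w
        dfp = 1.0 - u
        fr = f[-1]
        out = np.empty((len(Tall) - 1, 3))
        for j, df in enumerate((dfa, dfb, dfp)):
            out[:, j] = (df[:-1] * fr - f[:-1] * df[-1]) / (fr * fr)
        return out

    def _attempt(start):
        try:
            sol = least_squares(
                _resid, np.asarray(start), jac=_jac, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=settings.max_nfev,
            )
        except ValueError:
            return None
        if not sol.success:
            return None
        return sol.x, float(2.0 * sol.cost)

    best = _attempt((a0, b0, p0))
    if best is None:
        # multi-start retry: 3x3 grid of perturbed (a0, b0)
        for fa in (0.5, 1.0, 2.0):
            for db in (-3.0, 0.0, 3.0):
                cand = (float(np.clip(a0 * fa, lo[0], hi[0])),
                        float(np.clip(b0 + db, lo[1], hi[1])), p0)
                got = _attempt(cand)
                if got is not None and (best is None or got[1] < best[1]):
                    best = got

    if best is None:
        return UnfoldingFit(
            curve.protein_id, curve.condition,
            np.nan, np.nan, np.nan, None, np.nan, np.nan, len(T),
            converged=False, reason="no_convergence",
        )

    (a, b, p), sse = best
    # goodness of fit is judged on the per-temperature replicate-mean
    # profile: replicate scatter is measurement noise, not model misfit
    Ts = np.unique(T)
    means = np.array([y[T == t].mean() for t in Ts])
    resid_mean = means - model(Ts, a, b, p)
    sse_mean = float(resid_mean @ resid_mean)
    ss_tot = float(np.sum((means - means.mean()) ** 2))
    r2 = 1.0 - sse_mean / ss_tot if ss_tot > 0 else np.nan
    rmse = float(np.sqrt(sse / len(T)))
    tm = melting_point(a, b, p) if a < 0 else None
    return UnfoldingFit(
        curve.protein_id, curve.condition,
        float(a), float(b), float(p), tm, r2, rmse, len(T), converged=True,
    )


def qc_filter(
    fit_control: UnfoldingFit,
    fit_treated: UnfoldingFit,
    thresholds: QcThresholds | None = None,
    temperature_window: tuple[float, float] | None = None,
) -> tuple[bool, list[str]]:
    """Decide whether a control/treated fit pair is usable for shift calling.

    A pair passes when both fits converged, both reach the goodness-of-fit
    floor, both plateaus stay below the plateau cap, and both melting points
    are defined and lie within the assayed temperature window (padded).
    Every violated check contributes a named reason code.
    """
    thresholds = thresholds or QcThresholds()
    reasons: list[str] = []
    for fit, tag in ((fit_control, "control"), (fit_treated, "treated")):
        if not fit.converged:
            reasons.append(f"not_converged_{tag}")
            continue
        if not np.isfinite(fit.r_squared) or fit.r_squared < thresholds.r2_min:
            reasons.append(f"low_r2_{tag}")
        if fit.p >= thresholds.plateau_max:
            reasons.append(f"high_plateau_{tag}")
        if fit.tm is None:
            reasons.append(f"no_tm_{tag}")
        elif temperature_window is not None:
            lo = temperature_window[0] - thresholds.tm_window_pad
            hi = temperature_window[1] + thresholds.tm_window_pad
            if not (lo <= fit.tm <= hi):
                reasons.append(f"tm_out_of_window_{tag}")
    return (len(reasons) == 0), reasons
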