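"""Melting-point shift computation, significance, classification, ranking.

A ligand that binds a protein typically stabilizes it against heat
denaturation, shifting its melting point upward; destabilization shifts it
down.  For every protein that passes curve-level QC the shift is

    delta_tm = tm_treated - tm_control   (degC)

Significance is assessed in one of two modes:

* ``proteome_null`` (default, works without replicate structure): the bulk
  of the proteome is assumed unshifted, so the robust z-score of each
  protein's delta-Tm against the proteome-wide median/MAD null gives a
  two-sided normal p-value.
* ``replicate``: a one-sample two-sided t-test of the per-replicate-pair
  delta-Tm values against zero.

Both modes are followed by Benjamini-Hochberg adjustment across proteins.
Candidates are classified stabilized/destabilized by a delta-Tm threshold
plus an FDR cutoff and ranked by descending |delta_tm|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .curves import (
    FitSettings,
    QcThresholds,
    UnfoldingFit,
    fit_unfolding,
    normalize_to_reference,
    qc_filter,
)

__all__ = [
    "ShiftSettings",
    "compute_shift",
    "benjamini_hochberg",
    "significance_scores",
    "classify_and_rank",
    "classify_dep",
    "analyze_shifts",
]

MAD_FLOOR = 1e-6  # degC; guards the degenerate all-identical null


@dataclass
class ShiftSettings:
    """Thresholds and mode of the shift-calling stage."""

    delta_threshold: float = 2.0   # degC; minimum |delta_tm| to call a class
    q_cutoff: float = 0.05         # BH-adjusted significance cutoff
    mode: str = "proteome_null"    # or "replicate"


def compute_shift(fit_control: UnfoldingFit, fit_treated: UnfoldingFit) -> float | None:
    """Melting-point shift tm_treated - tm_control, or None if either Tm is
    undefined (the pair is then QC-failed downstream)."""
    if fit_control.tm is None or fit_treated.tm is None:
        return None
    return fit_treated.tm - fit_control.tm


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment (step-up), NaN-tolerant."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def significance_scores(
    delta_tm,
    mode: str = "proteome_null",
    replicate_deltas: dict[str, np.ndarray] | None = None,
    protein_ids=None,
) -> pd.DataFrame:
    """Per-protein z-scores, p-values and BH q-values for melting shifts.

    Parameters
    ----------
    delta_tm : array-like
        Pooled-fit delta-Tm per protein (NaN where QC failed).
    mode : {"proteome_null", "replicate"}
        ``proteome_null`` standardizes each shift against the robust
        proteome-wide null, z = (d - median) / (1.4826 * MAD), two-sided
        normal p.  ``replicate`` runs a one-sample two-sided t-test of each
        protein's replicate-pair delta-Tm values against 0 (needs >= 2
        values per protein, supplied via ``replicate_deltas``).

    Returns a DataFrame with columns ``z_score, p_value, q_value`` aligned
    with the input order.
    """
    d = np.asarray(delta_tm, dtype=float)
    n = len(d)
    z = np.full(n, np.nan)
    p = np.full(n, np.nan)

    if mode == "proteome_null":
        ok = np.isfinite(d)
        if ok.sum() < 3:
            raise ValueError(
                "proteome_null mode needs at least 3 QC-pass proteins to estimate the null"
            )
        med = float(np.median(d[ok]))
        mad = float(np.median(np.abs(d[ok] - med)))
        scale = max(1.4826 * mad, MAD_FLOOR)
        z[ok] = (d[ok] - med) / scale
        p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    elif mode == "replicate":
        if replicate_deltas is None or protein_ids is None:
            raise ValueError("replicate mode needs replicate_deltas keyed by protein_id")
        for i, pid in enumerate(protein_ids):
            vals = np.asarray(replicate_deltas.get(pid, ()), dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) < 2:
                continue
            if np.std(vals, ddof=1) == 0:
                # exact replicates: t undefined; treat nonzero mean as extreme
                z[i] = np.inf if vals.mean() != 0 else 0.0
                p[i] = 0.0 if vals.mean() != 0 else 1.0
                continue
            t, pv = stats.ttest_1samp(vals, 0.0)
            z[i], p[i] = float(t), float(pv)
    else:
        raise ValueError(f"unknown significance mode {mode!r}")

    return pd.DataFrame({"z_score": z, "p_value": p, "q_value": benjamini_hochberg(p)})


def classify_and_rank(
    results: pd.DataFrame,
    delta_threshold: float = 2.0,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Assign stability classes and candidate ranks.

    ``results`` needs columns ``protein_id, delta_tm, q_value, qc_pass``.
    stabilized: delta_tm >= +threshold and q <= cutoff; destabilized:
    delta_tm <= -threshold and q <= cutoff; otherwise unchanged; QC
    failures are ``qc_failed`` and carry no rank.  Rank is 1..n over
    QC-pass proteins by descending |delta_tm|, ties by ascending q_value
    then lexicographic protein_id.
    """
    if results.empty:
        raise ValueError("no shift results to classify")
    df = results.copy()
    qc = df["qc_pass"].to_numpy(dtype=bool)
    d = df["delta_tm"].to_numpy(dtype=float)
    q = df["q_value"].to_numpy(dtype=float)

    cls = np.where(
        ~qc, "qc_failed",
        np.where(
            (d >= delta_threshold) & (q <= q_cutoff), "stabilized",
            np.where((d <= -delta_threshold) & (q <= q_cutoff), "destabilized", "unchanged"),
        ),
    )
    df["stability_class"] = cls

    df["rank"] = np.nan
    sub = df.loc[qc, ["protein_id", "delta_tm", "q_value"]].copy()
    if not sub.empty:
        sub["absd"] = sub["delta_tm"].abs()
        order = sub.sort_values(
            ["absd", "q_value", "protein_id"],
            ascending=[False, True, True],
            kind="mergesort",
        ).index
        df.loc[order, "rank"] = np.arange(1, len(order) + 1, dtype=float)
    return df


def classify_dep(
    table: pd.DataFrame,
    fold_cutoff: float = 2.0,
    q_cutoff: float = 0.05,
    reference_temperature: float | None = None,
) -> pd.DataFrame:
    """Two-fold differential-expression rule at the non-denaturing reference.

    Uses intensities at the lowest (or given) temperature — the condition
    closest to an unheated comparative-proteomics measurement.  Per
    protein: log2 fold change of replicate means (treated / vehicle), Welch
    two-sample t-test on log intensities, BH adjustment across proteins;
    ``up`` iff fold change >= ``fold_cutoff`` ("twice or more" is
    inclusive) with q <= cutoff, ``down`` iff fold change <= 1/fold_cutoff
    with q <= cutoff.
    """
    if reference_temperature is None:
        reference_temperature = float(table["temperature_c"].min())
    sub = table.loc[table["temperature_c"] == reference_temperature]

    rows = []
    for pid, grp in sub.groupby("protein_id", sort=True):
        tr = grp.loc[grp["condition"] == "treated", "intensity"].to_numpy(dtype=float)
        ct = grp.loc[grp["condition"] == "vehicle", "intensity"].to_numpy(dtype=float)
        if len(tr) < 2 or len(ct) < 2:
            rows.append((pid, np.nan, np.nan, "insufficient_replicates"))
            continue
        if ct.mean() <= 0:
            rows.append((pid, np.nan, np.nan, "zero_control"))
            continue
        l2fc = float(np.log2(tr.mean() / ct.mean()))
        with np.errstate(divide="ignore"):
            lt, lc = np.log(tr[tr > 0]), np.log(ct[ct > 0])
        if len(lt) < 2 or len(lc) < 2:
            rows.append((pid, l2fc, np.nan, "zero_intensities"))
            continue
        if np.std(lt, ddof=1) == 0 and np.std(lc, ddof=1) == 0:
            pv = 1.0 if np.isclose(lt.mean(), lc.mean()) else 0.0
        else:
            _, pv = stats.ttest_ind(lt, lc, equal_var=False)
        rows.append((pid, l2fc, float(pv), ""))

    dep = pd.DataFrame(rows, columns=["protein_id", "log2_fold_change", "p_value", "flag"])
    dep["q_value"] = benjamini_hochberg(dep["p_value"])
    fc = 2.0 ** dep["log2_fold_change"]
    dep["dep_class"] = np.where(
        dep["flag"] != "", "flagged",
        np.where(
            (fc >= fold_cutoff) & (dep["q_value"] <= q_cutoff), "up",
            np.where((fc <= 1.0 / fold_cutoff) & (dep["q_value"] <= q_cutoff), "down", "unchanged"),
        ),
    )
    return dep


def _fit_condition(table, pid, cond, settings):
    curve, reason = normalize_to_reference(
        table, pid, cond
    )
    if curve is None:
        return UnfoldingFit(pid, cond, np.nan, np.nan, np.nan, None,
                            np.nan, np.nan, 0, converged=False, reason=reason)
    return fit_unfolding(curve, settings)


def analyze_shifts(
    table: pd.DataFrame,
    fit_settings: FitSettings | None = None,
    qc_thresholds: QcThresholds | None = None,
    shift_settings: ShiftSettings | None = None,
) -> pd.DataFrame:
    """Full shift analysis of a long-format abundance table.

    Normalizes each protein/condition, fits the unfolding model pooled
    across replicates, applies QC, computes delta-Tm, scores significance
    (replicate-wise fits feed the ``replicate`` mode), classifies and
    ranks.  Returns one row per protein (the shift table).
    """
    fit_settings = fit_settings or FitSettings()
    qc_thresholds = qc_thresholds or QcThresholds()
    shift_settings = shift_settings or ShiftSettings()

    window = (float(table["temperature_c"].min()), float(table["temperature_c"].max()))
    need_replicates = shift_settings.mode == "replicate"

    rows = []
    replicate_deltas: dict[str, np.ndarray] = {}
    cols = ["condition", "replicate", "temperature_c", "intensity"]
    for pid, grp in table.groupby("protein_id", sort=True):
        fits = {}
        for cond in ("vehicle", "treated"):
            sub = grp.loc[grp["condition"] == cond, cols]
            fits[cond] = _fit_condition(sub, pid, cond, fit_settings)
        fc, ft = fits["vehicle"], fits["treated"]
        ok, reasons = qc_filter(fc, ft, qc_thresholds, temperature_window=window)
        delta = compute_shift(fc, ft) if ok else None

        if need_replicates and ok:
            reps = sorted(set(grp["replicate"]))
            deltas = []
            for rep in reps:
                pair = []
                for cond in ("vehicle", "treated"):
                    sub = grp.loc[
                        (grp["condition"] == cond) & (grp["replicate"] == rep), cols
                    ]
                    pair.append(_fit_condition(sub, pid, cond, fit_settings))
                d = compute_shift(pair[0], pair[1])
                if d is not None:
                    deltas.append(d)
            replicate_deltas[pid] = np.asarray(deltas)

        rows.append(
            {
                "protein_id": pid,
                "tm_control": fc.tm,
                "tm_treated": ft.tm,
                "delta_tm": delta if delta is not None else np.nan,
                "r2_control": fc.r_squared,
                "r2_treated": ft.r_squared,
                "plateau_control": fc.p,
                "plateau_treated": ft.p,
                "rmse_control": fc.rmse,
                "rmse_treated": ft.rmse,
                "n_points_control": fc.n_points,
                "n_points_treated": ft.n_points,
                "converged_control": fc.converged,
                "converged_treated": ft.converged,
                "qc_pass": ok,
                "qc_flags": ";".join(reasons),
            }
        )

    out = pd.DataFrame(rows)
    scores = significance_scores(
        out["delta_tm"],
        mode=shift_settings.mode,
        replicate_deltas=replicate_deltas if need_replicates else None,
        protein_ids=out["protein_id"] if need_replicates else None,
    )
    out = pd.concat([out, scores], axis=1)
    out = classify_and_rank(
        out, shift_settings.delta_threshold, shift_settings.q_cutoff
    )
    return out
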