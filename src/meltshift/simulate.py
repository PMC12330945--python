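"""Synthetic thermal-proteome and CETSA data with known ground truth.

The generator emulates a TPP-TR (temperature-range thermal proteome
profiling) experiment: each protein has a sigmoidal melting curve with a
high-temperature plateau; treated and vehicle conditions share the slope and
plateau, and a spiked subset of ligand targets shifts its inflection
temperature by a known delta-Tm.  Observed intensities are the noise-free
fraction folded scaled by a per-protein base intensity and perturbed by
multiplicative log-normal quantification noise; observations are then
dropped completely at random at a configurable rate.

The defaults mirror a whole-cell TPP screen read out at six temperatures
evenly spaced from 43 to 60 degrees C (step 3.4) with three replicates per
condition, drug treatment at 15 uM for 24 h recorded as metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import fraction_folded

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "DEFAULT_TEMPERATURES",
    "simulate_dataset",
    "simulate_cetsa",
    "truths_to_frame",
]

# six temperatures evenly spaced over 43-60 degC: step (60-43)/5 = 3.4
DEFAULT_TEMPERATURES: tuple[float, ...] = (43.0, 46.4, 49.8, 53.2, 56.6, 60.0)


class ConfigError(ValueError):
    """A simulation configuration field violates its constraint."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic TPP experiment.

    Attributes
    ----------
    n_proteins : int
        Number of simulated proteins (a real screen measures ~3000).
    fraction_stabilized, fraction_destabilized : float
        Fractions of proteins spiked as ligand-stabilized (positive
        delta-Tm) or destabilized (negative); counts are
        ``round(fraction * n_proteins)``.
    temperatures : tuple of float
        Strictly increasing heating gradient in degC, at least 4 points.
    n_replicates : int
        Replicates per condition.
    slope_range : (float, float)
        Uniform range for the slope ``a`` (1/degC); entirely negative.
    tm_range : (float, float)
        Uniform range for the control inflection ``b`` (degC).
    plateau_range : (float, float)
        Uniform range for the plateau ``p``; must stay inside [0, 0.5) so
        every simulated curve has a defined melting point.
    effect_distribution : ("constant", m) | ("uniform", lo, hi) | ("normal", mu, sd)
        Distribution of true delta-Tm magnitudes (degC) for spiked targets;
        magnitudes are taken as absolute values, the class sets the sign.
    noise_cv : float
        Coefficient of variation (linear scale) of the multiplicative
        log-normal quantification noise.
    missing_rate : float
        Per-observation probability of being dropped (missing completely at
        random).
    base_intensity_range : (float, float)
        Log-uniform range of the per-protein reference-temperature raw
        intensity (arbitrary LFQ units).
    seed : int
        Random seed; identical configs give bit-identical output.
    """

    n_proteins: int = 3000
    fraction_stabilized: float = 0.02
    fraction_destabilized: float = 0.02
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    n_replicates: int = 3
    slope_range: tuple[float, float] = (-1.5, -0.5)
    tm_range: tuple[float, float] = (47.0, 53.0)
    plateau_range: tuple[float, float] = (0.0, 0.3)
    effect_distribution: tuple = ("uniform", 2.0, 8.0)
    noise_cv: float = 0.1
    missing_rate: float = 0.05
    base_intensity_range: tuple[float, float] = (1e6, 1e9)
    seed: int = 0
    treatment_label: str = "15 uM ligand, 24 h"

    def validate(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if len(t) < 4 or not np.all(np.diff(t) > 0):
            raise ConfigError("temperatures must be strictly increasing with length >= 4")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        for name in ("fraction_stabilized", "fraction_destabilized"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.fraction_stabilized + self.fraction_destabilized > 1.0:
            raise ConfigError("fraction_stabilized + fraction_destabilized must be <= 1")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be positive")
        if not (self.slope_range[0] < self.slope_range[1] < 0):
            raise ConfigError("slope_range must be an increasing, entirely negative interval")
        if not (0.0 <= self.plateau_range[0] <= self.plateau_range[1] < 0.5):
            raise ConfigError("plateau_range must be contained in [0, 0.5)")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if not (0 < self.base_intensity_range[0] <= self.base_intensity_range[1]):
            raise ConfigError("base_intensity_range must be a positive interval")
        kind = self.effect_distribution[0]
        if kind not in ("constant", "uniform", "normal"):
            raise ConfigError(f"effect_distribution kind {kind!r} not recognized")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth curve parameters and spiked effect for one protein."""

    protein_id: str
    a_control: float
    b_control: float
    p_control: float
    true_delta_tm: float
    true_class: str  # stabilized | destabilized | unchanged


def _lognormal_sigma(cv: float) -> float:
    """Log-scale sigma giving a linear-scale coefficient of variation cv.

    For X = exp(N(0, sigma^2)) the CV is sqrt(exp(sigma^2) - 1); the median
    of the noise factor is 1, so the log factors average to zero.
    """
    return math.sqrt(math.log1p(cv * cv))


def _draw_effects(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    kind = dist[0]
    if kind == "constant":
        return np.full(n, abs(float(dist[1])))
    if kind == "uniform":
        return rng.uniform(abs(float(dist[1])), abs(float(dist[2])), n)
    if kind == "normal":
        return np.abs(rng.normal(float(dist[1]), float(dist[2]), n))
    raise ConfigError(f"effect_distribution kind {kind!r} not recognized")


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, list[SimulationTruth]]:
    """Generate a long-format abundance table and the matching ground truth.

    Returns
    -------
    table : DataFrame
        Columns ``protein_id, gene_symbol, condition, replicate,
        temperature_c, intensity`` with conditions ``vehicle`` and
        ``treated``; missing observations are absent rows.
    truths : list of SimulationTruth
        One entry per protein, in protein-id order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    temps = np.asarray(config.temperatures, dtype=float)

    n_stab = round(config.fraction_stabilized * n)
    n_dest = round(config.fraction_destabilized * n)
    classes = np.array(["unchanged"] * n, dtype=object)
    spiked = rng.permutation(n)[: n_stab + n_dest]
    classes[spiked[:n_stab]] = "stabilized"
    classes[spiked[n_stab : n_stab + n_dest]] = "destabilized"

    a = rng.uniform(config.slope_range[0], config.slope_range[1], n)
    b = rng.uniform(config.tm_range[0], config.tm_range[1], n)
    p = rng.uniform(config.plateau_range[0], config.plateau_range[1], n)
    lo, hi = config.base_intensity_range
    base = np.exp(rng.uniform(math.log(lo), math.log(hi), n))

    magnitudes = _draw_effects(rng, config.effect_distribution, n)
    delta = np.where(
        classes == "stabilized", magnitudes,
        np.where(classes == "destabilized", -magnitudes, 0.0),
    )

    width = len(str(n))
    ids = [f"P{i + 1:0{width}d}" for i in range(n)]
    truths = [
        SimulationTruth(ids[i], float(a[i]), float(b[i]), float(p[i]),
                        float(delta[i]), str(classes[i]))
        for i in range(n)
    ]

    sigma = _lognormal_sigma(config.noise_cv)
    n_t, n_r = len(temps), config.n_replicates
    frames = []
    for cond, shift in (("vehicle", np.zeros(n)), ("treated", delta)):
        # fraction folded: proteins x temperatures
        frac = (1.0 - p[:, None]) / (
            1.0 + np.exp(np.clip(-a[:, None] * (temps[None, :] - (b + shift)[:, None]), -700, 700))
        ) + p[:, None]
        clean = base[:, None] * frac  # proteins x temps
        for rep in range(1, n_r + 1):
            if sigma > 0:
                noise = np.exp(rng.normal(0.0, sigma, size=(n, n_t)))
            else:
                noise = np.ones((n, n_t))
            intensity = clean * noise
            keep = (
                rng.random((n, n_t)) >= config.missing_rate
                if config.missing_rate > 0
                else np.ones((n, n_t), dtype=bool)
            )
            pid_grid = np.repeat(ids, n_t)
            frames.append(
                pd.DataFrame(
                    {
                        "protein_id": pid_grid[keep.ravel()],
                        "gene_symbol": pid_grid[keep.ravel()],
                        "condition": cond,
                        "replicate": rep,
                        "temperature_c": np.tile(temps, n)[keep.ravel()],
                        "intensity": intensity.ravel()[keep.ravel()],
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(
        ["protein_id", "condition", "replicate", "temperature_c"]
    ).reset_index(drop=True)
    table.attrs["seed"] = config.seed
    table.attrs["treatment"] = config.treatment_label
    return table, truths


def truths_to_frame(truths: list[SimulationTruth]) -> pd.DataFrame:
    """Tabulate ground truth as a DataFrame (one row per protein)."""
    return pd.DataFrame(
        {
            "protein_id": [t.protein_id for t in truths],
            "a": [t.a_control for t in truths],
            "b": [t.b_control for t in truths],
            "p": [t.p_control for t in truths],
            "true_delta_tm": [t.true_delta_tm for t in truths],
            "true_class": [t.true_class for t in truths],
        }
    )


def simulate_cetsa(
    tm_control: float,
    delta_tm: float,
    a: float = -0.8,
    p: float = 0.0,
    temperatures=DEFAULT_TEMPERATURES,
    noise_cv: float = 0.0,
    seed: int = 0,
    target_name: str = "target",
    replicate: int = 1,
):
    """Simulate one pair of CETSA densitometry series (vehicle, treated).

    Band intensities are proportional to the fraction folded with inflection
    ``tm_control`` (vehicle) and ``tm_control + delta_tm`` (treated), with
    optional multiplicative log-normal noise.  Intensities are scaled so the
    lowest-temperature band is about 1.  ``p`` must be < 0.5 so the 50%
    crossing exists.

    Returns a pair of :class:`~meltshift.cetsa.DensitometryCurve`.
    """
    from .cetsa import DensitometryCurve  # local import avoids a cycle

    temps = np.asarray(temperatures, dtype=float)
    if len(temps) < 2 or not np.all(np.diff(temps) > 0):
        raise ConfigError("temperatures must be strictly increasing")
    if p >= 0.5:
        raise ConfigError("plateau p must be < 0.5 (50% crossing undefined otherwise)")
    if a >= 0:
        raise ConfigError("slope a must be negative")

    rng = np.random.default_rng(seed)
    sigma = _lognormal_sigma(noise_cv)
    curves = []
    for cond, b in (("vehicle", tm_control), ("treated", tm_control + delta_tm)):
        y = fraction_folded(temps, a, b, p)
        if sigma > 0:
            y = y * np.exp(rng.normal(0.0, sigma, size=len(temps)))
        curves.append(
            DensitometryCurve(
                target_name=target_name,
                condition=cond,
                temperatures=temps.copy(),
                intensities=np.asarray(y, dtype=float),
                replicate=replicate,
            )
        )
    return tuple(curves)
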