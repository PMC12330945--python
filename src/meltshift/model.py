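"""Three-parameter equilibrium unfolding model for protein melting curves.

The fraction of natively folded protein remaining soluble after heating to
temperature ``T`` is modeled by a logistic decay with a high-temperature
plateau::

    f(T) = (1 - p) / (1 + exp(-a * (T - b))) + p

where ``a`` (< 0, per degree C) controls the steepness of denaturation,
``b`` (degrees C) is the inflection temperature, and ``p`` in [0, 0.5) is
the residual heat-resistant fraction.  With ``a < 0`` the curve decreases
from 1 (fully folded) toward ``p``.

The melting point ``Tm`` is defined as the temperature at which half of the
protein is denatured, i.e. the absolute ``f(T) = 0.5`` crossing — not the
midpoint between plateaus.  It exists only when ``p < 0.5``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit

__all__ = ["fraction_folded", "melting_point"]


def fraction_folded(T, a: float, b: float, p: float):
    """Evaluate the unfolding model f(T) = (1-p)/(1+exp(-a(T-b))) + p.

    Parameters
    ----------
    T : float or array-like
        Temperature(s) in degrees Celsius.
    a : float
        Slope parameter (1/degC).  Negative for a melting (decreasing) curve.
    b : float
        Inflection temperature (degC); f(b) = (1+p)/2.
    p : float
        Lower plateau, the high-temperature asymptote for ``a < 0``.

    Returns
    -------
    float or ndarray
        Fraction folded, computed overflow-safely for large ``|a*(T-b)|``.

    Raises
    ------
    ValueError
        If any of a, b, p or T is non-finite.
    """
    T = np.asarray(T, dtype=float)
    if not (np.isfinite(a) and np.isfinite(b) and np.isfinite(p)):
        raise ValueError("unfolding parameters must be finite")
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature must be finite")
    # 1/(1+exp(-x)) == expit(x); expit saturates cleanly instead of overflowing
    out = (1.0 - p) * expit(a * (T - b)) + p
    return float(out) if out.ndim == 0 else out


def melting_point(a: float, b: float, p: float) -> float | None:
    """Closed-form melting point: the temperature where f(T) = 0.5.

    Solving (1-p)/(1+exp(-a(Tm-b))) + p = 0.5 gives

        Tm = b - ln(0.5 / (0.5 - p)) / a

    Returns ``None`` when ``p >= 0.5``: the curve then never drops to 50%
    and the melting point is undefined.

    Requires ``a < 0`` (a melting curve); ``a >= 0`` raises ``ValueError``.
    """
    if not (np.isfinite(a) and np.isfinite(b) and np.isfinite(p)):
        raise ValueError("unfolding parameters must be finite")
    if a >= 0:
        raise ValueError(f"slope a must be negative for a melting curve, got {a}")
    if p >= 0.5:
        return None
    if p == 0.0:
        return b  # symmetric logistic: midpoint is the inflection
    return b - math.log(0.5 / (0.5 - p)) / a
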