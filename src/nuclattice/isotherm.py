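"""Closed-form McGhee–von Hippel reference isotherm.

For a homogeneous, infinite lattice with a single non-cooperative species of
footprint ``m`` and activity ``a``, the bound-particle density per lattice
unit ``nu`` satisfies

    nu / a = (1 - m nu) * ((1 - m nu) / (1 - (m - 1) nu))**(m - 1)

The interior of a long hard-wall lattice converges to this density, which
makes the isotherm an independent closed-form check on the transfer DP.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


class IsothermError(RuntimeError):
    """Root finding for the binding isotherm failed."""


def log_mcghee_von_hippel_activity(nu: float, m: int) -> float:
    """log of the activity at which the isotherm density equals ``nu``.

    Computed in log space so densities arbitrarily close to saturation
    (``nu -> 1/m``) stay representable.
    """
    if not 0 < nu < 1.0 / m:
        raise IsothermError(f"density must be in (0, 1/m), got {nu}")
    free = 1.0 - m * nu
    return float(
        np.log(nu) - np.log(free) - (m - 1) * (np.log(free) - np.log(1.0 - (m - 1) * nu))
    )


def mcghee_von_hippel_activity(nu: float, m: int) -> float:
    """Activity ``a`` at which the isotherm density equals ``nu``.

    Inverse of :func:`interior_density`; ``nu`` must lie in [0, 1/m).
    """
    if nu == 0:
        return 0.0
    return float(np.exp(log_mcghee_von_hippel_activity(nu, m)))


def interior_density(footprint: int, activity: float) -> float:
    """Bound-particle density ``nu`` per lattice unit (coverage = m * nu).

    Solves the non-cooperative McGhee–von Hippel isotherm; the Langmuir
    ``a / (1 + a)`` limit is recovered for ``footprint = 1``.
    """
    m = int(footprint)
    if m < 1:
        raise IsothermError(f"footprint must be >= 1, got {footprint}")
    if activity < 0:
        raise IsothermError(f"activity must be >= 0, got {activity}")
    if activity == 0:
        return 0.0
    if m == 1:
        return activity / (1.0 + activity)

    log_a = np.log(activity)

    def g(nu: float) -> float:
        return log_mcghee_von_hippel_activity(nu, m) - log_a

    # log a(nu) is monotone increasing from -inf (nu -> 0) to +inf
    # (nu -> 1/m); bracket the root and bisect in log space
    hi_in = (1.0 / m) * (1.0 - 1e-13)
    lo = min(activity, 0.5) * 1e-6 / m
    while g(lo) > 0:
        lo *= 1e-3
        if lo < 1e-300:
            raise IsothermError("no root in [0, 1/m)")
    if g(hi_in) < 0:
        raise IsothermError("no root in [0, 1/m)")
    eps = np.finfo(float).eps
    try:
        return float(brentq(g, lo, hi_in, xtol=eps, rtol=8 * eps, maxiter=500))
    except ValueError as exc:  # pragma: no cover
        raise IsothermError(str(exc)) from exc
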