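"""The Churchill/Usagi growth-and-decline curve.

Batch cultures of phytoplankton (and their co-cultured bacteria) typically
rise exponentially, peak, and then decline.  On the natural-log count scale
this unimodal trajectory is captured by a harmonic blend of two asymptotic
exponentials,

    ln N(t) = [ (1/K1) e^(-lambda1 t) + (1/K2) e^(lambda2 t) ]^(-1)

where ``lambda1`` (h^-1) governs the rising, log-growth phase, ``lambda2``
(h^-1) governs the post-peak decline, and ``K1``/``K2`` set the initial and
peak ln-abundance scales.  At t=0 the curve equals the harmonic-style
combination K1*K2/(K1+K2); as t grows the decline term dominates and the
curve tends to zero from above.

This module holds the parameter container and the closed-form pieces (curve
value, analytic gradient, peak time).  Fitting lives in
:mod:`bloomfit.model`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = ["ChurchillParams", "ln_abundance", "gradient", "peak_time"]


@dataclass(frozen=True)
class ChurchillParams:
    """The four curve parameters.

    Attributes
    ----------
    k1 : float
        ln-abundance scale of the growth regime, units ln(cells/µL).
    k2 : float
        ln-abundance scale of the decline regime, same units.
    lambda1 : float
        Growth exponent, h^-1.
    lambda2 : float
        Decline exponent, h^-1.

    All four must be strictly positive and finite.
    """

    k1: float
    k2: float
    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        vals = (self.k1, self.k2, self.lambda1, self.lambda2)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise InvalidParameterError(
                f"all parameters must be finite and > 0, got {vals}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.lambda1, self.lambda2])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "ChurchillParams":
        return cls(*(float(v) for v in theta))


def ln_abundance(params: ChurchillParams, t):
    """Evaluate the curve: predicted ln count at time ``t`` (hours).

    Accepts a scalar or array of times; times must be >= 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    denom = (np.exp(-params.lambda1 * t) / params.k1
             + np.exp(params.lambda2 * t) / params.k2)
    return 1.0 / denom


def gradient(params: ChurchillParams, t) -> np.ndarray:
    """Analytic partial derivatives of :func:`ln_abundance`.

    Returns an array of shape ``(4,) + shape(t)`` holding the partials with
    respect to (k1, k2, lambda1, lambda2).  With y = 1/S and
    S = (1/K1)e^(-l1 t) + (1/K2)e^(l2 t), each partial is -dS/dtheta * y^2.
    """
    t = np.asarray(t, dtype=float)
    y = ln_abundance(params, t)
    y2 = y * y
    e_g = np.exp(-params.lambda1 * t)  # growth-regime exponential
    e_d = np.exp(params.lambda2 * t)   # decline-regime exponential
    d_k1 = y2 * e_g / params.k1**2
    d_k2 = y2 * e_d / params.k2**2
    d_l1 = y2 * t * e_g / params.k1
    d_l2 = -y2 * t * e_d / params.k2
    return np.stack([d_k1, d_k2, d_l1, d_l2])


def peak_time(params: ChurchillParams) -> float:
    """Time (h) at which the curve is maximal.

    Setting the derivative of the two-term denominator to zero gives the
    closed form ln(lambda1*K2 / (lambda2*K1)) / (lambda1 + lambda2).  The
    value is negative when the decline term already dominates at t=0, i.e.
    the curve is monotonically decreasing on t >= 0.
    """
    return float(
        np.log(params.lambda1 * params.k2 / (params.lambda2 * params.k1))
        / (params.lambda1 + params.lambda2)
    )
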