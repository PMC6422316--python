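"""Sigmoidal Z-regulation kernels.

All thrombopoietin-dependent feedbacks of the model (progenitor amplification,
proplatelet-formation probabilities, reactivation of dormant megakaryocytes)
are mediated by a common family of bounded sigmoid functions of a relative
signal ``x`` (steady state at ``x = 1``).  The kernel is parameterized by the
minimal, normal (steady-state) and maximal values of the regulated quantity,
a steepness exponent ``b`` and a saturation bound ``lim_sig`` applied to the
transformed argument so that extreme signals cannot push the exponent outside
a numerically safe range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ZParams", "trans_tanh", "z_function"]


def trans_tanh(x, lim_sig):
    """Saturating transform ``exp(lim_sig * tanh(ln(x) / lim_sig))``.

    Behaves like the identity for ``x`` close to 1 and saturates at
    ``exp(±lim_sig)`` for extreme arguments, which bounds the exponent of the
    Z-function below.

    Parameters
    ----------
    x : float or ndarray
        Positive argument (a relative signal, possibly raised to a power).
    lim_sig : float
        Positive saturation bound of the transformed argument.

    Returns
    -------
    float or ndarray
        Value in the open interval ``(exp(-lim_sig), exp(lim_sig))``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("trans_tanh requires x > 0")
    if lim_sig <= 0.0:
        raise ValueError("trans_tanh requires lim_sig > 0")
    out = np.exp(lim_sig * np.tanh(np.log(x) / lim_sig))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ZParams:
    """Parameters of one Z-regulation.

    Attributes
    ----------
    y_min, y_nor, y_max:
        Minimal, normal (steady-state) and maximal value of the regulated
        quantity; ``y_min < y_nor < y_max`` is required.
    b:
        Steepness exponent applied to the signal (``> 0``).
    lim_sig:
        Saturation bound of the transformed argument (``> 0``).
    direction:
        ``"increasing"`` or ``"decreasing"``.  A decreasing regulation is
        realized by evaluating the increasing kernel at ``1/x``, which keeps
        the ``y_min < y_nor < y_max`` ordering uniform for both directions.
    """

    y_min: float
    y_nor: float
    y_max: float
    b: float = 1.0
    lim_sig: float = 2.0
    direction: str = "increasing"

    def __post_init__(self):
        if not (self.y_min < self.y_nor < self.y_max):
            raise ValueError(
                f"ZParams requires y_min < y_nor < y_max, got "
                f"({self.y_min}, {self.y_nor}, {self.y_max})"
            )
        if self.b <= 0.0:
            raise ValueError("ZParams requires b > 0")
        if self.lim_sig <= 0.0:
            raise ValueError("ZParams requires lim_sig > 0")
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def as_tuple(self):
        """Flat numeric form ``(y_min, y_nor, y_max, b, lim_sig, sign)`` with
        ``sign = +1`` for increasing and ``-1`` for decreasing regulations."""
        sign = 1.0 if self.direction == "increasing" else -1.0
        return (self.y_min, self.y_nor, self.y_max, self.b, self.lim_sig, sign)


def z_function(x, params: ZParams):
    """Evaluate the Z-regulation at relative signal ``x``.

    ``z(1) = y_nor`` exactly; the value is strictly within ``(y_min, y_max)``
    and strictly monotone in ``x`` (increasing or decreasing per
    ``params.direction``).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("z_function requires x > 0")
    if params.direction == "decreasing":
        x = 1.0 / x
    t = trans_tanh(x ** params.b, params.lim_sig)
    span = params.y_max - params.y_min
    base = (params.y_max - params.y_nor) / span
    out = params.y_max - span * base ** t
    return float(out) if np.ndim(out) == 0 else out
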