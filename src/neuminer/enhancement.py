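"""Gamma and derivative-truncated gamma (DTGT) intensity transforms.

Plain gamma correction ``g(x) = x**gamma`` with ``gamma < 1`` amplifies weak
neurite signal, but its derivative ``gamma * x**(gamma-1)`` drops below 1 at
high intensities, washing out local contrast around bright fibers -- the
diffusive "halo" artifact. The derivative-truncated variant keeps the gamma
curve only up to the truncation point ``delta`` where the derivative equals
1, and continues with a unit-slope identity above it:

    g_hat(x) = x**gamma              for x in [0, delta]
             = x - delta + delta**gamma   for x in (delta, 1]

so contrast is never compressed anywhere. ``delta = gamma**(1/(1-gamma))``
solves ``gamma * delta**(gamma-1) = 1``. After the transform, values are
divided by ``g_hat(1) = 1 - delta + delta**gamma`` so the output range stays
[0, 1].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize_intensities",
    "gamma_transform",
    "truncation_point",
    "dtgt_transform",
    "standardize_range",
]

DEFAULT_GAMMA = 0.4


def normalize_intensities(vol: np.ndarray, bit_depth: int | None = None,
                          max_value: float | None = None) -> np.ndarray:
    """Scale a raw intensity volume into [0, 1] by its dtype maximum.

    Absolute scaling (division by 2**bit_depth - 1), not per-volume min-max,
    so the weak-fiber threshold keeps a fixed meaning across volumes. For
    integer input the bit depth is inferred from the dtype when not given;
    float input requires an explicit ``max_value``.
    """
    vol = np.asarray(vol)
    if np.issubdtype(vol.dtype, np.signedinteger) and vol.min() < 0:
        raise ValueError("negative intensities are not meaningful here")
    if max_value is None:
        if bit_depth is None:
            if not np.issubdtype(vol.dtype, np.integer):
                raise ValueError("float input needs bit_depth or max_value")
            bit_depth = np.iinfo(vol.dtype).bits
        if bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        max_value = float(2**bit_depth - 1)
    out = vol.astype(np.float64) / max_value
    if out.min() < 0:
        raise ValueError("negative intensities are not meaningful here")
    return out


def gamma_transform(x, gamma: float):
    """Elementwise gamma (power-law) transform on values in [0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = np.asarray(x, dtype=np.float64)
    if x.min() < 0 or x.max() > 1:
        raise ValueError("gamma transform expects values in [0, 1]")
    return x**gamma


def truncation_point(gamma: float) -> float:
    """Intensity delta where the gamma curve's derivative equals 1.

    Closed form delta = exp(ln(gamma) / (1 - gamma)) = gamma**(1/(1-gamma)).
    Below delta the gamma derivative exceeds 1 (weak signal amplified);
    above it the plain gamma would compress contrast.
    """
    if not 0 < gamma < 1:
        raise ValueError("truncation point is defined for gamma in (0, 1)")
    return float(np.exp(np.log(gamma) / (1.0 - gamma)))


def standardize_range(vol, gamma: float):
    """Rescale a DTGT output back to [0, 1] by dividing by g_hat(1).

    The divisor ``1 - delta + delta**gamma`` is the transform's fixed
    maximum, not a data statistic, so the rescaling is order-preserving and
    keeps the unit-slope (anti-halo) property intact up to a constant.
    """
    if gamma == 1.0:
        return np.asarray(vol, dtype=np.float64)
    delta = truncation_point(gamma)
    divisor = 1.0 - delta + delta**gamma
    return np.asarray(vol, dtype=np.float64) / divisor


def dtgt_transform(vol, gamma: float = DEFAULT_GAMMA, standardize: bool = True):
    """Derivative-truncated gamma transform of a [0, 1] volume.

    ``gamma = 1`` is the exact identity. With ``standardize=False`` the raw
    piecewise transform is returned (range [0, g_hat(1)]).
    """
    if not 0 < gamma <= 1:
        raise ValueError("gamma must be in (0, 1]")
    x = np.asarray(vol, dtype=np.float64)
    if x.size and (x.min() < 0 or x.max() > 1):
        raise ValueError("dtgt expects values in [0, 1]")
    if gamma == 1.0:
        return x.copy()
    delta = truncation_point(gamma)
    out = np.where(x <= delta, x**gamma, x - delta + delta**gamma)
    if standardize:
        out = standardize_range(out, gamma)
    return out
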