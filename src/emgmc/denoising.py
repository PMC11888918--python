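"""Wavelet threshold denoising with hard, soft and improved threshold rules.

The signal is decomposed with a multilevel orthogonal discrete wavelet
transform, every detail coefficient is passed through a threshold function,
and the signal is reconstructed.  Three rules are provided:

* ``hard``      — keep-or-kill: coefficients below the threshold die,
  the rest pass unchanged (discontinuous at +/- lambda);
* ``soft``      — kill-and-shrink: survivors are pulled toward zero by
  lambda (continuous, but biased for large coefficients);
* ``improved``  — an exponential blend controlled by a coefficient ``a``:
  inside (-lambda, lambda) the output is a*|exp(c) - 1|, outside it the
  soft rule is shifted by a*(exp(+/-lambda) - 1) so the function stays
  continuous while the large-coefficient bias shrinks as ``a`` grows.

The literal ``improved`` transition maps negative coefficients in
(-lambda, 0) to positive values, i.e. it is continuous but not odd.
``improved_odd`` applies the same rule to |c| and restores the sign,
giving the odd-symmetric shape one would normally draw; both variants are
exposed and tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt

THRESHOLD_METHODS = ("hard", "soft", "improved", "improved_odd")
LAMBDA_RULES = ("universal_per_level", "fixed")

#: scale factor turning the median absolute deviation of Gaussian draws
#: into a standard-deviation estimate
_MAD_GAUSS = 0.6745


@dataclass
class WaveletDecomposition:
    """Multilevel DWT coefficients for one channel.

    ``detail_coeffs`` is ordered coarse -> fine, matching the reconstruction
    order of the underlying filter bank.
    """

    wavelet_name: str
    n_levels: int
    approx_coeffs: np.ndarray
    detail_coeffs: list[np.ndarray]
    original_length: int
    mode: str = "symmetric"

    def coeff_list(self) -> list[np.ndarray]:
        return [self.approx_coeffs, *self.detail_coeffs]


@dataclass
class ThresholdSpec:
    """Which threshold function to apply and how to pick lambda per level."""

    method: str = "improved"
    lambda_rule: str = "universal_per_level"
    fixed_lambda: float | None = None
    control_a: float = 0.3

    def __post_init__(self) -> None:
        if self.method not in THRESHOLD_METHODS:
            raise ValueError(f"method must be one of {THRESHOLD_METHODS}")
        if self.lambda_rule not in LAMBDA_RULES:
            raise ValueError(f"lambda_rule must be one of {LAMBDA_RULES}")
        if self.lambda_rule == "fixed":
            if self.fixed_lambda is None or self.fixed_lambda < 0:
                raise ValueError("fixed rule requires fixed_lambda >= 0")
        if self.control_a <= 0:
            raise ValueError("control_a must be > 0")


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------

def decompose(
    signal, wavelet_name: str = "db4", n_levels: int = 4, mode: str = "symmetric"
) -> WaveletDecomposition:
    """Multilevel DWT; requires ``len(signal) >= 2**n_levels``."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("decompose expects a 1-D signal")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    min_len = 2**n_levels
    if len(x) < min_len:
        raise ValueError(
            f"signal of length {len(x)} too short for {n_levels} levels; "
            f"need at least {min_len} samples"
        )
    coeffs = pywt.wavedec(x, wavelet_name, level=n_levels, mode=mode)
    return WaveletDecomposition(
        wavelet_name=wavelet_name,
        n_levels=n_levels,
        approx_coeffs=coeffs[0],
        detail_coeffs=list(coeffs[1:]),
        original_length=len(x),
        mode=mode,
    )


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Inverse DWT, trimmed to the original signal length."""
    x = pywt.waverec(decomp.coeff_list(), decomp.wavelet_name, mode=decomp.mode)
    return x[: decomp.original_length]


# ---------------------------------------------------------------------------
# threshold functions
# ---------------------------------------------------------------------------

def _as_array(c):
    arr = np.asarray(c, dtype=float)
    return arr, arr.ndim == 0


def threshold_hard(c, lam: float):
    """c for |c| >= lambda, else 0."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    arr, scalar = _as_array(c)
    out = np.where(np.abs(arr) >= lam, arr, 0.0)
    return float(out) if scalar else out


def threshold_soft(c, lam: float):
    """Shrink survivors toward zero by lambda; kill the rest."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    arr, scalar = _as_array(c)
    out = np.sign(arr) * np.maximum(np.abs(arr) - lam, 0.0)
    return float(out) if scalar else out


def threshold_improved(c, lam: float, a: float = 0.3):
    """Exponential-transition threshold with control coefficient ``a``.

    Piecewise: ``c - lam + a*e**lam - a`` for c >= lam;
    ``a*|e**c - 1|`` for -lam <= c < lam;
    ``c + lam - a*e**(-lam) + a`` for c <= -lam.
    Continuous at both break points by construction.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if a <= 0:
        raise ValueError("control coefficient a must be > 0")
    arr, scalar = _as_array(c)
    out = np.empty_like(arr)
    hi = arr >= lam
    lo = arr <= -lam
    mid = ~(hi | lo)
    out[hi] = arr[hi] - lam + a * math.exp(lam) - a
    out[lo] = arr[lo] + lam - a * math.exp(-lam) + a
    out[mid] = a * np.abs(np.exp(arr[mid]) - 1.0)
    return float(out) if scalar else out


def threshold_improved_odd(c, lam: float, a: float = 0.3):
    """Odd-symmetric variant: sign(c) * improved(|c|, lambda, a)."""
    arr, scalar = _as_array(c)
    out = np.sign(arr) * threshold_improved(np.abs(arr), lam, a)
    return float(out) if scalar else out


_THRESHOLD_FUNCS = {
    "hard": lambda c, lam, a: threshold_hard(c, lam),
    "soft": lambda c, lam, a: threshold_soft(c, lam),
    "improved": threshold_improved,
    "improved_odd": threshold_improved_odd,
}


# ---------------------------------------------------------------------------
# lambda selection
# ---------------------------------------------------------------------------

def select_lambda(
    decomp: WaveletDecomposition,
    rule: str = "universal_per_level",
    fixed_lambda: float | None = None,
) -> list[float]:
    """Per-detail-level threshold.

    ``universal_per_level``: lambda_j = sigma_j * sqrt(2 ln N_j) with the
    noise scale sigma_j estimated per level as median(|d_j|) / 0.6745.
    ``fixed``: the supplied constant for every level.
    """
    if rule not in LAMBDA_RULES:
        raise ValueError(f"rule must be one of {LAMBDA_RULES}")
    lams = []
    for d in decomp.detail_coeffs:
        if len(d) == 0:
            raise ValueError("empty detail coefficient level")
        if rule == "fixed":
            if fixed_lambda is None or fixed_lambda < 0:
                raise ValueError("fixed rule requires fixed_lambda >= 0")
            lams.append(float(fixed_lambda))
        else:
            sigma = np.median(np.abs(d)) / _MAD_GAUSS
            lams.append(float(sigma * math.sqrt(2.0 * math.log(len(d)))))
    return lams


# ---------------------------------------------------------------------------
# denoising
# ---------------------------------------------------------------------------

def denoise(
    signal,
    spec: ThresholdSpec | None = None,
    wavelet_name: str = "db4",
    n_levels: int = 4,
    mode: str = "symmetric",
) -> np.ndarray:
    """Decompose, threshold every detail level, reconstruct.

    Approximation coefficients are never touched; output length equals
    input length.
    """
    spec = spec or ThresholdSpec()
    decomp = decompose(signal, wavelet_name, n_levels, mode)
    lams = select_lambda(decomp, spec.lambda_rule, spec.fixed_lambda)
    fn = _THRESHOLD_FUNCS[spec.method]
    decomp.detail_coeffs = [
        fn(d, lam, spec.control_a) for d, lam in zip(decomp.detail_coeffs, lams)
    ]
    return reconstruct(decomp)


def denoise_recording(recording, spec=None, wavelet_name="db4", n_levels=4,
                      mode="symmetric"):
    """Per-channel :func:`denoise` over a multi-channel recording."""
    from .synthetic import MultiChannelRecording

    cols = [
        denoise(recording.values[:, j], spec, wavelet_name, n_levels, mode)
        for j in range(recording.n_channels)
    ]
    return MultiChannelRecording(
        np.column_stack(cols), recording.sampling_rate, list(recording.channel_names)
    )


def snr_db(reference, estimate) -> float:
    """10 log10( sum(ref^2) / sum((ref - est)^2) ); +inf for a zero residual."""
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("reference and estimate must have equal length")
    p_ref = float(np.sum(ref**2))
    if p_ref == 0:
        raise ValueError("reference has zero power")
    p_res = float(np.sum((ref - est) ** 2))
    if p_res == 0:
        return math.inf
    return 10.0 * math.log10(p_ref / p_res)
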