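"""Haar maximum-overlap discrete wavelet transform (MODWT) of a single chromosome.

The MODWT is the non-decimated wavelet transform: one coefficient per grid position
per scale.  With circular (periodic) filtering and the maximum-overlap normalization
used here — level-``j`` Haar taps equal to ``+2**-j`` for the first ``2**(j-1)``
positions and ``-2**-j`` for the next ``2**(j-1)`` — the per-level wavelet variances
plus the scaling variance sum *exactly* to the population variance of the signal.
That exact additivity is the property the genome-wide decompositions are built on,
and is why circular filtering and the divide-by-L variance convention are the only
options offered.

Coefficients are computed with cumulative window sums rather than FFTs so that a
constant signal yields exactly zero wavelet coefficients at every level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .signals import EvenSignal

__all__ = [
    "HaarFilter",
    "haar_filter",
    "scaling_filter",
    "WaveletCoefficients",
    "modwt",
    "modwt_brute_force",
    "ChromSpectrum",
    "wavelet_variance",
]


@dataclass(frozen=True)
class HaarFilter:
    """Level-``j`` maximum-overlap Haar wavelet filter.

    ``taps`` has length ``2**j``: the first half equals ``+2**-j`` and the second
    half ``-2**-j``, so the taps sum to zero and their energy is ``2**-j``.
    ``scale_label`` is lambda_j = ``2**(j-1) * resolution_d``, the length of each
    constant stretch.
    """

    level_j: int
    taps: np.ndarray
    scale_label: float


def haar_filter(level_j: int, resolution_d: float = 1.0) -> HaarFilter:
    """Return the level-``j`` Haar MODWT wavelet filter."""
    if not isinstance(level_j, (int, np.integer)) or level_j < 1:
        raise ValueError(f"wavelet level must be a positive integer, got {level_j!r}")
    half = 2 ** (level_j - 1)
    amp = 2.0 ** (-level_j)
    taps = np.concatenate([np.full(half, amp), np.full(half, -amp)])
    return HaarFilter(int(level_j), taps, half * resolution_d)


def scaling_filter(level_j: int) -> np.ndarray:
    """All-positive averaging filter at level ``j``: ``2**j`` taps of ``2**-j``."""
    if not isinstance(level_j, (int, np.integer)) or level_j < 1:
        raise ValueError(f"wavelet level must be a positive integer, got {level_j!r}")
    return np.full(2 ** level_j, 2.0 ** (-level_j))


@dataclass
class WaveletCoefficients:
    """MODWT wavelet coefficients for levels ``1..max_level`` plus scaling
    coefficients at ``max_level``, for one chromosome.

    ``boundary[j]`` flags the coefficients whose circular filter wrapped around the
    chromosome end (the first ``2**j - 1`` positions).
    """

    chrom_id: str
    max_level: int
    resolution_d: float
    wavelet: Dict[int, np.ndarray]
    scaling: np.ndarray
    boundary: Dict[int, np.ndarray] = field(repr=False)
    signal_mean: float = 0.0

    @property
    def n(self) -> int:
        return self.scaling.size


def _half_window_sums(x: np.ndarray, w: int) -> np.ndarray:
    """Circular sliding sums of ``w`` consecutive values.

    Returns ``S`` of length ``L + w`` with ``S[i] = sum(ext[i:i+w])`` where ``ext``
    prepends the last ``2w - 1`` values of ``x`` (requires ``2w <= L``).
    """
    L = x.size
    ext = np.concatenate([x[L - (2 * w - 1):], x])
    return np.lib.stride_tricks.sliding_window_view(ext, w).sum(axis=-1)


def modwt(signal: EvenSignal, max_level: Optional[int] = None) -> WaveletCoefficients:
    """Haar MODWT of ``signal`` under circular boundary conditions.

    The coefficient at level ``j``, position ``t`` is
    ``w[j, t] = sum_l taps_l * x[(t - l) mod L]``; scaling coefficients at the
    maximum level use the all-positive averaging filter.

    Raises
    ------
    ValueError
        If ``2**max_level > L`` (filter support does not fit the chromosome).
    """
    x = signal.values
    L = x.size
    if max_level is None:
        max_level = signal.max_level
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    if 2 ** max_level > L:
        raise ValueError(
            f"level {max_level} needs filter support {2 ** max_level} but chromosome "
            f"{signal.chrom_id!r} has only {L} grid points"
        )
    wav: Dict[int, np.ndarray] = {}
    bnd: Dict[int, np.ndarray] = {}
    S = None
    for j in range(1, max_level + 1):
        w = 2 ** (j - 1)
        S = _half_window_sums(x, w)
        # window ext[t:t+2w] holds positions (t-2w+1..t); taps are + on the later
        # half (positions t-w+1..t) and - on the earlier half.
        wav[j] = (S[w:] - S[:L]) * 2.0 ** (-j)
        flags = np.zeros(L, dtype=bool)
        flags[: 2 ** j - 1] = True
        bnd[j] = flags
    scal = (S[:L] + S[2 ** (max_level - 1):]) * 2.0 ** (-max_level)
    return WaveletCoefficients(
        chrom_id=signal.chrom_id,
        max_level=max_level,
        resolution_d=signal.resolution_d,
        wavelet=wav,
        scaling=scal,
        boundary=bnd,
        signal_mean=float(x.mean()),
    )


def modwt_brute_force(signal: EvenSignal, level_j: int, position_t: int) -> float:
    """Independent oracle: the MODWT coefficient at ``(level_j, position_t)``
    evaluated literally as the dot product of the signal with an explicitly
    constructed, circularly wrapped wavelet vector."""
    x = signal.values
    L = x.size
    if 2 ** level_j > L:
        raise ValueError(
            f"level {level_j} needs filter support {2 ** level_j} but chromosome "
            f"{signal.chrom_id!r} has only {L} grid points"
        )
    filt = haar_filter(level_j)
    psi = np.zeros(L)
    for l, tap in enumerate(filt.taps):
        psi[(position_t - l) % L] += tap
    return float(psi @ x)


@dataclass
class ChromSpectrum:
    """Per-level wavelet variances and the scaling variance of one chromosome."""

    levels: Dict[int, float]
    scaling_variance: float

    @property
    def total(self) -> float:
        return sum(self.levels.values()) + self.scaling_variance


def wavelet_variance(
    coeffs: WaveletCoefficients,
    signal_mean: Optional[float] = None,
    drop_boundary: bool = False,
) -> ChromSpectrum:
    """Per-level wavelet variances and the scaling variance.

    The level-``j`` wavelet variance is the mean of squared coefficients over all
    ``L`` positions (the boundary-inclusive estimator, under which the variance
    decomposition is exactly additive).  With ``drop_boundary=True`` the mean
    excludes wrapped coefficients (the boundary-excluding alternative; additivity
    then holds only approximately).  The scaling variance is
    ``mean(v**2) - signal_mean**2`` and is non-negative because the scaling
    coefficients average to the signal mean.
    """
    if signal_mean is None:
        signal_mean = coeffs.signal_mean
    levels: Dict[int, float] = {}
    for j, w in coeffs.wavelet.items():
        if drop_boundary:
            keep = ~coeffs.boundary[j]
            levels[j] = float(np.mean(w[keep] ** 2)) if keep.any() else float("nan")
        else:
            levels[j] = float(np.mean(w * w))
    v = coeffs.scaling
    scal = float(np.mean(v * v)) - float(signal_mean) ** 2
    if -1e-12 < scal < 0.0:  # rounding only; the estimator is non-negative
        scal = 0.0
    return ChromSpectrum(levels=levels, scaling_variance=scal)
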