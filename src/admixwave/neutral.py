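"""Neutral-theory expectations for ancestry signals after a single admixture pulse.

Model: two populations mix once, ``t`` generations ago, in proportions ``alpha``
and ``1 - alpha``, followed by closed random mating with *no genetic drift* (an
effectively infinite population).  Without drift, two lineages never coalesce, so
the expected product of ancestry states at two loci depends only on whether they
are co-inherited: on the same haplotype the loci share a founder unless a
recombination (rate ``r`` per generation) separated them at some point in the
``t`` generations, giving

    E[x(l) x(l')] = alpha * exp(-r t) + alpha**2 * (1 - exp(-r t))

while on different haplotypes the product is simply ``alpha**2``.  The covariance
of the *sample mean* ancestry across ``n`` independent haplotypes is then
``alpha (1 - alpha) exp(-r t) / n``.

Substituting this stationary covariance into the squared-coefficient double sum
of the Haar MODWT yields the expected wavelet power spectrum of mean ancestry in
closed form, including the circular wrap of boundary coefficients so that the
expectation matches the circular-filtering estimator exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Union

import numpy as np

from .modwt import haar_filter, scaling_filter

__all__ = ["PulseModel"]


@dataclass
class PulseModel:
    """Single admixture pulse without drift.

    Parameters
    ----------
    alpha : float
        Admixture proportion, in (0, 1).
    t_gen : float
        Generations since the pulse, >= 0.
    n_hap : int
        Number of sampled haplotypes averaged into the mean-ancestry signal.
    """

    alpha: float
    t_gen: float
    n_hap: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.t_gen < 0:
            raise ValueError("t_gen must be >= 0")
        if self.n_hap < 1:
            raise ValueError("n_hap must be >= 1")

    # -- two-locus moments ---------------------------------------------------

    def expected_ancestry_product(self, r, same_haplotype: bool = True):
        """Expected product of ancestry states at two loci separated by
        per-generation recombination rate ``r``."""
        r = np.asarray(r, dtype=float)
        if np.any(r < 0):
            raise ValueError("recombination rate must be >= 0")
        a = self.alpha
        if not same_haplotype:
            out = np.full_like(r, a * a)
        else:
            e = np.exp(-r * self.t_gen)
            out = a * e + a * a * (1.0 - e)
        return float(out) if out.ndim == 0 else out

    def mean_ancestry_covariance(self, r):
        """Covariance of the sample mean ancestry at two loci separated by
        per-generation recombination rate ``r``:
        ``alpha (1 - alpha) exp(-r t) / n`` (at r = 0 the Bernoulli variance
        over ``n`` haplotypes)."""
        r = np.asarray(r, dtype=float)
        if np.any(r < 0):
            raise ValueError("recombination rate must be >= 0")
        a = self.alpha
        out = a * (1.0 - a) * np.exp(-r * self.t_gen) / self.n_hap
        return float(out) if out.ndim == 0 else out

    # -- expected power spectrum ---------------------------------------------

    def _rate(self, k_bins: np.ndarray, d: float, recomb_model: str) -> np.ndarray:
        """Per-generation recombination rate between grid points ``k`` bins apart."""
        m = k_bins * d
        if recomb_model == "distance":
            return m
        if recomb_model == "haldane":
            return 0.5 * (1.0 - np.exp(-2.0 * m))
        raise ValueError("recomb_model must be 'distance' or 'haldane'")

    def expected_power_spectrum(
        self,
        n_bins: int,
        resolution_d: float,
        levels: Optional[Sequence[int]] = None,
        include_scaling: bool = False,
        recomb_model: str = "distance",
        covariance_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    ) -> Dict[Union[int, str], float]:
        """Expected per-level wavelet variance of mean ancestry.

        Parameters
        ----------
        n_bins : int
            Chromosome length L in grid points.
        resolution_d : float
            Grid spacing in Morgans; the recombination rate between neighbours
            is taken as the map distance (or its Haldane transform).
        levels : sequence of int, optional
            Levels to evaluate; defaults to ``1..floor(log2 L)``.
        include_scaling : bool
            Also return the expected scaling variance under key ``"scaling"``.
        covariance_fn : callable, optional
            Plug-in two-locus covariance of the mean ancestry as a function of
            the per-generation recombination rate array; replaces the no-drift
            closed form (e.g. a Monte-Carlo or drift-aware covariance).

        Returns
        -------
        dict
            Level -> expected wavelet variance (all values >= 0), plus
            ``"scaling"`` when requested.
        """
        L = int(n_bins)
        if L < 2:
            raise ValueError("n_bins must be >= 2")
        Jmax = int(math.floor(math.log2(L)))
        if levels is None:
            levels = range(1, Jmax + 1)
        levels = [int(j) for j in levels]
        if any(j < 1 or j > Jmax for j in levels):
            raise ValueError(f"levels must lie in 1..{Jmax} for L={L}")
        cov = covariance_fn or (lambda r: self.mean_ancestry_covariance(r))
        d = float(resolution_d)

        # covariance at all circular lags 0..L-1 (wrapped filters see L - k)
        kfull = np.arange(L)
        Cfull = np.asarray(cov(self._rate(kfull, d, recomb_model)), dtype=float)

        def wrapped_mean_cov(k: np.ndarray) -> np.ndarray:
            # average genomic distance over the L circular placements of a lag-k
            # tap pair: distance k for L-k placements, L-k for the remaining k
            return ((L - k) * Cfull[k] + k * Cfull[(L - k) % L]) / L

        out: Dict[Union[int, str], float] = {}
        for j in sorted(set(levels)):
            taps = haar_filter(j).taps
            acov = np.correlate(taps, taps, mode="full")[taps.size - 1:]
            k = np.arange(taps.size)
            cbar = wrapped_mean_cov(k)
            val = float(acov[0] * cbar[0] + 2.0 * np.sum(acov[1:] * cbar[1:]))
            out[j] = max(val, 0.0)
        if include_scaling:
            J = max(levels)
            g = scaling_filter(J)
            gcov = np.correlate(g, g, mode="full")[g.size - 1:]
            k = np.arange(g.size)
            cbar = wrapped_mean_cov(k)
            e_sq = float(gcov[0] * cbar[0] + 2.0 * np.sum(gcov[1:] * cbar[1:]))
            ks = np.arange(1, L)
            e_meansq = (L * Cfull[0] + 2.0 * np.sum((L - ks) * Cfull[ks])) / (L * L)
            out["scaling"] = max(e_sq - e_meansq, 0.0)
        return out
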