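"""Preparation of ancestry and recombination signals for wavelet analysis.

Converts heterogeneous inputs — unevenly spaced ancestry calls, diploid genotype
posteriors, BED-style introgressed-fragment calls, LD-based recombination maps —
into evenly spaced :class:`~admixwave.signals.EvenSignal` values on a physical
(bp) or genetic (Morgan) grid.

Coordinate conventions: input map and site positions are 1-based bp (standard
map-file convention); grid windows are 0-based half-open and grid positions are
window midpoints, which makes overlap arithmetic with BED fragments unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .signals import GENETIC, PHYSICAL, EvenSignal, GenomeSignal

__all__ = [
    "RecombMap",
    "diploid_dosage",
    "threshold_posteriors",
    "build_grid",
    "interpolate_to_grid",
    "fragments_to_windows",
    "prepare_ld_map",
    "convert_coordinates",
    "log_transform_rates",
    "recomb_rate_signal",
    "physical_to_genetic_grid",
]


@dataclass
class RecombMap:
    """Monotone correspondence between physical (bp) and genetic (Morgan)
    coordinates along one chromosome.

    ``pos_bp`` are 1-based anchor positions (strictly increasing) and ``gpos``
    the cumulative genetic position in Morgans (non-decreasing) at each anchor.
    """

    chrom_id: str
    pos_bp: np.ndarray
    gpos: np.ndarray

    def __post_init__(self) -> None:
        self.pos_bp = np.asarray(self.pos_bp, dtype=float)
        self.gpos = np.asarray(self.gpos, dtype=float)
        if self.pos_bp.size < 2:
            raise ValueError(f"map for {self.chrom_id!r} needs >= 2 anchors")
        if self.pos_bp.size != self.gpos.size:
            raise ValueError("pos_bp and gpos must have equal length")
        if np.any(np.diff(self.pos_bp) <= 0):
            raise ValueError(f"anchor bp positions not strictly increasing in {self.chrom_id!r}")
        if np.any(np.diff(self.gpos) < 0):
            bad = int(np.flatnonzero(np.diff(self.gpos) < 0)[0])
            raise ValueError(
                f"genetic positions decrease at bp {self.pos_bp[bad + 1]:.0f} in {self.chrom_id!r}"
            )

    @classmethod
    def uniform(cls, chrom_id: str, length_bp: float, total_morgans: float) -> "RecombMap":
        return cls(chrom_id, np.array([1.0, float(length_bp)]),
                   np.array([0.0, float(total_morgans)]))

    @property
    def length_bp(self) -> float:
        return float(self.pos_bp[-1])

    @property
    def genetic_length(self) -> float:
        return float(self.gpos[-1] - self.gpos[0])

    def rates(self) -> np.ndarray:
        """Per-interval recombination rate in Morgans/bp."""
        return np.diff(self.gpos) / np.diff(self.pos_bp)

    def rate_at(self, pos_bp) -> np.ndarray:
        """Local rate (Morgans/bp) of the anchor interval containing each position."""
        pos = np.asarray(pos_bp, dtype=float)
        idx = np.clip(np.searchsorted(self.pos_bp, pos, side="right") - 1,
                      0, self.pos_bp.size - 2)
        return self.rates()[idx]

    def bp_to_morgans(self, positions) -> np.ndarray:
        return convert_coordinates(self, positions, "bp_to_morgans")

    def morgans_to_bp(self, positions) -> np.ndarray:
        return convert_coordinates(self, positions, "morgans_to_bp")


def convert_coordinates(map: RecombMap, positions, direction: str) -> np.ndarray:
    """Piecewise-linear conversion along map anchors; monotone non-decreasing.

    Positions outside the map span are clamped to the ends with a warning.
    """
    pos = np.atleast_1d(np.asarray(positions, dtype=float))
    if direction == "bp_to_morgans":
        xp, fp = map.pos_bp, map.gpos
    elif direction == "morgans_to_bp":
        xp, fp = map.gpos, map.pos_bp
    else:
        raise ValueError("direction must be 'bp_to_morgans' or 'morgans_to_bp'")
    if np.any(pos < xp[0]) or np.any(pos > xp[-1]):
        warnings.warn(
            f"positions outside the span of map {map.chrom_id!r} were clamped",
            stacklevel=2,
        )
    out = np.interp(pos, xp, fp)
    return out if np.ndim(positions) else out


def diploid_dosage(p_AA, p_Aa, p_aa):
    """Expected frequency of the A allele from diploid genotype posteriors,
    ``P(AA) + 0.5 * P(Aa)``."""
    p_AA = np.asarray(p_AA, dtype=float)
    p_Aa = np.asarray(p_Aa, dtype=float)
    p_aa = np.asarray(p_aa, dtype=float)
    s = p_AA + p_Aa + p_aa
    if np.any(np.abs(s - 1.0) > 1e-3):
        raise ValueError("genotype posteriors must sum to 1 (tolerance 1e-3)")
    out = p_AA + 0.5 * p_Aa
    return float(out) if out.ndim == 0 else out


def threshold_posteriors(values, cutoff: float):
    """Binary calls: 1 where the posterior exceeds ``cutoff``, else 0."""
    v = np.asarray(values, dtype=float)
    out = (v > cutoff).astype(float)
    return float(out) if out.ndim == 0 else out


def build_grid(
    span: Optional[float] = None,
    resolution_d: float = 1.0,
    map_units: str = PHYSICAL,
    recomb_map: Optional[RecombMap] = None,
) -> np.ndarray:
    """Evenly spaced window-midpoint positions covering a chromosome.

    The grid has ``floor(span / resolution_d)`` points at ``(i + 0.5) * d``.
    For a genetic grid a :class:`RecombMap` is required (it supplies the span
    when ``span`` is omitted and anchors the grid to physical coordinates).
    """
    if map_units == GENETIC:
        if recomb_map is None:
            raise ValueError("a RecombMap is required for a genetic grid")
        if span is None:
            span = recomb_map.genetic_length
    elif span is None:
        if recomb_map is None:
            raise ValueError("span or recomb_map required")
        span = recomb_map.length_bp
    if span <= 0:
        raise ValueError("span must be positive")
    n = int(np.floor(span / resolution_d))
    if n < 1:
        raise ValueError("resolution is larger than the chromosome span")
    return (np.arange(n) + 0.5) * resolution_d


def interpolate_to_grid(positions, values, grid) -> np.ndarray:
    """Linear interpolation of site values onto grid positions, with constant
    extrapolation beyond the first/last site."""
    pos = np.asarray(positions, dtype=float)
    val = np.asarray(values, dtype=float)
    if pos.size < 2:
        raise ValueError("need at least 2 sites per chromosome to interpolate")
    if np.any(np.diff(pos) < 0):
        raise ValueError("site positions must be sorted")
    return np.interp(np.asarray(grid, dtype=float), pos, val)


def fragments_to_windows(starts, ends, freqs, grid, resolution_d: float) -> np.ndarray:
    """Coverage-weighted window frequencies from BED-style fragments.

    Each window's value is the sum over fragments of
    ``frequency * (overlap bp / window bp)``; fragments are 0-based half-open
    and may overlap.  Windows with no fragments get 0.
    """
    starts = np.atleast_1d(np.asarray(starts, dtype=float))
    ends = np.atleast_1d(np.asarray(ends, dtype=float))
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(starts >= ends):
        raise ValueError("fragments must have start < end")
    grid = np.asarray(grid, dtype=float)
    d = float(resolution_d)
    nwin = grid.size
    out = np.zeros(nwin)
    for s, e, f in zip(starts, ends, freqs):
        w0 = max(int(np.floor(s / d)), 0)
        w1 = min(int(np.ceil(e / d)), nwin)
        if w1 <= w0:
            continue
        widx = np.arange(w0, w1)
        lo = np.maximum(s, widx * d)
        hi = np.minimum(e, (widx + 1) * d)
        out[widx] += f * (hi - lo) / d
    return out


def prepare_ld_map(
    ld_maps: Mapping[str, Tuple[Sequence[float], Sequence[float]]],
    truncation_cutoff: float,
    reference_lengths: Mapping[str, float],
) -> Tuple[Dict[str, RecombMap], float]:
    """Calibrate an LD-based map (per-interval ``2*Ne*r`` values) to Morgans.

    Each chromosome is given as ``(anchor_pos_bp, interval_values)`` with one
    value per interval between consecutive anchors, in units of ``2*Ne*r`` per
    interval.  Values are capped at ``truncation_cutoff``; the cumulative capped
    lengths per chromosome are regressed through the origin on the reference
    genetic lengths (Morgans), and the slope — an estimate of ``2*Ne`` — divides
    the whole map.

    Returns the calibrated maps and the ``2*Ne`` estimate.
    """
    if not truncation_cutoff > 0:
        raise ValueError("truncation_cutoff must be positive")
    common = [c for c in ld_maps if c in reference_lengths]
    if len(common) < 2:
        raise ValueError("reference lengths must cover >= 2 chromosomes")
    ld_len = {}
    capped: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for cid, (pos, vals) in ld_maps.items():
        pos = np.asarray(pos, dtype=float)
        vals = np.minimum(np.asarray(vals, dtype=float), truncation_cutoff)
        if vals.size != pos.size - 1:
            raise ValueError(f"chromosome {cid!r}: need one interval value per anchor gap")
        cum = np.concatenate([[0.0], np.cumsum(vals)])
        capped[cid] = (pos, cum)
        ld_len[cid] = float(cum[-1])
    ref = np.array([reference_lengths[c] for c in common])
    ld = np.array([ld_len[c] for c in common])
    denom = float(np.sum(ref * ref))
    if denom == 0:
        raise ValueError("zero-variance regression input (all reference lengths zero)")
    slope = float(np.sum(ref * ld)) / denom
    if slope <= 0:
        raise ValueError("non-positive regression slope; cannot calibrate map")
    maps = {
        cid: RecombMap(cid, pos, cum / slope) for cid, (pos, cum) in capped.items()
    }
    return maps, slope


def log_transform_rates(rates, base: float = 10.0) -> np.ndarray:
    """Log-transform recombination rates, flooring non-positive values at the
    smallest positive rate present."""
    r = np.asarray(rates, dtype=float).copy()
    pos = r[r > 0]
    if pos.size == 0:
        raise ValueError("no positive rates to log-transform")
    r[r <= 0] = pos.min()
    return np.log(r) / np.log(base)


def physical_to_genetic_grid(
    g: GenomeSignal,
    maps: Mapping[str, RecombMap],
    resolution_d: float,
) -> GenomeSignal:
    """Re-express physically gridded signals on an even genetic grid by linear
    interpolation.

    Measurements taken at positions evenly spaced in bp are carried to their
    genetic coordinates through the map and linearly interpolated onto
    midpoints evenly spaced in Morgans.  This mirrors the standard processing
    for genetic-map analyses of physically sampled data; note that in
    high-recombination regions (physical sampling genetically sparse) the
    interpolation smooths fine-genetic-scale variation.
    """
    if g.map_units != PHYSICAL:
        raise ValueError("input signals must be on a physical grid")
    sigs = []
    for sig in g:
        m = maps[sig.chrom_id]
        mid_bp = (np.arange(sig.n) + 0.5) * sig.resolution_d
        gpos = m.bp_to_morgans(np.clip(mid_bp, m.pos_bp[0], m.pos_bp[-1]))
        grid = build_grid(resolution_d=resolution_d, map_units=GENETIC, recomb_map=m)
        sigs.append(EvenSignal(sig.chrom_id, np.interp(grid, gpos, sig.values),
                               resolution_d, GENETIC))
    return GenomeSignal(sigs)


def recomb_rate_signal(
    maps: Mapping[str, RecombMap],
    resolution_d: float,
    map_units: str = PHYSICAL,
    log10: bool = False,
) -> GenomeSignal:
    """Local recombination rate (cM/Mb) evaluated at grid midpoints.

    On a genetic grid the midpoints are laid out in Morgans and converted to bp
    through the map before the local rate is read off.
    """
    sigs = []
    for cid, m in maps.items():
        grid = build_grid(resolution_d=resolution_d, map_units=map_units, recomb_map=m)
        bp = m.morgans_to_bp(grid) if map_units == GENETIC else grid
        rate = m.rate_at(bp) * 1e8  # Morgans/bp -> cM/Mb
        if log10:
            rate = log_transform_rates(rate)
        sigs.append(EvenSignal(cid, rate, resolution_d, map_units))
    return GenomeSignal(sigs)
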