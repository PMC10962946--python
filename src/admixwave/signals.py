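"""Evenly spaced genomic signals and genome-wide signal collections.

An :class:`EvenSignal` holds a signal sampled at evenly spaced positions along one
contiguous chromosome, on either a physical (bp) or genetic (Morgan) grid.  It is the
object every wavelet transform consumes.  A :class:`GenomeSignal` bundles one
``EvenSignal`` per chromosome, all sharing grid resolution and map units, and carries
the chromosome-length weights used for genome-wide averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Mapping, Sequence

import numpy as np

PHYSICAL = "physical"
GENETIC = "genetic"
_UNITS = (PHYSICAL, GENETIC)


@dataclass
class EvenSignal:
    """A signal sampled at evenly spaced positions along one chromosome.

    Parameters
    ----------
    chrom_id : str
        Chromosome label.
    values : array-like of float
        Signal values ``x(l)``, ``l = 0..L-1``, at consecutive grid midpoints.
    resolution_d : float
        Grid spacing: base pairs on a physical map, Morgans on a genetic map.
    map_units : {"physical", "genetic"}
        Which coordinate system the grid lives on.
    """

    chrom_id: str
    values: np.ndarray
    resolution_d: float
    map_units: str = PHYSICAL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signal values must be one-dimensional")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in signal for chromosome {self.chrom_id!r}")
        if not self.resolution_d > 0:
            raise ValueError("resolution_d must be positive")
        if self.map_units not in _UNITS:
            raise ValueError(f"map_units must be one of {_UNITS}, got {self.map_units!r}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        """Number of grid points L."""
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def population_variance(self) -> float:
        """Divide-by-L variance; the convention under which the wavelet
        decomposition is exactly additive."""
        v = self.values
        return float(np.mean(v * v) - float(v.mean()) ** 2)

    @property
    def max_level(self) -> int:
        """Largest wavelet level J whose filter support ``2**J`` fits in L."""
        if self.n < 2:
            raise ValueError(
                f"chromosome {self.chrom_id!r} has {self.n} grid points; need >= 2"
            )
        return int(np.floor(np.log2(self.n)))

    def scale_of_level(self, level_j: int) -> float:
        """Scale label lambda_j = 2**(j-1) * resolution_d (length of each constant
        stretch of the Haar wavelet; the filter support is twice this)."""
        return 2.0 ** (level_j - 1) * self.resolution_d


class GenomeSignal:
    """A set of per-chromosome :class:`EvenSignal` objects sharing one grid.

    Chromosome weights for genome-wide averages are the number of grid points
    (chromosome length in grid units).
    """

    def __init__(self, chromosomes: Iterable[EvenSignal]):
        chroms = list(chromosomes)
        if not chroms:
            raise ValueError("GenomeSignal needs at least one chromosome")
        ids = [c.chrom_id for c in chroms]
        if len(set(ids)) != len(ids):
            raise ValueError("chromosome ids must be unique")
        res = {c.resolution_d for c in chroms}
        units = {c.map_units for c in chroms}
        if len(res) != 1 or len(units) != 1:
            raise ValueError("all chromosomes must share resolution_d and map_units")
        self._chroms: Dict[str, EvenSignal] = {c.chrom_id: c for c in chroms}

    @classmethod
    def from_arrays(
        cls,
        values: Mapping[str, Sequence[float]],
        resolution_d: float,
        map_units: str = PHYSICAL,
    ) -> "GenomeSignal":
        return cls(
            EvenSignal(cid, np.asarray(v, dtype=float), resolution_d, map_units)
            for cid, v in values.items()
        )

    def __iter__(self) -> Iterator[EvenSignal]:
        return iter(self._chroms.values())

    def __len__(self) -> int:
        return len(self._chroms)

    def __getitem__(self, chrom_id: str) -> EvenSignal:
        return self._chroms[chrom_id]

    @property
    def chrom_ids(self) -> list:
        return list(self._chroms)

    @property
    def resolution_d(self) -> float:
        return next(iter(self._chroms.values())).resolution_d

    @property
    def map_units(self) -> str:
        return next(iter(self._chroms.values())).map_units

    @property
    def weights(self) -> np.ndarray:
        """Chromosome lengths in grid units (the jackknife block weights)."""
        return np.array([c.n for c in self], dtype=float)

    @property
    def total_n(self) -> int:
        return int(sum(c.n for c in self))

    @property
    def max_level(self) -> int:
        return max(c.max_level for c in self)

    @property
    def chrom_means(self) -> np.ndarray:
        return np.array([c.mean for c in self])

    @property
    def pooled_mean(self) -> float:
        w = self.weights
        return float(np.sum(w * self.chrom_means) / w.sum())

    @property
    def pooled_variance(self) -> float:
        """Population variance of all grid values pooled across chromosomes."""
        v = np.concatenate([c.values for c in self])
        return float(np.mean(v * v) - float(v.mean()) ** 2)

    @property
    def among_chrom_variance(self) -> float:
        """Length-weighted variance of chromosome mean values (the 'chrom' component)."""
        w = self.weights
        m = self.chrom_means
        mbar = np.sum(w * m) / w.sum()
        return float(np.sum(w * (m - mbar) ** 2) / w.sum())

    def subset(self, chrom_ids: Sequence[str]) -> "GenomeSignal":
        return GenomeSignal(self._chroms[cid] for cid in chrom_ids)

    def same_grid_as(self, other: "GenomeSignal") -> bool:
        if self.chrom_ids != other.chrom_ids:
            return False
        if self.resolution_d != other.resolution_d or self.map_units != other.map_units:
            return False
        return all(self[cid].n == other[cid].n for cid in self.chrom_ids)
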