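"""Forward Wright-Fisher simulation of a hybridization pulse with tract-level
ancestry tracking.

The simulator follows a diploid population of ``N`` individuals founded at
generation 0 by an admixture pulse: exactly ``round(2 N alpha)`` of the ``2N``
founding haploid genomes are single full-length introgressed tracts.  Each
subsequent generation draws ``2N`` gametes from diploid parents sampled with
probability proportional to fitness (soft selection); meiosis places a
Poisson(map length) number of crossovers at positions uniform on the genetic
map, with no interference, and chromosomes assort independently.

Ancestry is tracked as tracts: each haplotype is a sorted list of breakpoints
partitioning ``[0, chrom_length_bp)`` into segments alternating between the two
ancestries, so runtime scales with the number of ancestry junctions rather than
the number of loci.

Selection is the linear polygenic hybrid-fitness model: an individual carrying
the introgressed allele at a fraction ``p`` of its selected-locus allele copies
has fitness ``w = 1 - p S`` (or ``1 - (1 - p) S`` in generations where the
direction is reversed to favor introgressed ancestry).  Selected alleles are
read directly off the tract labels — every introgressed tract carries them —
matching a model of alleles fixed between the source populations.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .prep import RecombMap, build_grid
from .signals import GENETIC, PHYSICAL, EvenSignal, GenomeSignal

__all__ = [
    "Haplotype",
    "Demography",
    "SelectionModel",
    "ChromosomeSpec",
    "SimConfig",
    "fitness",
    "meiosis",
    "simulate",
    "SimulationResult",
    "tracts_to_signal",
    "make_scenario",
    "default_genome",
    "sample_pulse_haplotypes",
    "haplotype_values",
]

#: A haplotype is ``(first_label, breakpoints)``: ``first_label`` is the
#: ancestry (0 recipient, 1 introgressed) of the leftmost tract and
#: ``breakpoints`` a strictly increasing list of positions in ``(0, L)`` at
#: which the ancestry flips.
Haplotype = Tuple[int, list]


@dataclass
class Demography:
    """Schedule of diploid population sizes.

    ``epochs`` is a list of ``(gen_start, gen_end, N)`` with inclusive
    generation ranges that must jointly cover every simulated generation.
    """

    epochs: List[Tuple[int, int, int]]

    def __post_init__(self) -> None:
        for g0, g1, N in self.epochs:
            if N < 1:
                raise ValueError("population sizes must be >= 1")
            if g1 < g0:
                raise ValueError("epoch ranges must have gen_end >= gen_start")

    @classmethod
    def constant(cls, n_diploid: int, n_generations: int) -> "Demography":
        return cls([(0, n_generations, n_diploid)])

    def size_at(self, gen: int) -> int:
        for g0, g1, N in self.epochs:
            if g0 <= gen <= g1:
                return N
        raise ValueError(f"demographic schedule does not cover generation {gen}")

    def validate_coverage(self, n_generations: int) -> None:
        for g in range(n_generations + 1):
            self.size_at(g)


@dataclass
class SelectionModel:
    """Polygenic selection against (or for) introgressed ancestry.

    ``loci`` maps chromosome name to selected-locus bp positions; ``s_total``
    is the total selection strength S (F1 fitness is ``1 - S/2``); ``windows``
    is a list of ``(gen_start, gen_end, direction)`` with direction ``+1``
    against introgressed ancestry and ``-1`` favoring it.
    """

    loci: Dict[str, np.ndarray]
    s_total: float
    windows: List[Tuple[int, int, int]] = field(default_factory=lambda: [(1, 10 ** 9, +1)])

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_total <= 1.0:
            raise ValueError("selection strength S must lie in [0, 1]")
        self.loci = {c: np.sort(np.asarray(p, dtype=float)) for c, p in self.loci.items()}
        spans = sorted((g0, g1) for g0, g1, _ in self.windows)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError("selection windows must not overlap")

    @property
    def n_loci(self) -> int:
        return int(sum(p.size for p in self.loci.values()))

    def direction_at(self, gen: int) -> int:
        """+1 / -1 while a window is active, 0 outside all windows."""
        for g0, g1, direction in self.windows:
            if g0 <= gen <= g1:
                return direction
        return 0


@dataclass
class ChromosomeSpec:
    """A simulated chromosome: physical length and recombination map."""

    name: str
    length_bp: float
    recomb_map: RecombMap

    def __post_init__(self) -> None:
        if self.recomb_map.length_bp < self.length_bp:
            raise ValueError(
                f"recombination map for {self.name!r} does not cover the chromosome"
            )

    @property
    def genetic_length(self) -> float:
        return self.recomb_map.genetic_length


@dataclass
class SimConfig:
    """Full configuration of a forward simulation."""

    demography: Demography
    alpha: float
    chromosomes: List[ChromosomeSpec]
    n_generations: int
    selection: Optional[SelectionModel] = None
    snapshot_generations: Tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        self.demography.validate_coverage(self.n_generations)
        if self.selection is not None:
            names = {c.name for c in self.chromosomes}
            for cname, pos in self.selection.loci.items():
                if cname not in names:
                    raise ValueError(f"selected loci on unknown chromosome {cname!r}")
                L = next(c.length_bp for c in self.chromosomes if c.name == cname)
                if pos.size and (pos.min() < 0 or pos.max() > L):
                    raise ValueError(f"selected loci outside chromosome {cname!r}")
        bad = [g for g in self.snapshot_generations if not 0 <= g <= self.n_generations]
        if bad:
            raise ValueError(f"snapshot generations outside the run: {bad}")


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def _label_at(hap: Haplotype, idx_parity: int) -> int:
    return hap[0] ^ idx_parity


def haplotype_values(hap: Haplotype, positions: np.ndarray) -> np.ndarray:
    """Ancestry label of a tract haplotype at each query position."""
    first, breaks = hap
    idx = np.searchsorted(np.asarray(breaks), positions, side="right")
    return (idx & 1) ^ first


def _recombine(h0: Haplotype, h1: Haplotype, xo: Sequence[float], start: int) -> Haplotype:
    """Assemble a gamete alternating between two parental haplotypes at the
    crossover positions ``xo`` (sorted, strictly inside the chromosome)."""
    if not xo:
        return h0 if start == 0 else h1
    parents = (h0, h1)
    out: list = []
    cur = start
    lo = 0.0
    cur_label = -1
    out_first = 0
    n_seg = len(xo)
    c = 0.0
    for si in range(n_seg + 1):
        f, bl = parents[cur]
        i0 = bisect_right(bl, lo)
        if si == n_seg:
            i1 = len(bl)
        else:
            c = xo[si]
            i1 = bisect_left(bl, c)
        entry = f ^ (i0 & 1)
        if cur_label < 0:
            out_first = entry
        elif entry != cur_label:
            out.append(lo)
        cur_label = entry ^ ((i1 - i0) & 1)
        if i1 > i0:
            out.extend(bl[i0:i1])
        cur = 1 - cur
        lo = c
    return (out_first, out)


def _sanitize_crossovers(xs: list, length_bp: float) -> list:
    """Keep sorted crossovers strictly inside the chromosome; coincident
    positions (possible on flat map segments) cancel pairwise."""
    while xs and xs[0] <= 0.0:
        xs.pop(0)
    while xs and xs[-1] >= length_bp:
        xs.pop()
    for a, b in zip(xs, xs[1:]):
        if a == b:
            vals, cnts = np.unique(np.asarray(xs), return_counts=True)
            return vals[cnts % 2 == 1].tolist()
    return xs


def _draw_crossovers(cspec: ChromosomeSpec, k: int, rng: np.random.Generator) -> list:
    """Crossover bp positions for one meiosis: ``k`` uniform genetic positions
    mapped to bp, kept strictly inside the chromosome, cancelling coincident
    pairs (possible on flat map segments)."""
    if k == 0:
        return []
    g = np.sort(rng.random(k)) * cspec.genetic_length + cspec.recomb_map.gpos[0]
    bp = np.interp(g, cspec.recomb_map.gpos, cspec.recomb_map.pos_bp)
    bp = bp[(bp > 0.0) & (bp < cspec.length_bp)]
    if bp.size > 1 and np.any(np.diff(bp) <= 0):
        vals, counts = np.unique(bp, return_counts=True)
        bp = vals[counts % 2 == 1]
    return bp.tolist()


def meiosis(
    parent: Tuple[Haplotype, Haplotype],
    cspec: ChromosomeSpec,
    rng: np.random.Generator,
) -> Haplotype:
    """One meiosis of one chromosome: Poisson(map length) crossovers at
    positions uniform on the genetic map, starting haplotype by fair coin."""
    k = int(rng.poisson(cspec.genetic_length))
    xo = _draw_crossovers(cspec, k, rng)
    start = int(rng.integers(0, 2))
    return _recombine(parent[0], parent[1], xo, start)


def _introgressed_allele_fraction(
    individual: Sequence[Tuple[Haplotype, Haplotype]],
    loci_arrays: Sequence[Optional[np.ndarray]],
    n_allele_copies: int,
) -> float:
    tot = 0
    for (hA, hB), loci in zip(individual, loci_arrays):
        if loci is None or loci.size == 0:
            continue
        for f, b in (hA, hB):
            idx = np.searchsorted(b, loci, side="right")
            tot += int(np.count_nonzero((idx & 1) ^ f))
    return tot / n_allele_copies


def fitness(
    individual: Sequence[Tuple[Haplotype, Haplotype]],
    selection: SelectionModel,
    generation: int,
    chromosome_names: Sequence[str],
) -> float:
    """Fitness of one diploid under the linear hybrid-fitness model.

    ``p`` is the fraction of the individual's selected-locus allele copies
    (both homologs) carrying the introgressed allele; ``w = 1 - p S`` while a
    ``+`` window is active for the individual's own generation,
    ``1 - (1 - p) S`` in a reversed window, 1 outside all windows.  Windows
    index hybrid generations (1 = the F1s), so the founding parental
    generation is never under selection.
    """
    direction = selection.direction_at(generation)
    if direction == 0:
        return 1.0
    loci_arrays = [selection.loci.get(name) for name in chromosome_names]
    n_copies = 2 * selection.n_loci
    if n_copies == 0:
        return 1.0
    p = _introgressed_allele_fraction(individual, loci_arrays, n_copies)
    S = selection.s_total
    return 1.0 - p * S if direction > 0 else 1.0 - (1.0 - p) * S


# ---------------------------------------------------------------------------
# the generation loop
# ---------------------------------------------------------------------------

def _found_population(n_diploid: int, alpha: float, n_chrom: int) -> list:
    """Deterministic pulse: haplotypes 0..k-1 (individual-major order) are
    single full-length introgressed tracts, k = round(2 N alpha)."""
    k = round(2 * n_diploid * alpha)
    pop = []
    for i in range(n_diploid):
        ind = []
        labA = 1 if 2 * i < k else 0
        labB = 1 if 2 * i + 1 < k else 0
        for _ in range(n_chrom):
            ind.append(((labA, []), (labB, [])))
        pop.append(ind)
    return pop


def _next_generation(
    pop: list,
    n_children: int,
    chromosomes: Sequence[ChromosomeSpec],
    rng: np.random.Generator,
    weights: Optional[np.ndarray],
) -> list:
    n_prev = len(pop)
    n_gam = 2 * n_children
    if weights is None:
        pidx = rng.integers(0, n_prev, size=n_gam).tolist()
    else:
        tot = weights.sum()
        p = weights / tot if tot > 0 else None
        pidx = rng.choice(n_prev, size=n_gam, p=p).tolist()
    per_chrom = []
    for cs in chromosomes:
        G = cs.genetic_length
        length_bp = cs.length_bp
        counts = rng.poisson(G, n_gam)
        u = rng.random(int(counts.sum()))
        gpos = cs.recomb_map.gpos
        if gpos.size == 2:  # uniform map: genetic position scales linearly to bp
            bp_all = u * length_bp
        else:
            bp_all = np.interp(u * G + gpos[0], gpos, cs.recomb_map.pos_bp)
        offs = np.concatenate([[0], np.cumsum(counts)]).tolist()
        starts = rng.integers(0, 2, size=n_gam).tolist()
        per_chrom.append((counts.tolist(), bp_all, offs, starts, length_bp))
    children = []
    rec = _recombine
    for i in range(n_children):
        ind = []
        g0 = 2 * i
        g1 = g0 + 1
        ci = 0
        for (counts, bp_all, offs, starts, length_bp) in per_chrom:
            pair = []
            for g in (g0, g1):
                k = counts[g]
                if k:
                    xs = bp_all[offs[g]:offs[g + 1]].tolist()
                    if k > 1:
                        xs.sort()
                        xs = _sanitize_crossovers(xs, length_bp)
                    elif not 0.0 < xs[0] < length_bp:
                        xs = []
                else:
                    xs = []
                hp = pop[pidx[g]][ci]
                pair.append(rec(hp[0], hp[1], xs, starts[g]))
            ind.append((pair[0], pair[1]))
            ci += 1
        children.append(ind)
    return children


@dataclass
class SimulationResult:
    """Snapshots of a forward run, keyed by generation."""

    config: SimConfig
    snapshots: Dict[int, list]

    def ancestry_signal(
        self,
        generation: int,
        resolution_d: float,
        map_units: str = PHYSICAL,
        aggregate: str = "mean",
    ):
        return tracts_to_signal(
            self.snapshots[generation], self.config.chromosomes,
            resolution_d, map_units, aggregate,
        )

    def introgressed_fraction(self, generation: int) -> float:
        """Genome-wide introgressed ancestry proportion (tract-length weighted)."""
        pop = self.snapshots[generation]
        tot = 0.0
        length = sum(c.length_bp for c in self.config.chromosomes)
        for ind in pop:
            for (hA, hB), cs in zip(ind, self.config.chromosomes):
                for f, b in (hA, hB):
                    edges = np.concatenate([[0.0], np.asarray(b), [cs.length_bp]])
                    seg = np.diff(edges)
                    labels = (np.arange(seg.size) & 1) ^ f
                    tot += float(seg[labels == 1].sum())
        return tot / (2 * len(pop) * length)


def simulate(config: SimConfig) -> SimulationResult:
    """Run the forward Wright-Fisher simulation described by ``config``.

    Reproducible: every generation uses an RNG substream derived from
    ``(config.seed, generation)``.  Extinction of either ancestry is allowed.
    """
    chroms = config.chromosomes
    names = [c.name for c in chroms]
    snaps = set(config.snapshot_generations)
    pop = _found_population(config.demography.size_at(0), config.alpha, len(chroms))
    out: Dict[int, list] = {}
    if 0 in snaps:
        out[0] = pop
    sel = config.selection
    loci_arrays = [sel.loci.get(n) for n in names] if sel is not None else None
    n_copies = 2 * sel.n_loci if sel is not None else 0
    for gen in range(1, config.n_generations + 1):
        rng = np.random.default_rng([int(config.seed), gen])
        weights = None
        if sel is not None and n_copies > 0:
            # selection weights the reproducing parents (generation gen - 1);
            # windows start at 1, so the founding parental generation is exempt
            # and a window opening at generation 1 first shapes generation 2,
            # the offspring of the F1 hybrids.
            direction = sel.direction_at(gen - 1)
            if direction != 0:
                S = sel.s_total
                w = np.empty(len(pop))
                for i, ind in enumerate(pop):
                    p = _introgressed_allele_fraction(ind, loci_arrays, n_copies)
                    w[i] = 1.0 - p * S if direction > 0 else 1.0 - (1.0 - p) * S
                weights = w
        pop = _next_generation(pop, config.demography.size_at(gen), chroms, rng, weights)
        if gen in snaps:
            out[gen] = pop
    return SimulationResult(config, out)


# ---------------------------------------------------------------------------
# signals from tracts
# ---------------------------------------------------------------------------

def tracts_to_signal(
    population: list,
    chromosomes: Sequence[ChromosomeSpec],
    resolution_d: float,
    map_units: str = PHYSICAL,
    aggregate: str = "mean",
):
    """Ancestry signal(s) on an even grid from a population snapshot.

    Grid midpoints are laid out on the physical map (bp) or the genetic map
    (Morgans, converted to bp through each chromosome's recombination map); the
    value at a midpoint is the tract label there (per haplotype) or the mean
    over all ``2N`` haplotypes.

    Returns a :class:`GenomeSignal` for ``aggregate="mean"``, or a dict
    ``chrom -> (n_hap, L) array`` for ``aggregate="per-haplotype"``.
    """
    if aggregate not in ("mean", "per-haplotype"):
        raise ValueError("aggregate must be 'mean' or 'per-haplotype'")
    mean_sigs = []
    per_hap: Dict[str, np.ndarray] = {}
    for ci, cs in enumerate(chromosomes):
        if map_units == GENETIC:
            grid = build_grid(resolution_d=resolution_d, map_units=GENETIC,
                              recomb_map=cs.recomb_map)
            pos = cs.recomb_map.morgans_to_bp(grid + cs.recomb_map.gpos[0])
        else:
            grid = build_grid(span=cs.length_bp, resolution_d=resolution_d)
            pos = grid
        rows = []
        for ind in population:
            for hap in ind[ci]:
                rows.append(haplotype_values(hap, pos))
        mat = np.asarray(rows, dtype=float)
        if aggregate == "mean":
            mean_sigs.append(EvenSignal(cs.name, mat.mean(axis=0), resolution_d, map_units))
        else:
            per_hap[cs.name] = mat
    return GenomeSignal(mean_sigs) if aggregate == "mean" else per_hap


# ---------------------------------------------------------------------------
# drift-free sampling (single pulse, effectively infinite population)
# ---------------------------------------------------------------------------

def sample_pulse_haplotypes(
    alpha: float,
    t_gen: float,
    n_hap: int,
    genetic_length: float,
    rng: np.random.Generator,
) -> List[Tuple[int, np.ndarray]]:
    """Sample haplotypes ``t`` generations after a pulse with drift disabled.

    In an effectively infinite population no two lineages coalesce, so each
    sampled haplotype is an independent mosaic: crossover junctions accumulate
    as Poisson(t * map length) uniform points, and every segment descends from
    a distinct founder whose ancestry is an independent Bernoulli(alpha) draw.
    Breakpoints are returned in genetic coordinates (Morgans); adjacent
    same-label segments are merged.
    """
    out = []
    for _ in range(n_hap):
        k = int(rng.poisson(t_gen * genetic_length))
        pos = np.sort(rng.random(k)) * genetic_length
        labels = (rng.random(k + 1) < alpha).astype(int)
        keep = labels[1:] != labels[:-1]
        out.append((int(labels[0]), pos[keep]))
    return out


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------

def default_genome(length_bp: float = 32e6, n_chrom: int = 3,
                   rates_cm_mb: Tuple[float, float] = (5.0, 0.5),
                   jitter: float = 0.05, interval_bp: float = 50e3) -> List[ChromosomeSpec]:
    """Synthetic heterogeneous-recombination genome.

    Each chromosome has a 10-fold broad-scale rate contrast between its two
    halves, crossed smoothly: constant at one rate over the first 40% of the
    chromosome, a linear ramp over the middle 20%, constant at the other rate
    over the last 40% (orientation alternating across chromosomes so that
    chromosome-mean rates are equal).  On top of this profile every
    ``interval_bp`` map interval carries a deterministic multiplicative jitter
    uniform in ``[1 - jitter, 1 + jitter]``.  Real genetic maps vary at fine
    scales everywhere along the chromosome; a hard block boundary instead
    concentrates fine-scale rate power at the one position where broad-scale
    selection signals also step, which confounds fine-scale correlations —
    hence the ramp plus distributed jitter.
    """
    hi, lo = rates_cm_mb
    rng = np.random.default_rng(718_293)  # fixed: the genome is a constant
    chroms = []
    for i in range(n_chrom):
        r0, r1 = (hi, lo) if i % 2 == 0 else (lo, hi)
        n_int = int(round(length_bp / interval_bp))
        edges = np.linspace(0.0, length_bp, n_int + 1)
        edges[0] = 1.0
        mid = 0.5 * (edges[:-1] + edges[1:])
        frac = np.clip((mid / length_bp - 0.4) / 0.2, 0.0, 1.0)
        block = r0 + (r1 - r0) * frac
        rates = block * rng.uniform(1.0 - jitter, 1.0 + jitter, size=n_int)
        gpos = np.concatenate([[0.0], np.cumsum(rates * 1e-8 * np.diff(edges))])
        m = RecombMap(f"chr{i + 1}", edges, gpos)
        chroms.append(ChromosomeSpec(f"chr{i + 1}", length_bp, m))
    return chroms


_SCENARIOS = ("constant", "bottleneck", "early_selection", "late_selection",
              "reversal", "neutral_pulse")


def make_scenario(
    name: str,
    scale: float = 1.0,
    n_generations: int = 1000,
    snapshot_generations: Tuple[int, ...] = (10, 100, 1000),
    seed: int = 0,
) -> SimConfig:
    """Fully specified configuration for a named demographic/selection scenario.

    Baseline parameter values: a 50/50 pulse into a population of 2N = 20,000
    diploid genomes (bottleneck: 2N = 200 for generations 1-10 only), total
    selection strength S = 1 spread over 10,000 loci placed uniformly at
    random; early-only selection acts in generations 1-10, late-onset selection
    begins at generation 500, and the reversal scenario flips direction at
    generation 100 to favor the alternate ancestry.  ``scale`` divides the
    population sizes and locus count for desk-scale runs.
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; options: {', '.join(_SCENARIOS)}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    N_big = max(2, round(10000 / scale))
    N_bottle = max(2, round(100 / scale))
    n_loci = max(10, round(10000 / scale))
    snapshot_generations = tuple(g for g in snapshot_generations if g <= n_generations)
    chroms = default_genome()
    if name == "bottleneck":
        demog = Demography([(0, 0, N_big), (1, min(10, n_generations), N_bottle),
                            (11, max(n_generations, 11), N_big)])
    else:
        demog = Demography.constant(N_big, n_generations)
    selection = None
    if name in ("early_selection", "late_selection", "reversal"):
        rng = np.random.default_rng([seed, 917])
        total_bp = sum(c.length_bp for c in chroms)
        pos = np.sort(rng.random(n_loci)) * total_bp
        loci: Dict[str, np.ndarray] = {}
        off = 0.0
        for c in chroms:
            sel_pos = pos[(pos >= off) & (pos < off + c.length_bp)] - off
            loci[c.name] = sel_pos
            off += c.length_bp
        if name == "early_selection":
            windows = [(1, 10, +1)]
        elif name == "late_selection":
            windows = [(500, n_generations, +1)]
        else:
            windows = [(1, 100, +1), (101, n_generations, -1)]
        selection = SelectionModel(loci=loci, s_total=1.0, windows=windows)
    return SimConfig(
        demography=demog,
        alpha=0.5,
        chromosomes=chroms,
        n_generations=n_generations,
        selection=selection,
        snapshot_generations=snapshot_generations,
        seed=seed,
    )
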