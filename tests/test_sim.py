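"""Tests for the tract-based forward Wright-Fisher simulator."""

import numpy as np
import pytest

from admixwave import (
    ChromosomeSpec,
    Demography,
    RecombMap,
    SelectionModel,
    SimConfig,
    default_genome,
    fitness,
    make_scenario,
    meiosis,
    sample_pulse_haplotypes,
    simulate,
    tracts_to_signal,
)


def one_chrom(G=1.0, L=1e6, name="chr1"):
    return ChromosomeSpec(name, L, RecombMap.uniform(name, L, G))


def f1_individual(n_chrom=1):
    """One haplotype fully introgressed, the other fully recipient: p = 0.5."""
    return [((1, []), (0, [])) for _ in range(n_chrom)]


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def test_f1_fitness_is_half_at_full_strength():
    sel = SelectionModel(loci={"chr1": np.linspace(1e4, 9e5, 100)}, s_total=1.0,
                         windows=[(1, 100, +1)])
    w = fitness(f1_individual(), sel, generation=5, chromosome_names=["chr1"])
    assert w == 0.5


def test_fitness_extremes_and_direction():
    sel = SelectionModel(loci={"chr1": np.linspace(1e4, 9e5, 50)}, s_total=1.0,
                         windows=[(1, 100, +1)])
    pure_recipient = [((0, []), (0, []))]
    pure_introgressed = [((1, []), (1, []))]
    assert fitness(pure_recipient, sel, 5, ["chr1"]) == 1.0
    assert fitness(pure_introgressed, sel, 5, ["chr1"]) == 0.0
    # outside the window fitness is 1 for everyone
    assert fitness(pure_introgressed, sel, 500, ["chr1"]) == 1.0
    # reversed direction favors introgressed ancestry
    rev = SelectionModel(loci=sel.loci, s_total=0.4, windows=[(1, 100, -1)])
    assert fitness(pure_recipient, rev, 5, ["chr1"]) == pytest.approx(0.6)
    assert fitness(pure_introgressed, rev, 5, ["chr1"]) == 1.0


def test_selection_strength_above_one_rejected():
    with pytest.raises(ValueError, match="S"):
        SelectionModel(loci={"chr1": np.array([1.0])}, s_total=1.5)
    with pytest.raises(ValueError, match="overlap"):
        SelectionModel(loci={"chr1": np.array([1.0])}, s_total=0.5,
                       windows=[(1, 10, 1), (5, 20, -1)])


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def test_meiosis_with_zero_map_length_copies_a_parent():
    cs = one_chrom(G=0.0)
    rng = np.random.default_rng(1)
    parent = ((1, [2e5, 7e5]), (0, [5e5]))
    for _ in range(10):
        g = meiosis(parent, cs, rng)
        assert g in parent


def test_meiosis_crossover_count_matches_map_length():
    """On a 1-Morgan chromosome with fully distinct parents, every crossover
    is a visible junction: mean count over many meioses is Poisson(1)."""
    cs = one_chrom(G=1.0)
    rng = np.random.default_rng(7)
    parent = ((1, []), (0, []))
    n = 10_000
    counts = [len(meiosis(parent, cs, rng)[1]) for _ in range(n)]
    se = np.sqrt(1.0 / n)
    assert abs(np.mean(counts) - 1.0) < 3 * se


def test_meiosis_breakpoints_inside_and_alternating():
    cs = one_chrom(G=5.0)
    rng = np.random.default_rng(3)
    pA = (1, [1e5, 4e5, 8e5])
    pB = (0, [3e5, 6e5])
    for _ in range(200):
        f, b = meiosis((pA, pB), cs, rng)
        assert f in (0, 1)
        arr = np.asarray(b)
        if arr.size:
            assert arr.min() > 0 and arr.max() < cs.length_bp
            assert np.all(np.diff(arr) > 0)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def test_founding_pulse_fraction_is_exact():
    cfg = SimConfig(demography=Demography.constant(7, 0), alpha=0.3,
                    chromosomes=[one_chrom()], n_generations=0,
                    snapshot_generations=(0,), seed=1)
    res = simulate(cfg)
    assert res.introgressed_fraction(0) == pytest.approx(round(14 * 0.3) / 14)


def test_neutral_mean_fraction_stays_near_alpha():
    fracs = []
    for rep in range(20):
        cfg = SimConfig(demography=Demography.constant(200, 50), alpha=0.5,
                        chromosomes=[one_chrom(G=1.0)], n_generations=50,
                        snapshot_generations=(50,), seed=3000 + rep)
        fracs.append(simulate(cfg).introgressed_fraction(50))
    drift_sd = np.sqrt(0.25 * (1 - (1 - 1 / 400) ** 50))
    se = drift_sd / np.sqrt(20)
    assert abs(np.mean(fracs) - 0.5) < 3 * se


def test_neutral_drift_variance_matches_wright_fisher():
    """With a near-zero map the genome drifts as one locus: the replicate
    variance of the final fraction follows alpha(1-alpha)(1-(1-1/2N)^t)."""
    reps = 60
    fracs = []
    for rep in range(reps):
        cfg = SimConfig(demography=Demography.constant(50, 10), alpha=0.5,
                        chromosomes=[one_chrom(G=0.01)], n_generations=10,
                        snapshot_generations=(10,), seed=4000 + rep)
        fracs.append(simulate(cfg).introgressed_fraction(10))
    expected = 0.25 * (1 - (1 - 1 / 100) ** 10)
    observed = np.var(fracs)
    se = expected * np.sqrt(2 / (reps - 1))
    assert abs(observed - expected) < 3 * se


def test_selection_removes_introgressed_ancestry():
    wins = 0
    for rep in range(20):
        sel = SelectionModel(loci={"chr1": np.linspace(1e4, 9.9e5, 50)},
                             s_total=1.0, windows=[(1, 10, +1)])
        cfg = SimConfig(demography=Demography.constant(100, 10), alpha=0.5,
                        chromosomes=[one_chrom(G=1.0)], n_generations=10,
                        selection=sel, snapshot_generations=(10,), seed=5000 + rep)
        wins += simulate(cfg).introgressed_fraction(10) < 0.5
    assert wins >= 19


def test_tract_invariants_after_many_generations():
    cfg = SimConfig(demography=Demography.constant(30, 25), alpha=0.5,
                    chromosomes=[one_chrom(G=2.0), one_chrom(G=1.0, name="chr2")],
                    n_generations=25, snapshot_generations=(25,), seed=11)
    pop = simulate(cfg).snapshots[25]
    for ind in pop:
        for (hA, hB), cs in zip(ind, cfg.chromosomes):
            for f, b in (hA, hB):
                assert f in (0, 1)
                arr = np.asarray(b)
                if arr.size:
                    assert 0 < arr.min() and arr.max() < cs.length_bp
                    assert np.all(np.diff(arr) > 0)


def test_simulate_is_reproducible():
    def run(seed):
        cfg = SimConfig(demography=Demography.constant(40, 15), alpha=0.5,
                        chromosomes=[one_chrom(G=1.0)], n_generations=15,
                        snapshot_generations=(15,), seed=seed)
        return simulate(cfg)

    a, b, c = run(9), run(9), run(10)
    assert a.introgressed_fraction(15) == b.introgressed_fraction(15)
    assert a.snapshots[15][0] == b.snapshots[15][0]
    assert a.introgressed_fraction(15) != c.introgressed_fraction(15)


def test_config_validation():
    with pytest.raises(ValueError, match="cover"):
        SimConfig(demography=Demography([(0, 5, 10)]), alpha=0.5,
                  chromosomes=[one_chrom()], n_generations=10)
    with pytest.raises(ValueError, match="snapshot"):
        SimConfig(demography=Demography.constant(10, 5), alpha=0.5,
                  chromosomes=[one_chrom()], n_generations=5,
                  snapshot_generations=(9,))
    with pytest.raises(ValueError, match="unknown chromosome"):
        SimConfig(demography=Demography.constant(10, 5), alpha=0.5,
                  chromosomes=[one_chrom()], n_generations=5,
                  selection=SelectionModel(loci={"nope": np.array([1.0])}, s_total=0.5))


# ---------------------------------------------------------------------------
# signals from tracts
# ---------------------------------------------------------------------------

def test_tracts_to_signal_basic_cases():
    cs = one_chrom(G=1.0, L=1e6)
    full = [[((1, []), (1, []))]]  # one individual, both haplotypes introgressed
    g = tracts_to_signal(full, [cs], 1e5)
    assert np.all(g["chr1"].values == 1.0)
    step = [[((1, [5e5]), (1, [5e5]))]]
    g = tracts_to_signal(step, [cs], 1e5)
    assert g["chr1"].values.tolist() == [1.0] * 5 + [0.0] * 5
    mixed = [[((1, [5e5]), (0, []))]]
    g = tracts_to_signal(mixed, [cs], 1e5)
    assert g["chr1"].values.tolist() == [0.5] * 5 + [0.0] * 5
    per = tracts_to_signal(mixed, [cs], 1e5, aggregate="per-haplotype")
    assert per["chr1"].shape == (2, 10)
    with pytest.raises(ValueError, match="aggregate"):
        tracts_to_signal(mixed, [cs], 1e5, aggregate="median")


def test_tracts_to_signal_on_genetic_grid():
    cs = one_chrom(G=0.5, L=1e6)
    step = [[((1, [5e5]), (1, [5e5]))]]
    g = tracts_to_signal(step, [cs], 2.0**-4, map_units="genetic")
    assert g["chr1"].n == 8
    assert g["chr1"].values.tolist() == [1.0] * 4 + [0.0] * 4


def test_drift_free_junction_accumulation():
    """Ancestry switches accumulate at 2 alpha (1 - alpha) t G per haplotype
    (crossover junctions at rate t G, thinned by the chance the flanking
    founders differ in ancestry)."""
    rng = np.random.default_rng(21)
    t, G, n = 20.0, 2.0, 4000
    haps = sample_pulse_haplotypes(0.5, t, n, G, rng)
    counts = [b.size for _, b in haps]
    expected = 2 * 0.5 * 0.5 * t * G
    se = np.sqrt(expected / n)  # thinned-Poisson SE of the mean
    assert abs(np.mean(counts) - expected) < 3 * se


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def test_make_scenario_parameter_values():
    b = make_scenario("bottleneck")
    assert b.demography.size_at(0) == 10_000      # 2N = 20,000
    assert b.demography.size_at(1) == 100         # 2N = 200 during the bottleneck
    assert b.demography.size_at(10) == 100
    assert b.demography.size_at(11) == 10_000
    c = make_scenario("constant")
    assert all(c.demography.size_at(g) == 10_000 for g in (0, 500, 1000))
    r = make_scenario("reversal")
    assert r.selection is not None and r.selection.s_total == 1.0
    assert r.selection.direction_at(100) == +1
    assert r.selection.direction_at(101) == -1
    e = make_scenario("early_selection")
    assert e.selection.direction_at(10) == +1 and e.selection.direction_at(11) == 0
    late = make_scenario("late_selection")
    assert late.selection.direction_at(499) == 0 and late.selection.direction_at(500) == +1
    assert make_scenario("neutral_pulse").selection is None


def test_make_scenario_scaling_and_errors():
    s = make_scenario("constant", scale=100.0, n_generations=20)
    assert s.demography.size_at(0) == 100
    with pytest.raises(ValueError, match="options"):
        make_scenario("meteor_strike")
    with pytest.raises(ValueError, match="scale"):
        make_scenario("constant", scale=0.0)


def test_default_genome_has_tenfold_block_heterogeneity():
    chroms = default_genome()
    assert len(chroms) == 3
    for cs in chroms:
        rates = cs.recomb_map.rates()
        # block structure: first-half mean and second-half mean differ 10-fold
        half = rates.size // 2
        ratio = rates[:half].mean() / rates[half:].mean()
        assert 5 < ratio < 20 or 5 < 1 / ratio < 20
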