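"""Deterministic fixture datasets for tests and demonstrations.

Everything is generated from a seed at run time: a 3-chromosome toy site table
whose chromosome lengths in grid units are deliberately not powers of two (so a
scaling-variance component exists), a heterogeneous recombination map, and a
pair of small simulated datasets (neutral and selected, S = 1).
"""

from __future__ import annotations

import pathlib

import numpy as np

from . import io
from .sim import _SCENARIOS, make_scenario, simulate

_TOY_SPANS = {"chr1": 1_050_000, "chr2": 850_000, "chr3": 650_000}
_TOY_RESOLUTION = 50_000  # 21 / 17 / 13 grid windows: none a power of two


def generate_fixtures(scenario: str, seed: int, out_dir) -> list:
    """Write the fixture file set for ``scenario`` under ``out_dir``.

    ``scenario`` must be one of the named simulation scenarios; it selects the
    selected-dataset configuration (falling back to early-onset selection for
    neutral scenario names).  Returns the list of files written.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; options: {', '.join(_SCENARIOS)}"
        )
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    rng = np.random.default_rng([seed, 101])

    # toy site table: smooth noisy ancestry-like values at uneven positions
    rows = {"chrom": [], "pos": [], "value": []}
    for cid, span in _TOY_SPANS.items():
        n_sites = int(span // 20_000)
        pos = np.sort(rng.choice(np.arange(1, span, 500), size=n_sites, replace=False))
        base = 0.5 + 0.2 * np.sin(2 * np.pi * pos / span * rng.integers(1, 4))
        vals = np.clip(base + rng.normal(0.0, 0.05, size=pos.size), 0.0, 1.0)
        rows["chrom"] += [cid] * pos.size
        rows["pos"] += pos.tolist()
        rows["value"] += vals.tolist()
    import pandas as pd

    sites = pd.DataFrame(rows)
    p = out / "toy_sites.tsv"
    io.write_site_table(sites, p)
    written.append(p)

    # heterogeneous map over the toy genome: rates alternate 10-fold in blocks
    maps = {}
    from .prep import RecombMap

    for i, (cid, span) in enumerate(_TOY_SPANS.items()):
        edges = np.linspace(1, span, 5)
        hi, lo = 5e-8, 5e-9
        rates = [hi, lo, hi, lo] if i % 2 == 0 else [lo, hi, lo, hi]
        gpos = np.concatenate([[0.0], np.cumsum(np.diff(edges) * rates)])
        maps[cid] = RecombMap(cid, edges, gpos)
    p = out / "toy_map.tsv"
    io.write_recomb_map(maps, p, dialect="hapmap")
    written.append(p)

    # small simulated datasets: neutral and selected (S = 1)
    sel_name = scenario if scenario in ("early_selection", "late_selection", "reversal") \
        else "early_selection"
    sim_map_written = False
    for label, name in (("neutral", "neutral_pulse"), ("selected", sel_name)):
        cfg = make_scenario(name, scale=200.0, n_generations=20,
                            snapshot_generations=(20,), seed=seed)
        if not sim_map_written:
            io.write_recomb_map({c.name: c.recomb_map for c in cfg.chromosomes},
                                out / "sim_genome_map.tsv", dialect="cumulative")
            written.append(out / "sim_genome_map.tsv")
            sim_map_written = True
        if label == "selected" and cfg.selection is not None:
            # ensure the selection window overlaps this short run
            cfg.selection.windows = [(1, 20, +1)]
        res = simulate(cfg)
        pop = res.snapshots[20]
        bed = out / f"{label}_tracts.bed"
        io.write_tract_bed(pop, cfg.chromosomes, bed)
        written.append(bed)
        sig = res.ancestry_signal(20, resolution_d=500_000.0)
        tab = out / f"{label}_ancestry.tsv"
        io.write_site_table(io.genome_to_site_table(sig), tab)
        written.append(tab)
        raw = dict(
            seed=seed,
            scenario=name,
            admixture=dict(alpha=cfg.alpha),
            demography=dict(epochs=[list(e) for e in cfg.demography.epochs]),
            generations=cfg.n_generations,
            snapshots=list(cfg.snapshot_generations),
            selection=None if cfg.selection is None else dict(
                S=cfg.selection.s_total,
                n_loci=cfg.selection.n_loci,
                windows=[list(w) for w in cfg.selection.windows],
            ),
            genome=dict(chromosomes=[
                dict(name=c.name, length_bp=c.length_bp,
                     map=dict(file="sim_genome_map.tsv", dialect="cumulative"))
                for c in cfg.chromosomes
            ]),
            output=dict(resolution=500_000.0, units="physical"),
        )
        cfgp = out / f"{label}_config.yaml"
        io.write_sim_config(raw, cfgp)
        written.append(cfgp)
    return written
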