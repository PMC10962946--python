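"""Readers and writers for the tab-separated formats used throughout.

Conventions: all tables are tab-separated with a header row; floats are
serialized with 12 significant digits so that write/read round-trips are stable;
site-table positions are 1-based (map-file convention) while tract/fragment BED
intervals are 0-based half-open.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .decomposition import (
    TABLE_COLUMNS,
    CorrelationDecompositionResults,
    VarianceDecompositionResults,
)
from .prep import RecombMap, build_grid, diploid_dosage, interpolate_to_grid
from .signals import GENETIC, PHYSICAL, EvenSignal, GenomeSignal
from .sim import (
    ChromosomeSpec,
    Demography,
    SelectionModel,
    SimConfig,
)

FLOAT_FMT = "%.12g"

_POSTERIOR_COLS = ["p_AA", "p_Aa", "p_aa"]


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

def read_site_table(path) -> pd.DataFrame:
    """Read and validate a site table.

    Required columns: ``chrom``, ``pos``; optionally ``gpos``; and either
    ``value`` or the posterior triple ``p_AA``/``p_Aa``/``p_aa``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("chrom", "pos") if c not in df.columns]
    if missing:
        raise ValueError(f"site table {path} is missing required columns: {', '.join(missing)}")
    has_value = "value" in df.columns
    has_post = all(c in df.columns for c in _POSTERIOR_COLS)
    if not (has_value or has_post):
        raise ValueError(
            f"site table {path} needs a 'value' column or posterior columns "
            f"{'/'.join(_POSTERIOR_COLS)}"
        )
    for cid, sub in df.groupby("chrom", sort=False):
        d = np.diff(sub["pos"].to_numpy())
        if np.any(d < 0):
            row = sub.index[int(np.flatnonzero(d < 0)[0]) + 1]
            raise ValueError(
                f"site table {path}: positions not sorted within chromosome {cid!r} "
                f"(first offending row index {row})"
            )
    if has_post:
        s = df[_POSTERIOR_COLS].sum(axis=1).to_numpy()
        bad = np.flatnonzero(np.abs(s - 1.0) > 1e-6)
        if bad.size:
            raise ValueError(
                f"site table {path}: genotype posteriors do not sum to 1 at row {int(bad[0])}"
            )
    return df


def write_site_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def site_table_to_genome(
    df: pd.DataFrame,
    resolution_d: float,
    map_units: str = PHYSICAL,
    maps: Optional[Dict[str, RecombMap]] = None,
    log10_values: bool = False,
) -> GenomeSignal:
    """Interpolate a site table onto an even grid, one chromosome at a time.

    Posterior triples are collapsed to the diploid dosage ``P_AA + P_Aa / 2``
    first.  On a genetic grid, site positions come from the ``gpos`` column or
    are converted through the supplied maps; the chromosome span comes from the
    map when available.  Chromosomes with fewer than two sites are skipped with
    a warning.
    """
    sigs = []
    for cid, sub in df.groupby("chrom", sort=False):
        if "value" in sub.columns:
            vals = sub["value"].to_numpy(dtype=float)
        else:
            vals = diploid_dosage(*(sub[c].to_numpy(dtype=float) for c in _POSTERIOR_COLS))
        if map_units == GENETIC:
            if "gpos" in sub.columns and sub["gpos"].notna().all():
                pos = sub["gpos"].to_numpy(dtype=float)
            elif maps and cid in maps:
                pos = maps[cid].bp_to_morgans(sub["pos"].to_numpy(dtype=float))
            else:
                raise ValueError(
                    f"genetic-grid interpolation needs a gpos column or a map for {cid!r}"
                )
            span = maps[cid].genetic_length if maps and cid in maps else float(pos[-1])
        else:
            pos = sub["pos"].to_numpy(dtype=float)
            span = float(pos[-1])
        if pos.size < 2:
            warnings.warn(f"chromosome {cid!r} has < 2 sites; skipped")
            continue
        grid = build_grid(span=span, resolution_d=resolution_d)
        values = interpolate_to_grid(pos, vals, grid)
        if log10_values:
            from .prep import log_transform_rates

            values = log_transform_rates(values)
        sigs.append(EvenSignal(str(cid), values, resolution_d, map_units))
    if not sigs:
        raise ValueError("no chromosome had enough sites to interpolate")
    return GenomeSignal(sigs)


def genome_to_site_table(g: GenomeSignal) -> pd.DataFrame:
    """Serialize a gridded signal back to the site-table dialect (positions are
    grid midpoints, 1-based on a physical map)."""
    frames = []
    for sig in g:
        pos = (np.arange(sig.n) + 0.5) * sig.resolution_d
        col = "pos" if sig.map_units == PHYSICAL else "gpos"
        d = {"chrom": sig.chrom_id, "pos": pos, "value": sig.values}
        if col == "gpos":
            d = {"chrom": sig.chrom_id, "pos": np.arange(1, sig.n + 1),
                 "gpos": pos, "value": sig.values}
        frames.append(pd.DataFrame(d))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# recombination maps
# ---------------------------------------------------------------------------

def read_recomb_map(path, dialect: str = "hapmap") -> Dict[str, RecombMap]:
    """Read recombination maps.

    ``hapmap`` dialect: columns ``chrom``, ``pos``, ``rate_cM_per_Mb``,
    ``map_cM`` (cumulative cM, converted to Morgans).  ``cumulative`` dialect:
    columns ``chrom``, ``pos``, ``morgans``.
    """
    df = pd.read_csv(path, sep="\t")
    if dialect == "hapmap":
        need = ["chrom", "pos", "rate_cM_per_Mb", "map_cM"]
        gcol, scale = "map_cM", 0.01
    elif dialect == "cumulative":
        need = ["chrom", "pos", "morgans"]
        gcol, scale = "morgans", 1.0
    else:
        raise ValueError("dialect must be 'hapmap' or 'cumulative'")
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"map file {path} is missing columns: {', '.join(missing)}")
    out = {}
    for cid, sub in df.groupby("chrom", sort=False):
        out[str(cid)] = RecombMap(
            str(cid),
            sub["pos"].to_numpy(dtype=float),
            sub[gcol].to_numpy(dtype=float) * scale,
        )
    return out


def write_recomb_map(maps: Dict[str, RecombMap], path, dialect: str = "hapmap") -> None:
    frames = []
    for cid, m in maps.items():
        if dialect == "hapmap":
            rates = np.append(m.rates() * 1e8, 0.0)  # Morgans/bp -> cM/Mb; last row 0
            frames.append(pd.DataFrame({
                "chrom": cid, "pos": m.pos_bp, "rate_cM_per_Mb": rates,
                "map_cM": m.gpos * 100.0,
            }))
        elif dialect == "cumulative":
            frames.append(pd.DataFrame({"chrom": cid, "pos": m.pos_bp, "morgans": m.gpos}))
        else:
            raise ValueError("dialect must be 'hapmap' or 'cumulative'")
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# decomposition tables
# ---------------------------------------------------------------------------

def spectrum_frame(results: VarianceDecompositionResults) -> pd.DataFrame:
    """Stacked magnitude + proportion table in the standard column order."""
    return pd.concat(
        [results.magnitude[TABLE_COLUMNS], results.proportion[TABLE_COLUMNS]],
        ignore_index=True,
    )


def correlation_frame(results: CorrelationDecompositionResults) -> pd.DataFrame:
    """Long-form correlation table in the standard column order: one row per
    component per statistic (rho, weight, contribution) plus a total row."""
    rows = []
    for _, r in results.table.iterrows():
        for stat in ("rho", "weight", "contribution"):
            rows.append(dict(
                component=r["component"], scale_value=r["scale_value"],
                scale_units=r["scale_units"], statistic=stat, estimate=r[stat],
                se=r["se"] if stat == "rho" else float("nan"),
                ci_lo=r["ci_lo"] if stat == "rho" else float("nan"),
                ci_hi=r["ci_hi"] if stat == "rho" else float("nan"),
                n_chrom=r["n_chrom"],
            ))
    rows.append(dict(component="total", scale_value=float("nan"),
                     scale_units=results.table["scale_units"].iloc[0],
                     statistic="correlation", estimate=results.total_correlation,
                     se=float("nan"), ci_lo=float("nan"), ci_hi=float("nan"),
                     n_chrom=len(results.x)))
    return pd.DataFrame(rows)[TABLE_COLUMNS]


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# tract BED
# ---------------------------------------------------------------------------

def write_tract_bed(population, chromosomes: Sequence[ChromosomeSpec], path) -> None:
    """Write a population snapshot as tract intervals: ``chrom``, ``start``,
    ``end`` (0-based half-open bp; breakpoints from map interpolation may be
    fractional), ``individual``, ``haplotype``, ``ancestry``."""
    rows = []
    for i, ind in enumerate(population):
        for (hA, hB), cs in zip(ind, chromosomes):
            for hname, (f, b) in (("A", hA), ("B", hB)):
                edges = np.concatenate([[0.0], np.asarray(b, dtype=float), [cs.length_bp]])
                for k in range(edges.size - 1):
                    rows.append((cs.name, edges[k], edges[k + 1], i, hname, (k & 1) ^ f))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "individual",
                                "haplotype", "ancestry"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_fragment_bed(path) -> pd.DataFrame:
    """BED3+1 fragment calls: chrom, start, end (0-based half-open), freq."""
    df = pd.read_csv(path, sep="\t")
    need = ["chrom", "start", "end", "freq"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"fragment BED {path} is missing columns: {', '.join(missing)}")
    if np.any(df["start"].to_numpy() >= df["end"].to_numpy()):
        raise ValueError(f"fragment BED {path}: fragments must have start < end")
    return df


# ---------------------------------------------------------------------------
# simulation configs (YAML)
# ---------------------------------------------------------------------------

def _chromosomes_from_config(section, base_dir) -> list:
    chroms = []
    for c in section["chromosomes"]:
        name, length = str(c["name"]), float(c["length_bp"])
        m = c.get("map", {})
        if "uniform_cm_per_mb" in m:
            total = float(m["uniform_cm_per_mb"]) * 1e-8 * length
            rmap = RecombMap.uniform(name, length, total)
        elif "file" in m:
            maps = read_recomb_map(base_dir / m["file"], m.get("dialect", "hapmap"))
            rmap = maps[name]
        else:
            raise ValueError(f"chromosome {name!r}: map needs 'uniform_cm_per_mb' or 'file'")
        chroms.append(ChromosomeSpec(name, length, rmap))
    return chroms


def read_sim_config(path) -> Tuple[SimConfig, dict]:
    """Parse a YAML simulation config; returns the config plus output options
    (snapshot grid resolution and units)."""
    import pathlib

    path = pathlib.Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    chroms = _chromosomes_from_config(raw["genome"], path.parent)
    demog = Demography([tuple(e) for e in raw["demography"]["epochs"]])
    seed = int(raw.get("seed", 0))
    selection = None
    if "selection" in raw and raw["selection"]:
        s = raw["selection"]
        if "loci" in s:
            loci = {str(c): np.asarray(v, dtype=float) for c, v in s["loci"].items()}
        else:
            n_loci = int(s["n_loci"])
            rng = np.random.default_rng([seed, 917])
            total = sum(c.length_bp for c in chroms)
            pos = np.sort(rng.random(n_loci)) * total
            loci, off = {}, 0.0
            for c in chroms:
                loci[c.name] = pos[(pos >= off) & (pos < off + c.length_bp)] - off
                off += c.length_bp
        selection = SelectionModel(
            loci=loci, s_total=float(s["S"]),
            windows=[tuple(w) for w in s.get("windows", [(1, 10 ** 9, 1)])],
        )
    cfg = SimConfig(
        demography=demog,
        alpha=float(raw["admixture"]["alpha"]),
        chromosomes=chroms,
        n_generations=int(raw["generations"]),
        selection=selection,
        snapshot_generations=tuple(raw.get("snapshots", [])),
        seed=seed,
    )
    return cfg, dict(raw.get("output", {}))


def write_sim_config(raw: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
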