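"""Genome-wide wavelet variance and correlation decompositions.

Built in the model/results style: construct a model object from one or two
:class:`~admixwave.signals.GenomeSignal` objects, call :meth:`fit`, and read the
estimates, jackknife uncertainties and ``summary()`` off the returned Results
object.

The genome-wide variance decomposition applies the Haar MODWT to each chromosome
separately and combines per-scale variances across chromosomes in two ways, both
weighting by chromosome length in grid units:

* ``magnitude`` — per scale, the average over only those chromosomes on which the
  scale is present (filter support fits), giving the magnitude of the wavelet
  variance at that scale;
* ``proportion`` — per scale, absent chromosomes contribute zero and the weighted
  average is divided by the total genomic variance, so that all components (scales,
  scaling, and the among-chromosome 'chrom' component) sum to one.

The among-chromosome component ('chrom') is the length-weighted variance of
chromosome mean values; by the law of total variance the within-chromosome
decomposition plus 'chrom' recovers the population variance of the pooled signal
exactly.

The correlation decomposition expresses the pooled Pearson correlation between two
signals on the same grid as an exactly additive sum of per-scale contributions
``c_lambda * rho_lambda`` plus scaling and 'chrom' terms, where ``rho_lambda`` is
the pooled correlation of level-``lambda`` wavelet coefficients and ``c_lambda``
is the geometric mean of the two signals' per-scale variance proportions.

Uncertainty comes from a weighted delete-one-chromosome jackknife with blocks
weighted by chromosome grid length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd

from .modwt import modwt, wavelet_variance
from .signals import GenomeSignal

__all__ = [
    "TABLE_COLUMNS",
    "VarianceDecomposition",
    "VarianceDecompositionResults",
    "CorrelationDecomposition",
    "CorrelationDecompositionResults",
    "wavelet_correlation",
    "scale_regression",
    "RegressionResult",
    "jackknife",
]

#: Column order for all tab-separated output tables.
TABLE_COLUMNS = [
    "component",
    "scale_value",
    "scale_units",
    "statistic",
    "estimate",
    "se",
    "ci_lo",
    "ci_hi",
    "n_chrom",
]

_Z95 = 1.96  # normal-approximation multiplier for 95% CIs


# ---------------------------------------------------------------------------
# weighted block jackknife
# ---------------------------------------------------------------------------

def _weighted_jackknife_core(
    theta: float, loo: np.ndarray, m: np.ndarray
) -> Tuple[float, float]:
    """Bias-corrected estimate and SE of the weighted delete-one jackknife.

    ``m`` are block weights (chromosome grid lengths), ``loo`` the delete-one
    estimates.  With ``h_h = M / m_h`` the bias-corrected estimate is
    ``theta_J = n_b * theta - sum_h (1 - m_h / M) * loo_h`` and the variance is
    ``(1/n_b) * sum_h (h_h*theta - (h_h-1)*loo_h - theta_J)**2 / (h_h - 1)``.
    """
    m = np.asarray(m, dtype=float)
    loo = np.asarray(loo, dtype=float)
    n_b = m.size
    M = m.sum()
    h = M / m
    theta_J = n_b * theta - float(np.sum((1.0 - m / M) * loo))
    var = float(np.sum((h * theta - (h - 1.0) * loo - theta_J) ** 2 / (h - 1.0))) / n_b
    return theta_J, math.sqrt(max(var, 0.0))


def jackknife(
    statistic: Callable[..., float], *genomes: GenomeSignal
) -> Tuple[float, float, float, float]:
    """Weighted delete-one-chromosome jackknife of an arbitrary statistic.

    ``statistic`` is called with the full genome(s) and with each delete-one
    subset; block weights are chromosome grid lengths.  Returns the
    bias-corrected estimate, its SE, and a 95% normal CI.  If the statistic is
    undefined (raises ``ValueError`` or returns NaN) on any delete-one set, the
    full-data estimate is returned with NaN uncertainty.
    """
    g0 = genomes[0]
    ids = g0.chrom_ids
    if len(ids) < 3:
        raise ValueError("jackknife needs at least 3 chromosomes")
    m = g0.weights
    theta = float(statistic(*genomes))
    loo = []
    for drop in ids:
        keep = [c for c in ids if c != drop]
        try:
            v = float(statistic(*(g.subset(keep) for g in genomes)))
        except ValueError:
            v = float("nan")
        loo.append(v)
    loo_arr = np.array(loo)
    if np.isnan(loo_arr).any() or math.isnan(theta):
        return theta, float("nan"), float("nan"), float("nan")
    est, se = _weighted_jackknife_core(theta, loo_arr, m)
    return est, se, est - _Z95 * se, est + _Z95 * se


# ---------------------------------------------------------------------------
# per-chromosome summaries
# ---------------------------------------------------------------------------

@dataclass
class _ChromVar:
    chrom_id: str
    n: int
    mean: float
    J: int
    level_vars: Dict[int, float]
    scaling_var: float

    @property
    def within(self) -> float:
        return sum(self.level_vars.values()) + self.scaling_var


def _variance_summaries(g: GenomeSignal) -> List[_ChromVar]:
    out = []
    for sig in g:
        coeffs = modwt(sig)
        spec = wavelet_variance(coeffs)
        out.append(
            _ChromVar(sig.chrom_id, sig.n, sig.mean, coeffs.max_level,
                      spec.levels, spec.scaling_variance)
        )
    return out


def _aggregate_variance(summaries: List[_ChromVar], mode: str) -> Dict[object, Tuple[float, int]]:
    """Map component key -> (estimate, n_chrom_present).

    Keys are level integers, 'scaling' and 'chrom'.  Returns NaN magnitude for a
    scale present on no chromosome in the subset (cannot happen for the full set).
    """
    n = np.array([c.n for c in summaries], dtype=float)
    M = n.sum()
    means = np.array([c.mean for c in summaries])
    pooled_mean = float(np.sum(n * means) / M)
    among = float(np.sum(n * (means - pooled_mean) ** 2) / M)
    total = float(np.sum(n * np.array([c.within for c in summaries])) / M) + among
    Jmax = max(c.J for c in summaries)
    out: Dict[object, Tuple[float, int]] = {}
    for j in range(1, Jmax + 1):
        pres = [c for c in summaries if c.J >= j]
        wsum = float(np.sum([c.n * c.level_vars[j] for c in pres]))
        if mode == "magnitude":
            denom = float(np.sum([c.n for c in pres]))
            est = wsum / denom if denom > 0 else float("nan")
        else:
            est = (wsum / M) / total
        out[j] = (est, len(pres))
    scal = float(np.sum([c.n * c.scaling_var for c in summaries])) / M
    out["scaling"] = (
        (scal, len(summaries)) if mode == "magnitude" else (scal / total, len(summaries))
    )
    out["chrom"] = (
        (among, len(summaries)) if mode == "magnitude" else (among / total, len(summaries))
    )
    return out


# ---------------------------------------------------------------------------
# variance decomposition model
# ---------------------------------------------------------------------------

class VarianceDecomposition:
    """Scale decomposition of the variance of a genomic signal.

    Parameters
    ----------
    genome : GenomeSignal
        The per-chromosome signals to decompose.

    Examples
    --------
    >>> res = VarianceDecomposition(genome).fit(jackknife=True)
    >>> res.magnitude            # doctest: +SKIP
    >>> print(res.summary())     # doctest: +SKIP
    """

    def __init__(self, genome: GenomeSignal):
        self.genome = genome

    def fit(self, jackknife: bool = False) -> "VarianceDecompositionResults":
        summaries = _variance_summaries(self.genome)
        if jackknife and len(summaries) < 3:
            raise ValueError("jackknife needs at least 3 chromosomes")
        frames = {}
        for mode in ("magnitude", "proportion"):
            est = _aggregate_variance(summaries, mode)
            jk: Dict[object, Tuple[float, float, float]] = {}
            if jackknife:
                jk = self._jackknife(summaries, mode, est)
            frames[mode] = self._frame(est, jk, mode)
        return VarianceDecompositionResults(
            self.genome, frames["magnitude"], frames["proportion"]
        )

    def _jackknife(self, summaries, mode, full):
        m = np.array([c.n for c in summaries], dtype=float)
        loo_aggs = []
        for i in range(len(summaries)):
            sub = summaries[:i] + summaries[i + 1:]
            loo_aggs.append(_aggregate_variance(sub, mode))
        out = {}
        for key, (theta, _) in full.items():
            loo = np.array(
                [agg.get(key, (float("nan"), 0))[0] for agg in loo_aggs]
            )
            if np.isnan(loo).any() or math.isnan(theta):
                out[key] = (float("nan"), float("nan"), float("nan"))
                continue
            est, se = _weighted_jackknife_core(theta, loo, m)
            out[key] = (se, est - _Z95 * se, est + _Z95 * se)
        return out

    def _frame(self, est, jk, mode) -> pd.DataFrame:
        d = self.genome.resolution_d
        units = "bp" if self.genome.map_units == "physical" else "morgans"
        rows = []
        for key, (theta, npres) in est.items():
            if isinstance(key, int):
                comp = f"{2.0 ** (key - 1) * d:.12g}"
                scale_value = 2.0 ** (key - 1) * d
            else:
                comp = key
                scale_value = float("nan")
            se, lo, hi = jk.get(key, (float("nan"),) * 3)
            rows.append(
                dict(component=comp, scale_value=scale_value, scale_units=units,
                     statistic=mode, estimate=theta, se=se, ci_lo=lo, ci_hi=hi,
                     n_chrom=npres, level=key if isinstance(key, int) else key)
            )
        return pd.DataFrame(rows)[TABLE_COLUMNS + ["level"]]


@dataclass
class VarianceDecompositionResults:
    """Fitted genome-wide wavelet variance decomposition.

    ``magnitude`` and ``proportion`` are tables with one row per component
    (each dyadic scale, 'scaling', 'chrom').  In proportion mode the estimates
    sum to one.
    """

    genome: GenomeSignal
    magnitude: pd.DataFrame
    proportion: pd.DataFrame

    def spectrum(self, mode: str = "magnitude") -> pd.DataFrame:
        if mode not in ("magnitude", "proportion"):
            raise ValueError("mode must be 'magnitude' or 'proportion'")
        return getattr(self, mode)

    @property
    def total_variance(self) -> float:
        return self.genome.pooled_variance

    def summary(self) -> str:
        lines = [
            "Wavelet variance decomposition",
            f"  chromosomes: {len(self.genome)}   grid points: {self.genome.total_n}",
            f"  resolution:  {self.genome.resolution_d:g} "
            f"({'bp' if self.genome.map_units == 'physical' else 'Morgans'})",
            f"  total variance: {self.total_variance:.6g}",
            "",
            self.magnitude.drop(columns='level').to_string(index=False,
                                                           float_format=lambda v: f"{v:.6g}"),
            "",
            self.proportion.drop(columns='level').to_string(index=False,
                                                            float_format=lambda v: f"{v:.6g}"),
        ]
        return "\n".join(lines)

    def plot(self, mode: str = "magnitude", ax=None):
        """Minimal spectrum plot: estimate (with CI bars where available) vs scale."""
        import matplotlib.pyplot as plt

        frame = self.spectrum(mode)
        sel = frame[frame["scale_value"].notna()]
        if ax is None:
            _, ax = plt.subplots()
        ax.set_xscale("log", base=2)
        yerr = None
        if sel["se"].notna().any():
            yerr = np.vstack([
                sel["estimate"] - sel["ci_lo"], sel["ci_hi"] - sel["estimate"]
            ])
        ax.errorbar(sel["scale_value"], sel["estimate"], yerr=yerr, fmt="o-")
        ax.set_xlabel(f"scale ({sel['scale_units'].iloc[0]})")
        ax.set_ylabel(f"wavelet variance ({mode})")
        return ax


# ---------------------------------------------------------------------------
# correlation decomposition
# ---------------------------------------------------------------------------

@dataclass
class _ChromCross:
    chrom_id: str
    n: int
    x_mean: float
    y_mean: float
    J: int
    sxy: Dict[int, float]
    sxx: Dict[int, float]
    syy: Dict[int, float]
    scal_xy: float
    scal_xx: float
    scal_yy: float


def _cross_summaries(x: GenomeSignal, y: GenomeSignal) -> List[_ChromCross]:
    out = []
    for cid in x.chrom_ids:
        sx, sy = x[cid], y[cid]
        cx, cy = modwt(sx), modwt(sy)
        J = cx.max_level
        n = sx.n
        sxy = {j: float(cx.wavelet[j] @ cy.wavelet[j]) for j in range(1, J + 1)}
        sxx = {j: float(cx.wavelet[j] @ cx.wavelet[j]) for j in range(1, J + 1)}
        syy = {j: float(cy.wavelet[j] @ cy.wavelet[j]) for j in range(1, J + 1)}
        xm, ym = sx.mean, sy.mean
        out.append(
            _ChromCross(
                cid, n, xm, ym, J, sxy, sxx, syy,
                scal_xy=float(cx.scaling @ cy.scaling) - n * xm * ym,
                scal_xx=float(cx.scaling @ cx.scaling) - n * xm * xm,
                scal_yy=float(cy.scaling @ cy.scaling) - n * ym * ym,
            )
        )
    return out


def _aggregate_correlation(cross: List[_ChromCross]) -> Dict[str, object]:
    n = np.array([c.n for c in cross], dtype=float)
    M = n.sum()
    xm = np.array([c.x_mean for c in cross])
    ym = np.array([c.y_mean for c in cross])
    xg = float(np.sum(n * xm) / M)
    yg = float(np.sum(n * ym) / M)
    among_xy = float(np.sum(n * (xm - xg) * (ym - yg)) / M)
    among_xx = float(np.sum(n * (xm - xg) ** 2) / M)
    among_yy = float(np.sum(n * (ym - yg) ** 2) / M)
    Jmax = max(c.J for c in cross)
    cov = {j: sum(c.sxy.get(j, 0.0) for c in cross) / M for j in range(1, Jmax + 1)}
    vx = {j: sum(c.sxx.get(j, 0.0) for c in cross) / M for j in range(1, Jmax + 1)}
    vy = {j: sum(c.syy.get(j, 0.0) for c in cross) / M for j in range(1, Jmax + 1)}
    cov["scaling"] = sum(c.scal_xy for c in cross) / M
    vx["scaling"] = sum(c.scal_xx for c in cross) / M
    vy["scaling"] = sum(c.scal_yy for c in cross) / M
    cov["chrom"], vx["chrom"], vy["chrom"] = among_xy, among_xx, among_yy
    var_x = sum(vx.values())
    var_y = sum(vy.values())
    if var_x <= 0 or var_y <= 0:
        raise ValueError("zero total variance in one of the signals")
    sd = math.sqrt(var_x * var_y)
    n_present = {
        j: sum(1 for c in cross if c.J >= j) for j in range(1, Jmax + 1)
    }
    n_present["scaling"] = n_present["chrom"] = len(cross)
    return dict(cov=cov, vx=vx, vy=vy, sd=sd, var_x=var_x, var_y=var_y,
                n_present=n_present, Jmax=Jmax,
                total=sum(cov.values()) / sd)


def _rho(agg, key) -> float:
    vxk, vyk = agg["vx"][key], agg["vy"][key]
    if vxk <= 0 or vyk <= 0:
        return float("nan")
    return agg["cov"][key] / math.sqrt(vxk * vyk)


def wavelet_correlation(x: GenomeSignal, y: GenomeSignal, level_j: int) -> float:
    """Pooled wavelet correlation between two signals at one scale.

    The covariance and variances of level-``j`` coefficients are pooled
    (length-weighted) across the chromosomes on which the scale is present.
    Returns NaN when either pooled variance is zero.
    """
    if not x.same_grid_as(y):
        raise ValueError("signals must be on identical grids")
    agg = _aggregate_correlation(_cross_summaries(x, y))
    if not 1 <= level_j <= agg["Jmax"]:
        raise ValueError(f"scale level {level_j} is present on no chromosome")
    return _rho(agg, level_j)


class RegressionResult(NamedTuple):
    slope: float
    r: float
    r_squared: float


def scale_regression(x: GenomeSignal, y: GenomeSignal, level_j: int) -> RegressionResult:
    """Least-squares regression of x wavelet coefficients on y wavelet
    coefficients at one scale, pooled across chromosomes.

    The coefficients sum to zero per chromosome, so the fit is through the
    origin; ``r`` equals the wavelet correlation at that level and ``r**2``
    estimates the proportion of variance in ``x`` at that scale explained by
    ``y``.
    """
    if not x.same_grid_as(y):
        raise ValueError("signals must be on identical grids")
    agg = _aggregate_correlation(_cross_summaries(x, y))
    if not 1 <= level_j <= agg["Jmax"]:
        raise ValueError(f"scale level {level_j} is present on no chromosome")
    syy = agg["vy"][level_j]
    if syy <= 0:
        raise ValueError("zero predictor variance at this scale")
    slope = agg["cov"][level_j] / syy
    r = _rho(agg, level_j)
    return RegressionResult(slope, r, r * r if not math.isnan(r) else float("nan"))


class CorrelationDecomposition:
    """Scale decomposition of the correlation between two genomic signals.

    Both signals must live on identical grids (same chromosomes, lengths,
    resolution and units).  ``fit()`` returns a Results object whose per-scale
    contributions sum exactly to the pooled Pearson correlation.
    """

    def __init__(self, x: GenomeSignal, y: GenomeSignal):
        if not x.same_grid_as(y):
            raise ValueError("signals must be on identical grids")
        self.x = x
        self.y = y

    def fit(self, jackknife: bool = False) -> "CorrelationDecompositionResults":
        cross = _cross_summaries(self.x, self.y)
        if jackknife and len(cross) < 3:
            raise ValueError("jackknife needs at least 3 chromosomes")
        agg = _aggregate_correlation(cross)
        keys = list(range(1, agg["Jmax"] + 1)) + ["scaling", "chrom"]
        jk: Dict[object, Tuple[float, float, float]] = {}
        if jackknife:
            m = np.array([c.n for c in cross], dtype=float)
            loo_aggs = []
            for i in range(len(cross)):
                sub = cross[:i] + cross[i + 1:]
                try:
                    loo_aggs.append(_aggregate_correlation(sub))
                except ValueError:
                    loo_aggs.append(None)
            for key in keys:
                theta = _rho(agg, key)
                loo = np.array([
                    _rho(a, key) if a is not None and (not isinstance(key, int) or key <= a["Jmax"])
                    else float("nan")
                    for a in loo_aggs
                ])
                if math.isnan(theta) or np.isnan(loo).any():
                    jk[key] = (float("nan"),) * 3
                else:
                    est, se = _weighted_jackknife_core(theta, loo, m)
                    jk[key] = (se, est - _Z95 * se, est + _Z95 * se)
        d = self.x.resolution_d
        units = "bp" if self.x.map_units == "physical" else "morgans"
        sd = agg["sd"]
        rows = []
        for key in keys:
            rho = _rho(agg, key)
            vxk = max(agg["vx"][key], 0.0)
            vyk = max(agg["vy"][key], 0.0)
            weight = math.sqrt(vxk * vyk) / sd
            contribution = agg["cov"][key] / sd
            se, lo, hi = jk.get(key, (float("nan"),) * 3)
            if isinstance(key, int):
                comp = f"{2.0 ** (key - 1) * d:.12g}"
                scale_value = 2.0 ** (key - 1) * d
            else:
                comp, scale_value = key, float("nan")
            rows.append(dict(component=comp, scale_value=scale_value,
                             scale_units=units, rho=rho, weight=weight,
                             contribution=contribution, se=se, ci_lo=lo,
                             ci_hi=hi, n_chrom=agg["n_present"][key],
                             level=key))
        table = pd.DataFrame(rows)
        return CorrelationDecompositionResults(
            self.x, self.y, table, float(agg["total"]), agg
        )


@dataclass
class CorrelationDecompositionResults:
    """Fitted wavelet correlation decomposition.

    ``table`` has one row per component with the wavelet correlation ``rho``,
    the variance-proportion weight, and the contribution ``weight * rho``; the
    contributions sum to ``total_correlation``, the pooled Pearson correlation
    between the two signals.
    """

    x: GenomeSignal
    y: GenomeSignal
    table: pd.DataFrame
    total_correlation: float
    _agg: Dict[str, object]

    def rho(self, level_j: int) -> float:
        return _rho(self._agg, level_j)

    def scale_regression(self, level_j: int) -> RegressionResult:
        syy = self._agg["vy"].get(level_j)
        if syy is None:
            raise ValueError(f"scale level {level_j} is present on no chromosome")
        if syy <= 0:
            raise ValueError("zero predictor variance at this scale")
        slope = self._agg["cov"][level_j] / syy
        r = _rho(self._agg, level_j)
        return RegressionResult(slope, r, r * r if not math.isnan(r) else float("nan"))

    def summary(self) -> str:
        lines = [
            "Wavelet correlation decomposition",
            f"  chromosomes: {len(self.x)}   grid points: {self.x.total_n}",
            f"  total correlation: {self.total_correlation:.6g}",
            "",
            self.table.drop(columns="level").to_string(
                index=False, float_format=lambda v: f"{v:.6g}"
            ),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        sel = self.table[self.table["scale_value"].notna()]
        if ax is None:
            _, ax = plt.subplots()
        ax.set_xscale("log", base=2)
        yerr = None
        if sel["se"].notna().any():
            yerr = np.vstack([sel["rho"] - sel["ci_lo"], sel["ci_hi"] - sel["rho"]])
        ax.errorbar(sel["scale_value"], sel["rho"], yerr=yerr, fmt="o-")
        ax.axhline(0.0, color="gray", lw=0.5)
        ax.set_xlabel(f"scale ({sel['scale_units'].iloc[0]})")
        ax.set_ylabel("wavelet correlation")
        return ax
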