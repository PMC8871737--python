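"""Crossover counts per RIL and the spacing of crossovers along the map.

At fixation a selfed RIL accumulates about twice the crossovers of a single
meiosis in observable form, so with a mean of lambda crossovers per gamete
per chromosome the expected junction count per RIL chromosome is ~2*lambda.
Junction counts per linkage group are summarised against the Poisson
benchmark (variance/mean ~ 1; slightly under 1 when every bivalent must
carry a chiasma).  If crossovers fall at random on the genetic map, the
distances L between successive junctions follow a geometric law with per-cM
event rate eps, giving the runs-theory log-frequency line

    log F_L = 2 log(eps) + L log(1 - eps) - eps log(1 - eps)

whose slope identifies eps (natural logarithms used throughout, so
eps_hat = 1 - exp(slope)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coding import IntegratedGenotypeMatrix
from .mapping import LinkageMap, PopulationArrays
from .simulate import POPULATIONS


@dataclass
class CrossoverProfile:
    """Per-(line, LG) junction counts, positions and spacing intervals."""

    counts: pd.DataFrame                  # line x LG junction counts (NaN = excluded)
    junction_positions: dict = field(default_factory=dict)  # (line, LG) -> ndarray cM
    intervals: dict = field(default_factory=dict)           # (line, LG) -> ndarray cM
    end_segments: dict = field(default_factory=dict)        # (line, LG) -> (first, last)
    n_excluded: int = 0  # (line, LG) cells with < 2 informative markers

    def summary(self) -> pd.DataFrame:
        """Per-LG mean, variance, maximum and variance/mean of counts."""
        rows = []
        for lg in self.counts.columns:
            col = self.counts[lg].dropna()
            mean = float(col.mean())
            var = float(col.var(ddof=1))
            rows.append({"LG": lg, "n_lines": int(len(col)), "mean": mean,
                         "variance": var, "maximum": int(col.max()),
                         "variance_mean_ratio": var / mean if mean else np.nan})
        return pd.DataFrame(rows).set_index("LG")

    def genome_counts(self) -> pd.Series:
        """Total junctions per line across all linkage groups."""
        return self.counts.sum(axis=1, skipna=True)

    def all_intervals(self, include_end_segments: bool = False) -> np.ndarray:
        """Pooled inter-junction map distances (cM) across lines and LGs.

        End segments (map end to first/last junction) are censored
        observations of the spacing law and are excluded by default.
        """
        vals = [v for v in self.intervals.values() if len(v)]
        out = np.concatenate(vals) if vals else np.empty(0)
        if include_end_segments:
            ends = [np.asarray(v) for v in self.end_segments.values()]
            if ends:
                out = np.concatenate([out] + ends)
        return out


def crossover_counts(matrix: IntegratedGenotypeMatrix, lmap: LinkageMap
                     ) -> CrossoverProfile:
    """Count parent-of-origin junctions per line along each linkage group.

    Missing calls are skipped: a junction is scored between a line's nearest
    informative flanking markers, at the cM midpoint of that bracketing
    interval.  Lines with fewer than two informative markers on an LG are
    excluded from that LG (counted in ``n_excluded``).
    """
    pv = PopulationArrays(matrix)
    lgs = sorted(lmap.intervals)
    all_lines = [ln for pop in POPULATIONS for ln in pv.lines[pop]]
    counts = pd.DataFrame(np.nan, index=all_lines, columns=lgs)
    junctions: dict = {}
    intervals: dict = {}
    end_segments: dict = {}
    n_excluded = 0
    for lg in lgs:
        sub = lmap.table[lmap.table["LG"] == lg]
        markers = [m for m in sub["marker"] if m in pv.pos]
        order_idx = np.array([pv.pos[m] for m in markers])
        cm = sub.set_index("marker")["cM"].loc[markers].to_numpy(dtype=float)
        lg_start, lg_end = float(cm[0]), float(cm[-1])
        for pop in POPULATIONS:
            arr = pv.arrays[pop]
            if arr.shape[1] == 0:
                continue
            block = arr[order_idx]
            for j, line in enumerate(pv.lines[pop]):
                col = block[:, j]
                inf = col >= 0
                if inf.sum() < 2:
                    n_excluded += 1
                    continue
                vals = col[inf]
                pos = cm[inf]
                chg = np.flatnonzero(vals[1:] != vals[:-1])
                jpos = 0.5 * (pos[chg] + pos[chg + 1])
                counts.loc[line, lg] = len(jpos)
                junctions[(line, lg)] = jpos
                intervals[(line, lg)] = np.diff(jpos)
                if len(jpos):
                    end_segments[(line, lg)] = (float(jpos[0] - lg_start),
                                                float(lg_end - jpos[-1]))
    return CrossoverProfile(counts=counts, junction_positions=junctions,
                            intervals=intervals, end_segments=end_segments,
                            n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# map length vs crossover number
# ---------------------------------------------------------------------------

def length_vs_crossovers_regression(lg_lengths_cM, mean_counts) -> dict:
    """OLS of linkage-group map length (cM) on mean crossovers per RIL.

    With one obligate crossover per bivalent the expected relationship has a
    positive intercept of the order of half a crossover's worth of map and a
    slope of ~50 cM per crossover.  Requires at least three linkage groups.
    """
    x = np.asarray(mean_counts, dtype=float)
    y = np.asarray(lg_lengths_cM, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched lengths and counts for >= 3 linkage groups")
    lr = stats.linregress(x, y)
    return {"intercept": float(lr.intercept), "slope": float(lr.slope),
            "r_squared": float(lr.rvalue ** 2), "n": len(x)}


# ---------------------------------------------------------------------------
# runs-theory distribution of inter-crossover distances
# ---------------------------------------------------------------------------

@dataclass
class RunsModel:
    slope: float
    intercept: float
    r: float                  # regression coefficient of the fitted line
    eps_from_slope: float     # 1 - exp(slope)
    eps_from_totals: float    # n_intervals / total interval length
    bins: pd.DataFrame        # bin_mid, count, rel_freq, log_freq
    n_intervals: int


def runs_log_frequency(eps: float, L) -> np.ndarray | float:
    """Predicted log F_L = 2 log(eps) + L log(1-eps) - eps log(1-eps)."""
    L = np.asarray(L, dtype=float)
    out = 2 * np.log(eps) + L * np.log1p(-eps) - eps * np.log1p(-eps)
    return float(out) if out.ndim == 0 else out


def runs_distribution_fit(interval_lengths, bin_width: float = 2.0) -> RunsModel:
    """Fit the runs-theory line to observed inter-junction distances.

    Interval lengths (cM) are binned at ``bin_width``; empty bins are
    dropped; the natural-log relative frequency is regressed on the bin
    midpoint by count-weighted least squares (the sampling variance of a
    log frequency is ~1/count, so sparse tail bins would otherwise flatten
    the slope).  Two event-rate estimates are reported: from the fitted
    slope (eps = 1 - exp(slope)) and from totals (interval count / total
    length).
    """
    lengths = np.asarray(interval_lengths, dtype=float)
    lengths = lengths[np.isfinite(lengths)]
    if len(lengths) == 0:
        raise ValueError("no intervals to fit")
    edges = np.arange(0.0, lengths.max() + bin_width, bin_width)
    if len(edges) < 3:
        raise ValueError("all intervals fall in one bin; fit undefined")
    count, edges = np.histogram(lengths, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    rel = count / count.sum()
    keep = count > 0
    if keep.sum() < 2:
        raise ValueError("fewer than two occupied bins; fit undefined")
    slope, intercept, rval = _weighted_linregress(
        mids[keep], np.log(rel[keep]), count[keep].astype(float))
    log_freq = np.full(len(mids), np.nan)
    log_freq[keep] = np.log(rel[keep])
    bins = pd.DataFrame({"bin_mid": mids, "count": count, "rel_freq": rel,
                         "log_freq": log_freq})
    total = float(lengths.sum())
    return RunsModel(slope=slope, intercept=intercept, r=rval,
                     eps_from_slope=float(1.0 - np.exp(slope)),
                     eps_from_totals=float(len(lengths) / total) if total else np.nan,
                     bins=bins, n_intervals=len(lengths))


def _weighted_linregress(x, y, w) -> tuple[float, float, float]:
    w = w / w.sum()
    xm = (w * x).sum()
    ym = (w * y).sum()
    cov = (w * (x - xm) * (y - ym)).sum()
    vx = (w * (x - xm) ** 2).sum()
    vy = (w * (y - ym) ** 2).sum()
    slope = cov / vx
    return float(slope), float(ym - slope * xm), float(cov / np.sqrt(vx * vy))
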