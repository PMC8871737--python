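"""Parental relatedness from marker segregation patterns.

With three founders, a marker scored in two populations fixes the full trio
state, so pairwise difference fractions dBE, dBK, dEK fall straight out of
the segregation tallies.  The three pairwise distances decompose uniquely
onto a trifurcating (star) tree: the branch from the trifurcation point to
founder X is dXt = (dXY + dXZ - dYZ) / 2.  Per-linkage-group chi-square
tests flag groups whose marker counts deviate from proportionality, the
signature of regional identity by descent between particular founders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding import TrioAlleleTable
from .simulate import POPULATIONS

_PAIRS = (("B", "E"), ("B", "K"), ("E", "K"))


@dataclass
class TrioDistances:
    """Pairwise difference fractions and trifurcation branch lengths."""

    scope: str
    n_markers: int
    dBE: float
    dBK: float
    dEK: float
    dBt: float
    dEt: float
    dKt: float
    triangle_violated: bool = False

    def as_dict(self) -> dict:
        return {"scope": self.scope, "n_markers": self.n_markers,
                "dBE": self.dBE, "dBK": self.dBK, "dEK": self.dEK,
                "dBt": self.dBt, "dEt": self.dEt, "dKt": self.dKt,
                "triangle_violated": self.triangle_violated}


def _branches(dbe: float, dbk: float, dek: float) -> tuple[float, float, float, bool]:
    dbt = 0.5 * (dbe + dbk - dek)
    det = 0.5 * (dbe + dek - dbk)
    dkt = 0.5 * (dbk + dek - dbe)
    violated = min(dbt, det, dkt) < 0
    return dbt, det, dkt, violated


def distances_from_counts(n_diff: dict[str, int], n_total: int,
                          scope: str = "all") -> TrioDistances:
    """Distances from per-pair difference counts out of ``n_total`` markers.

    ``n_diff`` keys 'BE', 'BK', 'EK': the number of markers at which that
    pair of founders differ — equivalently the number of markers segregating
    in that population.
    """
    if n_total <= 0:
        raise ValueError(f"no usable markers in scope {scope!r}")
    dbe, dbk, dek = (n_diff[p] / n_total for p in POPULATIONS)
    dbt, det, dkt, viol = _branches(dbe, dbk, dek)
    return TrioDistances(scope=scope, n_markers=n_total, dBE=dbe, dBK=dbk,
                         dEK=dek, dBt=dbt, dEt=det, dKt=dkt,
                         triangle_violated=viol)


def distance_fractions(trio: TrioAlleleTable,
                       lg_of: pd.Series | None = None) -> pd.DataFrame:
    """Overall and (optionally) per-LG difference fractions and branches.

    Only markers with a known trio state (pattern B=E / B=K / E=K, i.e.
    scored in two populations) enter the denominator; monomorphic markers
    carry no pairwise information.  Scopes with zero usable markers are
    reported absent.
    """
    t = trio.table
    poly = t[t["pattern"] != "mono"]
    scopes: list[tuple[str, pd.DataFrame]] = [("all", poly)]
    if lg_of is not None:
        lgs = lg_of.reindex(poly.index)
        for lg in sorted(pd.unique(lgs.dropna())):
            scopes.append((str(lg), poly[lgs == lg]))
    out = []
    for scope, sub in scopes:
        if len(sub) == 0:
            continue
        n_diff = {}
        for a, b in _PAIRS:
            seg = sub["segregates_in"].map(lambda s, p=a + b: p in s)
            n_diff[a + b] = int(seg.sum())
        out.append(distances_from_counts(n_diff, len(sub), scope).as_dict())
    return pd.DataFrame(out)


def distances_from_shared_tallies(shared: dict[str, int],
                                  scope: str = "all") -> TrioDistances:
    """Distances from shared-by-two-population marker tallies.

    ``shared`` keys 'BE&BK', 'BE&EK', 'BK&EK': counts of markers scored in
    exactly those two populations.  A marker segregates in population P iff
    it appears in one of the two tallies containing P.
    """
    n_total = sum(shared.values())
    n_diff = {}
    for pop in POPULATIONS:
        n_diff[pop] = sum(v for k, v in shared.items() if pop in k.split("&"))
    return distances_from_counts(n_diff, n_total, scope)


@dataclass
class ChiSqReport:
    """Observed vs proportional-expected marker counts per (LG, population)."""

    table: pd.DataFrame  # columns: LG, population, observed, expected, chisq, shaded
    shading_threshold: float = 10.0


def lg_chisq(tallies: pd.DataFrame, lg_totals: pd.Series | None = None,
             shading_threshold: float = 10.0) -> ChiSqReport:
    """Chi-square deviation of per-LG marker counts from proportionality.

    ``tallies``: rows = LGs, columns = population labels, values = observed
    segregating-marker counts.  Expected(LG, pop) = pop total x LG share of
    the grand total.  The LG share comes from ``lg_totals`` — the number of
    distinct markers per LG — when given (each marker is scored in two
    populations, so summing the population columns would double-count);
    otherwise it falls back to the per-population column sums.  Cells are
    shaded (consistent with proportionality) when their chi-square
    contribution is below ``shading_threshold``.
    """
    obs = tallies.astype(float)
    if (obs.to_numpy() < 0).any():
        raise ValueError("negative tallies")
    grand = obs.to_numpy().sum()
    if grand <= 0:
        raise ValueError("empty tally table")
    if lg_totals is None:
        lg_totals = obs.sum(axis=1)
    else:
        lg_totals = lg_totals.reindex(obs.index).astype(float)
    lg_share = lg_totals / lg_totals.sum()
    pop_totals = obs.sum(axis=0)
    rows = []
    for lg in obs.index:
        for pop in obs.columns:
            e = pop_totals[pop] * lg_share[lg]
            o = obs.loc[lg, pop]
            if e == 0:
                rows.append({"LG": lg, "population": pop, "observed": o,
                             "expected": 0.0, "chisq": np.nan,
                             "computable": o == 0, "shaded": False})
                continue
            chisq = (o - e) ** 2 / e
            rows.append({"LG": lg, "population": pop, "observed": o,
                         "expected": e, "chisq": chisq, "computable": True,
                         "shaded": bool(chisq < shading_threshold)})
    return ChiSqReport(table=pd.DataFrame(rows),
                       shading_threshold=shading_threshold)


def trifurcation_coordinates(d: TrioDistances) -> dict[str, tuple[float, float]]:
    """Endpoints of the three branch vectors at 120 degree spacing, for the
    star plot of parental relatedness (B up, E lower-left, K lower-right)."""
    angles = {"B": 90.0, "E": 210.0, "K": 330.0}
    lengths = {"B": d.dBt, "E": d.dEt, "K": d.dKt}
    return {p: (lengths[p] * np.cos(np.deg2rad(a)),
                lengths[p] * np.sin(np.deg2rad(a)))
            for p, a in angles.items()}
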