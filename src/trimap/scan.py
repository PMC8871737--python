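"""Single-marker quantitative-trait scan across the integrated populations.

Traits are z-scored within each RIL population (mean 0, SD 1), which
absorbs population-specific location/scale effects and makes the three
populations commensurable.  For each marker the lines carrying the two
parental alleles are compared by a pooled-variance Student's t test; the
sign convention is (alphabetically earlier parent) minus (later), so a
positive t means the earlier parent's allele raises the trait.  Each marker
yields a per-population series for the populations in which it segregates
plus a pooled series over their union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coding import IntegratedGenotypeMatrix
from .mapping import LinkageMap
from .simulate import MISSING


def normalize_trait(phenotypes: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score the trait within each population.

    ``phenotypes`` columns: line, population, trait.  Missing values
    propagate; a population with fewer than two non-missing values or zero
    spread is rejected.  ``ddof=1`` (sample SD) is the default convention.
    """
    out = phenotypes.copy()
    out["z"] = np.nan
    for pop, sub in phenotypes.groupby("population"):
        vals = sub["trait"].astype(float)
        ok = vals.notna()
        if ok.sum() < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 trait values")
        sd = vals[ok].std(ddof=ddof)
        if not sd > 0:
            raise ValueError(f"population {pop!r} has zero trait variance")
        out.loc[sub.index, "z"] = (vals - vals[ok].mean()) / sd
    return out


def pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Two-sample pooled-variance Student's t; returns (t, df)."""
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), df


@dataclass
class ScanResult:
    table: pd.DataFrame   # marker, scope, class labels/means/sizes, t, df, p
    n_min: int
    blocks: pd.DataFrame | None = None  # cosegregating-block summary

    def extrema(self, lmap: LinkageMap | None = None) -> pd.DataFrame:
        """Per (LG, scope) markers attaining the extreme |t|."""
        t = self.table.dropna(subset=["t"])
        if lmap is not None:
            pos = lmap.table.set_index("marker")
            t = t.join(pos[["LG", "cM"]], on="marker")
        else:
            t = t.assign(LG="all")
        rows = []
        for (lg, scope), sub in t.groupby(["LG", "scope"]):
            best = sub.loc[sub["t"].abs().idxmax()]
            rows.append(best)
        return pd.DataFrame(rows).reset_index(drop=True)


def marker_t_scan(matrix: IntegratedGenotypeMatrix, zscores: pd.DataFrame,
                  n_min: int = 5) -> ScanResult:
    """Student's t between genotype classes at every segregating marker.

    For each marker and each population in which it segregates, lines are
    split by parent-of-origin code and compared on the normalized scale;
    a pooled series concatenates the informative lines of the two
    populations.  Classes smaller than ``n_min`` lines leave the statistic
    omitted (flagged) — small classes driven by missing scores produce
    artifact extremes.
    """
    z = zscores.set_index("line")["z"]
    rows = []
    for marker in matrix.codes.index:
        pops = sorted(matrix.marker_populations.get(marker, frozenset()))
        if not pops:
            continue
        codes = matrix.codes.loc[marker]
        # the parent present in both segregating populations carries the
        # minor allele; the other two labels share the major allele and are
        # pooled into one class for the combined series
        pooled: dict[str, list] = {}
        diff_parent = None
        if len(pops) == 2:
            common = set(pops[0]) & set(pops[1])
            diff_parent = next(iter(common)) if len(common) == 1 else None
        for pop in pops:
            lines = matrix.lines_of(pop)
            sub = codes[lines]
            cls = {}
            for p in (pop[0], pop[1]):
                sel = [ln for ln in lines if sub[ln] == p and ln in z.index
                       and np.isfinite(z[ln])]
                cls[p] = np.array([z[ln] for ln in sel])
                if diff_parent is not None:
                    key = p if p == diff_parent else "".join(
                        sorted(set("BEK") - {diff_parent}))
                    pooled.setdefault(key, []).extend(cls[p])
            rows.append(_scan_row(marker, pop, cls, n_min,
                                  n_missing=int((sub == MISSING).sum())))
        if diff_parent is not None:
            cls = {p: np.asarray(v) for p, v in pooled.items() if len(v)}
            if len(cls) == 2:
                rows.append(_scan_row(marker, "pooled", cls, n_min, n_missing=0))
    table = pd.DataFrame(rows)
    # raw extrema are what the scan reports; a Bonferroni column is emitted
    # for users who want a family-wise guard (tests per scope)
    if len(table):
        n_tests = table.groupby("scope")["t"].transform(lambda s: s.notna().sum())
        table["p_bonferroni"] = np.minimum(table["p"] * n_tests, 1.0)
    return ScanResult(table=table, n_min=n_min)


def _scan_row(marker: str, scope: str, cls: dict, n_min: int,
              n_missing: int) -> dict:
    labels = sorted(cls)  # alphabetical: sign = earlier minus later
    row = {"marker": marker, "scope": scope, "n_missing": n_missing,
           "t": np.nan, "df": np.nan, "p": np.nan, "flagged": False}
    if len(labels) == 2:
        a, b = labels
        row.update({"class_a": a, "class_b": b,
                    "n_a": len(cls[a]), "n_b": len(cls[b]),
                    "mean_a": float(cls[a].mean()) if len(cls[a]) else np.nan,
                    "mean_b": float(cls[b].mean()) if len(cls[b]) else np.nan})
        if len(cls[a]) >= n_min and len(cls[b]) >= n_min:
            t, df = pooled_t(cls[a], cls[b])
            row.update({"t": t, "df": df,
                        "p": float(2 * stats.t.sf(abs(t), df))})
        else:
            row["flagged"] = True
    else:
        row.update({"class_a": labels[0] if labels else None, "class_b": None,
                    "n_a": len(cls[labels[0]]) if labels else 0, "n_b": 0,
                    "mean_a": np.nan, "mean_b": np.nan, "flagged": True})
    return row


def cosegregating_blocks(matrix: IntegratedGenotypeMatrix,
                         scan: ScanResult | None = None) -> pd.DataFrame:
    """Group markers with identical code vectors into blocks.

    Cosegregating markers carry a single statistical signal; summaries
    should count each block once (one representative t) rather than once
    per marker.  Returns block id, representative (first marker), size and,
    when a scan is supplied, the representative's pooled t.
    """
    key = matrix.codes.apply(lambda row: "".join(map(str, row)), axis=1)
    rows = []
    for block_id, (sig, members) in enumerate(key.groupby(key).groups.items()):
        members = list(members)
        rep = members[0]
        row = {"block": block_id, "representative": rep, "n_markers": len(members),
               "markers": ",".join(members)}
        if scan is not None:
            sub = scan.table[(scan.table["marker"] == rep)
                             & (scan.table["scope"] == "pooled")]
            if len(sub) == 0:
                sub = scan.table[scan.table["marker"] == rep]
            row["t"] = float(sub["t"].iloc[0]) if len(sub) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
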