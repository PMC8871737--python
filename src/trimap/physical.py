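"""Genetic map against physical assembly: cM/Mb profiles and nonlinearity.

Recombination rate along a chromosome is profiled as the ratio of genetic
to physical distance between markers a fixed number of map intervals apart
(span 10 by default).  Pairs straddling assembly problems show up as
negative physical differences and are skipped; positive but anomalously
large physical differences are retained and simply depress the local cM/Mb
value.  Pericentromeric regions appear as near-zero ratios (the steep
sections of the sigmoid cM-vs-Mb curve); per-arm summaries take the
centromere position as an input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import LinkageMap
from .recomb import CrossoverProfile


@dataclass
class RateProfile:
    pairs: pd.DataFrame      # LG, left, right, dcM, dMb, ratio
    per_lg: pd.DataFrame     # LG, n_pairs, mean, sd, skipped counts
    n_off_pseudomolecule: int = 0
    n_unanchored: int = 0


def _lg_frame(lmap: LinkageMap, anchors: pd.DataFrame, lg) -> pd.DataFrame:
    sub = lmap.table[lmap.table["LG"] == lg][["marker", "cM"]].copy()
    a = anchors.set_index("marker") if "marker" in anchors.columns else anchors
    sub["bp"] = sub["marker"].map(a["bp"])
    sub["chrom"] = sub["marker"].map(a["chrom"])
    return sub


def cm_mb_profile(lmap: LinkageMap, anchors: pd.DataFrame, span: int = 10
                  ) -> RateProfile:
    """cM/Mb ratios for marker pairs ``span`` map intervals apart.

    For each marker with a marker ``span`` intervals later on the same LG:
    the pair is used when both markers anchor to the LG's pseudomolecule
    and the physical difference is positive; negative differences are
    skipped and counted; end-of-LG positions with no partner are counted
    separately.  Mean and SD are over retained pair ratios.
    """
    if span < 1:
        raise ValueError("span must be >= 1")
    pair_rows = []
    lg_rows = []
    n_off = n_unanchored = 0
    for lg in sorted(lmap.table["LG"].unique()):
        sub = _lg_frame(lmap, anchors, lg)
        # dominant pseudomolecule of the LG = modal chromosome among anchors
        chroms = sub["chrom"].dropna()
        pseudo = chroms.mode().iloc[0] if len(chroms) else None
        off = (sub["chrom"].notna() & (sub["chrom"] != pseudo)).sum()
        unanch = sub["chrom"].isna().sum()
        n_off += int(off)
        n_unanchored += int(unanch)
        n = len(sub)
        n_end = min(span, n)  # trailing markers with no partner
        n_skipped_neg = n_skipped_anchor = 0
        ratios = []
        cm = sub["cM"].to_numpy(dtype=float)
        bp = sub["bp"].to_numpy(dtype=float)
        ch = sub["chrom"].to_numpy(dtype=object)
        mk = sub["marker"].to_numpy(dtype=object)
        for i in range(n - span):
            j = i + span
            if ch[i] != pseudo or ch[j] != pseudo or np.isnan(bp[i]) or np.isnan(bp[j]):
                n_skipped_anchor += 1
                continue
            dmb = (bp[j] - bp[i]) / 1e6
            dcm = cm[j] - cm[i]
            if dmb < 0:
                n_skipped_neg += 1
                continue
            ratio = dcm / dmb if dmb > 0 else np.nan
            pair_rows.append({"LG": lg, "left": mk[i], "right": mk[j],
                              "dcM": dcm, "dMb": dmb, "ratio": ratio})
            if np.isfinite(ratio):
                ratios.append(ratio)
        ratios = np.asarray(ratios)
        lg_rows.append({
            "LG": lg, "n_pairs": len(ratios),
            "mean": float(ratios.mean()) if len(ratios) else np.nan,
            "sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else np.nan,
            "skipped_negative": n_skipped_neg,
            "skipped_anchor": n_skipped_anchor,
            "end_positions": n_end})
    return RateProfile(pairs=pd.DataFrame(pair_rows),
                       per_lg=pd.DataFrame(lg_rows).set_index("LG"),
                       n_off_pseudomolecule=n_off, n_unanchored=n_unanchored)


@dataclass
class ArmRates:
    per_arm: pd.DataFrame  # arm, n_markers, mean, sd, cM_length, crossover_share


def arm_rates(lmap: LinkageMap, anchors: pd.DataFrame, lg,
              centromere_bp: float, span: int = 10,
              profile: CrossoverProfile | None = None,
              chrom_length_bp: float | None = None) -> ArmRates:
    """Per-arm cM/Mb summary for one linkage group.

    Markers are partitioned into short/long arms by bp side of the supplied
    centromere position (no inference is attempted); the cM/Mb profile is
    recomputed within each arm, and, when a crossover profile is given, the
    share of junctions falling on each arm is reported.  A centromere
    outside the chromosome (``chrom_length_bp`` when given, otherwise 10x
    the outermost marker) is rejected; one beyond the outermost marker but
    inside the chromosome leaves that arm empty.
    """
    sub = _lg_frame(lmap, anchors, lg)
    bp = sub["bp"].to_numpy(dtype=float)
    limit = chrom_length_bp if chrom_length_bp is not None else 10 * np.nanmax(bp)
    if not 0 < centromere_bp <= limit:
        raise ValueError("centromere position outside the chromosome span")
    cm_at_centromere = float(np.interp(centromere_bp,
                                       bp[np.argsort(bp)],
                                       sub["cM"].to_numpy()[np.argsort(bp)]))
    rows = []
    for arm, mask in (("left", bp <= centromere_bp), ("right", bp > centromere_bp)):
        arm_sub = sub[mask]
        if len(arm_sub) == 0:
            rows.append({"arm": arm, "n_markers": 0, "mean": np.nan,
                         "sd": np.nan, "cM_length": 0.0, "n_junctions": 0})
            continue
        arm_map = LinkageMap(table=pd.DataFrame({
            "LG": lg, "marker": arm_sub["marker"], "cM": arm_sub["cM"]}))
        prof = cm_mb_profile(arm_map, anchors, span=min(span, max(1, len(arm_sub) - 1)))
        stats_row = prof.per_lg.iloc[0] if len(prof.per_lg) else None
        n_junc = 0
        if profile is not None:
            lo, hi = float(arm_sub["cM"].min()), float(arm_sub["cM"].max())
            for (line, jlg), jpos in profile.junction_positions.items():
                if jlg == lg:
                    n_junc += int(((jpos >= lo) & (jpos <= hi)).sum())
        rows.append({"arm": arm, "n_markers": int(len(arm_sub)),
                     "mean": float(stats_row["mean"]) if stats_row is not None else np.nan,
                     "sd": float(stats_row["sd"]) if stats_row is not None else np.nan,
                     "cM_length": float(arm_sub["cM"].max() - arm_sub["cM"].min()),
                     "n_junctions": n_junc})
    df = pd.DataFrame(rows).set_index("arm")
    total = df["n_junctions"].sum()
    df["crossover_share"] = df["n_junctions"] / total if total else np.nan
    df.attrs["cM_at_centromere"] = cm_at_centromere
    return ArmRates(per_arm=df)


def nonlinearity_report(lmap: LinkageMap, anchors: pd.DataFrame) -> pd.DataFrame:
    """Count markers whose map rank disagrees with their physical rank.

    Per LG, markers anchored to the LG's pseudomolecule are ranked by map
    position and by bp; a disagreement marks a local inversion between the
    genetic map and the assembly (zero for a perfectly monotone anchoring).
    """
    rows = []
    for lg in sorted(lmap.table["LG"].unique()):
        sub = _lg_frame(lmap, anchors, lg).dropna(subset=["bp"])
        chroms = sub["chrom"].dropna()
        if len(chroms) == 0:
            continue
        pseudo = chroms.mode().iloc[0]
        sub = sub[sub["chrom"] == pseudo]
        map_rank = sub["cM"].rank(method="first").to_numpy()
        bp_rank = sub["bp"].rank(method="first").to_numpy()
        # orient: compare against the better of the two strand orientations
        n_fwd = int((map_rank != bp_rank).sum())
        n_rev = int((map_rank != (len(sub) + 1 - bp_rank)).sum())
        rows.append({"LG": lg, "n_markers": len(sub),
                     "n_rank_disagreements": min(n_fwd, n_rev)})
    return pd.DataFrame(rows).set_index("LG")
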