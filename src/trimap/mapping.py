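"""Integrated linkage-map construction for three pooled RIL populations.

The map is built on the physical marker order (anchors on pseudomolecules),
locally refined by colormapping — greedy rearrangement that minimises
apparent close double recombinants (singleton genotype runs) — and measured
by pooling recombinant counts across the populations in which each adjacent
marker pair segregates.  The pooled RIL recombination fraction R is
converted to the per-meiosis fraction r through the selfed-RIL map
expansion r = R / (2(1-R)) and then to centimorgans with Haldane's mapping
function d = -50 ln(1-2r) (Kosambi available as an option).  Extended
intervals devoid of markers in every population are flagged as presumptive
identity-by-descent gaps; their lengths are carried by the recombination
fraction between the flanking markers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import IntegratedGenotypeMatrix
from .simulate import MISSING, POPULATIONS

# ---------------------------------------------------------------------------
# mapping functions and RIL map expansion
# ---------------------------------------------------------------------------

def ril_to_meiotic(R):
    """Selfed-RIL map expansion: observed RIL fraction R -> meiotic r.

    At fixation a fraction R = 2r / (1+2r) of selfed RILs are recombinant
    between two loci with per-meiosis recombination fraction r; inverting
    gives r = R / (2(1-R)).  Accepts scalars or arrays, requires 0 <= R < 1.
    """
    R = np.asarray(R, dtype=float)
    if (R < 0).any() or (R >= 1).any():
        raise ValueError("RIL recombination fraction must lie in [0, 1)")
    r = R / (2.0 * (1.0 - R))
    return float(r) if r.ndim == 0 else r


def meiotic_to_ril(r):
    """Inverse of :func:`ril_to_meiotic`: R = 2r / (1+2r)."""
    r = np.asarray(r, dtype=float)
    R = 2.0 * r / (1.0 + 2.0 * r)
    return float(R) if R.ndim == 0 else R


def haldane_cM(r):
    """Haldane map distance d = -50 ln(1-2r) cM (no interference)."""
    r = np.asarray(r, dtype=float)
    if (r < 0).any() or (r >= 0.5).any():
        raise ValueError("meiotic recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log1p(-2.0 * r)
    return float(d) if d.ndim == 0 else d


def kosambi_cM(r):
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) cM."""
    r = np.asarray(r, dtype=float)
    if (r < 0).any() or (r >= 0.5).any():
        raise ValueError("meiotic recombination fraction must lie in [0, 0.5)")
    d = 25.0 * (np.log1p(2.0 * r) - np.log1p(-2.0 * r))
    return float(d) if d.ndim == 0 else d


MAPPING_FUNCTIONS = {"haldane": haldane_cM, "kosambi": kosambi_cM}


# ---------------------------------------------------------------------------
# integer views of the coded matrix, per population
# ---------------------------------------------------------------------------

class PopulationArrays:
    """Per-population integer genotype arrays for fast pairwise counting.

    For population P with parents (a, b): value 0 = allele of a, 1 = allele
    of b, -1 = missing (no-call, heterozygous residual, or marker not scored
    in P).
    """

    def __init__(self, matrix: IntegratedGenotypeMatrix):
        self.marker_index = matrix.codes.index
        self.pos = {m: i for i, m in enumerate(self.marker_index)}
        self.arrays: dict[str, np.ndarray] = {}
        self.scored: dict[str, np.ndarray] = {}
        self.lines: dict[str, list[str]] = {}
        for pop in POPULATIONS:
            lines = matrix.lines_of(pop)
            self.lines[pop] = lines
            scored = matrix.marker_populations.map(
                lambda s, p=pop: p in s).to_numpy(dtype=bool)
            self.scored[pop] = scored
            if not lines:
                self.arrays[pop] = np.full((len(self.marker_index), 0), -1, np.int8)
                continue
            sub = matrix.codes[lines].to_numpy(dtype=object)
            arr = np.full(sub.shape, -1, dtype=np.int8)
            arr[sub == pop[0]] = 0
            arr[sub == pop[1]] = 1
            arr[~scored, :] = -1
            self.arrays[pop] = arr

    def pair_counts(self, i_idx: np.ndarray, j_idx: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Informative and recombinant line counts for marker-index pairs,
        pooled over populations in which both markers are scored."""
        i_idx = np.asarray(i_idx)
        j_idx = np.asarray(j_idx)
        n_inf = np.zeros(len(i_idx), dtype=np.int64)
        n_rec = np.zeros(len(i_idx), dtype=np.int64)
        for pop in POPULATIONS:
            arr = self.arrays[pop]
            if arr.shape[1] == 0:
                continue
            both = self.scored[pop][i_idx] & self.scored[pop][j_idx]
            if not both.any():
                continue
            a = arr[i_idx]
            b = arr[j_idx]
            valid = (a >= 0) & (b >= 0) & both[:, None]
            n_inf += valid.sum(axis=1)
            n_rec += ((a != b) & valid).sum(axis=1)
        return n_inf, n_rec


# ---------------------------------------------------------------------------
# initial order and colormapping refinement
# ---------------------------------------------------------------------------

def initial_order(anchors: pd.DataFrame,
                  orientation: dict | None = None) -> dict:
    """Physical initial order: per LG, markers sorted by bp (ties broken
    lexicographically by marker id, so the order is deterministic).

    ``anchors`` columns: marker, chrom (pseudomolecule = LG assignment), bp.
    ``orientation`` maps LG -> True to flip that group.  A marker appearing
    twice is rejected.
    """
    df = anchors.copy()
    if "marker" not in df.columns:
        df = df.reset_index()
    dupes = df["marker"][df["marker"].duplicated()]
    if len(dupes):
        raise ValueError(f"markers with multiple anchors: {sorted(set(dupes))}")
    order: dict = {}
    for lg, sub in df.groupby("chrom"):
        sub = sub.sort_values(["bp", "marker"], kind="mergesort")
        markers = list(sub["marker"])
        if orientation and orientation.get(lg, False):
            markers = markers[::-1]
        order[lg] = markers
    return order


def _informative_codes(codes_block: np.ndarray) -> list[np.ndarray]:
    """Per line (column), the compressed sequence of non-missing codes."""
    out = []
    for j in range(codes_block.shape[1]):
        col = codes_block[:, j]
        out.append(col[col != MISSING])
    return out


def count_close_double_recombinants(order: list, matrix: IntegratedGenotypeMatrix,
                                    window: int = 1) -> int:
    """Apparent close double recombinants proposed by a marker order.

    Along each line's informative (non-missing) code sequence, counts
    interior runs of length <= ``window`` — genotype blocks requiring two
    nearby crossovers, which a correct order makes rare.  ``window=1``
    counts singleton runs.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    block = matrix.codes.loc[order].to_numpy(dtype=object)
    return _count_short_runs(block, window)


def _count_short_runs(block: np.ndarray, window: int) -> int:
    total = 0
    for seq in _informative_codes(block):
        if len(seq) < 3:
            continue
        change = np.flatnonzero(seq[1:] != seq[:-1])
        if len(change) < 2:
            continue
        run_lengths = np.diff(change)  # lengths of interior runs
        total += int((run_lengths <= window).sum())
    return total


def _objective(block: np.ndarray, perm: np.ndarray, window: int) -> int:
    return _count_short_runs(block[perm], window)


def colormap_refine(order: list, matrix: IntegratedGenotypeMatrix,
                    window: int = 1, move_window: int = 3,
                    exhaustive_max: int = 7) -> list:
    """Refine a marker order to minimise close double recombinants.

    For small groups (<= ``exhaustive_max`` markers) the optimum is found by
    exhaustive permutation.  Larger groups use greedy local search over
    adjacent transpositions and segment inversions of length <=
    ``move_window``; a move is accepted only if it strictly reduces the
    count, so the objective is non-increasing, the search terminates at a
    local minimum, and refinement is idempotent at convergence.
    """
    block = matrix.codes.loc[order].to_numpy(dtype=object)
    n = len(order)
    if n <= 1:
        return list(order)
    if n <= exhaustive_max:
        best_perm = tuple(range(n))
        best = _objective(block, np.array(best_perm), window)
        for perm in itertools.permutations(range(n)):
            c = _objective(block, np.array(perm), window)
            if c < best:
                best, best_perm = c, perm
        return [order[i] for i in best_perm]
    perm = np.arange(n)
    current = _objective(block, perm, window)
    improved = True
    while improved and current > 0:
        improved = False
        for i in range(n - 1):
            for seg in range(2, move_window + 1):
                if i + seg > n:
                    break
                cand = perm.copy()
                cand[i:i + seg] = cand[i:i + seg][::-1]
                c = _objective(block, cand, window)
                if c < current:
                    perm, current = cand, c
                    improved = True
    return [order[i] for i in perm]


# ---------------------------------------------------------------------------
# interval estimates
# ---------------------------------------------------------------------------

@dataclass
class IntervalEstimate:
    """Recombination estimate for one adjacent marker pair."""

    left: str
    right: str
    n_informative: int
    n_recombinant: int
    R: float
    r: float
    d: float
    low_confidence: bool = False  # informative count below n_min
    inherited: bool = False       # R copied from nearest well-estimated interval
    bridged: bool = False         # computed line-wise via flanking markers


def interval_R(matrix: IntegratedGenotypeMatrix, marker_a: str, marker_b: str
               ) -> tuple[int, int]:
    """Informative and recombinant counts for one marker pair.

    Lines come from populations in which both markers are scored; a line is
    informative when non-missing at both markers and recombinant when its
    two codes name different parents.
    """
    pv = PopulationArrays(matrix)
    i = np.array([pv.pos[marker_a]])
    j = np.array([pv.pos[marker_b]])
    n_inf, n_rec = pv.pair_counts(i, j)
    return int(n_inf[0]), int(n_rec[0])


def _bridged_counts(pv: PopulationArrays, order_idx: np.ndarray, k: int
                    ) -> tuple[int, int]:
    """Line-wise interval counts when the flanking pair shares no scored
    population: each line contributes via its own population's nearest
    informative markers on either side of the interval (bridging rule),
    mirroring how per-line crossovers are counted."""
    n_inf = n_rec = 0
    for pop in POPULATIONS:
        arr = pv.arrays[pop]
        if arr.shape[1] == 0:
            continue
        left_block = arr[order_idx[:k + 1]]
        right_block = arr[order_idx[k + 1:]]
        for j in range(arr.shape[1]):
            lcol = left_block[:, j]
            rcol = right_block[:, j]
            lval = lcol[lcol >= 0]
            rval = rcol[rcol >= 0]
            if len(lval) == 0 or len(rval) == 0:
                continue
            n_inf += 1
            n_rec += int(lval[-1] != rval[0])
    return n_inf, n_rec


@dataclass
class LinkageMap:
    """Ordered markers with cumulative cM per LG, plus interval estimates."""

    table: pd.DataFrame  # columns: LG, marker, cM, bp, chrom, populations
    intervals: dict = field(default_factory=dict)  # LG -> [IntervalEstimate]
    unplaced: list = field(default_factory=list)
    mapping_function: str = "haldane"

    def lg_length(self, lg) -> float:
        sub = self.table[self.table["LG"] == lg]
        return float(sub["cM"].max()) if len(sub) else 0.0

    def total_length(self) -> float:
        return float(sum(self.lg_length(lg) for lg in self.table["LG"].unique()))

    def positions(self, lg) -> pd.Series:
        sub = self.table[self.table["LG"] == lg]
        return pd.Series(sub["cM"].to_numpy(), index=sub["marker"].to_numpy())


def assemble_map(order: dict, matrix: IntegratedGenotypeMatrix,
                 n_min: int = 20, mapping_function: str = "haldane",
                 refine: bool = False, window: int = 1) -> LinkageMap:
    """Build the linkage map from a per-LG marker order.

    Adjacent-interval recombination fractions are pooled over the
    populations in which both flanking markers segregate; intervals with
    fewer than ``n_min`` informative lines inherit the nearest
    well-estimated R on the same LG (flagged); pairs sharing no scored
    population fall back to the line-wise bridging rule.  R is converted to
    r and then to cM with the chosen mapping function; cumulative positions
    start at 0 at the first placed marker of each LG.
    """
    if mapping_function not in MAPPING_FUNCTIONS:
        raise ValueError(f"unknown mapping function {mapping_function!r}")
    to_cm = MAPPING_FUNCTIONS[mapping_function]
    pv = PopulationArrays(matrix)
    anchors = matrix.anchors
    rows = []
    intervals: dict = {}
    for lg in sorted(order):
        # markers scored in no population are unmappable and stay unplaced
        markers = [m for m in order[lg] if m in pv.pos
                   and len(matrix.marker_populations.get(m, frozenset())) > 0]
        if refine:
            markers = colormap_refine(markers, matrix, window=window)
        if not markers:
            continue
        order_idx = np.array([pv.pos[m] for m in markers])
        n_inf, n_rec = pv.pair_counts(order_idx[:-1], order_idx[1:])
        ests: list[IntervalEstimate] = []
        for k in range(len(markers) - 1):
            bridged = False
            ni, nr = int(n_inf[k]), int(n_rec[k])
            if ni == 0:
                ni, nr = _bridged_counts(pv, order_idx, k)
                bridged = True
            R = nr / ni if ni else 0.0
            R = min(R, 1.0 - 1e-12)
            r = ril_to_meiotic(R)
            d = to_cm(min(r, 0.5 - 1e-12))
            ests.append(IntervalEstimate(
                left=markers[k], right=markers[k + 1], n_informative=ni,
                n_recombinant=nr, R=R, r=r, d=d,
                low_confidence=ni < n_min, bridged=bridged))
        _inherit_sparse(ests, n_min, to_cm)
        cum = np.concatenate(([0.0], np.cumsum([e.d for e in ests])))
        for m, c in zip(markers, cum):
            row = {"LG": lg, "marker": m, "cM": float(c)}
            if anchors is not None and m in anchors.index:
                row["bp"] = anchors.loc[m, "bp"]
                row["chrom"] = anchors.loc[m, "chrom"]
            pops = matrix.marker_populations.get(m, frozenset())
            row["populations"] = "|".join(sorted(pops))
            rows.append(row)
        intervals[lg] = ests
    table = pd.DataFrame(rows)
    placed = set(table["marker"]) if len(table) else set()
    unplaced = [m for m in matrix.codes.index if m not in placed]
    return LinkageMap(table=table, intervals=intervals, unplaced=unplaced,
                      mapping_function=mapping_function)


def _inherit_sparse(ests: list, n_min: int, to_cm) -> None:
    """Low-confidence intervals inherit the nearest well-estimated R."""
    good = [k for k, e in enumerate(ests) if not e.low_confidence and not e.bridged]
    if not good:
        return
    for k, e in enumerate(ests):
        if not e.low_confidence:
            continue
        nearest = min(good, key=lambda g: (abs(g - k), g))
        src = ests[nearest]
        e.R, e.r, e.d = src.R, src.r, src.d
        e.inherited = True


# ---------------------------------------------------------------------------
# unanchored marker placement
# ---------------------------------------------------------------------------

def place_unanchored(marker: str, matrix: IntegratedGenotypeMatrix,
                     lmap: LinkageMap, n_min: int = 20) -> dict | None:
    """Place a scaffold/unanchored marker next to its closest placed marker.

    Closeness is the pairwise RIL recombination fraction over shared
    informative lines (at least ``n_min`` of them); ties resolve to the
    marker earlier in map order.  Returns None (reported unplaced) when no
    placed marker shares enough informative lines.
    """
    pv = PopulationArrays(matrix)
    if marker not in pv.pos:
        raise KeyError(f"unknown marker {marker!r}")
    placed = [m for m in lmap.table["marker"] if m in pv.pos and m != marker]
    if not placed:
        return None
    i = np.full(len(placed), pv.pos[marker])
    j = np.array([pv.pos[m] for m in placed])
    n_inf, n_rec = pv.pair_counts(i, j)
    ok = n_inf >= n_min
    if not ok.any():
        return None
    R = np.where(ok, n_rec / np.maximum(n_inf, 1), np.inf)
    best = int(np.argmin(R))  # argmin returns the first (earlier) on ties
    host = placed[best]
    host_row = lmap.table[lmap.table["marker"] == host].iloc[0]
    return {"marker": marker, "host": host, "R": float(R[best]),
            "n_informative": int(n_inf[best]),
            "LG": host_row["LG"], "cM": float(host_row["cM"])}


# ---------------------------------------------------------------------------
# IBD gaps
# ---------------------------------------------------------------------------

@dataclass
class IBDGap:
    lg: object
    left: str
    right: str
    start_cM: float
    end_cM: float
    length_cM: float
    lacking_populations: tuple  # populations with no marker inside the gap


def detect_ibd_gaps(lmap: LinkageMap, threshold: float = 10.0) -> list[IBDGap]:
    """Adjacent-marker intervals longer than ``threshold`` cM.

    Between adjacent markers of the integrated map no population has a
    segregating marker, so a long interval is devoid of polymorphism in all
    three populations — the signature of a region identical by descent in
    all three founders; its length is set by the recombination fraction
    between the flanking markers.
    """
    gaps = []
    for lg, ests in lmap.intervals.items():
        pos = lmap.positions(lg)
        for e in ests:
            if e.d > threshold:
                gaps.append(IBDGap(
                    lg=lg, left=e.left, right=e.right,
                    start_cM=float(pos[e.left]), end_cM=float(pos[e.right]),
                    length_cM=float(e.d),
                    lacking_populations=tuple(POPULATIONS)))
    return gaps


def population_marker_gaps(lmap: LinkageMap, matrix: IntegratedGenotypeMatrix,
                           threshold: float = 10.0) -> pd.DataFrame:
    """Per-population spans of the map devoid of that population's markers.

    A long span lacking markers that segregate in population XY means the
    parents X and Y share the region identically by descent (pairwise IBD),
    even where the integrated map itself is well covered by the other two
    populations.  Returns one row per (population, span) over ``threshold``.
    """
    rows = []
    for lg in sorted(lmap.intervals):
        sub = lmap.table[lmap.table["LG"] == lg]
        for pop in POPULATIONS:
            scored = sub["populations"].str.contains(pop, regex=False)
            pts = sub.loc[scored, "cM"].to_numpy()
            bounds = np.concatenate(([sub["cM"].min()], pts, [sub["cM"].max()]))
            d = np.diff(bounds)
            for k in np.flatnonzero(d > threshold):
                rows.append({"LG": lg, "population": pop,
                             "start_cM": float(bounds[k]),
                             "end_cM": float(bounds[k + 1]),
                             "length_cM": float(d[k]),
                             "implied_sharing": pop})
    return pd.DataFrame(rows, columns=["LG", "population", "start_cM",
                                       "end_cM", "length_cM", "implied_sharing"])
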