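"""Parent-of-origin coding of biallelic SNP calls across three founders.

A biallelic SNP among three inbred founders is either monomorphic or splits
them 2:1 — two founders share an allele and the third differs.  Recording
each RIL call as the *letter of the parent* carrying that allele (B/E/K)
rather than the nucleotide makes one marker informative in the two
populations where it segregates, which is what allows the three biparental
maps to be merged into a single integrated matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import MISSING, PARENTS, POPULATIONS

#: segregation pattern labels, keyed by the pair of founders sharing an allele
PATTERNS = {"BE": "B=E", "BK": "B=K", "EK": "E=K"}


@dataclass
class TrioAlleleTable:
    """Per-marker alleles of the three founders plus the derived pattern.

    ``table`` columns: marker (index), allele_B, allele_E, allele_K,
    pattern in {'B=E', 'B=K', 'E=K', 'mono'}, segregates_in (frozenset of
    population labels).  Markers with more than two distinct alleles across
    the trio are rejected and listed in ``rejected``.
    """

    table: pd.DataFrame
    rejected: list[str] = field(default_factory=list)


def _pattern(a_b: str, a_e: str, a_k: str) -> str:
    if a_b == a_e == a_k:
        return "mono"
    if a_b == a_e:
        return "B=E"
    if a_b == a_k:
        return "B=K"
    return "E=K"


#: populations in which a marker of a given pattern segregates
PATTERN_POPULATIONS = {
    "B=E": frozenset({"BK", "EK"}),
    "B=K": frozenset({"BE", "EK"}),
    "E=K": frozenset({"BE", "BK"}),
    "mono": frozenset(),
}


def build_trio_table(parent_calls: pd.DataFrame) -> TrioAlleleTable:
    """Classify markers from the three founders' calls.

    ``parent_calls``: columns allele_B/allele_E/allele_K (or B/E/K), indexed
    by marker or with a 'marker' column.  Markers with a missing parental
    call or more than two distinct alleles are rejected.
    """
    df = parent_calls.copy()
    if "marker" in df.columns:
        df = df.set_index("marker")
    df = df.rename(columns={p: f"allele_{p}" for p in PARENTS})
    cols = [f"allele_{p}" for p in PARENTS]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"parent call table lacks columns {missing}")
    rejected = []
    rows = []
    for marker, row in df[cols].iterrows():
        alleles = [str(row[c]) for c in cols]
        if MISSING in alleles or len(set(alleles)) > 2:
            rejected.append(marker)
            continue
        pat = _pattern(*alleles)
        rows.append({"marker": marker, "allele_B": alleles[0],
                     "allele_E": alleles[1], "allele_K": alleles[2],
                     "pattern": pat,
                     "segregates_in": PATTERN_POPULATIONS[pat]})
    table = pd.DataFrame(rows).set_index("marker") if rows else pd.DataFrame(
        columns=["allele_B", "allele_E", "allele_K", "pattern", "segregates_in"])
    return TrioAlleleTable(table=table, rejected=rejected)


@dataclass
class CodedMatrix:
    """Coded calls for one population: marker x line, values in {B,E,K,'-'}.

    ``structural_missing`` flags markers that do not segregate between the
    population's parents (every line '-' by construction, not by no-call);
    ``n_mismatched`` counts calls matching neither parental allele (set to
    missing and reported rather than guessed)."""

    population: str
    codes: pd.DataFrame
    structural_missing: pd.Series
    n_mismatched: int


def classify_and_encode(trio: TrioAlleleTable, pop_calls: pd.DataFrame,
                        population: str) -> CodedMatrix:
    """Map a population's raw nucleotide calls to parent-of-origin codes.

    A line's allele becomes the letter of the parent (within this
    population's parental pair) carrying that allele.  Markers monomorphic
    between the two parents are structurally missing; no-calls stay missing;
    alleles matching neither parent are counted and set missing.  Calls
    already given as parent letters pass through unchanged (the two dialects
    can be mixed per marker, since codes and nucleotides never collide).
    """
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}")
    pa, pb = population[0], population[1]
    t = trio.table
    idx = pop_calls.index.intersection(t.index)
    calls = pop_calls.loc[idx]
    allele_a = t.loc[idx, f"allele_{pa}"].to_numpy()
    allele_b = t.loc[idx, f"allele_{pb}"].to_numpy()
    segregates = allele_a != allele_b
    vals = calls.to_numpy(dtype=object)
    out = np.full(vals.shape, MISSING, dtype=object)
    seg = segregates[:, None]
    # nucleotide dialect, plus pass-through of calls already given as the
    # letters of this population's parents (the two never collide)
    is_a = seg & ((vals == allele_a[:, None]) | (vals == pa))
    is_b = seg & ((vals == allele_b[:, None]) | (vals == pb))
    out[is_a] = pa
    out[is_b] = pb
    unrecognised = seg & ~is_a & ~is_b & (vals != MISSING)
    n_mismatch = int(unrecognised.sum())
    codes = pd.DataFrame(out, index=idx, columns=calls.columns)
    codes.index.name = "marker"
    return CodedMatrix(population=population, codes=codes,
                       structural_missing=pd.Series(~segregates, index=idx),
                       n_mismatched=n_mismatch)


@dataclass
class IntegratedGenotypeMatrix:
    """One row per marker, one column per RIL across all three populations."""

    codes: pd.DataFrame                 # marker x line
    line_populations: pd.Series         # line -> population label
    marker_populations: pd.Series       # marker -> frozenset of populations
                                        # in which it was scored (segregating)
    anchors: pd.DataFrame | None = None

    def lines_of(self, population: str) -> list[str]:
        return list(self.line_populations[self.line_populations == population].index)


def merge_populations(coded: dict[str, CodedMatrix],
                      anchors: pd.DataFrame | None = None
                      ) -> IntegratedGenotypeMatrix:
    """Merge per-population coded matrices into the integrated matrix.

    Line ids must be unique across populations (use population-prefixed
    names); duplicate ids are rejected.  A marker's scored-population set is
    the set of populations in which it segregates and has at least one
    non-missing call.
    """
    all_lines: list[str] = []
    pops: list[str] = []
    for pop_name, cm in coded.items():
        all_lines.extend(cm.codes.columns)
        pops.extend([pop_name] * len(cm.codes.columns))
    dupes = pd.Index(all_lines).duplicated()
    if dupes.any():
        raise ValueError(
            f"duplicate line ids across populations: {list(pd.Index(all_lines)[dupes])}")
    markers = pd.Index([])
    for cm in coded.values():
        markers = markers.union(cm.codes.index)
    blocks = []
    scored: dict[str, set[str]] = {m: set() for m in markers}
    for pop_name, cm in coded.items():
        block = cm.codes.reindex(markers, fill_value=MISSING)
        seg = ~cm.structural_missing.reindex(markers, fill_value=True)
        has_call = (block.to_numpy(dtype=object) != MISSING).any(axis=1)
        for m in markers[seg.to_numpy() & has_call]:
            scored[m].add(pop_name)
        blocks.append(block)
    codes = pd.concat(blocks, axis=1)
    codes.index.name = "marker"
    line_pops = pd.Series(pops, index=all_lines, name="population")
    marker_pops = pd.Series({m: frozenset(s) for m, s in scored.items()},
                            name="populations").reindex(markers)
    if anchors is not None and "marker" in anchors.columns:
        anchors = anchors.set_index("marker")
    return IntegratedGenotypeMatrix(codes=codes, line_populations=line_pops,
                                    marker_populations=marker_pops,
                                    anchors=anchors)


def marker_summary(matrix: IntegratedGenotypeMatrix,
                   lg_of: pd.Series | None = None) -> pd.DataFrame:
    """Per-LG tally of scored markers: totals, per population, unique-to and
    shared-by columns — the bookkeeping table behind the relatedness tests.

    ``lg_of`` maps marker -> linkage group; defaults to the anchor
    chromosome.  Markers scored in a single population (allele-calling
    dropouts) appear in the unique-to columns; the shared-by columns cover
    markers scored in exactly two populations.
    """
    if lg_of is None:
        if matrix.anchors is None:
            raise ValueError("need anchors or an explicit marker->LG mapping")
        lg_of = matrix.anchors["chrom"]
    mp = matrix.marker_populations
    rows = {}
    lgs = sorted(pd.unique(lg_of.loc[mp.index].dropna()))
    for lg in lgs:
        members = mp[lg_of.reindex(mp.index) == lg]
        members = members[members.map(len) > 0]
        row = {"total": len(members)}
        for pop in POPULATIONS:
            row[pop] = int(members.map(lambda s: pop in s).sum())
        for pop in POPULATIONS:
            row[f"unique_{pop}"] = int(members.map(lambda s: s == {pop}).sum())
        for pair in ("BE&BK", "BE&EK", "BK&EK"):
            a, b = pair.split("&")
            row[f"shared_{pair}"] = int(members.map(lambda s: s == {a, b}).sum())
        rows[lg] = row
    df = pd.DataFrame(rows).T
    df.index.name = "LG"
    df.loc["total"] = df.sum(axis=0)
    return df.astype(int)


def decode(coded: CodedMatrix, trio: TrioAlleleTable) -> pd.DataFrame:
    """Invert the coding: parent letters back to nucleotides ('-' preserved)."""
    t = trio.table
    codes = coded.codes
    out = codes.copy()
    for p in PARENTS:
        allele = t[f"allele_{p}"].reindex(codes.index)
        mask = codes == p
        for col in codes.columns:
            out.loc[mask[col], col] = allele[mask[col]]
    return out
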