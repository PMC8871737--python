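"""Forward simulation of three-way recombinant inbred line (RIL) populations.

Three inbred founders (labelled B, E and K) are given marker genotypes with a
controlled identity-by-descent (IBD) structure; the three pairwise crosses
(BE, BK, EK) are then advanced by single-seed descent (SSD), with meioses
drawing Poisson crossovers on the genetic (cM) scale.  The module emits the
same plain-text tables a genotyping provider would: raw nucleotide calls or
parent-of-origin codes per population, a physical/genetic marker anchor
table, a phenotype table with planted additive QTL, and a truth record of
realised crossover junctions for validation.

Genomes are represented continuously: a haplotype is a piecewise-constant
founder-origin function on [0, L] cM, stored as sorted breakpoints plus an
origin label per segment.  Markers only come in at read-out time, so marker
density and crossover process are decoupled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

PARENTS = ("B", "E", "K")
POPULATIONS = ("BE", "BK", "EK")
MISSING = "-"

# Nucleotide pairs cycled over when assigning SNP alleles to markers.
_SNP_PAIRS = (("T", "C"), ("T", "G"), ("A", "G"), ("A", "C"))

# Pea-like defaults: seven chromosomes, genetic lengths (cM) and physical
# pseudomolecule lengths (Mb) of the order seen in cultivated pea.
_DEFAULT_CM = (110.0, 126.0, 151.0, 132.0, 126.0, 138.0, 145.0)
_DEFAULT_MB = (342.0, 384.0, 463.0, 357.0, 438.0, 298.0, 393.0)


@dataclass(frozen=True)
class IBDBlock:
    """A genomic segment shared identically by two or all three founders."""

    chrom: int  # 1-based chromosome index
    start_cM: float
    end_cM: float
    sharing: str  # "BEK", "BE", "BK" or "EK"

    def __post_init__(self) -> None:
        if self.sharing not in ("BEK", "BE", "BK", "EK"):
            raise ValueError(f"unknown sharing set {self.sharing!r}")
        if not self.start_cM < self.end_cM:
            raise ValueError("IBD block must have start_cM < end_cM")


@dataclass
class SimConfig:
    """Parameters of the founder/RIL simulation.

    The mean number of crossovers per gamete on chromosome ``c`` is tied to
    its genetic length: ``lambda_gamete[c] = chrom_cM[c] / 100``.  With
    ``obligate_chiasma`` the bivalent draws a zero-truncated Poisson count
    (mean ``2*lambda``) and each crossover is transmitted to the gamete with
    probability one half, so every bivalent has at least one chiasma while
    the gamete-level mean stays close to ``lambda``.
    """

    n_chromosomes: int = 7
    chrom_cM: Sequence[float] = _DEFAULT_CM
    chrom_Mb: Sequence[float] = _DEFAULT_MB
    n_markers_per_chrom: int = 650
    obligate_chiasma: bool = True
    n_lines: int = 200  # per population
    generations: int | str = 13  # final generation number, or "fixation"
    missing_rate: float = 0.02
    ibd_blocks: Sequence[IBDBlock] = ()
    # probability that the differing founder of a marker is B, E, K
    diff_parent_props: Sequence[float] = (0.25, 0.25, 0.5)
    # central fraction of the physical length that is pericentromeric, and
    # the fraction of the genetic length it carries (recombination-poor)
    pericentromere_bp_frac: float = 0.4
    pericentromere_cM_frac: float = 0.1
    qtl: Sequence[tuple[str, float]] = ()
    pheno_sigma: float = 1.0
    seed: int = 0

    @property
    def lambda_gamete(self) -> np.ndarray:
        """Mean crossovers per gamete per chromosome (= chrom_cM / 100)."""
        return np.asarray(self.chrom_cM, dtype=float) / 100.0

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if len(self.chrom_cM) != self.n_chromosomes:
            raise ValueError("chrom_cM length != n_chromosomes")
        if len(self.chrom_Mb) != self.n_chromosomes:
            raise ValueError("chrom_Mb length != n_chromosomes")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        props = np.asarray(self.diff_parent_props, dtype=float)
        if props.shape != (3,) or (props < 0).any() or not np.isclose(props.sum(), 1.0):
            raise ValueError("diff_parent_props must be three probabilities summing to 1")
        if not (0.0 < self.pericentromere_bp_frac < 1.0
                and 0.0 < self.pericentromere_cM_frac < 1.0):
            raise ValueError("pericentromere fractions must lie in (0, 1)")
        if isinstance(self.generations, str):
            if self.generations != "fixation":
                raise ValueError("generations must be an int >= 2 or 'fixation'")
        elif self.generations < 2:
            raise ValueError("generations < 2: no selfing has happened")
        for blk in self.ibd_blocks:
            if not 1 <= blk.chrom <= self.n_chromosomes:
                raise ValueError(f"IBD block on unknown chromosome {blk.chrom}")
            if blk.end_cM > self.chrom_cM[blk.chrom - 1]:
                raise ValueError("IBD block extends past chromosome end")
        _check_block_overlaps(self.ibd_blocks)


def _check_block_overlaps(blocks: Sequence[IBDBlock]) -> None:
    """Reject overlapping blocks with different sharing sets.

    Two overlapping pairwise blocks with different sharing (e.g. BE and BK)
    would force all three founders identical, contradicting the pairwise
    label; overlaps are rejected outright rather than silently merged.
    """
    by_chrom: dict[int, list[IBDBlock]] = {}
    for blk in blocks:
        by_chrom.setdefault(blk.chrom, []).append(blk)
    for blks in by_chrom.values():
        blks = sorted(blks, key=lambda b: b.start_cM)
        for a, b in zip(blks, blks[1:]):
            if b.start_cM < a.end_cM and a.sharing != b.sharing:
                raise ValueError(
                    f"contradictory overlapping IBD blocks {a} and {b}")


# ---------------------------------------------------------------------------
# physical <-> genetic coordinate map
# ---------------------------------------------------------------------------

def _bp_cm_nodes(length_mb: float, length_cm: float, bp_frac: float,
                 cm_frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear bp->cM map: two recombining arms flanking a
    recombination-poor pericentromeric core, giving the sigmoid shape seen
    when genetic maps are plotted against chromosome assemblies."""
    bp = np.array([0.0,
                   length_mb * (1 - bp_frac) / 2,
                   length_mb * (1 + bp_frac) / 2,
                   length_mb]) * 1e6
    cm = np.array([0.0,
                   length_cm * (1 - cm_frac) / 2,
                   length_cm * (1 + cm_frac) / 2,
                   length_cm])
    return bp, cm


def cm_from_bp(config: SimConfig, chrom: int, bp: np.ndarray) -> np.ndarray:
    """Map physical positions (bp) to genetic positions (cM) on a chromosome."""
    nodes_bp, nodes_cm = _bp_cm_nodes(
        config.chrom_Mb[chrom - 1], config.chrom_cM[chrom - 1],
        config.pericentromere_bp_frac, config.pericentromere_cM_frac)
    return np.interp(np.asarray(bp, dtype=float), nodes_bp, nodes_cm)


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

@dataclass
class FounderSet:
    """Marker anchors plus the three founders' alleles at every marker.

    ``markers`` columns: marker, chrom, bp, cM, allele_B, allele_E, allele_K,
    diff_parent ('B'/'E'/'K' for the founder carrying the minor allele, or
    'mono' for a marker identical in all three founders).
    """

    markers: pd.DataFrame
    config: SimConfig

    def segregating(self, population: str) -> pd.Series:
        """Boolean mask of markers polymorphic between a population's parents."""
        a, b = population[0], population[1]
        return self.markers[f"allele_{a}"] != self.markers[f"allele_{b}"]


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None
                      ) -> FounderSet:
    """Place markers and assign founder alleles under the IBD-block model.

    Outside IBD blocks each marker's differing founder is drawn from
    ``diff_parent_props``, so every polymorphic marker separates exactly one
    founder from the other two.  Inside a pairwise block the differing
    founder is forced to the non-sharing one; inside a tri-shared (BEK)
    block markers are monomorphic and hence unmappable.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    n = config.n_markers_per_chrom
    for chrom in range(1, config.n_chromosomes + 1):
        length_bp = config.chrom_Mb[chrom - 1] * 1e6
        # near-uniform physical placement with jitter, kept sorted
        base = (np.arange(n) + 0.5) / n * length_bp
        jitter = rng.uniform(-0.4, 0.4, n) * length_bp / n
        bp = np.sort(np.clip(base + jitter, 1, length_bp)).round().astype(np.int64)
        cm = cm_from_bp(config, chrom, bp)
        blocks = [b for b in config.ibd_blocks if b.chrom == chrom]
        diff = rng.choice(PARENTS, size=n, p=list(config.diff_parent_props))
        for i in range(n):
            d = diff[i]
            for blk in blocks:
                if blk.start_cM <= cm[i] < blk.end_cM:
                    if blk.sharing == "BEK":
                        d = "mono"
                    else:
                        # the differing founder is the one not in the block
                        d = next(p for p in PARENTS if p not in blk.sharing)
                    break
            ref, alt = _SNP_PAIRS[rng.integers(len(_SNP_PAIRS))]
            alleles = {p: ref for p in PARENTS}
            if d != "mono":
                alleles[d] = alt
            rows.append({
                "marker": f"M{chrom}_{i:04d}", "chrom": chrom,
                "bp": int(bp[i]), "cM": cm[i],
                "allele_B": alleles["B"], "allele_E": alleles["E"],
                "allele_K": alleles["K"], "diff_parent": d,
            })
    return FounderSet(markers=pd.DataFrame(rows), config=config)


# ---------------------------------------------------------------------------
# haplotypes and meiosis
# ---------------------------------------------------------------------------
# A haplotype on one chromosome is (breaks, origins): `breaks` are the sorted
# interior breakpoints (cM) and `origins` the founder index (0 = parent A,
# 1 = parent B of the cross) on each of the len(breaks)+1 segments.

Haplotype = tuple[np.ndarray, np.ndarray]


def _fresh_haplotype(origin: int) -> Haplotype:
    return np.empty(0, dtype=float), np.array([origin], dtype=np.int8)


def _canonical(breaks: np.ndarray, origins: np.ndarray) -> Haplotype:
    """Merge adjacent segments with equal origin."""
    if len(origins) <= 1:
        return breaks, origins
    keep = origins[1:] != origins[:-1]
    return breaks[keep], np.concatenate(([origins[0]], origins[1:][keep]))


def _origin_at(hap: Haplotype, pos: np.ndarray) -> np.ndarray:
    breaks, origins = hap
    return origins[np.searchsorted(breaks, pos, side="right")]


def _n_crossovers(lam: float, obligate: bool, rng: np.random.Generator) -> int:
    if not obligate:
        return int(rng.poisson(lam))
    # zero-truncated Poisson on the bivalent (mean 2*lam), thinned by 1/2
    mu = 2.0 * lam
    k = int(rng.poisson(mu))
    while k == 0:
        k = int(rng.poisson(mu))
    return int(rng.binomial(k, 0.5))


def meiosis(hap_a: Haplotype, hap_b: Haplotype, length_cm: float, lam: float,
            obligate: bool, rng: np.random.Generator) -> Haplotype:
    """Produce one gamete from a diploid (hap_a, hap_b) on one chromosome.

    Crossover count is Poisson(lam) (optionally via an obligate-chiasma
    bivalent, see SimConfig); positions are uniform on the cM scale, i.e.
    no interference beyond the optional count truncation.
    """
    n_co = _n_crossovers(lam, obligate, rng)
    xs = np.sort(rng.uniform(0.0, length_cm, n_co))
    start = int(rng.integers(2))
    if n_co == 0:
        return (hap_a, hap_b)[start]
    haps = (hap_a, hap_b)
    out_breaks: list[float] = []
    out_origins: list[int] = []
    bounds = np.concatenate((xs, [length_cm]))
    seg_start = 0.0
    cur = start
    for x in bounds:
        br, og = haps[cur]
        i0 = int(np.searchsorted(br, seg_start, side="right"))
        i1 = int(np.searchsorted(br, x, side="left"))
        out_origins.append(int(og[i0]))
        for k in range(i0, i1):
            out_breaks.append(float(br[k]))
            out_origins.append(int(og[k + 1]))
        if x < length_cm:
            out_breaks.append(float(x))
        seg_start = x
        cur ^= 1
    return _canonical(np.asarray(out_breaks), np.asarray(out_origins, dtype=np.int8))


def _homozygous(pair: tuple[Haplotype, Haplotype]) -> bool:
    (ba, oa), (bb, ob) = pair
    return np.array_equal(oa, ob) and np.array_equal(ba, bb)


_MAX_FIXATION_GENERATIONS = 500


@dataclass
class RilLine:
    """One inbred line: per-chromosome haplotype pairs plus metadata."""

    name: str
    population: str
    chromosomes: list[tuple[Haplotype, Haplotype]]
    generation: int

    def is_fixed(self) -> bool:
        return all(_homozygous(pair) for pair in self.chromosomes)

    def junctions(self, chrom: int) -> np.ndarray:
        """Breakpoints (cM) of haplotype 1 on a chromosome (1-based index).
        At fixation both haplotypes agree, so these are the line's realised
        parent-of-origin junctions."""
        return self.chromosomes[chrom - 1][0][0].copy()


def _advance_line(line: RilLine, config: SimConfig, rng: np.random.Generator,
                  n_selfings: int | None) -> None:
    """Self by single-seed descent; None means until fully homozygous."""
    lam = config.lambda_gamete
    cm = config.chrom_cM
    done = 0
    while True:
        if n_selfings is not None and done >= n_selfings:
            break
        if n_selfings is None:
            if line.is_fixed():
                break
            if done >= _MAX_FIXATION_GENERATIONS:  # pragma: no cover
                raise RuntimeError("fixation not reached; check configuration")
        new = []
        for c, pair in enumerate(line.chromosomes):
            if _homozygous(pair):
                new.append(pair)  # selfing cannot change a homozygous chromosome
                continue
            g1 = meiosis(pair[0], pair[1], cm[c], lam[c], config.obligate_chiasma, rng)
            g2 = meiosis(pair[0], pair[1], cm[c], lam[c], config.obligate_chiasma, rng)
            new.append((g1, g2))
        line.chromosomes = new
        line.generation += 1
        done += 1


def simulate_ril_line(name: str, population: str, config: SimConfig,
                      rng: np.random.Generator) -> RilLine:
    f1 = [( _fresh_haplotype(0), _fresh_haplotype(1))
          for _ in range(config.n_chromosomes)]
    line = RilLine(name=name, population=population, chromosomes=f1, generation=1)
    if config.generations == "fixation":
        _advance_line(line, config, rng, None)
    else:
        _advance_line(line, config, rng, int(config.generations) - 1)
    return line


# ---------------------------------------------------------------------------
# population-level simulation and read-out
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPopulation:
    population: str  # e.g. "BE"
    lines: list[RilLine]
    genotypes: pd.DataFrame       # marker x line, codes in {A-parent, B-parent, '-'}
    raw_calls: pd.DataFrame       # marker x line, nucleotide calls or '-'


def simulate_ril_population(founders: FounderSet, parent_a: str, parent_b: str,
                            config: SimConfig, rng: np.random.Generator
                            ) -> SimulatedPopulation:
    """Simulate one biparental RIL population and read out marker calls.

    Parent-of-origin codes are the parent letters; residual heterozygous
    calls and uniformly-missing calls are emitted as '-'.  ``raw_calls``
    holds the corresponding nucleotide calls (the form a genotyping provider
    would deliver), derived from the founder alleles of the origin parent.
    """
    if parent_a == parent_b:
        raise ValueError("parents of a cross must differ")
    pop = parent_a + parent_b
    mk = founders.markers
    lines = [simulate_ril_line(f"{pop}{i + 1}", pop, config, rng)
             for i in range(config.n_lines)]
    code_cols: dict[str, np.ndarray] = {}
    parent_letters = np.array([parent_a, parent_b])
    n_mk = len(mk)
    pos_by_chrom = {c: (mk["chrom"] == c).to_numpy() for c in
                    range(1, config.n_chromosomes + 1)}
    for line in lines:
        codes = np.full(n_mk, MISSING, dtype=object)
        for chrom in range(1, config.n_chromosomes + 1):
            sel = pos_by_chrom[chrom]
            pos = mk.loc[sel, "cM"].to_numpy()
            o1 = _origin_at(line.chromosomes[chrom - 1][0], pos)
            o2 = _origin_at(line.chromosomes[chrom - 1][1], pos)
            hom = o1 == o2
            vals = np.where(hom, parent_letters[o1], MISSING)
            codes[sel] = vals
        if config.missing_rate > 0:
            mask = rng.random(n_mk) < config.missing_rate
            codes[mask] = MISSING
        code_cols[line.name] = codes
    geno = pd.DataFrame(code_cols, index=mk["marker"].to_numpy())
    geno.index.name = "marker"
    # nucleotide view: allele of the origin parent; '-' propagates
    raw = geno.copy()
    for p in (parent_a, parent_b):
        allele = mk.set_index("marker")[f"allele_{p}"]
        for col in raw.columns:
            raw[col] = np.where(geno[col].to_numpy() == p,
                                allele.to_numpy(), raw[col].to_numpy())
    # a marker monomorphic between this cross's parents is unobservable as a
    # parent-of-origin code (structural missing), though its shared
    # nucleotide is still called
    seg = founders.segregating(pop).to_numpy()
    geno.loc[~seg, :] = MISSING
    return SimulatedPopulation(population=pop, lines=lines,
                               genotypes=geno, raw_calls=raw)


def simulate_all_populations(founders: FounderSet, config: SimConfig,
                             rng: np.random.Generator | None = None
                             ) -> dict[str, SimulatedPopulation]:
    """Simulate the three pairwise crosses in the fixed order BE, BK, EK."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    return {p: simulate_ril_population(founders, p[0], p[1], config, rng)
            for p in POPULATIONS}


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(populations: dict[str, SimulatedPopulation],
                        founders: FounderSet, config: SimConfig,
                        rng: np.random.Generator | None = None,
                        pop_offsets: dict[str, tuple[float, float]] | None = None
                        ) -> pd.DataFrame:
    """Additive-QTL trait values per line.

    trait = sum_i effect_i * s_i + Normal(0, pheno_sigma), where the signed
    genotype s_i is +1 when the line carries the minor allele at QTL i (the
    allele of that marker's differing founder), -1 for the major allele and
    0 for a residually heterozygous call.  Genotypes come from the true
    simulated origins, so a QTL contributes in every population, also where
    the marker itself does not segregate.  ``pop_offsets`` maps population ->
    (location, scale) applied afterwards, to exercise normalisation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    mk = founders.markers.set_index("marker")
    for marker_id, _ in config.qtl:
        if marker_id not in mk.index:
            raise KeyError(f"unknown QTL marker {marker_id!r}")
    rows = []
    for pop_name, pop in populations.items():
        parent_letters = (pop_name[0], pop_name[1])
        for line in pop.lines:
            total = 0.0
            for marker_id, effect in config.qtl:
                row = mk.loc[marker_id]
                pos = np.array([row["cM"]])
                pair = line.chromosomes[int(row["chrom"]) - 1]
                o1 = int(_origin_at(pair[0], pos)[0])
                o2 = int(_origin_at(pair[1], pos)[0])
                if o1 != o2:
                    continue  # residual heterozygote: no additive contribution
                carried = parent_letters[o1]
                minor = row["diff_parent"]
                s = 1.0 if carried == minor else -1.0
                total += effect * s
            trait = total + rng.normal(0.0, config.pheno_sigma)
            if pop_offsets and pop_name in pop_offsets:
                loc, scale = pop_offsets[pop_name]
                trait = trait * scale + loc
            rows.append({"line": line.name, "population": pop_name,
                         "trait": trait})
    return pd.DataFrame(rows, columns=["line", "population", "trait"])


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_dataset(out_dir: str | Path, founders: FounderSet,
                  populations: dict[str, SimulatedPopulation],
                  phenotypes: pd.DataFrame | None = None,
                  raw: bool = False) -> dict[str, str]:
    """Write the simulated dataset as plain-text tables; returns path map.

    Per population: genotype TSV (rows = markers, columns = lines; codes or,
    with ``raw=True``, nucleotide calls).  Plus parent-call TSV, anchor TSV
    (marker, chrom, bp, true_cM), optional phenotype CSV, and a truth JSON
    with per-line junction positions and the planted QTL.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    mk = founders.markers
    anchors = mk[["marker", "chrom", "bp", "cM"]].rename(columns={"cM": "true_cM"})
    p = out / "anchors.tsv"
    anchors.to_csv(p, sep="\t", index=False)
    paths["anchors"] = str(p)
    parents = mk[["marker", "allele_B", "allele_E", "allele_K"]]
    p = out / "parents.tsv"
    parents.to_csv(p, sep="\t", index=False)
    paths["parents"] = str(p)
    for pop_name, pop in populations.items():
        table = pop.raw_calls if raw else pop.genotypes
        p = out / f"genotypes_{pop_name}.tsv"
        table.to_csv(p, sep="\t")
        paths[f"genotypes_{pop_name}"] = str(p)
    if phenotypes is not None:
        p = out / "phenotypes.csv"
        phenotypes.to_csv(p, index=False)
        paths["phenotypes"] = str(p)
    truth = {
        "qtl": [list(q) for q in founders.config.qtl],
        "junctions": {
            line.name: {str(c): line.junctions(c).tolist()
                        for c in range(1, founders.config.n_chromosomes + 1)}
            for pop in populations.values() for line in pop.lines
        },
    }
    p = out / "truth.json"
    p.write_text(json.dumps(truth))
    paths["truth"] = str(p)
    return paths


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["ibd_blocks"] = [dataclasses.asdict(b) for b in config.ibd_blocks]
    d["chrom_cM"] = list(config.chrom_cM)
    d["chrom_Mb"] = list(config.chrom_Mb)
    d["diff_parent_props"] = list(config.diff_parent_props)
    d["qtl"] = [list(q) for q in config.qtl]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["ibd_blocks"] = tuple(IBDBlock(**b) for b in d.get("ibd_blocks", ()))
    d["qtl"] = tuple((str(m), float(e)) for m, e in d.get("qtl", ()))
    return SimConfig(**d)
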