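"""End-to-end orchestration: simulate -> encode -> relatedness -> map ->
stats -> physical -> scan -> enrich, with a manifest for reproducibility.

Every stage writes plain-text TSV/CSV and can be re-run from its inputs
alone; the manifest records the configuration hash, seed and a checksum per
output, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import coding, enrichment, mapping, physical, recomb, relatedness, scan
from .simulate import (IBDBlock, SimConfig, config_to_dict,
                       simulate_all_populations, simulate_founders,
                       simulate_phenotypes, write_dataset)

log = logging.getLogger("trimap")


@dataclass
class RunConfig:
    """Thresholds and switches of the analysis pipeline."""

    gap_threshold_cM: float = 10.0
    n_min_informative: int = 20
    scan_class_n_min: int = 5
    colormap_window: int = 1
    runs_bin_width_cM: float = 2.0
    cm_mb_span: int = 10
    mapping_function: str = "haldane"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> None:
        for name in ("gap_threshold_cM", "n_min_informative", "scan_class_n_min",
                     "colormap_window", "runs_bin_width_cM", "cm_mb_span"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.mapping_function not in mapping.MAPPING_FUNCTIONS:
            raise ValueError(f"unknown mapping function {self.mapping_function!r}")


def demo_config(seed: int = 0) -> RunConfig:
    """A small, fully-featured demonstration configuration: three
    chromosomes with tri-shared and pairwise IBD blocks, a pairwise block
    covering most of the last chromosome, and one planted seed-weight QTL."""
    sim = SimConfig(
        n_chromosomes=3,
        chrom_cM=(110.0, 126.0, 145.0),
        chrom_Mb=(342.0, 384.0, 393.0),
        n_markers_per_chrom=220,
        n_lines=120,
        generations=13,
        missing_rate=0.02,
        ibd_blocks=(
            IBDBlock(1, 40.0, 70.0, "BEK"),
            IBDBlock(2, 10.0, 35.0, "BK"),
            IBDBlock(3, 15.0, 130.0, "BE"),
        ),
        qtl=(("M1_0030", 1.0),),
        pheno_sigma=1.0,
        seed=seed,
    )
    return RunConfig(seed=seed, sim=sim)


def config_hash(config: RunConfig) -> str:
    d = dataclasses.asdict(config)
    d["sim"] = config_to_dict(config.sim)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage on a simulated dataset and write a report bundle.

    Returns the manifest (also written as ``manifest.json``): stage output
    paths with checksums, the config hash and the seed.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    manifest: dict = {"config_hash": config_hash(config), "seed": config.seed,
                      "stages": {}}

    # --- simulate ---------------------------------------------------------
    founders = simulate_founders(sim)
    pops = simulate_all_populations(founders, sim)
    pheno = simulate_phenotypes(pops, founders, sim)
    paths = write_dataset(out / "simulated", founders, pops, pheno, raw=True)
    manifest["stages"]["simulate"] = paths
    log.info("simulate: %d markers, %d lines", len(founders.markers),
             sum(len(p.lines) for p in pops.values()))

    # --- encode -----------------------------------------------------------
    parent_calls = pd.read_csv(paths["parents"], sep="\t")
    trio = coding.build_trio_table(parent_calls)
    coded = {}
    for pop_name in pops:
        raw = pd.read_csv(paths[f"genotypes_{pop_name}"], sep="\t",
                          index_col="marker", dtype=str)
        coded[pop_name] = coding.classify_and_encode(trio, raw, pop_name)
    anchors = pd.read_csv(paths["anchors"], sep="\t")
    matrix = coding.merge_populations(coded, anchors=anchors)
    p = out / "integrated_matrix.tsv"
    matrix.codes.to_csv(p, sep="\t")
    summary = coding.marker_summary(matrix)
    ps = out / "marker_summary.tsv"
    summary.to_csv(ps, sep="\t")
    manifest["stages"]["encode"] = {"matrix": str(p), "summary": str(ps)}
    log.info("encode: %d markers in matrix, %d rejected trio markers",
             len(matrix.codes), len(trio.rejected))

    # --- relatedness ------------------------------------------------------
    lg_of = anchors.set_index("marker")["chrom"]
    dist = relatedness.distance_fractions(trio, lg_of=lg_of)
    p = out / "relatedness.tsv"
    dist.to_csv(p, sep="\t", index=False)
    tallies = summary.drop(index="total")[list(coding.POPULATIONS)]
    chi = relatedness.lg_chisq(tallies, lg_totals=summary.drop(index="total")["total"])
    pc = out / "lg_chisq.tsv"
    chi.table.to_csv(pc, sep="\t", index=False)
    manifest["stages"]["relatedness"] = {"distances": str(p), "chisq": str(pc)}

    # --- map --------------------------------------------------------------
    order = mapping.initial_order(anchors)
    lmap = mapping.assemble_map(order, matrix, n_min=config.n_min_informative,
                                mapping_function=config.mapping_function)
    p = out / "linkage_map.tsv"
    lmap.table.to_csv(p, sep="\t", index=False)
    gaps = mapping.detect_ibd_gaps(lmap, threshold=config.gap_threshold_cM)
    pg = out / "ibd_gaps.tsv"
    pd.DataFrame([dataclasses.asdict(g) for g in gaps]).to_csv(
        pg, sep="\t", index=False)
    pop_gaps = mapping.population_marker_gaps(lmap, matrix,
                                              threshold=config.gap_threshold_cM)
    pp = out / "population_gaps.tsv"
    pop_gaps.to_csv(pp, sep="\t", index=False)
    manifest["stages"]["map"] = {"map": str(p), "gaps": str(pg),
                                 "population_gaps": str(pp)}
    log.info("map: %.1f cM total, %d IBD gaps", lmap.total_length(), len(gaps))

    # --- stats ------------------------------------------------------------
    profile = recomb.crossover_counts(matrix, lmap)
    psum = out / "crossover_summary.tsv"
    xo_summary = profile.summary()
    xo_summary.to_csv(psum, sep="\t")
    if len(xo_summary) >= 3:
        reg = recomb.length_vs_crossovers_regression(
            [lmap.lg_length(lg) for lg in xo_summary.index],
            xo_summary["mean"].to_numpy())
    else:
        reg = {"note": "regression needs >= 3 linkage groups",
               "n": len(xo_summary)}
    pr = out / "length_regression.json"
    pr.write_text(json.dumps(reg))
    runs_path = None
    intervals = profile.all_intervals()
    if len(intervals) >= 10:
        runs = recomb.runs_distribution_fit(intervals,
                                            bin_width=config.runs_bin_width_cM)
        runs_path = out / "runs_fit.json"
        runs_path.write_text(json.dumps({
            "slope": runs.slope, "intercept": runs.intercept, "r": runs.r,
            "eps_from_slope": runs.eps_from_slope,
            "eps_from_totals": runs.eps_from_totals,
            "n_intervals": runs.n_intervals}))
    manifest["stages"]["stats"] = {"summary": str(psum), "regression": str(pr),
                                   "runs": str(runs_path) if runs_path else None}

    # --- physical ---------------------------------------------------------
    prof = physical.cm_mb_profile(lmap, anchors, span=config.cm_mb_span)
    p = out / "cm_mb_profile.tsv"
    prof.per_lg.to_csv(p, sep="\t")
    nonlin = physical.nonlinearity_report(lmap, anchors)
    pn = out / "nonlinearity.tsv"
    nonlin.to_csv(pn, sep="\t")
    manifest["stages"]["physical"] = {"profile": str(p), "nonlinearity": str(pn)}

    # --- scan -------------------------------------------------------------
    pheno = pd.read_csv(paths["phenotypes"])
    z = scan.normalize_trait(pheno)
    result = scan.marker_t_scan(matrix, z, n_min=config.scan_class_n_min)
    p = out / "trait_scan.tsv"
    result.table.to_csv(p, sep="\t", index=False)
    extrema = result.extrema(lmap)
    pe = out / "scan_extrema.tsv"
    extrema.to_csv(pe, sep="\t", index=False)
    manifest["stages"]["scan"] = {"scan": str(p), "extrema": str(pe)}

    # --- enrich -----------------------------------------------------------
    # demonstration gene set: midpoints of marker pairs along each pseudomolecule
    genes = _demo_gene_positions(anchors)
    report = enrichment.gap_enrichment_from_positions(genes, lmap, anchors, gaps)
    p = out / "gap_enrichment.json"
    p.write_text(json.dumps(dataclasses.asdict(report)))
    manifest["stages"]["enrich"] = {"report": str(p)}

    for stage, entries in manifest["stages"].items():
        for key, path in list(entries.items()):
            if path is not None:
                entries[key] = {"path": path, "sha256_16": _checksum(Path(path))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _demo_gene_positions(anchors: pd.DataFrame, step: int = 10) -> pd.DataFrame:
    a = anchors.sort_values(["chrom", "bp"])
    rows = []
    for chrom, sub in a.groupby("chrom"):
        bp = sub["bp"].to_numpy()
        for i in range(0, len(bp) - 1, step):
            rows.append({"gene": f"G{chrom}_{i:04d}", "chrom": chrom,
                         "bp": int(0.5 * (bp[i] + bp[i + 1]))})
    return pd.DataFrame(rows)
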