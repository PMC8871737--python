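"""Map construction: ordering, colormapping, interval estimation, mapping
functions and IBD gap detection, against brute-force and chain oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (brute_force_short_runs, build_matrix,
                      selfing_fixation_R)
from trimap import coding, mapping
from trimap.simulate import (IBDBlock, SimConfig, simulate_all_populations,
                             simulate_founders)


def toy_matrix(codes_by_marker: dict, population: str = "BE",
               anchors: pd.DataFrame | None = None):
    """Build a one-population integrated matrix from literal code strings."""
    markers = list(codes_by_marker)
    n_lines = len(next(iter(codes_by_marker.values())))
    lines = [f"{population}{i+1}" for i in range(n_lines)]
    codes = pd.DataFrame(
        [list(codes_by_marker[m]) for m in markers], index=markers,
        columns=lines)
    codes.index.name = "marker"
    struct = pd.Series([set(codes_by_marker[m]) <= {"-"} for m in markers],
                       index=markers)
    cm = coding.CodedMatrix(population, codes, struct, 0)
    return coding.merge_populations({population: cm}, anchors=anchors)


class TestMappingFunctions:
    def test_ril_to_meiotic_closed_form(self):
        assert mapping.ril_to_meiotic(0.0) == 0.0
        assert mapping.ril_to_meiotic(1 / 3) == pytest.approx(0.25)
        # a single recombinant among ~600 lines resolves to ~0.08 cM
        r = mapping.ril_to_meiotic(1 / 600)
        assert r == pytest.approx(0.000834, abs=2e-6)
        assert round(100 * r, 2) == 0.08

    def test_ril_to_meiotic_rejects_R_of_one(self):
        with pytest.raises(ValueError):
            mapping.ril_to_meiotic(1.0)

    @pytest.mark.parametrize("r", np.linspace(0.0, 0.49, 25))
    def test_map_expansion_matches_selfing_chain(self, r):
        # independent absorption-chain oracle: R at fixation = 2r/(1+2r)
        R = mapping.meiotic_to_ril(r)
        assert selfing_fixation_R(r) == pytest.approx(R, abs=1e-9)
        assert mapping.ril_to_meiotic(R) == pytest.approx(r, abs=1e-12)

    def test_haldane_values(self):
        assert mapping.haldane_cM(0.0) == 0.0
        assert mapping.haldane_cM(0.01) == pytest.approx(1.0102, abs=1e-4)
        assert mapping.haldane_cM(0.25) == pytest.approx(34.657, abs=1e-3)
        with pytest.raises(ValueError):
            mapping.haldane_cM(0.5)

    def test_haldane_roundtrip_against_poisson_crossovers(self):
        # crossovers Poisson on a 34.66 cM interval -> recombinant fraction 0.25
        rng = np.random.default_rng(0)
        d = mapping.haldane_cM(0.25)
        n = 200_000
        odd = rng.poisson(d / 100, n) % 2 == 1
        assert odd.mean() == pytest.approx(0.25, abs=0.005)

    def test_kosambi_below_haldane_and_linear_for_small_r(self):
        r = np.linspace(0.01, 0.45, 20)
        assert (mapping.kosambi_cM(r) <= mapping.haldane_cM(r)).all()
        assert mapping.kosambi_cM(0.001) == pytest.approx(0.1, rel=1e-3)


class TestInitialOrder:
    ANCHORS = pd.DataFrame({
        "marker": ["m1", "m2", "m3", "m4"],
        "chrom": [1, 1, 1, 1],
        "bp": [100, 500, 500, 900]})

    def test_sorted_anchors_give_identity_order(self):
        assert mapping.initial_order(self.ANCHORS)[1] == ["m1", "m2", "m3", "m4"]

    def test_shuffled_anchor_table_gives_same_order(self):
        shuffled = self.ANCHORS.sample(frac=1, random_state=3)
        assert mapping.initial_order(shuffled) == mapping.initial_order(self.ANCHORS)

    def test_bp_ties_broken_lexicographically(self):
        anchors = self.ANCHORS.copy()
        anchors.loc[anchors["marker"] == "m2", "marker"] = "zz"
        order = mapping.initial_order(anchors)[1]
        assert order == ["m1", "m3", "zz", "m4"]

    def test_duplicate_anchor_rejected(self):
        dup = pd.concat([self.ANCHORS, self.ANCHORS.iloc[[0]]])
        with pytest.raises(ValueError, match="multiple anchors"):
            mapping.initial_order(dup)

    def test_orientation_flip(self):
        order = mapping.initial_order(self.ANCHORS, orientation={1: True})[1]
        assert order == ["m4", "m3", "m2", "m1"]


class TestCloseDoubleRecombinants:
    def test_singleton_counted(self):
        m = toy_matrix({"m1": "B", "m2": "B", "m3": "K", "m4": "B", "m5": "B"},
                       population="BK")
        assert mapping.count_close_double_recombinants(
            ["m1", "m2", "m3", "m4", "m5"], m) == 1

    def test_block_boundary_not_counted(self):
        m = toy_matrix({"m1": "B", "m2": "B", "m3": "K", "m4": "K",
                        "m5": "B", "m6": "B"}, population="BK")
        assert mapping.count_close_double_recombinants(list(m.codes.index), m) == 0

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.sampled_from("BK-"), min_size=6, max_size=12))
    def test_matches_brute_force_run_enumeration(self, seq):
        markers = {f"m{i}": c for i, c in enumerate(seq)}
        if all(c == "-" for c in seq):
            return
        m = toy_matrix(markers, population="BK")
        got = mapping.count_close_double_recombinants(list(markers), m)
        want = brute_force_short_runs([c for c in seq if c != "-"])
        assert got == want


def _objective_oracle(matrix, order):
    """Independent objective: brute-force singleton-run count."""
    total = 0
    block = matrix.codes.loc[order]
    for col in block.columns:
        seq = [v for v in block[col] if v != "-"]
        total += brute_force_short_runs(seq)
    return total


class TestColormapRefine:
    def test_local_minimum_left_unchanged(self):
        m = toy_matrix({"m1": "BBBB", "m2": "BBKK", "m3": "BKKK",
                        "m4": "KKKK"}, population="BK")
        order = ["m1", "m2", "m3", "m4"]
        assert mapping.colormap_refine(order, m) == order

    def test_reaches_exhaustive_optimum_on_small_instances(self):
        # 20 lines, 5 markers, marker 3 and 4 swapped relative to truth
        rng = np.random.default_rng(5)
        truth = rng.choice(["B", "K"], size=(5, 20))
        for j in range(20):  # make columns smooth in the true order
            truth[:, j] = sorted(truth[:, j])
        markers = {f"m{i}": "".join(truth[i]) for i in range(5)}
        scrambled = ["m0", "m1", "m3", "m2", "m4"]
        m = toy_matrix(markers, population="BK")
        refined = mapping.colormap_refine(scrambled, m)
        best = min(_objective_oracle(m, list(p))
                   for p in itertools.permutations(markers))
        assert _objective_oracle(m, refined) == best

    def test_objective_never_increases_and_idempotent(self, small_matrix):
        order = list(small_matrix.codes.index[:30])
        rng = np.random.default_rng(1)
        shuffled = list(rng.permutation(order))
        before = mapping.count_close_double_recombinants(shuffled, small_matrix)
        refined = mapping.colormap_refine(shuffled, small_matrix,
                                          exhaustive_max=0)
        after = mapping.count_close_double_recombinants(refined, small_matrix)
        assert after <= before
        assert mapping.colormap_refine(refined, small_matrix,
                                       exhaustive_max=0) == refined

    def test_refinement_recovers_order_closer_to_truth(self, big_matrix):
        # dense markers (~0.4 cM apart), 600 lines: singleton runs pinpoint
        # local order errors, so refinement moves back toward the truth
        from scipy.stats import kendalltau
        order = list(big_matrix.codes.index[:25])
        rng = np.random.default_rng(2)
        shuffled = order.copy()
        for _ in range(6):
            i = rng.integers(len(order) - 1)
            shuffled[i], shuffled[i + 1] = shuffled[i + 1], shuffled[i]
        rank = {m: i for i, m in enumerate(order)}
        refined = mapping.colormap_refine(shuffled, big_matrix,
                                          exhaustive_max=0, move_window=4)
        tau_before = kendalltau(range(len(order)),
                                [rank[m] for m in shuffled]).statistic
        tau_after = kendalltau(range(len(order)),
                               [rank[m] for m in refined]).statistic
        assert tau_after >= tau_before


class TestIntervalR:
    def test_counting_with_missing_line_excluded(self):
        m = toy_matrix({"m1": "BBBBBBBBB-", "m2": "KBBBBBBBB-"},
                       population="BK")
        ni, nr = mapping.interval_R(m, "m1", "m2")
        assert (ni, nr) == (9, 1)

    def test_identical_vectors_give_zero(self):
        m = toy_matrix({"m1": "BKBKBK", "m2": "BKBKBK"}, population="BK")
        ni, nr = mapping.interval_R(m, "m1", "m2")
        assert nr == 0

    def test_pooling_across_populations_equals_concatenated_count(self):
        rng = np.random.default_rng(0)
        be = rng.choice(["B", "E"], size=(2, 60))
        bk = rng.choice(["B", "K"], size=(2, 40))
        cms = {}
        for pop, arr in (("BE", be), ("BK", bk)):
            codes = pd.DataFrame(arr, index=["m1", "m2"],
                                 columns=[f"{pop}{i}" for i in range(arr.shape[1])])
            cms[pop] = coding.CodedMatrix(
                pop, codes, pd.Series([False, False], index=["m1", "m2"]), 0)
        matrix = coding.merge_populations(cms)
        ni, nr = mapping.interval_R(matrix, "m1", "m2")
        want_rec = int((be[0] != be[1]).sum() + (bk[0] != bk[1]).sum())
        assert (ni, nr) == (100, want_rec)

    def test_equals_hamming_oracle_on_all_pairs(self, small_matrix):
        sub = list(small_matrix.codes.index[:30])
        pv = mapping.PopulationArrays(small_matrix)
        for a, b in itertools.combinations(sub[:10], 2):
            ni, nr = mapping.interval_R(small_matrix, a, b)
            # oracle: loop over populations and lines explicitly
            exp_n = exp_r = 0
            for pop in ("BE", "BK", "EK"):
                pops_a = small_matrix.marker_populations[a]
                pops_b = small_matrix.marker_populations[b]
                if pop not in pops_a or pop not in pops_b:
                    continue
                for line in small_matrix.lines_of(pop):
                    ca = small_matrix.codes.loc[a, line]
                    cb = small_matrix.codes.loc[b, line]
                    if ca != "-" and cb != "-":
                        exp_n += 1
                        exp_r += ca != cb
            assert (ni, nr) == (exp_n, exp_r)


class TestAssembleAndGaps:
    def test_gap_length_from_flank_R_formula_chain(self):
        # R = 0.33 -> r ~ 0.2463 -> Haldane ~ 33.9 cM, flagged as a gap
        r = mapping.ril_to_meiotic(0.33)
        assert r == pytest.approx(0.2463, abs=1e-4)
        d = mapping.haldane_cM(r)
        assert d == pytest.approx(33.9, abs=0.1)
        assert d > 10

    def test_dense_markers_without_ibd_give_no_gaps(self, big_map):
        gaps = mapping.detect_ibd_gaps(big_map, threshold=10.0)
        assert gaps == []

    def test_cumulative_positions_nondecreasing_every_marker_placed_once(
            self, big_matrix, big_map):
        seen = []
        for lg in big_map.table["LG"].unique():
            pos = big_map.table[big_map.table["LG"] == lg]["cM"].to_numpy()
            assert (np.diff(pos) >= 0).all()
            assert pos[0] == 0.0
            seen.extend(big_map.table[big_map.table["LG"] == lg]["marker"])
        assert len(seen) == len(set(seen))
        assert len(seen) + len(big_map.unplaced) == len(big_matrix.codes)

    def test_total_length_consistent_with_simulated_truth(self, big_map):
        # 7 chromosomes totalling 928 cM, 600 RILs: estimate within 5%
        assert big_map.total_length() == pytest.approx(928.0, rel=0.05)

    def test_per_lg_lengths_match_nominal(self, big_sim, big_map):
        cfg, founders, pops = big_sim
        for lg, nominal in zip(sorted(big_map.table["LG"].unique()),
                               cfg.chrom_cM):
            # marker span is slightly inside the chromosome ends
            assert big_map.lg_length(lg) == pytest.approx(nominal, rel=0.12)

    def test_planted_tri_shared_block_recovered_as_single_gap(self):
        cfg = SimConfig(n_chromosomes=1, chrom_cM=(110.0,), chrom_Mb=(342.0,),
                        n_markers_per_chrom=220, n_lines=200, generations=13,
                        obligate_chiasma=False, missing_rate=0.02,
                        ibd_blocks=(IBDBlock(1, 40.0, 70.0, "BEK"),), seed=17)
        f = simulate_founders(cfg)
        pops = simulate_all_populations(f, cfg)
        matrix = build_matrix(f, pops)
        order = mapping.initial_order(f.markers[["marker", "chrom", "bp"]])
        lmap = mapping.assemble_map(order, matrix)
        gaps = mapping.detect_ibd_gaps(lmap, threshold=10.0)
        assert len(gaps) == 1
        mk = f.markers.set_index("marker")
        assert mk.loc[gaps[0].left, "cM"] < 40.0
        assert mk.loc[gaps[0].right, "cM"] >= 70.0
        assert gaps[0].lacking_populations == ("BE", "BK", "EK")

    def test_pairwise_block_shows_as_population_gap_not_integrated_gap(self):
        cfg = SimConfig(n_chromosomes=1, chrom_cM=(110.0,), chrom_Mb=(342.0,),
                        n_markers_per_chrom=220, n_lines=100, generations=13,
                        obligate_chiasma=False, missing_rate=0.02,
                        ibd_blocks=(IBDBlock(1, 40.0, 70.0, "BE"),), seed=19)
        f = simulate_founders(cfg)
        pops = simulate_all_populations(f, cfg)
        matrix = build_matrix(f, pops)
        order = mapping.initial_order(f.markers[["marker", "chrom", "bp"]])
        lmap = mapping.assemble_map(order, matrix)
        # markers inside a pairwise block still segregate in two populations
        assert mapping.detect_ibd_gaps(lmap, threshold=10.0) == []
        pop_gaps = mapping.population_marker_gaps(lmap, matrix, threshold=10.0)
        be = pop_gaps[pop_gaps["population"] == "BE"]
        assert len(be) >= 1
        assert be["length_cM"].max() == pytest.approx(30.0, rel=0.4)

    def test_low_confidence_interval_inherits_neighbour(self):
        # middle interval has almost no informative lines -> inherits R
        codes = {"m1": "B" * 30, "m2": "B" * 25 + "K" * 5,
                 "m3": "-" * 29 + "K", "m4": "B" * 20 + "K" * 10}
        m = toy_matrix(codes, population="BK")
        order = {1: ["m1", "m2", "m3", "m4"]}
        lmap = mapping.assemble_map(order, m, n_min=20)
        ests = lmap.intervals[1]
        assert ests[1].low_confidence and ests[1].inherited
        assert ests[1].R == ests[0].R or ests[1].R == ests[2].R


class TestPlaceUnanchored:
    def test_identical_marker_colocated_with_R_zero(self, small_matrix):
        lmap = mapping.assemble_map(
            {1: list(small_matrix.codes.index[:40])}, small_matrix)
        probe = small_matrix.codes.index[5]
        other = [m for m in lmap.table["marker"] if m != probe]
        lmap.table = lmap.table[lmap.table["marker"] != probe]
        placed = mapping.place_unanchored(probe, small_matrix, lmap)
        # nearest neighbour on a dense map has near-zero recombination
        assert placed is not None
        assert placed["R"] < 0.05
        host_idx = other.index(placed["host"])
        assert abs(host_idx - 5) <= 2

    def test_no_informative_overlap_reported_unplaced(self):
        m = toy_matrix({"m1": "BBBB", "m2": "----"}, population="BK")
        lmap = mapping.assemble_map({1: ["m1"]}, m)
        assert mapping.place_unanchored("m2", m, lmap, n_min=1) is None

    def test_tie_resolves_to_earlier_map_marker(self):
        m = toy_matrix({"m1": "BBKK", "m2": "BBKK", "m3": "BKBK"},
                       population="BK")
        lmap = mapping.assemble_map({1: ["m1", "m2"]}, m, n_min=1)
        placed = mapping.place_unanchored("m3", m, lmap, n_min=1)
        assert placed["host"] == "m1"  # equal R to m1 and m2

    def test_simulated_scaffold_markers_placed_near_truth(self, big_sim,
                                                          big_matrix, big_map):
        cfg, founders, pops = big_sim
        rng = np.random.default_rng(4)
        mk = founders.markers.set_index("marker")
        probes = rng.choice(big_map.table["marker"].to_numpy(), 40,
                            replace=False)
        pos = big_map.table.set_index("marker")["cM"]
        lg_col = big_map.table.set_index("marker")["LG"]
        ok = 0
        for probe in probes:
            reduced = mapping.LinkageMap(
                table=big_map.table[big_map.table["marker"] != probe],
                intervals=big_map.intervals)
            placed = mapping.place_unanchored(probe, big_matrix, reduced)
            if placed is None:
                continue
            if placed["LG"] == lg_col[probe] and abs(
                    placed["cM"] - pos[probe]) <= 2.0:
                ok += 1
        assert ok >= 0.95 * len(probes)
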