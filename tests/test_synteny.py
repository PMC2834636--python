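"""Synteny partnerships, rearrangement detectors, rates and coverage."""

import itertools

import numpy as np
import pytest

from salicoid import synteny as syn
from salicoid.simulate import build_linkage_map, sample_markers, simulate_pair

from conftest import small_params, truth_correspondence


def corr_from_ranks(bp_ranks, lg="LG1", chrom="C1", mb=1e6):
    """Correspondence with markers in cM order carrying given bp ranks."""
    rows = [(f"m{i}", lg, float(i), chrom, rank * mb)
            for i, rank in enumerate(bp_ranks)]
    return syn.make_correspondence(rows)


def min_reversals_to_sorted(perm, cap=2):
    """BFS minimal number of segment reversals to reach either orientation.

    The genetic axis has no intrinsic direction, so distance is taken to the
    closer of the ascending and descending orders.  Independent of the
    detector: plain breadth-first search over all reversal moves.
    """
    targets = {tuple(sorted(perm)), tuple(sorted(perm, reverse=True))}
    frontier = {tuple(perm)}
    seen = set(frontier)
    for depth in range(cap + 1):
        if frontier & targets:
            return depth
        nxt = set()
        for state in frontier:
            for i in range(len(state)):
                for j in range(i + 2, len(state) + 1):
                    child = state[:i] + state[i:j][::-1] + state[j:]
                    if child not in seen:
                        seen.add(child)
                        nxt.add(child)
        frontier = nxt
    return cap + 1


class TestPartners:
    def test_published_lg1_configuration(self):
        rows = []
        for i, bp in enumerate((0.3e6, 7e6, 14.8e6)):
            rows.append((f"a{i}", "Ia", i * 10.0, "I", bp))
        for i, bp in enumerate((16e6, 25e6, 35.3e6)):
            rows.append((f"b{i}", "Ib", i * 10.0, "I", bp))
        for i, bp in enumerate((1e6, 3e6, 5e6)):
            rows.append((f"x{i}", "Ib", 100.0 + i * 10.0, "XVI", bp))
        table = syn.assign_syntenic_groups(syn.make_correspondence(rows))
        assert table.partners_of_group("Ia") == {"I"}
        assert table.partners_of_group("Ib") == {"I", "XVI"}
        assert len(syn.detect_fission_fusion(table)) == 2

    def test_one_to_one_genomes_have_single_partners(self, quiet_markers):
        params, focal, reference, truth, markers, lmap = quiet_markers
        corr = truth_correspondence(focal, reference, markers, lmap)
        table = syn.assign_syntenic_groups(corr)
        for lg in corr["linkage_group"].unique():
            assert len(table.partners_of_group(lg)) == 1
        assert syn.detect_fission_fusion(table) == []

    def test_bp_range_reported(self):
        rows = [(f"m{i}", "L", float(i), "C", bp)
                for i, bp in enumerate((2e6, 9e6, 4e6))]
        table = syn.assign_syntenic_groups(syn.make_correspondence(rows))
        entry = table.entries[0]
        assert (entry.bp_min, entry.bp_max) == (2e6, 9e6)
        assert entry.majority


class TestFissionFusionSimulated:
    @staticmethod
    def _single_event_sim(event_type, seed):
        params = small_params(
            event_rate=0.012, seed=seed,
            event_mix={event_type: 1.0},
            n_chromosomes=3, genes_per_chromosome=8,
            intron_length_range=(40, 60))
        focal, reference, truth = simulate_pair(params)
        markers = sample_markers(focal, params)
        lmap = build_linkage_map(focal, markers, params)
        corr = truth_correspondence(focal, reference, markers, lmap)
        return truth, corr

    def test_simulated_fission_and_fusion_recovered(self):
        """Detection is exact for events that are detectable in principle.

        A fission leaving fewer markers than ``min_markers`` on one product
        cannot establish the second partnership, chained events collapse
        into one observable signature, and reciprocal events in the two
        lineages can cancel; so the check conditions on scenarios with a
        single simple event whose products all carry >= 3 markers.
        """
        found_any = 0
        checked = 0
        for event_type in ("fission", "fusion"):
            for seed in range(30):
                truth, corr = self._single_event_sim(event_type, seed)
                if len(truth.events) > 1:
                    continue
                if truth.events:
                    ev = truth.events[0]
                    if ev.type == "fission":
                        cut = ev.detail["cut_index"]
                        sides = (cut, 8 - cut)
                        if min(sides) < 3:
                            continue
                checked += 1
                table = syn.assign_syntenic_groups(corr)
                events = syn.detect_fission_fusion(table,
                                                   unplaced_prefix="\0")
                assert len(events) == len(truth.events)
                found_any += len(truth.events)
        assert checked >= 10
        assert found_any >= 3  # the scenario actually exercised detections


class TestInversions:
    def test_identity_order_has_no_inversions(self):
        corr = corr_from_ranks(range(1, 9))
        assert syn.detect_inversions(corr) == []

    def test_single_reversed_segment_found_with_members(self):
        corr = corr_from_ranks([1, 2, 6, 5, 4, 3, 7, 8])
        events = syn.detect_inversions(corr, min_inv_markers=3)
        assert len(events) == 1
        assert events[0].members == ("m2", "m3", "m4", "m5")
        assert events[0].support == 4

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_matches_minimal_reversal_oracle(self, n):
        """Detected count equals BFS reversal distance for 1-step permutations."""
        identity = list(range(1, n + 1))
        cases = [tuple(identity)]
        for i in range(n):
            for j in range(i + 2, n + 1):
                cases.append(tuple(identity[:i] + identity[i:j][::-1]
                                   + identity[j:]))
        for perm in cases:
            corr = corr_from_ranks(perm)
            detected = len(syn.detect_inversions(corr, min_inv_markers=2))
            assert detected == min_reversals_to_sorted(perm), perm

    def test_invariant_under_cm_axis_reversal(self):
        """Same inversions whichever way the cM axis is drawn.

        Orientation is ambiguous when genetic and physical order are
        uncorrelated (tau = 0), so only permutations with a dominant
        orientation are checked.
        """
        from scipy.stats import kendalltau

        g = np.random.default_rng(0)
        checked = 0
        while checked < 20:
            ranks = list(g.permutation(np.arange(1, 11)))
            if kendalltau(range(10), ranks).statistic == 0:
                continue
            checked += 1
            fwd = syn.detect_inversions(corr_from_ranks(ranks), 2)
            rev = syn.detect_inversions(corr_from_ranks(ranks[::-1]), 2)
            remap = {f"m{i}": f"m{len(ranks) - 1 - i}" for i in range(10)}
            assert sorted(sorted(e.members) for e in fwd) == \
                sorted(sorted(remap[m] for m in e.members) for e in rev)

    def test_tied_cm_blocks_contribute_no_breakpoints(self):
        rows = [("m0", "L", 0.0, "C", 1e6), ("m1", "L", 1.0, "C", 2e6),
                ("m2", "L", 2.0, "C", 4e6), ("m3", "L", 2.0, "C", 3e6),
                ("m4", "L", 3.0, "C", 5e6), ("m5", "L", 4.0, "C", 6e6)]
        corr = syn.make_correspondence(rows)
        assert syn.detect_inversions(corr, min_inv_markers=2) == []

    def test_simulated_inversion_recovered_exactly(self):
        recovered = total = 0
        for seed in range(25):
            params = small_params(
                event_rate=0.012, seed=seed,
                event_mix={"inversion": 1.0},
                inversion_size_range=(4, 6),
                n_chromosomes=3, genes_per_chromosome=10,
                intron_length_range=(40, 60))
            focal, reference, truth = simulate_pair(params)
            markers = sample_markers(focal, params)
            lmap = build_linkage_map(focal, markers, params)
            corr = truth_correspondence(focal, reference, markers, lmap)
            # inversions overlapping in gene content (including on
            # homologous chromosomes of the two lineages) compose into
            # non-elementary signatures; condition on disjoint events
            segs = [set(e.gene_keys) for e in truth.events]
            if any(a & b for i, a in enumerate(segs) for b in segs[:i]):
                continue
            events = syn.detect_inversions(corr, min_inv_markers=3)
            marker_genes = dict(zip(markers["marker"],
                                    zip(markers["ancestral_id"],
                                        markers["wgd_copy"])))
            true_segments = [frozenset(e.gene_keys) for e in truth.events]
            total += len(true_segments)
            detected_segments = [
                frozenset(marker_genes[m] for m in e.members) for e in events]
            # precision: every detected event is a true injected segment
            for seg in detected_segments:
                assert seg in true_segments
            recovered += sum(seg in detected_segments for seg in true_segments)
        assert total >= 10
        assert recovered == total  # recall 1.0 noise-free


class TestTranslocations:
    def test_concordant_map_has_no_translocations(self, quiet_markers):
        params, focal, reference, truth, markers, lmap = quiet_markers
        corr = truth_correspondence(focal, reference, markers, lmap)
        table = syn.assign_syntenic_groups(corr)
        assert syn.detect_single_marker_translocations(corr, table) == []

    def test_simulated_translocation_found_at_truth_locus(self):
        hits = total = 0
        for seed in range(20):
            params = small_params(
                event_rate=0.012, seed=seed,
                event_mix={"translocation": 1.0},
                n_chromosomes=3, genes_per_chromosome=8,
                intron_length_range=(40, 60))
            focal, reference, truth = simulate_pair(params)
            markers = sample_markers(focal, params)
            lmap = build_linkage_map(focal, markers, params)
            corr = truth_correspondence(focal, reference, markers, lmap)
            table = syn.assign_syntenic_groups(corr)
            events = syn.detect_single_marker_translocations(corr, table)
            marker_genes = dict(zip(markers["marker"],
                                    zip(markers["ancestral_id"],
                                        markers["wgd_copy"])))
            true_moved = {e.gene_keys[0] for e in truth.events}
            detected = {marker_genes[m] for e in events for m in e.members}
            assert detected <= true_moved  # precision 1.0
            hits += len(detected & true_moved)
            total += len(true_moved)
        assert total >= 5
        assert hits == total  # recall 1.0 noise-free

    def test_adjacent_markers_merge_into_one_event(self):
        rows = [(f"bb{i}", "A", i * 5.0, "CA", bp)
                for i, bp in enumerate((1e6, 3e6, 5e6))]
        rows += [(f"cc{i}", "B", i * 5.0, "CB", bp)
                 for i, bp in enumerate((1e6, 3e6, 5e6))]
        rows += [("t1", "B", 16.0, "CA", 20e6), ("t2", "B", 17.0, "CA", 21e6)]
        corr = syn.make_correspondence(rows)
        table = syn.assign_syntenic_groups(corr)
        events = syn.detect_single_marker_translocations(corr, table)
        assert len(events) == 1
        assert events[0].members == ("t1", "t2")


class TestRatesAndCoverage:
    def test_published_rate_arithmetic(self):
        assert syn.rearrangement_rate(13, 45) == pytest.approx(13 / 90)
        assert round(syn.rearrangement_rate(13, 45), 2) == 0.14
        assert syn.rearrangement_rate(0, 45) == 0.0
        assert syn.rearrangement_rate(9, 30) == pytest.approx(0.15)

    def test_rate_scaling_properties(self):
        g = np.random.default_rng(1)
        for _ in range(50):
            n = int(g.integers(0, 40))
            t = float(g.uniform(1, 200))
            k = float(g.uniform(0.1, 5))
            assert syn.rearrangement_rate(2 * n, t) == \
                pytest.approx(2 * syn.rearrangement_rate(n, t))
            assert syn.rearrangement_rate(n, k * t) * k == \
                pytest.approx(syn.rearrangement_rate(n, t))

    def test_rate_rejects_nonpositive_time(self):
        with pytest.raises(syn.ParameterError):
            syn.rearrangement_rate(3, 0)

    def test_coverage_arithmetic(self):
        rows = [("m1", "L", 0.0, "C", 1e6), ("m2", "L", 1.0, "C", 5e6)]
        corr = syn.make_correspondence(rows)
        covered, percent = syn.map_coverage(corr, 10e6)
        assert covered == 4e6
        assert percent == pytest.approx(40.0)

    def test_coverage_of_empty_table_is_zero(self):
        import pandas as pd

        empty = pd.DataFrame(columns=syn.CORR_COLUMNS)
        assert syn.map_coverage(empty, 1e6) == (0.0, 0.0)
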