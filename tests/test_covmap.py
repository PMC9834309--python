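"""Consensus mapping, coverage profiles, and copy-number arithmetic."""

import math

import numpy as np
import pytest

from wrepscan import covmap as cm
from wrepscan.seqs import revcomp, seq_to_array
from wrepscan.simgenome import random_monomer


REF = random_monomer(1000, gc=0.45, seed=77)


def substitute(seq, positions):
    arr = list(seq)
    for p in positions:
        arr[p] = "ACGT"[("ACGT".index(arr[p]) + 1) % 4]
    return "".join(arr)


class TestMapping:
    def test_exact_substring_maps_at_identity_one(self):
        read = REF[200:340]
        hits, profile = cm.map_reads([("r1", read)], REF)
        (hit,) = hits
        assert (hit.ref_start, hit.ref_end, hit.strand) == (200, 340, "+")
        assert hit.identity == 1.0
        expected = np.zeros(1000)
        expected[200:340] = 1
        assert (profile.depth == expected).all()

    def test_reverse_strand_read_maps_to_same_interval(self):
        read = revcomp(REF[200:340])
        hits, _ = cm.map_reads([("r1", read)], REF)
        (hit,) = hits
        assert (hit.ref_start, hit.ref_end, hit.strand) == (200, 340, "-")

    def test_identity_threshold_boundary_at_95_percent(self):
        # 7 substitutions in 140 bp -> 133/140 = 0.95 exactly: retained
        seven = substitute(REF[100:240], range(10, 140, 20))
        # 8 substitutions -> 132/140 < 0.95: rejected
        eight = substitute(REF[100:240], range(10, 140, 17))
        hits, _ = cm.map_reads(
            [("seven", seven), ("eight", eight)], REF, min_identity=0.95
        )
        assert [h.read_id for h in hits] == ["seven"]
        assert hits[0].identity == pytest.approx(133 / 140)

    def test_overhanging_read_counts_overlap_columns_only(self):
        read = "ACGT" * 10 + REF[:100]  # 40 bp of foreign sequence 5' of the ref
        hits, profile = cm.map_reads([("r1", read)], REF)
        (hit,) = hits
        assert (hit.ref_start, hit.ref_end) == (0, 100)
        assert hit.aligned_columns == 100
        assert profile.depth[:100].sum() == 100

    def test_short_overlap_rejected_by_aligned_fraction(self):
        read = "ACGT" * 15 + REF[:60]  # only 60 of 120 bp on the reference
        hits, _ = cm.map_reads([("r1", read)], REF, min_aligned_frac=0.6)
        assert hits == []

    def test_retained_set_matches_exhaustive_alignment_oracle(self):
        """Seeded mapping equals brute-force scanning of every diagonal."""
        rng = np.random.default_rng(12)
        reads = []
        for i in range(60):
            start = int(rng.integers(0, 1000 - 140 + 1))
            frag = REF[start : start + 140]
            n_sub = int(rng.integers(0, 12))
            frag = substitute(frag, rng.choice(140, n_sub, replace=False))
            if rng.random() < 0.5:
                frag = revcomp(frag)
            reads.append((f"r{i}", frag))
        reads += [(f"bg{i}", random_monomer(140, seed=500 + i)) for i in range(20)]

        hits, _ = cm.map_reads(reads, REF, min_identity=0.95)
        got = {h.read_id: (h.ref_start, h.ref_end, h.identity) for h in hits}

        ref_arr = seq_to_array(REF)
        expected = {}
        for rid, seq in reads:
            best = None
            for oriented in (seq, revcomp(seq)):
                arr = seq_to_array(oriented)
                for d in range(-70, 1000 - 70):
                    a, b = max(0, d), min(1000, d + 140)
                    if b - a < 70:
                        continue
                    ident = (
                        np.count_nonzero(ref_arr[a:b] == arr[a - d : b - d])
                        / (b - a)
                    )
                    if best is None or ident > best[2]:
                        best = (a, b, ident)
            if best and best[2] >= 0.95:
                expected[rid] = best
        assert set(got) == set(expected)
        for rid, (a, b, ident) in expected.items():
            assert got[rid][2] == pytest.approx(ident)

    def test_depth_conservation(self):
        rng = np.random.default_rng(5)
        reads = [
            (f"r{i}", REF[s : s + 140])
            for i, s in enumerate(rng.integers(0, 861, size=30))
        ]
        hits, profile = cm.map_reads(reads, REF)
        assert profile.depth.sum() == sum(h.aligned_columns for h in hits)

    def test_identity_monotonicity(self):
        rng = np.random.default_rng(6)
        reads = []
        for i in range(40):
            s = int(rng.integers(0, 861))
            frag = substitute(
                REF[s : s + 140], rng.choice(140, int(rng.integers(0, 10)), replace=False)
            )
            reads.append((f"r{i}", frag))
        prev = None
        for ident in (0.9, 0.95, 0.99, 1.0):
            hits, profile = cm.map_reads(reads, REF, min_identity=ident)
            ids = {h.read_id for h in hits}
            if prev is not None:
                assert ids <= prev[0]
                assert (profile.depth <= prev[1]).all()
            prev = (ids, profile.depth)

    def test_doubling_reads_doubles_depth(self):
        reads = [("r1", REF[100:240]), ("r2", REF[300:440])]
        _, single = cm.map_reads(reads, REF)
        _, double = cm.map_reads(reads + [("r3", REF[100:240]), ("r4", REF[300:440])], REF)
        assert (double.depth == 2 * single.depth).all()

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cm.map_reads([("r1", "ACGT")], "")

    def test_min_identity_range_enforced(self):
        with pytest.raises(ValueError, match="min_identity"):
            cm.map_reads([], REF, min_identity=0.3)


class TestCoverageArithmetic:
    def test_genome_coverage_examples(self):
        assert cm.estimate_genome_coverage(631e6, 631e6) == 1.0
        assert round(cm.estimate_genome_coverage(100_000 * 140, 631e6), 2) == 0.02
        with pytest.raises(ValueError):
            cm.estimate_genome_coverage(100, 0)

    @pytest.mark.parametrize(
        "element,genome,copies",
        [(774.6, 2.38, 325), (39.2, 2.24, 17), (840.0, 2.38, 353), (698.5, 2.38, 293)],
    )
    def test_round_half_down_calibration(self, element, genome, copies):
        est = cm.estimate_copies(element, genome)
        assert est.copies == copies
        assert est.copies_raw == pytest.approx(element / genome)

    def test_zero_element_coverage_gives_zero_copies(self):
        assert cm.estimate_copies(0.0, 2.38).copies == 0

    def test_fold_difference(self):
        assert cm.fold_difference(325, 17) == 19
        assert cm.fold_difference(10, 10) == 1
        assert cm.fold_difference(353, 1) == 353
        assert cm.fold_difference(5, 0) == math.inf

    def test_round_half_down_halves(self):
        assert cm.round_half_down(17.5) == 17
        assert cm.round_half_down(17.501) == 18
        assert cm.round_half_down(0.5) == 0


class TestDeletionCalls:
    def test_equal_coverage_gives_null_call(self):
        call = cm.call_deletion(840.0, 840.0, 2.38)
        assert call.drop_percent == 0 and call.carrier_copies == 0

    def test_carriers_are_difference_of_rounded_copies(self):
        call = cm.call_deletion(698.5, 840.0, 2.38)
        assert call.drop_percent == 17
        assert call.carrier_copies == 353 - 293 == 60
        # a rounded difference of raws would give 59 — the convention matters
        assert cm.round_half_down((840.0 - 698.5) / 2.38) == 59

    def test_zero_outside_coverage_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            cm.call_deletion(0.0, 0.0, 2.38)

    def test_analyze_deletion_reads_profile(self):
        depth = np.full(1000, 120.0)
        depth[400:613] = 96.0
        profile = cm.CoverageProfile("ref", 1000, depth)
        call = cm.analyze_deletion(profile, (400, 613), genome_coverage=2.0)
        assert call.coverage_inside == pytest.approx(96.0)
        assert call.coverage_outside == pytest.approx(120.0)
        assert call.drop_percent == 20
        call2 = cm.analyze_deletion(
            profile, (400, 613), genome_coverage=2.0, coverage_outside=118.0
        )
        assert call2.coverage_outside == 118.0


class TestDeletionScan:
    def test_flat_profile_yields_no_candidates(self):
        profile = cm.CoverageProfile("ref", 800, np.full(800, 50.0))
        assert cm.scan_deletion_regions(profile, window_bp=50) == []

    def test_planted_drop_detected_with_boundaries_in_window(self):
        rng = np.random.default_rng(8)
        depth = rng.poisson(200, 2000).astype(float)
        depth[700:913] = rng.poisson(160, 213)
        profile = cm.CoverageProfile("ref", 2000, depth)
        regions = cm.scan_deletion_regions(
            profile, window_bp=100, drop_threshold=0.9, edge_trim_bp=140
        )
        top = regions[0]
        assert abs(top[0] - 700) <= 100 and abs(top[1] - 913) <= 100

    def test_degenerate_threshold_flags_every_below_average_window(self):
        rng = np.random.default_rng(9)
        depth = rng.poisson(100, 600).astype(float)
        profile = cm.CoverageProfile("ref", 600, depth)
        regions = cm.scan_deletion_regions(
            profile, window_bp=20, drop_threshold=1.0, edge_trim_bp=0
        )
        assert len(regions) > 5
        mask = np.zeros(600, dtype=bool)
        for s, e in regions:
            mask[s:e] = True
        assert 0 < mask.sum() < 600
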