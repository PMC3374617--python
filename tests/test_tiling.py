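import numpy as np
import pytest

from noveltax import (
    DatasetTag,
    SeqRecord,
    SupportAlignment,
    ValidationConfig,
    build_profile,
    check_breadth,
    check_spanning_pair,
    classify,
    detect_valley,
    find_tiling_path,
)

from _oracles import (
    brute_force_depth,
    brute_force_max_len_at_start,
    chain_exists,
)
from conftest import random_seq


def sup(ts, te, qid="r", frag=None, mate=None, target="c"):
    return SupportAlignment(
        query_id=qid,
        target_id=target,
        q_start=0,
        q_end=te - ts,
        t_start=ts,
        t_end=te,
        strand="+",
        full_read_aligned=True,
        fragment_id=frag,
        mate_id=mate,
    )


def cand(length=200, cid="c", seed=0):
    rng = np.random.default_rng(seed)
    return SeqRecord(id=cid, bases=random_seq(rng, length))


class TestProfile:
    def test_no_supports(self):
        p = build_profile(cand(100), [])
        assert p.breadth == 0.0
        assert p.median_depth == 0.0

    def test_single_full_cover(self):
        p = build_profile(cand(100), [sup(0, 100)])
        assert p.breadth == 1.0
        assert (p.depth == 1).all()
        assert p.max_len_at_start[0] == 100

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_position_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(80, 300))
        c = cand(n, seed=seed)
        intervals = []
        for _ in range(int(rng.integers(0, 120))):
            s = int(rng.integers(0, n - 10))
            e = int(rng.integers(s + 10, min(n, s + 120) + 1))
            intervals.append((s, e))
        p = build_profile(c, [sup(s, e, qid=f"r{i}") for i, (s, e) in enumerate(intervals)])
        depth = brute_force_depth(n, intervals)
        assert list(p.depth) == depth
        assert list(p.max_len_at_start) == brute_force_max_len_at_start(n, intervals)
        assert p.breadth == sum(d > 0 for d in depth) / n
        assert p.median_depth == float(np.median(depth))

    def test_out_of_bounds_support_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_profile(cand(50), [sup(0, 60)])

    def test_wrong_target_rejected(self):
        with pytest.raises(ValueError, match="candidate"):
            build_profile(cand(100), [sup(0, 50, target="other")])


class TestBreadth:
    def test_wgs_requires_every_base(self, cfg):
        c = cand(100)
        p = build_profile(c, [sup(0, 99)])  # one uncovered base
        ok, breadth = check_breadth(p, DatasetTag.LONG_WGS, cfg)
        assert not ok and breadth == 0.99
        ok, _ = check_breadth(build_profile(c, [sup(0, 100)]), DatasetTag.LONG_WGS, cfg)
        assert ok

    def test_amplicon_boundary_is_strict(self, cfg):
        c = cand(100)
        exactly95 = build_profile(c, [sup(0, 95)])
        assert not check_breadth(exactly95, DatasetTag.AMPLICON_V13, cfg)[0]
        at96 = build_profile(c, [sup(0, 96)])
        assert check_breadth(at96, DatasetTag.AMPLICON_V13, cfg)[0]


class TestValley:
    def _profile(self, length, starts):
        """starts: {position: max aligned length}."""
        c = cand(length)
        supports = [
            sup(pos, pos + ln, qid=f"r{pos}") for pos, ln in starts.items()
        ]
        return build_profile(c, supports)

    def test_descend_and_recover_is_a_valley(self, cfg):
        p = self._profile(400, {0: 100, 100: 100, 150: 60, 200: 100, 250: 100})
        v = detect_valley(p, cfg, short_read_max_len=100)
        assert v == (150, 60)

    def test_floor_boundary_70_vs_71(self, cfg):
        at70 = self._profile(400, {0: 100, 150: 70, 250: 100})
        assert detect_valley(at70, cfg, 100) == (150, 70)
        at71 = self._profile(400, {0: 100, 150: 71, 250: 100})
        assert detect_valley(at71, cfg, 100) is None

    def test_shoulder_boundary_90_vs_89(self, cfg):
        with90 = self._profile(400, {0: 90, 150: 60, 250: 90})
        assert detect_valley(with90, cfg, 100) is not None
        with89 = self._profile(400, {0: 89, 150: 60, 250: 89})
        assert detect_valley(with89, cfg, 100) is None

    def test_decline_inside_terminal_window_exempt(self, cfg):
        """Aligned lengths naturally shrink at the candidate end; a dip in
        the last read-length window is not a valley."""
        p = self._profile(400, {0: 100, 150: 100, 320: 65, 330: 70})
        assert detect_valley(p, cfg, short_read_max_len=100) is None

    def test_dip_needs_shoulders_on_both_sides(self, cfg):
        left_only = self._profile(400, {0: 100, 100: 100, 150: 60})
        assert detect_valley(left_only, cfg, 100) is None

    def test_deepest_floor_reported(self, cfg):
        p = self._profile(400, {0: 100, 120: 65, 180: 62, 250: 100})
        assert detect_valley(p, cfg, 100) == (180, 62)


class TestTilingPath:
    def test_three_step_chain_with_end_exemption(self, cfg):
        c = cand(200)
        supports = [sup(0, 100, "a"), sup(80, 180, "b"), sup(160, 200, "d")]
        path = find_tiling_path(c, supports, DatasetTag.LONG_WGS, cfg)
        assert path == [0, 1, 2]

    def test_insufficient_overlap_fails(self, cfg):
        c = cand(200)
        supports = [sup(0, 100, "a"), sup(95, 200, "b")]  # 5-base overlap
        assert find_tiling_path(c, supports, DatasetTag.LONG_WGS, cfg) is None

    def test_insufficient_extension_fails(self, cfg):
        c = cand(300)
        # second interval extends by only 10 and does not reach the final
        # covered base (a third interval ends further right but overlaps
        # the first by too little to be chained directly)
        supports = [sup(0, 100, "a"), sup(30, 110, "b"), sup(95, 300, "d")]
        path = find_tiling_path(c, supports, DatasetTag.LONG_WGS, cfg)
        assert path is None

    def test_empty_supports(self, cfg):
        assert find_tiling_path(cand(100), [], DatasetTag.LONG_WGS, cfg) is None

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_chain_enumeration(self, seed, cfg):
        """Path finding succeeds exactly when exhaustive enumeration finds a
        valid chain, on random support sets."""
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(150, 400))
        c = cand(n, seed=seed)
        intervals = []
        for _ in range(int(rng.integers(3, 25))):
            s = int(rng.integers(0, n - 30))
            e = int(rng.integers(s + 30, min(n, s + 110) + 1))
            intervals.append((s, e))
        supports = [sup(s, e, qid=f"r{i}") for i, (s, e) in enumerate(intervals)]
        got = find_tiling_path(c, supports, DatasetTag.LONG_WGS, cfg)
        expected = chain_exists(
            intervals,
            n,
            cfg.tiling_min_overlap,
            cfg.tiling_min_extend,
            cfg.support_breadth_wgs,
            strict_span=False,
        )
        assert (got is not None) == expected
        if got is not None:
            # returned chain is itself valid: ordered, overlapping, spanning
            ivs = [(supports[i].t_start, supports[i].t_end) for i in got]
            leftmost = min(s for s, _ in intervals)
            assert ivs[0][0] == leftmost
            cur = ivs[0][1]
            for s, e in ivs[1:]:
                assert s <= cur - cfg.tiling_min_overlap
                assert e > cur
                cur = e
            assert (cur - leftmost) / n >= cfg.support_breadth_wgs


def test_valley_appears_at_chimera_junction_under_deep_variable_coverage(cfg):
    """With heterogeneous 60-100 bp reads at deep coverage, the per-start
    maximum-length profile dips to <=70 at a chimera junction and recovers:
    only ever-shorter reads can start as the junction approaches."""
    from noveltax import (
        CommunitySpec,
        LongReadSpec,
        ShortReadSpec,
        align_short_reads,
        generate_community,
        simulate_long_reads,
        simulate_short_pairs,
    )

    com = generate_community(CommunitySpec(n_taxa=2, seq_length=1500, seed=23))
    chims, truth = simulate_long_reads(
        com,
        LongReadSpec(
            n_reads=20,
            length_range=(400, 400),
            chimera_fraction=1.0,
            junction_guard_k=60,
            seed=31,
        ),
        id_prefix="chim",
    )
    mid = [
        (r, int(row.breakpoint))
        for r, (_, row) in zip(chims, truth.iterrows())
        if 130 <= row.breakpoint <= 270  # junction outside the terminal window
    ]
    assert len(mid) >= 3
    shorts, _ = simulate_short_pairs(
        com, ShortReadSpec(read_length=(60, 100), mean_depth=300, seed=29)
    )
    supports = align_short_reads([r for r, _ in mid], shorts, cfg)
    by = {}
    for s in supports:
        by.setdefault(s.target_id, []).append(s)
    for read, junction in mid:
        profile = build_profile(read, by[read.id])
        valley = detect_valley(profile, cfg, short_read_max_len=100)
        assert valley is not None, read.id
        # reads starting at the floor position end at or before the junction
        pos, value = valley
        assert pos + value <= junction


class TestSpanningPair:
    def _deep_profile(self, c, depth_value):
        # constant depth via stacked full-length supports
        return build_profile(
            c, [sup(0, len(c.bases), qid=f"d{i}") for i in range(depth_value)]
        )

    def test_gate_on_median_depth_is_strict(self, cfg):
        c = cand(300)
        supports = [
            sup(0, 100, "f/1", frag="f"),
            sup(210, 300, "f/2", frag="f"),
        ]
        at500 = self._deep_profile(c, 500)
        applied, _, _ = check_spanning_pair(c, supports, at500, cfg)
        assert not applied
        at501 = self._deep_profile(c, 501)
        applied, passed, best = check_spanning_pair(c, supports, at501, cfg)
        assert applied and passed
        assert best == ("f", 1.0)

    def test_gate_on_length_is_strict(self, cfg):
        c = cand(200)
        p = self._deep_profile(c, 600)
        applied, _, _ = check_spanning_pair(c, [], p, cfg)
        assert not applied  # length must exceed 200

    def test_span_fraction_boundary(self, cfg):
        c = cand(300)
        p = self._deep_profile(c, 501)
        near = [sup(0, 100, "f/1", frag="f"), sup(170, 269, "f/2", frag="f")]
        applied, passed, best = check_spanning_pair(c, near, p, cfg)
        assert applied and not passed
        assert best[1] == pytest.approx(269 / 300)
        at90 = [sup(0, 100, "f/1", frag="f"), sup(180, 270, "f/2", frag="f")]
        _, passed, _ = check_spanning_pair(c, at90, p, cfg)
        assert passed  # 270/300 = 0.90 exactly, inclusive

    def test_single_mate_never_spans(self, cfg):
        c = cand(300)
        p = self._deep_profile(c, 501)
        solo = [sup(0, 290, "f/1", frag="f")]
        _, passed, best = check_spanning_pair(c, solo, p, cfg)
        assert not passed and best is None


class TestClassify:
    def test_zero_supports_is_insufficient_breadth(self, cfg):
        v = classify(cand(100), [], DatasetTag.LONG_WGS, cfg)
        assert v.status.value == "INSUFFICIENT_BREADTH"
        assert v.breadth == 0.0

    def test_clean_candidate_validated_without_pair_test(
        self, community, cfg, clean_long_reads, support_index
    ):
        reads, _ = clean_long_reads
        v = classify(reads[0], support_index[reads[0].id], DatasetTag.LONG_WGS, cfg)
        assert v.status.value == "VALIDATED"
        assert not v.pair_test_applied  # median depth ~50, gate at >500

    def test_permutation_invariance(
        self, cfg, clean_long_reads, chimera_long_reads, support_index
    ):
        rng = np.random.default_rng(9)
        for read in (clean_long_reads[0][1], chimera_long_reads[0][2]):
            supports = support_index[read.id]
            base = classify(read, supports, DatasetTag.LONG_WGS, cfg)
            for _ in range(3):
                perm = [supports[i] for i in rng.permutation(len(supports))]
                again = classify(read, perm, DatasetTag.LONG_WGS, cfg)
                assert again.status == base.status
                assert again.breadth == base.breadth
                assert again.valley == base.valley
                assert again.tiling_path == base.tiling_path

    def test_first_failed_check_sets_status(self, cfg):
        """Breadth outranks valley: a candidate failing both reports
        INSUFFICIENT_BREADTH."""
        c = cand(400)
        supports = [
            sup(0, 100, "a"),
            sup(80, 180, "b"),
            sup(150, 210, "v"),  # 60-long start: a valley floor
            sup(190, 290, "d"),
            sup(270, 370, "e"),  # stops short of the end: breadth < 1
        ]
        v = classify(c, supports, DatasetTag.LONG_WGS, cfg)
        assert v.status.value == "INSUFFICIENT_BREADTH"
        assert v.valley is not None  # evidence still populated
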