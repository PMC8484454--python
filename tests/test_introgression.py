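import numpy as np
import pytest
from scipy.stats import chisquare

from germflow import introgression as intro
from germflow import synth
from germflow.io_core import PopulationMap, RegionSet, Window, iter_windows


def make_polarized(w, x, y, spacing=100, chrom="chr1"):
    w, x, y = (np.asarray(v, dtype=float) for v in (w, x, y))
    return intro.PolarizedSites(
        chrom=chrom,
        positions=np.arange(1, len(w) + 1) * spacing,
        w=w, x=x, y=y,
        n_excluded_outgroup=0,
        n_excluded_missing=0,
    )


class TestPolarize:
    @pytest.fixture
    def quartet(self):
        return intro.Quartet("A", "B", "C", "OUT")

    def test_outgroup_fixed_ref_derived_is_alt(self, make_vm, popmap_two_groups, quartet):
        # A alt-fixed, B half, C ref, outgroup hom-ref
        vm = make_vm([100], [[2, 2, 1, 1, 0, 0, 0, 0]],
                     sample_ids=list(popmap_two_groups.assignments))
        ps = intro.polarize(vm, popmap_two_groups, quartet)
        assert (ps.w[0], ps.x[0], ps.y[0]) == (1.0, 0.5, 0.0)

    def test_polymorphic_outgroup_excluded(self, make_vm, popmap_two_groups, quartet):
        vm = make_vm([100], [[1, 1, 1, 1, 1, 1, 1, 1]],
                     sample_ids=list(popmap_two_groups.assignments))
        ps = intro.polarize(vm, popmap_two_groups, quartet)
        assert len(ps.positions) == 0
        assert ps.n_excluded_outgroup == 1

    def test_outgroup_fixed_alt_flips_alleles(self, make_vm, popmap_two_groups, quartet):
        # outgroup hom-alt -> ancestral = alt, derived frequency = ref frequency
        vm = make_vm([100], [[0, 0, 1, 1, 2, 2, 2, 2]],
                     sample_ids=list(popmap_two_groups.assignments))
        ps = intro.polarize(vm, popmap_two_groups, quartet)
        assert (ps.w[0], ps.x[0], ps.y[0]) == (1.0, 0.5, 0.0)


class TestPattersonD:
    def test_single_abba_site_anchors_sign_convention(self):
        ps = make_polarized([0], [1], [1])
        res = intro.patterson_d(ps)  # default orientation
        assert res.d == -1.0  # P2-P3 derived sharing is negative
        assert intro.patterson_d(ps, convention="textbook").d == 1.0

    def test_equal_pattern_mass_gives_zero(self):
        ps = make_polarized([0, 1], [1, 0], [1, 1])
        assert intro.patterson_d(ps).d == 0.0

    def test_mixed_frequencies_match_direct_summation(self):
        ps = make_polarized([0, 0.5], [0.5, 0], [0.5, 0.5])
        abba = (1 - ps.w) * ps.x * ps.y
        baba = ps.w * (1 - ps.x) * ps.y
        expected = (abba.sum() - baba.sum()) / (abba.sum() + baba.sum())
        assert intro.patterson_d(ps, convention="textbook").d == pytest.approx(expected)
        assert expected == pytest.approx(0.0)

    def test_no_informative_sites_fatal(self):
        with pytest.raises(ValueError, match="informative"):
            intro.patterson_d(make_polarized([0.5], [0], [0]))

    def test_swapping_p1_p2_flips_sign_and_bounds(self, desk_cohort):
        # per-site numerator y(x - w) is antisymmetric in (P1, P2)
        q = intro.Quartet("NC_C", "NWC_C", "XJ_C", "peach")
        q_flip = intro.Quartet("NWC_C", "NC_C", "XJ_C", "peach")
        r1 = intro.dstat(desk_cohort.variants, desk_cohort.popmap, q,
                         block_size=synth.DESK_BLOCK_SIZE, convention="textbook")
        r2 = intro.dstat(desk_cohort.variants, desk_cohort.popmap, q_flip,
                         block_size=synth.DESK_BLOCK_SIZE, convention="textbook")
        assert abs(r1.d) <= 1
        assert r1.d == pytest.approx(-r2.d)


class TestBlockJackknife:
    def test_equal_blocks_match_textbook_leave_one_out(self):
        rng = np.random.default_rng(5)
        num = rng.normal(0.1, 1.0, 30)
        den = rng.uniform(0.5, 1.5, 30)
        ids = np.repeat(["b1", "b2", "b3"], 10)
        theta, se, z, g = intro.block_jackknife(num, den, ids)
        assert g == 3
        # independent oracle: recompute each delete-one ratio from scratch,
        # then apply the classic equal-weight jackknife SE formula
        thetas = []
        for b in ("b1", "b2", "b3"):
            keep = ids != b
            thetas.append(num[keep].sum() / den[keep].sum())
        thetas = np.asarray(thetas)
        se_expected = np.sqrt((3 - 1) / 3 * np.sum((thetas - thetas.mean()) ** 2))
        assert theta == pytest.approx(num.sum() / den.sum())
        assert se == pytest.approx(se_expected)
        assert z == pytest.approx(theta / se_expected)

    def test_identical_blocks_have_zero_se_and_flagged_z(self):
        num = np.tile([0.2, 0.4], 3)
        den = np.ones(6)
        ids = np.repeat(["a", "b", "c"], 2)
        theta, se, z, _ = intro.block_jackknife(num, den, ids)
        assert se == pytest.approx(0.0)
        assert z is None

    def test_fewer_than_two_blocks_fatal(self):
        with pytest.raises(ValueError, match="blocks"):
            intro.block_jackknife(np.ones(4), np.ones(4), np.array(["a"] * 4))


class TestFd:
    def test_equal_p2_p3_frequencies_give_fd_one(self):
        n = 35
        ps = make_polarized([0.0] * n, [0.5] * n, [0.5] * n)
        rec = intro.fd_window(ps, Window("chr1", 0, 4000))
        assert rec.fd == pytest.approx(1.0)
        assert not rec.excluded

    def test_negative_windowed_d_maps_to_zero(self):
        n = 35
        ps = make_polarized([0.9] * n, [0.1] * n, [0.5] * n)
        rec = intro.fd_window(ps, Window("chr1", 0, 4000))
        assert rec.fd == 0.0
        assert rec.window_d_sign < 0
        assert not rec.excluded

    def test_low_snp_windows_marked_excluded(self):
        ps = make_polarized([0.0] * 10, [0.5] * 10, [0.5] * 10)
        rec = intro.fd_window(ps, Window("chr1", 0, 4000), min_snps=30)
        assert rec.excluded
        assert rec.snp_count == 10

    def test_five_site_window_matches_independent_summation(self):
        rng = np.random.default_rng(12)
        w, x, y = rng.random((3, 5))
        ps = make_polarized(w, x, y)
        rec = intro.fd_window(ps, Window("chr1", 0, 1000), min_snps=5)
        num = ((1 - w) * x * y - w * (1 - x) * y).sum()
        p_d = np.maximum(x, y)
        den = ((1 - w) * p_d * p_d - w * (1 - p_d) * p_d).sum()
        if num <= 0:
            assert rec.fd == 0.0
        else:
            assert rec.fd == pytest.approx(num / den)
        assert rec.snp_count == 5

    def test_scaling_frequencies_of_contributions_preserved_by_ratio(self):
        # fd is a ratio of summed per-site terms: doubling every term's
        # weight (duplicating sites) cannot change it
        w, x, y = np.array([0.1, 0.0]), np.array([0.6, 0.3]), np.array([0.7, 0.5])
        one = intro.fd_window(make_polarized(w, x, y), Window("chr1", 0, 1000), min_snps=1)
        two = intro.fd_window(
            make_polarized(np.tile(w, 2), np.tile(x, 2), np.tile(y, 2)),
            Window("chr1", 0, 1000), min_snps=1,
        )
        assert one.fd == pytest.approx(two.fd)


class TestCandidateRegions:
    def _records(self, fds, size=20_000, step=10_000):
        out = []
        for i, fd in enumerate(fds):
            w = Window("chr1", i * step, i * step + size)
            out.append(intro.FdWindowRecord(w, fd, 50, 1, excluded=False))
        return out

    def test_five_percent_of_200_selects_ten(self):
        fds = np.linspace(0, 1, 200)
        crs = intro.call_candidate_regions(self._records(fds), 10_000_000, 0.05)
        assert crs.n_windows_selected == 10
        assert crs.threshold == pytest.approx(sorted(fds)[-10])

    def test_overlapping_selected_windows_merge(self):
        recs = self._records([0.9, 0.8] + [0.0] * 98)
        crs = intro.call_candidate_regions(recs, 10_000_000, 0.02)
        assert crs.regions.intervals == [("chr1", 0, 30_000)]

    def test_threshold_ties_all_retained(self):
        fds = [1.0] * 8 + [0.5] * 5 + [0.1] * 187  # k = 10 -> threshold 0.5
        crs = intro.call_candidate_regions(self._records(fds), 10_000_000, 0.05)
        assert crs.n_windows_selected == 13
        assert crs.n_windows_selected >= int(np.ceil(0.05 * 200))

    def test_excluded_windows_not_in_quantile_support(self):
        recs = self._records([0.9] + [0.1] * 99)
        for r in recs[50:]:
            r.excluded = True
        crs = intro.call_candidate_regions(recs, 10_000_000, 0.05)
        assert crs.threshold == pytest.approx(0.1)  # 50 usable -> k=3

    def test_no_usable_windows_fatal(self):
        recs = self._records([0.5, 0.6])
        for r in recs:
            r.excluded = True
        with pytest.raises(ValueError, match="usable"):
            intro.call_candidate_regions(recs, 1_000_000, 0.05)


class TestScanEvents:
    def _events(self):
        q1 = intro.Quartet("NC_C", "NWC_C", "XJ_C", "peach")
        q2 = intro.Quartet("NC_C", "KU_C", "XJ_W", "peach")
        return [
            intro.MigrationEventSpec("m1", "XJ_C", "NWC_C", q1),
            intro.MigrationEventSpec("m2", "XJ_W", "KU_C", q2),
        ]

    def test_union_matches_interval_arithmetic_oracle(self, desk_cohort):
        res = intro.scan_events(
            desk_cohort.variants, desk_cohort.popmap, self._events(),
            synth.DESK_GENOME, block_size=synth.DESK_BLOCK_SIZE,
        )
        # oracle: merge all per-event intervals with a plain sweep
        raw = sorted(
            iv for crs in res.events.values() for iv in crs.regions.intervals
        )
        merged = []
        for chrom, s, e in raw:
            if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
                merged[-1][2] = max(merged[-1][2], e)
            else:
                merged.append([chrom, s, e])
        oracle_len = sum(e - s for _, s, e in merged)
        assert res.union.total_length == oracle_len
        assert res.union_fraction == pytest.approx(oracle_len / 4_000_000)
        fractions = [crs.genome_fraction for crs in res.events.values()]
        assert res.union_fraction <= sum(fractions) + 1e-12

    def test_single_event_union_is_its_region_set(self, desk_cohort):
        res = intro.scan_events(
            desk_cohort.variants, desk_cohort.popmap, self._events()[:1],
            synth.DESK_GENOME, block_size=synth.DESK_BLOCK_SIZE,
        )
        assert res.union == res.events["m1"].regions

    def test_disjoint_region_sets_union_additively(self):
        a = RegionSet([("chr1", 0, 100)])
        b = RegionSet([("chr2", 0, 50), ("chr1", 500, 600)])
        assert (a | b).total_length == a.total_length + b.total_length


def test_null_candidate_windows_not_positionally_enriched(desk_cohort):
    """Without introgression the unavoidable top-5% call should be spread
    uniformly along the genome (chi-square over coarse bins)."""
    q = intro.Quartet("NC_C", "NWC_C", "XJ_C", "peach")
    ev = intro.MigrationEventSpec("m1", "XJ_C", "NWC_C", q)
    res = intro.scan_events(
        desk_cohort.variants, desk_cohort.popmap, [ev], synth.DESK_GENOME,
        block_size=synth.DESK_BLOCK_SIZE,
    )
    selected = [
        r for r in res.fd_records["m1"]
        if not r.excluded and r.fd >= res.events["m1"].threshold
    ]
    bins = np.zeros(4)
    for r in selected:
        offset = 0 if r.window.chrom == "chr1" else 2
        bins[offset + (r.window.start >= 1_000_000)] += 1
    stat, p = chisquare(bins)
    assert p >= 0.01


def test_migration_event_roles_validated():
    q = intro.Quartet("A", "B", "C", "O")
    with pytest.raises(ValueError, match="donor"):
        intro.MigrationEventSpec("m1", donor="B", recipient="C", quartet=q)
    with pytest.raises(ValueError, match="distinct"):
        intro.Quartet("A", "A", "C", "O")
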