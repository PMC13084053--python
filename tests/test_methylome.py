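"""Fragment filtering, window counting, NRPM/beta computation and library QC."""

import numpy as np
import pytest

from ewingsign.methylome import (
    CalibrationError,
    array_to_profile,
    beta_from_counts,
    compute_beta,
    count_windows,
    filter_fragments,
    normalize_nrpm,
    qc_stats,
)
from ewingsign.samples import FragmentSet, RegionSet, build_grid


def _frags(rows):
    return FragmentSet(
        [r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows],
        [r[3] for r in rows],
    )


class TestFilterFragments:
    @pytest.mark.parametrize(
        "mapq,length,kept",
        [
            (9, 150, False),
            (10, 150, True),
            (30, 69, False),
            (30, 70, True),
            (30, 1000, True),
            (30, 1001, False),
        ],
    )
    def test_boundary_rules(self, mapq, length, kept):
        fs = _frags([("chr1", 0, length, mapq)])
        assert len(filter_fragments(fs)) == (1 if kept else 0)

    def test_toy_set_with_three_violations(self):
        rows = [
            ("chr1", 0, 150, 30),     # keep
            ("chr1", 0, 69, 30),      # too short
            ("chr1", 0, 150, 9),      # low MAPQ
            ("chr1", 0, 1100, 30),    # too long
            ("chr1", 10, 180, 10),    # keep (MAPQ boundary)
            ("chr1", 0, 70, 60),      # keep (length boundary)
            ("chr1", 0, 1000, 60),    # keep (length boundary)
            ("chr2", 5, 205, 40),     # keep
            ("chr2", 5, 500, 12),     # keep
            ("chr2", 5, 300, 25),     # keep
        ]
        kept = filter_fragments(_frags(rows))
        assert len(kept) == 7
        # order preserved
        assert kept.start.tolist() == [0, 10, 0, 0, 5, 5, 5]


class TestCountWindows:
    def test_midpoint_assignment(self):
        grid = build_grid({"chr1": 900}, 300)
        fs = FragmentSet(["chr1", "chr1"], [100, 250], [200, 350])
        prof = count_windows(fs, grid)
        # midpoints 150 -> window 0; 300 -> window 1 (floor rule)
        assert prof.counts.tolist() == [1, 1, 0]
        assert prof.total_valid_fragments == 2
        assert prof.unassigned == 0

    def test_empty_set_gives_all_zero(self):
        grid = build_grid({"chr1": 900}, 300)
        prof = count_windows(FragmentSet([], [], []), grid)
        assert prof.counts.sum() == 0

    def test_off_grid_fragments_tallied_not_dropped(self):
        grid = build_grid({"chr1": 900}, 300)
        fs = FragmentSet(["chr1", "chrUn"], [850, 0], [980, 100])  # midpoints 915, 50
        prof = count_windows(fs, grid)
        assert prof.counts.sum() == 0
        assert prof.unassigned == 2

    def test_count_conservation(self, rng):
        grid = build_grid({"chr1": 30_000}, 300)
        n = 500
        starts = rng.integers(0, 31_000, size=n)
        fs = FragmentSet(np.full(n, "chr1", dtype=object), starts, starts + 160)
        prof = count_windows(fs, grid)
        assert prof.counts.sum() + prof.unassigned == n


class TestNormalizeAndBeta:
    def _profile(self, counts, grid=None):
        grid = grid or build_grid({"chr1": 300 * len(counts)}, 300)
        from ewingsign.methylome import MethylationProfile

        return MethylationProfile(
            "s", grid, np.array(counts), total_valid_fragments=int(sum(counts))
        )

    def test_nrpm_arithmetic(self):
        prof = normalize_nrpm(self._profile([1, 1]))
        assert prof.nrpm.tolist() == [5e5, 5e5]
        prof = normalize_nrpm(self._profile([3, 1, 0]))
        assert prof.nrpm.tolist() == [750_000.0, 250_000.0, 0.0]

    def test_cn_correction_halves_nrpm(self):
        base = normalize_nrpm(self._profile([2, 2]))
        corrected = normalize_nrpm(self._profile([2, 2]), cn_correction=np.array([2.0, 1.0]))
        assert corrected.nrpm[0] == base.nrpm[0] / 2
        assert corrected.nrpm[1] == base.nrpm[1]

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            normalize_nrpm(self._profile([0, 0]))

    def test_beta_anchored_at_calibration_median(self):
        prof = normalize_nrpm(self._profile([4, 2, 0, 4]))
        cal = RegionSet("cal", [("chr1", 0, 300)])  # window 0 anchors beta=1
        prof = compute_beta(prof, cal)
        assert prof.beta[0] == 1.0
        assert prof.beta[1] == 0.5
        assert prof.beta[2] == 0.0
        assert prof.beta[3] == 1.0  # clipped

    def test_beta_invariant_to_uniform_depth_rescaling(self):
        cal = RegionSet("cal", [("chr1", 0, 300)])
        a = compute_beta(normalize_nrpm(self._profile([8, 2, 4])), cal)
        b = compute_beta(normalize_nrpm(self._profile([80, 20, 40])), cal)
        assert np.allclose(a.beta, b.beta)

    def test_calibration_failure_raises(self):
        prof = normalize_nrpm(self._profile([0, 5]))
        with pytest.raises(CalibrationError, match="calibration"):
            compute_beta(prof, RegionSet("cal", [("chr1", 0, 300)]))


class TestQcStats:
    def test_relh_one_when_coverage_matches_genome_density(self):
        # one 100 bp fragment covering exactly 1 CpG; genome density 0.01/bp
        fs = FragmentSet(["chr1"], [0], [100])
        cpg = RegionSet("cpg", [("chr1", 50, 52)])
        qc = qc_stats(fs, cpg, RegionSet("hs", [("chr1", 0, 100)]), 0.01)
        assert qc.relH == pytest.approx(1.0)
        assert qc.hyperstable_fraction == 1.0

    def test_hand_computed_pass_case(self):
        # 4 fragments x 100 bp = 400 bases; 12 covered CpGs; density 0.01
        # -> relH = (12/400)/0.01 = 3.0; 2 of 4 midpoints in hyperstable
        fs = FragmentSet(
            ["chr1"] * 4, [0, 200, 400, 600], [100, 300, 500, 700]
        )
        cpg = RegionSet("cpg", [("chr1", 10 * i, 10 * i + 2) for i in range(10)]
                        + [("chr1", 210, 212), ("chr1", 250, 252)])
        hyperstable = RegionSet("hs", [("chr1", 0, 100), ("chr1", 400, 500)])
        qc = qc_stats(fs, cpg, hyperstable, 0.01)
        assert qc.relH == pytest.approx(3.0)
        assert qc.hyperstable_fraction == pytest.approx(0.5)
        assert qc.pass_ is True

    def test_fail_when_not_enriched(self):
        fs = FragmentSet(["chr1"], [0], [100])
        cpg = RegionSet("cpg", [("chr1", 50, 52)])
        qc = qc_stats(fs, cpg, RegionSet("hs", [("chr2", 0, 10)]), 0.01)
        assert qc.hyperstable_fraction == 0.0
        assert qc.pass_ is False

    def test_empty_fragments_rejected(self):
        with pytest.raises(ValueError):
            qc_stats(FragmentSet([], [], []), RegionSet("c", []), RegionSet("h", []), 0.01)


class TestArrayToProfile:
    def test_deterministic_conversion(self):
        grid = build_grid({"chr1": 600}, 300)
        prof = array_to_profile(np.array([1.0, 0.0]), grid, 100, deterministic=True)
        assert prof.counts.tolist() == [100, 0]
        prof = array_to_profile(np.array([0.5, 0.5]), grid, 100, deterministic=True)
        assert prof.counts.tolist() == [50, 50]

    def test_stochastic_counts_concentrate(self, rng):
        betas = np.array([0.5, 0.3, 0.2])
        grid = build_grid({"chr1": 900}, 300)
        prof = array_to_profile(betas, grid, 100_000, seed=4)
        expected = betas / betas.sum() * 100_000
        assert np.all(np.abs(prof.counts - expected) / expected < 0.02)

    def test_all_zero_betas_rejected(self):
        grid = build_grid({"chr1": 600}, 300)
        with pytest.raises(ValueError):
            array_to_profile(np.zeros(2), grid, 100)

    @pytest.mark.parametrize("deterministic,min_r", [(True, 0.999), (False, 0.95)])
    def test_beta_roundtrip_identity(self, rng, deterministic, min_r):
        """array -> counts -> nrpm -> beta recovers the input betas.

        The deterministic conversion is an identity up to rounding; the
        stochastic one is limited by multinomial noise (~50 reads/window at
        this depth), hence the looser bound.
        """
        n = 2000
        betas = rng.uniform(0.0, 0.6, size=n)
        cal_idx = rng.choice(n, size=40, replace=False)
        betas[cal_idx] = 1.0
        grid = build_grid({"chr1": 300 * n}, 300)
        prof = array_to_profile(betas, grid, 100_000, seed=8, deterministic=deterministic)
        prof = normalize_nrpm(prof)
        cal = RegionSet("cal", [("chr1", 300 * int(i), 300 * int(i) + 300) for i in cal_idx])
        prof = compute_beta(prof, cal)
        r = np.corrcoef(prof.beta, betas)[0, 1]
        assert r >= min_r

    def test_beta_from_counts_matches_profile_route(self, rng):
        counts = rng.integers(0, 50, size=100)
        cal_idx = np.array([5, 17, 40])
        counts[cal_idx] = 60
        grid = build_grid({"chr1": 300 * 100}, 300)
        from ewingsign.methylome import MethylationProfile

        prof = MethylationProfile("s", grid, counts, total_valid_fragments=int(counts.sum()))
        prof = normalize_nrpm(prof)
        cal = RegionSet("cal", [("chr1", 300 * int(i), 300 * int(i) + 300) for i in cal_idx])
        prof = compute_beta(prof, cal)
        direct = beta_from_counts(counts, cal_idx)
        assert np.allclose(prof.beta, direct)
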