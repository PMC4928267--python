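import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitis_ancestry import (
    MISSING,
    CurationConfig,
    HweCounts,
    filter_by_maf,
    filter_hwe,
    hwe_het_excess_pvalue,
    site_maf,
)
from vitis_ancestry.qc import (
    _levene_haldane_log_pmf,
    filter_samples_by_missingness,
    filter_sites_by_missingness,
    mask_low_depth,
)

from conftest import make_matrix, random_matrix
from oracles import hwe_excess_pvalue_enumeration


class TestDepthMask:
    def test_boundary_kept_at_exact_threshold(self):
        m = make_matrix([[1, 1]], depth=[[7, 8]])
        out = mask_low_depth(m, 8)
        assert out.dosage[0, 0] == MISSING
        assert out.dosage[0, 1] == 1

    def test_min_depth_zero_is_noop(self):
        m = make_matrix([[1, 2]], depth=[[0, 3]])
        assert np.array_equal(mask_low_depth(m, 0).dosage, m.dosage)

    def test_uniform_low_depth_masks_everything(self):
        m = make_matrix(np.ones((2, 3), dtype=np.int8), depth=np.full((2, 3), 3))
        assert (mask_low_depth(m, 8).dosage == MISSING).all()

    def test_requires_depth(self):
        with pytest.raises(ValueError, match="depth"):
            mask_low_depth(make_matrix([[1]]), 8)


class TestMissingnessFilters:
    def test_site_at_exact_threshold_dropped(self):
        # 10 samples; site0: 2/10 missing (=0.20, dropped), site1: 1/10 (kept)
        dosage = np.ones((10, 2), dtype=np.int8)
        dosage[0, 0] = dosage[1, 0] = MISSING
        dosage[0, 1] = MISSING
        out = filter_sites_by_missingness(make_matrix(dosage), 0.20)
        assert out.n_sites == 1
        assert out.sites[0].pos == 200

    def test_max_missing_one_keeps_all_sites(self):
        dosage = np.full((3, 4), MISSING, dtype=np.int8)
        dosage[0, :] = 1
        assert filter_sites_by_missingness(make_matrix(dosage), 1.0).n_sites == 4

    def test_sample_at_exact_threshold_kept(self):
        # 20 sites; sample missing fractions 0.0, 0.20, 0.25
        dosage = np.ones((3, 20), dtype=np.int8)
        dosage[1, :4] = MISSING
        dosage[2, :5] = MISSING
        out = filter_samples_by_missingness(make_matrix(dosage), 0.20)
        assert out.samples == ["s0", "s1"]

    def test_derived_three_sample_count(self):
        # missing fractions (0.0, 0.2, 0.3) over 10 sites -> 2 samples remain
        dosage = np.ones((3, 10), dtype=np.int8)
        dosage[1, :2] = MISSING
        dosage[2, :3] = MISSING
        assert filter_samples_by_missingness(make_matrix(dosage), 0.20).n_samples == 2

    def test_fully_observed_unchanged(self, rng):
        m = random_matrix(rng, missing_rate=0.0)
        out = filter_samples_by_missingness(m, 0.20)
        assert out.samples == m.samples
        assert np.array_equal(out.dosage, m.dosage)

    def test_idempotence(self, rng):
        m = random_matrix(rng, n=8, m=30, missing_rate=0.3)
        once = filter_sites_by_missingness(m, 0.25)
        twice = filter_sites_by_missingness(once, 0.25)
        assert np.array_equal(once.dosage, twice.dosage)
        s_once = filter_samples_by_missingness(m, 0.4)
        s_twice = filter_samples_by_missingness(s_once, 0.4)
        assert s_once.samples == s_twice.samples


class TestMaf:
    @pytest.mark.parametrize(
        "col,expected",
        [
            ([0, 1, 2], 0.5),
            ([2, 2, 2, 1], 0.125),  # f_alt = 7/8
            ([0, MISSING, 0], 0.0),
        ],
    )
    def test_site_maf_examples(self, col, expected):
        m = make_matrix(np.array(col, dtype=np.int8)[:, None])
        assert site_maf(m)[0] == pytest.approx(expected)

    def test_no_calls_flagged_nan(self):
        m = make_matrix(np.full((3, 1), MISSING, dtype=np.int8))
        assert np.isnan(site_maf(m)[0])

    def test_maf_range_property(self, rng):
        m = random_matrix(rng, n=10, m=50, missing_rate=0.2)
        maf = site_maf(m)
        ok = ~np.isnan(maf)
        assert ((maf[ok] >= 0) & (maf[ok] <= 0.5)).all()

    def test_boundary_nonstrict_keeps_at_threshold(self):
        # 10 samples, 1 alt copy of 20 -> MAF exactly 0.05
        dosage = np.zeros((10, 1), dtype=np.int8)
        dosage[0, 0] = 1
        assert filter_by_maf(make_matrix(dosage), 0.05, strict=False).n_sites == 1

    def test_boundary_strict_drops_at_threshold(self):
        # 10 samples, 2 alt copies of 20 -> MAF exactly 0.10
        dosage = np.zeros((10, 1), dtype=np.int8)
        dosage[0, 0] = 2
        assert filter_by_maf(make_matrix(dosage), 0.10, strict=True).n_sites == 0

    def test_min_maf_zero_removes_nothing(self, rng):
        m = random_matrix(rng, n=6, m=20, missing_rate=0.1)
        assert filter_by_maf(m, 0.0, strict=False).n_sites == 20

    def test_subset_filter_applies_to_whole_matrix(self):
        # polymorphic overall but monomorphic in the subset -> dropped
        dosage = np.array([[0, 1], [0, 1], [2, 1]], dtype=np.int8)
        m = make_matrix(dosage)
        out = filter_by_maf(m, 0.05, sample_subset=["s0", "s1"], strict=False)
        assert out.n_sites == 1
        assert out.n_samples == 3

    def test_unknown_subset_sample_raises(self):
        with pytest.raises(ValueError, match="ghost"):
            filter_by_maf(make_matrix([[0]]), 0.05, sample_subset=["ghost"])


class TestHwe:
    def test_zero_hets_gives_p_one(self):
        assert hwe_het_excess_pvalue(HweCounts(5, 0, 5)) == 1.0

    def test_two_sample_forced_configuration(self):
        # n=2, counts (0,2,0): 2 minor copies; h in {0, 2};
        # weights: h=0 -> C(2,1)=2 arrangements? exact: P(h=2) = 2/3
        p = hwe_het_excess_pvalue(HweCounts(0, 2, 0))
        assert p == pytest.approx(
            hwe_excess_pvalue_enumeration(0, 2, 0), abs=1e-12
        )
        assert p == pytest.approx(2 / 3, abs=1e-12)

    def test_panel_sized_example_matches_enumeration(self):
        p = hwe_het_excess_pvalue(HweCounts(5, 9, 0))
        assert p == pytest.approx(
            hwe_excess_pvalue_enumeration(5, 9, 0), abs=1e-10
        )

    def test_distribution_normalisation(self):
        for n, n_minor in [(5, 3), (14, 14), (20, 7)]:
            h, logp = _levene_haldane_log_pmf(n, n_minor)
            assert np.exp(logp).sum() == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n=st.integers(1, 20),
        data=st.data(),
    )
    def test_matches_enumeration_oracle(self, n, data):
        n_minor = data.draw(st.integers(0, n))
        h_choices = list(range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2))
        h = data.draw(st.sampled_from(h_choices))
        n_mm = (n_minor - h) // 2
        counts = HweCounts(n - n_mm - h, h, n_mm)
        assert hwe_het_excess_pvalue(counts) == pytest.approx(
            hwe_excess_pvalue_enumeration(*vars(counts).values()), abs=1e-10
        )

    def test_two_sided_at_least_observed_mass(self):
        c = HweCounts(4, 8, 2)
        assert hwe_het_excess_pvalue(c, "two_sided") <= 1.0
        assert hwe_het_excess_pvalue(c, "two_sided") > 0.0

    def test_asymptotic_agrees_in_direction(self):
        c = HweCounts(0, 20, 0)
        assert hwe_het_excess_pvalue(c, method="asymptotic") < 0.001

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            HweCounts(-1, 2, 0)


class TestFilterHwe:
    def test_all_het_site_removed(self):
        dosage = np.ones((20, 1), dtype=np.int8)
        assert filter_hwe(make_matrix(dosage), 0.001).n_sites == 0

    def test_monomorphic_site_kept(self):
        dosage = np.zeros((10, 1), dtype=np.int8)
        assert filter_hwe(make_matrix(dosage), 0.001).n_sites == 1

    def test_tiny_alpha_removes_nothing(self, rng):
        m = random_matrix(rng, n=10, m=30, missing_rate=0.1)
        assert filter_hwe(m, 1e-300).n_sites == 30

    def test_idempotence(self, rng):
        m = random_matrix(rng, n=12, m=40, missing_rate=0.1)
        once = filter_hwe(m, 0.05)
        twice = filter_hwe(once, 0.05)
        assert np.array_equal(once.dosage, twice.dosage)


def test_config_validation():
    with pytest.raises(ValueError):
        CurationConfig(min_depth=-1)
    with pytest.raises(ValueError):
        CurationConfig(max_site_missing=1.5)
    assert CurationConfig().min_depth == 8
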