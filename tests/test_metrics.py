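import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from octoquant.io import Stack, ValidationError
from octoquant.metrics import (
    apv_histogram,
    call_polarity,
    contributing_octants,
    fold_change,
    normalize_field,
    overlap_area,
    percent_difference,
    region_apv,
)
from octoquant.morphology import CellMask, centroid
from octoquant.partition import octant_labels


class TestRegionApv:
    def test_constant_stack(self):
        stack = Stack(np.full((3, 4, 4), 7.0), "DIC")
        region = np.zeros((3, 4, 4), dtype=bool)
        region[1, :2, :2] = True
        assert region_apv(stack, region) == 7.0

    def test_two_voxel_mean(self):
        vox = np.zeros((1, 2, 2))
        vox[0, 0, 0], vox[0, 0, 1] = 2.0, 4.0
        region = np.zeros_like(vox, dtype=bool)
        region[0, 0, :2] = True
        assert region_apv(Stack(vox, "DIC"), region) == 3.0

    def test_whole_cell_is_count_weighted_octant_mean(self, rng):
        """Conservation: whole-cell APV = TPN-weighted mean of octant APVs,
        checked against the brute-force mean over all voxels."""
        mask = CellMask("m", rng.random((12, 12)) > 0.4, 6)
        stack = Stack(rng.random((6, 12, 12)) * 100, "DIC")
        lab = octant_labels(mask, centroid(mask))
        octs = [(region_apv(stack, lab.region_mask(k)), lab.counts[k - 1]) for k in range(1, 9) if lab.counts[k - 1]]
        weighted = sum(a * n for a, n in octs) / sum(n for _, n in octs)
        whole = region_apv(stack, mask.mask3d)
        assert whole == pytest.approx(weighted, rel=1e-12)
        assert whole == pytest.approx(stack.voxels[mask.mask3d].mean(), rel=1e-12)

    def test_empty_region_rejected(self):
        stack = Stack(np.ones((2, 3, 3)), "DIC")
        with pytest.raises(ValidationError):
            region_apv(stack, np.zeros((2, 3, 3), dtype=bool))


class TestNormalize:
    def test_examples(self):
        np.testing.assert_allclose(normalize_field([2.0, 4.0]), [0.5, 1.0])
        np.testing.assert_allclose(normalize_field([3.0, 3.0, 3.0]), 1.0)

    def test_max_is_exactly_one(self, rng):
        out = normalize_field(rng.random(50) * 123)
        assert out.max() == 1.0

    def test_idempotence(self, rng):
        once = normalize_field(rng.random(20))
        np.testing.assert_array_equal(normalize_field(once), once)

    def test_dict_interface(self):
        out = normalize_field({"oct1": 2.0, "oct2": 8.0})
        assert out == {"oct1": 0.25, "oct2": 1.0}

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            normalize_field([0.0, 0.0])


def test_percent_difference_and_fold_change_identity():
    assert percent_difference(1.0, 1.0) == 0.0
    assert percent_difference(1.97, 1.0) == pytest.approx(97.0)
    assert fold_change(1.97, 1.0) == pytest.approx(1.97)
    a, b = 3.45, 1.0
    assert fold_change(a, b) == pytest.approx(1 + percent_difference(a, b) / 100)
    with pytest.raises(ValidationError):
        percent_difference(1.0, 0.0)


class TestCallPolarity:
    def test_identical_samples_are_nil(self):
        x = [0.5, 0.6, 0.7, 0.8]
        call = call_polarity(x, x, axis="z")
        assert call.t_statistic == 0.0
        assert call.direction == "nil"
        assert call.magnitude_pct == 0.0

    def test_recovers_imposed_basolateral_gradient(self, rng):
        """20% basolateral excess with 5% between-cell noise, n=50: direction
        must be basolateral and magnitude close to 20%."""
        apical = rng.normal(1.0, 0.05, 50)
        basal = rng.normal(1.2, 0.05, 50)
        call = call_polarity(apical, basal, axis="z")
        assert call.direction == "basolateral"
        assert 15.0 <= call.magnitude_pct <= 25.0

    def test_axis_labels(self, rng):
        hi = rng.normal(1.3, 0.02, 30)
        lo = rng.normal(1.0, 0.02, 30)
        assert call_polarity(hi, lo, axis="x").direction == "x_progressive"
        assert call_polarity(lo, hi, axis="y").direction == "y_regressive"

    def test_type_one_error_rate_near_alpha(self, rng):
        """Null populations trigger a call at roughly the alpha rate."""
        hits = sum(
            call_polarity(rng.normal(1, 0.05, 30), rng.normal(1, 0.05, 30), axis="z").direction
            != "nil"
            for _ in range(400)
        )
        assert 0.02 <= hits / 400 <= 0.09

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            call_polarity([1.0], [1.0, 2.0], axis="z")


class TestHistogram:
    def test_single_bin_mass(self):
        h = apv_histogram([0.55] * 9)
        assert h.freq[5] == 1.0
        assert h.freq.sum() == 1.0

    def test_uniform_spread(self):
        values = np.arange(10) / 10 + 0.05
        h = apv_histogram(values)
        np.testing.assert_allclose(h.freq, 0.1)

    def test_top_edge_inclusive(self):
        h = apv_histogram([1.0, 1.0])
        assert h.freq[-1] == 1.0

    def test_max_mode(self):
        h = apv_histogram([0.05, 0.15, 0.15], mode="max")
        assert h.freq.max() == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            apv_histogram([])
        with pytest.raises(ValidationError):
            apv_histogram([1.2])
        with pytest.raises(ValidationError):
            apv_histogram([0.5], bin_width=0.3)


class TestOverlap:
    def test_identical_and_disjoint(self, rng):
        h1 = apv_histogram(rng.random(40))
        assert overlap_area(h1, h1) == pytest.approx(1.0)
        lo = apv_histogram(rng.random(40) * 0.3)
        hi = apv_histogram(0.7 + rng.random(40) * 0.3)
        assert overlap_area(lo, hi) == 0.0

    def test_hand_computed_three_bin_case(self):
        h1 = apv_histogram([0.05, 0.05, 0.15, 0.15])  # [0.5, 0.5, 0, ...]
        h2 = apv_histogram([0.15, 0.15, 0.25, 0.25])  # [0, 0.5, 0.5, ...]
        assert overlap_area(h1, h2) == pytest.approx(0.5)
        assert overlap_area(h2, h1) == pytest.approx(0.5)  # symmetric

    @given(st.integers(0, 10_000))
    def test_equals_one_minus_total_variation(self, seed):
        """min-sum overlap == 1 - TV distance, via an independent computation."""
        rng = np.random.default_rng(seed)
        h1 = apv_histogram(rng.random(30))
        h2 = apv_histogram(rng.random(30))
        tv = 0.5 * np.abs(h1.freq - h2.freq).sum()
        ov = overlap_area(h1, h2)
        assert 0.0 <= ov <= 1.0
        assert ov == pytest.approx(1.0 - tv, abs=1e-12)

    def test_mismatched_bins_rejected(self):
        h1 = apv_histogram([0.5], bin_width=0.1)
        h2 = apv_histogram([0.5], bin_width=0.2)
        with pytest.raises(ValidationError):
            overlap_area(h1, h2)


class TestContributingOctants:
    def _hists(self, shifted=(), n=4000, lo=(0.2, 0.8), hi=(0.5, 1.0)):
        """Normal octants draw NAPVs from U(*lo*); shifted ones from U(*hi*),
        which still overlaps the common band as a real gradient would."""
        rng = np.random.default_rng(0)
        out = {}
        for k in range(1, 9):
            a, b = hi if k in shifted else lo
            out[k] = apv_histogram(a + rng.random(n) * (b - a), region=f"oct{k}")
        return out

    def test_identical_distributions_contribute_nothing(self):
        h = apv_histogram(np.linspace(0.2, 0.8, 50))
        assert contributing_octants({k: h for k in range(1, 9)}) == []

    def test_fully_shifted_octant_detected(self):
        hists = self._hists(shifted=(3,), lo=(0.3, 0.6), hi=(0.8, 1.0))
        assert contributing_octants(hists) == [3]

    def test_gradient_confined_to_octants_7_8(self):
        assert contributing_octants(self._hists(shifted=(7, 8))) == [7, 8]

    def test_requires_all_eight(self):
        h = apv_histogram([0.5])
        with pytest.raises(ValidationError):
            contributing_octants({k: h for k in range(1, 8)})


def test_scale_invariance_of_derived_metrics(rng):
    """Multiplying all intensities by k leaves NAPVs (hence histograms,
    overlaps and polarity calls) unchanged."""
    apvs = rng.random(16) * 50
    base = normalize_field(apvs)
    for k in (0.1, 3.0, 1000.0):
        np.testing.assert_allclose(normalize_field(apvs * k), base, rtol=1e-12)
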