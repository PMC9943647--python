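"""Lane normalization, per-base percent change and replicate averaging."""

import numpy as np
import pandas as pd
import pytest

from bindpoly.footprint import (
    FootprintQuantifier,
    LaneProfile,
    average_replicates,
    normalize_profiles,
    percent_change,
)
from bindpoly.synthetic import simulate_footprint


def make_profile(intensities, strand="top"):
    n = len(intensities)
    return LaneProfile(pd.DataFrame({
        "base_index": np.arange(1, n + 1),
        "base": list("ACGT" * (n // 4 + 1))[:n],
        "strand": strand,
        "intensity": np.asarray(intensities, dtype=float),
    }))


class TestNormalization:
    def test_identical_profiles_scale_one(self):
        free = make_profile([1, 2, 3, 4])
        _, scaled, scale = normalize_profiles(free, make_profile([1, 2, 3, 4]))
        assert scale == pytest.approx(1.0)
        assert np.allclose(scaled.intensity, free.intensity)

    def test_global_rescale_invariance(self):
        free = make_profile([1, 2, 3, 4])
        _, scaled, scale = normalize_profiles(free, make_profile([2, 4, 6, 8]))
        assert scale == pytest.approx(0.5)
        assert np.allclose(scaled.intensity, free.intensity)

    def test_single_halved_base_scale_is_total_ratio(self):
        free = make_profile([10, 10, 10, 10])
        cplx = make_profile([10, 5, 10, 10])
        _, scaled, scale = normalize_profiles(free, cplx)
        assert scale == pytest.approx(40 / 35)
        assert np.allclose(scaled.intensity, np.array([10, 5, 10, 10]) * 40 / 35)

    def test_reference_bases_restrict_the_normalization(self):
        free = make_profile([10, 10, 10, 10])
        cplx = make_profile([10, 5, 10, 10])
        _, scaled, scale = normalize_profiles(free, cplx,
                                              reference_bases=[1, 3, 4])
        assert scale == pytest.approx(1.0)
        assert scaled.intensity[1] == pytest.approx(5.0)

    def test_strand_mismatch_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            normalize_profiles(make_profile([1, 2], strand="top"),
                               make_profile([1, 2], strand="bottom"))

    def test_index_mismatch_rejected(self):
        free = make_profile([1, 2, 3])
        other = make_profile([1, 2, 3, 4])
        with pytest.raises(ValueError, match="base_index"):
            normalize_profiles(free, other)


class TestPercentChange:
    def test_identical_profiles_all_unchanged(self):
        free = make_profile([5, 6, 7, 8])
        report = percent_change(free, free)
        assert np.allclose(report.table["percent_change"], 0.0)
        assert (report.table["classification"] == "unchanged").all()

    def test_halved_base_is_protected(self):
        free = make_profile([10, 10, 10])
        cplx = make_profile([10, 5, 10])
        report = percent_change(free, cplx)
        assert report.table["percent_change"][1] == pytest.approx(-50.0)
        assert report.classification_of(2) == "protected"

    def test_thirty_percent_rise_is_hyperexposed(self):
        free = make_profile([10, 10, 10])
        cplx = make_profile([10, 13, 10])
        report = percent_change(free, cplx)
        assert report.table["percent_change"][1] == pytest.approx(30.0)
        assert report.classification_of(2) == "hyperexposed"

    def test_zero_free_intensity_flagged_not_dropped(self):
        free = make_profile([10, 0, 10])
        cplx = make_profile([10, 2, 10])
        report = percent_change(free, cplx)
        assert len(report.table) == 3
        assert report.classification_of(2) == "unquantifiable"
        assert np.isnan(report.table["percent_change"][1])

    def test_scale_invariance_of_full_report(self):
        free = make_profile([10.0, 12.0, 8.0, 20.0])
        cplx = make_profile([10.0, 6.0, 8.0, 28.0])
        base = percent_change(*normalize_profiles(free, cplx)[:2])
        for c in (0.2, 5.0):
            f2 = free.with_intensity(free.intensity * c)
            report = percent_change(*normalize_profiles(f2, cplx)[:2])
            assert np.allclose(report.table["percent_change"],
                               base.table["percent_change"])


class TestAverageReplicates:
    def test_two_identical_reports_unchanged(self):
        free = make_profile([10, 10])
        cplx = make_profile([5, 10])
        rep = percent_change(free, cplx)
        merged = average_replicates([rep, rep])
        assert np.allclose(merged.table["percent_change"],
                           rep.table["percent_change"])

    def test_mean_then_reclassify(self):
        free = make_profile([10.0, 10.0])
        reports = [percent_change(free, make_profile(i)) for i in
                   ([6.0, 13.0], [4.0, 9.0])]
        merged = average_replicates(reports)
        # (-40, -60) -> -50 protected; (+30, -10) -> +10 unchanged
        assert merged.table["percent_change"][0] == pytest.approx(-50.0)
        assert merged.classification_of(1) == "protected"
        assert merged.table["percent_change"][1] == pytest.approx(10.0)
        assert merged.classification_of(2) == "unchanged"

    def test_single_report_rejected(self):
        rep = percent_change(make_profile([10, 10]), make_profile([5, 10]))
        with pytest.raises(ValueError, match="two"):
            average_replicates([rep])


class TestSimulatorRoundTrip:
    def test_known_protection_factors_recovered(self):
        protection = np.ones(30)
        protection[[5, 6, 7]] = 0.5   # protected patch
        protection[15] = 1.4          # hyperexposed base
        reference = [i + 1 for i in range(30) if protection[i] == 1.0]
        free, cplx = simulate_footprint(protection, "A" * 30, sigma=0.0, seed=9)
        quant = FootprintQuantifier(reference_bases=reference)
        paired = free.table[["strand", "base_index", "base"]].copy()
        paired["intensity_free"] = free.intensity
        paired["intensity_complex"] = cplx.intensity
        table = quant.transform(paired)
        expected = 100.0 * (protection - 1.0)
        assert np.allclose(table["percent_change"], expected, atol=1e-9)
        assert table["classification"][5] == "protected"
        assert table["classification"][15] == "hyperexposed"
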