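import numpy as np
import pandas as pd
import pytest

from absanchor import (
    CVPoint,
    PowerLawCVFit,
    TaxonCountTable,
    expected_copies,
    fit_threshold,
    flag_blank_taxa,
    flag_dropouts_contaminants,
    lloq_per_gram,
    poisson_ci_band,
    poisson_threshold,
    replicate_cv,
    round_sig,
    threshold_vs_depth,
)
from absanchor.simulate import replicate_config, simulate_study


def make_replicates(columns: dict) -> TaxonCountTable:
    return TaxonCountTable(pd.DataFrame(columns, index=["r1", "r2", "r3", "r4"]))


class TestReplicateCV:
    def test_identical_replicates_have_zero_cv(self):
        table = make_replicates({"a": [10] * 4, "b": [90] * 4})
        assert all(p.cv_percent == 0.0 for p in replicate_cv(table))

    def test_hand_computed_cv(self):
        # counts 5,10,15,10 at constant depth 100: mean 0.1, sd 0.04082
        table = make_replicates({"a": [5, 10, 15, 10], "b": [95, 90, 85, 90]})
        point = replicate_cv(table)[0]
        assert point.mean_rel_abundance == pytest.approx(0.10)
        assert point.cv_percent == pytest.approx(40.8248, abs=1e-3)

    def test_single_replicate_presence_has_cv_200(self):
        # a taxon seen in 1 of 4 replicates maxes out the n=4 CV at 200%
        table = make_replicates({"a": [8, 0, 0, 0], "b": [92, 100, 100, 100]})
        point = replicate_cv(table)[0]
        assert point.mean_rel_abundance == pytest.approx(0.02)
        assert point.cv_percent == pytest.approx(200.0)

    def test_absent_taxa_omitted(self):
        table = make_replicates({"a": [1, 2, 1, 2], "ghost": [0, 0, 0, 0]})
        assert [p.taxon_id for p in replicate_cv(table)] == ["a"]

    def test_mismatched_taxon_sets_rejected(self):
        t1 = TaxonCountTable(pd.DataFrame({"a": [1]}, index=["r1"]))
        t2 = TaxonCountTable(pd.DataFrame({"b": [1]}, index=["r2"]))
        with pytest.raises(ValueError, match="mismatched"):
            replicate_cv([t1, t2])


class TestDropoutsContaminants:
    def test_partition(self):
        high = {"a", "b", "c"}
        low = {"b", "c", "kit_bug"}
        dropouts, contaminants = flag_dropouts_contaminants(high, low)
        assert dropouts == ["a"]
        assert contaminants == ["kit_bug"]

    def test_tables_as_input_use_presence(self):
        high = TaxonCountTable(pd.DataFrame({"a": [5], "b": [1], "c": [0]}, index=["h"]))
        low = TaxonCountTable(pd.DataFrame({"a": [0], "b": [2], "c": [3]}, index=["l"]))
        dropouts, contaminants = flag_dropouts_contaminants(high, low)
        assert (dropouts, contaminants) == (["a"], ["c"])


class TestBlankFlags:
    def test_ranking_and_tie_breaks(self):
        table = TaxonCountTable(
            pd.DataFrame({"x": [1], "y": [1], "z": [1], "clean": [1]}, index=["s"])
        )
        blanks = TaxonCountTable(
            pd.DataFrame(
                {"x": [5, 5], "y": [9, 0], "z": [9, 0], "clean": [0, 0]},
                index=["b1", "b2"],
            )
        )
        out = flag_blank_taxa(table, blanks)
        # x in both blanks -> rank 1; y and z tie on prevalence and reads -> lexical
        assert list(out.index) == ["x", "y", "z", "clean"]
        assert bool(out.loc["clean", "flagged"]) is False
        assert bool(out.loc["x", "flagged"]) is True

    def test_no_blanks_warns_and_returns_empty(self, small_table):
        with pytest.warns(UserWarning, match="no blank"):
            out = flag_blank_taxa(small_table, None)
        assert out.empty


class TestPoissonBand:
    def test_large_rate_band_near_closed_form(self):
        # at lambda = 1e6 the Poisson CV concentrates near 100/sqrt(lambda) = 0.1%
        band = poisson_ci_band(1e7, n_boot=2000, grid=np.array([0.1]), seed=0)
        assert band.lower[0] < 0.1 < band.upper[0]
        assert band.upper[0] < 0.3

    def test_typical_cv_at_100_copies_is_ten_percent(self):
        band = poisson_ci_band(1e4, n_boot=4000, grid=np.array([0.01]), seed=0)
        # middle of the band brackets the 10% closed form
        assert band.lower[0] < 10.0 < band.upper[0]

    def test_deterministic_given_seed(self):
        a = poisson_ci_band(28000, n_boot=500, seed=7)
        b = poisson_ci_band(28000, n_boot=500, seed=7)
        assert np.array_equal(a.lower, b.lower, equal_nan=True)
        assert np.array_equal(a.upper, b.upper, equal_nan=True)

    def test_band_ordering_and_zero_rate_skipped(self):
        with pytest.warns(UserWarning, match="rate 0"):
            band = poisson_ci_band(1e4, n_boot=500, grid=np.array([0.0, 0.01]), seed=1)
        assert np.isnan(band.lower[0])
        valid = ~np.isnan(band.lower)
        assert (band.lower[valid] <= band.upper[valid]).all()

    def test_band_width_shrinks_as_sqrt_abundance(self):
        # band midpoint ratio between p and 4p approaches 2 (1/sqrt scaling)
        band = poisson_ci_band(
            1e6, n_boot=20000, grid=np.array([1e-3, 4e-3]), seed=3
        )
        mid = (band.lower + band.upper) / 2
        assert mid[0] / mid[1] == pytest.approx(2.0, rel=0.1)

    def test_empirical_replicate_cv_lies_within_band(self):
        # multinomial replicate CVs should fall inside the 95% Poisson band
        # for at least 90% of taxa
        study = simulate_study(replicate_config(seed=11))
        points = replicate_cv(study.counts)
        depth = int(study.counts.read_depth.iloc[0])
        abundances = np.array([p.mean_rel_abundance for p in points])
        band = poisson_ci_band(depth, n_boot=4000, grid=abundances, seed=12)
        cvs = np.array([p.cv_percent for p in points])
        ok = (cvs >= band.lower) & (cvs <= band.upper)
        assert ok.mean() >= 0.90


class TestPowerLawFit:
    def test_exact_recovery_on_noiseless_power_law(self):
        x = np.logspace(-3, 1, 12)
        points = [
            CVPoint(f"t{i}", xi / 100, 3.0 * xi ** -0.5, 4) for i, xi in enumerate(x)
        ]
        fit = fit_threshold(points, cv_level=30)
        assert fit.a == pytest.approx(3.0, abs=1e-9)
        assert fit.b == pytest.approx(0.5, abs=1e-9)
        assert fit.threshold == pytest.approx(0.01, rel=1e-6)

    def test_threshold_boundary_when_cv_level_equals_a(self):
        x = np.logspace(-2, 2, 8)
        points = [CVPoint(f"t{i}", xi / 100, 30.0 * xi ** -0.7, 4) for i, xi in enumerate(x)]
        assert fit_threshold(points, cv_level=30).threshold == pytest.approx(1.0)

    def test_doubling_cv_level_quarters_threshold_at_b_half(self):
        x = np.logspace(-3, 1, 10)
        points = [CVPoint(f"t{i}", xi / 100, 5.0 * xi ** -0.5, 4) for i, xi in enumerate(x)]
        t30 = fit_threshold(points, cv_level=30).threshold
        t60 = fit_threshold(points, cv_level=60).threshold
        assert t60 == pytest.approx(t30 / 4)

    def test_all_zero_cv_is_an_error(self):
        points = [CVPoint(f"t{i}", 0.1, 0.0, 4) for i in range(5)]
        with pytest.raises(ValueError, match="no variation"):
            fit_threshold(points)

    def test_excluded_taxa_leave_the_fit(self):
        x = np.logspace(-3, 1, 10)
        points = [CVPoint(f"t{i}", xi / 100, 3.0 * xi ** -0.5, 4) for i, xi in enumerate(x)]
        outlier = CVPoint("contaminant", 1e-4, 500.0, 4)
        fit = fit_threshold(points + [outlier], exclude_taxa=["contaminant"])
        assert fit.b == pytest.approx(0.5, abs=1e-9)
        assert fit.n_points == 10

    def test_estimator_predict(self):
        model = PowerLawCVFit().fit([0.1, 1.0, 10.0], [10.0, 5.0, 2.5])
        assert model.predict([1.0]) == pytest.approx([model.a_])


class TestThresholdVsDepth:
    def test_thresholds_monotone_and_fits_reported(self):
        study = simulate_study(replicate_config(seed=5))
        res = threshold_vs_depth(
            study.counts, depths=[28000, 7000], cv_levels=(30,), seed=6
        )
        fits = res.fits.sort_values("read_depth")
        # deeper sequencing pushes the quantitation threshold down
        assert fits["threshold_percent"].is_monotonic_decreasing
        assert res.gamma[30.0] is not None and res.gamma[30.0] > 0

    def test_single_depth_leaves_gamma_undefined(self):
        study = simulate_study(replicate_config(seed=5))
        res = threshold_vs_depth(study.counts, depths=[28000], cv_levels=(30,), seed=6)
        assert res.gamma[30.0] is None
        assert len(res.fits) == 1


class TestClosedForms:
    @pytest.mark.parametrize(
        "cv, n, expected",
        [
            (30, 28000, 100 / (0.09 * 28000)),
            (100, 10000, 0.01),
        ],
    )
    def test_poisson_threshold(self, cv, n, expected):
        assert poisson_threshold(cv, n) == pytest.approx(expected)

    def test_poisson_threshold_scales_inversely_with_depth(self):
        assert poisson_threshold(30, 4 * 28000) == pytest.approx(
            poisson_threshold(30, 28000) / 4
        )

    @pytest.mark.parametrize(
        "p, n, rounded, expected",
        [
            (1e-4, 28000, False, 2.8),
            (1e-4, 28000, True, 3.0),
            (1e-4, 1.4e4, True, 1.0),
            (0.0, 28000, False, 0.0),
        ],
    )
    def test_expected_copies(self, p, n, rounded, expected):
        assert expected_copies(p, n, rounded=rounded) == pytest.approx(expected)


class TestLLOQ:
    def test_stool_limit_two_sig_figs(self):
        res = lloq_per_gram(8.3e4, 0.2, sig_figs=2)
        assert res.lloq == pytest.approx(4.2e5)

    def test_mucosa_limit_one_sig_fig(self):
        res = lloq_per_gram(8.3e4, 0.008, sig_figs=1)
        assert res.lloq == pytest.approx(1e7)

    def test_unit_mass_identity(self):
        assert lloq_per_gram(12345.0, 1.0).lloq == 12345.0

    @pytest.mark.parametrize(
        "value, sig, expected",
        [
            (415000.0, 2, 420000.0),  # half-up at the boundary
            (414999.99999999994, 2, 420000.0),  # float residue must not flip it
            (0.04567, 2, 0.046),
            (0.0, 3, 0.0),
        ],
    )
    def test_round_sig_half_up(self, value, sig, expected):
        assert round_sig(value, sig) == expected
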