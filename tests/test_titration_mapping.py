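import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiscan import synthetic_data as sd
from ppiscan.titration_mapping import (
    call_binding_sites,
    classify_csp,
    compare_preference,
    csp,
    intensity_ratios,
    significance_mask,
)

finite_ppm = st.floats(min_value=-50, max_value=200, allow_nan=False)


def ratio_frame(values, missing=None):
    """Build a per-residue ratio table: residue i+1 gets values[i]."""
    missing = missing or set()
    return pd.DataFrame({
        "residue": np.arange(1, len(values) + 1),
        "aa": ["A"] * len(values),
        "intensity_ratio": [np.nan if i + 1 in missing else v
                            for i, v in enumerate(values)],
        "missing": [i + 1 in missing for i in range(len(values))],
    })


class TestCsp:
    def test_identical_shifts_give_zero(self):
        assert csp(8.2, 120.0, 8.2, 120.0) == 0.0

    def test_combined_two_axis_value(self):
        # sqrt(0.030^2 + (0.10/5)^2)
        assert csp(8.0, 120.0, 8.030, 120.10) == pytest.approx(0.0360555, abs=1e-6)

    def test_nitrogen_only_scaling(self):
        assert csp(8.0, 120.0, 8.0, 120.5) == pytest.approx(0.1, abs=1e-12)

    @given(finite_ppm, finite_ppm, finite_ppm, finite_ppm)
    @settings(max_examples=50, deadline=None)
    def test_symmetric_under_state_exchange(self, a, b, c, d):
        assert csp(a, b, c, d) == pytest.approx(csp(c, d, a, b), rel=1e-12)


class TestClassifyCsp:
    @pytest.mark.parametrize("value,expected", [
        (0.010, "below"), (0.015, "below"),
        (0.020, "moderate"), (0.025, "moderate"),
        (0.030, "strong"),
    ])
    def test_threshold_bins(self, value, expected):
        assert classify_csp(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_csp(-0.01)


class TestIntensityRatios:
    def test_unchanged_intensities_give_unity(self, noiseless_titration):
        spec, series = noiseless_titration
        null = sd.generate_titration(
            sd.TitrationSpec(sequence=spec.sequence, sites=[], noise_sd=0.0, seed=1))
        ratios = intensity_ratios(null, null.ratios[-1])
        scored = ratios.loc[~ratios["missing"], "intensity_ratio"]
        assert (scored == 1.0).all()

    def test_single_halved_residue(self):
        base = pd.DataFrame({
            "residue": [1, 2, 3], "aa": list("AGV"),
            "d1H": [8.1, 8.2, 8.3], "d15N": [110.0, 115.0, 120.0],
            "intensity": [100.0, 100.0, 100.0], "assigned": [True] * 3,
        })
        bound = base.copy()
        bound.loc[1, "intensity"] = 50.0
        from ppiscan.titration_mapping import TitrationSeries

        series = TitrationSeries(reference=base, points={1.0: bound})
        out = intensity_ratios(series, 1.0).set_index("residue")["intensity_ratio"]
        assert out[2] == 0.5 and out[1] == 1.0 and out[3] == 1.0

    def test_matches_generative_closed_form(self, noiseless_titration):
        spec, series = noiseless_titration
        point = spec.ratios[-1]
        ratios = intensity_ratios(series, point).set_index("residue")
        fb = sd.bound_fraction(point, spec.kd, spec.substrate_conc)
        for res in range(1, len(spec.sequence) + 1):
            if spec.sequence[res - 1] == "P":
                assert ratios.at[res, "missing"]
                continue
            depth = next((d for s, e, d in spec.sites if s <= res <= e), 0.0)
            expected = spec.r2_free / (spec.r2_free + fb * depth * spec.delta_r2_max)
            assert ratios.at[res, "intensity_ratio"] == pytest.approx(expected, abs=1e-12)

    def test_proline_flagged_missing(self, noiseless_titration):
        _, series = noiseless_titration
        ratios = intensity_ratios(series, series.ratios[0]).set_index("residue")
        assert ratios.at[13, "missing"]  # control proline

    def test_unknown_point_raises(self, noiseless_titration):
        _, series = noiseless_titration
        with pytest.raises(KeyError):
            intensity_ratios(series, 99.0)


class TestCallBindingSites:
    def test_run_of_four_rejected_run_of_five_accepted(self):
        # "more than four residues" boundary
        four = ratio_frame([1, 1, 0.2, 0.2, 0.2, 0.2, 1, 1, 1, 1])
        five = ratio_frame([1, 1, 0.2, 0.2, 0.2, 0.2, 0.2, 1, 1, 1])
        sig4 = significance_mask(four, method="cutoff", cutoff=0.7)
        sig5 = significance_mask(five, method="cutoff", cutoff=0.7)
        assert call_binding_sites(four, sig4) == []
        sites = call_binding_sites(five, sig5)
        assert len(sites) == 1 and (sites[0].start, sites[0].end) == (3, 7)
        assert sites[0].n_scored == 5

    def test_missing_proline_bridges_a_site(self):
        # significant 251-254 and 256-259, proline 255 invisible
        values = [1.0] * 5 + [0.2] * 4 + [np.nan] + [0.2] * 4 + [1.0] * 5
        df = ratio_frame(values)
        df["residue"] = np.arange(246, 265)
        df["missing"] = df["intensity_ratio"].isna()
        sig = significance_mask(df, method="cutoff", cutoff=0.7)
        bridged = call_binding_sites(df, sig, bridge_missing=True)
        assert len(bridged) == 1
        assert (bridged[0].start, bridged[0].end) == (251, 259)
        assert bridged[0].n_scored == 8
        # strict mode splits into two runs of four, neither eligible
        assert call_binding_sites(df, sig, bridge_missing=False) == []

    def test_noiseless_planted_site_recovered_exactly(self, noiseless_titration):
        spec, series = noiseless_titration
        ratios = intensity_ratios(series, spec.ratios[-1])
        sites = call_binding_sites(ratios)
        assert [(s.start, s.end) for s in sites] == [(25, 33)]

    def test_relaxing_threshold_never_removes_site_residues(self):
        rng = np.random.default_rng(5)
        values = np.clip(rng.normal(1.0, 0.05, 40), 0, None)
        values[10:18] = 0.3
        df = ratio_frame(values.tolist())
        covered = {}
        for cutoff in (0.5, 0.7, 0.9):
            sig = significance_mask(df, method="cutoff", cutoff=cutoff)
            sites = call_binding_sites(df, sig)
            covered[cutoff] = {r for s in sites for r in range(s.start, s.end + 1)}
        assert covered[0.5] <= covered[0.7] <= covered[0.9]


class TestComparePreference:
    def test_identical_profiles_zero_difference(self):
        df = ratio_frame([0.3] * 8 + [1.0] * 4)
        sig = significance_mask(df, method="cutoff", cutoff=0.7)
        sites = call_binding_sites(df, sig)
        report = compare_preference(df, df, sites)
        assert np.allclose(report["difference"], 0.0)
        assert (report["preferred_by"] == "tie").all()

    def test_deeper_broadening_wins(self):
        a = ratio_frame([0.7] * 6 + [1.0] * 6)  # reduction 0.3 in site
        b = ratio_frame([0.2] * 6 + [1.0] * 6)  # reduction 0.8 in site
        sig = significance_mask(b, method="cutoff", cutoff=0.9)
        sites = call_binding_sites(b, sig)
        report = compare_preference(a, b, sites, label_A="PPD", label_B="SBD")
        assert report.loc[0, "preferred_by"] == "SBD"
        assert report.loc[0, "reduction_SBD"] == pytest.approx(0.8)

    def test_planted_depth_ordering_recovered(self, demo_sequence):
        spec = sd.TitrationSpec(
            sequence=demo_sequence, sites=[(5, 12, 0.4), (25, 33, 0.9)],
            noise_sd=0.0, seed=2,
        )
        series = sd.generate_titration(spec)
        ratios = intensity_ratios(series, spec.ratios[-1])
        sig = significance_mask(ratios, method="cutoff", cutoff=0.95)
        sites = call_binding_sites(ratios, sig)
        assert len(sites) == 2
        report = compare_preference(ratios, ratios, sites)
        by_depth = report.sort_values("reduction_A", ascending=False)
        assert (int(by_depth.iloc[0]["start"]), int(by_depth.iloc[0]["end"])) == (25, 33)

    def test_disjoint_residue_sets_rejected(self):
        a = ratio_frame([1.0] * 5)
        b = ratio_frame([1.0] * 5)
        b["residue"] += 100
        with pytest.raises(ValueError):
            compare_preference(a, b, [])
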