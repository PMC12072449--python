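"""Survival ratios, curve assembly, sigmoid fits, and ranking."""

import copy

import numpy as np
import pytest

import adductscreen as asc
from adductscreen.energetics import EnergyPoint
from adductscreen.stability import NUCLEOSIDES, UndefinedRatioError


def _curve(name, e_com, ratios, nucleoside="dG"):
    return asc.StabilityCurve(
        compound=name,
        nucleoside=nucleoside,
        points=[
            EnergyPoint(e_lab=10 + 5 * i, delta=1.0, e_com=e, ratio=r)
            for i, (e, r) in enumerate(zip(e_com, ratios))
        ],
    )


class TestSurvivalRatio:
    @pytest.mark.parametrize(
        "adduct, free, expected", [(0, 100, 0.0), (50, 100, 0.5), (120, 60, 2.0)]
    )
    def test_ratio(self, adduct, free, expected):
        assert asc.survival_ratio(adduct, free) == expected

    def test_zero_free_ion_is_explicit_error(self):
        with pytest.raises(UndefinedRatioError):
            asc.survival_ratio(10, 0)

    def test_negative_adduct_rejected(self):
        with pytest.raises(ValueError):
            asc.survival_ratio(-1, 100)


class TestBuildCurve:
    def test_five_voltages_five_points(self, panel, noise_free_sim, default_settings):
        runs, _, cfg = noise_free_sim
        curve = asc.build_curve(
            runs, panel[0].as_compound(), "dG", default_settings
        )
        assert len(curve.points) == len(cfg.cone_voltages)
        assert not curve.flagged

    def test_reproduces_generating_sigmoid(self, panel, noise_free_sim, default_settings):
        """Noise-free analyzer output equals the generator's closed form."""
        runs, gt, cfg = noise_free_sim
        for sc in panel:
            curve = asc.build_curve(runs, sc.as_compound(), "dG", default_settings)
            for point, voltage in zip(curve.points, cfg.cone_voltages):
                expected = asc.expected_ratio(gt, sc.name, voltage)
                assert point.ratio == pytest.approx(expected, rel=1e-6)

    def test_missing_voltage_listed(self, panel, noise_free_sim, default_settings):
        runs, _, _ = noise_free_sim
        partial = {v: r for v, r in runs.items() if v != 20.0}
        with pytest.raises(ValueError, match="20"):
            asc.build_curve(partial, panel[0].as_compound(), "dG", default_settings)

    def test_absent_compound_rejected(self, noise_free_sim, default_settings):
        runs, _, _ = noise_free_sim
        ghost = asc.Compound(
            name="ghost", formula=asc.parse_formula("C6H6O2"),
            rt_min=5.0, rt_max=5.5,
        )
        with pytest.raises(ValueError, match="undefined"):
            asc.build_curve(runs, ghost, "dG", default_settings)

    def test_undefined_point_dropped_and_flagged(
        self, panel, noise_free_sim, default_settings
    ):
        runs, _, _ = noise_free_sim
        compound = panel[0].as_compound()
        free_mz = asc.make_adduct(panel[0].formula, "proton_add").mz_mono
        broken = dict(runs)
        doctored = copy.deepcopy(runs[20.0])
        for pl in doctored.peak_lists:
            hit = np.abs(pl.mz - free_mz) <= 0.5
            pl.intensity[hit] = 0.0
        broken[20.0] = doctored
        curve = asc.build_curve(broken, compound, "dG", default_settings)
        assert curve.flagged
        assert curve.dropped_voltages == [20.0]
        assert len(curve.points) == 4

    def test_unknown_nucleoside(self, panel, noise_free_sim, default_settings):
        runs, _, _ = noise_free_sim
        with pytest.raises(ValueError, match="nucleoside"):
            asc.build_curve(runs, panel[0].as_compound(), "dU", default_settings)


class TestFitSigmoid:
    def test_exact_samples_recovered(self):
        e = np.linspace(0.1, 1.0, 8)
        r0, e50, slope = 1.0, 0.5, 10.0
        curve = _curve("x", e, r0 / (1 + np.exp(slope * (e - e50))))
        fit = asc.fit_sigmoid(curve)
        assert fit.converged
        assert fit.r0 == pytest.approx(r0, rel=1e-6)
        assert fit.e50 == pytest.approx(e50, rel=1e-6)
        assert fit.slope == pytest.approx(slope, rel=1e-6)

    def test_flat_curve_flagged_degenerate(self):
        curve = _curve("flat", [0.1, 0.2, 0.3, 0.4], [0.5, 0.5, 0.5, 0.5])
        fit = asc.fit_sigmoid(curve)
        assert not fit.converged
        assert "degenerate" in fit.message

    def test_needs_four_points(self):
        curve = _curve("short", [0.1, 0.2, 0.3], [0.9, 0.5, 0.1])
        with pytest.raises(ValueError, match="4"):
            asc.fit_sigmoid(curve)

    def test_decreasing_survival_gives_positive_slope(
        self, panel, noise_free_sim, default_settings
    ):
        runs, _, _ = noise_free_sim
        for sc in panel:
            fit = asc.fit_sigmoid(
                asc.build_curve(runs, sc.as_compound(), "dG", default_settings)
            )
            assert fit.converged and fit.slope > 0

    def test_noisy_e50_recovery_single_seed(self, panel):
        """5% multiplicative noise, 5 voltages: e50 still lands within 10%."""
        cfg = asc.SimConfig(seed=99, noise_cv=0.05)
        runs, gt = asc.simulate_run_set(panel, cfg)
        settings = asc.CollisionSettings(reference_dof=gt["reference_dof"])
        sc = panel[2]  # mid-range e50, strong signal
        fit = asc.fit_sigmoid(
            asc.build_curve(runs, sc.as_compound(), "dG", settings)
        )
        true = gt["compounds"][sc.name]["e50_true"]
        assert abs(fit.e50 - true) / true < 0.10


class TestRankCompounds:
    def test_ground_truth_order_noise_free(
        self, panel, noise_free_sim, default_settings
    ):
        runs, _, _ = noise_free_sim
        curves = [
            asc.build_curve(runs, sc.as_compound(), "dG", default_settings)
            for sc in panel
        ]
        extract = {
            "3-O-methylquercetin-7-O-glucoside",
            "4'-hydroxydehydrokawain-4'-O-glucoside",
            "3,5-di-O-caffeoylquinic acid",
        }
        for mode in ("pointwise", "e50"):
            names = [n for n, _ in asc.rank_compounds(curves, mode)]
            assert set(names[:3]) == extract
            assert names[3] == "rutin"
            assert names[4] == "isoquercitrin"

    def test_single_curve(self):
        # ratios linear in e_com, so the common-grid mean is exactly 0.5
        c = _curve("only", [0.1, 0.3, 0.5], [0.9, 0.5, 0.1])
        assert asc.rank_compounds([c]) == [("only", pytest.approx(0.5, abs=1e-9))]

    def test_tie_broken_lexicographically(self):
        e = [0.1, 0.3, 0.5]
        r = [0.9, 0.5, 0.1]
        ranked = asc.rank_compounds([_curve("beta", e, r), _curve("alpha", e, r)])
        assert [n for n, _ in ranked] == ["alpha", "beta"]

    def test_mixed_nucleosides_rejected(self):
        a = _curve("a", [0.1, 0.3], [0.9, 0.1], nucleoside="dG")
        b = _curve("b", [0.1, 0.3], [0.9, 0.1], nucleoside="G")
        with pytest.raises(ValueError, match="nucleoside"):
            asc.rank_compounds([a, b])

    def test_no_overlap_rejected(self):
        a = _curve("a", [0.1, 0.2], [0.9, 0.8])
        b = _curve("b", [0.5, 0.6], [0.4, 0.3])
        with pytest.raises(ValueError, match="overlap"):
            asc.rank_compounds([a, b], mode="pointwise")

    def test_unknown_mode(self):
        c = _curve("x", [0.1, 0.3], [0.9, 0.1])
        with pytest.raises(ValueError, match="mode"):
            asc.rank_compounds([c], mode="median")

    def test_curve_table_columns(self):
        c = _curve("x", [0.1, 0.3], [0.9, 0.1])
        table = asc.curve_table([c])
        assert list(table.columns) == [
            "compound", "nucleoside", "e_lab_V", "delta", "e_com_eV", "ratio"
        ]
        assert len(table) == 2

    def test_nucleoside_registry(self):
        assert set(NUCLEOSIDES) == {"dG", "G"}
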