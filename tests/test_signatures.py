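import numpy as np
import pytest

from ribodyn.core_models import DomainError, LinearParams, integrate
from ribodyn.linear_translation import linear_setting_params
from ribodyn import signatures as sg


def linear_steady_state(p: LinearParams) -> np.ndarray:
    c = np.array([1 / p.k1, 1 / p.k2, 1 / p.k3])
    return c * (p.total_40S / c.sum())


class TestRelaxationTime:
    def test_trajectory_already_at_steady_state(self, default_params):
        ss = sg.steady_state_exact(default_params)
        traj = integrate(default_params, init=ss.state_array(), t_end=10.0)
        assert sg.relaxation_time(traj, ss) == 0.0

    def test_band_nesting(self, default_params):
        ss = sg.steady_state_exact(default_params)
        traj = integrate(default_params, t_end=200.0, n_points=800)
        assert sg.relaxation_time(traj, ss, band=0.05) >= sg.relaxation_time(
            traj, ss, band=0.10
        )

    def test_not_converged_names_offender(self, default_params):
        ss = sg.steady_state_exact(default_params)
        traj = integrate(default_params, t_end=0.01)
        with pytest.raises(sg.NotConvergedError, match="c80S|cAUG|c40S"):
            sg.relaxation_time(traj, ss)

    def test_acap_k2_inhibition_drastically_slows_linear_relaxation(self):
        """A 100-fold k2 suppression on the A-cap linear model lengthens
        the measured relaxation at least tenfold (numeric oracle)."""
        base = linear_setting_params("acap")
        inhibited = base.replace(k2=base.k2 / 100.0)
        times = []
        for p in (base, inhibited):
            traj = integrate(p, t_end=50.0 / min(p.k1, p.k2), n_points=900)
            times.append(sg.relaxation_time(traj, linear_steady_state(p)))
        assert times[1] >= 10.0 * times[0]


class TestInhibitionScan:
    def test_unit_factor_is_exact_baseline(self, nonlinear_scans):
        scan = nonlinear_scans[("wt_inefficient", "k2")]
        base = sg.steady_state_exact(sg.NONLINEAR_SETTINGS["wt_inefficient"])
        assert scan.factors[0] == 1.0
        assert scan.steady_rates[0] == base.prsynth

    def test_elongation_scan_flat_in_rate_and_time(self, nonlinear_scans):
        scan = nonlinear_scans[("wt_inefficient", "k3")]
        m = scan.factors >= 0.05
        assert np.ptp(scan.steady_rates[m]) / scan.steady_rates[0] < 0.01
        z = scan.relaxation_times[m] / scan.relaxation_times[0]
        assert z.max() < 1.25

    def test_recycling_inhibition_flat_then_proportional(self, nonlinear_scans):
        """Inefficient baseline: the rate holds until the regime flips near
        the critical k4, then falls proportionally; the relaxation time
        rises and then comes back down."""
        scan = nonlinear_scans[("wt_inefficient", "k4")]
        y = scan.steady_rates / scan.steady_rates[0]
        before = scan.factors >= 0.6
        assert np.abs(y[before] - 1.0).max() < 0.05
        deep = scan.factors <= 0.05
        ratio = y[deep] / scan.factors[deep]
        assert np.ptp(ratio) / ratio.mean() < 0.15  # proportional decline
        z = scan.relaxation_times / scan.relaxation_times[0]
        peak = np.argmax(z)
        assert 0 < peak < len(z) - 1 and z[peak] > 2.0 * z[0]
        assert z[-1] < 0.5 * z[peak]

    def test_efficient_recycling_inhibition_proportional_rate_flat_time(
        self, nonlinear_scans
    ):
        scan = nonlinear_scans[("wt_efficient", "k4")]
        y = scan.steady_rates / scan.steady_rates[0]
        assert np.allclose(y, scan.factors, rtol=0.05)
        z = scan.relaxation_times / scan.relaxation_times[0]
        assert z.max() < 1.25 and z.min() > 0.8

    def test_invalid_inputs(self, default_params):
        with pytest.raises(DomainError):
            sg.inhibition_scan(default_params, "k9")
        with pytest.raises(DomainError):
            sg.inhibition_scan(default_params, "k1", factors=np.array([2.0]))


class TestClassifier:
    def test_flat_curve_is_no_change(self):
        scan = sg.ScanResult(
            "k3", "synthetic", np.geomspace(1, 1e-3, 20),
            np.full(20, 5.0), np.full(20, 1.0),
        )
        lab = sg.classify_signature(scan)
        assert lab == sg.SignatureLabel("no_change", "no_change")

    def test_rise_and_fall_relaxation_detected(self, nonlinear_scans):
        lab = sg.classify_signature(nonlinear_scans[("wt_efficient", "k2")])
        assert lab.time_label == "goes_up_and_down"

    def test_threshold_type_rate_detected(self, nonlinear_scans):
        lab = sg.classify_signature(nonlinear_scans[("acap_efficient", "k1")])
        assert lab.rate_label == "decreases_after_threshold"

    def test_vocabulary_is_closed(self):
        with pytest.raises(sg.VocabularyError):
            sg.SignatureLabel("vanishes", "no_change")

    def test_short_scan_warns(self):
        scan = sg.ScanResult(
            "k1", "synthetic", np.geomspace(1, 0.1, 8),
            np.linspace(5, 1, 8), np.full(8, 1.0),
        )
        with pytest.warns(UserWarning, match="decades"):
            sg.classify_signature(scan)


class TestTables:
    def test_nonlinear_table_reproduced(self, nonlinear_scans):
        """Every (setting, mechanism) cell of the non-linear signature table
        matches the reference qualitative predictions."""
        for setting in sg.NONLINEAR_SETTINGS:
            saliency = max(
                sg.time_window_fold(nonlinear_scans[(setting, m)])
                for m in ("k1", "k2", "k3", "k4")
            )
            for mech in ("k1", "k2", "k3", "k4"):
                lab = sg.classify_signature(
                    nonlinear_scans[(setting, mech)], time_saliency=saliency
                )
                ref = sg.REFERENCE_NONLINEAR_TABLE[(setting, mech)]
                assert (lab.rate_label, lab.time_label) == (
                    ref.rate_label, ref.time_label
                ), f"{setting}/{mech}"

    def test_linear_table_reproduced(self):
        table = sg.linear_signature_table()
        for key, ref in sg.REFERENCE_LINEAR_TABLE.items():
            lab = table[key]
            assert (lab.rate_label, lab.time_label) == (
                ref.rate_label, ref.time_label
            ), key

    def test_rate_breakpoints_match_critical_thresholds(self, nonlinear_scans):
        """The scan knee sits at the regime-flip threshold within 20%."""
        from ribodyn.nonlinear_steady import critical_thresholds
        from ribodyn.signatures import _first_departure, Thresholds

        th = Thresholds()
        cases = [
            ("wt_inefficient", "k4", "k4_threshold"),
            ("wt_efficient", "k2", "k2_threshold"),
        ]
        for setting, mech, key in cases:
            p = sg.NONLINEAR_SETTINGS[setting]
            scan = nonlinear_scans[(setting, mech)]
            y = scan.steady_rates / scan.steady_rates[0]
            knee = _first_departure(scan.factors, y, 1.0 / th.rate_no_change)
            expected = critical_thresholds(p)[key] / getattr(p, mech)
            assert knee == pytest.approx(expected, rel=0.20)


class TestLookup:
    def test_acap_linear_silent_rate_loud_time_points_to_k2(self):
        observed = {"acap": ("no_change", "increases_drastically")}
        assert sg.mechanism_lookup(observed, model="linear") == {"k2"}

    def test_all_silent_indistinguishable_from_no_effect(self):
        observed = {
            s: ("no_change", "no_change") for s in sg.NONLINEAR_SETTINGS
        }
        assert sg.mechanism_lookup(observed) == {"k3", "no_effect"}

    def test_contradictory_observations_give_empty_set(self):
        observed = {
            "wt_inefficient": ("decreases", "goes_up_and_down"),
            "wt_efficient": ("decreases_after_threshold", "no_change"),
        }
        assert sg.mechanism_lookup(observed) == set()

    def test_unknown_labels_rejected(self):
        with pytest.raises(sg.VocabularyError):
            sg.mechanism_lookup({"wt_inefficient": ("explodes", None)})
        with pytest.raises(sg.VocabularyError):
            sg.mechanism_lookup({"somewhere": ("no_change", None)})
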