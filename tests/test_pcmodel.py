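"""Model predictions, signal strengths, contrast profiles and adaptation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hierpc.contrasts import ContrastDefinition, enumerate_contrasts
from hierpc.paradigm import build_design, transition_probabilities
from hierpc.pcmodel import (
    MODEL_1LEVEL_SP,
    MODEL_1LEVEL_TP,
    MODEL_NO_ENDING,
    ModelSpec,
    ScalingFactors,
    across_contrast_profile,
    adaptation_response,
    adaptation_trial_responses,
    alt_model_profile,
    mspe1,
    mspe2,
    optimal_predictions,
    signal_strengths,
    single_trial_amplitudes,
    within_contrast_profile,
)

S1 = ScalingFactors()


def factors_strategy():
    return st.builds(
        ScalingFactors,
        s0=st.floats(0.0, 1.0),
        s1=st.floats(0.0, 2.0),
        s2=st.floats(0.0, 2.0),
    )


def counts_strategy():
    return (
        st.tuples(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
        .filter(lambda c: sum(c) > 0)
        .map(lambda c: {"xx": 4 * c[0], "xy": 4 * c[1], "xo": 4 * c[2]})
    )


class TestOptimalPredictions:
    def test_block1_closed_form(self, block1):
        pred = optimal_predictions(transition_probabilities(block1), S1, 2)
        assert pred.p1_x == pytest.approx(0.4)
        assert pred.p1_y == pytest.approx(0.1)
        assert pred.p2_x == pytest.approx((2 / 3) * 0.6 + (1 / 3) * 0.4)  # 0.5333
        assert pred.p2_y == pytest.approx((1 / 6) * 0.9 + (5 / 6) * 0.1)  # 0.2333

    def test_s1_zero_removes_first_level_prediction(self, block1):
        pred = optimal_predictions(transition_probabilities(block1), ScalingFactors(s1=0.0), 2)
        assert pred.p2_x == pytest.approx((2 / 3) * 1.0)  # SP_xx * s0^(n-1)
        assert pred.p2_y == pytest.approx(1 / 6)

    def test_closed_form_matches_bruteforce_minimizer(self, rng):
        # independent oracle: dense scan of the two mean-squared-error
        # objectives (20 random draws here; the acceptance suite runs 100)
        p1_grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        p2_grid = np.arange(0.0, 2.0 + 1e-9, 1e-4)
        for _ in range(20):
            n = int(rng.integers(2, 4))
            sp = rng.dirichlet([1.0, 1.0, 1.0])
            d = build_design("h", n, {"xx": int(400 * sp[0]) * 4, "xy": int(400 * sp[1]) * 4, "xo": 4 + int(400 * sp[2]) * 4})
            probs = transition_probabilities(d)
            f = ScalingFactors(s0=float(rng.uniform(0, 1)), s1=float(rng.uniform(0, 2)))
            pred = optimal_predictions(probs, f, n)
            in_x = f.s0 ** (n - 1)
            best_p1x = p1_grid[np.argmin(mspe1(p1_grid, probs.tp_x, in_x))]
            best_p1y = p1_grid[np.argmin(mspe1(p1_grid, probs.tp_y, 1.0))]
            assert pred.p1_x == pytest.approx(best_p1x, abs=2e-4)
            assert pred.p1_y == pytest.approx(best_p1y, abs=2e-4)
            best_p2x = p2_grid[np.argmin(mspe2(p2_grid, probs.sp_xx, in_x, pred.p1_x * f.s1))]
            best_p2y = p2_grid[np.argmin(mspe2(p2_grid, probs.sp_xy, 1.0, pred.p1_y * f.s1))]
            assert pred.p2_x == pytest.approx(best_p2x, abs=2e-4)
            assert pred.p2_y == pytest.approx(best_p2y, abs=2e-4)


class TestSignalStrengths:
    def test_block1_hand_values(self, block1):
        t = signal_strengths(block1, S1)
        assert t.pe1("xy") == pytest.approx(1.3)
        assert t.pe1("xx") == pytest.approx(0.7)
        assert t.pe2("xy") == pytest.approx(0.8)
        assert t.pe2("xx") == pytest.approx(0.2)

    def test_positive_only_omission_excludes_negative_errors(self, block1):
        # during xo both stream inputs are 0, so the level-1 signed errors
        # are negative and a positive-only computation yields 0
        t = signal_strengths(block1, S1, error_mode="positive_only")
        assert t.pe1("xo") == 0.0

    def test_unknown_error_mode_rejected(self, block1):
        with pytest.raises(ValueError):
            signal_strengths(block1, S1, error_mode="bogus")

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(counts=counts_strategy(), n=st.sampled_from([2, 3]), f=factors_strategy())
    def test_error_mode_decomposition(self, counts, n, f):
        d = build_design("h", n, counts)
        both = signal_strengths(d, f, "both")
        pos = signal_strengths(d, f, "positive_only")
        neg = signal_strengths(d, f, "negative_only")
        for t in ("xx", "xy", "xo"):
            assert both.pe1(t) == pytest.approx(pos.pe1(t) + neg.pe1(t), abs=1e-12)
            assert both.pe2(t) == pytest.approx(pos.pe2(t) + neg.pe2(t), abs=1e-12)
            assert both.pe1(t) >= 0 and both.pe2(t) >= 0


class TestContrastProfiles:
    def test_block1_within_contrast_values(self, designs8):
        prof = within_contrast_profile(designs8, S1)
        assert prof.row_names == ("PE1", "PE2")
        j = [c.label for c in prof.contrasts].index("B1:xy-xx")
        assert prof.values[0, j] == pytest.approx(0.6)
        assert prof.values[1, j] == pytest.approx(0.6)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(counts=counts_strategy(), n=st.sampled_from([2, 3]), f=factors_strategy())
    def test_prediction_signals_cancel_within_block(self, counts, n, f):
        # predictions precede the last tone and are common to all trial
        # types, so any within-block contrast of P1/P2 is exactly zero
        d = build_design("h", n, counts)
        t = signal_strengths(d, f)
        for a, b in (("xy", "xx"), ("xo", "xx"), ("xy", "xo")):
            assert t.p1 - t.p1 == 0.0 and t.p2 - t.p2 == 0.0

    def test_within_contrast_linearity(self, block1):
        # xy - xo equals (xy - xx) - (xo - xx) for any parameters
        f = ScalingFactors(s0=0.4, s1=1.4, s2=0.6)
        t = signal_strengths(block1, f)
        for pe in (t.pe1, t.pe2):
            assert pe("xy") - pe("xo") == pytest.approx(
                (pe("xy") - pe("xx")) - (pe("xo") - pe("xx")), abs=1e-12
            )

    def test_identical_blocks_give_zero_across_column(self):
        designs = [
            build_design("Ba", 2, {"xx": 96, "xy": 24, "xo": 24}),
            build_design("Bb", 2, {"xx": 96, "xy": 24, "xo": 24}),
            build_design("Bc", 2, {"xx": 24, "xy": 96, "xo": 24}),
            build_design("Bd", 2, {"xx": 36, "xy": 72, "xo": 36}),
            build_design("Be", 3, {"xx": 96, "xy": 24, "xo": 24}),
            build_design("Bf", 3, {"xx": 72, "xy": 36, "xo": 36}),
            build_design("Bg", 3, {"xx": 24, "xy": 96, "xo": 24}),
            build_design("Bh", 3, {"xx": 36, "xy": 72, "xo": 36}),
        ]
        prof = across_contrast_profile(designs, ScalingFactors(s0=0.5, s1=1.2, s2=0.8), a=0.3)
        for j, c in enumerate(prof.contrasts):
            if {c.minuend[0], c.subtrahend[0]} == {"Ba", "Bb"}:
                assert np.allclose(prof.values[:, j], 0.0)

    def test_mixing_weight_endpoints(self, designs8):
        f = ScalingFactors(s0=0.3)
        within = within_contrast_profile(designs8, f)
        at1 = across_contrast_profile(designs8, f, a=1.0)
        at0 = across_contrast_profile(designs8, f, a=0.0)
        # reconstruct the across PE rows from signal tables directly
        tables = {d.block_id: (d, f) for d in designs8}
        from hierpc.pcmodel import signal_strengths as ss

        for j, c in enumerate(at1.contrasts):
            ta = ss(*tables[c.minuend[0]])
            tb = ss(*tables[c.subtrahend[0]])
            t = c.minuend[1]
            assert at1.values[2, j] == pytest.approx(ta.pe1(t) - tb.pe1(t), abs=1e-12)
            assert at0.values[2, j] == pytest.approx(ta.pe2(t) - tb.pe2(t), abs=1e-12)

    def test_across_prediction_rows_recompute(self, designs8):
        f = ScalingFactors(s0=0.7, s1=1.4, s2=0.6)
        prof = across_contrast_profile(designs8, f, a=0.5)
        dmap = {d.block_id: d for d in designs8}
        for j, c in enumerate(prof.contrasts):
            pa = optimal_predictions(transition_probabilities(dmap[c.minuend[0]]), f, dmap[c.minuend[0]].n_tones)
            pb = optimal_predictions(transition_probabilities(dmap[c.subtrahend[0]]), f, dmap[c.subtrahend[0]].n_tones)
            assert prof.values[0, j] == pytest.approx(f.s1 * ((pa.p1_x + pa.p1_y) - (pb.p1_x + pb.p1_y)), abs=1e-12)
            assert prof.values[1, j] == pytest.approx(f.s2 * ((pa.p2_x + pa.p2_y) - (pb.p2_x + pb.p2_y)), abs=1e-12)


class TestAlternativeModels:
    def test_single_level_tp_matches_two_level_first_level(self, designs8, block1):
        spec = ModelSpec(MODEL_1LEVEL_TP, S1)
        prof = alt_model_profile(spec, designs8, "within")
        assert prof.row_names == ("PE1",)
        t = signal_strengths(block1, S1, model_id=MODEL_1LEVEL_TP)
        assert t.pe1("xx") == pytest.approx(0.7)
        assert t.predictions.p1_x == pytest.approx(0.4)

    def test_single_level_sp_uses_sequence_probabilities(self, block1):
        t = signal_strengths(block1, S1, model_id=MODEL_1LEVEL_SP)
        assert t.predictions.p1_x == pytest.approx(2 / 3)
        assert t.predictions.p1_y == pytest.approx(1 / 6)

    def test_no_ending_feeds_modified_transition_probability(self, block1):
        t = signal_strengths(block1, S1, model_id=MODEL_NO_ENDING)
        assert t.predictions.p1_x == pytest.approx(2 / 3)

    def test_alt_profile_rejects_proposed_model(self, designs8):
        from hierpc.pcmodel import MODEL_2LEVEL

        with pytest.raises(ValueError):
            alt_model_profile(ModelSpec(MODEL_2LEVEL, S1), designs8, "within")


class TestAdaptation:
    def test_no_adaptation_when_s0_is_one(self):
        amps = adaptation_response(np.arange(10) * 0.2, s0=1.0, tau0=0.5)
        assert np.allclose(amps, 1.0)

    def test_recovery_limits(self):
        amps = adaptation_response([0.0, 1e-9 + 0.0 + 1e-6, 1e6], s0=0.25, tau0=1.0)
        assert amps[1] == pytest.approx(0.25, abs=1e-5)  # immediately after
        assert amps[2] == pytest.approx(1.0)  # full recovery

    def test_nonmonotone_onsets_rejected(self):
        with pytest.raises(ValueError):
            adaptation_response([0.0, 0.5, 0.4], s0=0.5, tau0=1.0)

    def test_shorter_isi_lowers_mean_response(self, block1):
        slow = adaptation_trial_responses(block1, 0.3, 1.0, seed=0)[0]
        import hierpc.pcmodel as m

        # rebuild with compressed ISIs by shrinking tone spacing
        fast = adaptation_trial_responses(block1, 0.3, 1.0, seed=0, tone_soa=0.05)[0]
        mask = slow > 0
        assert fast[mask].mean() < slow[mask].mean()

    def test_omission_trials_evoke_no_response(self, block1):
        per_trial, per_type = adaptation_trial_responses(block1, 0.5, 1.0, seed=0)
        assert per_type["xo"] == 0.0
        assert 0 < per_type["xx"] <= 1.0


class TestSingleTrialCoupling:
    def test_dominant_sequence_correlation_signs(self):
        # the model's interaction structure: P2 drives PE2 positively and
        # PE1 drives PE2 negatively in xx-dominant blocks; both flip when
        # xy dominates (positive/negative errors switch roles)
        f = ScalingFactors(s0=0.3, s1=0.8, s2=1.0)
        vals = {"xx": [], "xy": []}
        for rep in range(6):
            for dom, counts in (("xx", {"xx": 96, "xy": 24, "xo": 24}), ("xy", {"xx": 24, "xy": 96, "xo": 24})):
                d = build_design("b", 3, counts)
                amp = single_trial_amplitudes(d, f, gain_sd=0.3, seed=rep)
                amp = amp[amp.trial_type == dom]
                vals[dom].append(
                    (np.corrcoef(amp.P2, amp.PE2)[0, 1], np.corrcoef(amp.PE1, amp.PE2)[0, 1])
                )
        xx = np.median(vals["xx"], axis=0)
        xy = np.median(vals["xy"], axis=0)
        assert xx[0] > 0 and xx[1] < 0
        assert xy[0] < 0 and xy[1] > 0
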