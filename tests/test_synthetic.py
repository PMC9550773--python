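"""Ground-truth generators: rank structure, determinism, epoch-level checks."""

import numpy as np
import pandas as pd
import pytest

from hierpc.contrasts import assemble_tensor, enumerate_contrasts
from hierpc.decomp import congruence, corcondia, parafac
from hierpc.paradigm import build_design
from hierpc.pcmodel import ScalingFactors
from hierpc.spectral import analysis_window, ersp, morlet_tfr
from hierpc.synthetic import (
    SynthConfig,
    make_ground_truth,
    model_contrast_tensor,
    random_rank_tensor,
    simulate_adaptation_only,
    simulate_contrast_maps,
    simulate_epochs,
    simulate_ersp_dataset,
    simulate_single_trial_ersps,
)


@pytest.fixture(scope="module")
def gt_small():
    return make_ground_truth(
        n_channels=10, freqs=np.arange(4.0, 101.0, 4.0), times=-0.25 + np.arange(25) * 0.03, seed=0
    )


class TestGroundTruth:
    def test_structures_are_identifiable(self, gt_small):
        labels = list(gt_small.structures)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                vi = np.outer(
                    gt_small.structures[labels[i]].spatial,
                    gt_small.structures[labels[i]].spectro_temporal.ravel(),
                )
                vj = np.outer(
                    gt_small.structures[labels[j]].spatial,
                    gt_small.structures[labels[j]].spectro_temporal.ravel(),
                )
                assert congruence(vi.ravel(), vj.ravel()) < 0.95

    def test_prediction_error_latencies_and_bands(self, gt_small):
        pe1 = gt_small.structures["PE1"].spectro_temporal
        f, t = np.unravel_index(np.argmax(pe1), pe1.shape)
        assert gt_small.freqs[f] > 30  # gamma band
        assert abs(gt_small.times[t] - 0.156) < 0.03


class TestErspDataset:
    def test_noise_free_within_tensor_is_rank_two(self, designs8):
        gt = make_ground_truth(
            n_channels=10, freqs=np.arange(4.0, 101.0, 4.0), times=-0.25 + np.arange(25) * 0.03,
            noise_sd=0.0, subject_sd=0.0, seed=1,
        )
        ds = simulate_ersp_dataset(SynthConfig(designs=designs8, n_subjects=2, seed=2), gt)
        defs = enumerate_contrasts(designs8, "within")
        maps = [ds[(0, c.minuend[0], c.minuend[1])] - ds[(0, c.subtrahend[0], c.subtrahend[1])] for c in defs]
        x = assemble_tensor(maps, defs).values
        fm2 = parafac(x, k=2, seed=0)
        assert corcondia(x, fm2) == pytest.approx(100.0, abs=0.5)
        assert fm2.rss < 1e-5 * np.sum(x**2)

    def test_identical_blocks_contrast_to_zero(self):
        designs = [
            build_design("Ba", 2, {"xx": 96, "xy": 24, "xo": 24}),
            build_design("Bb", 2, {"xx": 96, "xy": 24, "xo": 24}),
        ]
        gt = make_ground_truth(
            n_channels=6, freqs=np.arange(10.0, 81.0, 10.0), times=-0.25 + np.arange(10) * 0.05,
            noise_sd=0.0, subject_sd=0.0, seed=3,
        )
        ds = simulate_ersp_dataset(SynthConfig(designs=designs, n_subjects=1, seed=4), gt)
        for t in ("xx", "xy", "xo"):
            assert np.allclose(ds[(0, "Ba", t)], ds[(0, "Bb", t)])

    def test_seed_determinism(self, designs8, gt_small):
        a = simulate_ersp_dataset(SynthConfig(designs=designs8[:2], n_subjects=2, seed=5), gt_small)
        b = simulate_ersp_dataset(SynthConfig(designs=designs8[:2], n_subjects=2, seed=5), gt_small)
        for k in a:
            assert np.array_equal(a[k], b[k])


class TestRankTensors:
    def test_random_rank_tensor_noncollinear(self):
        x, loadings = random_rank_tensor((20, 100, 16), k=2, seed=6)
        for m in loadings:
            mn = m / np.linalg.norm(m, axis=0)
            assert abs(mn[:, 0] @ mn[:, 1]) < 0.95

    def test_model_tensor_reproducible(self, designs8):
        from hierpc.pcmodel import within_contrast_profile

        prof = within_contrast_profile(designs8, ScalingFactors(s0=0.3))
        x1, _, _ = model_contrast_tensor(prof.values, 8, 50, noise=0.1, seed=7)
        x2, _, _ = model_contrast_tensor(prof.values, 8, 50, noise=0.1, seed=7)
        assert np.array_equal(x1, x2)


@pytest.fixture(scope="module")
def epochs(block1, gt_small):
    return simulate_epochs(block1, gt_small, sfreq=200.0, snr=20.0, seed=8, n_channels=10)


class TestEpochSimulation:
    def test_epoch_geometry(self, epochs, block1):
        assert epochs.data.shape[0] == 144
        assert epochs.tmin == -1.5
        # 2-tone sequences: last tone at 0.2 s, epoch up to 2.1 s
        assert epochs.last_tone == pytest.approx(0.2)

    def test_burst_visible_in_ersp_at_injected_location(self, epochs, gt_small):
        xx = epochs.select(trial_type="xx")
        freqs = np.arange(4.0, 81.0, 4.0)
        tfr = morlet_tfr(xx, freqs=freqs, pad=True)
        db = analysis_window(ersp(tfr), last_tone=0.2, n_samples=None)
        # gamma-band PE1 burst at ~156 ms after the last tone
        gamma = db.values[:, freqs >= 50, :].mean(axis=(0, 1))
        assert abs(db.times[np.argmax(gamma)] - 0.156) < 0.08

    def test_doubling_amplitude_adds_six_db(self, block1, gt_small):
        base = simulate_epochs(block1, gt_small, sfreq=200.0, snr=1e9, seed=9, n_channels=6)
        doubled = base.data * 2.0
        freqs = np.arange(40.0, 81.0, 4.0)
        from hierpc.spectral import EpochSet

        ep2 = EpochSet(doubled, base.sfreq, base.ch_names, base.tmin, base.trial_info, base.last_tone)
        p1 = morlet_tfr(base.select(trial_type="xy"), freqs=freqs, pad=True)
        p2 = morlet_tfr(ep2.select(trial_type="xy"), freqs=freqs, pad=True)
        # dB difference at the burst peak pixel ~ 20*log10(2) = 6.02
        m1 = p1.values.mean(axis=0)
        pk = np.unravel_index(np.argmax(m1), m1.shape)
        ratio = 10 * np.log10(p2.values.mean(axis=0)[pk] / m1[pk])
        assert ratio == pytest.approx(6.02, abs=0.1)

    def test_nyquist_guard(self, block1, gt_small):
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_epochs(block1, gt_small, sfreq=100.0, seed=0)


class TestSingleTrialGenerator:
    def test_dominant_subset_and_determinism(self, block1, gt_small):
        maps, amp = simulate_single_trial_ersps(block1, gt_small, seed=10)
        assert set(amp.trial_type) == {"xx"}
        maps2, amp2 = simulate_single_trial_ersps(block1, gt_small, seed=10)
        assert np.array_equal(maps, maps2)
        pd.testing.assert_frame_equal(amp, amp2)

    def test_full_series_option(self, block1, gt_small):
        maps, amp = simulate_single_trial_ersps(block1, gt_small, seed=11, trials="all")
        assert len(amp) == 144


class TestAdaptationGenerator:
    def test_no_adaptation_is_flat(self, block1):
        per_trial, _ = simulate_adaptation_only(block1, s0=1.0, tau0=1.0, seed=0)
        delivered = per_trial > 0
        assert np.allclose(per_trial[delivered], 1.0)

    def test_repetition_attenuates_response(self, block1):
        _, per_type = simulate_adaptation_only(block1, s0=0.2, tau0=1.9, seed=0)
        # within a sequence the second tone follows after only 0.2 s
        assert per_type["xx"] < per_type["xy"] + 0.3
        assert per_type["xx"] < 1.0
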