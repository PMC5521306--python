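"""Synthetic protocol, neural forward model and recording generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dotppi.hemodynamics import build_canonical_hrf, convolve
from dotppi.synth import (CANONICAL_REGION_TABLE, GroundTruthCouplings,
                          RegionLayout, generate_design, generate_neural,
                          generate_recording, pink_noise)


class TestGenerateDesign:
    def test_protocol_counts_and_sentence_total(self):
        designs = generate_design(4, seed=7)
        assert len(designs) == 4
        total_sentences = sum(
            len(d.of_condition("easy")) + len(d.of_condition("complex"))
            for d in designs
        )
        assert total_sentences == 240
        for d in designs:
            assert len(d.of_condition("easy")) == 30
            assert len(d.of_condition("complex")) == 30
            assert len(d.of_condition("noise")) == 10

    def test_deterministic_for_fixed_seed(self):
        a = generate_design(1, seed=0)[0]
        b = generate_design(1, seed=0)[0]
        assert a.events == b.events

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_invariants_across_seeds(self, seed):
        d = generate_design(1, seed=seed)[0]
        onsets = [e.onset for e in d.events]
        assert all(b > a for a, b in zip(onsets, onsets[1:]))
        stim = d.stimulus_events
        isis = [b.onset - (a.onset + a.duration) for a, b in zip(stim, stim[1:])]
        assert all(2.0 - 1e-9 <= isi <= 10.0 + 1e-9 for isi in isis)
        # each sentence pairs with exactly one later button event
        sentences = [e for e in stim if e.condition in ("easy", "complex")]
        buttons = [e for e in d.events
                   if e.condition in ("button_left", "button_right")]
        assert len(buttons) == len(sentences)
        assert all(b.duration == 0 for b in buttons)
        for s, b in zip(sentences, sorted(buttons, key=lambda e: e.onset)):
            assert b.onset > s.onset

    @pytest.mark.parametrize("kwargs", [
        {"n_runs": 0},
        {"isi_range": (10.0, 2.0)},
        {"isi_range": (-1.0, 5.0)},
        {"stim_duration": 0.0},
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_design(**{"n_runs": 1, "seed": 0, **kwargs})


class TestRegionLayout:
    def test_default_layout_holds_ten_nonoverlapping_regions(self):
        layout = RegionLayout.default(3.0)
        assert len(layout.regions) == 10
        assert layout.grid_shape == (50, 58, 44)
        centers = np.array([r.center_mm for r in layout.regions])
        # canonical dorsal premotor center
        assert tuple(centers[0]) == (-61.5, 3.0, 45.5)

    def test_duplicate_labels_rejected(self):
        table = [("A", 0, 0, 0), ("A", 30, 0, 0)]
        with pytest.raises(ValueError, match="unique"):
            RegionLayout.default(3.0, table=table)


class TestGenerateNeural:
    def _layout(self):
        return RegionLayout.default(9.0)

    def test_null_model_is_all_zero(self):
        layout = self._layout()
        truth = GroundTruthCouplings.null(layout.labels)
        d = generate_design(1, seed=0)[0]
        n = generate_neural(d, layout, truth, noise_sd=0.0)
        assert np.all(n == 0)

    def test_single_region_boxcar_identity(self):
        layout = self._layout()
        truth = GroundTruthCouplings.null(layout.labels)
        truth.set_baseline(layout.labels[0], "easy", 1.0)
        d = generate_design(1, seed=0)[0]
        n = generate_neural(d, layout, truth, noise_sd=0.0)
        tv = d.task_vector("easy", 10.0, n.shape[1])
        assert np.allclose(n[0], tv)
        assert np.all(n[1:] == 0)

    def test_interaction_support(self):
        layout = self._layout()
        truth = GroundTruthCouplings.null(layout.labels)
        src, tgt = layout.labels[0], layout.labels[1]
        truth.set_baseline(src, "easy", 1.0)
        truth.set_modulation(tgt, src, "easy", 0.5)
        d = generate_design(1, seed=0)[0]
        n = generate_neural(d, layout, truth, noise_sd=0.0)
        tv = d.task_vector("easy", 10.0, n.shape[1])
        support = tv * n[layout.index(src)] != 0
        assert np.any(support)
        assert np.all(n[layout.index(tgt)][~support] == 0)
        assert np.any(n[layout.index(tgt)][support] != 0)

    def test_cyclic_couplings_rejected(self):
        layout = self._layout()
        truth = GroundTruthCouplings.null(layout.labels)
        # backwards edge: later-listed region drives an earlier one
        truth.set_coupling(layout.labels[0], layout.labels[1], 0.5)
        d = generate_design(1, seed=0)[0]
        with pytest.raises(ValueError, match="cyclic"):
            generate_neural(d, layout, truth)


class TestGenerateRecording:
    def test_noiseless_forward_model_at_region_center(self, hrf10):
        layout = RegionLayout.default(9.0)
        truth = GroundTruthCouplings.null(layout.labels)
        truth.set_baseline(layout.labels[0], "easy", 1.0)
        d = generate_design(1, seed=0)[0]
        rec = generate_recording([d], layout, truth, hrf10,
                                 superficial_amp=0, pink_amp=0, white_amp=0,
                                 neural_noise_sd=0, seed=0)
        n = generate_neural(d, layout, truth, noise_sd=0.0)
        expected = convolve(n[0], hrf10)
        center = np.asarray(layout.regions[0].center_mm)
        # nearest voxel to the region center carries the largest weight
        vox = np.round(np.linalg.solve(layout.affine[:3, :3],
                                       center - layout.affine[:3, 3])).astype(int)
        got = rec.series[0].data[tuple(vox)]
        d_mm = np.linalg.norm(layout.affine[:3, :3] @ vox
                              + layout.affine[:3, 3] - center)
        sigma2 = (14.0 / (2 * np.sqrt(2 * np.log(2)))) ** 2
        weight = np.exp(-d_mm**2 / (2 * sigma2))
        assert np.allclose(got, weight * expected, atol=1e-4 * np.abs(expected).max())

    def test_superficial_signal_raises_distant_voxel_correlation(self, hrf10):
        layout = RegionLayout.default(9.0)
        truth = GroundTruthCouplings.null(layout.labels)
        d = generate_design(1, seed=0)[0]

        def mean_corr(sup_amp):
            rec = generate_recording([d], layout, truth, hrf10,
                                     superficial_amp=sup_amp, pink_amp=1.0,
                                     white_amp=1.0, neural_noise_sd=0, seed=11)
            flat = rec.series[0].flat()
            rng = np.random.default_rng(5)
            cs = []
            for _ in range(20):
                i, j = rng.choice(flat.shape[0], 2, replace=False)
                cs.append(np.corrcoef(flat[i], flat[j])[0, 1])
            return np.mean(cs)

        assert mean_corr(3.0) > mean_corr(0.0)

    def test_deterministic_under_fixed_seed(self, hrf10):
        layout = RegionLayout.default(9.0)
        truth = GroundTruthCouplings.null(layout.labels)
        truth.baseline[:] = 1.0
        d = generate_design(1, seed=0)[0]
        kw = dict(superficial_amp=1, pink_amp=1, white_amp=1, seed=3)
        a = generate_recording([d], layout, truth, hrf10, **kw)
        b = generate_recording([d], layout, truth, hrf10, **kw)
        assert np.array_equal(a.series[0].data, b.series[0].data)
        assert np.array_equal(a.superficial[0], b.superficial[0])

    def test_sensitivity_image_is_positive_and_centrally_peaked(self, hrf10):
        layout = RegionLayout.default(9.0)
        truth = GroundTruthCouplings.null(layout.labels)
        d = generate_design(1, seed=0)[0]
        rec = generate_recording([d], layout, truth, hrf10, seed=0)
        sens = rec.sensitivity
        assert np.all(sens > 0)
        corner = sens[0, 0, 0]
        center = sens[tuple(np.array(sens.shape) // 2)]
        assert center > corner
        assert corner < sens.max() * 1e-2  # corners fall out of a 2-decade FOV

    def test_pink_noise_power_decreases_with_frequency(self):
        x = pink_noise(2**14, rate=10.0, rng=np.random.default_rng(0))
        f = np.fft.rfftfreq(x.size, 0.1)
        p = np.abs(np.fft.rfft(x)) ** 2
        # smooth in octave bands and require monotone decrease
        bands = [(0.01, 0.05), (0.05, 0.2), (0.2, 1.0), (1.0, 5.0)]
        powers = [p[(f >= lo) & (f < hi)].mean() for lo, hi in bands]
        assert all(a > b for a, b in zip(powers, powers[1:]))
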