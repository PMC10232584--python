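import numpy as np
import pandas as pd
import pytest

from stresseeg.cardiac import ibi_table
from stresseeg.stats import inclusion_filter
from stresseeg.synthetic import (
    BAND_EDGES,
    SimulationConfig,
    default_event_times,
    generate_epochs,
    generate_rpeaks,
    generate_scores,
    generate_study,
    participant_id,
)


class TestConfig:
    def test_defaults_match_study(self):
        cfg = SimulationConfig()
        assert cfg.n_participants == 73
        assert cfg.epoch_duration_s == 6.2
        assert cfg.fs == 512.0
        assert cfg.n_samples_per_epoch == 3174  # floor(6.2 · 512)
        assert len(cfg.regions) == 10

    def test_zero_sample_epoch_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(epoch_duration_s=1e-6, fs=100.0)

    def test_coupling_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                regions=("a", "b"),
                baseline_coupling={(("a", "b"), "alpha"): 1.0},
            )

    def test_unknown_region_in_effects_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(regions=("a",), band_effects={("z", "alpha"): 0.1})

    def test_rank_deficient_mixing_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            SimulationConfig(
                regions=("a", "b"),
                mixing_matrix=np.array([[1.0, 1.0], [2.0, 2.0]]),
            )

    def test_non_psd_coupling_errors_name_pairs(self):
        # pairwise correlations (a,b)=0.9, (a,c)=0.9, (b,c)=−0.9 are jointly impossible
        cfg = SimulationConfig(
            n_participants=1,
            n_epochs_per_condition=4,
            fs=128.0,
            regions=("a", "b", "c"),
            baseline_coupling={
                (("a", "b"), "alpha"): 0.9,
                (("a", "c"), "alpha"): 0.9,
            },
            coupling_effects={(("b", "c"), "alpha"): 0.0},
        )
        cfg.baseline_coupling[(("b", "c"), "alpha")] = -0.9  # bypass range check
        with pytest.raises(ValueError, match="unsatisfiable"):
            generate_epochs(cfg, 0, "control")


class TestGenerateEpochs:
    def test_deterministic_from_seed(self, tiny_config):
        a = generate_epochs(tiny_config, 0, "control")
        b = generate_epochs(tiny_config, 0, "control")
        np.testing.assert_array_equal(a.data, b.data)

    def test_different_seeds_differ(self, tiny_config):
        a = generate_epochs(tiny_config, 0, "control")
        cfg2 = SimulationConfig(**{**tiny_config.__dict__, "random_seed": 99, "_multipliers": None})
        b = generate_epochs(cfg2, 0, "control")
        assert not np.allclose(a.data, b.data)

    def test_participant_substreams_independent_of_cohort_size(self, tiny_config):
        a = generate_epochs(tiny_config, 2, "negative")
        cfg_big = SimulationConfig(
            **{**tiny_config.__dict__, "n_participants": 50, "_multipliers": None}
        )
        b = generate_epochs(cfg_big, 2, "negative")
        np.testing.assert_array_equal(a.data, b.data)

    def test_shape_and_labels(self, tiny_config):
        es = generate_epochs(tiny_config, 1, "negative")
        assert es.data.shape == (6, 3, tiny_config.n_samples_per_epoch)
        assert es.channel_labels == list(tiny_config.regions)
        assert es.participant == participant_id(1)

    def test_identity_mixing_channels_equal_rois(self):
        # with explicit identity mixing and no sensor noise the channel
        # data must equal the unmixed region data exactly
        base = dict(
            n_participants=1, n_epochs_per_condition=3, fs=128.0,
            regions=("a", "b"), random_seed=4,
        )
        plain = generate_epochs(SimulationConfig(**base), 0, "control")
        mixed = generate_epochs(
            SimulationConfig(**base, mixing_matrix=np.eye(2), channel_labels=("a", "b")),
            0,
            "control",
        )
        np.testing.assert_array_equal(plain.data, mixed.data)

    def test_coupling_half_realized_within_tolerance(self):
        # coupling 0.5 at 60 epochs × 6.2 s: stored envelopes correlate
        # within ±0.05 of the target
        cfg = SimulationConfig(
            n_participants=1,
            n_epochs_per_condition=60,
            fs=128.0,
            regions=("a", "b"),
            baseline_coupling={(("a", "b"), "alpha"): 0.5},
            random_seed=8,
        )
        es = generate_epochs(cfg, 0, "control")
        assert es.ground_truth["envelope_corr"]["a|b|alpha"] == pytest.approx(0.5, abs=0.05)

    def test_fourteen_epochs_fail_inclusion(self):
        cfg = SimulationConfig(
            n_participants=2, n_epochs_per_condition=14, fs=128.0,
            regions=("a",), random_seed=0,
        )
        counts = []
        for p, by_cond in generate_study(cfg):
            for cond, es in by_cond.items():
                counts.append(
                    {"participant": es.participant, "condition": cond, "n_epochs": es.n_epochs}
                )
        assert inclusion_filter(pd.DataFrame(counts), min_epochs=15) == []

    def test_condition_effect_scales_band_amplitude(self):
        cfg = SimulationConfig(
            n_participants=1, n_epochs_per_condition=4, fs=128.0,
            regions=("a", "b"), band_effects={("a", "alpha"): 0.5},
            random_seed=2,
        )
        ctrl = generate_epochs(cfg, 0, "control")
        neg = generate_epochs(cfg, 0, "negative")
        amp_c = ctrl.ground_truth["band_amplitude"]["a|alpha"]
        amp_n = neg.ground_truth["band_amplitude"]["a|alpha"]
        assert amp_n > amp_c
        # untouched region/band amplitudes identical across conditions
        assert neg.ground_truth["band_amplitude"]["b|alpha"] == pytest.approx(
            ctrl.ground_truth["band_amplitude"]["b|alpha"]
        )

    def test_invalid_condition_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            generate_epochs(tiny_config, 0, "sham")


class TestGenerateRpeaks:
    def test_strictly_increasing(self):
        cfg = SimulationConfig(random_seed=1)
        peaks = generate_rpeaks(cfg, default_event_times(10))
        assert np.all(np.diff(peaks) > 0)

    def test_deterministic(self):
        cfg = SimulationConfig(random_seed=1)
        ev = default_event_times(5)
        np.testing.assert_array_equal(
            generate_rpeaks(cfg, ev, "negative"), generate_rpeaks(cfg, ev, "negative")
        )

    def test_too_close_events_rejected(self):
        cfg = SimulationConfig()
        with pytest.raises(ValueError, match="spacing"):
            generate_rpeaks(cfg, [10.0, 12.0])

    def test_zero_effect_mean_diffs_near_zero(self):
        cfg = SimulationConfig(ibi_effect_ms=0.0, ibi_sd_ms=20.0, random_seed=6)
        ev = default_event_times(60)
        frames = [
            ibi_table(generate_rpeaks(cfg, ev, cond), ev, cond)
            for cond in ("control", "negative")
        ]
        table = pd.concat(frames)
        m = table.groupby(["condition", "index"])["diff_ms"].mean().unstack()
        contrast = m.loc["negative"] - m.loc["control"]
        # SE of the contrast ≈ sd·√2/√60 ≈ 3.7 ms per index
        assert np.abs(contrast).max() < 15.0

    def test_effect_recovered_at_indices_2_to_7(self):
        # near-deterministic train isolates the injected 30 ms shortening
        cfg = SimulationConfig(ibi_effect_ms=30.0, ibi_sd_ms=1.0, random_seed=9)
        ev = default_event_times(40)
        frames = [
            ibi_table(generate_rpeaks(cfg, ev, cond), ev, cond)
            for cond in ("control", "negative")
        ]
        m = pd.concat(frames).groupby(["condition", "index"])["diff_ms"].mean().unstack()
        contrast = m.loc["negative"] - m.loc["control"]
        for k in range(2, 8):
            assert contrast[k] == pytest.approx(-30.0, abs=2.0)
        for k in (-3, -1, 0, 1, 8):
            assert contrast[k] == pytest.approx(0.0, abs=2.0)

    def test_edge_event_warns_and_skips_modification(self):
        # a short pre-event pad leaves too few beats before the anchor
        cfg = SimulationConfig(ibi_effect_ms=30.0)
        with pytest.warns(UserWarning, match="edge"):
            generate_rpeaks(cfg, [0.0], "negative", pad_beats=3)


class TestGenerateScores:
    def test_deterministic_and_positive(self):
        cfg = SimulationConfig(n_participants=20, random_seed=3)
        a = generate_scores(cfg)
        b = generate_scores(cfg)
        pd.testing.assert_frame_equal(a, b)
        assert (a["value"] > 0).all()

    def test_zero_shift_contrast_centered(self):
        cfg = SimulationConfig(n_participants=200, score_shift=0.0, random_seed=4)
        df = generate_scores(cfg)
        m = df.groupby("condition")["value"].mean()
        assert m["negative"] - m["control"] == pytest.approx(0.0, abs=0.4)

    def test_likert_bounds(self):
        cfg = SimulationConfig(n_participants=50, likert=True, score_shift=-1.0, random_seed=5)
        df = generate_scores(cfg)
        assert df["value"].between(1, 9).all()
        assert (df["value"] == df["value"].round()).all()

    def test_nonpositive_mean_rejected(self):
        cfg = SimulationConfig(score_mean=1.0, score_shift=-2.0)
        with pytest.raises(ValueError, match="non-positive"):
            generate_scores(cfg)

    def test_both_sexes_present(self):
        df = generate_scores(SimulationConfig(n_participants=10))
        assert set(df["sex"]) == {"F", "M"}

    def test_shift_recovered_within_ci_in_most_replicates(self):
        # parameter recovery: fitted contrast CI covers the injected −1.0
        # shift in ≥ 90 % of replicate seeds (scaled-down cohort)
        from stresseeg.stats import fit_linear_mixed

        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            cfg = SimulationConfig(
                n_participants=73, score_shift=-1.0, random_seed=100 + seed
            )
            fit = fit_linear_mixed(generate_scores(cfg))
            lo, hi = fit.beta - 1.96 * fit.se, fit.beta + 1.96 * fit.se
            hits += lo <= -1.0 <= hi
        assert hits >= 9


class TestBandEdges:
    def test_match_analysis_bands(self):
        assert BAND_EDGES == {
            "theta": (4.0, 8.0),
            "alpha": (8.0, 13.0),
            "beta": (13.0, 30.0),
        }
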