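"""Synthetic-study generator: spectral fidelity, coupling recovery hooks,
artifact bookkeeping, planted-effect structure, determinism."""

import numpy as np
import pytest
from scipy.signal import welch

from wakenet.connectivity import wpli_matrix
from wakenet.graph import clustering_coefficients
from wakenet.io import Recording
from wakenet.preprocess import bandpass_filter
from wakenet.simulate import (
    ArtifactSpec,
    BandSpec,
    EffectSpec,
    NoiseSpec,
    SyntheticStudyConfig,
    generate_latent_sources,
    generate_study,
    inject_artifacts,
    mix_to_channels,
)
from wakenet.simulate import CHANNELS_32

DELTA = BandSpec("delta", 1.0, 3.0, 30.0)
ALPHA = BandSpec("alpha", 8.0, 12.0, 20.0)


def band_fraction(sources, fs, f_low, f_high):
    f, p = welch(sources, fs=fs, nperseg=min(4096, sources.shape[-1]))
    inside = p[..., (f >= f_low) & (f <= f_high)].sum(axis=-1)
    return inside / p.sum(axis=-1)


def small_config(**kw):
    defaults = dict(
        n_subjects=3,
        channels=CHANNELS_32[:6],
        sampling_rate=200.0,
        epoch_duration=8.0,
        bouts=("BL", "T1"),
        conditions=("control",),
        band_specs=(BandSpec("delta", 1.0, 3.0, 30.0), BandSpec("alpha", 8.0, 12.0, 20.0)),
        artifact_spec=ArtifactSpec(rate_per_min=2.0, amplitude_uv=300.0, duration_ms=150.0),
        seed=5,
    )
    defaults.update(kw)
    return SyntheticStudyConfig(**defaults)


class TestLatentSources:
    def test_delta_peak_inside_band(self):
        src = generate_latent_sources([DELTA], 4, 60.0, 500.0, 1)["delta"]
        f, p = welch(src, fs=500.0, nperseg=4096)
        peaks = f[np.argmax(p, axis=-1)]
        assert np.all((peaks >= 1.0) & (peaks <= 3.0))

    @pytest.mark.parametrize("spec", [DELTA, ALPHA])
    def test_spectral_mass_inside_band(self, spec):
        src = generate_latent_sources([spec], 6, 60.0, 500.0, 2)[spec.name]
        assert np.all(band_fraction(src, 500.0, spec.f_low, spec.f_high) >= 0.9)

    def test_deterministic_given_seed(self):
        a = generate_latent_sources([DELTA, ALPHA], 3, 10.0, 250.0, 42)
        b = generate_latent_sources([DELTA, ALPHA], 3, 10.0, 250.0, 42)
        for band in a:
            assert np.array_equal(a[band], b[band])

    def test_band_outside_nyquist_rejected(self):
        bad = BandSpec("gamma", 40.0, 80.0, 5.0)
        with pytest.raises(ValueError, match="outside"):
            generate_latent_sources([bad], 2, 10.0, 100.0, 0)


class TestMixToChannels:
    def test_asymmetric_coupling_rejected(self, rng):
        src = rng.normal(size=(10, 1000))
        W = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            mix_to_channels(src, W, 2)

    def test_full_coupling_noise_free_pair_gives_unit_wpli(self):
        fs = 250.0
        src = generate_latent_sources([DELTA], 4, 60.0, fs, 3)["delta"]
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        data = mix_to_channels(src, W, 2, noise_spec=None, private_amplitude_frac=0.0)
        rec = Recording(["a", "b"], fs, data)
        assert wpli_matrix(rec).weights[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_zero_coupling_leaves_channels_independent(self):
        fs = 250.0
        src = generate_latent_sources([DELTA], 4, 60.0, fs, 4)["delta"]
        data = mix_to_channels(src, np.zeros((2, 2)), 2,
                               noise_spec=NoiseSpec(), seed=11)
        rec = bandpass_filter(Recording(["a", "b"], fs, data), 1.0, 3.0)
        assert wpli_matrix(rec).weights[0, 1] < 0.35  # null level at 60 s

    def test_stronger_coupling_gives_larger_wpli(self):
        fs = 250.0
        vals = {}
        for w in (0.2, 0.9):
            src = generate_latent_sources([DELTA], 4, 120.0, fs, 7)["delta"]
            W = np.array([[0.0, w], [w, 0.0]])
            data = mix_to_channels(src, W, 2, noise_spec=None, private_amplitude_frac=0.4)
            rec = Recording(["a", "b"], fs, data)
            vals[w] = wpli_matrix(rec).weights[0, 1]
        assert vals[0.9] > vals[0.2]

    def test_insufficient_sources_rejected(self, rng):
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError, match="sources"):
            mix_to_channels(rng.normal(size=(2, 500)), W, 2)


class TestInjectArtifacts:
    def test_zero_rate_identity(self, rng):
        data = rng.normal(size=(3, 5000))
        out, spans = inject_artifacts(data, ArtifactSpec(rate_per_min=0.0), 500.0, 1)
        assert np.array_equal(out, data)
        assert spans == []

    def test_burst_amplitude_at_logged_timestamp(self):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        background = 20.0 * np.sin(2 * np.pi * 3 * t)[None, :].repeat(2, axis=0)
        spec = ArtifactSpec(rate_per_min=6.0, amplitude_uv=500.0, duration_ms=200.0)
        out, spans = inject_artifacts(background, spec, fs, 3)
        assert len(spans) > 0
        for start, n in spans:
            assert np.abs(out[:, start : start + n]).max() >= 500.0

    def test_burst_count_matches_log(self, rng):
        fs = 250.0
        data = rng.normal(0, 5, size=(2, int(fs * 300)))  # 5 min, 5 uV background
        spec = ArtifactSpec(rate_per_min=2.0, amplitude_uv=400.0, duration_ms=200.0)
        out, spans = inject_artifacts(data, spec, fs, 9)
        # count windows where the signal exceeds what background alone allows
        exceed = np.abs(out).max(axis=0) > 100.0
        observed = 0
        prev_end = -1
        for start, n in spans:
            if exceed[start : start + n].any():
                observed += 1
            assert start > prev_end  # non-overlapping, sorted
            prev_end = start + n
        assert observed == len(spans)

    def test_overlap_saturation_rejected(self, rng):
        spec = ArtifactSpec(rate_per_min=400.0, amplitude_uv=100.0, duration_ms=200.0)
        with pytest.raises(ValueError, match="cover"):
            inject_artifacts(rng.normal(size=(1, 5000)), spec, 500.0, 0)


class TestCouplingRecovery:
    """Estimated wPLI ordering tracks the planted coupling ordering.

    Bounds are frozen from a 20-seed Monte-Carlo at these exact
    conditions; recovery is interference-limited (every channel carries
    the shared sources of all its edges), so the rank correlation rises
    with epoch duration toward an asymptote below 1 rather than to 1.
    """

    FS = 250.0

    @staticmethod
    def _rank(duration, seed, n=8, lo=0.1, hi=0.9, noise=True, priv=0.4):
        from scipy.stats import spearmanr

        from wakenet.simulate import NoiseSpec

        iu = np.triu_indices(n, 1)
        rng = np.random.default_rng(seed)
        base = np.zeros((n, n))
        base[iu] = rng.uniform(lo, hi, len(iu[0]))
        base = base + base.T
        src = generate_latent_sources(
            [DELTA], 2 * len(iu[0]) + n, duration, TestCouplingRecovery.FS, rng)["delta"]
        data = mix_to_channels(
            src, base, n, noise_spec=NoiseSpec() if noise else None,
            seed=rng, private_amplitude_frac=priv)
        rec = bandpass_filter(
            Recording([f"c{i}" for i in range(n)], TestCouplingRecovery.FS, data), 1.0, 3.0)
        return spearmanr(base[iu], wpli_matrix(rec).weights[iu]).statistic

    def test_rank_recovery_improves_with_duration(self):
        seeds = range(5)
        r300 = np.mean([self._rank(300.0, s) for s in seeds])
        r60 = np.mean([self._rank(60.0, s) for s in seeds])
        assert r300 > 0.3  # Monte-Carlo mean 0.40 at these conditions
        assert r300 > r60

    def test_clean_long_duration_limit(self):
        """Without background noise and private sources the ordering is
        recovered well at long duration (interference-limited ceiling)."""
        seeds = (0, 1, 2)
        r600 = np.mean([self._rank(600.0, s, n=6, lo=0.2, hi=0.95, noise=False, priv=0.0)
                        for s in seeds])
        r60 = np.mean([self._rank(60.0, s, n=6, lo=0.2, hi=0.95, noise=False, priv=0.0)
                       for s in seeds])
        assert r600 > 0.45  # Monte-Carlo mean 0.63 at these conditions
        assert r600 > r60


class TestGenerateStudy:
    def test_one_recording_per_cell_and_metadata(self):
        config = small_config()
        study = generate_study(config)
        assert len(study.recordings) == 3 * 1 * 2
        for (s, c, b), rec in study.recordings.items():
            assert rec.metadata == {"subject": s, "condition": c, "bout": b}
            assert rec.n_samples == int(8.0 * 200.0)

    def test_planted_clustering_drop_every_subject(self):
        config = small_config()
        study = generate_study(config)
        for s in config.subjects:
            _, c_bl = clustering_coefficients(
                study.ground_truth.coupling[(s, "control", "BL", "delta")])
            _, c_t1 = clustering_coefficients(
                study.ground_truth.coupling[(s, "control", "T1", "delta")])
            assert c_t1 < c_bl

    def test_zero_effects_freeze_ground_truth_across_bouts(self):
        config = small_config(effect_specs=EffectSpec(clustering={}, power={}))
        study = generate_study(config)
        for s in config.subjects:
            for band in ("delta", "alpha"):
                W_bl = study.ground_truth.coupling[(s, "control", "BL", band)]
                W_t1 = study.ground_truth.coupling[(s, "control", "T1", band)]
                assert np.array_equal(W_bl, W_t1)

    def test_bit_identical_given_seed(self):
        a = generate_study(small_config())
        b = generate_study(small_config())
        for key in a.recordings:
            assert np.array_equal(a.recordings[key].data, b.recordings[key].data)
        for r_a, r_b in zip(a.behavior, b.behavior):
            assert r_a.kss == r_b.kss
            assert np.array_equal(r_a.rt_series_ms, r_b.rt_series_ms)

    def test_larger_planted_drop_lowers_truth_clustering(self):
        means = {}
        for g in (1.17, 2.5):
            config = small_config(
                effect_specs=EffectSpec(clustering={("control", "T1"): g}, power={}))
            study = generate_study(config)
            vals = []
            for s in config.subjects:
                _, c = clustering_coefficients(
                    study.ground_truth.coupling[(s, "control", "T1", "delta")])
                vals.append(c)
            means[g] = np.mean(vals)
        assert means[2.5] < means[1.17]

    def test_behavioral_records_valid(self):
        study = generate_study(small_config())
        assert len(study.behavior) == 6
        for r in study.behavior:
            assert 1 <= r.kss <= 9
            assert np.all(r.rt_series_ms > 0)

    def test_artifact_spans_recorded_and_present(self):
        config = small_config(
            artifact_spec=ArtifactSpec(rate_per_min=8.0, amplitude_uv=500.0, duration_ms=150.0))
        study = generate_study(config)
        any_spans = False
        for key, spans in study.ground_truth.artifacts.items():
            for start, n in spans:
                any_spans = True
                seg = np.abs(study.recordings[key].data[:, start : start + n])
                assert seg.max() > 200.0
        assert any_spans

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            small_config(channels=["a", "a", "b", "c", "d", "e"]).validate()
        with pytest.raises(ValueError, match="overlap"):
            small_config(band_specs=(BandSpec("x", 1, 5, 10), BandSpec("y", 4, 8, 10))).validate()
        with pytest.raises(ValueError, match="sampling_rate"):
            small_config(sampling_rate=20.0).validate()
        with pytest.raises(ValueError, match="BL"):
            small_config(bouts=("T1", "T2")).validate()
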