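"""Synthetic EEG studies with known ground truth.

The generator emulates the statistical structure a sleep-inertia EEG
analysis assumes: multichannel recordings per subject x condition x bout
(pre-sleep baseline BL and four post-awakening bouts T1-T4), band-limited
oscillatory sources, cross-channel coupling realized as *shared sources
observed at a fixed nonzero phase lag* (default pi/4) so that the weighted
phase lag index can recover the planted graph (wPLI is blind to zero-lag
mixing), 1/f background noise, occasional high-amplitude artifact bursts,
and behavioral records (KSS, PVT reaction times) correlated with the
planted network state.

Planted effects are expressed as target standardized paired effect sizes
(Hedges-g scale) for the *estimated* metrics, mirroring how such effects
are reported.  Because the wPLI estimator attenuates coupling differences
(its noise floor adds variance and compresses the response), a target g is
mapped to a larger truth-space drop: a bout's coupling matrix is the
subject's base graph scaled by 1 - delta_s, where delta_s is a Beta
deviate on [0, 1] with mean g * drop_scale and SD subject_sd; drop_scale
is a response factor calibrated once by power simulation against the
full pipeline.  The draw is realized through the inverse CDF on a
per-subject uniform, so the planted drop is strictly positive for every
subject and increasing g moves every subject's draw upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.stats import beta as beta_dist

from .io import Recording, write_matrix, write_brainvision
from .bands import BandDefinition
from .graph import clustering_coefficients
from .preprocess import butter_sos

#: standard 32-electrode 10-20 montage labels
CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
]


@dataclass(frozen=True)
class BandSpec:
    """A generative band: name, frequency interval (Hz), source amplitude (uV RMS)."""

    name: str
    f_low: float
    f_high: float
    amplitude_uv: float

    def as_definition(self) -> BandDefinition:
        return BandDefinition(self.name, self.f_low, self.f_high)


@dataclass(frozen=True)
class ArtifactSpec:
    """High-amplitude transient bursts: Poisson rate, peak amplitude, duration."""

    rate_per_min: float = 1.0
    amplitude_uv: float = 400.0
    duration_ms: float = 200.0


@dataclass(frozen=True)
class NoiseSpec:
    """1/f^exponent background noise with a target RMS amplitude."""

    exponent: float = 1.0
    amplitude_uv: float = 3.0


def _default_clustering_effects() -> dict:
    # standardized clustering reductions vs BL in the delta band:
    # a large immediate drop after awakening under control, attenuated but
    # still present under light, recovery from T2 onward
    return {("control", "T1"): 1.17, ("light", "T1"): 0.8}


def _default_power_effects() -> dict:
    # standardized global-power reductions vs BL (same under both
    # conditions: light leaves power essentially unchanged)
    eff = {}
    for cond in ("control", "light"):
        eff[(cond, "T1", "beta")] = 0.6
        eff[(cond, "T2", "beta")] = 0.56
        eff[(cond, "T3", "beta")] = 0.47
        eff[(cond, "T1", "alpha")] = 0.76
        eff[(cond, "T2", "alpha")] = 0.66
        eff[(cond, "T1", "theta")] = 0.71
    return eff


@dataclass
class EffectSpec:
    """Planted standardized effect sizes relative to baseline.

    ``clustering`` maps (condition, bout) to the target effect size of the
    clustering reduction in ``clustering_band``; the same weight scaling
    simultaneously lowers ground-truth clustering and raises path length.
    ``power`` maps (condition, bout, band) to a target reduction of that
    band's source amplitude.  A target g translates into a mean
    coupling-scale drop of ``g * drop_scale`` (amplitude drop of
    ``g * power_drop_scale``) with between-subject SD ``subject_sd``
    (``power_subject_sd``); the drop scales are response factors fixed by
    power simulation against the full estimation pipeline.
    """

    clustering: dict = field(default_factory=_default_clustering_effects)
    power: dict = field(default_factory=_default_power_effects)
    clustering_band: str = "delta"
    drop_scale: float = 0.46
    subject_sd: float = 0.15
    power_drop_scale: float = 0.2
    power_subject_sd: float = 0.08


@dataclass
class SyntheticStudyConfig:
    """Full description of one synthetic study.

    Defaults follow the emulated design: 11 subjects, 32 channels at
    500 Hz, bouts BL/T1-T4 under control and light conditions, four
    classical EEG bands.  ``epoch_duration`` defaults to the fast 60-s test
    scale; set 300 for full-scale 5-min bouts.
    """

    n_subjects: int = 11
    channels: list[str] = field(default_factory=lambda: list(CHANNELS_32))
    sampling_rate: float = 500.0
    epoch_duration: float = 60.0
    bouts: tuple[str, ...] = ("BL", "T1", "T2", "T3", "T4")
    conditions: tuple[str, ...] = ("control", "light")
    band_specs: tuple[BandSpec, ...] = (
        BandSpec("delta", 1.0, 3.0, 30.0),
        BandSpec("theta", 4.0, 7.0, 15.0),
        BandSpec("alpha", 8.0, 12.0, 20.0),
        BandSpec("beta", 15.0, 25.0, 8.0),
    )
    # generative coupling: full-density base graphs with weights drawn
    # uniformly in base_weight_mean +/- base_weight_spread per subject
    base_weight_mean: float = 0.7
    base_weight_spread: float = 0.15
    coupling_density: float = 1.0
    coupling_overrides: dict = field(default_factory=dict)  # (cond, bout, band) -> matrix
    effect_specs: EffectSpec = field(default_factory=EffectSpec)
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)
    phase_lag: float = np.pi / 4
    private_amplitude_frac: float = 0.4  # per-channel private source share
    edge_gain: float = 3.0  # shared-source gain multiplier (scaled by 1/sqrt(n-1))
    n_pvt_trials: int = 45
    behavior_coupling: float = 1.0  # 0 decouples behavior from network state
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if len(set(self.bouts)) != len(self.bouts) or len(set(self.conditions)) != len(self.conditions):
            raise ValueError("bout and condition labels must be unique")
        if "BL" not in self.bouts:
            raise ValueError("bouts must include the baseline label 'BL'")
        if self.epoch_duration <= 0:
            raise ValueError("epoch_duration must be positive")
        max_hi = max(b.f_high for b in self.band_specs)
        if not self.sampling_rate > 2 * max_hi:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz must exceed twice the highest "
                f"band edge ({max_hi} Hz)"
            )
        intervals = sorted((b.f_low, b.f_high, b.name) for b in self.band_specs)
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(intervals, intervals[1:]):
            if lo2 < hi1:
                raise ValueError(f"bands {n1!r} and {n2!r} overlap")
        for b in self.band_specs:
            if b.amplitude_uv <= 0:
                raise ValueError(f"band {b.name!r}: amplitude must be positive")
            b.as_definition().validate(self.sampling_rate / 2)
        if not (0 < self.coupling_density <= 1):
            raise ValueError("coupling_density must be in (0, 1]")
        if self.artifact_spec.rate_per_min * self.artifact_spec.duration_ms / 1000.0 >= 60.0:
            raise ValueError("artifact bursts would cover the whole epoch")

    @property
    def subjects(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(self.n_subjects)]


@dataclass
class GroundTruth:
    """Planted structure for parameter-recovery tests.

    ``coupling`` maps (subject, condition, bout, band) to the true
    symmetric coupling matrix; ``amplitudes`` to the true band source
    amplitude; ``artifacts`` maps (subject, condition, bout) to the
    injected burst spans as (start_sample, n_samples) pairs.
    """

    coupling: dict
    amplitudes: dict
    artifacts: dict


@dataclass
class BehavioralRecord:
    """One subject x condition x bout behavioral observation."""

    subject: str
    condition: str
    bout: str
    kss: int
    rt_series_ms: np.ndarray

    def __post_init__(self) -> None:
        self.rt_series_ms = np.asarray(self.rt_series_ms, dtype=float)
        if not (1 <= self.kss <= 9):
            raise ValueError(f"KSS rating must be in 1..9, got {self.kss}")
        if self.rt_series_ms.size == 0 or np.any(self.rt_series_ms <= 0):
            raise ValueError("rt_series must be nonempty and positive")


@dataclass
class StudyData:
    """One generated study: recordings, planted truth, behavioral records."""

    recordings: dict  # (subject, condition, bout) -> Recording
    ground_truth: GroundTruth
    behavior: list
    config: SyntheticStudyConfig


# ---------------------------------------------------------------------------
# low-level generators


def generate_latent_sources(
    band_specs,
    n_sources_per_band: int,
    duration: float,
    sampling_rate: float,
    seed,
) -> dict[str, np.ndarray]:
    """Narrowband latent sources per band, (n_sources, n_samples) each.

    Each source is band-limited white noise: sources are split into a few
    groups whose pass-bands are jittered sub-intervals of the nominal band,
    and per-source amplitudes carry mild lognormal jitter around the band's
    nominal RMS.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * sampling_rate))
    nyq = sampling_rate / 2.0
    out: dict[str, np.ndarray] = {}
    for spec in band_specs:
        if not (0 < spec.f_low < spec.f_high < nyq):
            raise ValueError(
                f"band {spec.name!r} [{spec.f_low}, {spec.f_high}] Hz outside (0, {nyq}) Hz"
            )
        if n_sources_per_band == 0:
            out[spec.name] = np.empty((0, n_samples))
            continue
        bw = spec.f_high - spec.f_low
        n_groups = min(3, n_sources_per_band)
        sizes = np.full(n_groups, n_sources_per_band // n_groups)
        sizes[: n_sources_per_band % n_groups] += 1
        chunks = []
        for size in sizes:
            # jittered sub-band, kept inside the nominal interval
            center = rng.uniform(spec.f_low + 0.45 * bw, spec.f_high - 0.45 * bw)
            half = 0.42 * bw
            sos = butter_sos(4, round(center - half, 4), round(center + half, 4), sampling_rate)
            white = rng.standard_normal((size, n_samples))
            narrow = signal.sosfiltfilt(sos, white, axis=-1)
            rms = np.sqrt(np.mean(narrow**2, axis=1, keepdims=True))
            amp = spec.amplitude_uv * rng.lognormal(0.0, 0.15, size=(size, 1))
            chunks.append(narrow / rms * amp)
        out[spec.name] = np.concatenate(chunks, axis=0)
    return out


def _phase_lagged(sources: np.ndarray, lag: float) -> np.ndarray:
    """Copy of each source advanced by a constant phase ``lag`` (radians)."""
    z = signal.hilbert(sources, axis=-1)
    return np.real(z * np.exp(-1j * lag))


def pink_noise(shape, exponent: float, rms: float, rng) -> np.ndarray:
    """1/f^exponent noise with the requested RMS, shaped in the Fourier domain."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    cur = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    return shaped / cur * rms


def mix_to_channels(
    sources: np.ndarray,
    coupling_matrix: np.ndarray,
    channel_count: int,
    phase_lag: float = np.pi / 4,
    noise_spec: NoiseSpec | None = None,
    seed=None,
    private_amplitude_frac: float = 0.4,
    edge_gain: float = 3.0,
) -> np.ndarray:
    """Mix latent sources into channels so wPLI recovers the coupling order.

    Each edge (i, j) with weight w > 0 consumes two dedicated sources, a
    shared one and an incoherent partner: channel i receives the shared
    source, and channel j receives ``w`` parts of its ``phase_lag``-shifted
    copy plus ``sqrt(1 - w^2)`` parts of the partner.  The coupling weight
    therefore sets the *coherent fraction* of the lagged common source
    while the per-edge power stays constant, which makes the expected wPLI
    rise monotonically (near-linearly) with w instead of being cancelled
    by the interference of the other edges.  The next ``channel_count``
    sources become private per-channel signals.  Coupling is never encoded
    through zero-lag leakage.  Optional independent 1/f noise is added per
    channel.
    """
    W = np.asarray(coupling_matrix, dtype=float)
    if W.shape != (channel_count, channel_count):
        raise ValueError(f"coupling matrix shape {W.shape} != ({channel_count}, {channel_count})")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("coupling matrix is not symmetric")
    if np.any(np.diag(W) != 0) or np.any(W < 0) or np.any(W > 1):
        raise ValueError("coupling weights must be in [0, 1] with zero diagonal")
    iu, ju = np.triu_indices(channel_count, k=1)
    active = W[iu, ju] > 0
    n_edges = int(active.sum())
    if sources.shape[0] < 2 * n_edges + channel_count:
        raise ValueError(
            f"need {2 * n_edges + channel_count} sources (2 x {n_edges} edges + "
            f"{channel_count} private), got {sources.shape[0]}"
        )
    n_samples = sources.shape[1]
    # per-edge amplitude normalized so total shared power per channel is
    # comparable across channel counts
    gain = edge_gain / np.sqrt(max(channel_count - 1, 1))

    data = np.zeros((channel_count, n_samples))
    edge_sources = sources[:n_edges]
    partners = sources[n_edges : 2 * n_edges]
    lagged = _phase_lagged(edge_sources, phase_lag) if n_edges else edge_sources
    weights = W[iu, ju][active]
    for e, (i, j, w) in enumerate(zip(iu[active], ju[active], weights)):
        data[i] += gain * edge_sources[e]
        data[j] += gain * (w * lagged[e] + np.sqrt(1.0 - w * w) * partners[e])
    data += private_amplitude_frac * sources[2 * n_edges : 2 * n_edges + channel_count]
    # normalize so the per-channel band RMS approximates the source
    # amplitude (the shared/private ratio, not the absolute scale, carries
    # the coupling information)
    data /= np.sqrt(edge_gain**2 + private_amplitude_frac**2)
    if noise_spec is not None and noise_spec.amplitude_uv > 0:
        rng = np.random.default_rng(seed)
        data += pink_noise(data.shape, noise_spec.exponent, noise_spec.amplitude_uv, rng)
    return data


def inject_artifacts(
    data: np.ndarray,
    artifact_spec: ArtifactSpec,
    sampling_rate: float,
    seed=None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Add high-amplitude transient bursts; return the new array and spans.

    Burst count is Poisson(rate x minutes); each burst is a Hann-windowed
    oscillation whose peak equals ``amplitude_uv`` on at least one channel,
    added coherently across channels with random per-channel gains.
    Returned spans are (start_sample, n_samples) pairs for bookkeeping.
    """
    n_ch, n_samples = data.shape
    dur = int(round(artifact_spec.duration_ms / 1000.0 * sampling_rate))
    if dur >= n_samples:
        raise ValueError("burst duration must be shorter than the epoch")
    minutes = n_samples / sampling_rate / 60.0
    if artifact_spec.rate_per_min * artifact_spec.duration_ms / 1000.0 >= 60.0:
        raise ValueError("artifact rate so high bursts would cover the whole epoch")
    rng = np.random.default_rng(seed)
    out = data.copy()
    spans: list[tuple[int, int]] = []
    if artifact_spec.rate_per_min <= 0:
        return out, spans
    n_bursts = rng.poisson(artifact_spec.rate_per_min * minutes)
    for _ in range(n_bursts):
        for _attempt in range(200):
            start = int(rng.integers(0, n_samples - dur))
            if all(start + dur <= s or start >= s + d for s, d in spans):
                break
        else:
            continue  # epoch too crowded; skip this burst
        t = np.arange(dur)
        center = (dur - 1) / 2.0
        f_burst = rng.uniform(15.0, 45.0)
        wave = signal.windows.hann(dur) * np.cos(2 * np.pi * f_burst * (t - center) / sampling_rate)
        peak = int(np.argmax(np.abs(wave)))
        wave /= np.abs(wave[peak])  # unit peak -> burst peak equals amplitude_uv
        gains = rng.uniform(0.6, 1.0, size=n_ch)
        full = int(rng.integers(0, n_ch))
        gains[full] = 1.0  # guarantee full amplitude somewhere
        # align polarity with the underlying signal at the peak sample so the
        # logged peak is at least the configured amplitude
        sign = 1.0 if out[full, start + peak] >= 0 else -1.0
        out[:, start : start + dur] += (
            artifact_spec.amplitude_uv * sign * gains[:, None] * wave[None, :]
        )
        spans.append((start, dur))
    spans.sort()
    return out, spans


# ---------------------------------------------------------------------------
# study-level generation


def _planted_drop(g: float, drop_scale: float, sigma: float, u: float) -> float:
    """Scale drop with mean g*drop_scale and SD ~sigma, bounded in (0, 1).

    The drop is a Beta deviate on [0, 1] moment-matched to mean
    ``g * drop_scale`` and SD ``sigma`` (SD shrunk when infeasible for the
    mean), realized through the inverse CDF on a shared per-subject
    uniform: every subject's drop is strictly positive and a larger g
    moves each subject's draw upward.
    """
    if g <= 0 or drop_scale <= 0 or sigma <= 0:
        return 0.0
    mu = min(g * drop_scale, 0.95)
    var = min(sigma * sigma, 0.95 * mu * (1.0 - mu))
    t = mu * (1.0 - mu) / var - 1.0
    return float(beta_dist.ppf(u, mu * t, (1.0 - mu) * t))


def _base_coupling(config: SyntheticStudyConfig, rng) -> np.ndarray:
    n = len(config.channels)
    upper = rng.uniform(
        config.base_weight_mean - config.base_weight_spread,
        config.base_weight_mean + config.base_weight_spread,
        size=(n, n),
    )
    if config.coupling_density < 1:
        mask = rng.random((n, n)) < config.coupling_density
        upper = np.where(mask, upper, 0.0)
    W = np.triu(upper, k=1)
    W = W + W.T
    return np.clip(W, 0.0, 0.95)


def generate_study(config: SyntheticStudyConfig) -> StudyData:
    """Generate one full synthetic study, fully deterministic given the seed.

    Returns one Recording per subject x condition x bout, the planted
    ground truth, and behavioral records correlated with the planted
    delta-band network state.
    """
    config.validate()
    eff = config.effect_specs
    n_ch = len(config.channels)
    n_edges_max = n_ch * (n_ch - 1) // 2
    band_names = [b.name for b in config.band_specs]

    recordings: dict = {}
    coupling_truth: dict = {}
    amp_truth: dict = {}
    artifact_truth: dict = {}
    behavior: list[BehavioralRecord] = []

    for si, subject in enumerate(config.subjects):
        rng_subject = np.random.default_rng(np.random.SeedSequence([config.seed, 11, si]))
        W_base = _base_coupling(config, rng_subject)

        # per-(condition, bout) uniforms shared across effect magnitudes
        # (common random numbers: monotone response to the planted g)
        u_cluster = {
            (c, b): rng_subject.random() for c in config.conditions for b in config.bouts
        }
        u_power = {
            (c, b, band): rng_subject.random()
            for c in config.conditions
            for b in config.bouts
            for band in band_names
        }

        for ci, condition in enumerate(config.conditions):
            for bi, bout in enumerate(config.bouts):
                key = (subject, condition, bout)
                if key in recordings:
                    raise ValueError(f"duplicate subject/condition/bout key {key}")
                drop = _planted_drop(
                    eff.clustering.get((condition, bout), 0.0),
                    eff.drop_scale,
                    eff.subject_sd,
                    u_cluster[(condition, bout)],
                )
                scale = max(1.0 - drop, 0.02)

                rng_rec = np.random.default_rng(
                    np.random.SeedSequence([config.seed, 23, si, ci, bi])
                )
                total = np.zeros((n_ch, int(round(config.epoch_duration * config.sampling_rate))))
                for spec in config.band_specs:
                    override = config.coupling_overrides.get((condition, bout, spec.name))
                    if override is not None:
                        W_true = np.asarray(override, dtype=float)
                    elif spec.name == eff.clustering_band:
                        W_true = np.clip(W_base * scale, 0.0, 1.0)
                    else:
                        W_true = W_base
                    coupling_truth[(subject, condition, bout, spec.name)] = W_true

                    amp_drop = _planted_drop(
                        eff.power.get((condition, bout, spec.name), 0.0),
                        eff.power_drop_scale,
                        eff.power_subject_sd,
                        u_power[(condition, bout, spec.name)],
                    )
                    amp = spec.amplitude_uv * max(1.0 - amp_drop, 0.05)
                    amp_truth[(subject, condition, bout, spec.name)] = amp

                    scaled_spec = BandSpec(spec.name, spec.f_low, spec.f_high, amp)
                    sources = generate_latent_sources(
                        [scaled_spec],
                        2 * n_edges_max + n_ch,
                        config.epoch_duration,
                        config.sampling_rate,
                        rng_rec,
                    )[spec.name]
                    total += mix_to_channels(
                        sources,
                        W_true,
                        n_ch,
                        phase_lag=config.phase_lag,
                        noise_spec=None,
                        private_amplitude_frac=config.private_amplitude_frac,
                        edge_gain=config.edge_gain,
                    )
                if config.noise_spec.amplitude_uv > 0:
                    total += pink_noise(
                        total.shape, config.noise_spec.exponent,
                        config.noise_spec.amplitude_uv, rng_rec,
                    )
                total, spans = inject_artifacts(
                    total, config.artifact_spec, config.sampling_rate, rng_rec
                )
                artifact_truth[key] = spans
                recordings[key] = Recording(
                    list(config.channels),
                    config.sampling_rate,
                    total,
                    {"subject": subject, "condition": condition, "bout": bout},
                )

                behavior.append(
                    _behavioral_record(config, subject, condition, bout, coupling_truth, rng_rec)
                )

    truth = GroundTruth(coupling_truth, amp_truth, artifact_truth)
    return StudyData(recordings, truth, behavior, config)


def _behavioral_record(config, subject, condition, bout, coupling_truth, rng) -> BehavioralRecord:
    """KSS and PVT series as linear functions of the planted network state."""
    eff = config.effect_specs
    band = eff.clustering_band if eff.clustering_band in {b.name for b in config.band_specs} \
        else config.band_specs[0].name
    c_bl, _ = clustering_coefficients(coupling_truth[(subject, condition, "BL", band)])
    c_now, _ = clustering_coefficients(coupling_truth[(subject, condition, bout, band)])
    drop = float(c_bl.mean() - c_now.mean())  # >= 0 when coupling weakened
    k = config.behavior_coupling
    kss = int(np.clip(round(3.0 + k * 80.0 * drop + rng.normal(0.0, 0.8)), 1, 9))
    mean_rt = 240.0 + k * 1500.0 * drop + rng.normal(0.0, 12.0)
    mean_rt = max(mean_rt, 150.0)
    rts = mean_rt * rng.lognormal(0.0, 0.22, size=config.n_pvt_trials)
    return BehavioralRecord(subject, condition, bout, kss, rts)


def delta_probe_config(seed: int, effects: bool = True, n_channels: int = 8) -> SyntheticStudyConfig:
    """Scaled-down two-bout delta-band study for power and recovery checks.

    11 subjects, ``n_channels`` electrodes at 250 Hz, 60-s epochs, baseline
    and first post-awakening bout under the control condition only, with
    the default planted delta clustering reduction (or none when
    ``effects`` is False).  This is the replicate unit used to verify that
    the pipeline detects the planted effect at the intended rate.
    """
    eff = EffectSpec() if effects else EffectSpec(clustering={}, power={})
    return SyntheticStudyConfig(
        n_subjects=11,
        channels=list(CHANNELS_32[:n_channels]),
        sampling_rate=250.0,
        epoch_duration=60.0,
        bouts=("BL", "T1"),
        conditions=("control",),
        band_specs=(BandSpec("delta", 1.0, 3.0, 30.0),),
        effect_specs=eff,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# persistence


def write_study(study: StudyData, outdir: str | Path, fmt: str = "matrix") -> Path:
    """Write a generated study to disk.

    Recordings go to ``recordings/`` as delimited matrices or BrainVision
    triplets; ground-truth coupling matrices, artifact spans and behavioral
    records as delimited tables; the config as YAML.
    """
    import pandas as pd
    import yaml

    outdir = Path(outdir)
    (outdir / "recordings").mkdir(parents=True, exist_ok=True)
    (outdir / "ground_truth").mkdir(exist_ok=True)

    manifest = []
    for (subject, condition, bout), rec in sorted(study.recordings.items()):
        stem = f"{subject}_{condition}_{bout}"
        if fmt == "matrix":
            path = outdir / "recordings" / f"{stem}.tsv"
            write_matrix(rec, path)
        elif fmt == "brainvision":
            path = outdir / "recordings" / f"{stem}.vhdr"
            write_brainvision(rec, path)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        manifest.append(
            {"path": str(path.relative_to(outdir)), "subject": subject,
             "condition": condition, "bout": bout}
        )
    pd.DataFrame(manifest).to_csv(outdir / "manifest.tsv", sep="\t", index=False)

    rows = []
    for (subject, condition, bout, band), W in sorted(study.ground_truth.coupling.items()):
        np.savetxt(
            outdir / "ground_truth" / f"coupling_{subject}_{condition}_{bout}_{band}.tsv",
            W, fmt="%.10g", delimiter="\t",
        )
        rows.append(
            {"subject": subject, "condition": condition, "bout": bout, "band": band,
             "amplitude_uv": study.ground_truth.amplitudes[(subject, condition, bout, band)]}
        )
    pd.DataFrame(rows).to_csv(outdir / "ground_truth" / "amplitudes.tsv", sep="\t", index=False)

    art_rows = [
        {"subject": s, "condition": c, "bout": b, "start_sample": start, "n_samples": n}
        for (s, c, b), spans in sorted(study.ground_truth.artifacts.items())
        for start, n in spans
    ]
    pd.DataFrame(art_rows, columns=["subject", "condition", "bout", "start_sample", "n_samples"]) \
        .to_csv(outdir / "ground_truth" / "artifacts.tsv", sep="\t", index=False)

    beh_rows = [
        {"subject": r.subject, "condition": r.condition, "bout": r.bout, "kss": r.kss,
         "rt_series_ms": ";".join(f"{v:.6g}" for v in r.rt_series_ms)}
        for r in study.behavior
    ]
    pd.DataFrame(beh_rows).to_csv(outdir / "behavior.tsv", sep="\t", index=False)

    cfg = asdict(study.config)
    cfg["coupling_overrides"] = {
        "|".join(k): np.asarray(v).tolist() for k, v in cfg["coupling_overrides"].items()
    }
    cfg["effect_specs"]["clustering"] = {
        "|".join(k): v for k, v in cfg["effect_specs"]["clustering"].items()
    }
    cfg["effect_specs"]["power"] = {
        "|".join(k): v for k, v in cfg["effect_specs"]["power"].items()
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return outdir
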