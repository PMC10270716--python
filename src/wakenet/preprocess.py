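"""Filtering and artifact cleaning.

The preprocessing chain mirrors standard practice for post-awakening EEG:
a third-order zero-phase Butterworth band-pass (0.5-50 Hz), construction of
a clean reference signal from low-amplitude segments, and a simplified
subspace cleaner that clamps high-variance excursions against the reference
statistics in short windows.  The cleaner targets artifact suppression in
the spirit of artifact subspace reconstruction (ASR); it is a fixed-window
principal-axis clamp, not a re-implementation of any particular ASR tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal


from .bands import BandDefinition
from .io import Recording


@lru_cache(maxsize=256)
def butter_sos(order: int, f_low: float, f_high: float, fs: float) -> np.ndarray:
    """Cached second-order-section band-pass Butterworth design."""
    return signal.butter(order, [f_low, f_high], btype="bandpass", fs=fs, output="sos")


class NoReferenceError(RuntimeError):
    """No segment qualifies for the clean reference signal."""


@dataclass
class ReferenceSignal:
    """Concatenated clean EEG used to calibrate the subspace cleaner.

    ``segments`` records the provenance of each contributing run as
    (start_sample, end_sample) half-open indices into the source recording.
    """

    data: np.ndarray  # channels x samples, microvolts
    channel_sd: np.ndarray  # per-channel standard deviation
    segments: list[tuple[int, int]]
    sampling_rate: float


def bandpass_filter(recording: Recording, f_low: float, f_high: float, order: int = 3) -> Recording:
    """Zero-phase Butterworth band-pass.

    The filter is designed at ``order`` and applied forward-backward
    (``sosfiltfilt``), so the effective magnitude response is the squared
    one-pass response and the phase response is zero.  Output length equals
    input length.
    """
    nyq = recording.nyquist
    if not (0 < f_low < f_high < nyq):
        raise ValueError(
            f"invalid band [{f_low}, {f_high}] Hz for sampling rate {recording.sampling_rate} Hz"
        )
    sos = butter_sos(order, f_low, f_high, recording.sampling_rate)
    filtered = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return recording.copy_with(filtered)


def build_reference_signal(
    recording: Recording,
    min_segment_ms: float = 1000.0,
    amp_threshold_uv: float = 100.0,
) -> ReferenceSignal:
    """Concatenate low-amplitude segments into a clean reference.

    A sample qualifies when *every* channel is strictly below
    ``amp_threshold_uv`` in absolute value; maximal runs of qualifying
    samples at least ``min_segment_ms`` long are concatenated in temporal
    order.  Raises :class:`NoReferenceError` when no run is long enough
    (the caller may then relax the threshold).
    """
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    clean = np.all(np.abs(recording.data) < amp_threshold_uv, axis=0)
    min_len = int(np.ceil(min_segment_ms / 1000.0 * recording.sampling_rate))

    segments: list[tuple[int, int]] = []
    # run-length encode the clean mask
    edges = np.flatnonzero(np.diff(clean.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [clean.size]))
    for s, e in zip(starts, ends):
        if clean[s] and (e - s) >= min_len:
            segments.append((int(s), int(e)))
    if not segments:
        raise NoReferenceError(
            f"no segment of >= {min_segment_ms:g} ms stays below {amp_threshold_uv:g} uV on all channels"
        )
    data = np.concatenate([recording.data[:, s:e] for s, e in segments], axis=1)
    return ReferenceSignal(
        data=data,
        channel_sd=data.std(axis=1, ddof=0),
        segments=segments,
        sampling_rate=recording.sampling_rate,
    )


def asr_clean(
    recording: Recording,
    reference: ReferenceSignal,
    window_ms: float = 500.0,
    k_sd: float = 5.0,
) -> Recording:
    """Clamp high-variance subspace excursions against the reference.

    The reference covariance defines principal axes and a per-axis RMS.
    The recording is processed in non-overlapping ``window_ms`` windows
    (last partial window as-is): each window is projected onto the
    reference axes, and any component whose windowed RMS exceeds
    ``k_sd`` x the reference RMS along that axis is attenuated down to that
    threshold before reconstruction.  Windows with no component over
    threshold pass through bit-identically.  The clamp only ever reduces
    per-axis RMS, never raises it.
    """
    if reference.data.shape[0] != recording.n_channels:
        raise ValueError("reference channel count does not match recording")
    win = int(round(window_ms / 1000.0 * recording.sampling_rate))
    if win < 1 or win > recording.n_samples:
        raise ValueError(
            f"window of {window_ms:g} ms ({win} samples) invalid for a "
            f"{recording.n_samples}-sample recording"
        )

    ref = reference.data - reference.data.mean(axis=1, keepdims=True)
    cov = ref @ ref.T / ref.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    ref_rms = np.sqrt(np.clip(eigval, 0.0, None))
    # guard rank-deficient references: a silent axis gets a tiny floor so
    # any signal along it is flagged rather than divided by zero
    floor = max(ref_rms.max(), 1e-12) * 1e-9
    threshold = k_sd * np.maximum(ref_rms, floor)

    out = recording.data.copy()
    for start in range(0, recording.n_samples, win):
        chunk = out[:, start : start + win]
        comps = eigvec.T @ chunk
        rms = np.sqrt(np.mean(comps**2, axis=1))
        over = rms > threshold
        if not np.any(over):
            continue
        scale = np.ones_like(rms)
        scale[over] = threshold[over] / rms[over]
        out[:, start : start + win] = eigvec @ (comps * scale[:, None])
    if not np.all(np.isfinite(out)):
        raise RuntimeError("non-finite samples after cleaning")
    return recording.copy_with(out)


def band_decompose(
    recording: Recording,
    band_definitions: tuple[BandDefinition, ...] | list[BandDefinition],
    order: int = 3,
) -> dict[str, Recording]:
    """Band-pass the (cleaned) recording into one copy per band."""
    out: dict[str, Recording] = {}
    for band in band_definitions:
        band.validate(recording.nyquist)
        out[band.name] = bandpass_filter(recording, band.f_low, band.f_high, order=order)
    return out
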