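"""Weighted phase lag index (wPLI) functional connectivity.

For each channel pair the per-sample imaginary cross-spectrum of the
analytic (Hilbert) signals is accumulated over the whole band-filtered
epoch:

    wPLI(i, j) = | sum_t Im(z_i,t conj(z_j,t)) | / sum_t | Im(z_i,t conj(z_j,t)) |

The index lives in [0, 1], ignores zero-lag (volume-conduction-like)
coupling by construction, and weights each sample by the magnitude of its
imaginary component.  Pairs whose denominator vanishes (for example exactly
zero-lag copies) are assigned 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import Recording


@dataclass
class ConnectivityMatrix:
    """Symmetric per-band wPLI weights with zero diagonal, entries in [0, 1]."""

    weights: np.ndarray
    channel_labels: list[str]
    band: str | None = None
    metadata: dict = field(default_factory=dict)
    n_samples: int = 0

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        validate_weights(W)
        self.weights = W

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


def validate_weights(W: np.ndarray) -> None:
    """Check symmetry, zero diagonal, and the [0, 1] range."""
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {W.shape}")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("weight matrix is not symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("weight matrix diagonal must be zero")
    if np.any(W < 0) or np.any(W > 1):
        raise ValueError("weights must lie in [0, 1]")


def analytic_signal(band_recording: Recording) -> np.ndarray:
    """Complex analytic representation (channels x samples) via Hilbert transform.

    The real part equals the input; instantaneous phase and amplitude are
    defined per sample.
    """
    if not np.all(np.isfinite(band_recording.data)):
        raise ValueError("recording contains non-finite samples")
    return signal.hilbert(band_recording.data, axis=-1)


#: a pair is degenerate when the summed |imaginary cross-spectrum| is this
#: small relative to the summed cross-amplitude |z_i||z_j| (catches exact
#: zero-lag copies despite floating-point residue in the complex product)
_DEGENERATE_RTOL = 1e-9


def wpli_pair(z_i: np.ndarray, z_j: np.ndarray) -> float:
    """wPLI of one analytic-signal pair; 0 when the denominator vanishes."""
    imag = np.imag(z_i * np.conj(z_j))
    denom = np.abs(imag).sum()
    scale = (np.abs(z_i) * np.abs(z_j)).sum()
    if denom <= _DEGENERATE_RTOL * scale:
        return 0.0
    # |sum| <= sum|.| mathematically; clip the floating-point residue
    return float(min(abs(imag.sum()) / denom, 1.0))


def wpli_matrix(
    band_recording: Recording,
    edge_trim_s: float = 2.0,
    band: str | None = None,
    segment_s: float | None = None,
) -> ConnectivityMatrix:
    """Pairwise wPLI over a band-filtered epoch.

    ``edge_trim_s`` seconds are discarded at each end before accumulation to
    suppress filter and Hilbert edge artifacts.  By default the index is
    accumulated over the whole trimmed epoch; with ``segment_s`` set, it is
    computed per non-overlapping segment of that length (partial trailing
    segment dropped) and the segment values averaged.  Degenerate pairs
    (zero denominator) are assigned 0 with a warning.
    """
    n = band_recording.n_channels
    if n < 2:
        raise ValueError("wPLI needs at least 2 channels")
    trim = int(round(edge_trim_s * band_recording.sampling_rate))
    if band_recording.n_samples - 2 * trim <= 0:
        raise ValueError(
            f"edge trim of {edge_trim_s:g} s leaves no usable samples in a "
            f"{band_recording.duration:g} s epoch"
        )
    z = analytic_signal(band_recording)
    if trim:
        z = z[:, trim:-trim]

    if segment_s is None:
        chunks = [z]
    else:
        seg = int(round(segment_s * band_recording.sampling_rate))
        if seg < 1 or seg > z.shape[1]:
            raise ValueError(f"segment of {segment_s:g} s invalid for the trimmed epoch")
        chunks = [z[:, k : k + seg] for k in range(0, z.shape[1] - seg + 1, seg)]

    W = np.zeros((n, n))
    degenerate = 0
    for i in range(n):
        vals = np.zeros(n - i - 1)
        for chunk in chunks:
            imag = np.imag(chunk[i][None, :] * np.conj(chunk[i + 1 :]))
            num = np.abs(imag.sum(axis=1))
            den = np.abs(imag).sum(axis=1)
            scale = (np.abs(chunk[i][None, :]) * np.abs(chunk[i + 1 :])).sum(axis=1)
            ok = den > _DEGENERATE_RTOL * scale
            degenerate += int(np.sum(~ok))
            vals += np.where(ok, num / np.where(ok, den, 1.0), 0.0)
        vals /= len(chunks)
        W[i, i + 1 :] = vals
        W[i + 1 :, i] = vals
    if degenerate:
        warnings.warn(f"{degenerate} channel pair(s) had zero imaginary cross-spectrum; wPLI set to 0")
    np.clip(W, 0.0, 1.0, out=W)
    return ConnectivityMatrix(
        W,
        list(band_recording.channel_labels),
        band=band,
        metadata=dict(band_recording.metadata),
        n_samples=z.shape[1],
    )
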