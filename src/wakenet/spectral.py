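"""Spectral power estimation and standardization.

Power spectral density is estimated with Welch's average modified
periodogram (4-s Hann windows, 50% overlap by default), log-transformed,
and z-scored per electrode across the entire frequency grid (0 to Nyquist).
Band power is the mean standardized value over a band's grid points, and
*global power* is the scalp average of the per-channel band powers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BandDefinition
from .io import Recording


@dataclass
class PSDMatrix:
    """Per-channel power spectral density on a common frequency grid.

    ``values`` is channels x frequencies; raw values are in uV^2/Hz, and
    after :func:`standardize_psd` they are per-channel z-scores of the
    log10 PSD (dimensionless).
    """

    frequencies: np.ndarray
    values: np.ndarray
    channel_labels: list[str]
    standardized: bool = False
    metadata: dict = field(default_factory=dict)


def welch_psd(recording: Recording, window_s: float = 4.0, overlap_frac: float = 0.5) -> PSDMatrix:
    """Welch PSD per channel, grid spanning 0 to Nyquist."""
    nperseg = int(round(window_s * recording.sampling_rate))
    if nperseg > recording.n_samples:
        raise ValueError(
            f"Welch window of {window_s:g} s exceeds the {recording.duration:g} s recording"
        )
    if not (0 <= overlap_frac < 1):
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    freqs, psd = signal.welch(
        recording.data,
        fs=recording.sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap_frac * nperseg)),
        axis=-1,
    )
    return PSDMatrix(freqs, psd, list(recording.channel_labels), standardized=False,
                     metadata=dict(recording.metadata))


def standardize_psd(psd: PSDMatrix) -> PSDMatrix:
    """log10-transform then z-score each channel across the full grid.

    Standardizing an already-standardized matrix is a no-op up to floating
    tolerance (the rows are refit to themselves without a second log).
    """
    if psd.standardized:
        vals = psd.values
    else:
        if np.any(psd.values <= 0):
            raise ValueError("PSD contains non-positive values; log10 undefined")
        vals = np.log10(psd.values)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("a channel has zero spectral variance; cannot standardize")
    return PSDMatrix(psd.frequencies.copy(), (vals - mu) / sd, list(psd.channel_labels),
                     standardized=True, metadata=dict(psd.metadata))


@dataclass
class BandPowerTable:
    """Tidy per-channel standardized band power with derived global power.

    ``channel_table`` columns: subject, condition, bout, band, channel, power.
    ``global_power()`` recomputes the scalp average exactly from the
    channel rows.
    """

    channel_table: pd.DataFrame

    def global_power(self) -> pd.DataFrame:
        keys = ["subject", "condition", "bout", "band"]
        out = (
            self.channel_table.groupby(keys, sort=False, dropna=False)["power"]
            .mean()
            .reset_index()
            .rename(columns={"power": "global_power"})
        )
        return out


def band_power(
    psd: PSDMatrix,
    band_definitions: tuple[BandDefinition, ...] | list[BandDefinition],
) -> BandPowerTable:
    """Average the standardized PSD over each band's grid points.

    Band membership is the closed interval f_low <= f <= f_high on the grid;
    a band capturing no grid point is a configuration error.
    """
    if not psd.standardized:
        raise ValueError("band_power expects a standardized PSD (run standardize_psd first)")
    meta = psd.metadata
    rows = []
    for band in band_definitions:
        mask = (psd.frequencies >= band.f_low) & (psd.frequencies <= band.f_high)
        if not np.any(mask):
            raise ValueError(f"band {band.name!r} contains no frequency grid point")
        means = psd.values[:, mask].mean(axis=1)
        for label, value in zip(psd.channel_labels, means):
            rows.append(
                {
                    "subject": meta.get("subject"),
                    "condition": meta.get("condition"),
                    "bout": meta.get("bout"),
                    "band": band.name,
                    "channel": label,
                    "power": value,
                }
            )
    return BandPowerTable(pd.DataFrame(rows))
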