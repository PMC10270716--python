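"""Reading and writing EEG containers.

Two on-disk forms are supported:

* BrainVision-dialect triplets (``.vhdr`` INI header, ``.vmrk`` marker file,
  multiplexed binary ``.eeg``) with 16-bit-integer-plus-resolution or
  IEEE-float-32 samples, the acquisition format of 32-channel
  BrainVision caps sampled at 500 Hz;
* a plain delimited numeric matrix, one row per channel, as a fallback.

All in-memory data are channels x samples in microvolts.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class FormatError(ValueError):
    """A container file violates the expected on-disk format."""


@dataclass
class Recording:
    """A labeled multichannel EEG time series.

    Attributes
    ----------
    channel_labels : ordered electrode names (10-20 positions in practice).
    sampling_rate : sampling frequency in Hz.
    data : float array, shape (n_channels, n_samples), in microvolts.
    metadata : free-form study keys; the pipeline uses ``subject``,
        ``condition`` and ``bout``.
    """

    channel_labels: list[str]
    sampling_rate: float
    data: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels but {self.data.shape[0]} data rows"
            )
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(list(self.channel_labels), self.sampling_rate, data, dict(self.metadata))


_BINARY_DTYPES = {"INT_16": np.int16, "IEEE_FLOAT_32": np.float32}


def write_brainvision(
    recording: Recording,
    header_path: str | Path,
    binary_format: str = "IEEE_FLOAT_32",
    resolution_uv: float = 0.1,
) -> Path:
    """Write a Recording as a BrainVision-dialect .vhdr/.vmrk/.eeg triplet.

    ``resolution_uv`` is the per-channel scaling applied to INT_16 data
    (stored integer x resolution = microvolts); it is recorded in the header
    for float data too but floats are stored in microvolts directly.
    """
    if binary_format not in _BINARY_DTYPES:
        raise FormatError(f"unsupported BinaryFormat {binary_format!r}")
    header_path = Path(header_path)
    stem = header_path.with_suffix("")
    eeg_path = stem.with_suffix(".eeg")
    vmrk_path = stem.with_suffix(".vmrk")

    interval_us = 1e6 / recording.sampling_rate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by wakenet",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={recording.n_channels}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    res = resolution_uv if binary_format == "INT_16" else 1.0
    for i, label in enumerate(recording.channel_labels, start=1):
        lines.append(f"Ch{i}={label},,{res:g},µV")
    header_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    vmrk_path.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg_path.name}\n\n"
        "[Marker Infos]\n"
        f"Mk1=New Segment,,1,1,0\n",
        encoding="utf-8",
    )

    if binary_format == "INT_16":
        scaled = np.round(recording.data / res)
        if np.abs(scaled).max(initial=0) > np.iinfo(np.int16).max:
            raise FormatError("data exceed INT_16 range at the requested resolution")
        raw = scaled.astype(np.int16)
    else:
        raw = recording.data.astype(np.float32)
    # multiplexed: sample-major interleaving of channels
    raw.T.tofile(eeg_path)
    return header_path


def _require(section: configparser.SectionProxy, key: str, header: Path):
    if key not in section:
        raise FormatError(f"{header.name}: missing required field {key!r} in [{section.name}]")
    return section[key]


def read_brainvision(header_path: str | Path) -> Recording:
    """Read a BrainVision-dialect triplet into a Recording (microvolts).

    Supports BINARY/MULTIPLEXED data in INT_16 (with per-channel resolution
    applied) or IEEE_FLOAT_32. Raises :class:`FormatError` naming the
    offending header field for malformed input.
    """
    header_path = Path(header_path)
    parser = configparser.ConfigParser(strict=False, interpolation=None)
    text = header_path.read_text(encoding="utf-8", errors="replace")
    # drop the magic first line and comments, which are not INI
    body = "\n".join(l for l in text.splitlines() if not l.startswith(("Brain Vision", ";")))
    parser.read_string(body)

    if "Common Infos" not in parser:
        raise FormatError(f"{header_path.name}: missing [Common Infos] section")
    common = parser["Common Infos"]
    data_file = _require(common, "DataFile", header_path)
    eeg_path = header_path.parent / data_file
    if not eeg_path.exists():
        raise FormatError(f"{header_path.name}: DataFile {data_file!r} does not exist")
    marker = common.get("MarkerFile")
    if marker and not (header_path.parent / marker).exists():
        raise FormatError(f"{header_path.name}: MarkerFile {marker!r} does not exist")
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise FormatError(f"{header_path.name}: unsupported DataFormat {common.get('DataFormat')!r}")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise FormatError(
            f"{header_path.name}: unsupported DataOrientation {common.get('DataOrientation')!r}"
        )
    n_channels = int(_require(common, "NumberOfChannels", header_path))
    interval_us = float(_require(common, "SamplingInterval", header_path))
    sampling_rate = 1e6 / interval_us

    if "Binary Infos" not in parser:
        raise FormatError(f"{header_path.name}: missing [Binary Infos] section")
    binary_format = parser["Binary Infos"].get("BinaryFormat", "INT_16").upper()
    if binary_format not in _BINARY_DTYPES:
        raise FormatError(f"{header_path.name}: unsupported BinaryFormat {binary_format!r}")

    if "Channel Infos" not in parser:
        raise FormatError(f"{header_path.name}: missing [Channel Infos] section")
    chsec = parser["Channel Infos"]
    labels: list[str] = []
    resolutions: list[float] = []
    for i in range(1, n_channels + 1):
        key = f"Ch{i}"
        if key not in chsec:
            raise FormatError(
                f"{header_path.name}: NumberOfChannels={n_channels} but {key!r} missing "
                "from [Channel Infos]"
            )
        parts = chsec[key].split(",")
        labels.append(parts[0])
        res_str = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res_str))

    raw = np.fromfile(eeg_path, dtype=_BINARY_DTYPES[binary_format])
    if raw.size % n_channels != 0:
        raise FormatError(
            f"{eeg_path.name}: {raw.size} samples not divisible by NumberOfChannels={n_channels}"
        )
    data = raw.reshape(-1, n_channels).T.astype(float)
    if binary_format == "INT_16":
        data *= np.asarray(resolutions)[:, None]
    return Recording(labels, sampling_rate, data)


def write_matrix(recording: Recording, path: str | Path, delimiter: str = "\t") -> Path:
    """Write the data matrix as delimited text, one row per channel."""
    path = Path(path)
    np.savetxt(path, recording.data, fmt="%.10g", delimiter=delimiter)
    return path


def read_matrix(
    path: str | Path,
    sampling_rate: float,
    labels: list[str] | None = None,
    delimiter: str | None = None,
    metadata: dict | None = None,
) -> Recording:
    """Read a plain delimited numeric matrix (rows = channels) into a Recording.

    Ragged or empty tables raise :class:`FormatError`.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(delimiter) if delimiter else line.replace(",", " ").split()
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: non-numeric value ({exc})") from None
    if not rows:
        raise FormatError(f"{path.name}: empty matrix file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path.name}: ragged rows (widths {sorted(widths)})")
    data = np.asarray(rows, dtype=float)
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    return Recording(list(labels), sampling_rate, data, dict(metadata or {}))
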