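"""Frequency-band definitions.

The analysis operates on four classical EEG bands; the gaps between them
(3-4, 7-8, 12-15 Hz) are deliberately unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named closed frequency interval [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def validate(self, nyquist: float | None = None) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(f"band {self.name!r}: need 0 < f_low < f_high, got [{self.f_low}, {self.f_high}]")
        if nyquist is not None and self.f_high >= nyquist:
            raise ValueError(f"band {self.name!r}: f_high {self.f_high} Hz >= Nyquist {nyquist} Hz")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 3.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 15.0, 25.0),
)
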