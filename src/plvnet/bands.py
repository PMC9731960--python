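"""Canonical frequency-band definitions.

The five bands used throughout the pipeline follow the standard clinical
EEG convention: delta 1-4 Hz, theta 4-8 Hz, alpha 8-12 Hz, beta 12-30 Hz,
gamma 30-45 Hz.  Adjacent bands share an edge; the edges are treated as the
half-power (-3 dB) corner frequencies of the Butterworth designs used for
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """One frequency band: a name and its lower/upper edge in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got lo={self.lo}, hi={self.hi}"
            )

    def validate_against_fs(self, fs: float) -> None:
        """Raise if the band does not fit below the Nyquist frequency."""
        if self.hi >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.hi} Hz is at or above "
                f"Nyquist ({fs / 2} Hz for fs={fs} Hz)"
            )


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 30.0),
    BandSpec("gamma", 30.0, 45.0),
)

BAND_INDEX: dict[str, int] = {b.name: i for i, b in enumerate(DEFAULT_BANDS)}
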