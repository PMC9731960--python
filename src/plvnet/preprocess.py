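"""Signal conditioning: re-referencing, broadband filtering, epoching, rejection.

The chain mirrors standard resting-state practice: common-average reference,
a linear-phase 0.5-45 Hz band-pass, segmentation into fixed-length
non-overlapping epochs, and rejection of epochs whose peak amplitude exceeds
a threshold.  The amplitude criterion is a deterministic stand-in for manual
artifact inspection; 100 uV is the conventional default and it is
configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


class PreprocessError(ValueError):
    pass


@dataclass
class Recording:
    """A continuous multichannel recording: channel x sample matrix plus fs."""

    data: np.ndarray  # (n_channels, n_samples), float
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise PreprocessError("recording data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise PreprocessError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise PreprocessError("recording contains non-finite samples")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise PreprocessError("channel label count does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Fixed-length epochs: epoch x channel x sample tensor."""

    data: np.ndarray  # (n_epochs, n_channels, epoch_samples)
    fs: float
    epoch_samples: int
    kept_epoch_indices: list[int]
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel.

    After the operation the column (per-sample) mean is zero; applying it
    twice is identical to applying it once.
    """
    if rec.n_channels < 2:
        raise PreprocessError("common-average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(data, rec.fs, list(rec.channel_labels))


def design_broadband_fir(fs: float, lo: float = 0.5, hi: float = 45.0) -> np.ndarray:
    """Odd-length Hamming-window band-pass FIR, length ~3.3*fs/lo."""
    if not (0 < lo < hi):
        raise PreprocessError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= fs / 2:
        raise PreprocessError(
            f"upper edge {hi} Hz at or above Nyquist ({fs / 2} Hz)"
        )
    numtaps = int(round(3.3 * fs / lo))
    if numtaps % 2 == 0:
        numtaps += 1
    return sps.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def broadband_filter(rec: Recording, lo: float = 0.5, hi: float = 45.0) -> Recording:
    """Linear-phase band-pass with zero net delay.

    The symmetric FIR kernel is applied centred (overlap-add convolution with
    ``mode='same'``), i.e. a forward application with the group delay
    compensated exactly; no phase distortion is introduced.
    """
    taps = design_broadband_fir(rec.fs, lo, hi)
    data = sps.oaconvolve(rec.data, taps[None, :], mode="same", axes=1)
    return Recording(data, rec.fs, list(rec.channel_labels))


def segment_epochs(rec: Recording, epoch_samples: int) -> EpochSet:
    """Cut the recording into consecutive non-overlapping epochs.

    The trailing remainder shorter than one epoch is discarded.  A recording
    shorter than one epoch yields zero epochs with a warning.
    """
    if epoch_samples < 2:
        raise PreprocessError("epoch_samples must be >= 2")
    n_epochs = rec.n_samples // epoch_samples
    if n_epochs == 0:
        warnings.warn(
            f"recording of {rec.n_samples} samples is shorter than one epoch "
            f"({epoch_samples} samples); zero epochs produced",
            stacklevel=2,
        )
    used = rec.data[:, : n_epochs * epoch_samples]
    data = used.reshape(rec.n_channels, n_epochs, epoch_samples).transpose(1, 0, 2)
    return EpochSet(
        np.ascontiguousarray(data),
        rec.fs,
        epoch_samples,
        list(range(n_epochs)),
        list(rec.channel_labels),
    )


def reject_epochs(epochs: EpochSet, amplitude_threshold: float = 100.0) -> EpochSet:
    """Drop epochs whose peak absolute amplitude on any channel exceeds threshold."""
    if amplitude_threshold <= 0:
        raise PreprocessError("amplitude threshold must be positive")
    if epochs.n_epochs == 0:
        raise PreprocessError("no epochs to screen")
    peaks = np.abs(epochs.data).max(axis=(1, 2))
    keep = peaks <= amplitude_threshold
    if not keep.any():
        raise PreprocessError(
            "all epochs exceed the amplitude threshold; no data to analyze"
        )
    kept_idx = [epochs.kept_epoch_indices[i] for i in np.flatnonzero(keep)]
    return EpochSet(
        epochs.data[keep],
        epochs.fs,
        epochs.epoch_samples,
        kept_idx,
        list(epochs.channel_labels),
    )


def preprocess_recording(
    rec: Recording,
    epoch_samples: int,
    lo: float = 0.5,
    hi: float = 45.0,
    amplitude_threshold: float = 100.0,
    reference: bool = True,
) -> EpochSet:
    """Full conditioning chain: reference -> filter -> epoch -> reject."""
    if reference:
        rec = common_average_reference(rec)
    rec = broadband_filter(rec, lo, hi)
    epochs = segment_epochs(rec, epoch_samples)
    return reject_epochs(epochs, amplitude_threshold)
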