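"""Band-pass filtering, 5-s epoching, and per-channel artifact rejection.

Two rejection rules operate on per-epoch band power, each applied to every
channel independently:

* EMG rule: an epoch is rejected when its 26-50 Hz power exceeds four times
  the moving median of that power over a 3-minute (36-epoch) window centred
  on the epoch (truncated at recording edges).
* Movement rule: an epoch is rejected when its 4-50 Hz power exceeds six
  times the whole-night median for that channel (median taken over *all*
  epochs, before any rejection).

Both comparisons are strict ("exceeds" means strictly greater), so an epoch
sitting exactly at the threshold is kept.  The EMG rule runs first; epochs
it removes remain in the movement rule's median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

EPOCH_SECONDS = 5.0

#: channels eligible for analysis entry (standard 10-20 subset)
ANALYSIS_CHANNELS = ("F3", "F4", "C3", "C4", "T3", "T4", "P3", "P4", "O1", "O2")

# rejection_reason codes
REASON_NONE = 0
REASON_EMG = 1
REASON_MOVEMENT = 2
REASON_LABELS = {REASON_NONE: "none", REASON_EMG: "emg", REASON_MOVEMENT: "movement"}

EMG_BAND = (26.0, 50.0)
MOVEMENT_BAND = (4.0, 50.0)
EMG_FACTOR = 4.0
MOVEMENT_FACTOR = 6.0
EMG_WINDOW_EPOCHS = 36  # 3 min of 5-s epochs


@dataclass
class Recording:
    """One subject-night of multichannel EEG in microvolts.

    ``samples`` is a (channels, time) array; ``channel_labels`` gives the
    row order.  Signals are assumed already referenced (linked mastoids).
    """

    subject_id: str
    night: int
    fs: float
    channel_labels: list[str]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length must match samples rows")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    def require_analysis_channels(self) -> None:
        bad = [c for c in self.channel_labels if c not in ANALYSIS_CHANNELS]
        if bad:
            raise ValueError(
                f"channels outside the analysis montage: {bad}; "
                f"allowed: {list(ANALYSIS_CHANNELS)}"
            )


@dataclass
class EpochGrid:
    """Per-channel 5-s epoch spectra and rejection masks for one recording.

    ``spectra`` holds the Hann-windowed one-sided rFFT of each epoch,
    shape (n_channels, n_epochs, n_bins); band powers are derived from it
    with periodogram (PSD) scaling.  ``keep_mask`` is True for retained
    epochs; ``rejection_reason`` records why an epoch was dropped.
    """

    subject_id: str
    night: int
    fs: float
    channel_labels: list[str]
    spectra: np.ndarray
    freqs: np.ndarray
    keep_mask: np.ndarray
    rejection_reason: np.ndarray
    epoch_length: float = EPOCH_SECONDS
    psd_scale: float = 1.0
    _band_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_epochs(self) -> int:
        return self.spectra.shape[1]

    @property
    def n_channels(self) -> int:
        return self.spectra.shape[0]

    def band_bins(self, low: float, high: float) -> np.ndarray:
        """Indices of frequency bins in the half-open band [low, high)."""
        return np.flatnonzero((self.freqs >= low) & (self.freqs < high))

    def band_power(self, low: float, high: float) -> np.ndarray:
        """Mean PSD over [low, high) per channel and epoch, shape (n_ch, n_ep)."""
        key = (low, high)
        if key not in self._band_cache:
            bins = self.band_bins(low, high)
            if bins.size == 0:
                raise ValueError(f"band [{low}, {high}) contains no frequency bins")
            psd = self.psd_scale * np.abs(self.spectra[:, :, bins]) ** 2
            # one-sided doubling except DC and Nyquist
            double = (self.freqs[bins] > 0) & (self.freqs[bins] < self.fs / 2)
            psd[:, :, double] *= 2.0
            self._band_cache[key] = psd.mean(axis=2)
        return self._band_cache[key]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in grid") from None


def bandpass(rec: Recording, low: float = 0.5, high: float = 50.0) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward).

    Zero-phase application means no group delay, so 5-s epoch boundaries
    align before and after filtering.
    """
    nyq = rec.fs / 2.0
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist ({nyq} Hz)")
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return Recording(
        subject_id=rec.subject_id,
        night=rec.night,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        samples=filtered,
    )


def segment_epochs(rec: Recording) -> EpochGrid:
    """Cut a recording into 5-s epochs and compute per-epoch spectra.

    A trailing partial epoch is discarded.  Each epoch is Hann-windowed and
    Fourier transformed once; all band powers and cross-spectra downstream
    derive from these coefficients (0.2 Hz bin spacing at 5 s).
    """
    n_per = int(round(EPOCH_SECONDS * rec.fs))
    if abs(EPOCH_SECONDS * rec.fs - n_per) > 1e-9:
        raise ValueError("fs times epoch length must be an integer sample count")
    n_samples = rec.samples.shape[1]
    n_epochs = n_samples // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {n_samples / rec.fs:.3f} s is shorter than one "
            f"{EPOCH_SECONDS:.0f}-s epoch"
        )
    x = rec.samples[:, : n_epochs * n_per].reshape(rec.samples.shape[0], n_epochs, n_per)
    window = signal.get_window("hann", n_per)
    spectra = np.fft.rfft(x * window, axis=2)
    freqs = np.fft.rfftfreq(n_per, d=1.0 / rec.fs)
    psd_scale = 1.0 / (rec.fs * np.sum(window**2))
    n_ch = rec.samples.shape[0]
    return EpochGrid(
        subject_id=rec.subject_id,
        night=rec.night,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        spectra=spectra,
        freqs=freqs,
        keep_mask=np.ones((n_ch, n_epochs), dtype=bool),
        rejection_reason=np.full((n_ch, n_epochs), REASON_NONE, dtype=np.uint8),
        psd_scale=psd_scale,
    )


def _moving_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving median with truncated (not padded) edge windows.

    For an even window w the span is [e - w//2, e + w//2), which contains
    the epoch itself.
    """
    n = values.shape[-1]
    half = window // 2
    out = np.empty_like(values, dtype=np.float64)
    for e in range(n):
        lo = max(0, e - half)
        hi = min(n, e + half)
        out[..., e] = np.median(values[..., lo:hi], axis=-1)
    return out


def reject_emg(grid: EpochGrid) -> EpochGrid:
    """Reject transient high-frequency (muscle) epochs.

    Per channel, epoch e is rejected iff its 26-50 Hz power strictly
    exceeds 4x the 3-minute moving median at e.  Already-rejected epochs
    stay rejected.
    """
    power = grid.band_power(*EMG_BAND)
    med = _moving_median(power, EMG_WINDOW_EPOCHS)
    bad = power > EMG_FACTOR * med
    newly = bad & grid.keep_mask
    grid.rejection_reason[newly] = REASON_EMG
    grid.keep_mask &= ~bad
    return grid


def reject_movement(grid: EpochGrid) -> EpochGrid:
    """Reject body/head-movement epochs.

    Per channel, epoch e is rejected iff its 4-50 Hz power strictly exceeds
    6x the whole-night median of that channel.  The median is computed over
    all epochs, including any already rejected by the EMG rule.
    """
    power = grid.band_power(*MOVEMENT_BAND)
    med = np.median(power, axis=1, keepdims=True)
    bad = power > MOVEMENT_FACTOR * med
    newly = bad & grid.keep_mask
    grid.rejection_reason[newly] = REASON_MOVEMENT
    grid.keep_mask &= ~bad
    return grid


def preprocess_recording(
    rec: Recording, low: float = 0.5, high: float = 50.0
) -> EpochGrid:
    """Full preprocessing chain: band-pass, epoch, EMG rule, movement rule."""
    rec.require_analysis_channels()
    grid = segment_epochs(bandpass(rec, low, high))
    grid = reject_emg(grid)
    grid = reject_movement(grid)
    return grid


def rejection_summary(grid: EpochGrid) -> dict[str, float]:
    """Fraction of epochs rejected per channel (for logging)."""
    frac = 1.0 - grid.keep_mask.mean(axis=1)
    return {ch: float(f) for ch, f in zip(grid.channel_labels, frac)}
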