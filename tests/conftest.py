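"""Shared fixtures: small constructed recordings and epoch grids."""

from __future__ import annotations

import numpy as np
import pytest

from stagefree.preprocessing import (
    REASON_NONE,
    EpochGrid,
    Recording,
    segment_epochs,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_recording(
    samples: np.ndarray,
    fs: float = 250.0,
    channels: list[str] | None = None,
    subject_id: str = "S001",
    night: int = 1,
) -> Recording:
    channels = channels or [f"C{i}" for i in range(samples.shape[0])]
    return Recording(
        subject_id=subject_id, night=night, fs=fs, channel_labels=channels, samples=samples
    )


def sine_recording(
    freq: float, duration: float = 60.0, fs: float = 250.0, amp: float = 50.0
) -> Recording:
    t = np.arange(int(duration * fs)) / fs
    return make_recording(amp * np.sin(2 * np.pi * freq * t)[None, :], fs=fs, channels=["C3"])


def noise_recording(
    rng: np.random.Generator,
    n_channels: int = 2,
    duration: float = 60.0,
    fs: float = 250.0,
) -> Recording:
    x = rng.standard_normal((n_channels, int(duration * fs)))
    return make_recording(x, fs=fs)


def grid_with_powers(
    emg_powers: np.ndarray | None = None, movement_powers: np.ndarray | None = None
) -> EpochGrid:
    """EpochGrid whose rejection-band powers are set directly (the spectra
    are placeholders); lets rule tests control the inputs exactly."""
    ref = emg_powers if emg_powers is not None else movement_powers
    arr = np.atleast_2d(np.asarray(ref, dtype=float))
    n_ch, n_ep = arr.shape
    grid = EpochGrid(
        subject_id="S001",
        night=1,
        fs=250.0,
        channel_labels=[f"C{i}" for i in range(n_ch)],
        spectra=np.zeros((n_ch, n_ep, 4), dtype=complex),
        freqs=np.array([0.0, 10.0, 30.0, 40.0]),
        keep_mask=np.ones((n_ch, n_ep), dtype=bool),
        rejection_reason=np.full((n_ch, n_ep), REASON_NONE, dtype=np.uint8),
    )
    if emg_powers is not None:
        grid._band_cache[(26.0, 50.0)] = np.atleast_2d(np.asarray(emg_powers, dtype=float))
    if movement_powers is not None:
        grid._band_cache[(4.0, 50.0)] = np.atleast_2d(np.asarray(movement_powers, dtype=float))
    return grid


@pytest.fixture
def white_noise_grid(rng) -> EpochGrid:
    return segment_epochs(noise_recording(rng, n_channels=3, duration=120.0))
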