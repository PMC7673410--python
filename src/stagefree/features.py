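"""Stage-independent whole-night spectral features: LP, LCV and WPLI.

Three feature families are computed from the artifact-free 5-s epochs of a
night, ignoring sleep stages:

* ``LP``  — mean over kept epochs of the natural-log band power of one
  channel in one band.
* ``LCV`` — coefficient of variation (sample SD / mean) of the same
  per-epoch log-power series.
* ``W``   — weighted phase lag index between a pair of channels in one
  band: ``|sum Im S_ij| / sum |Im S_ij|`` pooled over all jointly kept
  epochs and all frequency bins inside the band, where ``S_ij`` is the
  epoch cross-spectrum.  W lies in [0, 1]; 1 is perfect phase-lagged
  synchrony, 0 no consistent lag.

With 10 channels and the 12 canonical bands this yields
120 + 120 + 45x12 = 780 features per subject-night.  Feature names follow
the grammar ``<LP|LCV|W>-<channel[-channel2]>-<band>``, e.g. ``LP-C3-Lδ``
or ``W-C3-F3-Hβ`` (channel pairs list the lexicographically first channel
first).

Band edges are half-open [low, high): a bin at exactly 10 Hz belongs to
Hα, not Lα.  Logs are natural throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import EpochGrid

#: the 12 canonical bands spanning 0.5-40 Hz (name, low, high); contiguous
#: and non-overlapping, interpreted half-open [low, high).
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("SO", 0.5, 1.0),
    ("Lδ", 1.0, 2.0),
    ("Hδ", 2.0, 4.0),
    ("Lθ", 4.0, 6.0),
    ("Hθ", 6.0, 8.0),
    ("Lα", 8.0, 10.0),
    ("Hα", 10.0, 12.0),
    ("Lσ", 12.0, 14.0),
    ("Hσ", 14.0, 16.0),
    ("Lβ", 16.0, 24.0),
    ("Hβ", 24.0, 32.0),
    ("Lγ", 32.0, 40.0),
)

MISSING = float("nan")


@dataclass(frozen=True)
class BandSet:
    """Ordered, contiguous, non-overlapping frequency bands."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        prev_high = None
        for name, low, high in self.bands:
            if low >= high:
                raise ValueError(f"band {name}: low must be < high")
            if prev_high is not None and not math.isclose(low, prev_high):
                raise ValueError(f"band {name}: bands must be contiguous")
            prev_high = high

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def edges(self, name: str) -> tuple[float, float]:
        for n, low, high in self.bands:
            if n == name:
                return low, high
        raise KeyError(f"unknown band {name!r}")


def format_feature_name(kind: str, channels: tuple[str, ...], band: str) -> str:
    if kind not in ("LP", "LCV", "W"):
        raise ValueError(f"unknown feature kind {kind!r}")
    if kind == "W":
        if len(channels) != 2:
            raise ValueError("W features need a channel pair")
        channels = tuple(sorted(channels))
    elif len(channels) != 1:
        raise ValueError(f"{kind} features need exactly one channel")
    return "-".join([kind, *channels, band])


def parse_feature_name(name: str) -> tuple[str, tuple[str, ...], str]:
    """Inverse of :func:`format_feature_name`; round-trips all 780 names."""
    parts = name.split("-")
    kind = parts[0]
    if kind == "W":
        if len(parts) != 4:
            raise ValueError(f"malformed W feature name {name!r}")
        return kind, (parts[1], parts[2]), parts[3]
    if kind in ("LP", "LCV"):
        if len(parts) != 3:
            raise ValueError(f"malformed {kind} feature name {name!r}")
        return kind, (parts[1],), parts[2]
    raise ValueError(f"unknown feature kind in {name!r}")


def feature_names(channels: list[str], bandset: BandSet | None = None) -> list[str]:
    """Enumerate all feature names: LP, LCV per channel-band, then W per pair-band."""
    bandset = bandset or BandSet()
    names: list[str] = []
    for kind in ("LP", "LCV"):
        for ch in channels:
            for band in bandset.names:
                names.append(format_feature_name(kind, (ch,), band))
    for ch_i, ch_j in itertools.combinations(sorted(channels), 2):
        for band in bandset.names:
            names.append(format_feature_name("W", (ch_i, ch_j), band))
    return names


def expected_feature_count(n_channels: int, n_bands: int) -> int:
    """C*B (LP) + C*B (LCV) + C(C-1)/2*B (W)."""
    return 2 * n_channels * n_bands + n_channels * (n_channels - 1) // 2 * n_bands


def epoch_log_band_power(grid: EpochGrid, channel: str, band: tuple[float, float]) -> np.ndarray:
    """Natural-log band power per *kept* epoch of one channel.

    Raises if the channel has no kept epochs (empty-channel condition).
    """
    ci = grid.channel_index(channel)
    kept = grid.keep_mask[ci]
    if not kept.any():
        raise ValueError(f"channel {channel}: no kept epochs")
    power = grid.band_power(*band)[ci, kept]
    return np.log(power)


def lp_feature(series: np.ndarray) -> float:
    """Whole-night mean of the per-epoch log band power."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        return MISSING
    return float(series.mean())


def lcv_feature(series: np.ndarray) -> float:
    """Coefficient of variation (sample SD / mean) of the log-power series."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        return MISSING
    mean = series.mean()
    if mean == 0.0:
        return MISSING
    if series.size < 2:
        return 0.0
    return float(series.std(ddof=1) / mean)


def wpli_from_imag(imag: np.ndarray) -> float:
    """Weighted phase lag index from pooled imaginary cross-spectrum values.

    ``|sum(imag)| / sum(|imag|)``; missing (NaN) when the denominator is 0.
    """
    imag = np.asarray(imag, dtype=float)
    denom = np.abs(imag).sum()
    if denom == 0.0:
        return MISSING
    return float(abs(imag.sum()) / denom)


def wpli(grid: EpochGrid, channel_i: str, channel_j: str, band: tuple[float, float]) -> float:
    """WPLI between two channels over one band.

    Pools all frequency bins in the half-open band across all epochs kept
    in *both* channels' masks into a single ratio of sums.  Symmetric in
    channel order.
    """
    ci = grid.channel_index(channel_i)
    cj = grid.channel_index(channel_j)
    joint = grid.keep_mask[ci] & grid.keep_mask[cj]
    if not joint.any():
        return MISSING
    bins = grid.band_bins(*band)
    xi = grid.spectra[ci][joint][:, bins]
    xj = grid.spectra[cj][joint][:, bins]
    return wpli_from_imag(np.imag(xi * np.conj(xj)))


def compute_features(grid: EpochGrid, bandset: BandSet | None = None) -> dict[str, float]:
    """All LP/LCV/W features for one subject-night, keyed by feature name."""
    bandset = bandset or BandSet()
    out: dict[str, float] = {}
    # per-channel log-power series per band, reused by LP and LCV
    for ch in grid.channel_labels:
        for band_name in bandset.names:
            series = epoch_log_band_power(grid, ch, bandset.edges(band_name))
            out[format_feature_name("LP", (ch,), band_name)] = lp_feature(series)
            out[format_feature_name("LCV", (ch,), band_name)] = lcv_feature(series)
    for ch_i, ch_j in itertools.combinations(sorted(grid.channel_labels), 2):
        for band_name in bandset.names:
            out[format_feature_name("W", (ch_i, ch_j), band_name)] = wpli(
                grid, ch_i, ch_j, bandset.edges(band_name)
            )
    return out


METADATA_COLUMNS = ["subject_id", "night", "group", "age", "split"]


def assemble_features(
    grids: list[EpochGrid],
    meta: pd.DataFrame,
    bandset: BandSet | None = None,
    required_channels: list[str] | None = None,
) -> pd.DataFrame:
    """Build the feature table: one row per subject-night, 780 named columns.

    ``meta`` must have columns subject_id, group, age, split (one row per
    subject).  Fails loudly, listing absent channels, if any grid is
    missing a required channel.
    """
    bandset = bandset or BandSet()
    meta = meta.set_index("subject_id")
    rows = []
    for grid in grids:
        if required_channels is not None:
            absent = sorted(set(required_channels) - set(grid.channel_labels))
            if absent:
                raise ValueError(
                    f"{grid.subject_id} night {grid.night}: missing channels {absent}"
                )
        m = meta.loc[grid.subject_id]
        row = {
            "subject_id": grid.subject_id,
            "night": grid.night,
            "group": m["group"],
            "age": m["age"],
            "split": m["split"],
        }
        row.update(compute_features(grid, bandset))
        rows.append(row)
    table = pd.DataFrame(rows)
    return table.sort_values(["subject_id", "night"]).reset_index(drop=True)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature (non-metadata) column names of a feature table."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def synchrony_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in feature_columns(table) if c.startswith("W-")]
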