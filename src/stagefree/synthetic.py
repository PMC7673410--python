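"""Synthetic two-night EEG cohorts with the statistical structure the
analysis pipeline assumes.

Two tiers share one :class:`CohortConfig`:

* :func:`simulate_cohort` synthesises signal-level recordings: per band,
  band-limited Gaussian processes per channel; cross-channel phase
  coupling injected by adding a shared band-limited source to both
  channels of designated pairs with a quarter-cycle delay at band centre
  (guaranteeing a nonzero imaginary cross-spectrum, hence WPLI
  sensitivity); PTSD subjects get a multiplicative reduction of 1-4 Hz
  power and elevated alpha/gamma coupling; a per-subject random effect
  shared across nights produces the target night-to-night concordance;
  artifact epochs carry 26-50 Hz bursts (EMG rule) or large broadband
  power (movement rule).

* :func:`simulate_feature_table` skips signal synthesis and emits the
  780-column feature table directly (group effects, age slopes,
  between-night correlation, Gaussian noise), for testing the
  feature-level pipeline stages in milliseconds.  Synchrony (W) columns
  are a logistic transform of a latent Gaussian so they land in (0, 1) as
  the conditioning stage requires; effects are applied on the latent
  scale (a monotone map, so AUC-based behaviour is unchanged).

Same config and seed give byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import expit

from .features import BandSet, feature_names, parse_feature_name
from .preprocessing import ANALYSIS_CHANNELS, EPOCH_SECONDS, Recording

DELTA_BANDS = ("Lδ", "Hδ")
ALPHA_BANDS = ("Lα", "Hα")
GAMMA_BANDS = ("Lγ",)

#: between-subject SD of log band power (natural-log units); standardized
#: group effects are expressed in multiples of this
LOG_POWER_SD = 0.3
#: between-subject SD of log coupling strength
LOG_COUPLING_SD = 0.3
#: baseline shared-source amplitude as a fraction of band amplitude
BASE_COUPLING = 0.6


@dataclass
class CohortConfig:
    """Study-design parameters for synthetic cohorts.

    Defaults mirror the study design: 31 PTSD / 47 control combat-exposed
    Veteran men, two consecutive nights, 10 channels at 250 Hz, ages
    24-51, the consecutive-subject train/test split.  ``duration``
    defaults to the 600-s test scale (120 epochs); full-scale 28800 s is
    supported.  Effect sizes are standardized (multiples of the
    between-subject SD); ``effect_delta_power`` negative means lower
    delta power in PTSD.
    """

    n_ptsd: int = 31
    n_control: int = 47
    n_nights: int = 2
    duration: float = 600.0
    fs: float = 250.0
    channels: tuple[str, ...] = ANALYSIS_CHANNELS
    effect_delta_power: float = -0.8
    effect_alpha_sync: float = 0.8
    effect_gamma_sync: float = 0.8
    age_range: tuple[float, float] = (24.0, 51.0)
    age_effect_bands: dict = field(
        default_factory=lambda: {"SO": -0.02, "Lδ": -0.02, "Hδ": -0.015}
    )
    night_consistency: float = 0.85
    artifact_rate: float = 0.02
    train_fraction: float = 0.6
    coupling_pairs: tuple[tuple[str, str], ...] = (
        ("C4", "P3"),
        ("C4", "F3"),
        ("C3", "P4"),
        ("C3", "F4"),
    )
    planted_effects: dict = field(default_factory=dict)
    planted_age_slopes: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ptsd <= 0 or self.n_control <= 0 or self.n_nights <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 < self.night_consistency <= 1.0:
            raise ValueError("night_consistency must be in (0, 1]")
        if abs(self.fs * self.duration - round(self.fs * self.duration)) > 1e-9:
            raise ValueError("fs x duration must be an integer number of samples")
        if abs(self.duration / EPOCH_SECONDS - round(self.duration / EPOCH_SECONDS)) > 1e-9:
            raise ValueError(
                f"duration ({self.duration} s) must be a multiple of the "
                f"{EPOCH_SECONDS:.0f}-s epoch length"
            )
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must be in [0, 1)")

    @property
    def n_subjects(self) -> int:
        return self.n_ptsd + self.n_control

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration / EPOCH_SECONDS))

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["channels"] = list(payload["channels"])
        payload["coupling_pairs"] = [list(p) for p in payload["coupling_pairs"]]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class SubjectMeta:
    subject_id: str
    group: str  # "PTSD" | "control"
    age: float
    split: str  # "train" | "test"


def _group_sequence(n_ptsd: int, n_control: int) -> list[str]:
    """Deterministic proportional interleave, so the consecutive-subject
    split contains both classes in roughly the cohort ratio."""
    n = n_ptsd + n_control
    seq = []
    for i in range(n):
        if (i + 1) * n_ptsd // n > i * n_ptsd // n:
            seq.append("PTSD")
        else:
            seq.append("control")
    return seq


def make_metadata(config: CohortConfig, rng: np.random.Generator) -> list[SubjectMeta]:
    groups = _group_sequence(config.n_ptsd, config.n_control)
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=len(groups))
    n_train = math.ceil(config.train_fraction * len(groups))
    metas = []
    for i, g in enumerate(groups):
        metas.append(
            SubjectMeta(
                subject_id=f"S{i + 1:03d}",
                group=g,
                age=float(np.round(ages[i], 1)),
                split="train" if i < n_train else "test",
            )
        )
    return metas


def metadata_frame(metas: list[SubjectMeta]) -> pd.DataFrame:
    return pd.DataFrame([asdict(m) for m in metas])


# ---------------------------------------------------------------------------
# signal tier


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [low, high]."""
    sos = sps.butter(4, [low, min(high, fs / 2 * 0.99)], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _band_amplitude(low: float, high: float) -> float:
    """Baseline RMS (microvolts) per band; 1/f-like so delta dominates."""
    fc = math.sqrt(low * high)
    return 30.0 / fc**0.6


def simulate_cohort(config: CohortConfig) -> tuple[list[Recording], list[SubjectMeta]]:
    """Signal-level cohort: one Recording per subject-night.

    Signals are sums of per-band band-limited Gaussian processes.  The
    per-subject log-amplitude random effect (shared across nights, with a
    night-specific remainder sized by ``night_consistency``) carries the
    group, age, and test-retest structure into the downstream features.
    """
    rng = np.random.default_rng(config.seed)
    metas = make_metadata(config, rng)
    bandset = BandSet()
    channels = list(config.channels)
    n_samp = int(round(config.fs * config.duration))
    n_per_epoch = int(round(EPOCH_SECONDS * config.fs))
    rho = config.night_consistency
    age_mid = sum(config.age_range) / 2.0

    coupled_bands = set(ALPHA_BANDS) | set(GAMMA_BANDS)
    recordings: list[Recording] = []
    for meta in metas:
        is_ptsd = meta.group == "PTSD"
        # per-subject random effects, shared across nights
        eta_power = rng.normal(0.0, LOG_POWER_SD * math.sqrt(rho), size=len(bandset.bands))
        eta_coupling = rng.normal(
            0.0, LOG_COUPLING_SD * math.sqrt(rho), size=(len(config.coupling_pairs), len(bandset.bands))
        )
        for night in range(1, config.n_nights + 1):
            nu_power = rng.normal(
                0.0, LOG_POWER_SD * math.sqrt(1.0 - rho), size=len(bandset.bands)
            )
            nu_coupling = rng.normal(
                0.0,
                LOG_COUPLING_SD * math.sqrt(1.0 - rho),
                size=(len(config.coupling_pairs), len(bandset.bands)),
            )
            x = np.zeros((len(channels), n_samp))
            for bi, (band, low, high) in enumerate(bandset.bands):
                log_shift = eta_power[bi] + nu_power[bi]
                if band in config.age_effect_bands:
                    log_shift += config.age_effect_bands[band] * (meta.age - age_mid)
                if is_ptsd and band in DELTA_BANDS:
                    log_shift += config.effect_delta_power * LOG_POWER_SD
                amp = _band_amplitude(low, high) * math.exp(log_shift / 2.0)
                for ci in range(len(channels)):
                    x[ci] += amp * _band_noise(rng, n_samp, config.fs, low, high)
                if band in coupled_bands:
                    sync_effect = (
                        config.effect_alpha_sync if band in ALPHA_BANDS else config.effect_gamma_sync
                    )
                    fc = math.sqrt(low * high)
                    delay = max(1, int(round(config.fs / (4.0 * fc))))
                    for pi, (ch_i, ch_j) in enumerate(config.coupling_pairs):
                        if ch_i not in channels or ch_j not in channels:
                            continue
                        kappa = BASE_COUPLING * math.exp(
                            eta_coupling[pi, bi]
                            + nu_coupling[pi, bi]
                            + (sync_effect * LOG_COUPLING_SD if is_ptsd else 0.0)
                        )
                        src = amp * kappa * _band_noise(rng, n_samp, config.fs, low, high)
                        x[channels.index(ch_i)] += src
                        x[channels.index(ch_j)] += np.roll(src, delay)
            # artifact epochs
            n_epochs = n_samp // n_per_epoch
            if config.artifact_rate > 0:
                contaminated = rng.random(n_epochs) < config.artifact_rate
                kinds = rng.random(n_epochs) < 0.5  # True: EMG burst, False: movement
                ch_rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
                for e in np.flatnonzero(contaminated):
                    sl = slice(e * n_per_epoch, (e + 1) * n_per_epoch)
                    if kinds[e]:
                        hit = rng.choice(len(channels), size=3, replace=False)
                        for ci in hit:
                            burst = _band_noise(rng, n_per_epoch, config.fs, 26.0, 49.9)
                            x[ci, sl] += 6.0 * ch_rms[ci, 0] * burst
                    else:
                        for ci in range(len(channels)):
                            lurch = _band_noise(rng, n_per_epoch, config.fs, 4.0, 49.9)
                            x[ci, sl] += 8.0 * ch_rms[ci, 0] * lurch
            recordings.append(
                Recording(
                    subject_id=meta.subject_id,
                    night=night,
                    fs=config.fs,
                    channel_labels=channels,
                    samples=x,
                )
            )
    return recordings, metas


# ---------------------------------------------------------------------------
# feature-table tier


def _latent_effect(name: str, config: CohortConfig) -> float:
    """Standardized PTSD shift on a feature's latent scale.

    Delta-power reduction applies to every channel; synchrony elevation
    only to the designated coupling pairs, mirroring the signal tier.
    """
    if name in config.planted_effects:
        return float(config.planted_effects[name])
    kind, channels, band = parse_feature_name(name)
    if kind == "LP" and band in DELTA_BANDS:
        return config.effect_delta_power
    if kind == "W":
        coupled = {tuple(sorted(p)) for p in config.coupling_pairs}
        if tuple(sorted(channels)) in coupled:
            if band in ALPHA_BANDS:
                return config.effect_alpha_sync
            if band in GAMMA_BANDS:
                return config.effect_gamma_sync
    return 0.0


def _latent_age_slope(name: str, config: CohortConfig) -> float:
    if config.planted_age_slopes is not None:
        return float(config.planted_age_slopes.get(name, 0.0))
    kind, _, band = parse_feature_name(name)
    if kind == "LP" and band in config.age_effect_bands:
        return float(config.age_effect_bands[band])
    return 0.0


def _latent_baseline(name: str) -> float:
    kind, _, band = parse_feature_name(name)
    if kind == "LP":
        low, high = dict((b, (lo, hi)) for b, lo, hi in BandSet().bands)[band]
        return float(np.log(_band_amplitude(low, high) ** 2))
    if kind == "LCV":
        return 0.15
    return 0.0  # W latent, mapped through a sigmoid


def simulate_feature_table(config: CohortConfig) -> pd.DataFrame:
    """Directly emit a feature table with the configured structure.

    Latent model per feature, subject, night:
    ``mu + effect*1[PTSD] + slope*(age - midpoint) + b_subject + e_night``
    with Var(b) = rho and Var(e) = 1 - rho (unit total noise variance, so
    effects are standardized and the between-night correlation is rho).
    W columns are then mapped through ``expit(0.8*z - 1.5)`` into (0, 1).
    """
    rng = np.random.default_rng(config.seed)
    metas = make_metadata(config, rng)
    names = feature_names(list(config.channels))
    rho = config.night_consistency
    age_mid = sum(config.age_range) / 2.0

    effects = np.array([_latent_effect(n, config) for n in names])
    slopes = np.array([_latent_age_slope(n, config) for n in names])
    baselines = np.array([_latent_baseline(n) for n in names])
    is_w = np.array([n.startswith("W-") for n in names])

    rows = []
    for meta in metas:
        b = rng.normal(0.0, math.sqrt(rho), size=len(names))
        shift = (
            baselines
            + effects * (meta.group == "PTSD")
            + slopes * (meta.age - age_mid)
            + b
        )
        for night in range(1, config.n_nights + 1):
            e = rng.normal(0.0, math.sqrt(1.0 - rho), size=len(names))
            z = shift + e
            vals = np.where(is_w, expit(0.8 * z - 1.5), z)
            row = {
                "subject_id": meta.subject_id,
                "night": night,
                "group": meta.group,
                "age": meta.age,
                "split": meta.split,
            }
            row.update(dict(zip(names, vals)))
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_selection_table(
    n_ptsd: int = 60,
    n_control: int = 90,
    planted: dict | None = None,
    channels: tuple[str, ...] = ANALYSIS_CHANNELS,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature table for planted-support recovery benchmarks.

    Every feature is independent unit-Gaussian observation noise across
    subject-nights (so a null feature's two nightly group-association
    statistics are independent, and the two-night selection rule controls
    false positives at roughly the product of its per-night rates);
    ``planted`` features add the given standardized group shift.  This is
    the benchmark input for the selection -> clustering -> elimination
    stages; it deliberately omits the subject-level stability that real
    whole-night features carry, under which concordant-but-uninformative
    features are statistically indistinguishable from weak true effects
    at cohort scale (see the methods documentation).
    """
    planted = planted or {}
    rng = np.random.default_rng(seed)
    groups = _group_sequence(n_ptsd, n_control)
    names = feature_names(list(channels))
    effects = np.array([float(planted.get(n, 0.0)) for n in names])
    rows = []
    for i, g in enumerate(groups):
        for night in (1, 2):
            vals = rng.standard_normal(len(names)) + effects * (g == "PTSD")
            row = {
                "subject_id": f"S{i + 1:03d}",
                "night": night,
                "group": g,
                "age": 35.0,
                "split": "train",
            }
            row.update(dict(zip(names, vals)))
            rows.append(row)
    return pd.DataFrame(rows)
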