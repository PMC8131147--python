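"""Seeded synthetic EEG + face-feature trials with label-linked structure.

The generator emulates the statistical regularities the pipeline is built
to exploit: arousal drives the relative alpha/beta/theta band powers of a
32-channel EEG (beta dominates at high activation and is amplified over
frontal electrodes; alpha dominates at low activation), while valence
drives the class-conditional mean of a per-frame M x N face-feature
matrix.  Everything is deterministic given (config, trial_seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import montage
from .preprocessing import BANDS, RawEEG

N_LEVELS = 3

#: default absolute band powers (uV^2) per arousal level, (alpha, beta, theta).
#: Beta rises and alpha falls with activation; theta is flat.
DEFAULT_BAND_POWER_MAP: dict[int, tuple[float, float, float]] = {
    0: (40.0, 8.0, 15.0),
    1: (25.0, 25.0, 15.0),
    2: (8.0, 48.0, 15.0),
}


@dataclass(frozen=True)
class EmotionLabel:
    """Discrete 3-level arousal/valence rating of one trial."""

    arousal_level: int
    valence_level: int

    def __post_init__(self) -> None:
        for name, v in (("arousal_level", self.arousal_level),
                        ("valence_level", self.valence_level)):
            if not (isinstance(v, (int, np.integer)) and 0 <= v < N_LEVELS):
                raise ValueError(f"{name} must be an integer in 0..{N_LEVELS - 1}, got {v!r}")


@dataclass
class SynthConfig:
    n_trials: int = 90
    sampling_rate: float = 256.0  # Hz
    trial_duration: float = 2.0  # s
    segment_duration: float = 0.2  # s; 1/T is the face frame rate
    band_power_map: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_POWER_MAP)
    )
    frontal_beta_gain: float = 1.5  # amplitude multiplier on frontal beta
    noise_sd: float = 1.0  # uV white noise
    valence_effect_size: float = 1.0
    face_shape: tuple[int, int] = (16, 32)  # (M keypoints, N descriptor dims)
    n_components_per_band: int = 3  # sinusoids summed per band per channel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.sampling_rate <= 2 * 30.0:
            raise ValueError("sampling_rate must exceed twice the top band edge (30 Hz)")
        if self.frontal_beta_gain < 1.0:
            raise ValueError("frontal_beta_gain must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for lvl, powers in self.band_power_map.items():
            if lvl not in range(N_LEVELS) or len(powers) != 3 or any(p < 0 for p in powers):
                raise ValueError(f"invalid band_power_map entry {lvl}: {powers}")

    @property
    def frames_per_trial(self) -> int:
        return int(np.floor(self.trial_duration / self.segment_duration + 1e-9))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_power_map"] = {str(k): list(v) for k, v in self.band_power_map.items()}
        d["face_shape"] = list(self.face_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        d["band_power_map"] = {int(k): tuple(v) for k, v in d["band_power_map"].items()}
        d["face_shape"] = tuple(d["face_shape"])
        return cls(**d)


def _rng(config: SynthConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng([abs(int(config.seed)) % (2**31), *keys])


def generate_eeg_trial(config: SynthConfig, label: EmotionLabel, trial_seed: int) -> RawEEG:
    """One 32-channel trial whose band powers follow ``band_power_map``.

    Each band contributes a sum of random-phase sinusoids at random
    frequencies inside the band, per channel, scaled so the band variance
    equals the configured power.  Beta amplitude is multiplied by
    ``frontal_beta_gain`` on frontal electrodes.  White Gaussian noise of
    sd ``noise_sd`` uV is added.
    """
    if not isinstance(label, EmotionLabel):
        raise TypeError("label must be an EmotionLabel")
    if label.arousal_level not in config.band_power_map:
        raise ValueError(f"no band_power_map entry for arousal level {label.arousal_level}")
    rng = _rng(config, 1, int(trial_seed))
    n_ch = len(montage.CHANNEL_NAMES)
    L = int(round(config.trial_duration * config.sampling_rate))
    t = np.arange(L) / config.sampling_rate
    alpha_p, beta_p, theta_p = config.band_power_map[label.arousal_level]
    band_powers = {"alpha": alpha_p, "beta": beta_p, "theta": theta_p}
    frontal = montage.frontal_mask()

    x = np.zeros((n_ch, L))
    k = config.n_components_per_band
    for band, p in band_powers.items():
        lo, hi = BANDS[band]
        margin = 0.1 * (hi - lo)  # keep components off the band edges
        freqs = rng.uniform(lo + margin, hi - margin, size=(n_ch, k))
        phases = rng.uniform(0, 2 * np.pi, size=(n_ch, k))
        amp = np.sqrt(2.0 * p / k)  # k sinusoids of amplitude a: var = k a^2 / 2
        comp = amp * np.sin(2 * np.pi * freqs[..., None] * t + phases[..., None])
        comp = comp.sum(axis=1)
        if band == "beta":
            comp[frontal] *= config.frontal_beta_gain
        x += comp
    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, size=x.shape)
    return RawEEG(x, config.sampling_rate)


def generate_face_sequence(
    config: SynthConfig, label: EmotionLabel, trial_seed: int
) -> np.ndarray:
    """Per-frame M x N feature matrices driven by valence.

    Frames are sampled at 1/T (one per EEG segment).  Each frame is the
    valence class's mean pattern (fixed per config seed, scaled by
    ``valence_effect_size``) plus unit-variance Gaussian noise.
    """
    if not isinstance(label, EmotionLabel):
        raise TypeError("label must be an EmotionLabel")
    m, n = config.face_shape
    pattern = _rng(config, 2, label.valence_level).standard_normal((m, n))
    rng = _rng(config, 3, int(trial_seed))
    frames = config.frames_per_trial
    noise = rng.standard_normal((frames, m, n))
    return config.valence_effect_size * pattern[None] + noise


@dataclass
class Trial:
    eeg: RawEEG
    face: np.ndarray  # (frames, M, N)
    label: EmotionLabel
    trial_seed: int


@dataclass
class Dataset:
    trials: list[Trial]
    manifest: pd.DataFrame
    config: SynthConfig

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def arousal(self) -> np.ndarray:
        return np.array([t.label.arousal_level for t in self.trials])

    @property
    def valence(self) -> np.ndarray:
        return np.array([t.label.valence_level for t in self.trials])


def generate_dataset(config: SynthConfig) -> Dataset:
    """Paired (EEG, face, label) trials, round-robin balanced over the
    3 x 3 arousal-valence grid, plus a manifest sufficient for replay."""
    rows = []
    trials = []
    for i in range(config.n_trials):
        cell = i % (N_LEVELS * N_LEVELS)
        label = EmotionLabel(arousal_level=cell // N_LEVELS, valence_level=cell % N_LEVELS)
        eeg = generate_eeg_trial(config, label, trial_seed=i)
        face = generate_face_sequence(config, label, trial_seed=i)
        trials.append(Trial(eeg, face, label, trial_seed=i))
        rows.append(
            {
                "trial": i,
                "trial_seed": i,
                "arousal_level": label.arousal_level,
                "valence_level": label.valence_level,
            }
        )
    manifest = pd.DataFrame(rows)
    return Dataset(trials, manifest, config)


def replay_dataset(manifest: pd.DataFrame, config: SynthConfig) -> Dataset:
    """Regenerate a dataset exactly from its manifest and config."""
    trials = []
    for row in manifest.itertuples(index=False):
        label = EmotionLabel(int(row.arousal_level), int(row.valence_level))
        trials.append(
            Trial(
                generate_eeg_trial(config, label, int(row.trial_seed)),
                generate_face_sequence(config, label, int(row.trial_seed)),
                label,
                int(row.trial_seed),
            )
        )
    return Dataset(trials, manifest.copy(), config)


def save_dataset(dataset: Dataset, outdir: str | Path) -> None:
    """Write per-trial NPZ archives, a labels CSV, and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t in dataset.trials:
        np.savez(
            outdir / f"trial_{t.trial_seed:04d}.npz",
            eeg=t.eeg.samples,
            face=t.face,
            sampling_rate=t.eeg.sampling_rate,
            arousal_level=t.label.arousal_level,
            valence_level=t.label.valence_level,
        )
    dataset.manifest.to_csv(outdir / "labels.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"config": dataset.config.to_dict()}, fh, indent=2)


def load_dataset(indir: str | Path) -> Dataset:
    """Load a dataset written by :func:`save_dataset` (regenerates nothing)."""
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        config = SynthConfig.from_dict(json.load(fh)["config"])
    manifest = pd.read_csv(indir / "labels.csv")
    trials = []
    for row in manifest.itertuples(index=False):
        z = np.load(indir / f"trial_{int(row.trial_seed):04d}.npz")
        label = EmotionLabel(int(row.arousal_level), int(row.valence_level))
        trials.append(
            Trial(RawEEG(z["eeg"], float(z["sampling_rate"])), z["face"], label,
                  int(row.trial_seed))
        )
    return Dataset(trials, manifest, config)
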