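"""Synthetic multi-subject EEG with known class-conditioned band-power structure.

Every recording is a sum of band-limited Gaussian noise processes, one per
frequency band (theta/alpha/beta/gamma), whose per-channel power is the product
of

* a base band power (µV², a fixed rough approximation of resting spectra),
* a class-specific multiplier per scalp region (frontal / central / posterior),
* a subject-specific log-power offset per band,
* a trial-level multiplicative jitter,

plus white baseline noise, all scaled by a per-channel subject gain.  Because
each component is Gaussian noise band-limited by the same filters the feature
stage uses, the Gaussian closed form of differential entropy is approximately
exact on these signals, and band-power ratios between classes are controlled
analytically — which is what makes every downstream stage testable without any
licensed dataset.

The on-disk container is a single HDF5 file::

    /subjects/<id>/trials/<k>   dataset "data" (channels × samples, µV)
                                attrs: fs, label, channel_names, trial_id
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal

from .errors import FormatError, InvalidArgumentError, UnknownMontageError

# --------------------------------------------------------------------------
# Montages
# --------------------------------------------------------------------------

#: 62-channel cap used by the SEED recordings (fits an 8×9 scalp grid).
SEED62_CHANNELS: tuple[str, ...] = (
    "FP1", "FPZ", "FP2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "CB1", "O1", "OZ", "O2", "CB2",
)

#: 32-channel DEAP-like montage (10-20 names as distributed with DEAP).
DEAP32_CHANNELS: tuple[str, ...] = (
    "FP1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "OZ", "PZ",
    "FP2", "AF4", "FZ", "F4", "F8", "FC6", "FC2", "CZ",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

MONTAGES: dict[str, tuple[str, ...]] = {
    "seed62": SEED62_CHANNELS,
    "deap32": DEAP32_CHANNELS,
}

#: Scalp regions used for class band-power signatures, resolved from channel
#: name prefixes (longest prefix wins).
_REGION_PREFIXES = (
    ("FP", "frontal"), ("AF", "frontal"), ("FT", "frontal"), ("FC", "frontal"),
    ("F", "frontal"),
    ("TP", "central"), ("CP", "central"), ("T", "central"), ("C", "central"),
    ("PO", "posterior"), ("P", "posterior"), ("O", "posterior"),
    ("CB", "posterior"),
)

REGIONS = ("frontal", "central", "posterior")


def channel_region(name: str) -> str:
    """Scalp region ('frontal' | 'central' | 'posterior') for a channel name."""
    up = name.upper()
    for prefix, region in sorted(_REGION_PREFIXES, key=lambda p: -len(p[0])):
        if up.startswith(prefix):
            return region
    raise UnknownMontageError(f"cannot assign a scalp region to channel {name!r}")


# --------------------------------------------------------------------------
# Band model shared with the feature stage
# --------------------------------------------------------------------------

#: (name, low_hz, high_hz) — conventional split used throughout the package.
DEFAULT_BAND_EDGES: tuple[tuple[str, float, float], ...] = (
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 45.0),
)

#: Base band power in µV² before class/subject modulation; a coarse stand-in
#: for resting-state spectra (alpha-dominant, power falling with frequency).
BASE_BAND_POWER: dict[str, float] = {
    "theta": 12.0,
    "alpha": 16.0,
    "beta": 8.0,
    "gamma": 4.0,
}


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EmotionClassSpec:
    """A class signature: relative band power per scalp region.

    ``band_power[band][region]`` multiplies the base power of *band* on every
    channel belonging to *region*; entries default to 1.0.  ``jitter_sd`` is
    the standard deviation of the trial-to-trial multiplicative (lognormal)
    power jitter.
    """

    label: str
    band_power: dict[str, dict[str, float]] = field(default_factory=dict)
    jitter_sd: float = 0.15

    def multiplier(self, band: str, region: str) -> float:
        return float(self.band_power.get(band, {}).get(region, 1.0))

    def __post_init__(self) -> None:
        for band, per_region in self.band_power.items():
            for region, mult in per_region.items():
                if mult <= 0:
                    raise InvalidArgumentError(
                        f"class {self.label!r}: multiplier for {band}/{region} "
                        f"must be > 0, got {mult}")
        if self.jitter_sd < 0:
            raise InvalidArgumentError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject gain, baseline noise, and per-band log-power offsets."""

    subject_id: str
    gain: np.ndarray                    # (channels,), unitless, > 0
    baseline_noise_sd: float            # µV
    band_offset: dict[str, float]       # additive offset on log band power

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.gain) <= 0):
            raise InvalidArgumentError("all channel gains must be > 0")
        if self.baseline_noise_sd < 0:
            raise InvalidArgumentError("baseline_noise_sd must be >= 0")


@dataclass(frozen=True)
class RawRecording:
    """One multi-channel EEG trial (µV)."""

    data: np.ndarray                    # (channels, samples)
    fs: float                           # Hz
    channel_names: tuple[str, ...]
    subject_id: str
    label: str
    trial_id: str

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise InvalidArgumentError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channel_names)} channel names")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class DatasetSpec:
    """Full specification of a synthetic dataset; the seed fixes every byte."""

    n_subjects: int = 8
    trials_per_class: int = 20
    classes: tuple[EmotionClassSpec, ...] = ()
    duration_s: float = 60.0
    fs: float = 200.0
    montage: str = "seed62"
    seed: int = 42
    gain_log_sd: float = 0.4
    band_offset_sd: float = 0.8
    baseline_noise_range: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidArgumentError("n_subjects must be >= 2")
        if self.trials_per_class < 1:
            raise InvalidArgumentError("trials_per_class must be >= 1")
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise InvalidArgumentError(f"duplicate class labels: {labels}")
        if self.montage not in MONTAGES:
            raise UnknownMontageError(
                f"unknown montage {self.montage!r}; have {sorted(MONTAGES)}")


def seed_like_classes() -> tuple[EmotionClassSpec, ...]:
    """Three film-clip style classes with distinct region × band signatures.

    Negative emphasises frontal beta/gamma with suppressed posterior alpha;
    positive emphasises posterior alpha and frontal theta; neutral is flat.
    """
    return (
        EmotionClassSpec("negative", {
            "beta": {"frontal": 2.2, "central": 1.5},
            "gamma": {"frontal": 2.5, "central": 1.4},
            "alpha": {"posterior": 0.7},
        }),
        EmotionClassSpec("neutral", {}),
        EmotionClassSpec("positive", {
            "alpha": {"posterior": 2.5, "central": 1.4},
            "theta": {"frontal": 1.6},
            "gamma": {"posterior": 0.8},
        }),
    )


def deap_like_classes() -> tuple[EmotionClassSpec, ...]:
    """Binary valence classes: a continuous pleasantness score thresholded at
    its midpoint collapses to a low/high pair of band-power signatures."""
    return (
        EmotionClassSpec("low_valence", {
            "beta": {"frontal": 2.0},
            "gamma": {"frontal": 2.2},
            "alpha": {"posterior": 0.75},
        }),
        EmotionClassSpec("high_valence", {
            "alpha": {"posterior": 2.2, "central": 1.3},
            "theta": {"frontal": 1.5},
        }),
    )


def default_dataset_spec(**overrides) -> DatasetSpec:
    """The bundled study conditions: 8 subjects × 3 classes × 20 trials."""
    kw = dict(classes=seed_like_classes())
    kw.update(overrides)
    return DatasetSpec(**kw)


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _band_sos(low: float, high: float, fs: float):
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def draw_subject_profiles(spec: DatasetSpec,
                          rng: np.random.Generator) -> list[SubjectProfile]:
    """Reproducibly draw one profile per subject from the spec's priors."""
    channels = MONTAGES[spec.montage]
    lo, hi = spec.baseline_noise_range
    profiles = []
    for i in range(spec.n_subjects):
        gain = np.exp(rng.normal(0.0, spec.gain_log_sd, size=len(channels)))
        noise_sd = float(rng.uniform(lo, hi))
        offsets = {name: float(rng.normal(0.0, spec.band_offset_sd))
                   for name, _, _ in DEFAULT_BAND_EDGES}
        profiles.append(SubjectProfile(f"S{i:02d}", gain, noise_sd, offsets))
    return profiles


def generate_trial(class_spec: EmotionClassSpec,
                   profile: SubjectProfile,
                   duration_s: float,
                   fs: float,
                   seed,
                   montage: str = "seed62",
                   trial_id: str = "trial") -> RawRecording:
    """Synthesize one trial for (class, subject).

    Per band: white Gaussian noise is band-pass filtered, re-normalised to
    unit variance per channel, then scaled so its power equals
    ``BASE_BAND_POWER[band] · class multiplier(band, region) ·
    exp(subject band offset) · trial jitter``.  Bands are summed, white
    baseline noise is added, and the per-channel gain applied last.
    """
    if duration_s <= 0 or fs <= 0:
        raise InvalidArgumentError("duration_s and fs must be positive")
    n = duration_s * fs
    if abs(n - round(n)) > 1e-9:
        raise InvalidArgumentError(
            f"duration_s × fs must be an integer, got {n}")
    n = int(round(n))
    max_edge = max(high for _, _, high in DEFAULT_BAND_EDGES)
    if fs <= 2 * max_edge:
        raise InvalidArgumentError(
            f"fs={fs} must exceed twice the highest band edge ({max_edge} Hz)")
    if montage not in MONTAGES:
        raise UnknownMontageError(
            f"unknown montage {montage!r}; have {sorted(MONTAGES)}")
    channels = MONTAGES[montage]
    if len(profile.gain) != len(channels):
        raise InvalidArgumentError(
            f"profile gain length {len(profile.gain)} != montage size "
            f"{len(channels)}")

    rng = np.random.default_rng(seed)
    regions = [channel_region(c) for c in channels]
    data = np.zeros((len(channels), n))
    # pad so the filter transient never touches the kept segment
    pad = int(2 * fs)
    for band, low, high in DEFAULT_BAND_EDGES:
        sos = _band_sos(low, high, fs)
        raw = rng.standard_normal((len(channels), n + 2 * pad))
        filt = signal.sosfiltfilt(sos, raw, axis=-1)[:, pad:pad + n]
        sd = filt.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        filt = filt / sd
        jitter = np.exp(rng.normal(0.0, class_spec.jitter_sd)) \
            if class_spec.jitter_sd > 0 else 1.0
        power = np.array([
            BASE_BAND_POWER[band]
            * class_spec.multiplier(band, region)
            * np.exp(profile.band_offset.get(band, 0.0))
            * jitter
            for region in regions
        ])
        data += filt * np.sqrt(power)[:, None]
    if profile.baseline_noise_sd > 0:
        data += rng.standard_normal((len(channels), n)) * profile.baseline_noise_sd
    data *= np.asarray(profile.gain)[:, None]
    return RawRecording(data=data, fs=float(fs), channel_names=channels,
                        subject_id=profile.subject_id, label=class_spec.label,
                        trial_id=trial_id)


def generate_dataset(spec: DatasetSpec) -> list[RawRecording]:
    """All ``n_subjects × |classes| × trials_per_class`` trials, reproducibly.

    Profiles and per-trial seeds derive from ``spec.seed`` through a spawned
    ``SeedSequence`` tree, so the whole dataset is a pure function of the spec.
    """
    if not spec.classes:
        raise InvalidArgumentError("DatasetSpec.classes must be non-empty")
    root = np.random.SeedSequence(spec.seed)
    profile_ss, trials_ss = root.spawn(2)
    profiles = draw_subject_profiles(spec, np.random.default_rng(profile_ss))
    n_trials = spec.n_subjects * len(spec.classes) * spec.trials_per_class
    trial_seeds = trials_ss.spawn(n_trials)
    recordings = []
    k = 0
    for profile in profiles:
        for cls in spec.classes:
            for t in range(spec.trials_per_class):
                rec = generate_trial(
                    cls, profile, spec.duration_s, spec.fs, trial_seeds[k],
                    montage=spec.montage,
                    trial_id=f"{profile.subject_id}_{cls.label}_{t:03d}")
                recordings.append(rec)
                k += 1
    return recordings


# --------------------------------------------------------------------------
# HDF5 container
# --------------------------------------------------------------------------

def save_dataset(recordings: list[RawRecording], path) -> None:
    """Write recordings to the package's HDF5 layout (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "eegfusion-dataset-v1"
        subjects = f.create_group("subjects")
        counters: dict[str, int] = {}
        for rec in recordings:
            grp = subjects.require_group(rec.subject_id).require_group("trials")
            k = counters.get(rec.subject_id, 0)
            counters[rec.subject_id] = k + 1
            trial = grp.create_group(f"{k:04d}")
            trial.create_dataset("data", data=rec.data)
            trial.attrs["fs"] = rec.fs
            trial.attrs["label"] = rec.label
            trial.attrs["trial_id"] = rec.trial_id
            trial.attrs["channel_names"] = list(rec.channel_names)


def load_dataset(path) -> list[RawRecording]:
    """Read a dataset container; raises :class:`FormatError` naming any
    missing group or attribute."""
    recordings = []
    with h5py.File(path, "r") as f:
        if "subjects" not in f:
            raise FormatError("container is missing the 'subjects' group")
        for sid in sorted(f["subjects"]):
            subj = f["subjects"][sid]
            if "trials" not in subj:
                raise FormatError(f"subject {sid!r} is missing 'trials'")
            for k in sorted(subj["trials"]):
                trial = subj["trials"][k]
                if "data" not in trial:
                    raise FormatError(f"trial {sid}/{k} is missing 'data'")
                for attr in ("fs", "label", "trial_id", "channel_names"):
                    if attr not in trial.attrs:
                        raise FormatError(
                            f"trial {sid}/{k} is missing attribute {attr!r}")
                names = tuple(
                    n.decode() if isinstance(n, bytes) else str(n)
                    for n in trial.attrs["channel_names"])
                recordings.append(RawRecording(
                    data=trial["data"][()],
                    fs=float(trial.attrs["fs"]),
                    channel_names=names,
                    subject_id=sid,
                    label=str(trial.attrs["label"]),
                    trial_id=str(trial.attrs["trial_id"])))
    return recordings
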