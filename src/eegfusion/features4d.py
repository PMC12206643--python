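"""4D differential-entropy feature organization.

The pipeline turns a multi-channel EEG trial into a sequence of
``(T, 8, 9, 4)`` samples:

1. zero-phase band-pass filtering into theta/alpha/beta/gamma,
2. segmentation into fixed-length windows,
3. per-window, per-band differential entropy (DE) under the Gaussian closed
   form ``DE = ½·ln(2πe·σ²)`` (nats), where σ² is the sample variance of the
   band-filtered window — the standard reading for band-limited EEG,
4. mapping per-channel DE values onto an 8×9 scalp grid (empty cells are 0),
5. stacking T consecutive windows into one 4D sample
   (time step × row × col × band),
6. per-subject z-normalization over all non-structural cells.

Differential entropy of a Gaussian is monotone in variance and shifts by
``ln|a|`` under amplitude scaling ``x → a·x``; both identities are exploited
by the tests and the synthetic generator's class signatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import signal

from .errors import (DegenerateInputError, FormatError, InsufficientWindowsError,
                     InvalidArgumentError, InvalidBandError, MappingError)
from .synthetic_eeg import (DEAP32_CHANNELS, DEFAULT_BAND_EDGES, SEED62_CHANNELS,
                            RawRecording)

# --------------------------------------------------------------------------
# Bands
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise InvalidBandError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"[{self.low_hz}, {self.high_hz}]")

    def validate_for_fs(self, fs: float) -> None:
        if self.high_hz >= fs / 2:
            raise InvalidBandError(
                f"band {self.name!r} upper edge {self.high_hz} Hz >= "
                f"Nyquist {fs / 2} Hz")


def default_bands() -> tuple[BandDefinition, ...]:
    """Theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz."""
    return tuple(BandDefinition(n, lo, hi) for n, lo, hi in DEFAULT_BAND_EDGES)


# --------------------------------------------------------------------------
# Electrode grid
# --------------------------------------------------------------------------

# Shipped 62-channel layout on the 8×9 grid: row 0 is frontal, column 0 the
# left hemisphere; 10 of the 72 cells hold no electrode.  The assignment is a
# package default (documented, overridable), not a published table.
_SEED62_GRID_ROWS: tuple[tuple[str, ...], ...] = (
    ("", "AF3", "", "FP1", "FPZ", "FP2", "", "AF4", ""),
    ("F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8"),
    ("FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8"),
    ("T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8"),
    ("TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8"),
    ("P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8"),
    ("", "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8", ""),
    ("", "", "CB1", "O1", "OZ", "O2", "CB2", "", ""),
)

GRID_SHAPE = (8, 9)


@dataclass(frozen=True)
class ElectrodeGridMap:
    """Injective channel-name → (row, col) assignment on the 8×9 grid."""

    mapping: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[int, int], str] = {}
        for name, (r, c) in self.mapping.items():
            if not (0 <= r < GRID_SHAPE[0] and 0 <= c < GRID_SHAPE[1]):
                raise InvalidArgumentError(
                    f"channel {name!r} cell ({r},{c}) outside the "
                    f"{GRID_SHAPE} grid")
            if (r, c) in seen:
                raise InvalidArgumentError(
                    f"channels {seen[(r, c)]!r} and {name!r} share cell ({r},{c})")
            seen[(r, c)] = name

    def cell(self, name: str) -> tuple[int, int]:
        try:
            return self.mapping[name]
        except KeyError:
            raise MappingError(f"channel {name!r} has no grid cell") from None

    def structural_mask(self) -> np.ndarray:
        """Boolean (8,9) array: True where some electrode lives."""
        mask = np.zeros(GRID_SHAPE, dtype=bool)
        for r, c in self.mapping.values():
            mask[r, c] = True
        return mask


def seed62_grid() -> ElectrodeGridMap:
    mapping = {}
    for r, row in enumerate(_SEED62_GRID_ROWS):
        for c, name in enumerate(row):
            if name:
                mapping[name] = (r, c)
    assert set(mapping) == set(SEED62_CHANNELS)
    return ElectrodeGridMap(mapping)


def deap32_grid() -> ElectrodeGridMap:
    """The DEAP montage occupies the subset of SEED cells with matching names."""
    full = seed62_grid().mapping
    return ElectrodeGridMap({c: full[c] for c in DEAP32_CHANNELS})


def grid_for_montage(montage: str) -> ElectrodeGridMap:
    grids = {"seed62": seed62_grid, "deap32": deap32_grid}
    if montage not in grids:
        raise MappingError(f"no shipped grid for montage {montage!r}")
    return grids[montage]()


# --------------------------------------------------------------------------
# Feature containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DETensor:
    """Per-trial DE values: (windows × channels × bands), nats."""

    values: np.ndarray
    window_s: float
    channel_names: tuple[str, ...]
    band_names: tuple[str, ...]
    subject_id: str
    label: str

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise InvalidArgumentError("DETensor.values must be 3-D")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("DETensor contains non-finite values")


@dataclass(frozen=True)
class Feature4DSample:
    """One model input: (T, 8, 9, n_bands), label and subject attached."""

    tensor: np.ndarray
    label: str
    subject_id: str

    def __post_init__(self) -> None:
        if self.tensor.ndim != 4:
            raise InvalidArgumentError("Feature4DSample.tensor must be 4-D")
        if not np.all(np.isfinite(self.tensor)):
            raise InvalidArgumentError("Feature4DSample contains non-finite values")


@dataclass
class FeatureSet:
    """Stacked 4D samples ready for modelling.

    ``features`` has shape (N, T, 8, 9, n_bands); ``labels`` holds integer
    class indices into ``class_names``; ``structural_mask`` marks grid cells
    backed by an electrode.
    """

    features: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray          # array of subject-id strings
    class_names: tuple[str, ...]
    band_names: tuple[str, ...]
    structural_mask: np.ndarray   # (8, 9) bool

    def __len__(self) -> int:
        return len(self.features)


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def bandpass_filter(recording: RawRecording, band: BandDefinition,
                    order: int = 4) -> RawRecording:
    """Zero-phase (forward-backward) Butterworth band-pass of one recording."""
    band.validate_for_fs(recording.fs)
    sos = signal.butter(order, [band.low_hz, band.high_hz], btype="bandpass",
                        fs=recording.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return replace(recording, data=filtered)


def segment_windows(recording: RawRecording, window_s: float,
                    step_s: float | None = None) -> np.ndarray:
    """Slice a recording into windows.

    Returns an array of shape (n_windows, channels, window_samples) with
    ``n_windows = floor((samples − window)/step) + 1``.
    """
    if step_s is None:
        step_s = window_s
    wlen = window_s * recording.fs
    step = step_s * recording.fs
    if abs(wlen - round(wlen)) > 1e-9 or abs(step - round(step)) > 1e-9:
        raise InvalidArgumentError("window_s and step_s must be integer samples")
    wlen, step = int(round(wlen)), int(round(step))
    if wlen <= 0 or step <= 0:
        raise InvalidArgumentError("window and step must be positive")
    if wlen > recording.n_samples:
        raise InvalidArgumentError(
            f"window of {wlen} samples exceeds recording length "
            f"{recording.n_samples}")
    n_windows = (recording.n_samples - wlen) // step + 1
    starts = np.arange(n_windows) * step
    return np.stack([recording.data[:, s:s + wlen] for s in starts], axis=0)


_DE_EPS = 1e-12
_HALF_LN_2PIE = 0.5 * math.log(2 * math.pi * math.e)


def differential_entropy(window_samples: np.ndarray,
                         eps: float = _DE_EPS) -> float:
    """Gaussian differential entropy ``½·ln(2πe·σ²)`` of one window, in nats.

    σ² is the (population) sample variance.  Strictly increasing in σ² and
    satisfies DE(a·x) = DE(x) + ln|a|.  A constant window is degenerate.
    """
    x = np.asarray(window_samples, dtype=float).ravel()
    if x.size < 2:
        raise InvalidArgumentError("need at least 2 samples for a variance")
    var = float(x.var())
    if var < eps:
        raise DegenerateInputError(
            f"window variance {var:.3g} below guard {eps:.3g}")
    return _HALF_LN_2PIE + 0.5 * math.log(var)


def histogram_entropy(x: np.ndarray, bins: int = 100) -> float:
    """Plug-in Shannon entropy of a histogram density, in nats.

    Test oracle only: discretises the empirical density and computes
    −Σ p·ln p + ln(Δ) so it estimates the *differential* entropy.
    """
    x = np.asarray(x, dtype=float).ravel()
    counts, edges = np.histogram(x, bins=bins)
    widths = np.diff(edges)
    p = counts / counts.sum()
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz] / widths[nz])).sum())


def map_to_grid(values_per_channel: np.ndarray,
                channel_names: tuple[str, ...],
                grid: ElectrodeGridMap) -> np.ndarray:
    """Scatter per-channel values onto the 8×9 grid; empty cells are 0.

    Works on any leading value shape: input (..., channels) → (..., 8, 9).
    """
    values = np.asarray(values_per_channel, dtype=float)
    if values.shape[-1] != len(channel_names):
        raise InvalidArgumentError(
            f"last axis {values.shape[-1]} != {len(channel_names)} channels")
    out = np.zeros(values.shape[:-1] + GRID_SHAPE, dtype=float)
    for i, name in enumerate(channel_names):
        r, c = grid.cell(name)
        out[..., r, c] = values[..., i]
    return out


def compute_de_tensor(recording: RawRecording,
                      bands: tuple[BandDefinition, ...],
                      window_s: float = 1.0,
                      step_s: float | None = None) -> DETensor:
    """Filter → window → DE for one trial: (windows × channels × bands)."""
    per_band = []
    for band in bands:
        filtered = bandpass_filter(recording, band)
        windows = segment_windows(filtered, window_s, step_s)
        var = windows.var(axis=-1)
        if np.any(var < _DE_EPS):
            raise DegenerateInputError(
                f"trial {recording.trial_id}: constant window in band "
                f"{band.name!r}")
        per_band.append(_HALF_LN_2PIE + 0.5 * np.log(var))
    values = np.stack(per_band, axis=-1)
    return DETensor(values=values, window_s=window_s,
                    channel_names=recording.channel_names,
                    band_names=tuple(b.name for b in bands),
                    subject_id=recording.subject_id, label=recording.label)


def assemble_4d(de: DETensor, grid: ElectrodeGridMap, T: int = 6,
                stride: int = 1) -> list[Feature4DSample]:
    """Stack T consecutive windows into (T, 8, 9, n_bands) samples.

    Yields ``floor((windows − T)/stride) + 1`` samples; sample element
    (t, r, c, b) is the DE of window start+t, band b, channel at (r, c).
    """
    n_windows = de.values.shape[0]
    if n_windows < T:
        raise InsufficientWindowsError(
            f"{n_windows} windows < temporal depth T={T}")
    if stride < 1:
        raise InvalidArgumentError("stride must be >= 1")
    grid_values = map_to_grid(
        np.moveaxis(de.values, 1, -1),   # (windows, bands, channels)
        de.channel_names, grid)          # (windows, bands, 8, 9)
    grid_values = np.moveaxis(grid_values, 1, -1)   # (windows, 8, 9, bands)
    samples = []
    for start in range(0, n_windows - T + 1, stride):
        samples.append(Feature4DSample(
            tensor=grid_values[start:start + T].copy(),
            label=de.label, subject_id=de.subject_id))
    return samples


def normalize_per_subject(samples: list[Feature4DSample],
                          mask: np.ndarray) -> list[Feature4DSample]:
    """Z-score each subject's non-structural-zero cells to mean 0, sd 1.

    ``mask`` is the (8,9) structural mask; cells without an electrode stay 0.
    """
    by_subject: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        by_subject.setdefault(s.subject_id, []).append(i)
    out: list[Feature4DSample | None] = [None] * len(samples)
    for sid, idx in by_subject.items():
        if len(idx) < 2:
            raise InvalidArgumentError(
                f"subject {sid!r} has {len(idx)} sample(s); need >= 2")
        stack = np.stack([samples[i].tensor for i in idx])   # (n, T, 8, 9, B)
        cells = stack[:, :, mask, :]
        mean, sd = float(cells.mean()), float(cells.std())
        if sd < 1e-12:
            raise DegenerateInputError(
                f"subject {sid!r} has zero feature variance")
        normed = (stack - mean) / sd
        normed[:, :, ~mask, :] = 0.0
        for j, i in enumerate(idx):
            out[i] = replace(samples[i], tensor=normed[j])
    return [s for s in out if s is not None]


def extract_features(recordings: list[RawRecording],
                     bands: tuple[BandDefinition, ...] | None = None,
                     grid: ElectrodeGridMap | None = None,
                     window_s: float = 1.0,
                     T: int = 6,
                     stride: int | None = None,
                     normalize: bool = True) -> FeatureSet:
    """Full pipeline over a dataset: filter, DE, grid, stack, normalize.

    ``stride`` defaults to ``T`` (non-overlapping fragments) so that samples
    never share windows — overlapping fragments would leak information
    between cross-validation folds.
    """
    bands = bands if bands is not None else default_bands()
    if not recordings:
        mask = (grid.structural_mask() if grid is not None
                else np.zeros(GRID_SHAPE, bool))
        return FeatureSet(np.zeros((0, T) + GRID_SHAPE + (len(bands),)),
                          np.zeros(0, dtype=int), np.zeros(0, dtype=object),
                          (), tuple(b.name for b in bands), mask)
    if grid is None:
        grid = ElectrodeGridMap(
            {c: seed62_grid().mapping[c] for c in recordings[0].channel_names})
    stride = stride if stride is not None else T
    samples: list[Feature4DSample] = []
    for rec in recordings:
        de = compute_de_tensor(rec, bands, window_s=window_s)
        samples.extend(assemble_4d(de, grid, T=T, stride=stride))
    mask = grid.structural_mask()
    if normalize:
        samples = normalize_per_subject(samples, mask)
    class_names = tuple(sorted({s.label for s in samples}))
    label_index = {c: i for i, c in enumerate(class_names)}
    return FeatureSet(
        features=np.stack([s.tensor for s in samples]),
        labels=np.array([label_index[s.label] for s in samples], dtype=int),
        subjects=np.array([s.subject_id for s in samples], dtype=object),
        class_names=class_names,
        band_names=tuple(b.name for b in bands),
        structural_mask=mask)


# --------------------------------------------------------------------------
# Feature container I/O
# --------------------------------------------------------------------------

def save_features(fs: FeatureSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "eegfusion-features-v1"
        f.create_dataset("features", data=fs.features)
        f.create_dataset("labels", data=fs.labels)
        f.create_dataset("subjects",
                         data=np.array([str(s) for s in fs.subjects], dtype="S"))
        f.create_dataset("structural_mask", data=fs.structural_mask)
        f.attrs["class_names"] = list(fs.class_names)
        f.attrs["band_names"] = list(fs.band_names)


def load_features(path) -> FeatureSet:
    with h5py.File(path, "r") as f:
        for key in ("features", "labels", "subjects", "structural_mask"):
            if key not in f:
                raise FormatError(f"feature container missing dataset {key!r}")
        for attr in ("class_names", "band_names"):
            if attr not in f.attrs:
                raise FormatError(f"feature container missing attribute {attr!r}")
        return FeatureSet(
            features=f["features"][()],
            labels=f["labels"][()],
            subjects=np.array([s.decode() for s in f["subjects"][()]],
                              dtype=object),
            class_names=tuple(str(c) for c in f.attrs["class_names"]),
            band_names=tuple(str(b) for b in f.attrs["band_names"]),
            structural_mask=f["structural_mask"][()].astype(bool))
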