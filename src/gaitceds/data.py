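"""Synthetic IMU gait streams, window segmentation and dataset I/O.

A recording is a 6-channel inertial stream (3-axis accelerometer + 3-axis
gyroscope) sampled at a fixed rate.  Classification operates on 6x128
matrices cut from the stream either at a fixed window length or at
two-gait-cycle boundaries (the latter linearly interpolated to 128 time
steps).  The synthetic generator emulates per-subject quasi-periodic
walking signals: each subject walks at an individual cadence and each
channel is a small sum of harmonics of that cadence with subject- and
channel-specific amplitudes and phases, plus Gaussian sensor noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: Fixed channel order: accelerometer x/y/z then gyroscope x/y/z.
CHANNELS = ("Ax", "Ay", "Az", "Gx", "Gy", "Gz")

#: Number of time steps in one classification sample.
SAMPLE_LEN = 128


class InvalidConfigError(ValueError):
    """A configuration value is out of its admissible range."""


class DatasetFormatError(ValueError):
    """A dataset file does not follow the expected layout."""


@dataclass
class SensorStream:
    """One subject's continuous 6-channel inertial recording.

    Parameters
    ----------
    values : ndarray of shape (6, T)
        Rows in the fixed order ``Ax, Ay, Az, Gx, Gy, Gz``.
    rate_hz : float
        Sampling rate in Hz (50 for smartphone-style recordings, 100 for
        belt-mounted IMU recordings).
    subject_id : int
        Non-negative integer identity label.
    cadence_hz : float or None
        Gait-cycle frequency of the subject, when known (synthetic
        streams carry it; real recordings generally do not).
    units : dict
        Free-form unit metadata (e.g. ``{"acc": "m/s^2", "gyro": "rad/s"}``);
        carried along, never enforced.
    """

    values: np.ndarray
    rate_hz: float
    subject_id: int
    cadence_hz: float | None = None
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(CHANNELS):
            raise InvalidConfigError(
                f"stream must have exactly {len(CHANNELS)} rows, "
                f"got shape {self.values.shape}"
            )
        if self.values.shape[1] < 1:
            raise InvalidConfigError("stream must contain at least one sample")
        if not self.rate_hz > 0:
            raise InvalidConfigError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.subject_id < 0:
            raise InvalidConfigError("subject_id must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GaitSample:
    """One 6x128 sensor matrix with its subject label."""

    values: np.ndarray
    subject_id: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(CHANNELS), SAMPLE_LEN):
            raise InvalidConfigError(
                f"sample must be {len(CHANNELS)}x{SAMPLE_LEN}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidConfigError("sample contains non-finite values")
        if self.subject_id < 0:
            raise InvalidConfigError("subject_id must be non-negative")


@dataclass
class SegmentationConfig:
    """How to cut a stream into samples.

    mode
        ``"fixed_length"`` slides a constant-length window;
        ``"cycle_emulated"`` cuts two-gait-cycle spans (requires cadence
        metadata or explicit cycle boundaries) and resamples them to the
        window length.
    window_len
        Output sample length (128).
    overlap_fraction
        Fraction of each window shared with the next one (0, 0.50 and
        0.61 are the conventional regimes).
    """

    mode: str = "fixed_length"
    window_len: int = SAMPLE_LEN
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_length", "cycle_emulated"):
            raise InvalidConfigError(f"unknown segmentation mode {self.mode!r}")
        if self.window_len < 2:
            raise InvalidConfigError("window_len must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise InvalidConfigError("overlap_fraction must lie in [0, 1)")

    @property
    def stride(self) -> int:
        """Window advance in samples: round(window_len * (1 - overlap)).

        Rounding (rather than floor) is what makes fractional overlaps
        like 61% land on an integer grid (stride 50 at window 128).
        """
        s = int(round(self.window_len * (1.0 - self.overlap_fraction)))
        if s < 1:
            raise InvalidConfigError(
                f"overlap_fraction {self.overlap_fraction} yields stride 0 "
                f"at window_len {self.window_len}"
            )
        return s


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic gait-stream generator.

    Each subject receives a cadence drawn uniformly from
    ``cadence_range`` (a normal adult walking band, cycles per second).
    Every channel is a sum of ``n_harmonics`` harmonics of that cadence;
    harmonic amplitudes decay as 1/h with a random per-channel factor,
    phases are uniform.  Gaussian noise of standard deviation
    ``noise_sd`` (relative to the O(1) signal amplitude) is added i.i.d.
    All randomness derives from ``(seed, subject, channel)`` so streams
    are bit-for-bit reproducible.
    """

    n_subjects: int = 10
    stream_seconds_per_subject: float = 60.0
    rate_hz: float = 50.0
    n_harmonics: int = 4
    noise_sd: float = 0.1
    seed: int = 0
    cadence_range: tuple[float, float] = (0.7, 1.3)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidConfigError("n_subjects must be >= 2")
        if not self.stream_seconds_per_subject > 0:
            raise InvalidConfigError("stream_seconds_per_subject must be positive")
        if not self.rate_hz > 0:
            raise InvalidConfigError("rate_hz must be positive")
        if self.n_harmonics < 1:
            raise InvalidConfigError("n_harmonics must be >= 1")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        lo, hi = self.cadence_range
        if not 0 < lo <= hi:
            raise InvalidConfigError("cadence_range must be positive and ordered")


def generate_streams(cfg: SyntheticConfig) -> list[SensorStream]:
    """Generate one synthetic quasi-periodic stream per subject.

    Deterministic: the harmonic parameters of subject ``s`` channel ``c``
    are a pure function of ``(cfg.seed, s, c)``, and the noise of a pure
    function of ``(cfg.seed, s)``, so identical configs give identical
    streams.
    """
    t_len = int(round(cfg.stream_seconds_per_subject * cfg.rate_hz))
    if t_len < 1:
        raise InvalidConfigError("stream duration shorter than one sample period")
    t = np.arange(t_len) / cfg.rate_hz
    streams: list[SensorStream] = []
    for s in range(cfg.n_subjects):
        rng_s = np.random.default_rng(np.random.SeedSequence([cfg.seed, s]))
        lo, hi = cfg.cadence_range
        cadence = rng_s.uniform(lo, hi)
        values = np.empty((len(CHANNELS), t_len))
        for c in range(len(CHANNELS)):
            rng_c = np.random.default_rng(np.random.SeedSequence([cfg.seed, s, c]))
            x = np.zeros(t_len)
            for h in range(1, cfg.n_harmonics + 1):
                amp = rng_c.uniform(0.5, 1.5) / h
                phase = rng_c.uniform(0.0, 2.0 * math.pi)
                x += amp * np.sin(2.0 * math.pi * h * cadence * t + phase)
            values[c] = x
        if cfg.noise_sd > 0:
            values += cfg.noise_sd * rng_s.standard_normal(values.shape)
        streams.append(
            SensorStream(
                values=values,
                rate_hz=cfg.rate_hz,
                subject_id=s,
                cadence_hz=cadence,
                units={"acc": "m/s^2", "gyro": "rad/s"},
            )
        )
    return streams


def segment_fixed_length(
    stream: SensorStream, seg: SegmentationConfig
) -> list[GaitSample]:
    """Cut a stream into fixed-length windows with the configured overlap.

    Window starts advance by ``seg.stride``; a trailing partial window is
    discarded.  A stream shorter than one window yields an empty list.
    """
    if seg.mode != "fixed_length":
        raise InvalidConfigError("segment_fixed_length requires mode='fixed_length'")
    stride = seg.stride  # validates > 0
    n_t = stream.n_samples
    if n_t < seg.window_len:
        return []
    samples = []
    for start in range(0, n_t - seg.window_len + 1, stride):
        win = stream.values[:, start : start + seg.window_len]
        samples.append(GaitSample(values=win.copy(), subject_id=stream.subject_id))
    return samples


def n_fixed_windows(n_t: int, window_len: int, stride: int) -> int:
    """Closed-form window count: floor((T - L) / stride) + 1 (0 if T < L)."""
    if n_t < window_len:
        return 0
    return (n_t - window_len) // stride + 1


def interpolate_to_length(segment: np.ndarray, target_len: int = SAMPLE_LEN) -> np.ndarray:
    """Resample each row to ``target_len`` points by linear interpolation.

    The new sample grid spans the original index range [0, L-1], so the
    endpoints are preserved exactly and an input already at the target
    length passes through unchanged.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2:
        raise InvalidConfigError("segment must be a 2-D matrix")
    n_rows, length = segment.shape
    if length < 2:
        raise InvalidConfigError("segment must have at least 2 time steps")
    if length == target_len:
        return segment.copy()
    grid = np.linspace(0.0, length - 1.0, target_len)
    out = np.empty((n_rows, target_len))
    src = np.arange(length, dtype=float)
    for r in range(n_rows):
        out[r] = np.interp(grid, src, segment[r])
    return out


def segment_cycle_emulated(
    stream: SensorStream,
    seg: SegmentationConfig,
    cycle_boundaries: Sequence[int] | None = None,
) -> list[GaitSample]:
    """Cut two-gait-cycle spans and resample each to the window length.

    Cycle positions come from the stream's cadence metadata (synthetic
    streams) or from ``cycle_boundaries``, an increasing sequence of
    cycle-start sample indices.  This function never detects cycles from
    the raw signal.  Overlap acts at cycle granularity: 0 advances by two
    cycles, 0.5 by one.
    """
    if seg.mode != "cycle_emulated":
        raise InvalidConfigError("segment_cycle_emulated requires mode='cycle_emulated'")
    n_t = stream.n_samples
    if cycle_boundaries is not None:
        bounds = [int(b) for b in cycle_boundaries]
        if len(bounds) < 3 or any(b1 <= b0 for b0, b1 in zip(bounds, bounds[1:])):
            raise InvalidConfigError(
                "cycle_boundaries must be an increasing sequence of >= 3 indices"
            )
        # advance in cycles: 2 at overlap 0, 1 at overlap 0.5
        step = max(1, int(round(2 * (1.0 - seg.overlap_fraction))))
        samples = []
        for i in range(0, len(bounds) - 2, step):
            lo, hi = bounds[i], bounds[i + 2]
            if hi > n_t:
                break
            span = stream.values[:, lo:hi]
            samples.append(
                GaitSample(
                    values=interpolate_to_length(span, seg.window_len),
                    subject_id=stream.subject_id,
                )
            )
        return samples
    if stream.cadence_hz is None:
        raise InvalidConfigError(
            "cycle-based segmentation needs stream cadence metadata or explicit "
            "cycle_boundaries; cycle detection from the raw signal is not supported"
        )
    period = int(round(stream.rate_hz / stream.cadence_hz))
    if period < 1:
        raise InvalidConfigError("cadence implies a sub-sample gait period")
    span_len = 2 * period
    advance = max(1, int(round(span_len * (1.0 - seg.overlap_fraction))))
    samples = []
    start = 0
    while start + span_len <= n_t:
        span = stream.values[:, start : start + span_len]
        samples.append(
            GaitSample(
                values=interpolate_to_length(span, seg.window_len),
                subject_id=stream.subject_id,
            )
        )
        start += advance
    return samples


def split_stream_train_test(
    stream: SensorStream, test_fraction: float
) -> tuple[SensorStream, SensorStream]:
    """Cut a stream in time into a train part and a later test part.

    Segmenting the two parts separately guarantees that no window of the
    training set overlaps (or shares a start index with) any window of
    the test set.
    """
    if not 0.0 < test_fraction < 1.0:
        raise InvalidConfigError("test_fraction must lie in (0, 1)")
    n_t = stream.n_samples
    cut = int(round(n_t * (1.0 - test_fraction)))
    if cut < 1 or cut >= n_t:
        raise InvalidConfigError("stream too short to split at this fraction")

    def _part(sl: slice) -> SensorStream:
        return SensorStream(
            values=stream.values[:, sl].copy(),
            rate_hz=stream.rate_hz,
            subject_id=stream.subject_id,
            cadence_hz=stream.cadence_hz,
            units=dict(stream.units),
        )

    return _part(slice(0, cut)), _part(slice(cut, n_t))


def samples_to_arrays(samples: Sequence[GaitSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (n, 6, 128) values and an (n,) label vector."""
    if len(samples) == 0:
        raise InvalidConfigError("empty sample set")
    x = np.stack([s.values for s in samples]).astype(np.float32)
    y = np.array([s.subject_id for s in samples], dtype=np.int64)
    return x, y


def arrays_to_samples(x: np.ndarray, y: np.ndarray) -> list[GaitSample]:
    return [GaitSample(values=xi, subject_id=int(yi)) for xi, yi in zip(x, y)]


def save_dataset(path: str | Path, samples: Sequence[GaitSample]) -> None:
    """Write samples to a single array container (``.npz``: arrays x, y)."""
    x, y = samples_to_arrays(samples)
    np.savez(Path(path), x=x, y=y)


def load_dataset(path: str | Path) -> list[GaitSample]:
    """Read a dataset written by :func:`save_dataset`."""
    path = Path(path)
    try:
        with np.load(path) as npz:
            if "x" not in npz or "y" not in npz:
                raise DatasetFormatError(
                    f"{path}: expected arrays named 'x' and 'y', found {list(npz.keys())}"
                )
            x, y = npz["x"], npz["y"]
    except (OSError, ValueError) as exc:
        raise DatasetFormatError(f"{path}: not a readable array container: {exc}") from exc
    if x.ndim != 3 or x.shape[1:] != (len(CHANNELS), SAMPLE_LEN):
        raise DatasetFormatError(f"{path}: array 'x' has shape {x.shape}")
    if y.shape != (x.shape[0],):
        raise DatasetFormatError(f"{path}: label vector 'y' has shape {y.shape}")
    return arrays_to_samples(x, y)


def read_text_stream(
    path: str | Path,
    rate_hz: float,
    subject_id: int = 0,
    sidecar: str | Path | None = None,
) -> list[SensorStream]:
    """Read a delimited-text recording: one time step per row, 6 columns.

    Columns may be separated by whitespace or commas.  Without a sidecar
    the whole file is one stream labelled ``subject_id``.  A sidecar file
    holds one ``start end subject`` record per line (end exclusive) and
    splits the recording into per-subject streams.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != len(CHANNELS):
                raise DatasetFormatError(
                    f"{path}: line {lineno}: expected {len(CHANNELS)} numeric "
                    f"columns, got {len(fields)}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise DatasetFormatError(
                    f"{path}: line {lineno}: non-numeric field: {exc}"
                ) from exc
    if not rows:
        raise DatasetFormatError(f"{path}: no data rows")
    values = np.array(rows).T  # (6, T)
    if sidecar is None:
        return [SensorStream(values=values, rate_hz=rate_hz, subject_id=subject_id)]
    streams = []
    sidecar = Path(sidecar)
    with open(sidecar) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 3:
                raise DatasetFormatError(
                    f"{sidecar}: line {lineno}: expected 'start end subject'"
                )
            try:
                start, end, subj = (int(f) for f in fields)
            except ValueError as exc:
                raise DatasetFormatError(
                    f"{sidecar}: line {lineno}: non-integer field: {exc}"
                ) from exc
            if not 0 <= start < end <= values.shape[1]:
                raise DatasetFormatError(
                    f"{sidecar}: line {lineno}: span [{start}, {end}) outside "
                    f"recording of length {values.shape[1]}"
                )
            streams.append(
                SensorStream(
                    values=values[:, start:end].copy(),
                    rate_hz=rate_hz,
                    subject_id=subj,
                )
            )
    if not streams:
        raise DatasetFormatError(f"{sidecar}: no label records")
    return streams


def write_text_stream(path: str | Path, stream: SensorStream) -> None:
    """Write a stream as delimited text (one time step per row, 6 columns)."""
    np.savetxt(Path(path), stream.values.T, fmt="%.9g")


def zscore_channels(x: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Optionally standardize each channel of an (n, 6, 128) batch.

    Off by default everywhere; provided as an explicit preprocessing
    switch for experiments.
    """
    mean = x.mean(axis=(0, 2), keepdims=True)
    sd = x.std(axis=(0, 2), keepdims=True)
    return (x - mean) / np.maximum(sd, eps)


def make_classification_arrays(
    cfg: SyntheticConfig,
    seg: SegmentationConfig,
    test_fraction: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generate streams, split each in time and segment both parts.

    Returns ``(x_train, y_train, x_test, y_test)``.  The temporal split
    guarantees train and test windows never overlap.  Subjects whose
    stream is too short for a single window raise a warning and are
    skipped.
    """
    train_s, test_s = [], []
    for stream in generate_streams(cfg):
        tr, te = split_stream_train_test(stream, test_fraction)
        if seg.mode == "fixed_length":
            tr_w, te_w = segment_fixed_length(tr, seg), segment_fixed_length(te, seg)
        else:
            tr_w, te_w = segment_cycle_emulated(tr, seg), segment_cycle_emulated(te, seg)
        if not tr_w or not te_w:
            warnings.warn(
                f"subject {stream.subject_id}: stream too short for windows, skipped"
            )
            continue
        train_s.extend(tr_w)
        test_s.extend(te_w)
    x_tr, y_tr = samples_to_arrays(train_s)
    x_te, y_te = samples_to_arrays(test_s)
    return x_tr, y_tr, x_te, y_te
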