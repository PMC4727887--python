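"""Synthetic co-registered gaze + EEG/EOG data with a known fixation-related potential.

The generator emulates a visual-search session over a 12-object grid: the gaze
stream alternates fixations and short ballistic saccades, each fixation lands on
the target object, a non-target object, or the blank background, and the EEG
carries a class-dependent fixation-locked positive deflection on top of
autoregressive background noise plus saccade-locked ocular artifacts that
project mainly onto the EOG and frontal channels.  Every simulated fixation is
recorded in a :class:`GroundTruth` table so that downstream detection,
labelling, epoching and classification can be tested against a known answer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

CLASSES = ("target", "nontarget", "background")

EEG_CHANNELS = ("Fz", "F3", "F4", "Cz", "C3", "C4", "Pz", "P3", "P4", "PO7", "PO8", "Oz")
EOG_CHANNELS = ("VEOGu", "VEOGl", "HEOGl", "HEOGr")
ALL_CHANNELS = EEG_CHANNELS + EOG_CHANNELS

# Parieto-central topography: the fixation-locked positive component is largest
# over Pz/Cz, as is typical for P3-family potentials.
DEFAULT_TOPOGRAPHY = {
    "Fz": 0.4, "F3": 0.3, "F4": 0.3,
    "Cz": 0.8, "C3": 0.6, "C4": 0.6,
    "Pz": 1.0, "P3": 0.8, "P4": 0.8,
    "PO7": 0.5, "PO8": 0.5, "Oz": 0.4,
}

# Corneo-retinal artifact projection: strong on EOG electrodes, attenuated on
# frontal EEG, nearly absent posteriorly.
DEFAULT_EOG_ARTIFACT_GAIN = {
    "Fz": 0.15, "F3": 0.12, "F4": 0.12,
    "Cz": 0.06, "C3": 0.05, "C4": 0.05,
    "Pz": 0.02, "P3": 0.02, "P4": 0.02,
    "PO7": 0.01, "PO8": 0.01, "Oz": 0.01,
    "VEOGu": 1.0, "VEOGl": -0.9, "HEOGl": 0.8, "HEOGr": -0.8,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic session.

    Durations are milliseconds, amplitudes microvolts, positions pixels.
    ``fix_duration_means_ms`` defaults to the study's per-class means
    (target 270, non-target 281, background 241 ms).
    """

    n_subjects: int = 1
    n_trials_per_subject: int = 1
    n_fixations_per_trial: int = 120
    fs_eeg: float = 256.0
    fs_gaze: float = 120.0
    screen_size: tuple[int, int] = (1680, 1050)
    px_per_deg: float = 40.0
    object_radius_deg: float = 2.5
    grid_jitter_px: float = 15.0
    class_probs: dict[str, float] = field(
        default_factory=lambda: {"target": 0.15, "nontarget": 0.55, "background": 0.30}
    )
    fix_duration_means_ms: dict[str, float] = field(
        default_factory=lambda: {"target": 270.0, "nontarget": 281.0, "background": 241.0}
    )
    fix_duration_sds_ms: dict[str, float] = field(
        default_factory=lambda: {"target": 38.0, "nontarget": 37.0, "background": 29.0}
    )
    min_fix_duration_ms: float = 60.0
    within_fixation_jitter_px: float = 3.0
    saccade_duration_ms: float = 30.0
    min_centroid_separation_px: float = 150.0
    frp_amplitude_uv: dict[str, float] = field(
        default_factory=lambda: {"target": 6.0, "nontarget": 1.0, "background": 1.0}
    )
    frp_peak_latency_ms: float = 400.0
    frp_width_ms: float = 100.0
    topography: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TOPOGRAPHY))
    noise_ar_coef: float = 0.95
    noise_sd_uv: float = 10.0
    # Background EEG noise is spatially correlated: noise_rank AR(1) cortical
    # sources mixed into the 12 EEG channels, plus independent sensor noise.
    noise_rank: int = 10
    sensor_noise_sd_uv: float = 1.0
    saccade_artifact_uv: float = 200.0
    eog_artifact_gain: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EOG_ARTIFACT_GAIN)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_eeg <= 0 or self.fs_gaze <= 0:
            raise ValueError("sampling rates must be positive")
        for cls in CLASSES:
            if self.fix_duration_means_ms[cls] <= 0:
                raise ValueError(f"fixation duration mean for {cls!r} must be > 0")
            if self.fix_duration_sds_ms[cls] < 0:
                raise ValueError(f"fixation duration sd for {cls!r} must be >= 0")
        if set(self.topography) != set(EEG_CHANNELS):
            raise ValueError("topography must provide one gain per EEG channel")
        a = self.frp_amplitude_uv
        if not (a["target"] >= a["nontarget"] >= a["background"]):
            raise ValueError(
                "per-class FRP amplitude must satisfy target >= nontarget >= background"
            )

    @property
    def object_radius_px(self) -> float:
        return self.object_radius_deg * self.px_per_deg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["screen_size"] = list(d["screen_size"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "screen_size" in d:
            d["screen_size"] = tuple(d["screen_size"])
        return cls(**d)


@dataclass
class ObjectLayout:
    """Twelve object centers on a jittered 4x3 grid, one of them the target."""

    object_centers: np.ndarray  # (12, 2) px
    target_index: int
    object_radius_deg: float = 2.5

    def __post_init__(self) -> None:
        self.object_centers = np.asarray(self.object_centers, dtype=float)
        if self.object_centers.shape != (12, 2):
            raise ValueError("layout requires exactly 12 object centers")
        if not 0 <= self.target_index < 12:
            raise ValueError("target_index must be in [0, 11]")


@dataclass
class GroundTruth:
    """Oracle record of every simulated fixation (and injected component onsets)."""

    onset_ms: np.ndarray
    duration_ms: np.ndarray
    centroid_px: np.ndarray  # (n, 2)
    label: np.ndarray  # str array over CLASSES
    frp_onset_samples: np.ndarray  # indices at fs_eeg

    def __len__(self) -> int:
        return len(self.onset_ms)


@dataclass
class GazeStream:
    """Timestamped 2-D screen coordinates with per-sample validity flags."""

    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    fs_gaze: float

    def __len__(self) -> int:
        return len(self.t_ms)


def reference_high_snr_config(**overrides) -> SimConfig:
    """The package's reference high-SNR condition: a strong target-specific
    fixation-locked component (15 uV peak against 10 uV AR(1) noise) with
    non-target and background classes generated identically at 1 uV.  Fixed by
    a calibration run of the generator's SNR -> AUC curve; see docs/methods.md."""
    params = dict(
        n_fixations_per_trial=200,
        frp_amplitude_uv={"target": 15.0, "nontarget": 1.0, "background": 1.0},
    )
    params.update(overrides)
    return SimConfig(**params)


def generate_layout(config: SimConfig, rng: np.random.Generator) -> ObjectLayout:
    """Place 12 objects on a 4x3 grid with random per-object offsets.

    Raises ``ValueError`` if the jittered grid could place two objects closer
    than twice the object radius (overlap).
    """
    w, h = config.screen_size
    r = config.object_radius_px
    margin = r + config.grid_jitter_px + 1
    xs = np.linspace(margin, w - margin, 4)
    ys = np.linspace(margin, h - margin, 3)
    if min(np.diff(xs).min(), np.diff(ys).min()) <= 2 * r + 2 * config.grid_jitter_px:
        raise ValueError("screen too small for 12 non-overlapping objects at this px_per_deg")
    centers = np.array([(x, y) for y in ys for x in xs], dtype=float)
    centers += rng.uniform(-config.grid_jitter_px, config.grid_jitter_px, size=centers.shape)
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() <= 2 * r:
        raise ValueError("jittered layout produced overlapping objects")
    target_index = int(rng.integers(0, 12))
    return ObjectLayout(centers, target_index, config.object_radius_deg)


def _draw_duration_ms(cls: str, config: SimConfig, rng: np.random.Generator) -> float:
    """Truncated normal, lower bound = the temporal detection threshold."""
    mean = config.fix_duration_means_ms[cls]
    sd = config.fix_duration_sds_ms[cls]
    if sd == 0:
        return mean
    for _ in range(1000):
        d = rng.normal(mean, sd)
        if d >= config.min_fix_duration_ms:
            return d
    return config.min_fix_duration_ms


def _sample_location(
    cls: str,
    layout: ObjectLayout,
    config: SimConfig,
    rng: np.random.Generator,
    prev: np.ndarray | None,
    prev_object: int | None,
) -> tuple[np.ndarray, int | None]:
    """Fixation centroid for a class; background points keep clear of all objects
    and every centroid keeps a minimum distance from its predecessor so adjacent
    fixations cannot merge under dispersion grouping.  An object fixated on the
    immediately preceding fixation is not refixated."""
    r = config.object_radius_px
    w, h = config.screen_size
    centers = layout.object_centers
    for _ in range(10_000):
        if cls == "target":
            obj: int | None = layout.target_index
            p = centers[layout.target_index] + _uniform_disc(rng, 0.4 * r)
        elif cls == "nontarget":
            obj = int(rng.integers(0, 11))
            obj = obj if obj < layout.target_index else obj + 1
            if obj == prev_object:
                continue
            p = centers[obj] + _uniform_disc(rng, 0.4 * r)
        else:
            obj = None
            p = rng.uniform([10, 10], [w - 10, h - 10])
            if np.min(np.linalg.norm(centers - p, axis=1)) <= 1.2 * r:
                continue
        if prev is None or np.linalg.norm(p - prev) >= config.min_centroid_separation_px:
            return p, obj
    raise RuntimeError("could not place a fixation satisfying the separation constraint")


def _uniform_disc(rng: np.random.Generator, radius: float) -> np.ndarray:
    theta = rng.uniform(0, 2 * np.pi)
    rho = radius * np.sqrt(rng.uniform())
    return np.array([rho * np.cos(theta), rho * np.sin(theta)])


def simulate_scanpath(
    layout: ObjectLayout,
    config: SimConfig,
    rng: np.random.Generator,
    n_fixations: int | None = None,
) -> tuple[GazeStream, GroundTruth]:
    """Simulate an alternating fixation/saccade gaze stream over the layout.

    Fixation durations are drawn per true class from a truncated normal with the
    configured means/SDs; within-fixation samples jitter by a Gaussian whose SD
    is far below the detection dispersion radius; saccades are constant-velocity
    sample runs of ``saccade_duration_ms``.
    """
    for cls in CLASSES:
        if config.fix_duration_means_ms[cls] < config.min_fix_duration_ms:
            raise ValueError(
                f"duration mean for {cls!r} is below the {config.min_fix_duration_ms} ms "
                "detection threshold; such fixations would be undetectable"
            )
    n_fix = n_fixations if n_fixations is not None else config.n_fixations_per_trial
    dt = 1000.0 / config.fs_gaze
    n_sacc = max(1, round(config.saccade_duration_ms * config.fs_gaze / 1000.0))

    xs: list[float] = []
    ys: list[float] = []
    onsets, durations, centroids, labels = [], [], [], []
    classes = list(config.class_probs)
    probs = np.array([config.class_probs[c] for c in classes], dtype=float)
    probs /= probs.sum()
    prev_pos: np.ndarray | None = None
    prev_object: int | None = None
    prev_cls: str | None = None
    for _ in range(n_fix):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        # no immediate refixation of the same object: redraw target-after-target
        while cls == "target" and prev_cls == "target":
            cls = classes[int(rng.choice(len(classes), p=probs))]
        pos, prev_object = _sample_location(cls, layout, config, rng, prev_pos, prev_object)
        if prev_pos is not None:
            # ballistic saccade: samples on the middle of the straight segment,
            # keeping clear of the dispersion radius around both endpoints so a
            # saccade sample never joins a fixation's dispersion run
            if n_sacc == 1:
                fracs = np.array([0.5])
            else:
                fracs = 0.4 + 0.2 * np.arange(n_sacc) / (n_sacc - 1)
            for f in fracs:
                q = prev_pos + f * (pos - prev_pos)
                xs.append(q[0])
                ys.append(q[1])
        dur = _draw_duration_ms(cls, config, rng)
        n_samp = max(2, round(dur * config.fs_gaze / 1000.0))
        onset = len(xs) * dt
        jit = rng.normal(0.0, config.within_fixation_jitter_px, size=(n_samp, 2))
        for j in jit:
            xs.append(pos[0] + j[0])
            ys.append(pos[1] + j[1])
        onsets.append(onset)
        durations.append(dur)
        centroids.append(pos)
        labels.append(cls)
        prev_pos = pos
        prev_cls = cls

    t = np.arange(len(xs)) * dt
    stream = GazeStream(
        t_ms=t,
        x_px=np.array(xs),
        y_px=np.array(ys),
        valid=np.ones(len(xs), dtype=bool),
        fs_gaze=config.fs_gaze,
    )
    truth = GroundTruth(
        onset_ms=np.array(onsets),
        duration_ms=np.array(durations),
        centroid_px=np.array(centroids),
        label=np.array(labels),
        frp_onset_samples=np.round(np.array(onsets) * config.fs_eeg / 1000.0).astype(int),
    )
    return stream, truth


def frp_waveform(config: SimConfig, n_samples: int) -> np.ndarray:
    """Unit-amplitude Gaussian-windowed deflection, peaking
    ``frp_peak_latency_ms`` after fixation onset, sampled at fs_eeg."""
    t_ms = np.arange(n_samples) / config.fs_eeg * 1000.0
    return np.exp(-0.5 * ((t_ms - config.frp_peak_latency_ms) / config.frp_width_ms) ** 2)


def _artifact_pulse(n: int) -> np.ndarray:
    """Smooth unit pulse spanning a saccade (half-sine); models the transient
    corneo-retinal potential shift."""
    return np.sin(np.pi * (np.arange(n) + 0.5) / n)


def simulate_recording(
    truth: GroundTruth, config: SimConfig, rng: np.random.Generator
) -> "Recording":
    """Render a 16-channel (12 EEG + 4 EOG) recording at ``fs_eeg`` from the
    fixation ground truth.

    Per channel: AR(1) background noise + class-amplitude x Gaussian deflection
    x topography gain, injected at each fixation onset, + saccade-locked pulses
    scaled by the per-channel EOG-artifact gain.  Units are microvolts.
    """
    from .preprocess import Recording  # local import avoids a cycle

    if len(truth) == 0:
        raise ValueError("ground truth contains no fixations")
    fs = config.fs_eeg
    end_ms = truth.onset_ms[-1] + truth.duration_ms[-1] + 1000.0
    n = int(np.ceil(end_ms * fs / 1000.0))
    n_ch = len(ALL_CHANNELS)

    # AR(1) sources via an IIR filter; innovation sd chosen for stationary sd = 1
    a = config.noise_ar_coef
    n_eeg, n_eog = len(EEG_CHANNELS), len(EOG_CHANNELS)

    def ar_sources(k: int) -> np.ndarray:
        # Laplace innovations: real EEG background is bursty (super-Gaussian),
        # which also keeps the source model identifiable for ICA
        innov_sd = np.sqrt(max(1.0 - a * a, 1e-12))
        e = rng.laplace(0.0, innov_sd / np.sqrt(2.0), size=(k, n))
        e[:, 0] = rng.normal(0.0, 1.0, size=k)
        return lfilter([1.0], [1.0, -a], e, axis=1)

    data = np.zeros((n_ch, n))
    if config.noise_sd_uv > 0:
        # spatially correlated EEG background: noise_rank sources through a
        # random mixing with unit-norm rows, so each channel's noise sd stays
        # at noise_sd_uv; EOG channels carry independent noise
        k = min(config.noise_rank, n_eeg)
        M = rng.normal(size=(n_eeg, k))
        M /= np.linalg.norm(M, axis=1, keepdims=True)
        data[:n_eeg] = config.noise_sd_uv * (M @ ar_sources(k))
        data[n_eeg:] = config.noise_sd_uv * ar_sources(n_eog)
    if config.sensor_noise_sd_uv > 0:
        data += rng.normal(0.0, config.sensor_noise_sd_uv, size=(n_ch, n))

    # fixation-locked component
    span = int(np.ceil((config.frp_peak_latency_ms + 4 * config.frp_width_ms) * fs / 1000.0))
    wave = frp_waveform(config, span)
    topo = np.array([config.topography[ch] for ch in EEG_CHANNELS])
    for onset, cls in zip(truth.frp_onset_samples, truth.label):
        amp = config.frp_amplitude_uv[str(cls)]
        if amp == 0:
            continue
        stop = min(onset + span, n)
        if onset >= n:
            continue
        seg = wave[: stop - onset]
        data[: len(EEG_CHANNELS), onset:stop] += amp * topo[:, None] * seg[None, :]

    # saccade-locked ocular artifacts between consecutive fixations
    gain = np.array([config.eog_artifact_gain[ch] for ch in ALL_CHANNELS])
    if config.saccade_artifact_uv != 0:
        for i in range(len(truth) - 1):
            s0 = int(round((truth.onset_ms[i] + truth.duration_ms[i]) * fs / 1000.0))
            s1 = int(round(truth.onset_ms[i + 1] * fs / 1000.0))
            s1 = max(s1, s0 + 2)
            s0, s1 = max(s0, 0), min(s1, n)
            if s1 <= s0:
                continue
            pulse = config.saccade_artifact_uv * _artifact_pulse(s1 - s0)
            data[:, s0:s1] += gain[:, None] * pulse[None, :]

    roles = ["EEG"] * len(EEG_CHANNELS) + ["EOG"] * len(EOG_CHANNELS)
    return Recording(data=data, fs=fs, channel_names=list(ALL_CHANNELS), channel_roles=roles)


def simulate_subject(
    config: SimConfig, rng: np.random.Generator
) -> tuple[ObjectLayout, GazeStream, GroundTruth, "Recording"]:
    """One subject's session: layout, scanpath, ground truth and recording."""
    layout = generate_layout(config, rng)
    stream, truth = simulate_scanpath(layout, config, rng)
    rec = simulate_recording(truth, config, rng)
    return layout, stream, truth, rec


# ---------------------------------------------------------------------------
# persistence

def write_gaze_tsv(stream: GazeStream, path) -> None:
    pd.DataFrame(
        {"t_ms": stream.t_ms, "x_px": stream.x_px, "y_px": stream.y_px,
         "valid": stream.valid.astype(int)}
    ).to_csv(path, sep="\t", index=False)


def read_gaze_tsv(path, fs_gaze: float = 120.0) -> GazeStream:
    df = pd.read_csv(path, sep="\t")
    return GazeStream(
        t_ms=df["t_ms"].to_numpy(float),
        x_px=df["x_px"].to_numpy(float),
        y_px=df["y_px"].to_numpy(float),
        valid=df["valid"].to_numpy(bool),
        fs_gaze=fs_gaze,
    )


def write_truth_tsv(truth: GroundTruth, path) -> None:
    pd.DataFrame(
        {
            "onset_ms": truth.onset_ms,
            "duration_ms": truth.duration_ms,
            "cx_px": truth.centroid_px[:, 0],
            "cy_px": truth.centroid_px[:, 1],
            "label": truth.label,
        }
    ).to_csv(path, sep="\t", index=False)


def write_layout_tsv(layout: ObjectLayout, path) -> None:
    df = pd.DataFrame(layout.object_centers, columns=["cx_px", "cy_px"])
    df["is_target"] = [int(i == layout.target_index) for i in range(12)]
    df.to_csv(path, sep="\t", index=False)


def read_layout_tsv(path, object_radius_deg: float = 2.5) -> ObjectLayout:
    df = pd.read_csv(path, sep="\t")
    centers = df[["cx_px", "cy_px"]].to_numpy(float)
    target_index = int(np.flatnonzero(df["is_target"].to_numpy())[0])
    return ObjectLayout(centers, target_index, object_radius_deg)


def write_recording_h5(recording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=recording.data)
        f.create_dataset(
            "channels",
            data=np.array(
                [f"{n}:{r}" for n, r in zip(recording.channel_names, recording.channel_roles)],
                dtype=h5py.string_dtype(),
            ),
        )
        f.attrs["fs"] = recording.fs


def read_recording_h5(path):
    from .preprocess import Recording

    with h5py.File(path, "r") as f:
        data = f["eeg"][()]
        chans = [c.decode() if isinstance(c, bytes) else c for c in f["channels"][()]]
        fs = float(f.attrs["fs"])
    names = [c.split(":")[0] for c in chans]
    roles = [c.split(":")[1] for c in chans]
    return Recording(data=data, fs=fs, channel_names=names, channel_roles=roles)
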