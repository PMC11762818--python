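"""Synthetic multichannel EEG with directed, class-dependent inter-channel coupling.

Two cognitive-state classes ("pre" / "post") are emulated by changing only the
strength of a small set of directed, lagged couplings between band-limited
channel components.  Everything else — per-band oscillator spectra, broadband
noise, 50 Hz line interference, optional blink transients — is identical in
distribution between the classes, so a downstream classifier can only succeed
by detecting the coupling difference.

Each channel is a sum of independent narrowband oscillators, one per canonical
EEG band, realised as noise-driven damped AR(2) processes whose spectral peak
sits at the band's geometric-centre frequency.  A coupling edge
(src, dst, band, lag, strength) replaces the destination channel's band
component with the variance-preserving mixture

    sqrt(1 - s^2) * own_component + s * source_component(t - lag)

so coupling strength changes directed dependence without changing band power.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CANONICAL_BANDS",
    "DEFAULT_CHANNEL_LABELS",
    "CouplingEdge",
    "SimConfig",
    "RawRecording",
    "LabeledDataset",
    "simulate_recording",
    "simulate_dataset",
]

#: Canonical EEG band edges in Hz, ordered by lower edge.
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "Delta": (1.0, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha1": (8.0, 10.5),
    "Alpha2": (10.5, 13.0),
    "Beta1": (13.0, 20.0),
    "Beta2": (20.0, 30.0),
    "Gamma": (30.0, 40.0),
}

#: 16 generic 10–20-system electrode labels (frontal channels first: blink site).
DEFAULT_CHANNEL_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "Cz",
    "C3", "C4", "T3", "T4", "P3", "P4", "O1", "O2",
)

#: Typical resting scalp-EEG amplitudes per band, µV RMS.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "Delta": 20.0,
    "Theta": 10.0,
    "Alpha1": 10.0,
    "Alpha2": 10.0,
    "Beta1": 5.0,
    "Beta2": 4.0,
    "Gamma": 2.0,
}

LABELS = ("pre", "post")


@dataclass(frozen=True)
class CouplingEdge:
    """Directed lagged coupling src → dst within one band.

    lag is in samples at the simulation rate; strength is the mixing
    coefficient s in [0, 1].
    """

    src: int
    dst: int
    band: str
    lag: int
    strength: float


def _default_edges() -> list[CouplingEdge]:
    # One Alpha2 and one Gamma edge carry the class difference.
    return [
        CouplingEdge(src=8, dst=12, band="Alpha2", lag=10, strength=0.4),
        CouplingEdge(src=9, dst=13, band="Gamma", lag=5, strength=0.4),
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic EEG generator.

    class_effect is added to every edge's strength for label "post"; the
    invariant strength + class_effect <= 1 keeps the mixture well defined.
    artifact_rate is blink events per minute on the two frontal channels.
    """

    n_channels: int = 16
    fs: float = 1000.0
    duration: float = 60.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    coupling_edges: list[CouplingEdge] = field(default_factory=_default_edges)
    class_effect: float = 0.3
    line_noise_amp: float = 2.0
    noise_sd: float = 5.0
    artifact_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        n_samples = self.duration * self.fs
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError(
                f"duration*fs = {n_samples} is not an integer sample count"
            )
        if self.n_channels < 1 or self.fs <= 0:
            raise ValueError("need n_channels >= 1 and fs > 0")
        for band in self.band_amplitudes:
            if band not in CANONICAL_BANDS:
                raise ValueError(f"unknown band {band!r}")
        for e in self.coupling_edges:
            if not (0 <= e.src < self.n_channels and 0 <= e.dst < self.n_channels):
                raise ValueError(f"edge {e} references channel out of range")
            if e.src == e.dst:
                raise ValueError(f"self-coupling edge {e} not allowed")
            if e.lag < 1:
                raise ValueError(f"edge {e}: lag must be >= 1 sample")
            if e.band not in self.band_amplitudes:
                raise ValueError(f"edge {e}: band has no amplitude entry")
            if not (0.0 <= e.strength and e.strength + self.class_effect <= 1.0):
                raise ValueError(
                    f"edge {e}: need 0 <= strength and strength+class_effect <= 1"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class RawRecording:
    """channels × samples EEG in µV with metadata."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    label: str
    subject_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels × samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class LabeledDataset:
    """A collection of recordings with a per-recording manifest."""

    recordings: list[RawRecording]
    manifest: "pd.DataFrame"  # noqa: F821 — columns subject_id, label, seed

    def __post_init__(self) -> None:
        labels = {r.label for r in self.recordings}
        if len(self.recordings) and labels != set(LABELS):
            raise ValueError(f"both labels {LABELS} must be present, got {labels}")


def _band_center(band: str) -> float:
    low, high = CANONICAL_BANDS[band]
    return float(np.sqrt(low * high))


def _band_radius(band: str, fs: float) -> float:
    """AR(2) pole radius giving a 3 dB bandwidth of half the band's width.

    r = exp(-pi * bw / fs).  A fixed radius would make narrow bands (Alpha2 is
    2.5 Hz wide) leak most of their oscillator power into neighbouring
    analysis bands; tying the bandwidth to the band keeps each component
    genuinely band-limited.
    """
    low, high = CANONICAL_BANDS[band]
    bw = (high - low) / 2.0
    return float(np.exp(-np.pi * bw / fs))


def _ar2_series(
    rng: np.random.Generator, n: int, f_center: float, fs: float, radius: float
) -> np.ndarray:
    """Unit-RMS damped AR(2) oscillation with spectral peak near f_center.

    Poles at radius * exp(±i 2π f_center/fs); driven by white noise.  A lead-in
    of 2000 samples lets the process forget its zero initial state.
    """
    from scipy.signal import lfilter

    theta = 2.0 * np.pi * f_center / fs
    a1 = -2.0 * radius * np.cos(theta)
    a2 = radius * radius
    lead = 2000
    w = rng.standard_normal(n + lead)
    x = lfilter([1.0], [1.0, a1, a2], w)[lead:]
    rms = np.sqrt(np.mean(x * x))
    return x / rms


def _blink_waveform(fs: float, freq: float) -> np.ndarray:
    """Half-sine transient of a `freq` Hz sine: duration 1/(2 freq) s, peak 1."""
    n = int(round(fs / (2.0 * freq)))
    t = np.arange(n) / fs
    return np.sin(2.0 * np.pi * freq * t)


def simulate_recording(
    cfg: SimConfig, label: str, seed: int, subject_id: str = "S00"
) -> RawRecording:
    """Generate one labelled recording; bit-identical for equal (cfg, label, seed).

    The label enters only through the coupling strengths (strength +
    class_effect for "post"): the same seed produces the same underlying band
    oscillators and noise for both labels.
    """
    cfg.validate()
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    max_lag = max((e.lag for e in cfg.coupling_edges), default=0)

    # Per-channel, per-band unit-RMS components; extra max_lag samples of
    # lead-in so lagged source segments are fully defined.
    bands = list(cfg.band_amplitudes)
    comps = np.empty((cfg.n_channels, len(bands), n + max_lag))
    for ch in range(cfg.n_channels):
        for bi, band in enumerate(bands):
            comps[ch, bi] = _ar2_series(
                rng, n + max_lag, _band_center(band), cfg.fs, _band_radius(band, cfg.fs)
            )

    # Coupling: variance-preserving mixture in the band component.
    mixed = comps.copy()
    for e in cfg.coupling_edges:
        s = e.strength + (cfg.class_effect if label == "post" else 0.0)
        bi = bands.index(e.band)
        src = comps[e.src, bi]
        lagged = np.concatenate([src[:e.lag][::-1], src[:-e.lag]])
        mixed[e.dst, bi] = np.sqrt(1.0 - s * s) * comps[e.dst, bi] + s * lagged

    amps = np.array([cfg.band_amplitudes[b] for b in bands])
    data = np.einsum("b,cbt->ct", amps, mixed[:, :, max_lag:])

    t = np.arange(n) / cfg.fs
    if cfg.line_noise_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        data += cfg.line_noise_amp * np.sin(2 * np.pi * 50.0 * t + phase)
    if cfg.noise_sd > 0:
        data += cfg.noise_sd * rng.standard_normal(data.shape)

    if cfg.artifact_rate > 0 and cfg.n_channels >= 1:
        n_events = rng.poisson(cfg.artifact_rate * cfg.duration / 60.0)
        frontal = range(min(2, cfg.n_channels))
        for _ in range(n_events):
            freq = rng.uniform(1.0, 2.0)
            wave = 100.0 * _blink_waveform(cfg.fs, freq)
            start = rng.integers(0, max(1, n - len(wave)))
            stop = min(n, start + len(wave))
            for ch in frontal:
                data[ch, start:stop] += wave[: stop - start]

    labels = list(DEFAULT_CHANNEL_LABELS[: cfg.n_channels])
    if len(labels) < cfg.n_channels:
        labels += [f"EEG{i:02d}" for i in range(len(labels), cfg.n_channels)]
    return RawRecording(
        data=data, fs=cfg.fs, channel_labels=labels, label=label, subject_id=subject_id
    )


def recording_seed(master_seed: int, subject_index: int, recording_index: int) -> int:
    """Deterministic per-recording seed below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(subject_index, recording_index))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_dataset(
    cfg: SimConfig,
    n_subjects_per_class: int,
    recordings_per_subject: int,
    seed: int,
) -> LabeledDataset:
    """Simulate n_subjects_per_class × 2 subjects with the given recording count.

    Subject and recording seeds are derived from the master seed via
    SeedSequence spawn keys, so datasets are reproducible and any change of
    the master seed changes the data.
    """
    import pandas as pd

    if n_subjects_per_class < 1 or recordings_per_subject < 1:
        raise ValueError("counts must be >= 1")
    recs: list[RawRecording] = []
    rows = []
    subj_idx = 0
    for lbl in LABELS:
        for _ in range(n_subjects_per_class):
            sid = f"{lbl}-{subj_idx:03d}"
            for r in range(recordings_per_subject):
                s = recording_seed(seed, subj_idx, r)
                recs.append(simulate_recording(cfg, lbl, s, subject_id=sid))
                rows.append({"subject_id": sid, "label": lbl, "seed": s})
            subj_idx += 1
    manifest = pd.DataFrame(rows)
    return LabeledDataset(recordings=recs, manifest=manifest)


def config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["coupling_edges"] = [dataclasses.asdict(e) for e in cfg.coupling_edges]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "coupling_edges" in d:
        d["coupling_edges"] = [
            e if isinstance(e, CouplingEdge) else CouplingEdge(**e)
            for e in d["coupling_edges"]
        ]
    return SimConfig(**d)
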