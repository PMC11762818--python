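"""EEG preprocessing: filtering, artifact removal, downsampling, band split, windowing.

The stage order mirrors standard practice for coupling analysis:

1. Chebyshev-I bandpass 1–100 Hz plus a 50 Hz notch against line interference.
2. Best-effort FastICA artifact removal (blink-template correlation rule).
3. Anti-aliased downsampling 1000 → 125 Hz.
4. Zero-phase decomposition into the seven canonical bands
   (Delta 1–4, Theta 4–8, Alpha1 8–10.5, Alpha2 10.5–13, Beta1 13–20,
   Beta2 20–30, Gamma 30–40 Hz — all below the new 62.5 Hz Nyquist).
5. 4 s sliding windows with 2 s step (50 % overlap).
6. Named band-combination presets for feature selection.

All recursive filters are applied forward–backward (zero phase): phase
distortion would bias the lag-based coupling estimates downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .synthgen import CANONICAL_BANDS, RawRecording

logger = logging.getLogger(__name__)

__all__ = [
    "BandSet",
    "FilterSpec",
    "FilterCoefficients",
    "BandStack",
    "Segment",
    "BAND_PRESETS",
    "design_filter",
    "apply_filter",
    "remove_artifact_components",
    "downsample",
    "decompose_bands",
    "sliding_segments",
    "select_bands",
    "preprocess_recording",
]


@dataclass(frozen=True)
class BandSet:
    """Ordered (name, low, high) frequency bands."""

    bands: tuple[tuple[str, float, float], ...] = tuple(
        (name, lo, hi) for name, (lo, hi) in CANONICAL_BANDS.items()
    )

    def __post_init__(self) -> None:
        names = [b[0] for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")
        lows = []
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name}: need low < high")
            lows.append(lo)
        if lows != sorted(lows):
            raise ValueError("bands must be ordered by low edge")

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def edges(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return lo, hi
        raise KeyError(name)


#: The six band combinations evaluated in the experimental grid, plus "full".
BAND_PRESETS: dict[str, tuple[str, ...]] = {
    "delta-theta-alpha1-alpha2-beta1-beta2-gamma": (
        "Delta", "Theta", "Alpha1", "Alpha2", "Beta1", "Beta2", "Gamma"),
    "delta-theta-alpha2-beta1-beta2-gamma": (
        "Delta", "Theta", "Alpha2", "Beta1", "Beta2", "Gamma"),
    "delta-alpha2-beta1-beta2-gamma": ("Delta", "Alpha2", "Beta1", "Beta2", "Gamma"),
    "delta-alpha2-beta2-gamma": ("Delta", "Alpha2", "Beta2", "Gamma"),
    "delta-alpha2-gamma": ("Delta", "Alpha2", "Gamma"),
    "delta-gamma": ("Delta", "Gamma"),
}
BAND_PRESETS["full"] = BAND_PRESETS["delta-theta-alpha1-alpha2-beta1-beta2-gamma"]


@dataclass(frozen=True)
class FilterSpec:
    """Specification of a recursive filter.

    kind "bandpass-cheby1": edges = (low, high); order = Chebyshev order;
    passband_ripple in dB.  kind "notch": edges = (f0,); order unused;
    passband_ripple reinterpreted is ignored and quality factor q applies.
    """

    kind: str
    edges: tuple[float, ...]
    fs: float
    order: int = 4
    passband_ripple: float = 0.5
    q: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass-cheby1", "notch"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if any(e >= self.fs / 2 for e in self.edges):
            raise ValueError("filter edges must lie below Nyquist")
        if any(e <= 0 for e in self.edges):
            raise ValueError("filter edges must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class FilterCoefficients:
    """Second-order sections of a stable recursive filter, plus its rate."""

    sos: np.ndarray
    fs: float

    def response(self, freqs_hz: np.ndarray | float) -> np.ndarray:
        """Magnitude of the (single-pass) frequency response at freqs_hz."""
        w = 2 * np.pi * np.atleast_1d(np.asarray(freqs_hz, dtype=float)) / self.fs
        _, h = signal.sosfreqz(self.sos, worN=w)
        return np.abs(h)


def design_filter(spec: FilterSpec) -> FilterCoefficients:
    """Design a Chebyshev-I bandpass or a second-order IIR notch.

    Raises on unstable designs (any pole magnitude >= 1).
    """
    if spec.kind == "bandpass-cheby1":
        sos = signal.cheby1(
            spec.order, spec.passband_ripple, spec.edges, btype="bandpass",
            fs=spec.fs, output="sos",
        )
    else:
        b, a = signal.iirnotch(spec.edges[0], spec.q, fs=spec.fs)
        sos = signal.tf2sos(b, a)
    _, poles, _ = signal.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0):
        raise ValueError("unstable filter design (pole on or outside unit circle)")
    return FilterCoefficients(sos=sos, fs=spec.fs)


def _filtfilt(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=-1)


def apply_filter(rec: RawRecording, coeffs: FilterCoefficients) -> RawRecording:
    """Channel-wise zero-phase (forward–backward) filtering; shape preserved."""
    order = 2 * coeffs.sos.shape[0]  # effective order from section count
    if rec.n_samples < 3 * (order + 1):
        raise ValueError("recording shorter than 3x filter order")
    out = _filtfilt(coeffs.sos, rec.data)
    return replace(rec, data=out)


def _blink_template(rec: RawRecording) -> np.ndarray:
    """Low-frequency reference from the frontal channels (blink band 0.5–3 Hz)."""
    frontal = rec.data[: min(2, rec.n_channels)].mean(axis=0)
    sos = signal.cheby1(4, 0.5, (0.5, 3.0), btype="bandpass", fs=rec.fs, output="sos")
    return _filtfilt(sos, frontal)


def remove_artifact_components(
    rec: RawRecording,
    n_components: int | None = None,
    reject_rule=None,
    corr_threshold: float = 0.7,
    seed: int = 0,
) -> RawRecording:
    """Best-effort ICA artifact removal.

    Decomposes the recording with FastICA, zeroes the sources flagged by
    reject_rule, and reconstructs.  The default rule flags sources whose
    absolute Pearson correlation with a frontal-channel blink template
    (0.5–3 Hz bandpass of the mean frontal signal) exceeds corr_threshold.
    On decomposition failure the input is returned unchanged with a warning,
    matching the best-effort role of this stage.
    """
    from sklearn.decomposition import FastICA

    n_ch = rec.n_channels
    if n_components is None:
        n_components = n_ch
    if n_components > n_ch:
        raise ValueError("n_components cannot exceed channel count")
    if rec.n_samples < 10 * n_ch:
        raise ValueError("too few samples for ICA decomposition")

    X = rec.data.T  # samples × channels
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(
                n_components=n_components, random_state=seed, max_iter=500, tol=1e-3
            )
            S = ica.fit_transform(X)  # samples × components
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("ICA decomposition failed (%s); returning input unchanged", exc)
        return replace(rec, data=rec.data.copy())

    if reject_rule is None:
        template = _blink_template(rec)

        def reject_rule(sources: np.ndarray) -> np.ndarray:
            t = template - template.mean()
            tn = np.sqrt(np.sum(t * t))
            flags = np.zeros(sources.shape[1], dtype=bool)
            if tn == 0:
                return flags
            for k in range(sources.shape[1]):
                s = sources[:, k] - sources[:, k].mean()
                sn = np.sqrt(np.sum(s * s))
                if sn == 0:
                    continue
                flags[k] = abs(np.dot(s, t) / (sn * tn)) > corr_threshold
            return flags

    flags = np.asarray(reject_rule(S), dtype=bool)
    if flags.any():
        logger.info("rejecting %d ICA component(s)", int(flags.sum()))
    S_clean = S.copy()
    S_clean[:, flags] = 0.0
    X_clean = ica.inverse_transform(S_clean)
    return replace(rec, data=np.ascontiguousarray(X_clean.T))


def downsample(rec: RawRecording, target_fs: float = 125.0) -> RawRecording:
    """Anti-aliased decimation to target_fs; the rate ratio must be an integer."""
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"fs {rec.fs} is not an integer multiple of target {target_fs}"
        )
    factor = int(round(factor))
    if factor == 1:
        return replace(rec, data=rec.data.copy())
    # zero-phase FIR anti-alias filter (unit DC gain, reflection-padded edges)
    h = signal.firwin(20 * factor + 1, 1.0 / factor)
    filtered = signal.filtfilt(h, [1.0], rec.data, axis=-1)
    out = filtered[..., ::factor][..., : rec.n_samples // factor]
    return replace(rec, data=out, fs=target_fs)


@dataclass
class BandStack:
    """Per-band channels × samples arrays at a common sampling rate."""

    data: dict[str, np.ndarray]
    fs: float
    band_names: list[str]
    label: str
    subject_id: str
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {self.data[b].shape for b in self.band_names}
        if len(shapes) > 1:
            raise ValueError("all bands must share one channels × samples shape")

    @property
    def n_channels(self) -> int:
        return self.data[self.band_names[0]].shape[0]

    @property
    def n_samples(self) -> int:
        return self.data[self.band_names[0]].shape[1]


@dataclass
class Segment:
    """One fixed-length analysis window of a BandStack."""

    data: dict[str, np.ndarray]
    fs: float
    band_names: list[str]
    window_s: float
    start_s: float
    label: str
    subject_id: str

    @property
    def n_channels(self) -> int:
        return self.data[self.band_names[0]].shape[0]


def decompose_bands(rec: RawRecording, bands: BandSet | None = None) -> BandStack:
    """Zero-phase Chebyshev-I bandpass per band (order 4, 0.5 dB ripple)."""
    if bands is None:
        bands = BandSet()
    if not bands.bands:
        raise ValueError("empty BandSet")
    out: dict[str, np.ndarray] = {}
    for name, lo, hi in bands.bands:
        if hi >= rec.fs / 2:
            raise ValueError(f"band {name} upper edge {hi} Hz >= Nyquist {rec.fs / 2}")
        coeffs = design_filter(
            FilterSpec(kind="bandpass-cheby1", edges=(lo, hi), fs=rec.fs)
        )
        out[name] = _filtfilt(coeffs.sos, rec.data)
    return BandStack(
        data=out,
        fs=rec.fs,
        band_names=bands.names,
        label=rec.label,
        subject_id=rec.subject_id,
        channel_labels=list(rec.channel_labels),
    )


def sliding_segments(
    stack: BandStack, window_s: float = 4.0, step_s: float = 2.0
) -> list[Segment]:
    """Fixed windows aligned to the start; the trailing partial window is dropped.

    Count = floor((T - window)/step) + 1 for T >= window, else an empty list.
    """
    win = int(round(window_s * stack.fs))
    step = int(round(step_s * stack.fs))
    n = stack.n_samples
    if win <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if n < win:
        logger.warning("recording shorter than one window; no segments")
        return []
    starts = range(0, n - win + 1, step)
    segs = []
    for s0 in starts:
        segs.append(
            Segment(
                data={b: stack.data[b][:, s0 : s0 + win] for b in stack.band_names},
                fs=stack.fs,
                band_names=list(stack.band_names),
                window_s=window_s,
                start_s=s0 / stack.fs,
                label=stack.label,
                subject_id=stack.subject_id,
            )
        )
    return segs


def resolve_combo(combo: str | list[str] | tuple[str, ...]) -> list[str]:
    """Resolve a preset name or an explicit band-name list to canonical order."""
    if isinstance(combo, str):
        try:
            names = list(BAND_PRESETS[combo.lower()])
        except KeyError:
            raise KeyError(
                f"unknown band preset {combo!r}; available: {sorted(BAND_PRESETS)}"
            ) from None
    else:
        names = list(combo)
    if len(set(names)) != len(names):
        raise ValueError("duplicate band names in combination")
    canonical = list(CANONICAL_BANDS)
    for n in names:
        if n not in canonical:
            raise ValueError(f"unknown band name {n!r}")
    return sorted(names, key=canonical.index)


def select_bands(segment: Segment, combo: str | list[str]) -> Segment:
    """Retain the named bands (preset name or list) in canonical order."""
    names = resolve_combo(combo)
    missing = [n for n in names if n not in segment.band_names]
    if missing:
        raise ValueError(f"bands {missing} not present in segment")
    return Segment(
        data={b: segment.data[b] for b in names},
        fs=segment.fs,
        band_names=names,
        window_s=segment.window_s,
        start_s=segment.start_s,
        label=segment.label,
        subject_id=segment.subject_id,
    )


def preprocess_recording(
    rec: RawRecording,
    *,
    run_ica: bool = False,
    bands: BandSet | None = None,
    window_s: float = 4.0,
    step_s: float = 2.0,
    target_fs: float = 125.0,
    seed: int = 0,
) -> list[Segment]:
    """Full pipeline: 1–100 Hz bandpass, 50 Hz notch, optional ICA,
    downsampling, band decomposition, and sliding-window segmentation."""
    bp = design_filter(
        FilterSpec(kind="bandpass-cheby1", edges=(1.0, 100.0), fs=rec.fs)
    )
    notch = design_filter(FilterSpec(kind="notch", edges=(50.0,), fs=rec.fs))
    rec = apply_filter(rec, bp)
    rec = apply_filter(rec, notch)
    if run_ica:
        rec = remove_artifact_components(rec, seed=seed)
    rec = downsample(rec, target_fs=target_fs)
    stack = decompose_bands(rec, bands)
    return sliding_segments(stack, window_s=window_s, step_s=step_s)
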