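"""Permutation conditional mutual information (PCMI) and coupling feature tensors.

PCMI quantifies directed information flow between two time series by first
reducing each series to ordinal patterns — the permutation that sorts each
m-sample delay vector — and then estimating the conditional mutual information

    I(y_{t+delta} ; x_t | y_t)

between the symbol sequences, averaged over a small set of prediction lags
delta.  Working on ordinal patterns makes the estimate exactly invariant under
strictly increasing transforms of either series and robust to noise, at the
cost of discarding amplitude information.

Defaults: embedding order m = 3, embedding lag tau = 1, delta in {1, 2},
logarithms base 2 (bits).  With 4 s windows at 125 Hz (500 samples, ~498
symbols) the m = 3 trivariate histogram (6^3 = 216 cells) is adequately
populated, whereas m = 4 (24^3 cells) would be hopelessly sparse.  The
prediction lags delta = 1-2 samples (8-16 ms at 125 Hz) sit in the range of
cortico-cortical conduction delays; much longer lags dilute the directional
asymmetry of narrowband rhythms.

The per-band 16 x 16 directed coupling matrices, stacked over a band
combination, form the H x W x C feature tensors consumed by the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np

from .preprocess import Segment, resolve_combo

__all__ = [
    "SymbolSequence",
    "PcmiParams",
    "CouplingMatrix",
    "FeatureTensor",
    "ordinalize",
    "permutation_entropy",
    "pcmi_directed",
    "coupling_matrix",
    "feature_tensor",
]


@dataclass(frozen=True)
class SymbolSequence:
    """Ordinal-pattern codes of one channel; codes lie in [0, m! - 1]."""

    codes: np.ndarray
    m: int
    tau: int
    source_length: int

    def __post_init__(self) -> None:
        expected = self.source_length - (self.m - 1) * self.tau
        if len(self.codes) != expected:
            raise ValueError(
                f"code count {len(self.codes)} != expected {expected}"
            )


@dataclass(frozen=True)
class PcmiParams:
    """PCMI estimation parameters: embedding order/lag and prediction lags."""

    m: int = 3
    tau: int = 1
    delta_set: tuple[int, ...] = (1, 2)
    pseudo_count: float = 0.0

    def __post_init__(self) -> None:
        if not (2 <= self.m <= 7):
            raise ValueError("embedding order m must be in [2, 7]")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if not self.delta_set or min(self.delta_set) < 1:
            raise ValueError("delta_set must contain lags >= 1")


def _lehmer_codes(ranks: np.ndarray, m: int) -> np.ndarray:
    """Lexicographic rank of each permutation row (Lehmer code base conversion)."""
    n = ranks.shape[0]
    codes = np.zeros(n, dtype=np.int64)
    for i in range(m):
        # number of later entries smaller than ranks[:, i]
        smaller = np.zeros(n, dtype=np.int64)
        for j in range(i + 1, m):
            smaller += ranks[:, j] < ranks[:, i]
        codes += smaller * factorial(m - 1 - i)
    return codes


def ordinalize(x: np.ndarray, m: int = 3, tau: int = 1) -> SymbolSequence:
    """Map a 1-D series to ordinal-pattern codes.

    The code at index t is the lexicographic rank of the argsort permutation of
    (x_t, x_{t+tau}, ..., x_{t+(m-1)tau}).  Ties are broken by temporal order:
    of two equal samples the earlier one ranks lower (argsort stability).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if not (2 <= m <= 7):
        raise ValueError("embedding order m must be in [2, 7] (m! patterns)")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    n_vec = len(x) - (m - 1) * tau
    if n_vec < 1:
        raise ValueError(
            f"series of length {len(x)} too short for m={m}, tau={tau}"
        )
    idx = np.arange(n_vec)[:, None] + tau * np.arange(m)[None, :]
    vecs = x[idx]  # n_vec × m delay vectors
    # stable argsort => ties broken by temporal order
    order = np.argsort(vecs, axis=1, kind="stable")
    codes = _lehmer_codes(order, m)
    return SymbolSequence(codes=codes, m=m, tau=tau, source_length=len(x))


def permutation_entropy(s: SymbolSequence) -> float:
    """Shannon entropy (bits) of the plug-in ordinal-pattern distribution."""
    if len(s.codes) == 0:
        raise ValueError("empty symbol sequence")
    counts = np.bincount(s.codes, minlength=factorial(s.m))
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p))) + 0.0


def _cmi_from_counts(counts: np.ndarray, k: int) -> float:
    """Plug-in I(y'; x | y) in bits from a flattened k*k*k count array.

    Index layout: code = y' * k*k + x * k + y.  Zero cells contribute 0.
    """
    n = counts.sum()
    if n == 0:
        return 0.0
    joint = counts.reshape(k, k, k).astype(np.float64)  # (y', x, y)
    p_xyz = joint / n
    p_y = p_xyz.sum(axis=(0, 1))          # p(y)
    p_ypy = p_xyz.sum(axis=1)             # p(y', y)
    p_xy = p_xyz.sum(axis=0)              # p(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = p_xyz * p_y[None, None, :]
        den = p_ypy[:, None, :] * p_xy[None, :, :]
        ratio = np.where(p_xyz > 0, num / den, 1.0)
        terms = np.where(p_xyz > 0, p_xyz * np.log2(ratio), 0.0)
    return float(terms.sum())


def pcmi_directed(
    sx: SymbolSequence, sy: SymbolSequence, delta_set=(1, 2),
    pseudo_count: float = 0.0,
) -> float:
    """Directed coupling x -> y: mean over delta of plug-in I(y_{t+d}; x_t | y_t).

    Estimated from the empirical histogram of symbol triples
    (y_{t+d}, x_t, y_t); non-negative up to floating-point tolerance.
    """
    if (sx.m, sx.tau) != (sy.m, sy.tau):
        raise ValueError("sequences must share (m, tau)")
    if len(sx.codes) != len(sy.codes):
        raise ValueError("sequences must have equal length")
    n = len(sx.codes)
    dmax = max(delta_set)
    if n <= dmax:
        raise ValueError(f"sequence length {n} too short for delta {dmax}")
    k = factorial(sx.m)
    x = sx.codes
    y = sy.codes
    total = 0.0
    for d in delta_set:
        combined = y[d:] * (k * k) + x[: n - d] * k + y[: n - d]
        counts = np.bincount(combined, minlength=k**3).astype(np.float64)
        if pseudo_count:
            counts = counts + pseudo_count
        total += _cmi_from_counts(counts, k)
    return total / len(delta_set)


@dataclass(frozen=True)
class CouplingMatrix:
    """n x n directed PCMI matrix (bits); entry (i, j) is channel_i -> channel_j."""

    values: np.ndarray
    band: str

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("coupling matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("coupling matrix must be finite")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly 0")
        if np.any(v < -1e-9):
            raise ValueError("PCMI values must be non-negative (tolerance 1e-9)")


@dataclass(frozen=True)
class FeatureTensor:
    """H x W x C stack of per-band coupling matrices (classifier input)."""

    values: np.ndarray
    band_order: tuple[str, ...]
    label: str
    subject_id: str
    params: PcmiParams = field(default_factory=PcmiParams)

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("feature tensor must be H x W x C")
        if self.values.shape[2] != len(self.band_order):
            raise ValueError("channel axis must match band_order length")


def _band_symbols(seg: Segment, band: str, params: PcmiParams) -> np.ndarray:
    """Ordinal codes for every channel of one band: n_channels × n_symbols."""
    data = seg.data[band]
    return np.stack(
        [ordinalize(row, params.m, params.tau).codes for row in data]
    )


def coupling_matrix(
    seg: Segment, band: str, params: PcmiParams | None = None
) -> CouplingMatrix:
    """All ordered channel pairs' PCMI on one band of a segment; diagonal 0.

    Vectorised over source channels: for each (target j, delta) the target-side
    part of the triple code is shared across sources.
    """
    if params is None:
        params = PcmiParams()
    if band not in seg.band_names:
        raise ValueError(f"segment has no band {band!r}")
    S = _band_symbols(seg, band, params)
    n_ch, n = S.shape
    k = factorial(params.m)
    dmax = max(params.delta_set)
    if n <= dmax:
        raise ValueError("segment too short for the requested delta set")
    M = np.zeros((n_ch, n_ch))
    for j in range(n_ch):
        y = S[j]
        for d in params.delta_set:
            base = y[d:] * (k * k) + y[: n - d]
            for i in range(n_ch):
                if i == j:
                    continue
                combined = base + S[i, : n - d] * k
                counts = np.bincount(combined, minlength=k**3).astype(np.float64)
                if params.pseudo_count:
                    counts = counts + params.pseudo_count
                M[i, j] += _cmi_from_counts(counts, k)
    M /= len(params.delta_set)
    np.fill_diagonal(M, 0.0)
    M = np.maximum(M, 0.0)  # clip the -1e-16-scale round-off
    return CouplingMatrix(values=M, band=band)


def feature_tensor(
    seg: Segment, combo: str | list[str], params: PcmiParams | None = None
) -> FeatureTensor:
    """Stack per-band coupling matrices (canonical band order) into H x W x C."""
    if params is None:
        params = PcmiParams()
    names = resolve_combo(combo)
    if not names:
        raise ValueError("band combination must be non-empty")
    mats = [coupling_matrix(seg, b, params).values for b in names]
    values = np.stack(mats, axis=-1)
    return FeatureTensor(
        values=values,
        band_order=tuple(names),
        label=seg.label,
        subject_id=seg.subject_id,
        params=params,
    )
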