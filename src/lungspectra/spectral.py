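"""Short-time Fourier transform dimensionality reduction and statistics.

Each subject's expression profile is treated as a 1-D signal along the
array's native gene ordering.  The signal is split into Blackman-windowed
frames, each frame is Fourier-transformed, and the one-sided magnitude
spectra are averaged across frames.  With the default 4096-point transform a
12,533-gene profile reduces to 4096/2 + 1 = 2049 spectral features.

A statistical characterization battery (moments, entropies, correlation and
two-sample tests) summarizes the reduced features per class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidConfigError
from .synthdata import ADENO, MESO, ExpressionMatrix


@dataclass(frozen=True)
class WindowSpec:
    """Framing parameters for the short-time Fourier transform.

    ``transform_size`` is the DFT length; the one-sided output has
    transform_size/2 + 1 bins.  The window is always a symmetric Blackman
    window (endpoints vanish), the shape that minimizes spectral leakage
    among the classic three-term windows.
    """

    window_length: int = 4096
    hop: int = 2048
    transform_size: int = 4096

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.window_length <= self.transform_size):
            raise InvalidConfigError(
                "require 0 < hop <= window_length <= transform_size"
            )
        if self.transform_size % 2 != 0:
            raise InvalidConfigError("transform_size must be even")

    @property
    def n_features(self) -> int:
        return self.transform_size // 2 + 1


@dataclass
class SpectralFeatures:
    """Feature x subject matrix of aggregated one-sided spectral magnitudes."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise InvalidConfigError("values must be 2-D (features x subjects)")
        if self.labels.shape[0] != self.values.shape[1]:
            raise InvalidConfigError("label count must equal subject count")
        if np.any(self.values < 0):
            raise InvalidConfigError("spectral magnitudes must be non-negative")

    @property
    def feature_count(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    def class_values(self, label: str) -> np.ndarray:
        return self.values[:, self.labels == label]


def blackman_window(m: int) -> np.ndarray:
    """Symmetric Blackman window w[n] = 0.42 − 0.5cos(2πn/(M−1)) + 0.08cos(4πn/(M−1))."""
    if m < 2:
        raise InvalidConfigError("window length must be at least 2")
    return np.blackman(m)


def _frame_signal(x: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Split ``x`` into ceil(N/hop) frames of window_length, zero-padded."""
    n = x.shape[-1]
    n_frames = math.ceil(n / spec.hop)
    padded_len = (n_frames - 1) * spec.hop + spec.window_length
    pad = padded_len - n
    x = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(0, pad)])
    idx = np.arange(spec.window_length)[None, :] + (
        spec.hop * np.arange(n_frames)[:, None]
    )
    return x[..., idx]


def stft(signal: np.ndarray, spec: WindowSpec | None = None) -> np.ndarray:
    """Windowed frame-wise DFT of a real signal.

    Returns a complex (n_frames, transform_size/2 + 1) array of one-sided
    spectra; frame f, bin k is sum_n x[n]·w[n − f·hop]·exp(−j2πkn/Nfft).
    The signal is zero-padded so every frame is complete.
    """
    spec = spec or WindowSpec()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InvalidConfigError("signal must be a non-empty 1-D sequence")
    frames = _frame_signal(x, spec) * blackman_window(spec.window_length)
    return np.fft.rfft(frames, n=spec.transform_size, axis=-1)


def spectral_features(
    data: ExpressionMatrix,
    spec: WindowSpec | None = None,
    aggregate: str = "mean",
) -> SpectralFeatures:
    """Reduce each subject's gene vector to a fixed-length magnitude spectrum.

    Per subject, frame magnitudes are combined across frames by ``aggregate``
    ("mean", the default order-invariant reduction, or "max").  With default
    parameters a 12,533-gene subject yields 2049 features.
    """
    spec = spec or WindowSpec()
    if data.n_genes < spec.window_length:
        raise InvalidConfigError(
            f"gene count {data.n_genes} is smaller than the window length "
            f"{spec.window_length}; use a smaller window"
        )
    if aggregate not in ("mean", "max"):
        raise InvalidConfigError("aggregate must be 'mean' or 'max'")

    # frames for all subjects at once: (subjects, n_frames, M)
    frames = _frame_signal(data.values.T, spec) * blackman_window(spec.window_length)
    mags = np.abs(np.fft.rfft(frames, n=spec.transform_size, axis=-1))
    combined = mags.mean(axis=1) if aggregate == "mean" else mags.max(axis=1)
    return SpectralFeatures(values=combined.T, labels=data.labels.copy())


# ---------------------------------------------------------------------------
# statistical characterization battery
# ---------------------------------------------------------------------------


@dataclass
class StatSummary:
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    pcc: float
    permutation_entropy: float
    sample_entropy: float
    f_statistic: float
    t_statistic: float
    p_value: float
    cca: float
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy (natural log, divided by log(order!)).

    A strictly monotone series exhibits a single ordinal pattern and has
    entropy exactly 0; a fully irregular series approaches 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size - (order - 1) * delay
    if n < 1:
        raise InvalidConfigError("series too short for the requested order/delay")
    emb = np.stack([x[i * delay : i * delay + n] for i in range(order)], axis=1)
    patterns = np.argsort(emb, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / math.log(math.factorial(order)))


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy with template length ``m`` and tolerance ``r`` (0.2·sd)."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * float(np.std(x))
    n = x.size

    def _count(mm: int) -> int:
        # n - m templates for both lengths, the standard convention
        n_templ = n - m
        templ = np.stack([x[i : n_templ + i] for i in range(mm)], axis=1)
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
        mask = d <= r
        np.fill_diagonal(mask, False)
        return int(mask.sum())

    b = _count(m)
    a = _count(m + 1)
    if b == 0 or a == 0:
        return float("inf")
    return float(-math.log(a / b))


def first_canonical_correlation(
    class_a: np.ndarray, class_b: np.ndarray, max_rank: int = 10
) -> float:
    """Largest canonical correlation between two sample sets' leading subspaces.

    Each class matrix is feature x subject; its leading principal subspace
    (rank min(n_subjects)−1, capped at ``max_rank``) is computed in feature
    space and the largest principal-angle cosine between the two subspaces is
    returned.  Invariant to subject-column permutation; 1.0 for identical
    sample sets.  Ridge regularization keeps rank-deficient input finite.
    """
    a = np.asarray(class_a, dtype=float)
    b = np.asarray(class_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise InvalidConfigError("class matrices must share the feature dimension")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise InvalidConfigError("each class needs at least 2 subjects")
    rank = min(min(a.shape[1], b.shape[1]) - 1, max_rank)

    def _basis(x: np.ndarray) -> np.ndarray:
        xc = x - x.mean(axis=1, keepdims=True)
        try:
            u, _, _ = np.linalg.svd(xc, full_matrices=False)
        except np.linalg.LinAlgError:
            # ridge fallback for pathological (non-convergent) input
            g = xc @ xc.T + 1e-8 * np.eye(xc.shape[0])
            _, u = np.linalg.eigh(g)
            u = u[:, ::-1]
        return u[:, :rank]

    ua, ub = _basis(a), _basis(b)
    s = np.linalg.svd(ua.T @ ub, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def _mean_pairwise_pcc(columns: np.ndarray) -> float:
    if columns.shape[1] < 2:
        return float("nan")
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(columns.T)
    iu = np.triu_indices_from(c, k=1)
    vals = c[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def stat_summary(features: SpectralFeatures, class_label: str) -> StatSummary:
    """Characterize one class's spectral features against the other class.

    Moments are pooled over the class's feature values; entropies are
    computed per subject (permutation order 3 / lag 1, sample entropy m=2,
    r=0.2·sd) and averaged; the f- and t-tests compare the two classes'
    pooled values; CCA is the leading canonical correlation between the two
    classes' principal subspaces.
    """
    if class_label not in (ADENO, MESO):
        raise InvalidConfigError(f"unknown class label {class_label!r}")
    this = features.class_values(class_label)
    other_label = MESO if class_label == ADENO else ADENO
    other = features.class_values(other_label)
    if this.shape[1] < 2:
        raise InvalidConfigError("need at least 2 subjects for dispersion statistics")

    pooled = this.ravel()
    notes: list[str] = []
    degenerate = bool(np.ptp(pooled) == 0)
    if degenerate:
        notes.append("constant data: skewness/kurtosis reported as 0")
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(pooled))
        kurt = float(stats.kurtosis(pooled, fisher=False))

    pe = float(np.mean([permutation_entropy(col) for col in this.T]))
    se = float(np.mean([sample_entropy(col) for col in this.T]))

    pooled_other = other.ravel()
    var_this = float(np.var(pooled, ddof=1))
    var_other = float(np.var(pooled_other, ddof=1))
    if var_other > 0:
        f_stat = var_this / var_other
    else:
        f_stat = 0.0
        notes.append("degenerate f-test: reference class has zero variance")
    if degenerate and np.ptp(pooled_other) == 0:
        t_stat, p_val = 0.0, 1.0
        notes.append("degenerate t-test on constant data")
    else:
        t_res = stats.ttest_ind(pooled, pooled_other, equal_var=False)
        t_stat, p_val = float(t_res.statistic), float(t_res.pvalue)

    cca = first_canonical_correlation(this, other) if other.shape[1] >= 2 else float("nan")

    return StatSummary(
        mean=float(pooled.mean()),
        variance=var_this,
        skewness=skew,
        kurtosis=kurt,
        pcc=_mean_pairwise_pcc(this),
        permutation_entropy=pe,
        sample_entropy=se,
        f_statistic=f_stat,
        t_statistic=t_stat,
        p_value=p_val,
        cca=cca,
        degenerate=degenerate,
        notes=notes,
    )
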