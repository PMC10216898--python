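r"""Hankel embedding of EEG windows and GLCM/Haralick texture features.

The core idea: a 1-D EEG window :math:`X_1` of length :math:`L` is
embedded as an :math:`L \times L` Hankel matrix — first column
:math:`X_1`, last row the reversal of :math:`X_1`, constant along every
anti-diagonal — turning the segment into a 2-D "image" whose texture
reflects the signal's autocorrelation structure. The image is linearly
quantized to ``G`` gray levels (``G = 8`` by default), a gray-level
co-occurrence matrix (GLCM) is accumulated for a single pixel offset
(horizontal right-neighbor by default), and 19 Haralick texture
statistics are computed from the normalized GLCM and its marginals.

Per recording, each channel is cut into ``n_windows`` equal-length
non-overlapping windows (50 by default) and each window yields the 19
features, so a channel contributes ``n_windows * 19`` features
(950 at defaults) and a 57-channel recording contributes 54,150.

Because quantization rescales each image to its own min-max range, the
features are invariant to a positive rescaling of the window — class
information enters through waveform *shape* (e.g. oscillatory content),
not raw amplitude.

:class:`HankelTextureExtractor` wraps the whole per-subject extraction
as a scikit-learn transformer so it composes with pipelines and model
selection; the module-level functions are the individual stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.linalg import hankel
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import FeatureTable, Recording

__all__ = [
    "HARALICK_FEATURE_NAMES",
    "QuantizedImage",
    "GLCM",
    "segment",
    "hankelize",
    "quantize",
    "compute_glcm",
    "haralick_features",
    "extract_subject",
    "extract_cohort",
    "HankelTextureExtractor",
]

#: The 19 texture statistics, in the fixed (alphabetical) output order.
HARALICK_FEATURE_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "contrast",
    "correlation",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "imc1",
    "imc2",
    "inverse_difference",
    "max_probability",
    "sum_average",
    "sum_entropy",
    "sum_of_squares_variance",
    "sum_variance",
)


def segment(channel: np.ndarray, n_windows: int = 50) -> np.ndarray:
    """Cut a channel into equal-length non-overlapping windows.

    Returns an array of shape ``(n_windows, L)`` with
    ``L = floor(N / n_windows)``; the final ``N mod n_windows`` samples
    are discarded.
    """
    channel = np.asarray(channel, dtype=float).ravel()
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    length = channel.size // n_windows
    if length == 0:
        raise ValueError(
            f"channel of {channel.size} samples is too short for "
            f"{n_windows} windows"
        )
    return channel[: n_windows * length].reshape(n_windows, length)


def hankelize(window: np.ndarray) -> np.ndarray:
    """Embed a 1-D window as its square Hankel matrix.

    The first column is the window itself; the last row is the window
    reversed; every anti-diagonal is constant.
    """
    window = np.asarray(window, dtype=float).ravel()
    if window.size == 0:
        raise ValueError("cannot hankelize an empty window")
    return hankel(window, window[::-1])


@dataclass(frozen=True)
class QuantizedImage:
    """Integer image with entries in ``1..levels``."""

    values: np.ndarray
    levels: int
    gray_limits: tuple[float, float]


def quantize(
    img: np.ndarray,
    levels: int = 8,
    gray_limits: tuple[float, float] | None = None,
) -> QuantizedImage:
    """Linearly scale an image into ``levels`` gray levels.

    Equal-width bins over ``gray_limits`` (the image min-max when not
    given); values at or above the upper limit clamp to ``levels``,
    values at or below the lower limit map to 1. A constant image (zero
    range) maps entirely to level 1.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = np.asarray(img, dtype=float)
    lo, hi = gray_limits if gray_limits is not None else (img.min(), img.max())
    if hi <= lo:
        q = np.ones(img.shape, dtype=np.int64)
    else:
        scaled = (np.clip(img, lo, hi) - lo) / (hi - lo)
        q = np.minimum(np.floor(scaled * levels).astype(np.int64) + 1, levels)
    return QuantizedImage(values=q, levels=levels, gray_limits=(float(lo), float(hi)))


@dataclass(frozen=True)
class GLCM:
    """Gray-level co-occurrence counts for one pixel offset.

    ``counts[i, j]`` (0-based storage for levels ``i+1``, ``j+1``) is the
    number of pixel positions ``p`` with level ``i+1`` at ``p`` and level
    ``j+1`` at ``p + offset``. ``normalized`` is the joint probability
    ``p(i, j)``; marginals, sum/difference distributions, moments and
    entropies are derived from it (natural log, ``0 log 0 := 0``).
    """

    counts: np.ndarray
    offset: tuple[int, int]
    symmetric: bool = False

    @property
    def levels(self) -> int:
        return self.counts.shape[0]

    @cached_property
    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("GLCM has no counts")
        return self.counts / total

    @cached_property
    def px(self) -> np.ndarray:
        return self.normalized.sum(axis=1)

    @cached_property
    def py(self) -> np.ndarray:
        return self.normalized.sum(axis=0)

    @cached_property
    def p_sum(self) -> np.ndarray:
        """Distribution of ``i + j`` over levels; index k-2 holds k=2..2G."""
        G, p = self.levels, self.normalized
        out = np.zeros(2 * G - 1)
        i, j = np.indices((G, G))
        np.add.at(out, (i + j).ravel(), p.ravel())
        return out

    @cached_property
    def p_diff(self) -> np.ndarray:
        """Distribution of ``|i - j|``; index k holds k=0..G-1."""
        G, p = self.levels, self.normalized
        out = np.zeros(G)
        i, j = np.indices((G, G))
        np.add.at(out, np.abs(i - j).ravel(), p.ravel())
        return out


def compute_glcm(
    q: QuantizedImage | np.ndarray,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = False,
    levels: int | None = None,
) -> GLCM:
    """Accumulate the co-occurrence counts of a quantized image.

    ``offset = (row_shift, col_shift)`` names the neighbor of each pixel;
    the default ``(0, 1)`` is the horizontal right-neighbor at distance 1.
    With ``symmetric=True`` the transposed counts are added, making the
    matrix direction-insensitive.
    """
    if isinstance(q, QuantizedImage):
        values, G = q.values, q.levels
    else:
        values = np.asarray(q)
        G = levels if levels is not None else int(values.max())
    dr, dc = offset
    if dr == 0 and dc == 0:
        raise ValueError("offset must be nonzero")
    if values.min() < 1 or values.max() > G:
        raise ValueError(f"image entries must lie in 1..{G}")

    R, C = values.shape
    r0, r1 = max(0, -dr), R - max(0, dr)
    c0, c1 = max(0, -dc), C - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"image of shape {values.shape} too small for offset {offset}")
    a = values[r0:r1, c0:c1]
    b = values[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    flat = (a.astype(np.int64) - 1) * G + (b.astype(np.int64) - 1)
    counts = np.bincount(flat.ravel(), minlength=G * G).reshape(G, G)
    if symmetric:
        counts = counts + counts.T
    return GLCM(counts=counts, offset=(dr, dc), symmetric=symmetric)


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0 log 0 := 0 convention."""
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def haralick_features(g: GLCM) -> np.ndarray:
    """Compute the 19 texture statistics of a normalized GLCM.

    Levels are indexed 1..G. Returned in :data:`HARALICK_FEATURE_NAMES`
    order. Degenerate cases: correlation is 0 when either marginal has
    zero variance; imc1 is 0 when both marginal entropies are 0; the
    imc2 radicand is clamped at 0 against floating-point undershoot.
    """
    p = g.normalized
    G = g.levels
    levels = np.arange(1, G + 1, dtype=float)
    i = levels[:, None]
    j = levels[None, :]

    px, py = g.px, g.py
    mu_x = float((levels * px).sum())
    mu_y = float((levels * py).sum())
    sigma_x = float(np.sqrt(((levels - mu_x) ** 2 * px).sum()))
    sigma_y = float(np.sqrt(((levels - mu_y) ** 2 * py).sum()))

    # sum/difference distributions on their natural supports
    k_sum = np.arange(2, 2 * G + 1, dtype=float)
    p_sum = g.p_sum
    k_diff = np.arange(0, G, dtype=float)
    p_diff = g.p_diff

    hx, hy, hxy = _entropy(px), _entropy(py), _entropy(p)
    pxpy = px[:, None] * py[None, :]
    mask = pxpy > 0
    hxy1 = float(-(p[mask] * np.log(pxpy[mask])).sum())
    hxy2 = _entropy(pxpy.ravel())

    autocorrelation = float((i * j * p).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    if sigma_x * sigma_y > 0:
        correlation = (autocorrelation - mu_x * mu_y) / (sigma_x * sigma_y)
    else:
        correlation = 0.0
    shade_base = i + j - mu_x - mu_y
    cluster_shade = float((shade_base**3 * p).sum())
    cluster_prominence = float((shade_base**4 * p).sum())
    dissimilarity = float((np.abs(i - j) * p).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1 + (i - j) ** 2)).sum())
    inverse_difference = float((p / (1 + np.abs(i - j))).sum())
    max_probability = float(p.max())
    sum_average = float((k_sum * p_sum).sum())
    sum_entropy = _entropy(p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_of_squares_variance = float(((i - mu_x) ** 2 * p).sum())
    difference_entropy = _entropy(p_diff)
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    values = {
        "autocorrelation": autocorrelation,
        "cluster_prominence": cluster_prominence,
        "cluster_shade": cluster_shade,
        "contrast": contrast,
        "correlation": correlation,
        "difference_entropy": difference_entropy,
        "difference_variance": difference_variance,
        "dissimilarity": dissimilarity,
        "energy": energy,
        "entropy": hxy,
        "homogeneity": homogeneity,
        "imc1": imc1,
        "imc2": imc2,
        "inverse_difference": inverse_difference,
        "max_probability": max_probability,
        "sum_average": sum_average,
        "sum_entropy": sum_entropy,
        "sum_of_squares_variance": sum_of_squares_variance,
        "sum_variance": sum_variance,
    }
    return np.array([values[name] for name in HARALICK_FEATURE_NAMES])


def _window_features(
    window: np.ndarray,
    levels: int,
    offset: tuple[int, int],
    symmetric: bool,
) -> np.ndarray:
    img = hankelize(window)
    q = quantize(img, levels=levels)
    g = compute_glcm(q, offset=offset, symmetric=symmetric)
    return haralick_features(g)


def extract_subject(
    rec: Recording,
    n_windows: int = 50,
    levels: int = 8,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = False,
) -> tuple[np.ndarray, list[tuple[str, int, str]]]:
    """Extract one subject's full feature vector.

    Channel-major ordering: for each channel, for each window, the 19
    features in :data:`HARALICK_FEATURE_NAMES` order — total length
    ``n_channels * n_windows * 19``. Returns the vector and the matching
    ``(channel, window, feature)`` provenance triples.
    """
    parts: list[np.ndarray] = []
    feature_ids: list[tuple[str, int, str]] = []
    for ch_idx, name in enumerate(rec.channel_names):
        try:
            windows = segment(rec.data[ch_idx], n_windows)
        except ValueError as exc:
            raise ValueError(f"channel {name!r}: {exc}") from exc
        for w_idx in range(windows.shape[0]):
            parts.append(_window_features(windows[w_idx], levels, offset, symmetric))
            feature_ids.extend(
                (name, w_idx, feat) for feat in HARALICK_FEATURE_NAMES
            )
    return np.concatenate(parts), feature_ids


def extract_cohort(
    recordings: list[Recording],
    n_windows: int = 50,
    levels: int = 8,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = False,
) -> FeatureTable:
    """Extract a feature table for a list of recordings."""
    if not recordings:
        raise ValueError("no recordings given")
    rows, feature_ids = [], None
    for rec in recordings:
        vec, fids = extract_subject(rec, n_windows, levels, offset, symmetric)
        if feature_ids is None:
            feature_ids = fids
        elif fids != feature_ids:
            raise ValueError(
                f"subject {rec.subject_id!r} produced a different feature layout; "
                "all recordings must share channels and length"
            )
        rows.append(vec)
    return FeatureTable(
        values=np.vstack(rows),
        labels=np.array([rec.label for rec in recordings]),
        feature_ids=feature_ids,
        subject_ids=[rec.subject_id for rec in recordings],
    )


class HankelTextureExtractor(TransformerMixin, BaseEstimator):
    """Hankel-GLCM texture feature extraction as a sklearn transformer.

    Transforms a cohort — a list of :class:`~eegtexture.io.Recording` or
    an array of shape ``(n_subjects, n_channels, n_samples)`` — into a
    2-D feature matrix of shape ``(n_subjects, n_channels * n_windows * 19)``.
    The transform is stateless (``fit`` only records the layout), so it
    never leaks information across cross-validation folds.

    Parameters
    ----------
    n_windows : int, default=50
        Equal-length non-overlapping windows per channel.
    levels : int, default=8
        Gray levels for quantization.
    offset : tuple of int, default=(0, 1)
        GLCM neighbor offset (row shift, column shift).
    symmetric : bool, default=False
        Whether to symmetrize the co-occurrence counts.
    """

    def __init__(
        self,
        n_windows: int = 50,
        levels: int = 8,
        offset: tuple[int, int] = (0, 1),
        symmetric: bool = False,
    ):
        self.n_windows = n_windows
        self.levels = levels
        self.offset = offset
        self.symmetric = symmetric

    def _as_recordings(self, X) -> list[Recording]:
        if len(X) == 0:
            raise ValueError("empty cohort")
        if isinstance(X[0], Recording):
            return list(X)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 3:
            raise ValueError(
                "X must be a list of Recording or an array "
                "(n_subjects, n_channels, n_samples)"
            )
        names = [f"ch{c:02d}" for c in range(arr.shape[1])]
        return [
            Recording(subject_id=f"s{idx:03d}", data=arr[idx], fs=1.0,
                      channel_names=names)
            for idx in range(arr.shape[0])
        ]

    def fit(self, X, y=None):
        recs = self._as_recordings(X)
        _, fids = extract_subject(
            recs[0], self.n_windows, self.levels, tuple(self.offset), self.symmetric
        )
        self.feature_ids_ = fids
        self.n_features_out_ = len(fids)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "feature_ids_")
        tbl = extract_cohort(
            self._as_recordings(X),
            self.n_windows,
            self.levels,
            tuple(self.offset),
            self.symmetric,
        )
        if tbl.feature_ids != self.feature_ids_:
            raise ValueError("cohort layout differs from the fitted layout")
        return tbl.values

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "feature_ids_")
        return np.array([f"{c}.{w}.{f}" for c, w, f in self.feature_ids_], dtype=object)
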