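"""Gray-level co-occurrence (second-order) texture features of a lesion.

The lesion intensities are quantized to ``G`` gray levels (default 8; the
pattern granularity a reader distinguishes clinically), then for each of
the four principal directions a symmetric co-occurrence matrix is built
from pixel pairs at distance ``d`` (default 1) *both of which lie inside
the lesion mask* — background never leaks into the texture.  Fourteen
standard statistics are computed per direction and averaged element-wise
over the four directions.

Degenerate cases: a constant lesion has an undefined Correlation and
information measure (zero marginal variance / entropy); those entries are
``nan`` and propagate through the directional mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: canonical feature order, also the CSV column order
TEXTURE_FEATURE_NAMES = (
    "Autocorrelation",
    "Contrast",
    "Correlation",
    "ClusterProminence",
    "ClusterShade",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity",
    "DifferenceVariance",
    "DifferenceEntropy",
    "InformationMeasureOfCorrelation",
    "InverseDifferenceNormalized",
    "InverseDifferenceMoment",
)

#: direction -> (row, col) unit offset of the neighbor
DIRECTION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

DIRECTIONS = tuple(DIRECTION_OFFSETS)


class DegenerateGLCMError(ValueError):
    """Raised when a lesion contains no co-occurring pixel pair at all."""


@dataclass(frozen=True)
class QuantizedROI:
    """Gray levels in ``[0, n_levels)`` inside the mask."""

    levels: np.ndarray  # int, same shape as mask; meaningful only in-mask
    mask: np.ndarray  # bool
    n_levels: int


@dataclass(frozen=True)
class DirectedGLCM:
    counts: np.ndarray  # (G, G) int, symmetric
    probs: np.ndarray  # (G, G) float, sums to 1
    distance: int
    angle: int  # degrees, one of DIRECTIONS


def quantize(image: np.ndarray, mask: np.ndarray, n_levels: int = 8) -> QuantizedROI:
    """Quantize 8-bit intensities to ``floor(value * G / 256)``.

    The mapping is monotone and splits [0, 255] into G equal bins (32 values
    per level at G = 8).
    """
    if n_levels < 2:
        raise ValueError(f"need at least 2 gray levels, got {n_levels}")
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask dimensions differ")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    levels = (image.astype(np.int64) * n_levels) // 256
    return QuantizedROI(levels=levels, mask=mask, n_levels=n_levels)


def build_glcm(q: QuantizedROI, angle: int, distance: int = 1) -> DirectedGLCM:
    """Symmetric directed co-occurrence matrix over in-mask pixel pairs.

    For every in-mask pixel whose neighbor at ``distance`` along ``angle``
    is also in-mask, both ``counts[i, j]`` and ``counts[j, i]`` are
    incremented, so the matrix is symmetric by construction and its
    marginals are well defined.
    """
    if angle not in DIRECTION_OFFSETS:
        raise ValueError(f"angle must be one of {DIRECTIONS}, got {angle}")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    dr, dc = (distance * o for o in DIRECTION_OFFSETS[angle])
    h, w = q.mask.shape
    g = q.n_levels
    src_r = slice(max(0, -dr), h - max(0, dr))
    src_c = slice(max(0, -dc), w - max(0, dc))
    dst_r = slice(max(0, dr), h - max(0, -dr))
    dst_c = slice(max(0, dc), w - max(0, -dc))
    valid = q.mask[src_r, src_c] & q.mask[dst_r, dst_c]
    i = q.levels[src_r, src_c][valid]
    j = q.levels[dst_r, dst_c][valid]
    counts = np.zeros((g, g), dtype=np.int64)
    np.add.at(counts, (i, j), 1)
    np.add.at(counts, (j, i), 1)
    total = counts.sum()
    if total == 0:
        raise DegenerateGLCMError(
            f"lesion has no co-occurring pixel pair at d={distance}, theta={angle}"
        )
    return DirectedGLCM(
        counts=counts, probs=counts / total, distance=distance, angle=angle
    )


def _entropy(p: np.ndarray, log) -> float:
    nz = p[p > 0]
    return float(-(nz * log(nz)).sum())


def texture_statistics(glcm: DirectedGLCM, log_base: str = "natural") -> dict[str, float]:
    """The 14 co-occurrence statistics of one directed matrix.

    With ``p(i, j)`` the normalized matrix over levels ``0..G-1``, marginal
    means/SDs ``mu_x, mu_y, sigma_x, sigma_y`` and the gray-level difference
    distribution ``p_d(k) = sum_{|i-j|=k} p(i, j)``:

    * Autocorrelation          ``sum i*j*p``
    * Contrast                 ``sum (i-j)^2 * p``
    * Correlation              ``(sum i*j*p - mu_x*mu_y) / (sigma_x*sigma_y)``
    * ClusterProminence/Shade  ``sum (i+j-mu_x-mu_y)^{4,3} * p``
    * Dissimilarity            ``sum |i-j| * p``
    * Energy                   ``sum p^2``
    * Entropy                  ``-sum p log p``       (0 log 0 = 0)
    * Homogeneity              ``sum p / (1 + |i-j|)``
    * DifferenceVariance       variance of ``p_d``
    * DifferenceEntropy        ``-sum p_d log p_d``
    * InformationMeasureOfCorrelation  ``(HXY - HXY1) / max(HX, HY)``
    * InverseDifferenceNormalized      ``sum p / (1 + |i-j|/G)``
    * InverseDifferenceMoment          ``sum p / (1 + (i-j)^2/G^2)``

    Entropies use the natural log by default (``log_base='2'`` switches all
    of them to bits; base rescales, it never reorders cases).
    """
    if log_base in ("natural", "e"):
        log = np.log
    elif log_base in ("2", 2):
        log = np.log2
    else:
        raise ValueError(f"log_base must be 'natural' or '2', got {log_base!r}")
    p = glcm.probs
    g = p.shape[0]
    idx = np.arange(g, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    sigma_x = float(np.sqrt(((idx - mu_x) ** 2) @ px))
    sigma_y = float(np.sqrt(((idx - mu_y) ** 2) @ py))
    absdiff = np.abs(i - j)
    # gray-level difference distribution p_{x-y}
    p_d = np.zeros(g)
    for k in range(g):
        p_d[k] = p[absdiff == k].sum()
    k_idx = np.arange(g, dtype=float)
    mu_d = float(k_idx @ p_d)

    autocorr = float((i * j * p).sum())
    if sigma_x * sigma_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sigma_x * sigma_y)
    else:
        correlation = np.nan

    hxy = _entropy(p, log)
    hx = _entropy(px, log)
    hy = _entropy(py, log)
    # HXY1 = -sum p(i,j) log(px(i) py(j)) over cells with px*py > 0
    outer = px[:, None] * py[None, :]
    nz = outer > 0
    hxy1 = float(-(p[nz] * log(outer[nz])).sum())
    if max(hx, hy) > 0:
        imc = (hxy - hxy1) / max(hx, hy)
    else:
        imc = np.nan

    return {
        "Autocorrelation": autocorr,
        "Contrast": float(((i - j) ** 2 * p).sum()),
        "Correlation": float(correlation),
        "ClusterProminence": float(((i + j - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterShade": float(((i + j - mu_x - mu_y) ** 3 * p).sum()),
        "Dissimilarity": float((absdiff * p).sum()),
        "Energy": float((p * p).sum()),
        "Entropy": hxy,
        "Homogeneity": float((p / (1.0 + absdiff)).sum()),
        "DifferenceVariance": float(((k_idx - mu_d) ** 2) @ p_d),
        "DifferenceEntropy": _entropy(p_d, log),
        "InformationMeasureOfCorrelation": float(imc),
        "InverseDifferenceNormalized": float((p / (1.0 + absdiff / g)).sum()),
        "InverseDifferenceMoment": float((p / (1.0 + (i - j) ** 2 / g**2)).sum()),
    }


def mean_over_directions(vectors) -> dict[str, float]:
    """Element-wise mean of the four directional feature vectors.

    Undefined (nan) entries propagate: if any direction could not define a
    statistic, neither can the average.
    """
    vectors = list(vectors)
    if len(vectors) != len(DIRECTIONS):
        raise ValueError(f"expected {len(DIRECTIONS)} directional vectors, got {len(vectors)}")
    for v in vectors:
        if set(v) != set(TEXTURE_FEATURE_NAMES):
            raise ValueError("feature names do not match the canonical set")
    return {
        name: float(np.mean([v[name] for v in vectors]))
        for name in TEXTURE_FEATURE_NAMES
    }


def texture_features(
    image: np.ndarray,
    mask: np.ndarray,
    n_levels: int = 8,
    distance: int = 1,
    log_base: str = "natural",
) -> dict[str, float]:
    """Quantize, build the four directed GLCMs and average their statistics."""
    q = quantize(image, mask, n_levels)
    vectors = [
        texture_statistics(build_glcm(q, angle, distance), log_base=log_base)
        for angle in DIRECTIONS
    ]
    return mean_over_directions(vectors)
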