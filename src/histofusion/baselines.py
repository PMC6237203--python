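"""Engineered texture baselines (LBP, HOG) and the image-feature vs
pathway-score correlation procedure.

Per-patch descriptors are aggregated to a slide-level feature vector by
elementwise mean.  The correlation procedure repeatedly pairs equal-sized
random subsets of image features and pathway scores, computes pairwise
Pearson correlations across samples, and t-tests the coefficient set
against zero; the mean and sd of the p-values across repeats summarize
whether the two modalities are correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.color import rgb2gray
from skimage.feature import hog as _hog
from skimage.feature import local_binary_pattern


@dataclass
class TextureFeatureSet:
    patient_id: str
    method: str  # "lbp" or "hog"
    values: np.ndarray


def _to_gray(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = rgb2gray(arr[..., :3])
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    return arr


def lbp_features(image: np.ndarray, radius: int = 1,
                 points: int = 8) -> np.ndarray:
    """Rotation-invariant uniform LBP code histogram, normalized to sum 1.

    Uses the 'uniform' coding with P sampling points on a circle of the
    given radius; the histogram has P + 2 bins.  The image is quantized to
    8 bits first: LBP thresholds neighbors against the center pixel, and
    float round-off would otherwise scramble codes in flat regions.
    """
    gray = _to_gray(image)
    if min(gray.shape) < 2 * radius + 1:
        raise ValueError("image smaller than the LBP neighborhood")
    gray8 = np.round(gray * 255).astype(np.uint8)
    codes = local_binary_pattern(gray8, points, radius, method="uniform")
    # border pixels lack a full circular neighborhood; exclude them
    codes = codes[radius:-radius, radius:-radius]
    hist, _ = np.histogram(codes, bins=np.arange(points + 3) - 0.5)
    return hist / hist.sum()


def hog_features(image: np.ndarray, cell: int = 16, bins: int = 9,
                 block: int = 2) -> np.ndarray:
    """Histogram-of-oriented-gradients descriptor (L2 block norm)."""
    gray = _to_gray(image)
    h, w = gray.shape
    if h % cell or w % cell:
        raise ValueError(f"image edges {w}x{h} not divisible by cell {cell}")
    return _hog(gray, orientations=bins, pixels_per_cell=(cell, cell),
                cells_per_block=(block, block), block_norm="L2",
                feature_vector=True)


def slide_aggregate(descriptors: list[np.ndarray], patient_id: str = "",
                    method: str = "") -> TextureFeatureSet:
    """Elementwise mean of per-patch descriptors -> slide-level features."""
    if not descriptors:
        raise ValueError("no descriptors to aggregate")
    stack = np.vstack([np.asarray(d, dtype=float) for d in descriptors])
    return TextureFeatureSet(patient_id=patient_id, method=method,
                             values=stack.mean(axis=0))


def feature_pathway_correlation(image_features: np.ndarray,
                                pathway_scores: np.ndarray,
                                n_repeats: int = 50, seed: int = 0,
                                method: str = "pearson"):
    """Correlation screen between image features and pathway scores.

    Both matrices are samples x variables and must share the sample axis.
    Each repeat takes k = min(p_img, p_score) feature columns from each
    matrix, pairs them one-to-one, computes the k correlation coefficients
    across samples, and applies a one-sample two-sided t-test of the
    coefficients against zero.  The first repeats walk consecutive
    k-column blocks of the larger feature set (paired positionally with
    the smaller set) until every feature has been paired; extra repeats
    use random subsets and pairings.  One-to-one pairing keeps the
    coefficients within a repeat (approximately) independent, so the
    per-repeat p-values are calibrated under the no-correlation null.
    Returns (mean p-value, sd of p-values) over repeats.
    """
    X = np.asarray(image_features, dtype=float)
    Y = np.asarray(pathway_scores, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("sample axes differ")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 shared samples")
    rng = np.random.default_rng(seed)
    k = min(X.shape[1], Y.shape[1])
    big, small = (X, Y) if X.shape[1] >= Y.shape[1] else (Y, X)
    n_big = big.shape[1]
    blocks = [np.arange(i, i + k) for i in range(0, n_big - k + 1, k)]
    pvals = []
    for r in range(n_repeats):
        if r < len(blocks):
            big_idx = blocks[r]
            small_idx = np.arange(k)
        else:
            big_idx = np.sort(rng.choice(n_big, size=k, replace=False))
            small_idx = np.sort(rng.choice(small.shape[1], size=k,
                                           replace=False))
        A, B = big[:, big_idx], small[:, small_idx]
        coefs = []
        for i in range(k):
            a, b = A[:, i], B[:, i]
            if a.std() == 0 or b.std() == 0:
                continue
            if method == "spearman":
                coefs.append(stats.spearmanr(a, b).statistic)
            else:
                coefs.append(stats.pearsonr(a, b).statistic)
        if len(coefs) < 2:
            continue
        pvals.append(stats.ttest_1samp(coefs, 0.0).pvalue)
    pvals = np.asarray(pvals)
    return float(pvals.mean()), float(pvals.std(ddof=1))
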