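"""Gene-signature (pathway) scoring and the differential-signature screen.

Expression is preprocessed by log2(x+1) transform and per-gene median
centering.  A signature score is the per-sample mean of the signature's
genes; the differential screen is a two-sided two-sample t-test of scores
between patient groups (Welch by default), flagged at a raw p-value
threshold.  Significant scores can be exported with an average-linkage
hierarchical clustering for heatmap viewers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class PathwayScores:
    """Signatures x samples score matrix plus per-signature match counts."""

    scores: pd.DataFrame
    genes_matched: pd.Series


def preprocess_expression(raw: pd.DataFrame) -> pd.DataFrame:
    """log2(x+1) transform then per-gene median centering.

    Each gene's median across samples becomes exactly 0.  Raw values must
    be non-negative (expression-scale data).
    """
    if raw.index.has_duplicates:
        raise ValueError("duplicate gene symbols")
    values = raw.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative raw expression value")
    logged = np.log2(values + 1.0)
    centered = logged - np.median(logged, axis=1, keepdims=True)
    return pd.DataFrame(centered, index=raw.index, columns=raw.columns)


def signature_score(expr: pd.DataFrame, gene_set: list[str],
                    name: str = "signature") -> tuple[pd.Series, int]:
    """Per-sample mean expression over the signature's genes.

    Only genes present in the expression matrix contribute; the number of
    matched genes is returned alongside the score vector.  An empty
    intersection is an error naming the signature.
    """
    present = expr.index.intersection(pd.Index(gene_set))
    if len(present) == 0:
        raise ValueError(f"signature {name!r}: no genes found in matrix")
    score = expr.loc[present].mean(axis=0)
    return score, len(present)


def score_all(expr: pd.DataFrame, panel: dict[str, list[str]],
              strict: bool = False) -> PathwayScores:
    """Score every signature in the panel against the expression matrix.

    Signatures with no matching genes are skipped with a warning (or raise
    in strict mode).
    """
    rows, counts = {}, {}
    for name, genes in panel.items():
        try:
            score, n = signature_score(expr, genes, name=name)
        except ValueError:
            if strict:
                raise
            logger.warning("signature %r has no matching genes; skipped", name)
            continue
        rows[name] = score
        counts[name] = n
    scores = pd.DataFrame(rows).T
    if scores.empty:
        scores = pd.DataFrame(columns=expr.columns)
    return PathwayScores(scores=scores,
                         genes_matched=pd.Series(counts, dtype=int))


def differential_signatures(scores: pd.DataFrame, groups: pd.Series | np.ndarray,
                            alpha: float = 0.01, equal_var: bool = False,
                            fdr: bool = False) -> pd.DataFrame:
    """Two-sided two-sample t-test of each signature score between groups.

    ``groups`` is a binary labeling of the sample columns; direction is the
    sign of (group-True mean − group-False mean).  ``significant`` uses the
    strict inequality p < alpha on raw p-values; pass ``fdr=True`` for a
    Benjamini-Hochberg adjusted column instead of the raw screen.
    Welch's unequal-variance test by default (``equal_var=True`` pools).
    """
    g = np.asarray(groups, dtype=bool)
    if g.shape[0] != scores.shape[1]:
        raise ValueError("group labels do not match sample columns")
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    a = scores.to_numpy(dtype=float)[:, g]
    b = scores.to_numpy(dtype=float)[:, ~g]
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    # degenerate rows (zero variance, identical groups) -> no evidence
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    out = pd.DataFrame({
        "signature": scores.index,
        "t": t,
        "p": p,
        "direction": np.sign(a.mean(axis=1) - b.mean(axis=1)).astype(int),
    }).set_index("signature")
    if fdr:
        out["p_adj"] = _bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def cluster_export(scores: pd.DataFrame, method: str = "average",
                   metric: str = "correlation"):
    """Average-linkage hierarchical clustering of signature scores.

    Rows (signatures) are clustered on the chosen distance (1 − Pearson r
    by default); returns the linkage matrix and the score matrix reordered
    by deterministic leaf order, ready for TSV export to a heatmap viewer.
    """
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 signatures to cluster")
    x = scores.to_numpy(dtype=float)
    if metric == "correlation":
        # guard constant rows, for which Pearson r is undefined
        sd = x.std(axis=1)
        d = np.zeros((len(x), len(x)))
        for i in range(len(x)):
            for j in range(i + 1, len(x)):
                if sd[i] == 0 or sd[j] == 0:
                    dist = 0.0 if np.allclose(x[i], x[j]) else 1.0
                else:
                    dist = 1.0 - np.corrcoef(x[i], x[j])[0, 1]
                d[i, j] = d[j, i] = max(dist, 0.0)
        condensed = squareform(d, checks=False)
    else:
        from scipy.spatial.distance import pdist

        condensed = pdist(x, metric=metric)
    linkage = hierarchy.linkage(condensed, method=method)
    leaves = hierarchy.leaves_list(linkage)
    ordered = scores.iloc[leaves]
    return linkage, ordered
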