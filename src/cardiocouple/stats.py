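"""Per-feature group comparison and inter-feature correlation analysis.

Each feature is compared between the CAD and non-CAD groups with a
normality-gated test: both groups pass a Kolmogorov-Smirnov check against a
normal with the sample mean/sd -> two-sample t-test; otherwise Mann-Whitney U
(both two-sided). Raw p < 0.05 marks significance (no multiple-testing
correction by default, mirroring the single-feature screening convention;
Benjamini-Hochberg is available as an option). Note the KS gate with estimated
parameters is anticonservative; it is retained deliberately and the type-I
error of the combined procedure is what the test suite checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

ALPHA = 0.05


@dataclass
class FeatureTestResult:
    feature_index: int
    test_used: str  # 't_test' | 'mann_whitney'
    p_value: float
    significant: bool


def _is_normal(x: np.ndarray, alpha: float = ALPHA) -> bool:
    sd = x.std(ddof=1)
    if sd == 0:
        return False
    return sst.kstest(x, "norm", args=(x.mean(), sd)).pvalue >= alpha


def test_feature(
    group_a: np.ndarray, group_b: np.ndarray, feature_index: int = 0
) -> FeatureTestResult:
    """Normality-gated two-sided comparison of one feature between two groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    if a.std() == 0 and b.std() == 0 and len(a) and a[0] == b[0]:
        return FeatureTestResult(feature_index, "t_test", 1.0, False)
    if _is_normal(a) and _is_normal(b):
        p = float(sst.ttest_ind(a, b).pvalue)
        used = "t_test"
    else:
        p = float(sst.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        used = "mann_whitney"
    if np.isnan(p):
        p = 1.0
    return FeatureTestResult(feature_index, used, p, bool(p < ALPHA))


def test_features(
    features: np.ndarray, labels: np.ndarray, bh_correct: bool = False
) -> list[FeatureTestResult]:
    """Column-wise group comparison of a feature matrix against binary labels."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=int)
    a, b = features[labels == 0], features[labels == 1]
    results = [test_feature(a[:, j], b[:, j], j) for j in range(features.shape[1])]
    if bh_correct:
        ps = np.array([r.p_value for r in results])
        m = len(ps)
        order = np.argsort(ps)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, ps[order[rank]] * m / (rank + 1))
            adj[order[rank]] = running
        for r, q in zip(results, adj):
            r.p_value = float(q)
            r.significant = bool(q < ALPHA)
    return results


def correlation_matrix(block_a: np.ndarray, block_b: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlations between feature columns (within or across modalities).

    Zero-variance features yield NaN-masked rows/columns.
    """
    A = np.atleast_2d(np.asarray(block_a, dtype=float))
    if A.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if block_b is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.corrcoef(A, rowvar=False)
    B = np.atleast_2d(np.asarray(block_b, dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        full = np.corrcoef(A, B, rowvar=False)
    return full[: A.shape[1], A.shape[1] :]


def modality_correlations(blocks: dict[str, np.ndarray]) -> dict[tuple[str, str], np.ndarray]:
    """All within- and cross-modality correlation matrices (heat-map inputs)."""
    names = list(blocks)
    out = {}
    for i, a in enumerate(names):
        for b in names[i:]:
            out[(a, b)] = correlation_matrix(
                blocks[a], None if a == b else blocks[b]
            )
    return out


def plot_correlation_heatmaps(corrs: dict, out_dir) -> list:
    """Render each correlation matrix as a heat map PNG; returns written paths."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (a, b), mat in corrs.items():
        fig, ax = plt.subplots(figsize=(4, 3.4))
        im = ax.imshow(mat, vmin=-1, vmax=1, cmap="coolwarm", aspect="auto")
        ax.set_title(f"{a} vs {b}")
        fig.colorbar(im, ax=ax)
        p = out_dir / f"corr_{a}_{b}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths


def top_k_features(
    results_by_modality: dict[str, list[FeatureTestResult]],
    rankings_by_modality: dict[str, np.ndarray],
    k: int = 5,
) -> list[dict]:
    """Per-modality top-k features by RFE rank, with their p-values."""
    rows = []
    for mod, ranking in rankings_by_modality.items():
        results = {r.feature_index: r for r in results_by_modality[mod]}
        if k > len(ranking):
            raise ValueError("k exceeds feature count")
        order = np.argsort(np.asarray(ranking), kind="stable")[:k]
        for pos, j in enumerate(order, start=1):
            r = results[int(j)]
            rows.append(
                {
                    "modality": mod,
                    "rank": pos,
                    "feature_index": int(j),
                    "p_value": r.p_value,
                    "test_used": r.test_used,
                    "significant": r.significant,
                }
            )
    return rows
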