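"""Feature-importance analysis of the CNN's SNP-level calls.

The CNN itself is opaque, so importance is read off a random-forest
surrogate trained to reproduce its SNP labels (positive iff prediction
score > 0.5).  Gini importance (mean impurity decrease) ranks features;
per-feature permutation p-values come from refitting the forest on
label-permuted data; category over-representation among significant
features is tested with hypergeometric and binomial tails.  Repressive
histone marks (H3K9me3, H3K27me3) are excluded before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .features import REPRESSIVE_MARKS, FeatureTensor

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class ImportanceResult:
    feature: str
    category: str
    gini_importance: float
    perm_p: float | None = None

    @property
    def significant(self) -> bool | None:
        return None if self.perm_p is None else self.perm_p < SIGNIFICANCE_LEVEL


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both positive and negative SNP labels are required")


def fit_rf_surrogate(
    snp_vectors: np.ndarray,
    snp_labels: np.ndarray,
    n_trees: int = 100,
    mtry: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Gini importances from a random forest fit to the CNN's SNP labels.

    100 trees with 10 features sampled per split by default; deterministic
    given ``seed``.  Returns one importance per feature column.
    """
    x = np.asarray(snp_vectors)
    y = np.asarray(snp_labels)
    _check_two_classes(y)
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(mtry, x.shape[1]),
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(x, y)
    return rf.feature_importances_


def permutation_pvalues(
    snp_vectors: np.ndarray,
    snp_labels: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    n_trees: int = 100,
    mtry: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values for per-feature Gini importance.

    The labels are permuted ``n_perm`` times; for each feature,
    perm_p = (#permutations with permuted importance >= observed) / n_perm.
    Ties count against significance.  Returns (perm_p, observed_importance).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(snp_labels)
    _check_two_classes(y)
    rng = np.random.default_rng(seed)
    observed = fit_rf_surrogate(
        snp_vectors, y, n_trees=n_trees, mtry=mtry, seed=int(rng.integers(2**31))
    )
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = fit_rf_surrogate(
            snp_vectors,
            rng.permutation(y),
            n_trees=n_trees,
            mtry=mtry,
            seed=int(rng.integers(2**31)),
        )
        exceed += perm >= observed
    return exceed / n_perm, observed


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Over-representation tail P(X >= k) for k significant features in a
    category of size n, out of N features of which K are significant,
    under the hypergeometric pmf
    P(X = k) = C(K, k) C(N - K, n - k) / C(N, n).
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def binomial_annotation_test(k: int, n: int, p0: float) -> float:
    """One-sided upper-tail binomial probability P(X >= k | n, p0)."""
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"background fraction p0={p0} outside (0, 1)")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    return float(stats.binom.sf(k - 1, n, p0))


def _is_repressive(name: str, category: str) -> bool:
    return "repressive" in category.lower() or any(
        m.lower() in name.lower() for m in REPRESSIVE_MARKS
    )


def run_importance(
    tensor: FeatureTensor,
    scores: pd.DataFrame,
    n_trees: int = 100,
    mtry: int = 10,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full importance table for the CNN's calls on a tensor.

    SNP labels come from joining the scores table on (block_id, snp_id);
    repressive histone marks are dropped before fitting.  Returns a
    DataFrame (feature, category, gini, perm_p, significant).
    """
    vectors, keys = tensor.snp_vectors()
    score_map = {
        (r.block_id, r.snp_id): r.score for r in scores.itertuples(index=False)
    }
    try:
        labels = np.array([score_map[key] > 0.5 for key in keys], dtype=int)
    except KeyError as exc:
        raise ValueError(f"no score for SNP {exc.args[0]}") from None
    keep = [
        i
        for i, (name, cat) in enumerate(
            zip(tensor.feature_names, tensor.feature_categories)
        )
        if not _is_repressive(name, cat)
    ]
    vec = vectors[:, keep]
    perm_p, gini = permutation_pvalues(
        vec, labels, n_perm=n_perm, seed=seed, n_trees=n_trees, mtry=mtry
    )
    return pd.DataFrame(
        {
            "feature": [tensor.feature_names[i] for i in keep],
            "category": [tensor.feature_categories[i] for i in keep],
            "gini": gini,
            "perm_p": perm_p,
            "significant": perm_p < SIGNIFICANCE_LEVEL,
        }
    )


def category_enrichment(importance: pd.DataFrame) -> pd.DataFrame:
    """Category over-representation among significant features.

    For each category: N features overall, K significant overall, n in the
    category, k significant in the category; hypergeometric tail and a
    binomial tail at background rate K/N.
    """
    N = len(importance)
    K = int(importance.significant.sum())
    rows = []
    for cat, grp in importance.groupby("category", sort=True):
        n = len(grp)
        k = int(grp.significant.sum())
        p_hyper = hypergeometric_enrichment(N, K, n, k)
        p_binom = binomial_annotation_test(k, n, K / N) if 0 < K < N else 1.0
        rows.append(
            {"category": cat, "N": N, "K": K, "n": n, "k": k,
             "p_hyper": p_hyper, "p_binom": p_binom}
        )
    return pd.DataFrame(rows)
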