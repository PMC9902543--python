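"""Profile clustering of regulated proteins with gap-statistic k selection.

Proteins regulated in at least one comparison form a log2 fold-change
profile matrix (rows = proteins, columns = comparisons).  Pairwise profile
similarity is defined literally as ``1 - Euclidean distance`` (so values go
negative once distances exceed 1).  The number of clusters is chosen by the
gap statistic (Tibshirani, Walther & Hastie 2001): within-cluster dispersion
of the data is compared against B reference datasets drawn uniformly over
each column's observed range, and the smallest k satisfying
``gap(k) >= gap(k+1) - s_{k+1}`` is selected (the 1-standard-error rule).
The partitioner is k-means with multiple restarts, consistent with the
Euclidean geometry of the similarity; profiles are clustered unscaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .errors import ConfigError, SizeError
from .difftest import DEFAULT_FDR, DEFAULT_LFC_THRESHOLD

DEFAULT_K_MAX = 12
DEFAULT_B = 100
DEFAULT_RESTARTS = 25


def build_profile_matrix(
    protein_stats: pd.DataFrame,
    comparisons: list[str] | None = None,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Log2FC profiles of proteins regulated in >= 1 included comparison.

    Rows are proteins meeting |log2FC| >= ``lfc_threshold`` and adjusted
    p <= ``fdr`` in at least one included comparison AND quantified in all of
    them (Euclidean distances need complete vectors); entries are the raw
    log2 fold changes.  Returns an empty frame when no protein qualifies —
    the caller skips clustering.

    ``comparisons`` may mix comparison display names and objects with a
    ``.name``; defaults to every comparison present.
    """
    stats = protein_stats
    if comparisons is None:
        comps = sorted(stats["comparison"].unique())
    else:
        comps = [getattr(c, "name", c) for c in comparisons]
    lfc = stats.pivot_table(index="protein_group", columns="comparison",
                            values="log2fc")
    padj = stats.pivot_table(index="protein_group", columns="comparison",
                             values="p_adj")
    missing_cols = [c for c in comps if c not in lfc.columns]
    if missing_cols:
        raise ConfigError(f"no statistics for comparisons: {missing_cols}")
    lfc, padj = lfc[comps], padj[comps]
    complete = lfc.notna().all(axis=1) & padj.notna().all(axis=1)
    regulated_any = ((lfc.abs() >= lfc_threshold) & (padj <= fdr)).any(axis=1)
    out = lfc.loc[complete & regulated_any].sort_index()
    out.columns.name = "comparison"
    return out


def profile_similarity(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise profile similarity, 1 - Euclidean distance.

    Symmetric with unit diagonal; values below 0 occur whenever two profiles
    are more than one log2 unit apart (the definition is applied literally).
    """
    if len(profiles) < 2:
        raise SizeError("similarity needs >= 2 profiles")
    sim = 1.0 - squareform(pdist(profiles.to_numpy(), metric="euclidean"))
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=profiles.index, columns=profiles.index)


@dataclass
class ClusterAssignment:
    """k-means partition of the profile matrix."""

    labels: pd.Series          # protein_group -> cluster id in 1..k
    centroids: pd.DataFrame    # cluster id x comparison
    dispersion: float          # within-cluster sum of squares W_k

    @property
    def k(self) -> int:
        return len(self.centroids)


def within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Pooled within-cluster dispersion W.

    Defined as the sum over clusters of the within-cluster sum of pairwise
    squared Euclidean distances divided by twice the cluster size — which
    equals the sum of squared distances to the cluster centroids.
    """
    w = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        w += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return w


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int,
    seed: int | None = None,
    restarts: int = DEFAULT_RESTARTS,
) -> ClusterAssignment:
    """Partition profiles into k clusters by restarted k-means.

    Best of ``restarts`` initializations by within-cluster dispersion;
    deterministic given the seed.  Cluster ids are renumbered 1..k in order
    of first appearance down the (sorted) profile rows, so output labels do
    not depend on k-means' internal initialization order.
    """
    n = len(profiles)
    if not 1 <= k <= n:
        raise ConfigError(f"k={k} out of range for {n} profiles")
    X = profiles.to_numpy()
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=restarts,
                    random_state=_seed_int(seed), algorithm="lloyd")
        labels = km.fit_predict(X)
    # stable renumbering: 1..k by first appearance
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    new_labels = np.array([remap[lab] for lab in labels])
    centroids = pd.DataFrame(
        [X[new_labels == c].mean(axis=0) for c in range(1, k + 1)],
        index=pd.Index(range(1, k + 1), name="cluster"),
        columns=profiles.columns)
    return ClusterAssignment(
        labels=pd.Series(new_labels, index=profiles.index, name="cluster"),
        centroids=centroids,
        dispersion=within_dispersion(X, new_labels),
    )


@dataclass
class GapResult:
    """Gap-statistic scan over k = 1..k_max."""

    ks: np.ndarray
    W: np.ndarray             # within-cluster dispersion of the data
    log_W: np.ndarray
    gap: np.ndarray           # mean_b log W*_kb - log W_k
    s_k: np.ndarray           # sd_b(log W*_kb) * sqrt(1 + 1/B)
    chosen_k: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "W": self.W, "log_W": self.log_W,
                             "gap": self.gap, "s_k": self.s_k})


def gap_statistic(
    profiles: pd.DataFrame,
    k_max: int = DEFAULT_K_MAX,
    B: int = DEFAULT_B,
    seed: int | None = None,
    restarts: int = DEFAULT_RESTARTS,
) -> GapResult:
    """Choose the number of clusters by the gap statistic.

    For each k in 1..k_max the data and B reference datasets (uniform over
    each column's observed range) are partitioned by restarted k-means and
    the dispersion gap ``mean_b log W*_kb - log W_k`` computed;
    ``chosen_k`` is the smallest k with ``gap(k) >= gap(k+1) - s_{k+1}``
    (falling back to k_max when no k satisfies the rule).
    """
    n = len(profiles)
    if k_max >= n:
        raise ConfigError(f"k_max={k_max} must be < number of profiles ({n})")
    if k_max < 1:
        raise ConfigError("k_max must be >= 1")
    if B < 10:
        raise ConfigError("B must be >= 10 reference datasets")
    X = profiles.to_numpy()
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    ks = np.arange(1, k_max + 1)
    log_W = np.array([
        np.log(_best_dispersion(X, k, rng, restarts)) for k in ks])
    log_W_ref = np.empty((B, k_max))
    for b in range(B):
        Xb = rng.uniform(lo, hi, size=X.shape)
        for j, k in enumerate(ks):
            log_W_ref[b, j] = np.log(_best_dispersion(Xb, k, rng, restarts))
    gap = log_W_ref.mean(axis=0) - log_W
    s_k = log_W_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    chosen = int(ks[-1])
    for j in range(k_max - 1):
        if gap[j] >= gap[j + 1] - s_k[j + 1]:
            chosen = int(ks[j])
            break
    return GapResult(ks=ks, W=np.exp(log_W), log_W=log_W, gap=gap, s_k=s_k,
                     chosen_k=chosen)


def _best_dispersion(X: np.ndarray, k: int, rng: np.random.Generator,
                     restarts: int) -> float:
    if k == 1:
        return within_dispersion(X, np.zeros(len(X), dtype=int))
    km = KMeans(n_clusters=k, n_init=restarts,
                random_state=_seed_int(rng), algorithm="lloyd")
    labels = km.fit_predict(X)
    return within_dispersion(X, labels)


def _seed_int(seed) -> int | None:
    """Derive a 31-bit int seed for sklearn from a seed or Generator."""
    if seed is None:
        return None
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(2 ** 31))
    return int(seed) % (2 ** 31)
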