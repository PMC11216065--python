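"""Movement-behaviour profiles: standardisation, k-means and k selection.

The 13 features are z-scored, k-means (Lloyd with k-means++ seeding, best of
``n_init`` restarts) is fitted over a candidate range of k, and the number of
profiles is chosen by combining the elbow of the within-cluster sum-of-squares
curve with the Tibshirani gap statistic (uniform reference sampled in the
principal-component-aligned bounding box of the data).  Profiles are named
deterministically from their centroid structure, most active first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .features import FEATURE_COLUMNS

DEFAULT_N_INIT = 50
DEFAULT_MAX_ITER = 300
DEFAULT_TOL = 1e-6
DEFAULT_B = 50
GAP_REFERENCE_N_INIT = 5

PROFILE_NAMES_K5 = [
    "active",
    "active_sitters",
    "light_movers",
    "prolonged_sitters",
    "most_sedentary",
]

_AVG_ACC = FEATURE_COLUMNS[0]
_DUR_LIPA = FEATURE_COLUMNS[2]
_DUR_MVPA = FEATURE_COLUMNS[3]


@dataclass
class StandardizationParams:
    mean: pd.Series
    sd: pd.Series

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.mean) / self.sd

    def inverse(self, Z: pd.DataFrame) -> pd.DataFrame:
        return Z * self.sd + self.mean


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Column-wise z-scores (mean 0, SD 1; population SD)."""
    if X.isna().any().any():
        raise ValueError("missing values in feature matrix")
    mean = X.mean()
    sd = X.std(ddof=0)
    dead = sd[sd <= 0]
    if len(dead):
        raise ValueError(f"zero-variance feature(s): {list(dead.index)}")
    params = StandardizationParams(mean=mean, sd=sd)
    return params.transform(X), params


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    wss: float
    bss: float
    n_init_used: int
    seed: int | None


def total_ss(Z: np.ndarray) -> float:
    Z = np.asarray(Z, float)
    return float(((Z - Z.mean(axis=0)) ** 2).sum())


def kmeans_fit(
    Z,
    k: int,
    n_init: int = DEFAULT_N_INIT,
    seed: int | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> ClusterModel:
    """Best-of-restarts k-means on a (standardised) matrix."""
    Zv = np.asarray(Z, float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > Zv.shape[0]:
        raise ValueError(f"k={k} exceeds n={Zv.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter, tol=tol, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on k=1 / duplicate points
        km.fit(Zv)
    wss = float(km.inertia_)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=km.labels_.astype(np.int64),
        wss=wss,
        bss=total_ss(Zv) - wss,
        n_init_used=n_init,
        seed=seed,
    )


@dataclass
class KSelectionDiagnostics:
    candidate_k: list[int]
    wss: dict[int, float]
    gap: dict[int, float] = field(default_factory=dict)
    gap_se: dict[int, float] = field(default_factory=dict)
    elbow_k: int | None = None
    elbow_indeterminate: bool = False
    gap_k: int | None = None
    chosen_k: int | None = None


def elbow(wss: dict[int, float]) -> tuple[int | None, bool]:
    """Elbow of the WSS curve: argmax of the discrete second difference.

    Returns ``(elbow_k, indeterminate)``; a near-linear curve (no curvature
    above 1e-6 of the total WSS drop) is flagged indeterminate.
    """
    ks = sorted(wss)
    if len(ks) < 3:
        raise ValueError("elbow needs a WSS curve over at least 3 values of k")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("WSS curve must cover a contiguous k range")
    w = np.array([wss[k] for k in ks])
    d2 = w[:-2] - 2.0 * w[1:-1] + w[2:]
    span = abs(w[0] - w[-1])
    if span == 0 or d2.max() < 1e-6 * span:
        return None, True
    return ks[1 + int(np.argmax(d2))], False


def gap_statistic(
    Z,
    k_range,
    B: int = DEFAULT_B,
    seed: int | None = None,
    n_init: int = DEFAULT_N_INIT,
) -> tuple[dict[int, float], dict[int, float], int]:
    """Tibshirani gap statistic with a PCA-aligned uniform-box reference.

    gap(k) = mean_b log W*_kb - log W_k, s(k) = sd_b(log W*_kb) sqrt(1+1/B);
    the selected ``gap_k`` is the smallest k with gap(k) >= gap(k+1) - s(k+1)
    (falling back to the largest candidate when no k satisfies the rule).
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    Zv = np.asarray(Z, float)
    if np.allclose(Zv, Zv[0]):
        raise ValueError("degenerate data: all rows identical")
    ks = sorted(int(k) for k in k_range)
    rng = np.random.default_rng(seed)

    logW = {
        k: np.log(kmeans_fit(Zv, k, n_init=n_init, seed=int(rng.integers(2**31 - 1))).wss)
        for k in ks
    }

    mu = Zv.mean(axis=0)
    Xc = Zv - mu
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ Vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)
    logWstar = {k: np.empty(B) for k in ks}
    for b in range(B):
        ref = rng.uniform(lo, hi, size=Xp.shape) @ Vt + mu
        for k in ks:
            m = kmeans_fit(ref, k, n_init=GAP_REFERENCE_N_INIT, seed=int(rng.integers(2**31 - 1)))
            logWstar[k][b] = np.log(m.wss)

    gap = {k: float(logWstar[k].mean() - logW[k]) for k in ks}
    s = {k: float(logWstar[k].std(ddof=1) * np.sqrt(1.0 + 1.0 / B)) for k in ks}
    gap_k = ks[-1]
    for i, k in enumerate(ks[:-1]):
        if gap[k] >= gap[ks[i + 1]] - s[ks[i + 1]]:
            gap_k = k
            break
    return gap, s, gap_k


def select_k(diag: KSelectionDiagnostics) -> int:
    """Choose k among the candidates spanned by the elbow and gap solutions.

    The candidate set is the contiguous range between elbow_k and gap_k
    (intersected with the candidate range); among candidates the one with
    minimum WSS — hence maximum BSS — wins, ties broken toward larger k.
    """
    picks = [k for k in (diag.elbow_k, diag.gap_k) if k is not None]
    if not picks:
        raise ValueError("no k-selection criterion available")
    lo, hi = min(picks), max(picks)
    candidates = [k for k in diag.candidate_k if lo <= k <= hi]
    if not candidates:
        raise ValueError("empty candidate set")
    best = candidates[0]
    for k in candidates[1:]:
        if diag.wss[k] <= diag.wss[best]:
            best = k
    diag.chosen_k = best
    return best


def k_selection(
    Z,
    k_range=range(2, 9),
    B: int = DEFAULT_B,
    seed: int | None = None,
    n_init: int = DEFAULT_N_INIT,
) -> KSelectionDiagnostics:
    """Full k-selection sweep: WSS curve, elbow, gap statistic, chosen k."""
    ks = sorted(int(k) for k in k_range)
    rng = np.random.default_rng(seed)
    wss = {k: kmeans_fit(Z, k, n_init=n_init, seed=int(rng.integers(2**31 - 1))).wss for k in ks}
    diag = KSelectionDiagnostics(candidate_k=ks, wss=wss)
    diag.elbow_k, diag.elbow_indeterminate = elbow(wss)
    diag.gap, diag.gap_se, diag.gap_k = gap_statistic(
        Z, ks, B=B, seed=int(rng.integers(2**31 - 1)), n_init=n_init
    )
    select_k(diag)
    return diag


@dataclass
class ProfileSummary:
    names: list[str]  # indexed by cluster label
    sizes: list[int]
    mean_z: pd.DataFrame  # clusters x features, standardised scale


def characterize_profiles(model: ClusterModel, feature_names=FEATURE_COLUMNS) -> ProfileSummary:
    """Name clusters from their centroid structure.

    Clusters are ranked by the average-acceleration centroid coordinate,
    most active first.  For k=5 the canonical names are assigned in rank
    order, except that among ranks 2 and 3 the cluster with the larger
    MVPA-minus-LIPA duration contrast is the "active_sitters" (MVPA-leaning)
    and the other the "light_movers" (LIPA-leaning).  k=1 is named "all";
    other k get generic rank names.
    """
    feature_names = list(feature_names)
    C = np.asarray(model.centroids)
    mean_z = pd.DataFrame(C, columns=feature_names)
    sizes = [int(np.sum(model.assignments == j)) for j in range(model.k)]
    i_acc = feature_names.index(_AVG_ACC)
    order = list(np.argsort(-C[:, i_acc]))  # cluster labels, most active first
    names = [""] * model.k
    if model.k == 1:
        names[0] = "all"
    elif model.k == 5:
        ranked = PROFILE_NAMES_K5.copy()
        i_mvpa = feature_names.index(_DUR_MVPA)
        i_lipa = feature_names.index(_DUR_LIPA)
        a, b = order[1], order[2]
        contrast = C[:, i_mvpa] - C[:, i_lipa]
        if contrast[a] < contrast[b]:
            order[1], order[2] = b, a
        for rank, label in enumerate(order):
            names[label] = ranked[rank]
    else:
        for rank, label in enumerate(order):
            names[label] = f"profile_{rank + 1}"
    return ProfileSummary(names=names, sizes=sizes, mean_z=mean_z)


def pca_projection(Z) -> tuple[np.ndarray, np.ndarray]:
    """First-two-PC scores and the full variance-explained shares."""
    Zv = np.asarray(Z, float)
    p = PCA()
    scores = p.fit_transform(Zv)
    return scores[:, :2], p.explained_variance_ratio_


def plot_profile_means(summary: ProfileSummary, path=None):
    """Bar chart of mean standardised features per profile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k, p = summary.mean_z.shape
    fig, ax = plt.subplots(figsize=(12, 5))
    x = np.arange(p)
    width = 0.8 / k
    for j in range(k):
        ax.bar(x + j * width, summary.mean_z.iloc[j], width, label=summary.names[j])
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(summary.mean_z.columns, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("mean standardised value")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def profile_cohort(
    features: pd.DataFrame,
    k_range=range(2, 9),
    k_override: int | None = None,
    n_init: int = DEFAULT_N_INIT,
    B: int = DEFAULT_B,
    seed: int | None = None,
):
    """Standardise -> select k (unless overridden) -> fit -> characterise.

    Returns ``(model, params, diagnostics, summary, assignments)`` where
    ``assignments`` is a DataFrame of profile index and name per participant.
    """
    X = features[FEATURE_COLUMNS]
    Z, params = standardize(X)
    diag = k_selection(Z.to_numpy(), k_range=k_range, B=B, seed=seed, n_init=n_init)
    k = k_override if k_override is not None else diag.chosen_k
    model = kmeans_fit(Z.to_numpy(), k, n_init=n_init, seed=seed)
    summary = characterize_profiles(model)
    assignments = pd.DataFrame(
        {
            "profile_index": model.assignments,
            "profile": [summary.names[j] for j in model.assignments],
        },
        index=features.index,
    )
    return model, params, diag, summary, assignments
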