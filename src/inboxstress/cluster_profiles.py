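"""Gaussian-mixture clustering of inbox work patterns and group comparisons.

Physicians are clustered on the temporal distribution of their daily inbox
time — mean shares in work hours, after hours contiguous to a shift, and
after hours noncontiguous — using a Gaussian mixture fit by EM.  Because
mixture component order is arbitrary, components are mapped to stable group
labels by behaviour: group 1 has the highest noncontiguous after-hours
share (evenings / early mornings), group 2 the highest work-hours share of
the remainder, group 3 the rest (after-hours work contiguous to shifts).

Group characteristics are compared with ANOVA when a variable passes
normality (Shapiro–Wilk) and variance-homogeneity (Levene) screens in every
group, Kruskal–Wallis otherwise; posthoc pairwise tests are Tukey HSD or
Dunn respectively, and categorical variables use chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multicomp import pairwise_tukeyhsd

PROFILE_FEATURES = ["prop_in_hours", "prop_contiguous", "prop_noncontiguous"]
# default mixture features: all three temporal-split proportions (the
# square-root stabilization applied to the noncontiguous share inside
# fit_mixture also breaks their exact collinearity)
MIXTURE_FEATURES = PROFILE_FEATURES


@dataclass
class ClusterResult:
    """A fitted, label-mapped clustering of physician profiles."""

    K: int
    assignments: pd.Series  # physician_id -> group label (1..K)
    means: np.ndarray  # (K, p) in group-label order
    covariances: np.ndarray
    weights: np.ndarray
    silhouette: float
    feature_names: list = field(default_factory=list)

    def group_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def _map_components_to_groups(means: np.ndarray, feature_names: list) -> np.ndarray:
    """Order components as group 1 (max noncontiguous), 2 (max in-hours), 3...

    Returns ``order`` such that component ``order[g-1]`` is group ``g``.
    Falls back to noncontiguous-descending order when K != 3 or the
    features lack the named proportions.
    """
    K = len(means)
    try:
        i_nc = feature_names.index("prop_noncontiguous")
        i_in = feature_names.index("prop_in_hours")
    except ValueError:
        return np.arange(K)
    order_nc = np.argsort(-means[:, i_nc])
    if K != 3:
        return order_nc
    g1 = order_nc[0]
    rest = [c for c in range(K) if c != g1]
    g2 = rest[int(np.argmax(means[rest, i_in]))]
    g3 = next(c for c in rest if c != g2)
    return np.array([g1, g2, g3])


def fit_mixture(
    profiles: pd.DataFrame,
    K: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    feature_names: list | None = None,
    reg_covar: float = 1e-6,
) -> ClusterResult:
    """Fit a K-component Gaussian mixture to physician profile features.

    ``profiles`` must be indexed by physician id (or carry a
    ``physician_id`` column) with the feature columns present.  The best of
    ``n_restarts`` EM runs by likelihood is kept; the silhouette score is
    computed on the hard assignments with Euclidean distance (NaN for K=1
    or when a component is empty).
    """
    feature_names = list(feature_names or MIXTURE_FEATURES)
    if "physician_id" in profiles.columns:
        profiles = profiles.set_index("physician_id")
    X = profiles[feature_names].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profile features must be finite")
    if len(X) < K + 1:
        raise ValueError(f"need at least K+1={K + 1} physicians, got {len(X)}")
    # variance-stabilize the noncontiguous share: its dispersion grows with
    # its mean (near zero for the in-hours group), which otherwise lets a
    # wide component swallow two groups
    sqrt_cols = [i for i, f in enumerate(feature_names) if f == "prop_noncontiguous"]
    X = X.copy()
    for i in sqrt_cols:
        X[:, i] = np.sqrt(np.clip(X[:, i], 0.0, 1.0))

    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        n_init=n_restarts,
        random_state=seed,
        reg_covar=reg_covar,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = gm.fit_predict(X)
    order = _map_components_to_groups(gm.means_, feature_names)
    relabel = np.empty(K, dtype=np.int64)
    relabel[order] = np.arange(1, K + 1)
    groups = relabel[labels]

    if K > 1 and len(np.unique(groups)) > 1:
        sil = float(silhouette_score(X, groups))
    else:
        sil = float("nan")
    means = gm.means_[order].copy()
    for i in sqrt_cols:  # report means on the proportion scale
        means[:, i] = means[:, i] ** 2
    return ClusterResult(
        K=K,
        assignments=pd.Series(groups, index=profiles.index, name="group"),
        means=means,
        covariances=gm.covariances_[order],
        weights=gm.weights_[order],
        silhouette=sil,
        feature_names=feature_names,
    )


def select_clustering(
    profiles: pd.DataFrame,
    feature_sets: dict | None = None,
    K_values: tuple = (2, 3, 4),
    seed: int = 0,
    n_restarts: int = 10,
    min_group_size: int = 5,
) -> tuple[ClusterResult, pd.DataFrame]:
    """Sweep candidate feature sets and K; pick by silhouette under a size floor.

    The report tabulates silhouette and group-size balance (min/max ratio)
    for every candidate.  The chosen clustering maximizes silhouette among
    candidates whose smallest group has at least ``min_group_size``
    members (the balance constraint); if none qualifies, the best
    silhouette overall is returned with a warning.
    """
    feature_sets = feature_sets or {"simplex_2d": MIXTURE_FEATURES, "proportions_3d": PROFILE_FEATURES}
    rows = []
    results = {}
    for fs_name, feats in feature_sets.items():
        for K in K_values:
            res = fit_mixture(profiles, K=K, seed=seed, n_restarts=n_restarts, feature_names=feats)
            sizes = res.group_sizes()
            rows.append(
                {
                    "feature_set": fs_name,
                    "K": K,
                    "silhouette": res.silhouette,
                    "min_group_size": int(sizes.min()),
                    "balance": float(sizes.min() / sizes.max()),
                }
            )
            results[(fs_name, K)] = res
    report = pd.DataFrame(rows)
    ok = report[report["min_group_size"] >= min_group_size]
    if len(ok):
        best = ok.sort_values("silhouette", ascending=False).iloc[0]
    else:
        warnings.warn(
            "no candidate clustering meets the group-size floor; returning best silhouette"
        )
        best = report.sort_values("silhouette", ascending=False).iloc[0]
    return results[(best["feature_set"], int(best["K"]))], report


def label_agreement(true_labels, pred_labels) -> float:
    """Best-permutation accuracy between two labelings (Hungarian matching).

    Invariant to relabeling of either side; 1.0 means identical partitions
    up to label names.
    """
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    t_vals, t = np.unique(true_labels, return_inverse=True)
    p_vals, p = np.unique(pred_labels, return_inverse=True)
    C = np.zeros((len(t_vals), len(p_vals)), dtype=np.int64)
    np.add.at(C, (t, p), 1)
    r, c = linear_sum_assignment(-C)
    return float(C[r, c].sum() / len(true_labels))


def adjusted_agreement(true_labels, pred_labels) -> float:
    """Adjusted Rand index between two labelings."""
    return float(adjusted_rand_score(true_labels, pred_labels))


def dunn_test(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based pairwise posthoc test with tie correction.

    Pools all observations, ranks them, and compares pairwise mean ranks
    with z statistics; two-sided p-values are Holm-adjusted.  The standard
    nonparametric follow-up to a Kruskal–Wallis omnibus.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    N = len(values)
    ranks = stats.rankdata(values)
    # tie correction term: sum(t^3 - t) over tied groups
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12 * (N - 1))) if N > 1 else 0.0

    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    ns = {g: int((groups == g).sum()) for g in labels}
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / ns[a] + 1.0 / ns[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    # Holm step-down adjustment
    m = len(out)
    order = np.argsort(out["p_raw"].to_numpy())
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * out["p_raw"].iloc[idx])
        adj[idx] = min(running, 1.0)
    out["p_adj"] = adj
    return out


def _screen_normal_equal_var(samples: list[np.ndarray], alpha: float = 0.05) -> bool:
    """Shapiro–Wilk in every group and Levene across groups, both at alpha."""
    for s in samples:
        if len(s) < 3:
            return False
        if np.ptp(s) == 0:
            return False
        if stats.shapiro(s).pvalue < alpha:
            return False
    return stats.levene(*samples).pvalue >= alpha


def compare_groups(
    profiles: pd.DataFrame,
    assignments: pd.Series,
    continuous: list | None = None,
    categorical: list | None = None,
    alpha: float = 0.05,
    yates_2x2: bool = True,
) -> pd.DataFrame:
    """Group-comparison table mirroring a mean (SD) per group + p layout.

    For each continuous variable, ANOVA is used when all groups pass
    normality and variance-homogeneity screens, otherwise Kruskal–Wallis;
    posthoc pairwise results (Tukey HSD / Dunn) are attached in the
    ``posthoc`` column.  Categorical variables use the chi-square test on
    the contingency table (Yates continuity correction for 2x2 by
    default).  Variables with any group of size < 2 are skipped with a
    note.
    """
    if "physician_id" in profiles.columns:
        profiles = profiles.set_index("physician_id")
    continuous = continuous if continuous is not None else [
        c for c in profiles.columns if profiles[c].dtype.kind in "fi"
    ]
    categorical = categorical or []
    g = assignments.reindex(profiles.index)
    labels = np.sort(g.dropna().unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups to compare")

    rows = []
    for var in continuous:
        samples = [profiles.loc[g == lab, var].dropna().to_numpy(dtype=float) for lab in labels]
        summary = {
            f"group_{lab}": f"{s.mean():.2f} ({s.std(ddof=1):.2f})" if len(s) > 1 else "n<2"
            for lab, s in zip(labels, samples)
        }
        if any(len(s) < 2 for s in samples):
            rows.append({"variable": var, **summary, "test": "skipped: group of size <2",
                         "p": np.nan, "posthoc": None})
            continue
        if _screen_normal_equal_var(samples, alpha):
            test, p = "ANOVA", float(stats.f_oneway(*samples).pvalue)
            vals = np.concatenate(samples)
            labs = np.concatenate([[lab] * len(s) for lab, s in zip(labels, samples)])
            tk = pairwise_tukeyhsd(vals, labs, alpha=alpha)
            posthoc = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        else:
            test, p = "Kruskal-Wallis", float(stats.kruskal(*samples).pvalue)
            vals = np.concatenate(samples)
            labs = np.concatenate([[lab] * len(s) for lab, s in zip(labels, samples)])
            posthoc = dunn_test(vals, labs)
        rows.append({"variable": var, **summary, "test": test, "p": p, "posthoc": posthoc})

    for var in categorical:
        table = pd.crosstab(g, profiles[var])
        correction = yates_2x2 and table.shape == (2, 2)
        chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=correction)
        rows.append(
            {
                "variable": var,
                **{f"group_{lab}": "/".join(str(v) for v in table.loc[lab]) for lab in table.index},
                "test": f"chi-square (dof={dof})",
                "p": float(p),
                "posthoc": table,
            }
        )
    return pd.DataFrame(rows)
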