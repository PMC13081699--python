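"""Back-projection of ensemble weights and permutation-null enrichment tests.

Each ensemble member's SVR weights (1 x N, in component space) are
multiplied through its PCA component matrix (N x M) to give a weight
per original connection; these are averaged over permutations. A
coefficient's absolute value is its importance. Significance at the
edge level comes from shuffling the coefficient vector across edge
positions; ROI- and network-level overrepresentation among the
significant edges is tested against uniform with-replacement ROI
resampling, which by construction respects each network's spatial
extent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import classify_edges
from .pipeline import PermutationModel


def backproject(model: PermutationModel) -> np.ndarray:
    """Per-edge weight vector: SVR component weights through the PCA basis."""
    w = np.asarray(model.svr_weights).ravel()
    if w.shape[0] != model.pca_components.shape[0]:
        raise ValueError("weight length does not match the number of components")
    return w @ model.pca_components


def backproject_predict(model: PermutationModel, X: np.ndarray) -> np.ndarray:
    """Raw predictions computed in edge space (linear-equivalence oracle path)."""
    w_edge = backproject(model)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return (X - model.pca_mean) @ w_edge + model.svr_intercept


def average_coefficients(models) -> np.ndarray:
    """Element-wise mean of back-projected coefficients over the ensemble."""
    models = list(models)
    if not models:
        raise ValueError("need at least one permutation model")
    M = models[0].pca_components.shape[1]
    if any(m.pca_components.shape[1] != M for m in models):
        raise ValueError("inconsistent edge orders across permutation models")
    return np.mean([backproject(m) for m in models], axis=0)


def edge_significance(coefficients: np.ndarray, n_perm: int = 2500,
                      alpha: float = 0.05, random_state: int | None = None,
                      two_sided_signed: bool = False) -> pd.DataFrame:
    """Permutation p-value per edge from whole-vector coefficient shuffles.

    Each null draw shuffles the observed coefficients across edge
    positions; by default the comparison is one-sided on |coefficient|
    (importance framing). ``p = (1 + #{null |value| >= observed}) /
    (1 + n_perm)``.
    """
    c = np.asarray(coefficients, dtype=float)
    M = c.size
    if M < 2:
        raise ValueError("need at least 2 edges")
    rng = np.random.default_rng(random_state)
    obs = np.abs(c) if not two_sided_signed else c
    exceed = np.zeros(M, dtype=int)
    for _ in range(n_perm):
        draw = rng.permutation(c)
        if two_sided_signed:
            exceed += np.abs(draw) >= np.abs(c)
        else:
            exceed += np.abs(draw) >= obs
    p = (1 + exceed) / (1 + n_perm)
    rank = stats.rankdata(-np.abs(c), method="ordinal").astype(int)
    return pd.DataFrame({
        "coefficient": c,
        "abs_rank": rank,
        "p": p,
        "significant": p < alpha,
    })


def pool_roi_frequencies(significant_edges: np.ndarray,
                         parcellation: pd.DataFrame) -> pd.Series:
    """ROI occurrence counts among significant edges (both endpoints count).

    The frequencies sum to twice the number of significant edges.
    """
    edges = np.atleast_2d(np.asarray(significant_edges, dtype=int))
    if edges.size == 0:
        raise ValueError("significant edge set is empty")
    ids = parcellation["roi"].to_numpy()
    counts = pd.Series(0, index=pd.Index(ids, name="roi"), dtype=int)
    vals, n = np.unique(edges.ravel(), return_counts=True)
    counts.loc[vals] = n
    return counts


def _null_roi_frequencies(n_slots: int, roi_ids: np.ndarray, n_perm: int,
                          rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n_roi) matrix of with-replacement uniform ROI draw tallies."""
    n_roi = roi_ids.size
    draws = rng.integers(0, n_roi, size=(n_perm, n_slots))
    null = np.zeros((n_perm, n_roi), dtype=int)
    for i in range(n_perm):
        null[i] = np.bincount(draws[i], minlength=n_roi)
    return null


def roi_overrepresentation(frequencies: pd.Series, parcellation: pd.DataFrame,
                           n_perm: int = 2500, alpha: float = 1e-4,
                           random_state: int | None = None,
                           null_matrix: np.ndarray | None = None):
    """Test each ROI's frequency against uniform with-replacement resampling.

    Each null draw fills as many ROI slots as the observed pooled set
    (2 x number of significant edges) uniformly from the parcellation.
    Returns ``(table, null_matrix)`` so the same draws can be reused for
    the network-level test.
    """
    ids = parcellation["roi"].to_numpy()
    freqs = frequencies.reindex(ids, fill_value=0).to_numpy()
    n_slots = int(freqs.sum())
    rng = np.random.default_rng(random_state)
    if null_matrix is None:
        null_matrix = _null_roi_frequencies(n_slots, ids, n_perm, rng)
    exceed = (null_matrix >= freqs[None, :]).sum(axis=0)
    p = (1 + exceed) / (1 + null_matrix.shape[0])
    table = pd.DataFrame({
        "roi": ids,
        "frequency": freqs,
        "p": p,
        "significant": p < alpha,
        "network": parcellation["network"].to_numpy(),
    })
    return table, null_matrix


def network_representation(frequencies: pd.Series, parcellation: pd.DataFrame,
                           null_matrix: np.ndarray | None = None,
                           n_perm: int = 2500,
                           random_state: int | None = None) -> pd.DataFrame:
    """Per-network share of the pooled significant-edge ROIs vs the ROI null.

    Reuses the ROI-resampling null draws (pass ``null_matrix`` from
    :func:`roi_overrepresentation`); p-values are two-sided on the null
    share distribution, with the direction (over/under) reported.
    """
    ids = parcellation["roi"].to_numpy()
    nets = parcellation["network"].to_numpy()
    freqs = frequencies.reindex(ids, fill_value=0).to_numpy()
    n_slots = int(freqs.sum())
    if null_matrix is None:
        rng = np.random.default_rng(random_state)
        null_matrix = _null_roi_frequencies(n_slots, ids, n_perm, rng)
    n_draws = null_matrix.shape[0]
    rows = []
    for net in pd.unique(nets):
        mask = nets == net
        obs_share = freqs[mask].sum() / n_slots
        null_shares = null_matrix[:, mask].sum(axis=1) / n_slots
        p_hi = (1 + int((null_shares >= obs_share).sum())) / (1 + n_draws)
        p_lo = (1 + int((null_shares <= obs_share).sum())) / (1 + n_draws)
        rows.append({
            "network": net,
            "observed_share": obs_share,
            "null_mean_share": float(null_shares.mean()),
            "null_sd_share": float(null_shares.std()),
            "p": min(1.0, 2.0 * min(p_hi, p_lo)),
            "direction": "over" if obs_share > null_shares.mean() else "under",
        })
    return pd.DataFrame(rows)


def summarize_edge_classes(significant_edges: np.ndarray, all_edges: np.ndarray,
                           parcellation: pd.DataFrame) -> pd.DataFrame:
    """Census of within/between-network x LL/RR/inter classes.

    Counts and percentage shares for the significant and full edge sets,
    plus the ratio of rates (significant share / overall share) per class.
    """
    classes = [("within", "LL"), ("within", "RR"), ("within", "inter"),
               ("between", "LL"), ("between", "RR"), ("between", "inter")]
    rows = []
    sig = classify_edges(np.atleast_2d(significant_edges), parcellation) \
        if np.size(significant_edges) else None
    full = classify_edges(np.atleast_2d(all_edges), parcellation)
    n_sig = 0 if sig is None else len(sig)
    n_all = len(full)
    for net_rel, hemi_rel in classes:
        k_sig = 0 if sig is None else int(
            ((sig["network_relation"] == net_rel)
             & (sig["hemisphere_relation"] == hemi_rel)).sum())
        k_all = int(((full["network_relation"] == net_rel)
                     & (full["hemisphere_relation"] == hemi_rel)).sum())
        pct_sig = 100.0 * k_sig / n_sig if n_sig else np.nan
        pct_all = 100.0 * k_all / n_all if n_all else np.nan
        rows.append({
            "network_relation": net_rel,
            "hemisphere_relation": hemi_rel,
            "n_significant": k_sig,
            "pct_significant": pct_sig,
            "n_all": k_all,
            "pct_all": pct_all,
            "rate_ratio": pct_sig / pct_all if (n_sig and pct_all) else np.nan,
        })
    return pd.DataFrame(rows)


def top_edges_by_sd(coefficients: np.ndarray, n_sd: float = 2.5) -> np.ndarray:
    """Report filter: edges with |coefficient| > mean + n_sd * SD of |coefficient|."""
    a = np.abs(np.asarray(coefficients, dtype=float))
    return a > a.mean() + n_sd * a.std()
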