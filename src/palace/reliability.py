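"""Room pattern reliability: similarity matrices, scores, group map,
and the room-feature regression.

Room reliability is a per-room stability-minus-distinctiveness statistic:
the cross-run correlation of a room's pattern with itself (diagonal of the
similarity matrix) minus its average cross-run correlation with every other
room (that row's off-diagonal mean). It is computed from templates fitted
on data acquired *before* room-object pairings are learned, so it cannot be
contaminated by object information.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scaffold import fdr_threshold, two_sided_permutation_p

__all__ = [
    "similarity_matrix",
    "reliability_scores",
    "group_reliability_map",
    "feature_regression",
]


def similarity_matrix(templates_run1, templates_run2) -> np.ndarray:
    """Cross-run Pearson similarity: S[i, j] = corr(run-1 room i, run-2 room j).

    Rows are run-1 rooms, columns run-2 rooms; the matrix is not symmetric
    in general. Zero-variance patterns yield NaN entries with a warning.
    """
    x = np.asarray(getattr(templates_run1, "patterns", templates_run1), float)
    y = np.asarray(getattr(templates_run2, "patterns", templates_run2), float)
    if x.shape != y.shape:
        raise ValueError("template sets must share vertex dimension and rooms")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum(axis=1))
    bad_x = xs < 1e-12
    bad_y = ys < 1e-12
    xs[bad_x] = 1.0
    ys[bad_y] = 1.0
    S = (xc / xs[:, None]) @ (yc / ys[:, None]).T
    if bad_x.any() or bad_y.any():
        warnings.warn("zero-variance pattern(s); similarity entries set to NaN")
        S[bad_x, :] = np.nan
        S[:, bad_y] = np.nan
    return np.clip(S, -1.0, 1.0)  # clip float fuzz; NaN propagates


def reliability_scores(S: np.ndarray) -> np.ndarray:
    """rel_r = S[r, r] - mean_{r' != r} S[r, r'] (row-wise off-diagonals)."""
    S = np.asarray(S, float)
    n = S.shape[0]
    if n < 2 or S.shape[1] != n:
        raise ValueError("similarity matrix must be square with n_rooms >= 2")
    diag = np.diag(S)
    off_mean = (S.sum(axis=1) - diag) / (n - 1)
    return diag - off_mean


def group_reliability_map(
    mean_rel: np.ndarray, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Group map from per-participant room-averaged reliabilities.

    ``mean_rel`` is participants x searchlights (each entry a participant's
    reliability averaged across rooms at that searchlight). Per searchlight,
    a one-sample t-test against zero across participants; Benjamini-Hochberg
    FDR across searchlights. Zero-variance searchlights get NaN p and are
    excluded from the FDR.
    """
    mean_rel = np.asarray(mean_rel, float)
    n_part, n_sl = mean_rel.shape
    if n_part < 3:
        raise ValueError("group map requires at least 3 participants")
    t = np.full(n_sl, np.nan)
    p = np.full(n_sl, np.nan)
    for j in range(n_sl):
        col = mean_rel[:, j]
        col = col[np.isfinite(col)]
        if len(col) < 3 or np.ptp(col) == 0.0:
            continue
        t[j], p[j] = stats.ttest_1samp(col, 0.0)
    q, sig = fdr_threshold(p, q_threshold)
    return pd.DataFrame(
        {
            "searchlight": np.arange(n_sl),
            "stat": t,
            "mean": np.nanmean(mean_rel, axis=0),
            "p": p,
            "q": q,
            "sig": sig,
        }
    )


def feature_regression(
    rel: np.ndarray,
    features: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.001,
    binary_columns: Sequence[str] = ("has_window",),
) -> dict:
    """Regress per-room reliability on room features, with a permutation null.

    ``rel`` is (participants, searchlights, rooms). Features are z-scored
    (binary columns kept as-is) and used in a per-participant OLS with
    intercept; the map statistic per feature is the across-participant mean
    beta. The null shuffles each participant's room-to-reliability
    assignment ``n_perm`` times (features fixed), p-values are two-sided
    permutation p with add-one correction, and BH-FDR runs across
    searchlights separately per feature.
    """
    rel = np.asarray(rel, float)
    P, S, R = rel.shape
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    cols = list(features.columns)
    X = features.to_numpy(dtype=float).copy()
    for j, c in enumerate(cols):
        if c in binary_columns:
            continue
        sd = X[:, j].std()
        if sd < 1e-12:
            raise ValueError(f"feature {c!r} is constant")
        X[:, j] = (X[:, j] - X[:, j].mean()) / sd
    design = np.column_stack([np.ones(R), X])
    if np.linalg.cond(design) > 1e8:
        raise ValueError("room features are collinear (condition number > 1e8)")
    pinv = np.linalg.pinv(design)  # (k+1, R)

    rng = np.random.default_rng(seed)
    # Permutation index table: independent room shuffles per participant.
    perms = np.stack(
        [
            np.stack([rng.permutation(R) for _ in range(P)])
            for _ in range(n_perm)
        ]
    )  # (n_perm, P, R)

    def mean_betas(rel_prs: np.ndarray) -> np.ndarray:
        # rel_prs: (P, S, R) -> mean over participants of per-fit betas (S, k)
        betas = np.einsum("kr,psr->psk", pinv, rel_prs)
        return betas.mean(axis=0)[:, 1:]  # drop intercept

    true_b = mean_betas(rel)  # (S, n_features)
    null_b = np.empty((n_perm, S, X.shape[1]))
    for i in range(n_perm):
        shuffled = np.take_along_axis(rel, perms[i][:, None, :], axis=2)
        null_b[i] = mean_betas(shuffled)

    out = {}
    for j, c in enumerate(cols):
        p = two_sided_permutation_p(true_b[:, j], null_b[:, :, j].T)
        q, sig = fdr_threshold(p, q_threshold)
        out[c] = pd.DataFrame(
            {
                "searchlight": np.arange(S),
                "stat": true_b[:, j],
                "p": p,
                "q": q,
                "sig": sig,
            }
        )
    return out
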