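"""Map-level inference relating room reliability to object reinstatement.

The central statistic is a *composite z* per searchlight: within each
participant and recall task, the Pearson correlation across room-object
pairs between room reliability (at the focal searchlight) and the network
reinstatement score of the paired object, Fisher-z transformed, then
averaged across participants and across the two recall task types. The null
shuffles the object-to-room assignment within participant (one shuffle per
participant per permutation, applied to both recall tasks, since the
pairing is common to them), recomputing the identical composite each time;
p-values are two-sided
permutation p with an add-one correction and Benjamini-Hochberg FDR across
searchlights.

Inputs are "pair tables" packed as arrays:

* ``rel``:    (n_searchlights, n_participants, n_rooms) reliability
* ``scores``: (n_participants, n_tasks, n_rooms) network reinstatement of
  the object paired to each room (NaN where never recalled)
* ``covariates``: (n_participants, n_tasks, n_rooms, 2) room-reinstatement
  covariates for the partial-correlation control

Rows with NaN scores are dropped per (participant, task) before anything
else; permutations shuffle within the retained rows, keeping the
exchangeable set fixed. Cells with fewer than ``min_pairs`` complete rows
are excluded from the composite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairTables",
    "MapResult",
    "fdr_threshold",
    "two_sided_permutation_p",
    "fisher_average_map",
    "participant_specific_delta",
    "partial_correlation_map",
    "map_contrast",
]

_R_CLIP = 1.0 - 1e-7
MIN_PAIRS = 4


def fdr_threshold(p_values, q: float) -> tuple:
    """Benjamini-Hochberg step-up; NaN p-values are excluded (NaN q, not sig)."""
    p = np.asarray(p_values, float)
    q_vals = np.full(p.shape, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.sum():
        rej, qv, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
        q_vals[ok] = qv
        sig[ok] = rej
    return q_vals, sig


def two_sided_permutation_p(observed, null) -> np.ndarray:
    """p = (1 + #{|null| >= |obs|}) / (1 + n_perm), vectorized over units.

    ``observed`` has shape (S,), ``null`` shape (S, n_perm).
    """
    observed = np.atleast_1d(np.asarray(observed, float))
    null = np.asarray(null, float)
    n_perm = null.shape[-1]
    count = (np.abs(null) >= np.abs(observed)[..., None] - 1e-12).sum(axis=-1)
    p = (1.0 + count) / (1.0 + n_perm)
    p[~np.isfinite(observed)] = np.nan
    return p


@dataclass
class PairTables:
    """Room-aligned per-participant pair tables (see module docstring)."""

    rel: np.ndarray  # (S, P, R)
    scores: np.ndarray  # (P, T, R)
    covariates: Optional[np.ndarray] = None  # (P, T, R, 2)
    task_names: tuple = ("guided", "free")

    def __post_init__(self) -> None:
        self.rel = np.asarray(self.rel, float)
        self.scores = np.asarray(self.scores, float)
        if self.rel.ndim != 3 or self.scores.ndim != 3:
            raise ValueError("rel must be (S,P,R); scores must be (P,T,R)")
        if self.rel.shape[1] != self.scores.shape[0]:
            raise ValueError("participant dimensions disagree")
        if self.rel.shape[2] != self.scores.shape[2]:
            raise ValueError("room dimensions disagree")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, float)
            if self.covariates.shape[:3] != self.scores.shape:
                raise ValueError("covariates must align with scores")

    @property
    def n_searchlights(self) -> int:
        return self.rel.shape[0]

    @property
    def n_participants(self) -> int:
        return self.scores.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.scores.shape[1]


@dataclass
class MapResult:
    """Per-searchlight composite statistic with permutation inference."""

    stat: np.ndarray  # (S,)
    null: np.ndarray  # (S, n_perm)
    p: np.ndarray
    q: np.ndarray
    sig: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "searchlight": np.arange(len(self.stat)),
                "stat": self.stat,
                "p": self.p,
                "q": self.q,
                "sig": self.sig,
            }
        )


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center/normalize the last axis; constant rows become NaN."""
    xc = x - np.nanmean(x, axis=-1, keepdims=True)
    norm = np.sqrt(np.nansum(xc**2, axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = xc / norm
    out[np.broadcast_to(norm < 1e-12, out.shape)] = np.nan
    return out


def _participant_keys(
    rng: np.random.Generator, n_participants: int, n_rooms: int, n_perm: int
) -> np.ndarray:
    """Per-participant room-label permutations, shared across recall tasks.

    One room permutation per (participant, permutation); row 0 is the
    identity (the observed assignment). The same object-label shuffle
    drives both tasks — a participant's pairing does not change between
    guided and free recall, and shuffling the tasks independently would
    understate the null variance of the task-averaged composite. Rooms
    never recalled travel with the shuffle (the NaN mask moves), which
    keeps the permutation distribution exactly exchangeable with the
    observed data; the number of complete pairs is permutation-invariant.
    """
    keys = np.empty((n_participants, n_perm + 1, n_rooms), dtype=int)
    keys[:, 0] = np.arange(n_rooms)
    for p in range(n_participants):
        for k in range(1, n_perm + 1):
            keys[p, k] = rng.permutation(n_rooms)
    return keys


def _induced_orders(keys_p: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Positions table (n_perm+1, n): room permutations restricted to ``valid``.

    Used where a shuffle must act on vectors that only exist on the valid
    subset (the residual shuffles of the partial-correlation null): each
    shared room permutation is restricted to the rooms in ``valid`` (order
    of appearance), giving one uniform shuffle per task that is coupled
    across tasks and coincides with the raw map's label shuffle whenever
    every room is valid.
    """
    n_rooms = keys_p.shape[1]
    pos = np.full(n_rooms, -1)
    pos[valid] = np.arange(len(valid))
    mapped = pos[keys_p]  # (K, R); -1 where the room is not valid
    out = np.empty((keys_p.shape[0], len(valid)), dtype=int)
    for k in range(keys_p.shape[0]):
        out[k] = mapped[k][mapped[k] >= 0]
    return out


def _masked_pearson(x: np.ndarray, Y: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pearson r of ``x`` rows vs each row of ``Y`` over that row's mask.

    ``x``: (..., R); ``Y``, ``M``: (K, R) with M boolean. Returns (..., K).
    Rows where either side is constant on the mask give NaN.
    """
    Mf = M.astype(float)
    n = Mf.sum(axis=1)  # (K,)
    Ym = np.where(M, Y, 0.0)
    Sy = Ym.sum(axis=1)
    Syy = (Ym**2).sum(axis=1)
    Sx = x @ Mf.T
    Sxx = (x**2) @ Mf.T
    Sxy = x @ Ym.T
    num = n * Sxy - Sx * Sy
    var_x = n * Sxx - Sx**2
    var_y = n * Syy - Sy**2
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.sqrt(var_x * var_y)
    r = np.where((var_x <= 1e-12) | (var_y <= 1e-12), np.nan, r)
    return np.clip(r, -1.0, 1.0)


def _cell_iter(tables: PairTables, min_pairs: int):
    """Yield (participant, task, valid-room indices) for usable cells."""
    for p in range(tables.n_participants):
        for t in range(tables.n_tasks):
            valid = np.flatnonzero(np.isfinite(tables.scores[p, t]))
            if len(valid) < min_pairs:
                warnings.warn(
                    f"participant {p}, task {t}: only {len(valid)} complete "
                    "pairs, excluded from the composite"
                )
                continue
            yield p, t, valid


def _composite_with_null(
    tables: PairTables,
    n_perm: int,
    seed: int,
    partial: bool,
    min_pairs: int = MIN_PAIRS,
) -> tuple:
    """Composite z and its permutation null, shared by raw and partial maps.

    Raw: correlate reliability with scores; the null applies each
    participant's room-label permutation to the score vector (NaN rows
    travel with it). Partial: residualize both the scores and the
    reliability on the two room-reinstatement covariates (OLS with
    intercept, within participant/task, over the complete rows), correlate
    the residuals, and shuffle the score residuals in the null.
    Returns (stat (S,), null (S, n_perm)).
    """
    S = tables.n_searchlights
    rng = np.random.default_rng(seed)
    keys = _participant_keys(
        rng, tables.n_participants, tables.scores.shape[2], n_perm
    )
    acc = np.zeros((S, n_perm + 1))
    n_cells = np.zeros(S)
    for p, t, valid in _cell_iter(tables, min_pairs):
        n = len(valid)
        if partial:
            x = tables.rel[:, p, valid]  # (S, n)
            y = tables.scores[p, t, valid]  # (n,)
            cov = tables.covariates[p, t, valid]  # (n, 2)
            keep = cov.std(axis=0) > 1e-12  # constant covariates drop out
            Z = np.column_stack([np.ones(n), cov[:, keep]])
            if np.linalg.cond(Z) > 1e8:
                warnings.warn(
                    f"participant {p}, task {t}: collinear covariates, excluded"
                )
                continue
            H = np.eye(n) - Z @ np.linalg.pinv(Z)
            orders = _induced_orders(keys[p], valid)
            xs = _standardize_rows(x @ H.T)  # (S, n)
            ys = _standardize_rows((H @ y)[orders])  # (n_perm+1, n)
            r = np.clip(xs @ ys.T, -1.0, 1.0)  # (S, n_perm+1)
        else:
            Y = tables.scores[p, t][keys[p]]  # (n_perm+1, R), NaNs move
            M = np.isfinite(Y)
            r = _masked_pearson(tables.rel[:, p, :], Y, M)
        z = _fisher_z(r)
        cell_ok = np.isfinite(z).all(axis=1)
        acc[cell_ok] += z[cell_ok]
        n_cells[cell_ok] += 1
    if (n_cells == 0).any():
        warnings.warn("some searchlights have no usable cells; stat set to NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = acc / n_cells[:, None]
    return comp[:, 0], comp[:, 1:]


def fisher_average_map(
    tables: PairTables,
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.05,
    min_pairs: int = MIN_PAIRS,
) -> MapResult:
    """Composite Fisher-z map of reliability vs object reinstatement.

    The null (object-label shuffle within participant and task) is computed
    alongside; each permutation produces a full composite statistic, so the
    null respects the same averaging as the true map.
    """
    if tables.n_participants < 3:
        raise ValueError("need at least 3 participants")
    stat, null = _composite_with_null(
        tables, n_perm, seed, partial=False, min_pairs=min_pairs
    )
    p = two_sided_permutation_p(stat, null)
    q, sig = fdr_threshold(p, q_threshold)
    return MapResult(stat=stat, null=null, p=p, q=q, sig=sig)


def partial_correlation_map(
    tables: PairTables,
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.05,
    min_pairs: int = MIN_PAIRS,
) -> MapResult:
    """Composite map after residualizing on room-reinstatement covariates.

    Both the object reinstatement scores and the reliabilities are
    residualized (within participant/task) on the room-recall and
    object-recall room-reinstatement covariates before correlating; the
    null shuffles the score residuals within participant.
    """
    if tables.covariates is None:
        raise ValueError("partial correlation requires covariates")
    stat, null = _composite_with_null(
        tables, n_perm, seed, partial=True, min_pairs=min_pairs
    )
    p = two_sided_permutation_p(stat, null)
    q, sig = fdr_threshold(p, q_threshold)
    return MapResult(stat=stat, null=null, p=p, q=q, sig=sig)


def map_contrast(
    raw: MapResult,
    partial: MapResult,
    q_threshold: float = 0.05,
) -> MapResult:
    """Difference map raw - partial with a paired permutation null.

    Requires both maps to carry the same number of permutations (generated
    from the same seed so permutation k is paired across maps).
    """
    if raw.null.shape != partial.null.shape:
        raise ValueError("permutation counts differ; contrast requires pairing")
    stat = raw.stat - partial.stat
    null = raw.null - partial.null
    p = two_sided_permutation_p(stat, null)
    q, sig = fdr_threshold(p, q_threshold)
    return MapResult(stat=stat, null=null, p=p, q=q, sig=sig)


@dataclass
class DeltaResult:
    """Participant-specific model comparison (own vs other R^2)."""

    delta: np.ndarray  # (S,)
    null: np.ndarray  # (S, n_perm)
    p: np.ndarray
    q: np.ndarray
    sig: np.ndarray
    intersection: Optional[np.ndarray] = None  # sig & positive & raw-map sig+

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "searchlight": np.arange(len(self.delta)),
                "delta": self.delta,
                "p": self.p,
                "q": self.q,
                "sig": self.sig,
            }
        )
        if self.intersection is not None:
            out["intersection"] = self.intersection
        return out


def participant_specific_delta(
    tables: PairTables,
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.05,
    raw_map: Optional[MapResult] = None,
    min_pairs: int = MIN_PAIRS,
) -> DeltaResult:
    """Own-vs-other R^2 comparison across participants.

    For each searchlight and participant, R^2_own is the coefficient of
    determination of an OLS predicting the participant's reinstatement
    scores from their *own* room reliabilities; R^2_other refits the model
    with each other participant's reliabilities (room-aligned) in turn and
    averages the N-1 values. delta = mean over participants and tasks of
    (R^2_own - mean R^2_other); the null applies the same object-label
    shuffles. If ``raw_map`` is given, an intersection mask of positive
    significant delta with positive significant raw-map searchlights is
    attached.
    """
    S, P, R = tables.rel.shape
    rng = np.random.default_rng(seed)
    keys = _participant_keys(rng, P, tables.scores.shape[2], n_perm)
    acc = np.zeros((S, n_perm + 1))
    n_cells = np.zeros(S)
    for i, t, valid in _cell_iter(tables, min_pairs):
        Y = tables.scores[i, t][keys[i]]  # (n_perm+1, R), NaNs move
        M = np.isfinite(Y)
        x_flat = tables.rel.reshape(S * P, R)
        r = _masked_pearson(x_flat, Y, M).reshape(S, P, n_perm + 1)
        skip = ~np.isfinite(r).all(axis=2)  # constant predictor (s, j) pairs
        if skip.any():
            warnings.warn("constant reliability predictor; pair(s) skipped")
        r = np.nan_to_num(r)
        r2 = r**2  # (S, P, n_perm+1); simple OLS R^2 = corr^2
        own = r2[:, i, :]
        counts = np.sum(~skip, axis=1, keepdims=True) - (~skip[:, [i]]).astype(int)
        others = np.where(skip[..., None], 0.0, r2).sum(axis=1) - np.where(
            skip[:, [i], None], 0.0, r2[:, [i], :]
        ).squeeze(1)
        with np.errstate(invalid="ignore", divide="ignore"):
            other_mean = others / counts
        delta_cell = own - other_mean
        ok = np.isfinite(delta_cell).all(axis=1) & ~skip[:, i]
        acc[ok] += delta_cell[ok]
        n_cells[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = acc / n_cells[:, None]
    delta, null = comp[:, 0], comp[:, 1:]
    p = two_sided_permutation_p(delta, null)
    q, sig = fdr_threshold(p, q_threshold)
    inter = None
    if raw_map is not None:
        inter = sig & (delta > 0) & raw_map.sig & (raw_map.stat > 0)
    return DeltaResult(delta=delta, null=null, p=p, q=q, sig=sig,
                       intersection=inter)
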