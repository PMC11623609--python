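"""Design matrices and GLM-derived condition templates.

A *template* is the vector of per-vertex GLM coefficients characterizing one
condition's evoked spatial pattern. Designs are boxcar indicators convolved
with a canonical double-gamma hemodynamic response function (HRF) and
z-scored per column; templates are ordinary least squares fits of the
z-scored vertex timeseries on that design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _stats

from .events import NO_LABEL, EventMatrix

__all__ = [
    "HRFParams",
    "DesignMatrix",
    "TemplateSet",
    "double_gamma_hrf",
    "build_design_matrix",
    "fit_templates",
]


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF: difference of two gamma densities.

    ``peak`` and ``undershoot`` are the gamma shape parameters (unit scale,
    so the response peaks near ``peak - 1`` seconds and the undershoot near
    ``undershoot - 1``); ``ratio`` scales the undershoot; the kernel is
    truncated at ``length`` seconds and normalized to unit area, so a
    sustained boxcar of amplitude ``a`` plateaus at ``a``.
    """

    peak: float = 6.0
    undershoot: float = 16.0
    ratio: float = 1.0 / 6.0
    length: float = 32.0


def double_gamma_hrf(dt: float, params: HRFParams = HRFParams()) -> np.ndarray:
    """Sample the double-gamma HRF on a grid of spacing ``dt`` seconds."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0, params.length + dt / 2, dt)
    h = _stats.gamma.pdf(t, params.peak) - params.ratio * _stats.gamma.pdf(
        t, params.undershoot
    )
    return h / (h.sum() * dt)


@dataclass
class DesignMatrix:
    """TR x condition matrix of HRF-convolved, z-scored regressors."""

    data: np.ndarray
    condition_ids: np.ndarray
    tr_seconds: float
    hrf_params: HRFParams = field(default_factory=HRFParams)
    zero_columns: np.ndarray = None  # conditions absent from the events

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.condition_ids = np.asarray(self.condition_ids, dtype=int)
        if self.zero_columns is None:
            self.zero_columns = np.zeros(len(self.condition_ids), dtype=bool)

    @property
    def n_tr(self) -> int:
        return self.data.shape[0]


@dataclass
class TemplateSet:
    """Condition x vertex matrix of GLM coefficients."""

    patterns: np.ndarray
    class_kind: str  # "room" | "object"
    participant_id: str
    run_scope: str  # "per-run" | "joint"
    condition_ids: np.ndarray = None

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.condition_ids is None:
            self.condition_ids = np.arange(self.patterns.shape[0])

    @property
    def n_conditions(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.patterns.shape[1]


def _zscore_columns(x: np.ndarray, warn_zero: bool = False) -> np.ndarray:
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    degenerate = sd < 1e-12
    out = np.zeros_like(x)
    good = ~degenerate
    out[:, good] = (x[:, good] - mean[good]) / sd[good]
    return out, degenerate


def build_design_matrix(
    events: EventMatrix,
    n_conditions: int,
    hrf_params: HRFParams = HRFParams(),
    oversample_dt: float = 0.05,
    kind: Optional[str] = None,
) -> DesignMatrix:
    """Boxcar indicators convolved with the HRF, sampled at TR onsets.

    Each condition's per-TR indicator (optionally restricted to one event
    kind) is upsampled to a fine grid, convolved with the double-gamma HRF,
    sampled back at TR onset times, and z-scored. Conditions absent from the
    events keep an all-zero column and trigger a warning.
    """
    tr = events.tr_seconds
    n_tr = events.n_tr
    labels = events.labels
    active = labels != NO_LABEL
    if kind is not None:
        active &= events.kinds == kind
    upsample = max(int(round(tr / oversample_dt)), 1)
    dt = tr / upsample
    hrf = double_gamma_hrf(dt, hrf_params)
    fine_len = n_tr * upsample
    box = np.zeros((fine_len, n_conditions))
    for c in range(n_conditions):
        mask = active & (labels == c)
        box[:, c] = np.repeat(mask.astype(float), upsample)
    conv = np.apply_along_axis(
        lambda col: np.convolve(col, hrf)[:fine_len], 0, box
    )
    sampled = conv[::upsample]
    data, degenerate = _zscore_columns(sampled)
    if degenerate.any():
        missing = np.flatnonzero(degenerate).tolist()
        warnings.warn(f"conditions absent from events, zero columns kept: {missing}")
    return DesignMatrix(
        data=data,
        condition_ids=np.arange(n_conditions),
        tr_seconds=tr,
        hrf_params=hrf_params,
        zero_columns=degenerate,
    )


def _check_rank(design: np.ndarray, condition_ids: np.ndarray) -> None:
    nz = np.flatnonzero(design.std(axis=0) > 1e-12)
    sub = design[:, nz]
    if sub.size == 0:
        return
    rank = np.linalg.matrix_rank(sub)
    if rank < sub.shape[1]:
        corr = np.corrcoef(sub.T)
        pairs = [
            (int(condition_ids[nz[i]]), int(condition_ids[nz[j]]))
            for i in range(len(nz))
            for j in range(i + 1, len(nz))
            if abs(corr[i, j]) > 1 - 1e-8
        ]
        raise ValueError(
            f"design is rank-deficient (rank {rank} < {sub.shape[1]}); "
            f"collinear condition pairs: {pairs if pairs else 'non-pairwise'}"
        )


def fit_templates(
    timeseries,
    design,
    class_kind: str,
    run_scope: str,
    participant_id: str = "",
) -> TemplateSet:
    """Ordinary least squares template extraction.

    ``timeseries`` and ``design`` may each be a single array / DesignMatrix
    or a sequence of them; sequences are concatenated along time (the
    "joint" scope used for object templates, which are fitted simultaneously
    across both object-video runs; room templates are fitted per run).
    """
    if run_scope not in ("per-run", "joint"):
        raise ValueError("run_scope must be 'per-run' or 'joint'")
    ts_list = timeseries if isinstance(timeseries, (list, tuple)) else [timeseries]
    ds_list = design if isinstance(design, (list, tuple)) else [design]
    if len(ts_list) != len(ds_list):
        raise ValueError("need one design per timeseries")
    y = np.vstack([np.asarray(getattr(t, "data", t), dtype=float) for t in ts_list])
    xs = [d.data if isinstance(d, DesignMatrix) else np.asarray(d, float) for d in ds_list]
    x = np.vstack(xs)
    condition_ids = (
        ds_list[0].condition_ids
        if isinstance(ds_list[0], DesignMatrix)
        else np.arange(x.shape[1])
    )
    if y.shape[0] != x.shape[0]:
        raise ValueError("design rows must match timeseries rows")
    _check_rank(x, condition_ids)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return TemplateSet(
        patterns=beta,
        class_kind=class_kind,
        participant_id=participant_id,
        run_scope=run_scope,
        condition_ids=np.asarray(condition_ids),
    )
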