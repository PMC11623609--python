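"""End-to-end analysis: templates -> reliability -> decoding -> scaffold maps.

Runs the full chain on a :class:`~palace.sim.SyntheticDataset` (or any
object with the same layout): per-participant GLM templates, per-searchlight
room reliability, leave-one-participant-out classifier networks, recall
reinstatement scores, and the map-level statistics relating reliability to
reinstatement (raw, participant-specific delta-R^2, partial-correlation
control, and their contrast).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import decoding, scaffold
from .events import KIND_OBJECT, KIND_ROOM, NO_LABEL
from .reliability import group_reliability_map, reliability_scores, similarity_matrix
from .sim import SyntheticDataset
from .templates import build_design_matrix, fit_templates

__all__ = ["AnalysisOptions", "AnalysisResult", "analyze_dataset",
           "participant_templates", "reliability_by_searchlight"]

TASKS = ("guided", "free")


@dataclass
class AnalysisOptions:
    seed: int = 0
    n_perm: int = 200
    k_network: int = 50
    hrf_shift_tr: int = 4
    q_threshold: float = 0.05
    classifier: decoding.ClassifierSpec = None
    networks: tuple = ("rocn",)
    compute_partial: bool = False  # requires "rrcn" in networks
    compute_delta: bool = False
    compute_group_map: bool = True

    def __post_init__(self) -> None:
        if self.classifier is None:
            self.classifier = decoding.ClassifierSpec()
        if self.compute_partial and "rrcn" not in self.networks:
            self.networks = tuple(self.networks) + ("rrcn",)


@dataclass
class AnalysisResult:
    rel: np.ndarray  # (S, P, R)
    group_map: Optional[pd.DataFrame]
    networks: dict  # name -> NetworkMask
    accuracy: dict  # name -> {"true": (units,), "null": (units, n_perm)}
    tables: scaffold.PairTables
    raw_map: scaffold.MapResult
    delta: Optional[scaffold.DeltaResult] = None
    partial_map: Optional[scaffold.MapResult] = None
    contrast_map: Optional[scaffold.MapResult] = None


def participant_templates(ds: SyntheticDataset) -> dict:
    """Per-participant template sets.

    Room templates are fitted per pre-learning run (two separate sets, the
    inputs to the reliability similarity matrix) and jointly across both
    runs (the set used to train room classifiers); object templates are
    fitted jointly across both object-video runs.
    """
    R = ds.config.n_rooms
    out = {}
    for pid in ds.participant_ids:
        runs = ds.runs[pid]
        room_designs, room_data = [], []
        per_run = []
        for k in (1, 2):
            run = runs[f"room_video_{k}"]
            design = build_design_matrix(run.event_matrix(), R, kind=KIND_ROOM)
            per_run.append(
                fit_templates(run.timeseries, design, "room", "per-run", pid)
            )
            room_designs.append(design)
            room_data.append(run.timeseries)
        room_joint = fit_templates(room_data, room_designs, "room", "joint", pid)
        obj_designs, obj_data = [], []
        for k in (1, 2):
            run = runs[f"object_video_{k}"]
            obj_designs.append(
                build_design_matrix(run.event_matrix(), R, kind=KIND_OBJECT)
            )
            obj_data.append(run.timeseries)
        obj_joint = fit_templates(obj_data, obj_designs, "object", "joint", pid)
        out[pid] = {
            "room_run1": per_run[0],
            "room_run2": per_run[1],
            "room_joint": room_joint,
            "object_joint": obj_joint,
        }
    return out


def reliability_by_searchlight(ds: SyntheticDataset, templates: dict) -> np.ndarray:
    """rel[searchlight, participant, room] from per-run room templates."""
    cfg = ds.config
    S, P, R = cfg.n_searchlights, cfg.n_participants, cfg.n_rooms
    rel = np.empty((S, P, R))
    for p, pid in enumerate(ds.participant_ids):
        t1 = templates[pid]["room_run1"].patterns
        t2 = templates[pid]["room_run2"].patterns
        for sl in range(S):
            slc = ds.searchlight_slice(sl)
            rel[sl, p] = reliability_scores(similarity_matrix(t1[:, slc], t2[:, slc]))
    return rel


def _test_runs_for(network: str, runs: dict) -> list:
    if network == "rocn":
        return [runs["room_recall_1"], runs["room_recall_2"]]
    if network in ("pocn", "rrcn"):
        return [runs["object_video_1"], runs["object_video_2"]]
    raise ValueError(f"unknown network {network!r}")


def _test_labels(network: str, run, pairing) -> np.ndarray:
    """Correct per-TR class labels for a validation run of a given network."""
    em = run.event_matrix()
    labels = em.labels.copy()
    active = labels != NO_LABEL
    if network == "rocn":
        # room videos shown, paired object recalled: object classes
        labels[active] = pairing.room_to_object[labels[active]]
    elif network == "rrcn":
        # object videos shown, paired room recalled: room classes
        labels[active] = pairing.object_to_room[labels[active]]
    # pocn: object videos with object classes; labels already correct
    return labels


def _recall_runs(runs: dict, task: str) -> list:
    if task == "guided":
        return [runs[name] for name in sorted(runs) if name.startswith("guided_")]
    return [runs["free"]]


def analyze_dataset(ds: SyntheticDataset, options: AnalysisOptions) -> AnalysisResult:
    opt = options
    cfg = ds.config
    S, P, R = cfg.n_searchlights, cfg.n_participants, cfg.n_rooms
    pids = ds.participant_ids
    spec = decoding.ClassifierSpec(
        n_classes=R,
        regularization_strength=opt.classifier.regularization_strength,
        max_iter=opt.classifier.max_iter,
        tol=opt.classifier.tol,
        feature_standardization=opt.classifier.feature_standardization,
    )

    templates = participant_templates(ds)
    rel = reliability_by_searchlight(ds, templates)
    group_map = None
    if opt.compute_group_map:
        group_map = group_reliability_map(
            rel.mean(axis=2).T, q_threshold=opt.q_threshold
        )

    need_object_clf = bool({"rocn", "pocn"} & set(opt.networks))
    need_room_clf = "rrcn" in opt.networks

    # --- LOPO classifiers per (searchlight, fold) --------------------------
    obj_clf = {}  # (sl, fold) -> TrainedClassifier
    room_clf = {}
    for fold, held in enumerate(pids):
        train_pids = [q for q in pids if q != held]
        obj_sets = [templates[q]["object_joint"] for q in train_pids]
        room_sets = [templates[q]["room_joint"] for q in train_pids]
        for sl in range(S):
            slc = ds.searchlight_slice(sl)
            if need_object_clf:
                sliced = [
                    type(ts)(
                        patterns=ts.patterns[:, slc], class_kind=ts.class_kind,
                        participant_id=ts.participant_id, run_scope=ts.run_scope,
                        condition_ids=ts.condition_ids,
                    )
                    for ts in obj_sets
                ]
                obj_clf[sl, fold] = decoding.train_classifier(sliced, spec)
            if need_room_clf:
                sliced = [
                    type(ts)(
                        patterns=ts.patterns[:, slc], class_kind=ts.class_kind,
                        participant_id=ts.participant_id, run_scope=ts.run_scope,
                        condition_ids=ts.condition_ids,
                    )
                    for ts in room_sets
                ]
                room_clf[sl, fold] = decoding.train_classifier(sliced, spec)

    # --- network selection -------------------------------------------------
    rng = np.random.default_rng(opt.seed)
    networks = {}
    accuracy = {}
    for net in opt.networks:
        clf_table = room_clf if net == "rrcn" else obj_clf
        acc_sum = np.zeros(S)
        null_sum = np.zeros((S, opt.n_perm))
        n_cells = 0
        for fold, held in enumerate(pids):
            pairing = ds.pairings[fold]
            for run in _test_runs_for(net, ds.runs[held]):
                labels = _test_labels(net, run, pairing)
                null_seed = int(rng.integers(2**31))
                for sl in range(S):
                    slc = ds.searchlight_slice(sl)
                    ev = decoding.predict_evidence(
                        clf_table[sl, fold], run.timeseries[:, slc],
                        opt.hrf_shift_tr,
                    )
                    acc_sum[sl] += decoding.score_accuracy(ev, labels)
                    null_sum[sl] += decoding.contiguity_null(
                        labels, ev, n_perm=opt.n_perm, seed=null_seed
                    )
            n_cells += len(_test_runs_for(net, ds.runs[held]))
        true_acc = acc_sum / n_cells
        null_acc = null_sum / n_cells
        accuracy[net] = {"true": true_acc, "null": null_acc}
        networks[net] = decoding.select_network(
            true_acc, null_acc, k=min(opt.k_network, S), name=net
        )

    # --- recall evidence within networks -----------------------------------
    def network_evidence(net: str, fold: int, run) -> np.ndarray:
        clf_table = room_clf if net == "rrcn" else obj_clf
        members = networks[net].members
        acc = None
        for sl in members:
            slc = ds.searchlight_slice(int(sl))
            ev = decoding.predict_evidence(
                clf_table[int(sl), fold], run.timeseries[:, slc], opt.hrf_shift_tr
            )
            acc = ev if acc is None else acc + ev
        return acc / len(members)

    scores = np.full((P, len(TASKS), R), np.nan)
    covariates = None
    if opt.compute_partial:
        covariates = np.full((P, len(TASKS), R, 2), np.nan)

    for fold, pid in enumerate(pids):
        pairing = ds.pairings[fold]
        # RRCN covariates pool timepoints across guided AND free recall: one
        # room-reinstatement score per room per participant, shared by both
        # task rows of the pair table.
        rrcn_ev, room_labels, objroom_labels = [], [], []
        for t, task in enumerate(TASKS):
            runs = _recall_runs(ds.runs[pid], task)
            obj_ev, obj_labels = [], []
            for run in runs:
                em = run.event_matrix()
                if "rocn" in networks:
                    obj_ev.append(network_evidence("rocn", fold, run))
                    lbl = em.labels.copy()
                    lbl[em.kinds != KIND_OBJECT] = NO_LABEL
                    obj_labels.append(lbl)
                if opt.compute_partial:
                    rrcn_ev.append(network_evidence("rrcn", fold, run))
                    room_lbl = em.labels.copy()
                    room_lbl[em.kinds != KIND_ROOM] = NO_LABEL
                    room_labels.append(room_lbl)
                    # room class active while the paired object is spoken
                    obj_lbl = em.labels.copy()
                    is_obj = em.kinds == KIND_OBJECT
                    obj_lbl[~is_obj] = NO_LABEL
                    obj_lbl[is_obj] = pairing.object_to_room[obj_lbl[is_obj]]
                    objroom_labels.append(obj_lbl)
            if "rocn" in networks:
                per_object = decoding.reinstatement_scores(obj_ev, obj_labels, R)
                scores[fold, t] = per_object[pairing.room_to_object]
        if opt.compute_partial:
            room_recall_cov = decoding.reinstatement_scores(
                rrcn_ev, room_labels, R
            )
            object_recall_cov = decoding.reinstatement_scores(
                rrcn_ev, objroom_labels, R
            )
            for t in range(len(TASKS)):
                covariates[fold, t, :, 0] = room_recall_cov
                covariates[fold, t, :, 1] = object_recall_cov

    if covariates is not None:
        # pairwise NaN dropping: a row missing any covariate is unusable
        incomplete = ~np.isfinite(covariates).all(axis=3)
        scores[incomplete] = np.nan

    tables = scaffold.PairTables(rel=rel, scores=scores, covariates=covariates)

    # --- map-level statistics ----------------------------------------------
    map_seed = int(np.random.default_rng(opt.seed + 1).integers(2**31))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        raw_map = scaffold.fisher_average_map(
            tables, n_perm=opt.n_perm, seed=map_seed, q_threshold=opt.q_threshold
        )
        delta = None
        if opt.compute_delta:
            delta = scaffold.participant_specific_delta(
                tables, n_perm=opt.n_perm, seed=map_seed,
                q_threshold=opt.q_threshold, raw_map=raw_map,
            )
        partial_map = contrast_map = None
        if opt.compute_partial:
            partial_map = scaffold.partial_correlation_map(
                tables, n_perm=opt.n_perm, seed=map_seed,
                q_threshold=opt.q_threshold,
            )
            contrast_map = scaffold.map_contrast(
                raw_map, partial_map, q_threshold=opt.q_threshold
            )

    return AnalysisResult(
        rel=rel,
        group_map=group_map,
        networks=networks,
        accuracy=accuracy,
        tables=tables,
        raw_map=raw_map,
        delta=delta,
        partial_map=partial_map,
        contrast_map=contrast_map,
    )
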