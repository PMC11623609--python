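"""Dataset and result serialization (delimited text formats throughout)."""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from .sim import (
    PalaceGraph,
    Pairing,
    RunData,
    SimConfig,
    SyntheticDataset,
)
from .templates import HRFParams

__all__ = ["write_dataset", "load_dataset", "write_maps"]

_TASK_TO_BIDS = {
    "room_video": "roomvideo",
    "object_video": "objectvideo",
    "room_recall": "roomrecall",
    "guided": "guided",
    "free": "free",
}
_BIDS_TO_TASK = {v: k for k, v in _TASK_TO_BIDS.items()}


def _bids_name(run: RunData) -> tuple:
    m = re.match(r"(.*?)_?(\d+)?$", run.name)
    idx = int(m.group(2)) if m.group(2) else 1
    return _TASK_TO_BIDS[run.task], idx


def _run_name(task: str, idx: int) -> str:
    if task == "free":
        return "free"
    if task == "guided":
        return f"guided_{idx:02d}"
    return f"{task}_{idx}"


def write_dataset(ds: SyntheticDataset, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ds.graph.edges(), columns=["room_a", "room_b"]).to_csv(
        out / "palace_edges.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"participant_id": p.participant_id, "room": r, "object": int(o)}
            for p in ds.pairings
            for r, o in enumerate(p.room_to_object)
        ]
    ).to_csv(out / "pairings.tsv", sep="\t", index=False)
    ds.features.rename_axis("room_name").to_csv(out / "features.tsv", sep="\t")
    truth = ds.truth
    pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "room": r,
                "object": int(p.room_to_object[r]),
                "lambda": truth["lambdas"][s, r],
                "m": truth["m"][s, r],
                "a": truth["a_by_room"][s, r],
            }
            for s, p in enumerate(ds.pairings)
            for r in range(ds.config.n_rooms)
        ]
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"searchlight": truth["signal_searchlights"]}
    ).to_csv(out / "signal_searchlights.tsv", sep="\t", index=False)

    cfg = dataclasses.asdict(ds.config)
    cfg["degree_sequence"] = list(cfg["degree_sequence"])
    cfg["hrf_params"] = dataclasses.asdict(ds.config.hrf_params)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)

    for pid, runs in ds.runs.items():
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        for run in runs.values():
            task, idx = _bids_name(run)
            stem = f"{pid}_task-{task}_run-{idx}"
            np.savetxt(
                pdir / f"{stem}_bold.tsv.gz", run.timeseries,
                fmt="%.5f", delimiter="\t",
            )
            ev.segments_to_frame(run.segments).to_csv(
                pdir / f"{stem}_events.tsv", sep="\t", index=False
            )
    return out


def load_dataset(indir) -> SyntheticDataset:
    src = Path(indir)
    with open(src / "config.yaml") as fh:
        cfg_dict = yaml.safe_load(fh)
    cfg_dict["degree_sequence"] = tuple(cfg_dict["degree_sequence"])
    cfg_dict["hrf_params"] = HRFParams(**cfg_dict["hrf_params"])
    cfg = SimConfig(**cfg_dict)

    edges = pd.read_csv(src / "palace_edges.tsv", sep="\t")
    adjacency = np.zeros((cfg.n_rooms, cfg.n_rooms), dtype=bool)
    adjacency[edges.room_a, edges.room_b] = True
    adjacency[edges.room_b, edges.room_a] = True
    graph = PalaceGraph(
        adjacency=adjacency,
        room_names=tuple(f"room_{i:02d}" for i in range(cfg.n_rooms)),
    )

    pair_rows = pd.read_csv(src / "pairings.tsv", sep="\t")
    pairings = []
    for pid, grp in pair_rows.groupby("participant_id", sort=True):
        mapping = np.empty(cfg.n_rooms, dtype=int)
        mapping[grp.room.to_numpy()] = grp.object.to_numpy()
        pairings.append(Pairing(participant_id=pid, room_to_object=mapping))

    features = pd.read_csv(src / "features.tsv", sep="\t", index_col="room_name")

    truth_rows = pd.read_csv(src / "truth.tsv", sep="\t")
    P, R = cfg.n_participants, cfg.n_rooms
    lam = np.empty((P, R))
    m = np.empty((P, R))
    a_room = np.empty((P, R))
    pid_index = {p.participant_id: i for i, p in enumerate(pairings)}
    for row in truth_rows.itertuples():
        i = pid_index[row.participant_id]
        lam[i, row.room] = getattr(row, "_4")  # "lambda" is a keyword
        m[i, row.room] = row.m
        a_room[i, row.room] = row.a
    a_obj = np.empty((P, R))
    for i, p in enumerate(pairings):
        a_obj[i, p.room_to_object] = a_room[i]
    signal = pd.read_csv(src / "signal_searchlights.tsv", sep="\t")

    runs: dict = {}
    for p in pairings:
        pid = p.participant_id
        runs[pid] = {}
        for bold in sorted((src / pid).glob("*_bold.tsv.gz")):
            mt = re.match(rf"{pid}_task-(\w+)_run-(\d+)_bold", bold.name)
            task = _BIDS_TO_TASK[mt.group(1)]
            idx = int(mt.group(2))
            name = _run_name(task, idx)
            data = np.loadtxt(bold, delimiter="\t", ndmin=2)
            segs = ev.segments_from_frame(
                pd.read_csv(
                    bold.with_name(bold.name.replace("_bold.tsv.gz", "_events.tsv")),
                    sep="\t",
                )
            )
            runs[pid][name] = RunData(
                name=name, task=task, timeseries=data, segments=segs,
                tr_seconds=cfg.tr_seconds,
            )

    truth = {
        "lambdas": lam,
        "m": m,
        "a_by_room": a_room,
        "a_by_object": a_obj,
        "group_effect": None,
        "signal_searchlights": signal.searchlight.to_numpy(),
        "cued_paths": None,
    }
    return SyntheticDataset(
        config=cfg, graph=graph, pairings=pairings, features=features,
        runs=runs, truth=truth,
    )


def write_maps(result, outdir, manifest: dict = None) -> Path:
    """Serialize an AnalysisResult's maps and networks as TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.raw_map.to_frame().to_csv(out / "map_raw.tsv", sep="\t", index=False)
    if result.group_map is not None:
        result.group_map.to_csv(out / "map_reliability_group.tsv", sep="\t",
                                index=False)
    if result.delta is not None:
        result.delta.to_frame().to_csv(out / "map_delta_r2.tsv", sep="\t",
                                       index=False)
    if result.partial_map is not None:
        result.partial_map.to_frame().to_csv(out / "map_partial.tsv", sep="\t",
                                             index=False)
    if result.contrast_map is not None:
        result.contrast_map.to_frame().to_csv(out / "map_contrast.tsv", sep="\t",
                                              index=False)
    for name, mask in result.networks.items():
        pd.DataFrame(
            {"member": mask.members}
        ).to_csv(out / f"network_{name}.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "unit": np.arange(len(mask.zscores)),
                "z": mask.zscores,
                "true_accuracy": result.accuracy[name]["true"],
            }
        ).to_csv(out / f"accuracy_{name}.tsv", sep="\t", index=False)
    if manifest:
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)
    return out
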