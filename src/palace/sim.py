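"""Synthetic memory-palace datasets with planted, recoverable effects.

The generator emulates a two-session room/object fMRI design: participants
learn a 23-room palace, are scanned watching room videos before learning
room-object pairings (two runs), learn one object per room, and are scanned
again watching object videos (two runs, during which they recall the paired
room), watching room videos while recalling the paired object (two runs),
and performing 11 guided (5-room cued path) plus one free verbal recall.

Planted generative model (all vertex patterns unit-normal):

* group room template ``G_r`` and object template ``O_o`` per condition;
* participant template ``P_{s,r} = sqrt(1-tau) G_r + sqrt(tau) eta_{s,r}``
  (``tau`` = idiosyncratic variance share);
* per-room reliability ``lambda_{s,r} = clip(lambda0 + g_r + u_{s,r},
  0.01, 0.99)`` with ``g_r`` shared across participants and ``u_{s,r}``
  idiosyncratic;
* run-k room pattern ``sqrt(lambda) P_{s,r} + sqrt(1-lambda) fresh-noise``;
* room reinstatement amplitude ``m_{s,r} = gamma lambda_{s,r} + noise``;
  object reinstatement amplitude ``a_{s,o} = alpha + beta_direct
  lambda_{s,r(o)} + beta_mediated m_{s,r(o)} + noise``;
* per run, the neural signal at each TR is the sum of active condition
  patterns weighted by their amplitudes, convolved with the HRF, plus white
  vertex noise, then z-scored per vertex per run;
* only a configured subset of searchlights carries room/object structure;
  the rest are pure noise.

``beta_direct`` plants a direct reliability-to-object-reinstatement path;
``beta_mediated`` (with ``gamma``) plants the indirect path through room
reinstatement, so the partial-correlation control has a testable target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from . import events as ev
from .templates import HRFParams, double_gamma_hrf

__all__ = [
    "DEFAULT_DEGREE_SEQUENCE",
    "PalaceGraph",
    "Pairing",
    "SimConfig",
    "RunData",
    "SyntheticDataset",
    "build_palace_graph",
    "sample_pairings",
    "simulate_dataset",
]

# 16 rooms of degree 2, 6 of degree 3, 1 of degree 4 — the palace's layout.
DEFAULT_DEGREE_SEQUENCE = (2,) * 16 + (3,) * 6 + (4,)


@dataclass(frozen=True)
class PalaceGraph:
    """Symmetric, connected room-adjacency graph."""

    adjacency: np.ndarray
    room_names: tuple

    @property
    def n_rooms(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def edges(self) -> list:
        a, b = np.nonzero(np.triu(self.adjacency))
        return list(zip(a.tolist(), b.tolist()))


@dataclass(frozen=True)
class Pairing:
    """One participant's random room -> object bijection."""

    participant_id: str
    room_to_object: np.ndarray

    @property
    def object_to_room(self) -> np.ndarray:
        inv = np.empty_like(self.room_to_object)
        inv[self.room_to_object] = np.arange(len(self.room_to_object))
        return inv


def build_palace_graph(
    degree_sequence: Sequence[int] = DEFAULT_DEGREE_SEQUENCE,
    seed: int = 0,
    max_retries: int = 10_000,
) -> PalaceGraph:
    """Uniform-ish simple connected graph with the exact degree sequence.

    Stub-matching configuration model with rejection of self-loops,
    multi-edges and disconnected realizations, retried up to
    ``max_retries`` times. Deterministic per seed.
    """
    seq = [int(d) for d in degree_sequence]
    if not nx.is_graphical(seq):
        raise ValueError(f"degree sequence {seq} is not graphical")
    n = len(seq)
    stubs = np.repeat(np.arange(n), seq)
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        perm = rng.permutation(stubs)
        a, b = perm[0::2], perm[1::2]
        if np.any(a == b):
            continue
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        keys = lo * n + hi
        if len(np.unique(keys)) != len(keys):
            continue
        adjacency = np.zeros((n, n), dtype=bool)
        adjacency[a, b] = True
        adjacency[b, a] = True
        if nx.is_connected(nx.from_numpy_array(adjacency)):
            return PalaceGraph(
                adjacency=adjacency,
                room_names=tuple(f"room_{i:02d}" for i in range(n)),
            )
    raise RuntimeError(
        f"no connected simple realization of {seq} found in {max_retries} retries"
    )


def sample_pairings(
    n_rooms: int, n_participants: int, seed: int = 0
) -> list:
    """Independent uniform room->object permutations, one per participant."""
    if n_participants < 2:
        raise ValueError(
            "need at least 2 participants (leave-one-out is undefined otherwise)"
        )
    rng = np.random.default_rng(seed)
    return [
        Pairing(
            participant_id=f"sub-{i + 1:02d}",
            room_to_object=rng.permutation(n_rooms),
        )
        for i in range(n_participants)
    ]


@dataclass
class SimConfig:
    """Study-design and generative-model parameters.

    Defaults follow the emulated design: 25 participants, 23 rooms with the
    palace degree split, 1.3 s TR, 10 s videos with 5 s gaps, 11 guided
    recalls with 5-room cued paths, one free recall.
    """

    seed: int  # mandatory
    n_participants: int = 25
    n_rooms: int = 23
    degree_sequence: tuple = DEFAULT_DEGREE_SEQUENCE
    vertices_per_searchlight: int = 30
    n_searchlights: int = 40
    signal_searchlight_fraction: float = 0.25
    tr_seconds: float = 1.3
    video_seconds: float = 10.0
    isi_seconds: float = 5.0
    tau_idiosyncrasy: float = 0.3
    lambda0: float = 0.50
    g_sd: float = 0.20
    u_sd: float = 0.15
    alpha: float = 1.0
    beta_direct: float = 0.5
    beta_mediated: float = 0.0
    gamma: float = 0.2
    sigma_m: float = 0.05
    sigma_a: float = 0.10
    noise_sd: float = 1.0
    n_guided_runs: int = 11
    guided_path_len: int = 5
    pad_seconds: float = 8.0
    hrf_params: HRFParams = field(default_factory=HRFParams)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("tau_idiosyncrasy", "signal_searchlight_fraction", "lambda0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("tr_seconds", "video_seconds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.degree_sequence) != self.n_rooms:
            raise ValueError("degree_sequence length must equal n_rooms")

    @property
    def n_vertices(self) -> int:
        return self.n_searchlights * self.vertices_per_searchlight


@dataclass
class RunData:
    """One run's z-scored timeseries plus its second-resolution events."""

    name: str
    task: str  # room_video | object_video | room_recall | guided | free
    timeseries: np.ndarray  # TR x vertex, z-scored per vertex
    segments: list  # TranscriptSegment list (video schedule or transcript)
    tr_seconds: float

    @property
    def n_tr(self) -> int:
        return self.timeseries.shape[0]

    def event_matrix(self) -> ev.EventMatrix:
        return ev.events_from_segments(self.segments, self.tr_seconds, self.n_tr)


@dataclass
class SyntheticDataset:
    config: SimConfig
    graph: PalaceGraph
    pairings: list
    features: "object"  # pandas DataFrame, rooms x features
    runs: dict  # participant_id -> {run_name: RunData}
    truth: dict  # lambdas (P,R), m (P,R), a_by_object (P,O), signal_searchlights,
    #              group_effect g_r, cued_paths

    @property
    def participant_ids(self) -> list:
        return [p.participant_id for p in self.pairings]

    def searchlight_slice(self, searchlight: int) -> slice:
        v = self.config.vertices_per_searchlight
        return slice(searchlight * v, (searchlight + 1) * v)


def _room_features(graph: PalaceGraph, rng: np.random.Generator):
    import pandas as pd

    n = graph.n_rooms
    return pd.DataFrame(
        {
            "degree": graph.degrees,
            "occupied_ratio": rng.uniform(0.1, 0.6, n),
            "object_count": rng.poisson(8, n),
            "floor_area": rng.uniform(10, 60, n),
            "corners": rng.integers(4, 11, n),
            "has_window": rng.integers(0, 2, n),
        },
        index=[graph.room_names[i] for i in range(n)],
    )


def _self_avoiding_walk(
    graph: PalaceGraph, length: int, rng: np.random.Generator, attempts: int = 50
) -> list:
    """A path of ``length`` rooms along edges, self-avoiding when possible."""
    adj = [np.flatnonzero(graph.adjacency[r]) for r in range(graph.n_rooms)]
    best = None
    for _ in range(attempts):
        path = [int(rng.integers(graph.n_rooms))]
        for _ in range(length - 1):
            nxt = adj[path[-1]]
            fresh = [v for v in nxt if v not in path]
            step = fresh if fresh else list(nxt)
            path.append(int(rng.choice(step)))
        if len(set(path)) == length:
            return path
        best = path
    return best


def _recall_transcript(
    rooms: Sequence[int],
    pairing: Pairing,
    rng: np.random.Generator,
) -> list:
    """Interleaved room-then-object segments, durations uniform on [3, 10] s."""
    segs = []
    t = float(rng.uniform(1.0, 3.0))
    for r in rooms:
        d_room = float(rng.uniform(3.0, 10.0))
        segs.append(ev.TranscriptSegment(int(r), ev.KIND_ROOM, t, t + d_room))
        t += d_room + float(rng.uniform(0.3, 1.5))
        d_obj = float(rng.uniform(3.0, 10.0))
        segs.append(
            ev.TranscriptSegment(
                int(pairing.room_to_object[r]), ev.KIND_OBJECT, t, t + d_obj
            )
        )
        t += d_obj + float(rng.uniform(0.3, 1.5))
    return segs


def _amplitude_matrix(
    segments: Sequence[ev.TranscriptSegment],
    n_tr: int,
    cfg: SimConfig,
    room_amp,
    object_amp,
    extra_room_for_object=None,
    extra_room_amp=None,
) -> tuple:
    """HRF-convolved per-TR amplitude courses for room and object channels.

    ``room_amp[r]`` / ``object_amp[o]`` weight each condition while its
    segment is active; ``extra_room_for_object`` optionally co-activates a
    room channel (at ``extra_room_amp[room]``) whenever an object segment is
    active, modelling recall of the paired room during object viewing.
    """
    dt = 0.1
    fine_len = int(math.ceil(n_tr * cfg.tr_seconds / dt)) + 1
    n_rooms, n_objects = cfg.n_rooms, cfg.n_rooms
    amp = np.zeros((fine_len, n_rooms + n_objects))
    t_fine = np.arange(fine_len) * dt
    for seg in segments:
        active = (t_fine >= seg.onset) & (t_fine < seg.offset)
        if seg.kind == ev.KIND_ROOM:
            amp[active, seg.label] += room_amp[seg.label]
        else:
            amp[active, n_rooms + seg.label] += object_amp[seg.label]
            if extra_room_for_object is not None:
                room = int(extra_room_for_object[seg.label])
                amp[active, room] += extra_room_amp[room]
    # Discrete convolution scaled by dt approximates the continuous integral,
    # so a sustained boxcar of amplitude a plateaus at a (unit-area HRF).
    hrf = double_gamma_hrf(dt, cfg.hrf_params) * dt
    conv = np.empty_like(amp)
    for c in range(amp.shape[1]):
        if np.any(amp[:, c]):
            conv[:, c] = np.convolve(amp[:, c], hrf)[:fine_len]
        else:
            conv[:, c] = 0.0
    tr_idx = np.clip(
        np.round(np.arange(n_tr) * cfg.tr_seconds / dt).astype(int), 0, fine_len - 1
    )
    courses = conv[tr_idx]
    return courses[:, :n_rooms], courses[:, n_rooms:]


def _zscore_runs(y: np.ndarray) -> np.ndarray:
    mean = y.mean(axis=0)
    sd = y.std(axis=0)
    sd[sd < 1e-12] = 1.0  # degenerate (all-zero) columns stay zero
    return (y - mean) / sd


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset under the planted model."""
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    (s_graph, s_pair, s_feat, s_truth, s_patterns, s_runs) = root.spawn(6)

    graph = build_palace_graph(cfg.degree_sequence, seed=s_graph.generate_state(1)[0])
    pairings = sample_pairings(
        cfg.n_rooms, cfg.n_participants, seed=s_pair.generate_state(1)[0]
    )
    features = _room_features(graph, np.random.default_rng(s_feat))

    R = cfg.n_rooms
    P = cfg.n_participants
    V = cfg.n_vertices
    rng_truth = np.random.default_rng(s_truth)

    n_signal = int(round(cfg.signal_searchlight_fraction * cfg.n_searchlights))
    signal_searchlights = np.sort(
        rng_truth.choice(cfg.n_searchlights, size=n_signal, replace=False)
    )
    signal_mask = np.zeros(V, dtype=bool)
    vps = cfg.vertices_per_searchlight
    for sl in signal_searchlights:
        signal_mask[sl * vps : (sl + 1) * vps] = True
    n_sig_v = int(signal_mask.sum())

    # Planted reliabilities and reinstatement amplitudes.
    g_r = rng_truth.normal(0.0, cfg.g_sd, R)
    u_sr = rng_truth.normal(0.0, cfg.u_sd, (P, R))
    lam = np.clip(cfg.lambda0 + g_r[None, :] + u_sr, 0.01, 0.99)
    clipped = np.mean((lam <= 0.01) | (lam >= 0.99))
    if clipped > 0.10:
        warnings.warn(
            f"reliability clipped at its bounds for {clipped:.0%} of rooms; "
            "consider shrinking lambda0/g_sd/u_sd"
        )
    m = cfg.gamma * lam + rng_truth.normal(0.0, cfg.sigma_m, (P, R))
    a_by_room = (
        cfg.alpha
        + cfg.beta_direct * lam
        + cfg.beta_mediated * m
        + rng_truth.normal(0.0, cfg.sigma_a, (P, R))
    )
    a_by_object = np.empty((P, R))
    for s, pairing in enumerate(pairings):
        a_by_object[s, pairing.room_to_object] = a_by_room[s]

    # Group and participant patterns on signal vertices only.
    rng_pat = np.random.default_rng(s_patterns)
    tau = cfg.tau_idiosyncrasy
    G_room = rng_pat.standard_normal((R, n_sig_v))
    G_obj = rng_pat.standard_normal((R, n_sig_v))

    runs: dict = {}
    truth_paths: dict = {}
    participant_seeds = s_runs.spawn(P)
    for s, pairing in enumerate(pairings):
        pid = pairing.participant_id
        rng = np.random.default_rng(participant_seeds[s])
        eta_room = rng.standard_normal((R, n_sig_v))
        eta_obj = rng.standard_normal((R, n_sig_v))
        P_room = math.sqrt(1 - tau) * G_room + math.sqrt(tau) * eta_room
        P_obj = math.sqrt(1 - tau) * G_obj + math.sqrt(tau) * eta_obj
        sq_lam = np.sqrt(lam[s])[:, None]
        run_room_patterns = [
            sq_lam * P_room + np.sqrt(1 - lam[s])[:, None] * rng.standard_normal(
                (R, n_sig_v)
            )
            for _ in range(2)
        ]

        ones = np.ones(R)
        p_runs: dict = {}

        def make_run(name, task, segments, room_amp, object_amp,
                     room_patterns, extra_room=False):
            last = max(seg.offset for seg in segments)
            n_tr = int(math.ceil((last + cfg.pad_seconds) / cfg.tr_seconds))
            A_room, A_obj = _amplitude_matrix(
                segments,
                n_tr,
                cfg,
                room_amp,
                object_amp,
                extra_room_for_object=pairing.object_to_room if extra_room else None,
                extra_room_amp=m[s] if extra_room else None,
            )
            y = np.zeros((n_tr, V))
            y[:, signal_mask] = A_room @ room_patterns + A_obj @ P_obj
            y += cfg.noise_sd * rng.standard_normal((n_tr, V))
            return RunData(
                name=name,
                task=task,
                timeseries=_zscore_runs(y),
                segments=segments,
                tr_seconds=cfg.tr_seconds,
            )

        # Pre-learning room videos: presented room, amplitude 1, run-specific
        # mixed pattern (this is what makes empirical reliability track lambda).
        for k in range(2):
            order = rng.permutation(R)
            segs = ev.video_segments(order, cfg.video_seconds, cfg.isi_seconds,
                                     kind=ev.KIND_ROOM)
            p_runs[f"room_video_{k + 1}"] = make_run(
                f"room_video_{k + 1}", "room_video", segs,
                room_amp=ones, object_amp=np.zeros(R),
                room_patterns=run_room_patterns[k],
            )

        # Post-learning object videos (object-video room recall): presented
        # object at amplitude 1 plus the paired room reinstated at m_{s,r}.
        for k in range(2):
            order = rng.permutation(R)
            segs = ev.video_segments(order, cfg.video_seconds, cfg.isi_seconds,
                                     kind=ev.KIND_OBJECT)
            p_runs[f"object_video_{k + 1}"] = make_run(
                f"object_video_{k + 1}", "object_video", segs,
                room_amp=np.zeros(R), object_amp=ones,
                room_patterns=P_room, extra_room=True,
            )

        # Room-video object recall: cued room at m_{s,r}, recalled object at
        # a_{s,o}, simultaneously during the room video.
        for k in range(2):
            order = rng.permutation(R)
            room_segs = ev.video_segments(order, cfg.video_seconds,
                                          cfg.isi_seconds, kind=ev.KIND_ROOM)
            obj_segs = [
                ev.TranscriptSegment(
                    int(pairing.room_to_object[seg.label]), ev.KIND_OBJECT,
                    seg.onset, seg.offset,
                )
                for seg in room_segs
            ]
            last = max(seg.offset for seg in room_segs)
            n_tr = int(math.ceil((last + cfg.pad_seconds) / cfg.tr_seconds))
            A_room, _ = _amplitude_matrix(room_segs, n_tr, cfg, m[s], np.zeros(R))
            _, A_obj = _amplitude_matrix(
                obj_segs, n_tr, cfg, np.zeros(R), a_by_object[s]
            )
            y = np.zeros((n_tr, V))
            y[:, signal_mask] = A_room @ P_room + A_obj @ P_obj
            y += cfg.noise_sd * rng.standard_normal((n_tr, V))
            p_runs[f"room_recall_{k + 1}"] = RunData(
                name=f"room_recall_{k + 1}", task="room_recall",
                timeseries=_zscore_runs(y), segments=room_segs,
                tr_seconds=cfg.tr_seconds,
            )

        # Guided recalls: 5-room cued paths; free recall: all rooms.
        paths = []
        for g in range(cfg.n_guided_runs):
            path = _self_avoiding_walk(graph, cfg.guided_path_len, rng)
            paths.append(path)
            segs = _recall_transcript(path, pairing, rng)
            p_runs[f"guided_{g + 1:02d}"] = make_run(
                f"guided_{g + 1:02d}", "guided", segs,
                room_amp=m[s], object_amp=a_by_object[s], room_patterns=P_room,
            )
        free_order = rng.permutation(R)
        segs = _recall_transcript(free_order, pairing, rng)
        p_runs["free"] = make_run(
            "free", "free", segs,
            room_amp=m[s], object_amp=a_by_object[s], room_patterns=P_room,
        )

        runs[pid] = p_runs
        truth_paths[pid] = paths

    truth = {
        "lambdas": lam,
        "m": m,
        "a_by_object": a_by_object,
        "a_by_room": a_by_room,
        "group_effect": g_r,
        "signal_searchlights": signal_searchlights,
        "cued_paths": truth_paths,
    }
    return SyntheticDataset(
        config=cfg,
        graph=graph,
        pairings=pairings,
        features=features,
        runs=runs,
        truth=truth,
    )
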