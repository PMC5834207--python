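"""Network-level simulation: state, spatial index, stepping, trajectories.

The engine advances all microtubules through discrete time steps.  Within a
step the order is fixed: nucleation, minus-end updates in creation order,
plus-end updates in creation order (newly appended segments are immediately
visible to later filaments in the same step), removal of empty filaments.
Neighbour queries run against a persistent spatial hash of 50 nm buckets
(twice the 25 nm interaction radius, so scanning the buckets overlapped by
the query ball suffices).  All randomness is drawn from a single stream
seeded once per run, making trajectories bit-reproducible for identical
(seed, parameters, mesh).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _kernels as K
from .geometry import CellSurface
from .mt_model import CueField, GrowthParams


class EngineError(RuntimeError):
    pass


_SNAPSHOT_COLUMNS = ["step", "mt_id", "seg_index", "x_um", "y_um", "z_um",
                     "dx", "dy", "dz"]


@dataclass
class Snapshot:
    """Immutable per-segment record set at one time step.

    Positions are segment endpoints (μm); directions are unit vectors.
    """

    step: int
    mt_id: np.ndarray
    seg_index: np.ndarray
    positions: np.ndarray
    directions: np.ndarray
    seed: int | None = None
    params_hash: str | None = None

    @property
    def n_segments(self) -> int:
        return len(self.mt_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": np.full(self.n_segments, self.step, dtype=np.int64),
            "mt_id": self.mt_id,
            "seg_index": self.seg_index,
            "x_um": self.positions[:, 0],
            "y_um": self.positions[:, 1],
            "z_um": self.positions[:, 2],
            "dx": self.directions[:, 0],
            "dy": self.directions[:, 1],
            "dz": self.directions[:, 2],
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.9g")

    @classmethod
    def from_tsv(cls, path) -> "Snapshot":
        df = pd.read_csv(path, sep="\t")
        missing = set(_SNAPSHOT_COLUMNS) - set(df.columns)
        if missing:
            raise EngineError(f"snapshot file misses columns {sorted(missing)}")
        step = int(df["step"].iloc[0]) if len(df) else 0
        return cls(step=step,
                   mt_id=df["mt_id"].to_numpy(np.int64),
                   seg_index=df["seg_index"].to_numpy(np.int64),
                   positions=df[["x_um", "y_um", "z_um"]].to_numpy(float),
                   directions=df[["dx", "dy", "dz"]].to_numpy(float))


def _git_hash() -> str | None:
    import subprocess
    try:
        out = subprocess.run(["git", "rev-parse", "HEAD"],
                             capture_output=True, text=True, timeout=5,
                             cwd=__file__.rsplit("/", 1)[0])
        return out.stdout.strip() or None
    except Exception:
        return None


def params_hash(params: GrowthParams, extra: dict | None = None) -> str:
    payload = {**asdict(params), **(extra or {})}
    return hashlib.sha1(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


class SpatialHashIndex:
    """Open-addressed spatial hash over segment endpoints.

    The same compiled insert/remove/query routines back the stepping kernel;
    this class exposes them for direct use and testing.  ``query`` returns a
    superset of the segments within ``radius`` (bucket granularity); pass
    ``exact=True`` to filter by true distance.  ``radius`` must not exceed
    the bucket size.
    """

    def __init__(self, bucket: float = 0.05, capacity: int = 1024,
                 table_bits: int = 16):
        self.bucket = float(bucket)
        self._mask = (1 << table_bits) - 1
        self._tab_key = np.full(self._mask + 1, -1, dtype=np.int64)
        self._tab_head = np.full(self._mask + 1, -1, dtype=np.int32)
        self._cellnext = np.full(capacity, -1, dtype=np.int32)
        self._alive = np.zeros(capacity, dtype=np.uint8)
        self._pos = np.zeros((capacity, 3), dtype=np.float64)
        self._ctr = np.zeros(K.N_COUNTERS, dtype=np.int64)
        self._n = 0

    def build(self, points: np.ndarray) -> None:
        points = np.asarray(points, dtype=np.float64)
        n = len(points)
        if n > len(self._alive):
            self._cellnext = np.full(n, -1, dtype=np.int32)
            self._alive = np.zeros(n, dtype=np.uint8)
            self._pos = np.zeros((n, 3), dtype=np.float64)
        need = 2 * n + 16
        if need > self._mask + 1:
            bits = int(need - 1).bit_length() + 1
            self._mask = (1 << bits) - 1
            self._tab_key = np.full(self._mask + 1, -1, dtype=np.int64)
            self._tab_head = np.full(self._mask + 1, -1, dtype=np.int32)
        self._pos[:n] = points
        self._alive[:n] = 1
        self._alive[n:] = 0
        self._n = n
        K.hash_rebuild(self._tab_key, self._tab_head, self._mask,
                       self._alive, self._pos, self._cellnext,
                       1.0 / self.bucket, n, self._ctr)

    def query(self, point, radius: float, exact: bool = False) -> np.ndarray:
        if radius > self.bucket + 1e-12:
            raise EngineError("query radius exceeds the bucket size")
        out = np.empty(max(self._n, 1), dtype=np.int32)
        p = np.asarray(point, dtype=float)
        n = K.hash_query(p[0], p[1], p[2], radius, self.bucket,
                         self._tab_key, self._tab_head, self._mask,
                         self._cellnext, self._alive, out)
        idx = np.sort(out[:n])
        if exact:
            d = np.linalg.norm(self._pos[idx] - p, axis=1)
            idx = idx[d <= radius]
        return idx


@dataclass
class Trajectory:
    snapshots: list
    config: dict
    seed: int
    wall_seconds: float = 0.0
    events: dict = field(default_factory=dict)

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]

    @property
    def real_time_minutes(self) -> float:
        return (self.config.get("n_steps", 0)
                * self.config.get("step_seconds", 0.0) / 60.0)

    def save(self, out_dir) -> None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        for snap in self.snapshots:
            snap.to_tsv(os.path.join(out_dir, f"snapshot_{snap.step:07d}.tsv"))
        manifest = {"config": self.config, "seed": self.seed,
                    "wall_seconds": self.wall_seconds, "events": self.events,
                    "snapshots": [s.step for s in self.snapshots],
                    "git_hash": _git_hash()}
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)


class Simulation:
    """Mutable network state bound to a surface, parameters and a seed."""

    def __init__(self, surface: CellSurface, params: GrowthParams,
                 cue: CueField | None = None, seed: int = 0,
                 seg_capacity: int = 1 << 18, mt_capacity: int = 1 << 14,
                 hash_bits: int = 20):
        self.surface = surface
        self.params = params
        self.cue = cue or CueField()
        self.seed = int(seed)
        self._alloc(seg_capacity, mt_capacity, hash_bits)
        self._P = np.zeros(K.N_PARAMS)
        self._P[K.P_ELL] = params.ell
        self._P[K.P_RD] = params.r_d
        self._P[K.P_BD] = params.b_d
        self._P[K.P_NS] = params.n_s
        self._P[K.P_NP] = params.n_p
        self._P[K.P_COSA] = np.cos(params.alpha_rad)
        self._P[K.P_SINA] = np.sin(params.alpha_rad)
        self._P[K.P_BUCKET] = 0.05
        self._P[K.P_RINT] = params.interaction_radius
        self._P[K.P_DMEM] = params.membrane_distance
        if params.interaction_radius > self._P[K.P_BUCKET]:
            raise EngineError("interaction radius must not exceed the "
                              "50 nm hash bucket")
        self._IP = np.zeros(K.N_IPARAMS, dtype=np.int64)
        self._IP[K.I_NTRIALS] = max(1, round(surface.area / params.ell ** 2))
        self._IP[K.I_ANCHOR] = 1 if params.anchoring == "strong" else 0
        self._IP[K.I_CUE] = 1 if self.cue.kind == "circumferential" else 0
        self._IP[K.I_NUCMODE] = (1 if params.nucleation_direction
                                 == "tangential" else 0)
        self._cue_axis = np.asarray(self.cue.axis, dtype=float)
        self._cue_center = np.asarray(self.cue.center, dtype=float)
        K.seed_rng(self.seed)

    def _alloc(self, seg_cap, mt_cap, hash_bits):
        self._seg_cap = seg_cap
        self.S_pos = np.zeros((seg_cap, 3))
        self.S_dir = np.zeros((seg_cap, 3))
        self.S_mt = np.full(seg_cap, -1, dtype=np.int32)
        self.S_next = np.full(seg_cap, -1, dtype=np.int32)
        self.S_prev = np.full(seg_cap, -1, dtype=np.int32)
        self.S_cellnext = np.full(seg_cap, -1, dtype=np.int32)
        self.S_alive = np.zeros(seg_cap, dtype=np.uint8)
        self.free_idx = np.arange(seg_cap - 1, -1, -1, dtype=np.int32)
        self._mt_cap = mt_cap
        self.M_head = np.full(mt_cap, -1, dtype=np.int32)
        self.M_tail = np.full(mt_cap, -1, dtype=np.int32)
        self.M_nseg = np.zeros(mt_cap, dtype=np.int32)
        self.M_minus = np.zeros(mt_cap, dtype=np.uint8)
        self.M_cat = np.zeros(mt_cap, dtype=np.uint8)
        self.M_alive = np.zeros(mt_cap, dtype=np.uint8)
        self.M_birth = np.full(mt_cap, -1, dtype=np.int32)
        self.M_nextchk = np.zeros(mt_cap, dtype=np.int64)
        self._hash_mask = (1 << hash_bits) - 1
        self.tab_key = np.full(self._hash_mask + 1, -1, dtype=np.int64)
        self.tab_head = np.full(self._hash_mask + 1, -1, dtype=np.int32)
        self.ctr = np.zeros(K.N_COUNTERS, dtype=np.int64)
        self.ctr[K.C_FREETOP] = seg_cap

    # -- growth of storage -------------------------------------------------

    def _grow_segments(self):
        old = self._seg_cap
        new = old * 2
        for name in ("S_pos", "S_dir"):
            arr = np.zeros((new, 3))
            arr[:old] = getattr(self, name)
            setattr(self, name, arr)
        for name, fill in (("S_mt", -1), ("S_next", -1), ("S_prev", -1),
                           ("S_cellnext", -1)):
            arr = np.full(new, fill, dtype=np.int32)
            arr[:old] = getattr(self, name)
            setattr(self, name, arr)
        alive = np.zeros(new, dtype=np.uint8)
        alive[:old] = self.S_alive
        self.S_alive = alive
        free = np.empty(new, dtype=np.int32)
        top = int(self.ctr[K.C_FREETOP])
        free[:top] = self.free_idx[:top]
        free[top:top + (new - old)] = np.arange(new - 1, old - 1, -1,
                                                dtype=np.int32)
        self.free_idx = free
        self.ctr[K.C_FREETOP] = top + (new - old)
        self._seg_cap = new

    def _grow_mts(self):
        old = self._mt_cap
        new = old * 2
        for name, fill, dt in (("M_head", -1, np.int32),
                               ("M_tail", -1, np.int32),
                               ("M_nseg", 0, np.int32),
                               ("M_minus", 0, np.uint8),
                               ("M_cat", 0, np.uint8),
                               ("M_alive", 0, np.uint8),
                               ("M_birth", -1, np.int32),
                               ("M_nextchk", 0, np.int64)):
            arr = np.full(new, fill, dtype=dt)
            arr[:old] = getattr(self, name)
            setattr(self, name, arr)
        self._mt_cap = new

    def _grow_hash(self):
        self._hash_mask = (self._hash_mask << 1) | 1
        self.tab_key = np.full(self._hash_mask + 1, -1, dtype=np.int64)
        self.tab_head = np.full(self._hash_mask + 1, -1, dtype=np.int32)
        K.hash_rebuild(self.tab_key, self.tab_head, self._hash_mask,
                       self.S_alive, self.S_pos, self.S_cellnext,
                       1.0 / self._P[K.P_BUCKET], self._seg_cap, self.ctr)

    # -- stepping ----------------------------------------------------------

    @property
    def step_count(self) -> int:
        return int(self.ctr[K.C_STEP])

    @property
    def n_segments(self) -> int:
        return int(self.ctr[K.C_NSEG])

    @property
    def n_microtubules(self) -> int:
        return int(self.ctr[K.C_NMT_LIVE])

    def step(self, n: int = 1) -> None:
        done = np.zeros(1, dtype=np.int64)
        while done[0] < n:
            status = K.step_kernel(
                n, done,
                self.S_pos, self.S_dir, self.S_mt, self.S_next, self.S_prev,
                self.S_cellnext, self.S_alive, self.free_idx,
                self.M_head, self.M_tail, self.M_nseg, self.M_minus,
                self.M_cat, self.M_alive, self.M_birth, self.M_nextchk,
                self.tab_key, self.tab_head, self._hash_mask,
                *self.surface.kernel_args,
                self._P, self._IP, self._cue_axis, self._cue_center, self.ctr)
            if status == K.STATUS_GROW_SEGS:
                self._grow_segments()
            elif status == K.STATUS_GROW_MTS:
                self._grow_mts()
            elif status == K.STATUS_GROW_HASH:
                self._grow_hash()
            elif status != K.STATUS_OK:  # pragma: no cover
                raise EngineError(f"kernel returned status {status}")

    def snapshot(self) -> Snapshot:
        n = self.n_segments
        mt = np.empty(n, dtype=np.int64)
        si = np.empty(n, dtype=np.int64)
        pos = np.empty((n, 3))
        dirs = np.empty((n, 3))
        k = K.extract_snapshot(int(self.ctr[K.C_NMT]), self.M_alive,
                               self.M_head, self.S_next, self.S_pos,
                               self.S_dir, mt, si, pos, dirs)
        if k != n:  # pragma: no cover - bookkeeping invariant
            raise EngineError("segment bookkeeping inconsistent")
        return Snapshot(step=self.step_count, mt_id=mt, seg_index=si,
                        positions=pos, directions=dirs, seed=self.seed,
                        params_hash=params_hash(self.params))

    def event_counts(self) -> dict:
        return {
            "segments_added": int(self.ctr[K.C_ADDED]),
            "segments_removed": int(self.ctr[K.C_REMOVED]),
            "nucleations": int(self.ctr[K.C_NUC]),
            "weak_anchoring_fallbacks": int(self.ctr[K.C_FALLBACK]),
            "zippers": int(self.ctr[K.C_ZIP]),
            "catastrophes_filament": int(self.ctr[K.C_CAT_MT]),
            "catastrophes_membrane": int(self.ctr[K.C_CAT_MEM]),
        }


def run(surface: CellSurface, params: GrowthParams, n_steps: int,
        snapshot_interval: int | None = None, seed: int = 0,
        cue: CueField | None = None) -> Trajectory:
    """Run a fresh simulation, emitting snapshots every ``snapshot_interval``
    steps (plus step 0 and the final step)."""
    if snapshot_interval is None:
        snapshot_interval = n_steps
    sim = Simulation(surface, params, cue=cue, seed=seed)
    t0 = time.perf_counter()
    snaps = [sim.snapshot()]
    remaining = n_steps
    while remaining > 0:
        chunk = min(snapshot_interval, remaining)
        sim.step(chunk)
        remaining -= chunk
        snaps.append(sim.snapshot())
    wall = time.perf_counter() - t0
    cfg = {"n_steps": n_steps, "snapshot_interval": snapshot_interval,
           "step_seconds": params.step_seconds, "params": asdict(params),
           "cue": asdict(cue) if cue else None}
    return Trajectory(snapshots=snaps, config=cfg, seed=seed,
                      wall_seconds=wall, events=sim.event_counts())
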