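"""Frame-to-frame trajectory linking and hop-chain reconstruction.

Linking follows the nearest-neighbour rule with a hard displacement
threshold ``d = 0.45 µm``: a spot is connected to the nearest spot in the
next frame if their distance is smaller than ``d``; otherwise the
trajectory ends (the spot "vanished") and unmatched next-frame spots start
new trajectories.  There is no gap closing — a missed frame always means a
vanishing.

Hop chains stitch a vanishing to a subsequent emergence within a larger
radius (2.0 µm) and a short frame gap, reconstructing the path of a
molecule that repeatedly dissociates and rebinds ("hops"); the chain's
time span is the hopping lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import CellGeometry, Spot, TrackSet, Trajectory

__all__ = ["LinkConfig", "HopChain", "link_spots", "reconstruct_hop_chains"]


@dataclass(frozen=True)
class LinkConfig:
    """Linking and chaining parameters.

    d : link threshold in µm (displacements >= d split trajectories).
    chain_r : hop-chain search radius in µm.
    chain_gap : maximum frame gap (emergence frame - vanishing frame)
        allowed inside a chain; gap 0 means same-frame co-occurrence.
    """

    d: float = 0.45
    chain_r: float = 2.0
    chain_gap: int = 1

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("link threshold d must be > 0")
        if self.d >= self.chain_r:
            raise ValueError("link threshold d must be < chain radius")
        if self.chain_gap < 0:
            raise ValueError("chain_gap must be >= 0")


@dataclass
class HopChain:
    """An ordered succession of trajectories attributed to one molecule."""

    trajectory_ids: list[int]
    hop_displacements: np.ndarray
    lifetime: float  # seconds, first emergence to last vanishing


def _greedy_match(
    prev_xy: np.ndarray, next_xy: np.ndarray, d: float,
    geometry: CellGeometry | None = None,
) -> list[tuple[int, int]]:
    """Greedy nearest-first matching of two point sets within distance < d.

    Candidate pairs are sorted by (distance, prev index, next index) so the
    outcome is deterministic; each point is used at most once.
    """
    if len(prev_xy) == 0 or len(next_xy) == 0:
        return []
    if geometry is not None and geometry.periodic:
        dx, dy = geometry.separation(
            prev_xy[:, None, 0], prev_xy[:, None, 1],
            next_xy[None, :, 0], next_xy[None, :, 1],
        )
        dist = np.hypot(dx, dy)
        cand = np.argwhere(dist < d)
        pairs = [(dist[i, j], i, j) for i, j in cand]
    else:
        tree = cKDTree(next_xy)
        pairs = []
        for i, p in enumerate(prev_xy):
            for j in tree.query_ball_point(p, d):
                dij = float(np.hypot(*(next_xy[j] - p)))
                if dij < d:
                    pairs.append((dij, i, j))
    pairs.sort()
    used_prev: set[int] = set()
    used_next: set[int] = set()
    matches = []
    for _, i, j in pairs:
        if i in used_prev or j in used_next:
            continue
        used_prev.add(i)
        used_next.add(j)
        matches.append((int(i), int(j)))
    return matches


def link_spots(
    spots_by_frame: dict[int, list[Spot]] | list[list[Spot]],
    config: LinkConfig = LinkConfig(),
    frame_interval: float = 0.033,
    pixel_size: float = 0.1,
    n_frames: int | None = None,
    geometry: CellGeometry | None = None,
) -> TrackSet:
    """Connect per-frame spots into trajectories.

    If there are multiple spots in the connection region the nearest one is
    selected (greedy, nearest pair first).  A spot with no partner within
    ``config.d`` in the next frame ends its trajectory.
    """
    if isinstance(spots_by_frame, dict):
        frames_present = sorted(spots_by_frame)
        frame_spots = {f: list(spots_by_frame[f]) for f in frames_present}
    else:
        frame_spots = {f: list(s) for f, s in enumerate(spots_by_frame)}
        frames_present = sorted(frame_spots)

    open_tracks: dict[int, list[Spot]] = {}  # spot-index-in-frame -> spots
    finished: list[list[Spot]] = []
    prev_spots: list[Spot] = []
    prev_track_of: list[list[Spot]] = []
    prev_frame = None

    for f in frames_present:
        cur = frame_spots[f]
        cur_track_of: list[list[Spot] | None] = [None] * len(cur)
        if prev_frame is not None and f == prev_frame + 1 and prev_spots:
            prev_xy = np.array([[s.x, s.y] for s in prev_spots])
            cur_xy = np.array([[s.x, s.y] for s in cur]) if cur else np.empty((0, 2))
            for i, j in _greedy_match(prev_xy, cur_xy, config.d, geometry):
                track = prev_track_of[i]
                track.append(cur[j])
                cur_track_of[j] = track
                prev_track_of[i] = None
        # unmatched previous tracks vanish
        for track in prev_track_of:
            if track is not None:
                finished.append(track)
        # unmatched current spots emerge
        for j, s in enumerate(cur):
            if cur_track_of[j] is None:
                cur_track_of[j] = [s]
        prev_spots = cur
        prev_track_of = list(cur_track_of)
        prev_frame = f

    finished.extend(t for t in prev_track_of if t is not None)
    finished.sort(key=lambda spots: (spots[0].frame, spots[0].x, spots[0].y))
    trajectories = [Trajectory.from_spots(i, s) for i, s in enumerate(finished)]
    return TrackSet(
        trajectories=trajectories,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
        n_frames=n_frames,
        geometry=geometry,
    )


def reconstruct_hop_chains(
    trackset: TrackSet, config: LinkConfig = LinkConfig()
) -> tuple[list[HopChain], np.ndarray]:
    """Stitch vanishings to nearby subsequent emergences into hop chains.

    A vanishing at frame ``f`` may claim an unclaimed emergence at frame
    ``f + g`` with ``0 <= g <= chain_gap`` whose distance is within
    ``chain_r``; ambiguities are resolved nearest-first.  An emergence is
    claimed by at most one vanishing (chains cannot branch).  Returns the
    chains with at least one hop, plus the array of all chain lifetimes in
    seconds (single-segment "chains" are not reported).
    """
    trajs = trackset.trajectories
    dt = trackset.frame_interval
    geom = trackset.geometry

    # candidate (distance, vanish idx, emerge idx) pairs
    pairs: list[tuple[float, int, int, int]] = []
    by_birth: dict[int, list[int]] = {}
    for idx, t in enumerate(trajs):
        by_birth.setdefault(t.birth_frame, []).append(idx)
    for i, t in enumerate(trajs):
        for g in range(config.chain_gap + 1):
            for j in by_birth.get(t.death_frame + g, ()):
                if j == i:
                    continue
                if g == 0 and trajs[j].birth_frame <= t.birth_frame:
                    continue  # same-frame: only later-emerging spots
                dx, dy = (
                    (trajs[j].x[0] - t.x[-1], trajs[j].y[0] - t.y[-1])
                    if geom is None
                    else geom.separation(t.x[-1], t.y[-1], trajs[j].x[0], trajs[j].y[0])
                )
                dist = float(np.hypot(dx, dy))
                if dist <= config.chain_r:
                    pairs.append((dist, i, j, g))

    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    succ: dict[int, int] = {}
    claimed: set[int] = set()
    has_pred: set[int] = set()
    for dist, i, j, _ in pairs:
        if i in succ or j in claimed:
            continue
        succ[i] = j
        claimed.add(j)
        has_pred.add(j)

    chains: list[HopChain] = []
    for i in range(len(trajs)):
        if i in has_pred or i not in succ:
            continue
        members = [i]
        while members[-1] in succ:
            members.append(succ[members[-1]])
        hops = []
        for a, b in zip(members[:-1], members[1:]):
            dx, dy = (
                (trajs[b].x[0] - trajs[a].x[-1], trajs[b].y[0] - trajs[a].y[-1])
                if geom is None
                else geom.separation(
                    trajs[a].x[-1], trajs[a].y[-1], trajs[b].x[0], trajs[b].y[0]
                )
            )
            hops.append(float(np.hypot(dx, dy)))
        lifetime = (trajs[members[-1]].death_frame - trajs[members[0]].birth_frame) * dt
        chains.append(
            HopChain(
                trajectory_ids=[trajs[m].id for m in members],
                hop_displacements=np.array(hops),
                lifetime=lifetime,
            )
        )
    lifetimes = np.array([c.lifetime for c in chains])
    return chains, lifetimes
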