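"""Stochastic simulator of membrane-binding molecules that hop.

The model: molecules associate with a W x H membrane as a spatio-temporal
Poisson process, diffuse laterally while bound (per-axis Gaussian steps of
standard deviation sqrt(2*D_mem*dt)), dissociate at rate k_off and, upon
dissociation, rebind nearby with probability p_reb after a cytosolic
excursion of duration t_return (displacement per axis
sqrt(2*D_cyto*t_return)).  Fluorophores photobleach at rate k_bleach
irrespective of molecular state — including while still in the cytosolic
pool, which is what makes the observed spot-emergence rate decay as
rho0*exp(-k_bleach*T) over the movie.

The domain is periodic (a torus): there is no boundary depletion, so the
spatial-homogeneity assumption behind the recruitment correction holds
exactly.  Observable track sets are produced by rendering the per-frame
positions through the same nearest-neighbour linker used for real movies,
so any single-step displacement >= d (0.45 µm), including hop returns,
splits the record into separate trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CellGeometry, Spot, TrackSet
from .link import LinkConfig, link_spots

__all__ = ["SimConfig", "Visit", "GroundTruth", "simulate", "render_movie"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (defaults are the reference condition).

    association_rate : molecules/µm²/s arriving from the cytosol.
    D_mem : lateral diffusion coefficient while bound, µm²/s.
    k_off : membrane dissociation rate, 1/s.
    p_reb : probability that a dissociating molecule hops back.
    D_cyto : diffusion coefficient during the excursion, µm²/s.
    t_return : excursion duration, s (must be a multiple of dt).
    k_bleach : photobleaching rate, 1/s.
    width, height : membrane domain, µm.
    dt : frame interval, s.
    n_steps : number of movie frames.
    n_trials : replicate simulations for aggregate statistics.
    """

    association_rate: float = 1.0
    D_mem: float = 0.01
    k_off: float = 1.0
    p_reb: float = 0.03
    D_cyto: float = 1.0
    t_return: float = 0.066
    k_bleach: float = 0.03
    width: float = 10.0
    height: float = 10.0
    dt: float = 0.033
    n_steps: int = 3000
    n_trials: int = 12
    link: LinkConfig = field(default_factory=LinkConfig)

    def __post_init__(self) -> None:
        for name in ("association_rate", "D_mem", "k_off", "D_cyto", "k_bleach"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.p_reb <= 1:
            raise ValueError("p_reb must be in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("domain dimensions must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        ratio = self.t_return / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("t_return must be a positive multiple of dt")

    @property
    def return_frames(self) -> int:
        return int(round(self.t_return / self.dt))

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def total_time(self) -> float:
        return self.n_steps * self.dt


@dataclass
class Visit:
    """One continuous membrane-bound interval of one molecule."""

    molecule_id: int
    first_frame: int
    x: np.ndarray  # positions at frames first_frame .. first_frame+n-1
    y: np.ndarray
    end_cause: str  # "dissociation" | "bleach" | "movie_end"
    rebinds: bool  # dissociation followed by a hop return

    @property
    def last_frame(self) -> int:
        return self.first_frame + len(self.x) - 1

    @property
    def n_frames(self) -> int:
        return len(self.x)


@dataclass
class GroundTruth:
    """Per-molecule truth from one simulation run."""

    config: SimConfig
    visits: list[Visit]
    n_molecules: int
    association_times: np.ndarray  # accepted (unbleached-pool) associations, s

    def residence_times(self) -> np.ndarray:
        """True membrane residence (s) of dissociation-ended visits.

        Visits censored by photobleaching or the movie end are excluded.
        A visit present in n frames survived n-1 frame transitions and
        dissociated on the n-th, so its residence time is n*dt.
        """
        return np.array(
            [v.n_frames * self.config.dt for v in self.visits
             if v.end_cause == "dissociation"]
        )

    def bound_step_displacements(self) -> tuple[np.ndarray, np.ndarray]:
        """All single-frame (dx, dy) of membrane-bound segments (µm)."""
        w, h = self.config.width, self.config.height
        dxs, dys = [], []
        for v in self.visits:
            if v.n_frames < 2:
                continue
            dx = np.diff(v.x)
            dy = np.diff(v.y)
            dx -= w * np.round(dx / w)
            dy -= h * np.round(dy / h)
            dxs.append(dx)
            dys.append(dy)
        if not dxs:
            return np.empty(0), np.empty(0)
        return np.concatenate(dxs), np.concatenate(dys)

    def emergence_times(self) -> np.ndarray:
        """Times (s) at which ground-truth visits start."""
        return np.array([v.first_frame * self.config.dt for v in self.visits])

    def n_hops(self) -> int:
        return sum(v.rebinds for v in self.visits)


def simulate(
    config: SimConfig = SimConfig(),
    seed: int | np.random.Generator | None = None,
) -> tuple[GroundTruth, TrackSet]:
    """Run one trial; return the ground truth and the observed track set.

    The observed track set is obtained by pooling the per-frame positions
    of all unbleached bound molecules and linking them with
    :func:`hoptrack.link.link_spots` under the configured threshold —
    exactly the observation rule applied to real movies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = config
    dt, w, h = cfg.dt, cfg.width, cfg.height
    T0 = cfg.total_time

    # Poisson association events, thinned by pool photobleaching
    n_raw = rng.poisson(cfg.association_rate * cfg.area * T0)
    t_raw = np.sort(rng.uniform(0.0, T0, n_raw))
    keep = rng.random(n_raw) < np.exp(-cfg.k_bleach * t_raw)
    t_assoc = t_raw[keep]
    first_frames = np.floor(t_assoc / dt).astype(int) + 1
    ok = first_frames < cfg.n_steps
    t_assoc = t_assoc[ok]
    first_frames = first_frames[ok]

    p_d = 1.0 - np.exp(-cfg.k_off * dt)
    p_b = 1.0 - np.exp(-cfg.k_bleach * dt)
    # per step: dissociation checked first, then bleaching
    p_end = p_d + (1.0 - p_d) * p_b
    p_dissoc_given_end = p_d / p_end if p_end > 0 else 0.0
    p_hop_survive = cfg.p_reb * np.exp(-cfg.k_bleach * cfg.t_return)
    step_sd = np.sqrt(2.0 * cfg.D_mem * dt)
    hop_sd = np.sqrt(2.0 * cfg.D_cyto * cfg.t_return)

    visits: list[Visit] = []
    for mol_id, f0 in enumerate(first_frames):
        x0 = rng.uniform(0.0, w)
        y0 = rng.uniform(0.0, h)
        frame = int(f0)
        while True:
            n_vis = rng.geometric(p_end) if p_end > 0 else cfg.n_steps
            cause = (
                "dissociation" if rng.random() < p_dissoc_given_end else "bleach"
            )
            if frame + n_vis > cfg.n_steps:
                n_vis = cfg.n_steps - frame
                cause = "movie_end"
            steps = rng.normal(0.0, step_sd, size=(n_vis - 1, 2))
            x = (x0 + np.concatenate(([0.0], np.cumsum(steps[:, 0])))) % w
            y = (y0 + np.concatenate(([0.0], np.cumsum(steps[:, 1])))) % h
            rebind = (
                cause == "dissociation"
                and rng.random() < p_hop_survive
                and frame + n_vis - 1 + cfg.return_frames < cfg.n_steps
            )
            visits.append(Visit(mol_id, frame, x, y, cause, rebind))
            if not rebind:
                break
            jump = rng.normal(0.0, hop_sd, size=2)
            x0 = (x[-1] + jump[0]) % w
            y0 = (y[-1] + jump[1]) % h
            frame = frame + n_vis - 1 + cfg.return_frames
        # molecule finished

    truth = GroundTruth(
        config=cfg,
        visits=visits,
        n_molecules=len(first_frames),
        association_times=t_assoc,
    )

    # observation: pool per-frame spots, then link
    spots_by_frame: dict[int, list[Spot]] = {}
    for v in visits:
        for k in range(v.n_frames):
            f = v.first_frame + k
            spots_by_frame.setdefault(f, []).append(
                Spot(frame=f, x=float(v.x[k]), y=float(v.y[k]))
            )
    geometry = CellGeometry.periodic_rectangle(w, h)
    trackset = link_spots(
        spots_by_frame,
        cfg.link,
        frame_interval=dt,
        pixel_size=0.1,
        n_frames=cfg.n_steps,
        geometry=geometry,
    )
    return truth, trackset


def render_movie(
    trackset: TrackSet,
    psf_sigma_px: float = 2.0,
    peak_intensity: float = 1000.0,
    background_level: float = 100.0,
    noise_sd: float = 10.0,
    pixel_size: float = 0.1,
    shape: tuple[int, int] | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render a track set as a 16-bit synthetic movie.

    Each visible molecule becomes a 2D Gaussian of width ``psf_sigma_px``
    on a constant background with additive Gaussian noise; values are
    clipped to the uint16 range.  Row index corresponds to y.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if shape is None:
        if trackset.geometry is not None and trackset.geometry.periodic:
            shape = (
                int(np.ceil(trackset.geometry.height / pixel_size)),
                int(np.ceil(trackset.geometry.width / pixel_size)),
            )
        else:
            xmax = max((t.x.max() for t in trackset), default=1.0)
            ymax = max((t.y.max() for t in trackset), default=1.0)
            shape = (
                int(np.ceil(ymax / pixel_size)) + 8,
                int(np.ceil(xmax / pixel_size)) + 8,
            )
    n_frames = trackset.n_frames or 1
    movie = np.full((n_frames, *shape), float(background_level))
    half = int(np.ceil(4 * psf_sigma_px))
    for traj in trackset:
        for f, x, y, inten in zip(traj.frames, traj.x, traj.y, traj.intensity):
            cx = x / pixel_size
            cy = y / pixel_size
            c0 = int(round(cx))
            r0 = int(round(cy))
            rows = np.arange(max(r0 - half, 0), min(r0 + half + 1, shape[0]))
            cols = np.arange(max(c0 - half, 0), min(c0 + half + 1, shape[1]))
            if len(rows) == 0 or len(cols) == 0:
                continue
            gy = np.exp(-((rows - cy) ** 2) / (2 * psf_sigma_px**2))
            gx = np.exp(-((cols - cx) ** 2) / (2 * psf_sigma_px**2))
            amp = peak_intensity * (inten if np.isfinite(inten) else 1.0)
            movie[f, rows[:, None], cols[None, :]] += amp * gy[:, None] * gx[None, :]
    if noise_sd > 0:
        movie += rng.normal(0.0, noise_sd, size=movie.shape)
    return np.clip(movie, 0, 65535).astype(np.uint16)
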