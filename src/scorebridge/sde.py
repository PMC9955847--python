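"""Time grids, trajectory ensembles and Euler--Maruyama simulation.

Internal time is always the normalised grid on ``[0, 1]``: a configuration
with ``n_steps = Nt`` and step ``dt`` has physical horizon ``Nt * dt``, but
drift networks only ever see the normalised forward-clock time.  Backward
integration proceeds over an ascending internal index while the physical
forward time runs ``1 -> 0``; the simulator performs that conversion before
calling the drift, so a single time convention suffices for both directions.

Time reversal here is *distributional*: reversing an ensemble re-indexes the
stored states, while a backward simulation always draws fresh noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SDEConfig", "TimeGrid", "TrajectoryEnsemble",
    "simulate_em", "reverse_ensemble", "slice_marginal",
    "SimulationDivergence",
]

_DIVERGENCE_BOUND = 1e6


class SimulationDivergence(RuntimeError):
    """A simulated state left the finite / bounded domain."""


@dataclass(frozen=True)
class SDEConfig:
    """Diffusion coefficient, step size, number of steps and dimension."""

    sigma: float
    dt: float
    n_steps: int
    dim: int

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1 or self.dim < 1:
            raise ValueError("n_steps and dim must be positive integers")

    @property
    def horizon(self):
        """Physical time span ``Nt * dt`` absorbed by normalisation."""
        return self.n_steps * self.dt

    def grid(self):
        return TimeGrid(np.linspace(0.0, 1.0, self.n_steps + 1))


@dataclass(frozen=True)
class TimeGrid:
    """Equally spaced normalised times ``0 = t_0 < ... < t_Nt = 1``."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("grid needs at least two points")
        if not (np.all(np.diff(pts) > 0) and abs(pts[0]) < 1e-12 and abs(pts[-1] - 1.0) < 1e-12):
            raise ValueError("grid must increase strictly from 0 to 1")
        object.__setattr__(self, "points", pts)

    def __len__(self):
        return self.points.size

    def reversed(self):
        return TimeGrid(np.sort(1.0 - self.points))


@dataclass
class TrajectoryEnsemble:
    """Batch of sample paths ``[Nx, Nt+1, D]`` on a shared grid.

    ``direction`` records which physical orientation the ascending internal
    index represents; ``forward_times`` gives the forward-clock time of each
    grid index regardless of direction.
    """

    states: np.ndarray
    grid: TimeGrid
    direction: str
    seed: int | None = None
    config: SDEConfig | None = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.float64)
        if self.states.ndim != 3:
            raise ValueError("states must be [Nx, Nt+1, D]")
        if self.states.shape[1] != len(self.grid):
            raise ValueError("states time axis does not match grid")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        if not np.all(np.isfinite(self.states)):
            raise SimulationDivergence("ensemble contains non-finite states")

    @property
    def n_paths(self):
        return self.states.shape[0]

    @property
    def dim(self):
        return self.states.shape[2]

    @property
    def forward_times(self):
        pts = self.grid.points
        return pts if self.direction == "forward" else 1.0 - pts

    def save(self, path):
        meta = dict(direction=self.direction, seed=self.seed,
                    config=None if self.config is None else vars(self.config).copy())
        np.savez(path, states=self.states, grid=self.grid.points, meta=json.dumps(meta))

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            cfg = meta["config"]
            return cls(states=f["states"], grid=TimeGrid(f["grid"]),
                       direction=meta["direction"], seed=meta["seed"],
                       config=None if cfg is None else SDEConfig(**cfg))


def simulate_em(drift, init_samples, config, direction="forward", rng_seed=0):
    """Euler--Maruyama integration of ``dX = mu dt + sigma dW``.

    Parameters
    ----------
    drift : callable
        ``drift(x, t) -> [Nx, D]`` with ``t`` the forward-clock normalised
        time; for ``direction='backward'`` the simulator feeds ``1 - tau``.
    init_samples : array [Nx, D]
        Draws from the initial marginal of the generating process (``pi_0``
        for forward runs, the end marginal for backward runs).
    config : SDEConfig
    direction : {"forward", "backward"}
    rng_seed : int
        Noise is drawn from a dedicated seeded generator; identical seeds
        give bit-identical ensembles.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    x0 = np.atleast_2d(np.asarray(init_samples, dtype=np.float64))
    if x0.shape[1] != config.dim:
        raise ValueError(f"init_samples dim {x0.shape[1]} != config.dim {config.dim}")
    if not np.all(np.isfinite(x0)):
        raise ValueError("init_samples must be finite")

    rng = np.random.default_rng(rng_seed)
    nx, d = x0.shape
    nt = config.n_steps
    grid = config.grid()
    sqdt = config.sigma * np.sqrt(config.dt)

    states = np.empty((nx, nt + 1, d))
    states[:, 0] = x0
    x = x0.copy()
    for k in range(nt):
        s = grid.points[k]
        t_fwd = s if direction == "forward" else 1.0 - s
        mu = np.asarray(drift(x, t_fwd), dtype=np.float64)
        x = x + mu * config.dt + sqdt * rng.standard_normal((nx, d))
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > _DIVERGENCE_BOUND:
            raise SimulationDivergence(f"simulation diverged at step {k + 1}")
        states[:, k + 1] = x

    return TrajectoryEnsemble(states=states, grid=grid, direction=direction,
                              seed=int(rng_seed), config=config)


def reverse_ensemble(traj):
    """Re-index an ensemble in the opposite time direction (involution)."""
    return TrajectoryEnsemble(
        states=traj.states[:, ::-1].copy(),
        grid=traj.grid.reversed(),
        direction="backward" if traj.direction == "forward" else "forward",
        seed=traj.seed,
        config=traj.config,
    )


def slice_marginal(traj, time_point):
    """State slice at the grid point nearest ``time_point``.

    Ties break toward the lower index (no interpolation between steps).
    Returns ``(samples [Nx, D], grid_time_used)``.
    """
    if traj.n_paths == 0:
        raise ValueError("empty ensemble")
    if not 0.0 <= time_point <= 1.0:
        raise ValueError("time_point must lie in [0, 1]")
    pts = traj.grid.points
    dist = np.abs(pts - time_point)
    k = int(np.argmin(dist + 1e-15 * np.arange(len(pts))))
    return traj.states[:, k].copy(), float(pts[k])
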