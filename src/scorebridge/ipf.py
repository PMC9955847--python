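"""Iterative proportional fitting: alternating half-bridge solves.

Each IPF iteration performs two half-bridge fits.  First the backward drift
is trained against trajectories simulated *forward* from ``pi_0`` under the
current forward drift (end marginal ``pi_1`` fixed); then the forward drift
is trained against trajectories simulated *backward* from ``pi_1`` under
the freshly trained backward drift.  Drifts warm-start across iterations —
exactly two networks exist for the whole run.

Each half-bridge owns its own replay buffer, cleared when its reference
drift changes and refilled during training in fixed-size batches of new
trajectories (oldest evicted beyond capacity), so the score-matching loss
only ever sees samples from the current reference process.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import wasserstein1
from .nets import DriftApproximator, ZeroDrift, build_drift
from .scorefit import HalfBridgeTrainConfig, TraceEstimatorSpec, train_half_bridge
from .sde import SDEConfig, simulate_em

__all__ = [
    "ReplayBuffer", "IPFConfig", "BridgeResult",
    "init_reference", "refresh_buffer", "run_ipf", "sigma_heuristic",
]


class ReplayBuffer:
    """Bounded FIFO pool of trajectories from one reference process."""

    def __init__(self, capacity=512):
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = int(capacity)
        self._entries = deque()
        self._grid = None
        self._direction = None
        self._cache = None

    def __len__(self):
        return len(self._entries)

    def push_ensemble(self, ens):
        """Append each trajectory of the ensemble, evicting oldest first."""
        if self._grid is not None:
            if ens.direction != self._direction or len(ens.grid) != len(self._grid):
                raise ValueError("buffer entries must share grid and direction")
        else:
            self._grid = ens.grid
            self._direction = ens.direction
        for i in range(ens.n_paths):
            self._entries.append(ens.states[i])
            if len(self._entries) > self.capacity:
                self._entries.popleft()
        self._cache = None

    def clear(self):
        self._entries.clear()
        self._grid = None
        self._direction = None
        self._cache = None

    def initial_states(self):
        """Start point of every stored trajectory (marginal anchoring)."""
        return np.array([s[0] for s in self._entries])

    def flat_points(self):
        """All (state, forward-time) pairs, flattened over the buffer."""
        if not self._entries:
            raise ValueError("replay buffer is empty")
        if self._cache is None:
            states = np.stack(list(self._entries))  # [n, Nt+1, D]
            pts = self._grid.points
            tf = pts if self._direction == "forward" else 1.0 - pts
            n, m, d = states.shape
            X = states.reshape(n * m, d)
            T = np.tile(tf, n)
            self._cache = (X, T)
        return self._cache


@dataclass
class IPFConfig:
    """Full configuration of an IPF run."""

    sde: SDEConfig
    n_ipf_iterations: int = 10
    n_new_trajectories: int = 128
    buffer_capacity: int = 512
    refresh_every: int = 250
    train: HalfBridgeTrainConfig = field(default_factory=HalfBridgeTrainConfig)
    trace: TraceEstimatorSpec = field(default_factory=TraceEstimatorSpec)
    init_mode: str = "untrained_net"
    n_eval: int = 512
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_new_trajectories > self.buffer_capacity:
            raise ValueError("n_new_trajectories must not exceed buffer capacity")
        if self.init_mode not in ("zero_drift", "untrained_net"):
            raise ValueError("init_mode must be 'zero_drift' or 'untrained_net'")


@dataclass
class BridgeResult:
    """Converged drifts plus per-iteration diagnostics."""

    forward_drift: DriftApproximator
    backward_drift: DriftApproximator
    diagnostics: list
    config: IPFConfig


def init_reference(dim, mode="untrained_net", rng_seed=0):
    """Reference drift for the first half-bridge.

    ``zero_drift`` gives the plain Wiener reference; ``untrained_net`` (the
    default) a freshly initialised network whose small final-layer weights
    make it a near-zero field, so the Wiener term still dominates while the
    parameters already serve as a warm start.
    """
    if mode == "zero_drift":
        return ZeroDrift(dim)
    if mode == "untrained_net":
        return build_drift(dim, rng_seed=rng_seed)
    raise ValueError(f"unknown init mode {mode!r}")


def _draw_starts(samples, n, rng):
    samples = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    replace_flag = n > samples.shape[0]
    idx = rng.choice(samples.shape[0], size=n, replace=replace_flag)
    return samples[idx]


def refresh_buffer(buffer, drift, marginal_samples, config, direction, rng=None):
    """Simulate a batch of new trajectories and append them to the buffer.

    Start points are drawn from the fixed-end marginal samples of the
    current half-bridge, so every stored trajectory is anchored exactly at
    the prescribed boundary.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    starts = _draw_starts(marginal_samples, config.n_new_trajectories, rng)
    seed = int(rng.integers(0, 2 ** 31 - 1))
    ens = simulate_em(drift, starts, config.sde, direction=direction, rng_seed=seed)
    buffer.push_ensemble(ens)
    return buffer


def sigma_heuristic(target_samples, horizon):
    """Diffusion scale making first-iteration paths cover the target.

    Chooses sigma so that the Brownian spread over the horizon,
    ``sigma * sqrt(Nt * dt)``, equals half the largest coordinate range of
    the target samples.
    """
    s = np.atleast_2d(np.asarray(target_samples, dtype=np.float64))
    span = float(np.max(s.max(axis=0) - s.min(axis=0)))
    if span <= 0:
        span = 1.0
    return 0.5 * span / np.sqrt(horizon)


def run_ipf(pi0_samples, pi1_samples, config):
    """Solve the bridge between two empirical marginals.

    Returns a :class:`BridgeResult` whose diagnostics record, per IPF
    iteration, the endpoint distances ``W1(p_fwd(1), pi_1)`` and
    ``W1(pi_0, p_bwd(0))`` together with the final half-bridge losses.
    """
    pi0 = np.atleast_2d(np.asarray(pi0_samples, dtype=np.float64))
    pi1 = np.atleast_2d(np.asarray(pi1_samples, dtype=np.float64))
    d = config.sde.dim
    if pi0.shape[1] != d or pi1.shape[1] != d:
        raise ValueError("marginal samples must share dimension config.sde.dim")

    ss = np.random.SeedSequence(config.rng_seed)
    seeds = ss.generate_state(6)
    rng_sim = np.random.default_rng(seeds[0])
    rng_eval = np.random.default_rng(seeds[1])

    fwd = build_drift(d, rng_seed=int(seeds[2]) % 2 ** 31)
    bwd = build_drift(d, rng_seed=int(seeds[3]) % 2 ** 31)
    # iteration-1 reference Q0*: the untrained forward net itself (default)
    # or the plain Wiener process (zero drift)
    fwd_ref = ZeroDrift(d) if config.init_mode == "zero_drift" else fwd

    diagnostics = []
    for it in range(config.n_ipf_iterations):
        losses = {}
        ref = fwd_ref if it == 0 else fwd
        # (i) backward half-bridge: reference = forward drift, paths from pi0
        buf = ReplayBuffer(config.buffer_capacity)
        refresh = lambda: refresh_buffer(buf, ref, pi0, config, "forward", rng_sim)
        tcfg = replace(config.train,
                       rng_seed=int(seeds[4]) % 2 ** 31 + 2 * it)
        _, log_b = train_half_bridge(bwd, ref, buf, config.sde.sigma,
                                     config.trace, tcfg,
                                     refresh_every=config.refresh_every,
                                     refresh_fn=refresh)
        losses["backward_final_loss"] = float(log_b[-1])

        # (ii) forward half-bridge: reference = backward drift, paths from pi1
        buf2 = ReplayBuffer(config.buffer_capacity)
        refresh2 = lambda: refresh_buffer(buf2, bwd, pi1, config, "backward", rng_sim)
        tcfg2 = replace(config.train,
                        rng_seed=int(seeds[4]) % 2 ** 31 + 2 * it + 1)
        _, log_f = train_half_bridge(fwd, bwd, buf2, config.sde.sigma,
                                     config.trace, tcfg2,
                                     refresh_every=config.refresh_every,
                                     refresh_fn=refresh2)
        losses["forward_final_loss"] = float(log_f[-1])

        # endpoint diagnostics
        n_ev = min(config.n_eval, pi0.shape[0], pi1.shape[0])
        s0 = _draw_starts(pi0, n_ev, rng_eval)
        ens_f = simulate_em(fwd, s0, config.sde, "forward",
                            rng_seed=int(rng_eval.integers(0, 2 ** 31 - 1)))
        s1 = _draw_starts(pi1, n_ev, rng_eval)
        ens_b = simulate_em(bwd, s1, config.sde, "backward",
                            rng_seed=int(rng_eval.integers(0, 2 ** 31 - 1)))
        ref1 = _draw_starts(pi1, n_ev, rng_eval)
        ref0 = _draw_starts(pi0, n_ev, rng_eval)
        w1_fwd = wasserstein1(ens_f.states[:, -1], ref1)
        w1_bwd = wasserstein1(ref0, ens_b.states[:, -1])
        diagnostics.append(dict(iteration=it + 1,
                                w1_forward_end=w1_fwd,
                                w1_backward_end=w1_bwd,
                                **losses))

    return BridgeResult(forward_drift=fwd, backward_drift=bwd,
                        diagnostics=diagnostics, config=config)
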