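"""Model / results interface for fitting Schrodinger bridges.

:class:`SchrodingerBridge` holds the two empirical boundary marginals and
the run configuration; :meth:`SchrodingerBridge.fit` runs iterative
proportional fitting and returns a :class:`SchrodingerBridgeResults`
carrying the trained forward and backward drift networks, per-iteration
diagnostics, a text ``summary()`` and simulation helpers.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .ipf import IPFConfig, run_ipf, sigma_heuristic
from .scorefit import HalfBridgeTrainConfig, TraceEstimatorSpec
from .sde import SDEConfig, simulate_em, slice_marginal

__all__ = ["SchrodingerBridge", "SchrodingerBridgeResults"]


class SchrodingerBridge:
    """Schrodinger bridge between two sample-based marginals.

    Parameters
    ----------
    pi0_samples, pi1_samples : arrays ``[N, D]``
        Draws from the initial and terminal distributions.
    sigma : float, optional
        Diffusion coefficient; by default set so the Brownian spread over
        the horizon covers half the widest coordinate range of ``pi_1``.
    n_steps, dt : int, float
        Euler--Maruyama grid (defaults 100 steps of 0.01).
    config : IPFConfig, optional
        Full configuration; overrides the convenience arguments.
    """

    def __init__(self, pi0_samples, pi1_samples, sigma=None,
                 n_steps=100, dt=0.01, config=None, **config_kwargs):
        self.pi0 = np.atleast_2d(np.asarray(pi0_samples, dtype=np.float64))
        self.pi1 = np.atleast_2d(np.asarray(pi1_samples, dtype=np.float64))
        if self.pi0.shape[1] != self.pi1.shape[1]:
            raise ValueError("marginals must share dimension")
        dim = self.pi0.shape[1]
        if config is None:
            if sigma is None:
                sigma = sigma_heuristic(self.pi1, n_steps * dt)
            sde = SDEConfig(sigma=float(sigma), dt=dt, n_steps=n_steps, dim=dim)
            config = IPFConfig(sde=sde, **config_kwargs)
        elif config.sde.dim != dim:
            raise ValueError("config.sde.dim does not match the samples")
        self.config = config

    @classmethod
    def from_dataframe(cls, df, group_col, value_cols, group0, group1, **kwargs):
        """Build from a long table: rows of ``group0`` are ``pi_0`` etc."""
        g0 = df.loc[df[group_col] == group0, value_cols].to_numpy(dtype=np.float64)
        g1 = df.loc[df[group_col] == group1, value_cols].to_numpy(dtype=np.float64)
        if g0.size == 0 or g1.size == 0:
            raise ValueError("one of the requested groups is empty")
        return cls(g0, g1, **kwargs)

    def fit(self):
        """Run IPF and return the fitted results object."""
        res = run_ipf(self.pi0, self.pi1, self.config)
        return SchrodingerBridgeResults(self, res)


class SchrodingerBridgeResults:
    """Fitted bridge: drift networks, diagnostics, simulation."""

    def __init__(self, model, bridge_result):
        self.model = model
        self._res = bridge_result
        self.forward_drift = bridge_result.forward_drift
        self.backward_drift = bridge_result.backward_drift

    @property
    def config(self):
        return self._res.config

    @property
    def diagnostics(self):
        """Per-iteration endpoint W1 values and final losses."""
        return pd.DataFrame(self._res.diagnostics)

    def simulate(self, direction="forward", n=512, rng_seed=0):
        """Simulate ``n`` bridge trajectories from the matching boundary."""
        rng = np.random.default_rng(rng_seed)
        src = self.model.pi0 if direction == "forward" else self.model.pi1
        idx = rng.choice(src.shape[0], size=n, replace=n > src.shape[0])
        drift = self.forward_drift if direction == "forward" else self.backward_drift
        return simulate_em(drift, src[idx], self.config.sde, direction,
                           rng_seed=int(rng.integers(0, 2 ** 31 - 1)))

    def sample(self, n=512, rng_seed=0, direction="forward"):
        """Endpoint samples generated by the fitted bridge."""
        return self.simulate(direction, n, rng_seed).states[:, -1]

    def marginal_at(self, time_point, n=512, rng_seed=0):
        """Generated marginal at a forward time in ``[0, 1]``."""
        ens = self.simulate("forward", n, rng_seed)
        samples, t_used = slice_marginal(ens, time_point)
        return samples, t_used

    def summary(self):
        """Human-readable fit report."""
        diag = self.diagnostics
        cfg = self.config
        buf = io.StringIO()
        buf.write("Schrodinger Bridge (score-based IPF)\n")
        buf.write("=" * 52 + "\n")
        buf.write(f"dim: {cfg.sde.dim}   sigma: {cfg.sde.sigma:.4g}   "
                  f"grid: {cfg.sde.n_steps} x {cfg.sde.dt:g}\n")
        buf.write(f"IPF iterations: {cfg.n_ipf_iterations}   "
                  f"trace estimator: {cfg.trace.kind}\n")
        buf.write(f"train steps/half-bridge: {cfg.train.n_train_steps}   "
                  f"lr: {cfg.train.lr_start:g} -> {cfg.train.lr_end:g}\n")
        buf.write("-" * 52 + "\n")
        buf.write(diag.to_string(index=False,
                                 float_format=lambda v: f"{v:10.4f}"))
        buf.write("\n" + "-" * 52 + "\n")
        last = diag.iloc[-1]
        buf.write(f"final W1(p_fwd(1), pi1) = {last.w1_forward_end:.4f}\n")
        buf.write(f"final W1(pi0, p_bwd(0)) = {last.w1_backward_end:.4f}\n")
        return buf.getvalue()

    def plot_marginals(self, ax=None, n=512, rng_seed=0):
        """Histogram/scatter of generated vs target end marginals."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        gen = self.sample(n=n, rng_seed=rng_seed)
        tgt = self.model.pi1
        if gen.shape[1] == 1:
            ax.hist(tgt[:, 0], bins=40, density=True, alpha=0.5, label="pi1")
            ax.hist(gen[:, 0], bins=40, density=True, alpha=0.5, label="generated")
        else:
            ax.scatter(tgt[:, 0], tgt[:, 1], s=5, alpha=0.4, label="pi1")
            ax.scatter(gen[:, 0], gen[:, 1], s=5, alpha=0.4, label="generated")
        ax.legend()
        return ax
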