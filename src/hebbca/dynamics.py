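"""Time-stepped integration of the graded-response network dynamics.

Every cell is a leaky integrator,

    tau * dV/dt = -V + k1 * (V_in + k2 * eta),

driven by its net synaptic input ``V_in`` (EPSPs positive, IPSPs
negative, plus the constant baseline ``Vb``) and independent white noise
``eta`` uniform on [-0.5, 0.5].  Excitatory cells emit a piecewise-linear
sigmoid of ``V`` above an adaptive threshold ``phi = alpha * omega``,
clipped to [0, 1]; inhibitory cells emit ``max(V, 0)``.  ``omega``
low-pass filters each excitatory cell's own output (time constant
``tauA``), and a per-area accumulator ``omegaS`` low-pass filters the
summed excitatory output (``tauS``), feeding back as the global
inhibition term ``kS * omegaS`` on every excitatory cell of the area.

Integration is an explicit Euler scheme with step ``dt``; all cells are
updated synchronously from the previous step's outputs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .architecture import Network
from .config import DynamicsParams, PlasticityParams
from .plasticity import apply_plasticity_edges


def excitatory_output(V, phi):
    """Piecewise-linear sigmoid: 0 below ``phi``, slope 1, clipped at 1."""
    return np.clip(np.asarray(V) - phi, 0.0, 1.0)


def inhibitory_output(V):
    """Rectified-linear inhibitory output: ``max(V, 0)``, unbounded above."""
    return np.maximum(np.asarray(V), 0.0)


def euler_step(x, drive, tau, dt):
    """One explicit Euler update of ``tau * dx/dt = -x + drive``."""
    return x + (dt / tau) * (drive - x)


class NonFiniteStateError(RuntimeError):
    """Raised when a membrane potential becomes non-finite."""

    def __init__(self, area: str, i: int, j: int):
        self.area, self.i, self.j = area, i, j
        super().__init__(f"non-finite membrane potential at {area}({i},{j})")


class Simulator:
    """Stateful stepper for one realised :class:`~hebbca.architecture.Network`.

    Parameters
    ----------
    net
        The realised network (weights are mutated in place by plasticity).
    dyn
        Dynamics constants.
    seed
        Seed (or ``numpy.random.SeedSequence``) for the noise stream.
        Identical seed and configuration give bit-identical trajectories.
    """

    def __init__(self, net: Network, dyn: DynamicsParams, seed=0):
        dyn.validate()
        self.net = net
        self.dyn = dyn
        self._seed = seed
        self.rng = np.random.default_rng(seed)
        N = net.n_cells
        self.N = N
        self.n_areas = len(net.areas)
        self.A = net.cells_per_area
        self._area_of = net.area_of
        # edge arrays for plasticity, aligned with W_ee.data
        self._edge_pre, self._edge_post = net.edge_arrays()
        self.reset()

    def reset(self, reseed: bool = False) -> None:
        """Return all state variables to rest (V = omega = omegaS = 0)."""
        N = self.N
        self.V_exc = np.zeros(N)
        self.V_inh = np.zeros(N)
        self.omega = np.zeros(N)
        self.omegaS = np.zeros(self.n_areas)
        self.O_exc = np.zeros(N)
        self.O_inh = np.zeros(N)
        self.t = 0
        if reseed:
            self.rng = np.random.default_rng(self._seed)

    # -- single step ------------------------------------------------------

    def step(
        self,
        stim: Optional[np.ndarray] = None,
        plasticity: Optional[PlasticityParams] = None,
    ) -> None:
        """Advance the network by one Euler step.

        ``stim``, if given, is an additive external input per excitatory
        cell.  If ``plasticity`` is given and enabled, the Hebbian rule is
        applied to every excitatory->excitatory weight using this step's
        presynaptic outputs and postsynaptic potentials.
        """
        d = self.dyn
        net = self.net
        # outputs at time t (from the previous step's potentials)
        O_e = excitatory_output(self.V_exc, d.alpha * self.omega)
        O_i = inhibitory_output(self.V_inh)

        # net input at time t
        exc_in = net.W_ee @ O_e
        exc_in -= net.w_ie * O_i
        exc_in += d.Vb
        exc_in -= d.kS * self.omegaS[self._area_of]
        if stim is not None:
            exc_in = exc_in + stim
        inh_in = net.W_ei @ O_e
        if d.inh_baseline:
            inh_in += d.Vb

        if plasticity is not None and plasticity.enabled:
            apply_plasticity_edges(
                net.W_ee.data, self._edge_pre, self._edge_post,
                O_e, self.V_exc, plasticity,
            )

        if d.k2 != 0.0:
            exc_in += d.k2 * (self.rng.random(self.N) - 0.5)
            inh_in += d.k2 * (self.rng.random(self.N) - 0.5)

        lam = d.dt / d.tau
        self.V_exc += lam * (d.k1 * exc_in - self.V_exc)
        self.V_inh += lam * (d.k1 * inh_in - self.V_inh)
        self.omega += (d.dt / d.tauA) * (O_e - self.omega)
        self.omegaS += (d.dt / d.tauS) * (
            O_e.reshape(self.n_areas, self.A).sum(axis=1) - self.omegaS
        )
        self.O_exc = O_e
        self.O_inh = O_i
        self.t += 1

        if not np.isfinite(self.V_exc.dot(self.V_exc)):
            bad = int(np.flatnonzero(~np.isfinite(self.V_exc))[0])
            area = self.net.areas[bad // self.A]
            local = bad % self.A
            raise NonFiniteStateError(
                area, local // net.params.cols, local % net.params.cols
            )

    # -- multi-step helpers ----------------------------------------------

    def run(
        self,
        steps: int,
        stim: Optional[np.ndarray] = None,
        plasticity: Optional[PlasticityParams] = None,
        record: Optional[np.ndarray] = None,
        record_offset: int = 0,
    ) -> None:
        """Advance ``steps`` steps; optionally write ``O_exc`` into
        ``record[record_offset + k]`` after each step ``k``."""
        for k in range(steps):
            self.step(stim=stim, plasticity=plasticity)
            if record is not None:
                record[record_offset + k] = self.O_exc

    def record_spontaneous(
        self, steps: int, settle: int = 0, dtype=np.float32
    ) -> np.ndarray:
        """Record excitatory outputs over ``steps`` stimulus-free steps
        with plasticity frozen.

        ``settle`` unrecorded steps are run first so the recording
        captures the running network rather than the startup transient of
        the artificial all-zero initial state (the constant baseline term
        reaches every cell simultaneously at t=0, a coherent kick that a
        running cortex never experiences).

        Returns an array of shape ``(steps, n_cells)``.
        """
        for _ in range(settle):
            self.step()
        out = np.empty((steps, self.N), dtype=dtype)
        for k in range(steps):
            self.step()
            out[k] = self.O_exc
        return out

    def stimulus_vector(self, cells: np.ndarray, amplitude: float) -> np.ndarray:
        """Dense additive-input vector with ``amplitude`` at ``cells``."""
        stim = np.zeros(self.N)
        stim[cells] = amplitude
        return stim
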