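"""Parameter containers and experiment presets.

All model constants are configuration fields. The shipped defaults were
calibrated (see ``scripts/calibrate.py``) so that, after training, cell
assemblies are bistable: ignitable by the intrinsic membrane noise, yet
self-terminating through adaptation and area-global inhibition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml


@dataclass
class DynamicsParams:
    """Constants of the leaky-integrator cell dynamics.

    The membrane potential of every cell follows
    ``tau * dV/dt = -V + k1 * (V_in + k2 * eta)`` with ``eta`` white noise
    uniform on [-0.5, 0.5], integrated with an explicit Euler step ``dt``.
    Excitatory cells adapt: their firing threshold is ``alpha * omega``
    where ``omega`` low-pass filters the cell's own output with time
    constant ``tauA``.  Each area feeds back a global inhibition term
    ``kS * omegaS`` (``omegaS`` low-pass filters the summed excitatory
    output of the area with time constant ``tauS``) onto every excitatory
    cell of that area.
    """

    tau: float = 2.5      # membrane time constant (arbitrary time units)
    k1: float = 1.0       # input scaling
    k2: float = 0.6       # noise scaling
    Vb: float = 0.02      # constant baseline input term
    alpha: float = 5.0    # adaptation strength (threshold per unit omega)
    tauA: float = 25.0    # adaptation time constant
    kS: float = 0.05      # area-global inhibition gain (scales ~1/area size)
    tauS: float = 7.5     # global inhibition time constant
    dt: float = 0.5       # Euler step
    inh_baseline: bool = True  # whether inhibitory cells also receive Vb

    def validate(self) -> None:
        if not (self.tau > 0 and self.tauA > 0 and self.tauS > 0):
            raise ValueError("time constants tau, tauA, tauS must be positive")
        if not (self.dt > 0 and self.dt <= self.tau):
            raise ValueError("require 0 < dt <= tau for Euler stability")
        if self.k1 <= 0:
            raise ValueError("k1 must be positive")
        if self.k2 < 0 or self.kS < 0 or self.alpha < 0:
            raise ValueError("k2, kS, alpha must be non-negative")


@dataclass
class ArchitectureParams:
    """Geometry and sparse-connectivity parameters of one network.

    Projections are topographic: a source cell at grid position (i, j)
    connects only within an ``n x n`` square centred on (i, j) of the
    target grid, with probability ``p0 * exp(-d^2 / (2 sigma^2))`` at
    grid distance d, clipped to zero outside the square.
    """

    rows: int = 25
    cols: int = 25
    n_exc: int = 19            # excitatory projection neighbourhood (odd)
    n_inh: int = 5             # excitatory->inhibitory neighbourhood (odd)
    sigma_exc: Optional[float] = None   # default n_exc / 4
    sigma_inh: Optional[float] = None   # default n_inh / 4
    p0_within: float = 0.28    # peak probability, within-area exc->exc
    p0_between: float = 0.28   # peak probability, between-area exc->exc
    p0_ei: float = 0.7         # peak probability, exc->inh (local)
    w_init_max: float = 0.1    # weights initialised uniformly in ]0, w_init_max]
    g_ei: float = 1.5          # gain on exc->inh drive
    w_ie: float = 1.0          # one-to-one inhibitory feedback weight

    @property
    def cells_per_area(self) -> int:
        return self.rows * self.cols

    def sigma(self, kind: str) -> float:
        if kind == "inh":
            return self.sigma_inh if self.sigma_inh is not None else self.n_inh / 4.0
        return self.sigma_exc if self.sigma_exc is not None else self.n_exc / 4.0

    def validate(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must be non-empty")
        if self.n_exc % 2 == 0 or self.n_inh % 2 == 0:
            raise ValueError("neighbourhood sizes must be odd")
        for p in (self.p0_within, self.p0_between, self.p0_ei):
            if not (0 < p <= 1):
                raise ValueError("connection probabilities must be in (0, 1]")
        if self.w_init_max <= 0:
            raise ValueError("w_init_max must be positive")


@dataclass
class PlasticityParams:
    """Discretised LTP/LTD rule (Artola-Broecher-Singer style).

    A link from cell x to cell y with presynaptic output ``O(x)`` and
    postsynaptic membrane potential ``V(y)`` is potentiated by ``delta_w``
    when ``O(x) >= theta_pre`` and ``V(y) >= theta_plus``; depressed by
    ``delta_w`` when the presynaptic side is active but ``theta_minus <=
    V(y) < theta_plus`` (homosynaptic LTD) or when the presynaptic side is
    inactive while ``V(y) >= theta_plus`` (heterosynaptic LTD); unchanged
    otherwise.  Weights are clipped to [0, w_max].
    """

    delta_w: float = 0.00167
    theta_pre: float = 0.05    # minimum presynaptic output, in ]0, 1]
    theta_plus: float = 0.05   # postsynaptic LTP threshold (potential)
    theta_minus: float = 0.025  # postsynaptic LTD threshold (potential)
    w_max: float = 0.5         # weight ceiling
    enabled: bool = True

    def validate(self) -> None:
        if not (0 < self.theta_pre <= 1):
            raise ValueError("theta_pre must be in ]0, 1]")
        if not self.theta_minus < self.theta_plus:
            raise ValueError("require theta_minus < theta_plus")
        if not (0 < self.delta_w < self.w_max):
            raise ValueError("require 0 < delta_w < w_max")


@dataclass
class PatternParams:
    """Sensorimotor pattern-pair generation settings."""

    n_patterns: int = 12
    cells_per_pattern: int = 20
    overlap_cells: int = 4     # shared with each ring-neighbouring pattern


@dataclass
class TrainingSchedule:
    """Training protocol: randomly interleaved pattern presentations."""

    presentations_per_pattern: int = 15000
    stimulus_steps: int = 16
    isi_range: Tuple[int, int] = (30, 80)   # uniform inclusive, in steps
    stimulus_amplitude: float = 10.0        # drives stimulated cells to output 1
    checkpoint_every: int = 0               # presentations; 0 disables

    def validate(self) -> None:
        if self.presentations_per_pattern < 1 or self.stimulus_steps < 1:
            raise ValueError("presentations and stimulus_steps must be >= 1")
        if self.isi_range[0] < 1 or self.isi_range[1] < self.isi_range[0]:
            raise ValueError("invalid ISI range")


@dataclass
class ProbeParams:
    """Post-training probe used to define CA membership.

    Each probe presents one pattern to the rested network (plasticity
    frozen) and averages every excitatory cell's output over
    ``window_len`` steps starting ``window_offset`` steps after stimulus
    onset, then averages over ``n_reps`` repetitions with noise on.
    """

    n_reps: int = 12
    window_offset: int = 1
    window_len: int = 15


@dataclass
class AnalysisParams:
    """CA membership, ignition detection and trial-averaging settings."""

    gamma: float = 0.5          # membership threshold fraction of area max
    ignition_fraction: float = 0.5   # fraction of CA cells that must fire
    min_gap: int = 0            # merge events separated by <= min_gap steps
    pre_onset: int = 10         # trial steps before ignition onset
    trial_len: int = 40         # total trial length in steps
    critical_window: int = 6    # steps analysed from the aligned baseline


@dataclass
class ExperimentConfig:
    """Complete, seedable description of one end-to-end experiment."""

    variant: str = "full"               # full | no_jumping | no_noise
    scale: str = "full"                 # label only: full | reduced
    seed: int = 0
    recording_steps: int = 20000
    settle_steps: int = 300             # unrecorded burn-in before recording
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    architecture: ArchitectureParams = field(default_factory=ArchitectureParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    patterns: PatternParams = field(default_factory=PatternParams)
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    probe: ProbeParams = field(default_factory=ProbeParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    VARIANTS = ("full", "no_jumping", "no_noise")

    def validate(self) -> None:
        if self.variant not in self.VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.recording_steps < 1:
            raise ValueError("recording_steps must be >= 1")
        self.dynamics.validate()
        self.architecture.validate()
        self.plasticity.validate()
        self.schedule.validate()

    @property
    def graph_variant(self) -> str:
        """Connectivity variant: 'serial' drops the jumping links."""
        return "serial" if self.variant == "no_jumping" else "full"

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule"]["isi_range"] = list(d["schedule"]["isi_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        for key, typ in (
            ("dynamics", DynamicsParams),
            ("architecture", ArchitectureParams),
            ("plasticity", PlasticityParams),
            ("patterns", PatternParams),
            ("schedule", TrainingSchedule),
            ("probe", ProbeParams),
            ("analysis", AnalysisParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        if isinstance(kwargs.get("schedule"), TrainingSchedule):
            kwargs["schedule"].isi_range = tuple(kwargs["schedule"].isi_range)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def full_preset(variant: str = "full", seed: int = 0) -> ExperimentConfig:
    """Reference-scale configuration: 25x25 areas, 12 patterns of 20
    cells, 15000 presentations per pattern, 20000-step spontaneous
    recording."""
    cfg = ExperimentConfig(variant=variant, scale="full", seed=seed)
    cfg.validate()
    return cfg


def reduced_preset(variant: str = "full", seed: int = 0) -> ExperimentConfig:
    """Scaled-down configuration that preserves the between-area degree
    ratios and the qualitative ignition dynamics while completing in
    minutes on one CPU: 12x12 areas, 6 patterns of 10 cells, 1000
    presentations per pattern, 4000-step spontaneous recording.
    Neighbourhoods and ISIs shrink proportionally with the grid."""
    cfg = ExperimentConfig(
        variant=variant,
        scale="reduced",
        seed=seed,
        recording_steps=4000,
        dynamics=DynamicsParams(kS=0.24),
        architecture=ArchitectureParams(
            rows=12, cols=12, n_exc=9, n_inh=3, p0_within=0.35, p0_between=0.8
        ),
        patterns=PatternParams(n_patterns=6, cells_per_pattern=10, overlap_cells=2),
        schedule=TrainingSchedule(
            presentations_per_pattern=1000, stimulus_steps=16, isi_range=(15, 40)
        ),
        probe=ProbeParams(n_reps=8),
    )
    cfg.validate()
    return cfg
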