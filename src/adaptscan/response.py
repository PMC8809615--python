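"""Step/staircase stimulation, adaptation metrics and staircase classes.

Adaptation of a simulated step response is quantified by two ratios:

* precision ``P = |dI/I1| / |dO/O1|`` — ratio of the relative input change
  to the relative *steady-state* output change; infinite for perfect
  adaptation (output returns exactly to baseline);
* sensitivity ``S = (|O_peak - O1|/O1) / (|dI|/I1)`` — relative transient
  excursion per relative input change.

A response "adapts" when ``P >= P_min`` and ``S >= S_min`` (defaults 10
and 1, the conventional screening thresholds).  A staircase stimulus probes
repeated adaptation: some networks adapt at every plateau (class ``PA``),
some only at the first step and are then unresponsive or non-adaptive
(class ``PA_ONCE`` — the "toilet-flush" phenomenon, typically caused by
loss of controllability at the shifted operating point), and some never
adapt (``NONE``).  Each plateau is re-linearized so the per-step linear
verdict can be compared with the simulated metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import RateField, find_steady_state, linearize
from .linear import FD_ZERO_TOL, LinearDiagnostics, adaptation_verdict

__all__ = [
    "Stimulus",
    "Trajectory",
    "ResponseMetrics",
    "StaircaseClassification",
    "simulate",
    "compute_metrics",
    "step_metrics",
    "classify_staircase",
    "DEFAULT_P_MIN",
    "DEFAULT_S_MIN",
    "PERFECT_P",
]

DEFAULT_P_MIN = 10.0
DEFAULT_S_MIN = 1.0
PERFECT_P = 1e3  # reporting threshold for "numerically perfect" adaptation


@dataclass(frozen=True)
class Stimulus:
    """Piecewise-constant disturbance protocol.

    ``levels[0]`` holds before ``switch_times[0]`` (the system is assumed
    pre-equilibrated at it); ``levels[k]`` holds from ``switch_times[k-1]``
    on.  A plain step is a two-level staircase.
    """

    levels: tuple[float, ...]
    switch_times: tuple[float, ...]
    kind: str = "step"

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError("a stimulus needs at least two levels")
        if len(self.switch_times) != len(self.levels) - 1:
            raise ValueError("need exactly one switch time per level change")
        if any(l <= 0 for l in self.levels):
            raise ValueError("stimulus levels must be positive")
        if any(t2 <= t1 for t1, t2 in zip(self.switch_times, self.switch_times[1:])):
            raise ValueError("switch times must be strictly increasing")

    @staticmethod
    def step(i1: float, i2: float, at: float = 0.0) -> "Stimulus":
        return Stimulus((i1, i2), (at,), "step")

    @staticmethod
    def staircase(levels, spacing: float) -> "Stimulus":
        levels = tuple(levels)
        times = tuple(spacing * (k + 1) for k in range(len(levels) - 1))
        return Stimulus(levels, times, "staircase")

    def level_at(self, t: float) -> float:
        k = int(np.searchsorted(np.asarray(self.switch_times), t, side="right"))
        return self.levels[k]


@dataclass
class Trajectory:
    t: np.ndarray
    x: np.ndarray          # shape (n_t, N)
    d: np.ndarray          # disturbance level at each sample
    node_labels: tuple[str, ...]
    output_index: int

    @property
    def y(self) -> np.ndarray:
        return self.x[:, self.output_index]


@dataclass
class ResponseMetrics:
    o1: float
    o2: float
    o_peak: float
    precision: float
    sensitivity: float
    peak_time: float
    settling_time: float
    adapted: bool
    perfect: bool
    settled: bool

    def to_dict(self) -> dict:
        return {
            "O1": self.o1, "O2": self.o2, "O_peak": self.o_peak,
            "precision": self.precision, "sensitivity": self.sensitivity,
            "peak_time": self.peak_time, "settling_time": self.settling_time,
            "adapted": self.adapted, "perfect": self.perfect, "settled": self.settled,
        }


@dataclass
class StaircaseClassification:
    per_step: list[ResponseMetrics]
    per_step_verdict: list[LinearDiagnostics]
    cls: str                    # PA | PA_ONCE | NONE
    flavor: str

    def to_dict(self) -> dict:
        return {
            "class": self.cls,
            "flavor": self.flavor,
            "steps": [m.to_dict() for m in self.per_step],
            "verdicts": [v.to_dict() for v in self.per_step_verdict],
        }


def simulate(field: RateField, stimulus: Stimulus, x0: np.ndarray,
             t_end: float, points_per_segment: int = 600,
             rtol: float = 1e-9, atol: float = 1e-12) -> Trajectory:
    """Integrate the rate field through the stimulus protocol.

    Integration restarts at every switch time (event handling by
    segmentation), using a stiff-capable solver.  The state box [0, 1]^N is
    respected by the enzymatic flavor's vector field itself.
    """
    from scipy.integrate import solve_ivp

    breaks = [0.0] + [t for t in stimulus.switch_times if 0.0 < t < t_end] + [t_end]
    ts: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    ds: list[np.ndarray] = []
    x = np.asarray(x0, dtype=float).copy()
    for t0, t1 in zip(breaks, breaks[1:]):
        lvl = stimulus.level_at(0.5 * (t0 + t1))
        t_eval = np.linspace(t0, t1, points_per_segment)
        jac = (lambda t, v, _l=lvl: field.jacobian(v, _l)) if field.jacobian else None
        sol = solve_ivp(lambda t, v, _l=lvl: field.f(v, _l), (t0, t1), x,
                        method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol, jac=jac)
        if not sol.success:
            raise RuntimeError(f"integration failed on [{t0}, {t1}]: {sol.message}")
        ts.append(sol.t)
        xs.append(sol.y.T)
        ds.append(np.full(sol.t.shape, lvl))
        x = sol.y[:, -1].copy()
    return Trajectory(np.concatenate(ts), np.vstack(xs), np.concatenate(ds),
                      field.graph.nodes, field.graph.output_index)


def _window_mean(t: np.ndarray, y: np.ndarray, t0: float, t1: float,
                 frac: float = 0.05) -> float:
    """Mean of y over the last ``frac`` of the window [t0, t1]."""
    lo = t1 - frac * (t1 - t0)
    mask = (t >= lo) & (t <= t1)
    return float(np.mean(y[mask])) if np.any(mask) else float(y[np.searchsorted(t, t1) - 1])


def compute_metrics(traj: Trajectory, stimulus: Stimulus, step_index: int = 0,
                    p_min: float = DEFAULT_P_MIN, s_min: float = DEFAULT_S_MIN,
                    settle_band: float = 0.02) -> ResponseMetrics:
    """Adaptation metrics for one level change of the protocol.

    O1 averages the tail of the pre-switch plateau, O2 the tail of the
    post-switch plateau; the peak is the largest excursion |y - O1| after
    the switch (undershoot-first responses are handled symmetrically).
    Perfect adaptation (O2 == O1 to tolerance) reports P = inf.
    """
    ts = stimulus.switch_times[step_index]
    t_pre0 = stimulus.switch_times[step_index - 1] if step_index > 0 else traj.t[0]
    t_post1 = (stimulus.switch_times[step_index + 1]
               if step_index + 1 < len(stimulus.switch_times) else traj.t[-1])
    i1, i2 = stimulus.levels[step_index], stimulus.levels[step_index + 1]
    t, y = traj.t, traj.y
    o1 = _window_mean(t, y, t_pre0, ts)
    o2 = _window_mean(t, y, ts, t_post1)
    seg = (t >= ts) & (t <= t_post1)
    dev = np.abs(y[seg] - o1)
    k = int(np.argmax(dev))
    o_peak = float(y[seg][k])
    t_peak = float(t[seg][k] - ts)
    di_rel = abs((i2 - i1) / i1)
    peak_rel = abs(o_peak - o1) / abs(o1) if o1 != 0 else float("inf")
    sensitivity = peak_rel / di_rel
    do_abs = abs(o2 - o1)
    zero_scale = max(abs(o_peak - o1), abs(o1), 1e-12)
    if do_abs <= 1e-9 * zero_scale:
        precision = float("inf")
    else:
        precision = di_rel / (do_abs / abs(o1)) if o1 != 0 else 0.0
    # settling: last excursion outside the band around O2
    band = settle_band * max(abs(o_peak - o1), 1e-15)
    outside = np.nonzero(np.abs(y[seg] - o2) > band)[0]
    settling = float(t[seg][outside[-1]] - ts) if outside.size else 0.0
    # settled when the final window is flat relative to the transient
    tail = y[seg][-max(3, int(0.05 * np.sum(seg))):]
    settled = bool(np.ptp(tail) <= 10 * band + 1e-12)
    adapted = bool(precision >= p_min and sensitivity >= s_min)
    return ResponseMetrics(o1, o2, o_peak, precision, sensitivity, t_peak,
                           settling, adapted, bool(precision >= PERFECT_P and
                                                   sensitivity >= s_min), settled)


def _plateau_scale(field: RateField, x_star: np.ndarray, d0: float) -> float:
    """Slowest linear time constant at an operating point (1/|Re lambda|)."""
    A = (field.jacobian(x_star, d0) if field.jacobian is not None
         else linearize(field, x_star, d0).A)
    re = np.abs(np.linalg.eigvals(A).real)
    re = re[re > 1e-9]
    return 1.0 / float(np.min(re)) if re.size else float("inf")


def step_metrics(field: RateField, i1: float, i2: float,
                 p_min: float = DEFAULT_P_MIN, s_min: float = DEFAULT_S_MIN,
                 t_end: float | None = None,
                 x_star: np.ndarray | None = None) -> tuple[ResponseMetrics, Trajectory]:
    """Equilibrate at ``i1``, apply a step to ``i2`` and score it."""
    if x_star is None:
        x_star = find_steady_state(field, i1).x
    if t_end is None:
        tau = _plateau_scale(field, x_star, i1)
        t_end = float(np.clip(40.0 * tau, 50.0, 4000.0))
    stim = Stimulus((i1, i2), (0.05 * t_end,), "step")
    traj = simulate(field, stim, x_star, t_end)
    return compute_metrics(traj, stim, 0, p_min, s_min), traj


def classify_staircase(field: RateField, stimulus: Stimulus,
                       p_min: float = DEFAULT_P_MIN, s_min: float = DEFAULT_S_MIN,
                       zero_tol: float = FD_ZERO_TOL,
                       min_spacing_factor: float = 10.0) -> StaircaseClassification:
    """Simulate a staircase and classify repeated-adaptation behavior.

    Refuses protocols whose plateau spacing is below ``min_spacing_factor``
    slowest time constants of the initial operating point.  At every
    post-step plateau the model is re-linearized (the steady state moves
    with each step) and the adaptation verdict recomputed — controllability
    can be lost at the new operating point even though it held initially.
    """
    ss0 = find_steady_state(field, stimulus.levels[0])
    tau = _plateau_scale(field, ss0.x, stimulus.levels[0])
    spacings = np.diff((0.0,) + stimulus.switch_times)
    if np.isfinite(tau) and np.any(spacings < min_spacing_factor * tau):
        raise ValueError(
            f"staircase spacing {float(np.min(spacings)):g} below "
            f"{min_spacing_factor} x slowest time constant ({tau:g})")
    t_end = stimulus.switch_times[-1] + float(np.min(spacings))
    traj = simulate(field, stimulus, ss0.x, t_end)
    per_step: list[ResponseMetrics] = []
    verdicts: list[LinearDiagnostics] = []
    for k in range(len(stimulus.levels) - 1):
        per_step.append(compute_metrics(traj, stimulus, k, p_min, s_min))
        lvl = stimulus.levels[k + 1]
        t_pl = (stimulus.switch_times[k + 1]
                if k + 1 < len(stimulus.switch_times) else traj.t[-1])
        x_end = traj.x[np.searchsorted(traj.t, t_pl) - 1]
        # polish the state actually reached on this plateau to a root, so the
        # re-linearization happens at the dynamically relevant steady state
        from scipy.optimize import root

        sol = root(lambda v: field.f(v, lvl), x_end,
                   jac=(lambda v: field.jacobian(v, lvl)) if field.jacobian else None,
                   method="hybr", tol=1e-12)
        x_lin = sol.x if np.max(np.abs(field.f(sol.x, lvl))) <= 1e-8 else x_end
        verdicts.append(adaptation_verdict(
            linearize(field, x_lin, lvl, residual_tol=np.inf), zero_tol=zero_tol))
    flags = [m.adapted for m in per_step]
    if all(flags):
        cls = "PA"
    elif flags[0] and not all(flags[1:]):
        cls = "PA_ONCE"
    else:
        cls = "NONE"
    return StaircaseClassification(per_step, verdicts, cls, field.flavor)
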