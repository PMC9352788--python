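"""Forward simulators: synthetic heats and power traces.

The generators emulate the data model of an ITC experiment: per
injection, the heat is the model isotherm value W * dH (either the
classical Wiseman model with a global K_a, or the coarse-grained
kinetics model with per-step K_i), optionally disturbed by independent
multiplicative uniform noise — the same noise model as the robustness
protocol.  Synthetic power traces place one rectangular or exponential
peak per injection window whose integral matches the requested heat in
closed form, so spline integration can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .experiment import (HeatSeries, KCAL_PER_UCAL_PER_UMOL, PowerTrace,
                         TitrationSchedule, total_concentrations)
from .ligand import free_ligand_series
from .qcfit import QcParams, _tight_binding_fraction
from .wiseman import WisemanParams, wiseman_function

__all__ = ["SimulationSpec", "simulate_heats", "simulate_power_trace"]


@dataclass
class SimulationSpec:
    """Study conditions of one synthetic experiment.

    ``truth`` is either :class:`WisemanParams` (global-K model) or
    :class:`QcParams` (per-step-K model); ``noise_width`` the half-width
    of the multiplicative uniform noise (0 = deterministic).
    """

    schedule: TitrationSchedule
    truth: object
    noise_width: float = 0.0
    trace_shape: str = "rectangular"   # or "exponential"
    tau: float = 8.0                   # s, exponential decay constant
    seed: int = 0
    ligand_mode: str = "cumulative"

    def __post_init__(self) -> None:
        if self.noise_width < 0:
            raise ValueError("noise_width must be nonnegative")
        if self.trace_shape not in ("rectangular", "exponential"):
            raise ValueError(f"unknown trace_shape {self.trace_shape!r}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def simulate_heats(spec: SimulationSpec) -> HeatSeries:
    """Per-injection heats q_i = W(.) * dH with multiplicative noise."""
    conc = total_concentrations(spec.schedule)
    truth = spec.truth
    if isinstance(truth, WisemanParams):
        W = wiseman_function(truth.K_a, truth.n, conc.l, conc.m)
    elif isinstance(truth, QcParams):
        series = free_ligand_series(truth.rates, truth.n, conc,
                                    mode=spec.ligand_mode)
        K = series.K_macro
        W = np.array([
            wiseman_function(K[i], truth.n, conc.l[i], conc.m[i])
            if np.isfinite(K[i])
            else _tight_binding_fraction(truth.n, conc.l[i], conc.m[i])
            for i in range(len(conc))
        ])
    else:
        raise TypeError(f"unsupported truth type {type(truth).__name__}")
    q = W * truth.dH
    if spec.noise_width > 0:
        rng = np.random.default_rng(spec.seed)
        q = q * rng.uniform(1.0 - spec.noise_width, 1.0 + spec.noise_width,
                            size=q.size)
    return HeatSeries(q=q)


def simulate_power_trace(spec: SimulationSpec, heats: HeatSeries,
                         window_s: float = 120.0,
                         samples_per_window: int = 240) -> PowerTrace:
    """Power trace whose per-window integrals equal the given heats.

    Injection i occupies [i*window_s, (i+1)*window_s).  The target
    integral in ucal is q_i * c_L * V_i / KCAL_PER_UCAL_PER_UMOL.  A
    rectangular peak of width window_s/4 sits centred in its window
    (integral exact); an exponential peak A*exp(-(t-t_i)/tau) decays
    from the window start (integral A*tau*(1-exp(-window_s/tau)),
    sampled densely enough for the spline check).
    """
    T = spec.schedule.T_inj
    if len(heats) != T:
        raise ValueError("heats length must match the schedule")
    t = np.linspace(0.0, T * window_s, T * samples_per_window, endpoint=False)
    p = np.zeros_like(t)
    inj = np.arange(T) * window_s
    umol = spec.schedule.c_L * spec.schedule.injection_volumes
    target_ucal = heats.q * umol / KCAL_PER_UCAL_PER_UMOL
    for i in range(T):
        t0 = inj[i]
        sel = (t >= t0) & (t < t0 + window_s)
        if spec.trace_shape == "rectangular":
            width = window_s / 4.0
            lo = t0 + (window_s - width) / 2.0
            box = sel & (t >= lo) & (t < lo + width)
            p[box] = target_ucal[i] / width
        else:
            A = target_ucal[i] / (spec.tau * (1.0 - np.exp(-window_s / spec.tau)))
            p[sel] = A * np.exp(-(t[sel] - t0) / spec.tau)
    return PowerTrace(time=t, power=p, injection_times=inj)
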