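"""Titration experiment representation and heat extraction.

An isothermal titration calorimetry (ITC) run is described by a
:class:`TitrationSchedule` (cell volume, syringe/cell concentrations and
per-injection volumes).  From the schedule the per-injection *total*
ligand and macromolecule concentrations follow from the displacement
corrections of Egawa-type mass balance:

    l_i = c_L * (sum V_k) * (2 V0 - sum V_k) / (2 V0^2)
    m_i = c_M * (2 V0 - sum V_k) / (2 V0 + sum V_k)

with the sums running over the first i injections.  Raw (already
deconvolved) compensation-power traces are integrated per injection
window with degree-5 univariate splines and normalised per mole of
injected ligand, yielding the heat series q_i in kcal/mol that the
fitting modules consume.

Units are fixed throughout the package: volumes in ml, concentrations in
mmol/l, power in ucal/s, time in s, heats in kcal/mol.  The single
conversion constant lives in :data:`KCAL_PER_UCAL_PER_UMOL`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import UnivariateSpline

__all__ = [
    "TitrationSchedule",
    "ConcentrationSeries",
    "PowerTrace",
    "HeatSeries",
    "total_concentrations",
    "integrate_peaks",
    "read_experiment",
    "write_experiment",
    "bivalent_schedule",
    "trivalent_schedule",
]

#: 1 ucal / 1 umol = 1 cal/mol = 1e-3 kcal/mol.  With concentrations in
#: mmol/l and volumes in ml, c_L * V_i is directly in umol.
KCAL_PER_UCAL_PER_UMOL = 1e-3


@dataclass
class TitrationSchedule:
    """Injection schedule and concentrations of one ITC experiment.

    Parameters
    ----------
    V0 : float
        Working cell volume in ml.
    injection_volumes : array-like of float
        Ordered injected volumes V_1..V_T in ml.
    c_L : float
        Syringe (ligand) concentration in mmol/l.
    c_M : float
        Initial cell (macromolecule) concentration in mmol/l.
    temperature_K : float, optional
        Experiment temperature in K, used for thermodynamic relations.
    valency : int, optional
        Valency s of the binding pair, used by the kinetic model.
    """

    V0: float
    injection_volumes: np.ndarray
    c_L: float
    c_M: float
    temperature_K: float = 298.15
    valency: int = 1

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.V0 <= 0:
            raise ValueError(f"V0 must be positive, got {self.V0}")
        if self.injection_volumes.ndim != 1 or self.injection_volumes.size < 1:
            raise ValueError("injection_volumes must be a non-empty 1-d sequence")
        if np.any(self.injection_volumes <= 0):
            bad = int(np.argmax(self.injection_volumes <= 0))
            raise ValueError(
                f"injection_volumes[{bad}] = {self.injection_volumes[bad]} is not positive"
            )
        if self.c_L <= 0 or self.c_M <= 0:
            raise ValueError("c_L and c_M must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        total = float(self.injection_volumes.sum())
        if total >= 2.0 * self.V0:
            raise ValueError(
                f"cumulative injected volume {total} ml must stay below 2*V0 = "
                f"{2 * self.V0} ml; the concentration formulas would go nonpositive"
            )

    @property
    def T_inj(self) -> int:
        """Number of injections."""
        return int(self.injection_volumes.size)

    @property
    def cumulative_volumes(self) -> np.ndarray:
        """Cumulative injected volume after each injection (ml)."""
        return np.cumsum(self.injection_volumes)


@dataclass
class ConcentrationSeries:
    """Per-injection total ligand/macromolecule concentrations (mmol/l)."""

    l: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if self.l.shape != self.m.shape or self.l.ndim != 1:
            raise ValueError("l and m must be 1-d arrays of equal length")
        if np.any(self.l <= 0) or np.any(self.m <= 0):
            raise ValueError("total concentrations must be positive")
        if np.any(np.diff(self.l) <= 0):
            raise ValueError("total ligand concentration must be strictly increasing")
        if np.any(np.diff(self.m) >= 0):
            raise ValueError("total macromolecule concentration must be strictly decreasing")

    @property
    def molar_ratio(self) -> np.ndarray:
        """Molar ratio r_i = l_i / m_i, the isotherm x-axis."""
        return self.l / self.m

    def __len__(self) -> int:
        return int(self.l.size)


@dataclass
class PowerTrace:
    """Deconvolved compensation-power trace.

    ``time`` in s (strictly increasing), ``power`` in ucal/s,
    ``injection_times`` the T onset times of the injections.
    """

    time: np.ndarray
    power: np.ndarray
    injection_times: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        self.injection_times = np.asarray(self.injection_times, dtype=float)
        if self.time.shape != self.power.shape or self.time.ndim != 1:
            raise ValueError("time and power must be 1-d arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(np.diff(self.injection_times) <= 0):
            raise ValueError("injection_times must be strictly increasing")
        if (
            self.injection_times[0] < self.time[0]
            or self.injection_times[-1] > self.time[-1]
        ):
            raise ValueError("injection_times must lie within the sampled time range")


@dataclass
class HeatSeries:
    """Integrated heat per injection, kcal per mole of injected ligand."""

    q: np.ndarray
    excluded: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 1:
            raise ValueError("q must be 1-d")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("q must be finite")
        self.excluded = frozenset(int(i) for i in self.excluded)
        for i in self.excluded:
            if not 0 <= i < self.q.size:
                raise ValueError(f"excluded index {i} out of range")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of injections that enter the fit."""
        keep = np.ones(self.q.size, dtype=bool)
        for i in self.excluded:
            keep[i] = False
        return keep

    def __len__(self) -> int:
        return int(self.q.size)


def total_concentrations(schedule: TitrationSchedule) -> ConcentrationSeries:
    """Total ligand/macromolecule concentrations after each injection.

    Applies the displacement-corrected mass-balance formulas (see module
    docstring).  The schedule invariant sum(V_i) < 2*V0 guarantees both
    series stay positive; l is strictly increasing and m strictly
    decreasing.
    """
    cum = schedule.cumulative_volumes
    V0 = schedule.V0
    l = schedule.c_L * cum * (2.0 * V0 - cum) / (2.0 * V0**2)
    m = schedule.c_M * (2.0 * V0 - cum) / (2.0 * V0 + cum)
    return ConcentrationSeries(l=l, m=m)


def _window_slices(trace: PowerTrace) -> list[slice]:
    """Half-open sample windows [t_i, t_{i+1}); the last extends to the end."""
    edges = list(trace.injection_times) + [np.inf]
    out = []
    for i in range(len(trace.injection_times)):
        lo = np.searchsorted(trace.time, edges[i], side="left")
        hi = (
            np.searchsorted(trace.time, edges[i + 1], side="left")
            if np.isfinite(edges[i + 1])
            else trace.time.size
        )
        out.append(slice(int(lo), int(hi)))
    return out


def integrate_peaks(
    trace: PowerTrace,
    schedule: TitrationSchedule,
    *,
    baseline: str = "linear",
    smoothing: float = 0.0,
) -> HeatSeries:
    """Integrate a power trace into per-injection heats (kcal/mol).

    Each injection window is fitted with a degree-5 univariate spline and
    integrated; the integral (ucal) is divided by the moles of ligand
    injected, c_L * V_i (umol), and converted to kcal/mol.

    Parameters
    ----------
    baseline : {"linear", "none"}
        With ``"linear"`` (default) a straight line through the mean power
        of the first and last 5% of samples of each window is subtracted
        before spline fitting.  ``"none"`` integrates the raw signal.
    smoothing : float
        Spline smoothing factor ``s``; 0 interpolates the samples exactly.

    Raises
    ------
    ValueError
        If a window holds fewer than 6 samples (a degree-5 spline needs
        at least 6 points) or the injection count does not match.
    """
    if baseline not in ("linear", "none"):
        raise ValueError(f"unknown baseline mode {baseline!r}")
    if trace.injection_times.size != schedule.T_inj:
        raise ValueError(
            f"trace has {trace.injection_times.size} injections, "
            f"schedule has {schedule.T_inj}"
        )
    q = np.empty(schedule.T_inj)
    for i, sl in enumerate(_window_slices(trace)):
        t = trace.time[sl]
        p = trace.power[sl].copy()
        if t.size < 6:
            raise ValueError(
                f"injection window {i} holds {t.size} samples; "
                "a degree-5 spline needs at least 6"
            )
        if baseline == "linear":
            k = max(1, int(round(0.05 * t.size)))
            t0, p0 = t[:k].mean(), p[:k].mean()
            t1, p1 = t[-k:].mean(), p[-k:].mean()
            slope = 0.0 if t1 == t0 else (p1 - p0) / (t1 - t0)
            p -= p0 + slope * (t - t0)
        spl = UnivariateSpline(t, p, k=5, s=smoothing)
        heat_ucal = spl.integral(t[0], t[-1])
        umol = schedule.c_L * schedule.injection_volumes[i]
        q[i] = heat_ucal / umol * KCAL_PER_UCAL_PER_UMOL / 1.0
    return HeatSeries(q=q)


# ---------------------------------------------------------------------------
# File formats
#
# config JSON: {"V0_ml": float, "c_L_mmol_per_l": float,
#   "c_M_mmol_per_l": float, "temperature_K": float, "valency": int,
#   "injection_volumes_ml": [...], optional "injection_times_s": [...]}
# heats CSV:  header "injection,q_kcal_per_mol"
# power CSV:  header "time_s,power_ucal_per_s"
# ---------------------------------------------------------------------------

_REQUIRED_CONFIG = {
    "V0_ml": (int, float),
    "c_L_mmol_per_l": (int, float),
    "c_M_mmol_per_l": (int, float),
    "injection_volumes_ml": list,
}


def _load_config(config_path) -> tuple[TitrationSchedule, dict]:
    with open(config_path) as fh:
        try:
            cfg = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{config_path}: invalid JSON ({exc})") from exc
    for key, typ in _REQUIRED_CONFIG.items():
        if key not in cfg:
            raise ValueError(f"{config_path}: missing required field {key!r}")
        if not isinstance(cfg[key], typ):
            raise ValueError(f"{config_path}: field {key!r} has wrong type")
    schedule = TitrationSchedule(
        V0=float(cfg["V0_ml"]),
        injection_volumes=cfg["injection_volumes_ml"],
        c_L=float(cfg["c_L_mmol_per_l"]),
        c_M=float(cfg["c_M_mmol_per_l"]),
        temperature_K=float(cfg.get("temperature_K", 298.15)),
        valency=int(cfg.get("valency", 1)),
    )
    return schedule, cfg


def read_experiment(config_path, data_path):
    """Read a (config JSON, data CSV) pair.

    Returns ``(schedule, data)`` where ``data`` is a :class:`HeatSeries`
    for an integrated-heats CSV or a :class:`PowerTrace` for a power CSV
    (the latter requires ``injection_times_s`` in the config).
    """
    schedule, cfg = _load_config(config_path)
    with open(data_path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{data_path}: empty file")
        header = [h.strip() for h in header]
        rows = [row for row in reader if row]

    if header == ["injection", "q_kcal_per_mol"]:
        q = np.full(schedule.T_inj, np.nan)
        for row in rows:
            try:
                idx, val = int(row[0]), float(row[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{data_path}: malformed row {row!r}") from exc
            if not 1 <= idx <= schedule.T_inj:
                raise ValueError(
                    f"{data_path}: injection index {idx} outside 1..{schedule.T_inj}"
                )
            q[idx - 1] = val
        if np.any(np.isnan(q)):
            missing = int(np.argmax(np.isnan(q))) + 1
            raise ValueError(f"{data_path}: no heat for injection {missing}")
        return schedule, HeatSeries(q=q)

    if header == ["time_s", "power_ucal_per_s"]:
        if "injection_times_s" not in cfg:
            raise ValueError(
                f"{config_path}: power traces need field 'injection_times_s'"
            )
        try:
            t = np.array([float(r[0]) for r in rows])
            p = np.array([float(r[1]) for r in rows])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{data_path}: malformed power row") from exc
        trace = PowerTrace(
            time=t, power=p, injection_times=np.asarray(cfg["injection_times_s"], float)
        )
        if trace.injection_times.size != schedule.T_inj:
            raise ValueError(
                f"{config_path}: {trace.injection_times.size} injection times for "
                f"{schedule.T_inj} injections"
            )
        return schedule, trace

    raise ValueError(f"{data_path}: unrecognised header {header!r}")


def write_experiment(config_path, data_path, schedule: TitrationSchedule, data) -> None:
    """Inverse of :func:`read_experiment` for heats or power traces."""
    cfg = {
        "V0_ml": schedule.V0,
        "c_L_mmol_per_l": schedule.c_L,
        "c_M_mmol_per_l": schedule.c_M,
        "temperature_K": schedule.temperature_K,
        "valency": schedule.valency,
        "injection_volumes_ml": schedule.injection_volumes.tolist(),
    }
    if isinstance(data, PowerTrace):
        cfg["injection_times_s"] = data.injection_times.tolist()
    with open(config_path, "w") as fh:
        json.dump(cfg, fh, indent=1)
    with open(data_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if isinstance(data, HeatSeries):
            writer.writerow(["injection", "q_kcal_per_mol"])
            for i, qi in enumerate(data.q, start=1):
                writer.writerow([i, repr(float(qi))])
        elif isinstance(data, PowerTrace):
            writer.writerow(["time_s", "power_ucal_per_s"])
            for ti, pi in zip(data.time, data.power):
                writer.writerow([repr(float(ti)), repr(float(pi))])
        else:
            raise TypeError(f"cannot write {type(data).__name__}")


def bivalent_schedule() -> TitrationSchedule:
    """The bivalent lectin/glycomacromolecule study schedule."""
    return TitrationSchedule(
        V0=1.442,
        injection_volumes=[0.001] + [0.01] * 13,
        c_L=0.7,
        c_M=0.071,
        valency=2,
    )


def trivalent_schedule() -> TitrationSchedule:
    """The trivalent lectin/glycomacromolecule study schedule."""
    return TitrationSchedule(
        V0=1.442,
        injection_volumes=[0.001] + [0.01] * 13,
        c_L=0.978,
        c_M=0.0918,
        valency=3,
    )
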