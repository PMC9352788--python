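"""Classical Wiseman isotherm fitting.

For 1:1 binding with association constant K_a, stoichiometry n and total
concentrations (l, m), the Wiseman function

    W(K_a, n; l, m) = 1/2 * (1 + (n - l/m - 1/(m K_a))
                             / sqrt((n + l/m + 1/(m K_a))^2 - 4 n l/m))

is the fraction of injected ligand that binds at that point of the
titration, so the model heat of injection i is W(K_a, n; l_i, m_i) * dH.
:class:`WisemanModel` estimates (K_a, n, dH) by Nelder-Mead minimisation
of the Euclidean norm of the (optionally weighted) residual against the
measured heats.

W itself is dimensionless; K_a carries the reciprocal unit of the
concentrations (here l/mmol), and a common rescaling of l and m with the
reciprocal rescaling of K_a leaves W unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .experiment import ConcentrationSeries, HeatSeries, TitrationSchedule, total_concentrations

__all__ = [
    "R_KCAL",
    "WisemanParams",
    "ThermoState",
    "wiseman_function",
    "wiseman_objective",
    "thermo_from_Ka",
    "WisemanModel",
    "WisemanResults",
]

#: Gas constant in kcal/(mol K).
R_KCAL = 1.98720425e-3


@dataclass(frozen=True)
class WisemanParams:
    """Association constant (l/mmol), stoichiometry and binding heat (kcal/mol)."""

    K_a: float
    n: float
    dH: float

    def __post_init__(self) -> None:
        if self.K_a <= 0:
            raise ValueError(f"K_a must be positive, got {self.K_a}")
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if not np.isfinite(self.dH):
            raise ValueError("dH must be finite")

    @property
    def K_d(self) -> float:
        """Dissociation constant, 1/K_a."""
        return 1.0 / self.K_a


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic state: dG = -R T ln K_a = dH - T dS (kcal/mol)."""

    T_kelvin: float
    dG: float
    dS: float
    R: float = R_KCAL

    def __post_init__(self) -> None:
        if self.T_kelvin <= 0:
            raise ValueError("T_kelvin must be positive")
        if self.R <= 0:
            raise ValueError("R must be positive")


def wiseman_function(K_a, n, l, m):
    """Bound fraction W(K_a, n; l, m); vectorised over l and m.

    Raises ``ValueError`` if the discriminant under the square root is
    not positive (which cannot happen for finite positive K_a, n, m and
    l >= 0; the guard catches invalid inputs).
    """
    K_a, n = float(K_a), float(n)
    l = np.asarray(l, dtype=float)
    m = np.asarray(m, dtype=float)
    if K_a <= 0 or n <= 0:
        raise ValueError("K_a and n must be positive")
    if np.any(m <= 0) or np.any(l < 0):
        raise ValueError("need m > 0 and l >= 0")
    r = l / m
    c = 1.0 / (m * K_a)
    disc = (n + r + c) ** 2 - 4.0 * n * r
    if np.any(disc <= 0):
        raise ValueError("nonpositive discriminant in Wiseman function")
    out = 0.5 * (1.0 + (n - r - c) / np.sqrt(disc))
    return out if out.ndim else float(out)


def wiseman_objective(
    params: WisemanParams,
    heats: HeatSeries,
    conc: ConcentrationSeries,
    weights=None,
) -> float:
    """Euclidean norm of the weighted residual q - W(K_a, n; l, m) * dH.

    Injections in ``heats.excluded`` are dropped; ``weights`` defaults to
    all ones over the remaining injections.
    """
    if len(heats) != len(conc):
        raise ValueError("heats and concentrations must have equal length")
    keep = heats.mask
    w = np.ones(keep.sum()) if weights is None else np.asarray(weights, float)[keep]
    model = wiseman_function(params.K_a, params.n, conc.l[keep], conc.m[keep]) * params.dH
    return float(np.linalg.norm(w * (heats.q[keep] - model)))


def thermo_from_Ka(K_a: float, dH: float, T_kelvin: float = 298.15) -> ThermoState:
    """Gibbs energy and entropy from K_a and dH at temperature T."""
    if K_a <= 0 or T_kelvin <= 0:
        raise ValueError("K_a and T_kelvin must be positive")
    dG = -R_KCAL * T_kelvin * np.log(K_a)
    dS = (dH - dG) / T_kelvin
    return ThermoState(T_kelvin=T_kelvin, dG=float(dG), dS=float(dS))


class WisemanModel:
    """Three-parameter Wiseman isotherm model for integrated ITC heats.

    Parameters
    ----------
    heats : HeatSeries
    conc : ConcentrationSeries
    weights : array-like, optional
        Per-injection residual weights (over all injections; excluded
        ones are dropped internally).

    Examples
    --------
    >>> model = WisemanModel.from_schedule(heats, schedule)
    >>> res = model.fit()
    >>> res.params.K_a, res.norm
    """

    def __init__(self, heats: HeatSeries, conc: ConcentrationSeries, weights=None):
        if len(heats) != len(conc):
            raise ValueError("heats and concentrations must have equal length")
        if len(heats) - len(heats.excluded) < 4:
            raise ValueError("need at least 4 usable injections for a 3-parameter fit")
        self.heats = heats
        self.conc = conc
        self.weights = None if weights is None else np.asarray(weights, float)

    @classmethod
    def from_schedule(cls, heats: HeatSeries, schedule: TitrationSchedule, weights=None):
        return cls(heats, total_concentrations(schedule), weights=weights)

    def objective(self, params: WisemanParams) -> float:
        return wiseman_objective(params, self.heats, self.conc, self.weights)

    def _default_init(self) -> WisemanParams:
        # K_a from the reciprocal macromolecule concentration at the
        # half-saturation injection (heat closest to q_1 / 2), n from the
        # molar ratio there, dH from the first usable heat.
        keep = self.heats.mask
        q = self.heats.q[keep]
        m = self.conc.m[keep]
        r = self.conc.molar_ratio[keep]
        mid = int(np.argmin(np.abs(q - 0.5 * q[0])))
        n0 = r[mid] if r[mid] > 0 else 1.0
        return WisemanParams(K_a=1.0 / m[mid], n=max(n0, 1e-3), dH=q[0] if q[0] != 0 else -1.0)

    def fit(self, init: WisemanParams | None = None, xtol=1e-8, ftol=1e-8,
            maxfev=100_000) -> "WisemanResults":
        """Nelder-Mead fit of (K_a, n, dH); K_a and n on log scale."""
        p0 = init if init is not None else self._default_init()
        x0 = np.array([np.log(p0.K_a), np.log(p0.n), p0.dH])

        def fun(x):
            return wiseman_objective(
                WisemanParams(np.exp(x[0]), np.exp(x[1]), x[2]),
                self.heats, self.conc, self.weights,
            )

        opt = minimize(fun, x0, method="Nelder-Mead",
                       options={"xatol": xtol, "fatol": ftol, "maxfev": maxfev})
        params = WisemanParams(float(np.exp(opt.x[0])), float(np.exp(opt.x[1])), float(opt.x[2]))
        return WisemanResults(
            model=self,
            params=params,
            norm=float(opt.fun),
            n_evals=int(opt.nfev),
            converged=bool(opt.success),
        )


class WisemanResults:
    """Fitted Wiseman parameters plus diagnostics."""

    def __init__(self, model, params: WisemanParams, norm: float, n_evals: int,
                 converged: bool):
        self.model = model
        self.params = params
        self.norm = norm
        self.n_evals = n_evals
        self.converged = converged

    @property
    def fitted_heats(self) -> np.ndarray:
        p = self.params
        return wiseman_function(p.K_a, p.n, self.model.conc.l, self.model.conc.m) * p.dH

    @property
    def resid(self) -> np.ndarray:
        return self.model.heats.q - self.fitted_heats

    def thermo(self, T_kelvin: float = 298.15) -> ThermoState:
        return thermo_from_Ka(self.params.K_a, self.params.dH, T_kelvin)

    def summary(self) -> str:
        p = self.params
        th = self.thermo()
        lines = [
            "Wiseman isotherm fit",
            "====================",
            f"K_a   {p.K_a:14.4f}  l/mmol",
            f"K_d   {p.K_d:14.6f}  mmol/l",
            f"n     {p.n:14.4f}",
            f"dH    {p.dH:14.4f}  kcal/mol",
            f"dG    {th.dG:14.4f}  kcal/mol (at {th.T_kelvin} K)",
            f"dS    {th.dS * 1e3:14.4f}  cal/(mol K)",
            f"norm  {self.norm:14.6f}  kcal/mol",
            f"nfev  {self.n_evals:8d}   converged: {self.converged}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Isotherm and fit over molar ratio."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.model.conc.molar_ratio
        ax.plot(r, self.model.heats.q, "o", label="measured")
        ax.plot(r, self.fitted_heats, "-", label="Wiseman fit")
        ax.set_xlabel("molar ratio l/m")
        ax.set_ylabel("q (kcal/mol)")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "K_a": self.params.K_a,
            "n": self.params.n,
            "dH_kcal_per_mol": self.params.dH,
            "norm": self.norm,
            "n_evals": self.n_evals,
            "converged": self.converged,
            "residuals": self.resid.tolist(),
        }
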