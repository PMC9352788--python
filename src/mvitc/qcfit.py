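"""Concentration-dependent (coarse-grained kinetics) isotherm fitting.

Instead of one global K_a, the model builds the s-valent generator Q
from microscopic on/off rates at the free-ligand concentration of every
titration step, coarse-grains it with PCCA+ to a per-step macroscopic
K_i, and feeds those into the Wiseman function:

    minimise || w * (q - W(K_i, n; l_i, m_i) * dH) ||
    over k_on_1..s, k_off_1..s, n, dH.

The optional Gaussian residual weighting concentrates the fit around
the isotherm slope (kernel exp(-(r - mu)^2 / (2 sigma^2)) on the
molar-ratio axis); individual injections can be excluded as outliers.

The landscape is rough in the rates, so estimation runs as a seeded
random search over log-uniform rate draws with a break condition (stop
as soon as a candidate beats a reference norm, typically the Wiseman
fit's), followed by Nelder-Mead refinement over (n, dH) only.  Only
rate *ratios* K_j = k_on_j / k_off_j are identifiable: the objective is
invariant under a common rescaling of all rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .experiment import ConcentrationSeries, HeatSeries
from .kinetics import MicroRates
from .ligand import free_ligand_series
from .wiseman import WisemanModel, wiseman_function

__all__ = ["QcParams", "WeightSpec", "SearchConfig", "gaussian_weights",
           "qc_objective", "QcModel", "QcResults"]


@dataclass(frozen=True)
class QcParams:
    """Microscopic rates plus stoichiometry and binding heat."""

    rates: MicroRates
    n: float
    dH: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not np.isfinite(self.dH):
            raise ValueError("dH must be finite")


@dataclass(frozen=True)
class WeightSpec:
    """Gaussian residual weighting on the molar-ratio axis.

    Defaults follow the trivalent study configuration: kernel mean 0.3
    (the slope location), sigma 0.1758, first injection excluded.
    """

    enabled: bool = True
    mu: float = 0.3
    sigma: float = 0.1758
    excluded: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.enabled and self.sigma <= 0:
            raise ValueError("sigma must be positive when weighting is enabled")
        object.__setattr__(self, "excluded", frozenset(int(i) for i in self.excluded))


@dataclass(frozen=True)
class SearchConfig:
    """Controls of the seeded random-search loop."""

    seed: int = 0
    rate_bounds: tuple = (1e-2, 1e4)
    max_draws: int = 1000
    break_norm: float | None = None  # default: the Wiseman norm

    def __post_init__(self) -> None:
        lo, hi = self.rate_bounds
        if not 0 < lo < hi:
            raise ValueError("rate_bounds must satisfy 0 < low < high")
        if self.max_draws < 1:
            raise ValueError("max_draws must be >= 1")


def gaussian_weights(molar_ratio, spec: WeightSpec) -> np.ndarray:
    """Unnormalised Gaussian kernel weights; excluded injections get 0."""
    r = np.asarray(molar_ratio, dtype=float)
    if spec.enabled:
        w = np.exp(-((r - spec.mu) ** 2) / (2.0 * spec.sigma**2))
    else:
        w = np.ones_like(r)
    for i in spec.excluded:
        w[i] = 0.0
    return w


def qc_objective(params: QcParams, heats: HeatSeries, conc: ConcentrationSeries,
                 spec: WeightSpec | None = None, mode: str = "cumulative") -> float:
    """Weighted residual norm of the per-step-K isotherm model."""
    if len(heats) != len(conc):
        raise ValueError("heats and concentrations must have equal length")
    series = free_ligand_series(params.rates, params.n, conc, mode=mode)
    K = series.K_macro
    W = np.array([
        wiseman_function(K[i], params.n, conc.l[i], conc.m[i]) if np.isfinite(K[i])
        else _tight_binding_fraction(params.n, conc.l[i], conc.m[i])
        for i in range(len(conc))
    ])
    w = gaussian_weights(conc.molar_ratio, spec) if spec is not None else np.ones(len(conc))
    keep = heats.mask
    resid = w[keep] * (heats.q[keep] - W[keep] * params.dH)
    return float(np.linalg.norm(resid))


def _tight_binding_fraction(n, l, m):
    # K_a -> inf limit of the Wiseman function: all ligand binds until the
    # n*m sites saturate
    return float(min(n * m, l)) / l if l > 0 else 1.0


class QcModel:
    """Coarse-grained multivalent kinetics model for integrated ITC heats.

    Parameters
    ----------
    heats, conc : measured heats and total concentrations.
    valency : int
        Number of sequential binding steps s (2..4 supported; 1 reduces
        to the classical single-site model).
    weights : WeightSpec, optional
        Gaussian weighting / outlier exclusion; default off.
    ligand_mode : {"cumulative", "increment"}
        Free-ligand recursion variant, see :mod:`mvitc.ligand`.
    """

    def __init__(self, heats: HeatSeries, conc: ConcentrationSeries, valency: int,
                 weights: WeightSpec | None = None, ligand_mode: str = "cumulative"):
        if len(heats) != len(conc):
            raise ValueError("heats and concentrations must have equal length")
        self.heats = heats
        self.conc = conc
        self.valency = int(valency)
        self.weights = weights
        self.ligand_mode = ligand_mode

    def objective(self, params: QcParams) -> float:
        return qc_objective(params, self.heats, self.conc, self.weights,
                            mode=self.ligand_mode)

    def _wiseman_reference(self):
        w = None
        if self.weights is not None:
            w = gaussian_weights(self.conc.molar_ratio, self.weights)
        heats = self.heats
        if self.weights is not None and self.weights.excluded:
            heats = HeatSeries(q=self.heats.q,
                               excluded=self.heats.excluded | self.weights.excluded)
        return WisemanModel(heats, self.conc, weights=w).fit()

    def fit(self, search: SearchConfig = SearchConfig(),
            wiseman_norm: float | None = None,
            polish_rates: bool = False, n_polish: int = 1,
            refine_maxfev: int = 20_000) -> "QcResults":
        """Random-search + Nelder-Mead estimation.

        Draws rates log-uniformly within ``search.rate_bounds`` and n
        uniformly on (0.05, 2), keeping dH at the Wiseman estimate; the
        loop breaks as soon as a candidate's norm beats the reference
        (``wiseman_norm`` or a fresh Wiseman fit).  The best candidate
        is then refined by Nelder-Mead over (n, dH) with rates held
        fixed.  ``polish_rates=True`` additionally polishes all
        parameters (off by default); with ``n_polish`` > 1 the polish
        restarts from that many of the best distinct candidates and
        keeps the overall best, guarding against local minima of the
        rough rate landscape.
        """
        ref = self._wiseman_reference()
        if wiseman_norm is None:
            wiseman_norm = ref.norm
        break_norm = search.break_norm if search.break_norm is not None else wiseman_norm

        rng = np.random.default_rng(search.seed)
        lo, hi = np.log10(search.rate_bounds[0]), np.log10(search.rate_bounds[1])
        s = self.valency
        dH0 = ref.params.dH

        top: list = []  # (norm, draw index, candidate), best first
        n_draws = 0
        for _ in range(search.max_draws):
            draw = 10.0 ** rng.uniform(lo, hi, size=2 * s)
            n_cand = rng.uniform(0.05, 2.0)
            cand = QcParams(
                rates=MicroRates(s=s, k_on=draw[:s], k_off=draw[s:]),
                n=n_cand, dH=dH0,
            )
            n_draws += 1
            try:
                norm = self.objective(cand)
            except ValueError:
                # draws whose slowest mode is not the overall binding event
                # have no meaningful 2-state projection; skip them
                continue
            top.append((norm, n_draws, cand))
            top.sort(key=lambda t: t[:2])
            del top[max(n_polish, 1):]
            if norm < break_norm:
                break

        if not top:
            raise RuntimeError("no random draw admitted a 2-state projection; "
                               "widen rate_bounds or increase max_draws")
        best_norm = top[0][0]
        refined, norm, nfev = top[0][2], best_norm, 0
        for _, _, cand in top[:max(n_polish, 1)]:
            ref_i, norm_i, nfev_i = self._refine(cand, polish_rates, refine_maxfev)
            nfev += nfev_i
            if norm_i < norm:
                refined, norm = ref_i, norm_i
        return QcResults(
            model=self, params=refined, norm=float(norm),
            n_evals=n_draws + nfev, n_draws=n_draws,
            converged=bool(best_norm < break_norm),
            wiseman_reference=ref,
        )

    def _refine(self, params: QcParams, polish_rates: bool,
                maxfev: int = 20_000):
        s = self.valency

        if polish_rates:
            def fun(x):
                try:
                    return self.objective(QcParams(
                        rates=MicroRates(s=s, k_on=np.exp(x[:s]), k_off=np.exp(x[s:2 * s])),
                        n=np.exp(x[2 * s]), dH=x[2 * s + 1]))
                except ValueError:
                    return np.inf  # invalid projection region
            x0 = np.concatenate([np.log(params.rates.k_on), np.log(params.rates.k_off),
                                 [np.log(params.n), params.dH]])
        else:
            def fun(x):
                return self.objective(QcParams(rates=params.rates,
                                               n=np.exp(x[0]), dH=x[1]))
            x0 = np.array([np.log(params.n), params.dH])

        opt = minimize(fun, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-8, "maxfev": maxfev})
        if polish_rates:
            out = QcParams(
                rates=MicroRates(s=s, k_on=np.exp(opt.x[:s]), k_off=np.exp(opt.x[s:2 * s])),
                n=float(np.exp(opt.x[2 * s])), dH=float(opt.x[2 * s + 1]))
        else:
            out = QcParams(rates=params.rates, n=float(np.exp(opt.x[0])),
                           dH=float(opt.x[1]))
        return out, float(opt.fun), int(opt.nfev)


class QcResults:
    """Fitted microscopic rates plus per-injection association constants."""

    def __init__(self, model: QcModel, params: QcParams, norm: float,
                 n_evals: int, n_draws: int, converged: bool,
                 wiseman_reference=None):
        self.model = model
        self.params = params
        self.norm = norm
        self.n_evals = n_evals
        self.n_draws = n_draws
        self.converged = converged
        self.wiseman_reference = wiseman_reference

    @property
    def micro_K(self) -> tuple:
        """Stepwise association constants K_j = k_on_j / k_off_j."""
        return self.params.rates.micro_K

    @property
    def ligand_series(self):
        return free_ligand_series(self.params.rates, self.params.n,
                                  self.model.conc, mode=self.model.ligand_mode)

    @property
    def K_series(self) -> np.ndarray:
        """Macroscopic K_a per injection at the fitted parameters."""
        return self.ligand_series.K_macro

    @property
    def fitted_heats(self) -> np.ndarray:
        p = self.params
        K = self.K_series
        conc = self.model.conc
        return np.array([
            (wiseman_function(K[i], p.n, conc.l[i], conc.m[i]) if np.isfinite(K[i])
             else _tight_binding_fraction(p.n, conc.l[i], conc.m[i])) * p.dH
            for i in range(len(conc))
        ])

    @property
    def resid(self) -> np.ndarray:
        return self.model.heats.q - self.fitted_heats

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Coarse-grained kinetics fit (s = {p.rates.s})",
            "=====================================",
        ]
        for j, (kon, koff, Kj) in enumerate(
                zip(p.rates.k_on, p.rates.k_off, self.micro_K), start=1):
            lines.append(f"k_on{j}  {kon:12.4f}   k_off{j} {koff:12.4f}   "
                         f"K{j} {Kj:10.4f}")
        lines += [
            f"n     {p.n:12.4f}",
            f"dH    {p.dH:12.4f}  kcal/mol",
            f"norm  {self.norm:12.6f}  kcal/mol",
            f"draws {self.n_draws:6d}   evals {self.n_evals:8d}   "
            f"converged: {self.converged}",
        ]
        if self.wiseman_reference is not None:
            lines.append(f"Wiseman reference norm: {self.wiseman_reference.norm:.6f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.model.conc.molar_ratio
        ax.plot(r, self.model.heats.q, "o", label="measured")
        ax.plot(r, self.fitted_heats, "-", label="coarse-grained kinetics fit")
        if self.wiseman_reference is not None:
            ax.plot(r, self.wiseman_reference.fitted_heats, "--", label="Wiseman fit")
        ax.set_xlabel("molar ratio l/m")
        ax.set_ylabel("q (kcal/mol)")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        p = self.params
        return {
            "valency": p.rates.s,
            "k_on": list(p.rates.k_on),
            "k_off": list(p.rates.k_off),
            "micro_K": list(self.micro_K),
            "n": p.n,
            "dH_kcal_per_mol": p.dH,
            "norm": self.norm,
            "n_draws": self.n_draws,
            "n_evals": self.n_evals,
            "converged": self.converged,
            "K_series": self.K_series.tolist(),
        }
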