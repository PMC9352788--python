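"""Free- and bound-ligand concentrations along the titration.

The kinetic model needs the free-ligand concentration [L]_i at every
injection, but only total concentrations are known.  The bound-ligand
concentration for given totals (l, m), stoichiometry n and association
constant K_a is the physical root of the 1:1 binding quadratic,

    L_b = (n m + l + 1/K_a - sqrt((n m + l + 1/K_a)^2 - 4 n m l)) / 2,

with 0 <= L_b <= min(n m, l).  The free-ligand series is then built
iteratively: [L]_1 = l_1, and for i > 1

    [L]_i = [L]_{i-1} + l_i - (L_b)_{i-1},

where (L_b)_{i-1} is evaluated with the macroscopic K_a obtained by
coarse-graining Q at [L]_{i-1} (lagged evaluation; this makes the
otherwise circular recursion explicit).  In the default "cumulative"
mode l_i is the total ligand concentration of step i, the literal
reading of the recursion; the alternative "increment" mode uses
l_i - l_{i-1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coarse import coarse_grain
from .experiment import ConcentrationSeries
from .kinetics import MicroRates, build_lumped_rate_matrix

__all__ = ["LigandSeries", "bound_ligand", "free_ligand_series"]


@dataclass
class LigandSeries:
    """Free and bound ligand concentration per injection (mmol/l)."""

    L_free: np.ndarray
    L_bound: np.ndarray
    K_macro: np.ndarray  # macroscopic K_a at [L]_i, one per injection

    def __post_init__(self) -> None:
        self.L_free = np.asarray(self.L_free, dtype=float)
        self.L_bound = np.asarray(self.L_bound, dtype=float)
        self.K_macro = np.asarray(self.K_macro, dtype=float)
        if not (self.L_free.shape == self.L_bound.shape == self.K_macro.shape):
            raise ValueError("series must have equal length")
        if np.any(self.L_free < 0) or np.any(self.L_bound < 0):
            raise ValueError("concentrations must be nonnegative")

    def __len__(self) -> int:
        return int(self.L_free.size)


def bound_ligand(n: float, m: float, l: float, K_a: float) -> float:
    """Bound-ligand concentration from the 1:1 binding quadratic."""
    if n < 0 or m < 0 or l < 0:
        raise ValueError("n, m, l must be nonnegative")
    if K_a <= 0:
        raise ValueError("K_a must be positive")
    a = n * m + l + 1.0 / K_a
    disc = a * a - 4.0 * n * m * l
    if disc < 0:
        raise ValueError("negative discriminant in bound-ligand quadratic")
    Lb = 0.5 * (a - np.sqrt(disc))
    # clip roundoff excursions outside the physical interval
    return float(min(max(Lb, 0.0), min(n * m, l)))


def free_ligand_series(rates: MicroRates, n: float, conc: ConcentrationSeries,
                       mode: str = "cumulative") -> LigandSeries:
    """Iterative free-ligand series [L]_1..[L]_T (see module docstring).

    The macroscopic K_a at each [L]_i is computed by PCCA+ coarse
    graining and returned alongside; entries that would go negative are
    floored at zero with a warning.
    """
    if mode not in ("cumulative", "increment"):
        raise ValueError(f"unknown mode {mode!r}")
    if n <= 0:
        raise ValueError("n must be positive")
    l, m = conc.l, conc.m
    T = len(conc)
    L = np.empty(T)
    Lb = np.empty(T)
    K = np.empty(T)
    L[0] = l[0]
    floored = False
    for i in range(T):
        # the lumped (bond-count) chain gives the same macroscopic K as
        # the full matrix, by exact lumpability
        K[i] = coarse_grain(build_lumped_rate_matrix(rates, L[i])).K_a_macro \
            if L[i] > 0 else np.inf
        Lb[i] = bound_ligand(n, m[i], l[i], K[i]) if np.isfinite(K[i]) \
            else min(n * m[i], l[i])
        if i + 1 < T:
            step = l[i + 1] if mode == "cumulative" else l[i + 1] - l[i]
            nxt = L[i] + step - Lb[i]
            if nxt < 0:
                floored = True
                nxt = 0.0
            L[i + 1] = nxt
    if floored:
        warnings.warn("free-ligand recursion went negative; floored at 0", stacklevel=2)
    return LigandSeries(L_free=L, L_bound=Lb, K_macro=K)
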