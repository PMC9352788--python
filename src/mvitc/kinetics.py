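"""Microscopic state space and rate matrix of an s-valent binding pair.

A ligand with s binding sites and a receptor with s accessible sites
form complexes described by partial matchings between ligand sites and
receptor sites.  With b bonds formed there are C(s,b)^2 * b! distinct
configurations; the total state count is 2, 7 and 34 for s = 1, 2, 3.

Transitions change one bond at a time.  From the fully unbound state a
first bond forms at rate k_on1 * [L] (one transition into each of the
s^2 singly-bound states); a (b+1)-th bond forms at k_on_{b+1} for each
admissible free-site pair; each bond of a b-bond state breaks at
k_off_b.  Diagonals are set so columns of the transposed generator Q^T
sum to zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = ["MicroRates", "BindingStateSpace", "RateMatrix",
           "enumerate_binding_states", "build_rate_matrix",
           "build_lumped_rate_matrix"]

_MAX_VALENCY = 4


@dataclass(frozen=True)
class MicroRates:
    """Per-step microscopic rates of an s-valent binding.

    ``k_on[0]`` multiplies the free-ligand concentration (first bond);
    subsequent entries are unimolecular relative rates, as are all
    ``k_off``.  The analysis is scale-free: only ratios are physically
    meaningful.
    """

    s: int
    k_on: tuple
    k_off: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_on", tuple(float(x) for x in self.k_on))
        object.__setattr__(self, "k_off", tuple(float(x) for x in self.k_off))
        if not 1 <= self.s <= _MAX_VALENCY:
            raise ValueError(f"valency s must be in 1..{_MAX_VALENCY}, got {self.s}")
        if len(self.k_on) != self.s or len(self.k_off) != self.s:
            raise ValueError("k_on and k_off must each have length s")
        if any(x <= 0 for x in self.k_on + self.k_off):
            raise ValueError("all rates must be positive")

    @property
    def micro_K(self) -> tuple:
        """Stepwise association constants K_j = k_on_j / k_off_j."""
        return tuple(a / b for a, b in zip(self.k_on, self.k_off))


@dataclass(frozen=True)
class BindingStateSpace:
    """Ordered partial matchings between s ligand and s receptor sites.

    States are sorted by bond count, then lexicographically by bond set,
    so matrices built on this ordering are reproducible bit-for-bit.
    The empty (fully unbound) configuration is first.
    """

    s: int
    states: tuple

    @property
    def n_states(self) -> int:
        return len(self.states)

    def bond_counts(self) -> np.ndarray:
        return np.array([len(st) for st in self.states])

    def index(self, bonds) -> int:
        return self.states.index(frozenset(bonds))


def enumerate_binding_states(s: int) -> BindingStateSpace:
    """All partial matchings of s ligand sites onto s receptor sites."""
    if not 1 <= s <= _MAX_VALENCY:
        raise ValueError(f"valency s must be in 1..{_MAX_VALENCY}, got {s}")
    states = []
    for b in range(s + 1):
        level = []
        for lig_sites in itertools.combinations(range(s), b):
            for rec_sites in itertools.permutations(range(s), b):
                level.append(frozenset(zip(lig_sites, rec_sites)))
        level.sort(key=lambda st: sorted(st))
        states.extend(level)
    return BindingStateSpace(s=s, states=tuple(states))


@dataclass
class RateMatrix:
    """Transposed generator Q^T of the binding chain at one [L].

    ``alpha`` is k_on1 * [L]; ``beta`` the magnitude of the singly-bound
    diagonal, k_off1 + k_on2 (for s >= 2).
    """

    QT: np.ndarray
    L_free: float
    space: BindingStateSpace | None = None
    rates: MicroRates | None = None

    @property
    def n_states(self) -> int:
        return self.QT.shape[0]

    @property
    def alpha(self) -> float:
        if self.rates is None:
            raise ValueError("alpha needs the microscopic rates")
        return self.rates.k_on[0] * self.L_free

    @property
    def beta(self) -> float:
        if self.rates is None or self.rates.s < 2:
            raise ValueError("beta is defined for s >= 2")
        return self.rates.k_off[0] + self.rates.k_on[1]

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted by |Re| ascending (zero first)."""
        w = np.linalg.eigvals(self.QT)
        return w[np.argsort(np.abs(w.real))]


def build_rate_matrix(rates: MicroRates, L_free: float,
                      space: BindingStateSpace | None = None) -> RateMatrix:
    """Assemble Q^T for the s-valent chain at free-ligand concentration [L].

    Off-diagonal entry QT[j, i] is the rate of the transition state_i ->
    state_j; diagonals make every column sum to zero (probability
    conservation of the continuous-time Markov chain).
    """
    if L_free < 0:
        raise ValueError("L_free must be nonnegative")
    if space is None:
        space = enumerate_binding_states(rates.s)
    elif space.s != rates.s:
        raise ValueError("state space valency does not match rates")
    s = rates.s
    idx = {st: i for i, st in enumerate(space.states)}
    n = space.n_states
    QT = np.zeros((n, n))
    for i, st in enumerate(space.states):
        b = len(st)
        used_l = {x for x, _ in st}
        used_r = {y for _, y in st}
        if b < s:
            gain = rates.k_on[0] * L_free if b == 0 else rates.k_on[b]
            for x in range(s):
                if x in used_l:
                    continue
                for y in range(s):
                    if y in used_r:
                        continue
                    QT[idx[st | {(x, y)}], i] += gain
        if b > 0:
            loss = rates.k_off[b - 1]
            for bond in st:
                QT[idx[st - {bond}], i] += loss
    np.fill_diagonal(QT, 0.0)
    np.fill_diagonal(QT, -QT.sum(axis=0))
    return RateMatrix(QT=QT, L_free=float(L_free), space=space, rates=rates)


def build_lumped_rate_matrix(rates: MicroRates, L_free: float) -> RateMatrix:
    """Bond-count (observable) chain of the s-valent binding, size s+1.

    The full chain is symmetric under permutations of ligand and of
    receptor sites, so it lumps exactly onto the number of bonds b:
    b -> b+1 at (s-b)^2 * k_on_{b+1} (k_on1 * [L] for b = 0) and
    b -> b-1 at b * k_off_b.  Spectral analysis and coarse graining on
    this chain give identical macroscopic rates to the full matrix at a
    fraction of the cost.
    """
    if L_free < 0:
        raise ValueError("L_free must be nonnegative")
    s = rates.s
    QT = np.zeros((s + 1, s + 1))
    for b in range(s):
        gain = rates.k_on[0] * L_free if b == 0 else rates.k_on[b]
        QT[b + 1, b] = (s - b) ** 2 * gain
    for b in range(1, s + 1):
        QT[b - 1, b] = b * rates.k_off[b - 1]
    np.fill_diagonal(QT, -QT.sum(axis=0))
    return RateMatrix(QT=QT, L_free=float(L_free), space=None, rates=rates)
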