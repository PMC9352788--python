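"""Spectral coarse graining of the binding chain to a 2-state macro model.

The full generator Q relaxes on several timescales; the slowest one is
the overall binding/unbinding of the complex.  Robust Perron cluster
analysis (PCCA+) assigns every micro state a fuzzy membership chi in the
two macro states "unbound" and "bound", built here with the inner
simplex algorithm (ISA) from the two dominant eigenvectors of Q.  The
projected generator

    Qc^T = (chi^T Pi chi)^{-1} chi^T Pi Q^T chi,   Pi = diag(pi),

has the 2-state template [[-k_on [L], k_off], [k_on [L], -k_off]] from
which the macroscopic association constant K_a = k_on / k_off follows.
Because Q depends on [L], so does K_a: one K per titration step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .kinetics import MicroRates, RateMatrix, build_rate_matrix, enumerate_binding_states

__all__ = ["Memberships", "CoarseGrained", "stationary_distribution",
           "pcca_memberships", "coarse_grain", "coarse_grain_rate_matrix",
           "association_constants"]

_IMAG_TOL = 1e-10
_GAP_TOL = 1e-12

MACRO_LABELS = ("unbound", "bound")


@dataclass
class Memberships:
    """Fuzzy membership matrix chi (n_states x 2); rows sum to one."""

    chi: np.ndarray
    macro_labels: tuple = MACRO_LABELS

    def __post_init__(self) -> None:
        chi = np.asarray(self.chi, dtype=float)
        if chi.ndim != 2 or chi.shape[1] != 2:
            raise ValueError("chi must be n_states x 2")
        if np.any(chi < -1e-10) or np.any(chi > 1 + 1e-10):
            raise ValueError("memberships must lie in [0, 1]")
        if np.any(np.abs(chi.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("membership rows must sum to 1")
        self.chi = chi


@dataclass
class CoarseGrained:
    """2-state projection of the binding chain at one [L]."""

    Qc_T: np.ndarray
    pi: np.ndarray
    chi: Memberships
    k_on_macro: float
    k_off_macro: float
    L_free: float

    @property
    def K_a_macro(self) -> float:
        return self.k_on_macro / self.k_off_macro


def _real_eig(QT: np.ndarray):
    """Right eigenpairs of the generator Q acting on state functions.

    Eigenvalues come sorted by |Re| ascending.  Imaginary parts below
    _IMAG_TOL (relative to the spectral radius) are discarded; larger
    ones raise, since the slow spectrum of a binding chain is real.
    """
    w, V = scipy.linalg.eig(QT.T)
    order = np.argsort(np.abs(w.real))
    w, V = w[order], V[:, order]
    scale = max(np.abs(w.real).max(), 1.0)
    if np.abs(w[:2].imag).max() > _IMAG_TOL * scale:
        raise ValueError("dominant eigenvalues have significant imaginary part")
    return w, V


def stationary_distribution(Q: RateMatrix) -> np.ndarray:
    """Unique probability vector pi with Q^T pi = 0.

    Requires an irreducible chain, i.e. [L] > 0; at [L] = 0 the unbound
    state is absorbing-from and the null space is degenerate.
    """
    QT = Q.QT
    n = QT.shape[0]
    if n > 1 and Q.L_free <= 0:
        raise ValueError("stationary distribution needs [L] > 0 (irreducible chain)")
    A = np.vstack([QT, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if pi.min() < -1e-8 * max(pi.max(), 1e-300):
        raise ValueError("stationary solve produced negative mass; chain reducible?")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _isa_two_state(QT: np.ndarray) -> np.ndarray:
    """Inner simplex algorithm memberships from the two dominant eigenvectors.

    The maximally separated rows of the second eigenvector act as
    simplex vertices; every state is expressed in barycentric
    coordinates of those vertices.  Small negative entries are clipped
    and rows renormalised.
    """
    n = QT.shape[0]
    if n < 2:
        raise ValueError("need at least two micro states")
    w, V = _real_eig(QT)
    if n > 2 and abs(abs(w[1].real) - abs(w[2].real)) < _GAP_TOL:
        warnings.warn("degenerate spectral gap: |lambda2| ~ |lambda3|", stacklevel=2)
    v = V[:, 1].real
    vmin, vmax = float(v.min()), float(v.max())
    if vmax - vmin < 1e-14:
        raise ValueError("second eigenvector is constant; cannot separate macrostates")
    chi = np.empty((n, 2))
    chi[:, 0] = (vmax - v) / (vmax - vmin)
    chi[:, 1] = (v - vmin) / (vmax - vmin)
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    return chi


def lumped_generator(Q: RateMatrix) -> np.ndarray:
    """Exact bond-count lumping of the binding chain (transposed, (s+1)^2).

    The generator is symmetric under permutations of ligand and receptor
    sites, so the chain is exactly lumpable onto the number of bonds:
    the aggregate rate from any state with b bonds into the set of
    states with c bonds is the same for every representative.
    """
    counts = Q.space.bond_counts()
    s = Q.space.s
    QTl = np.zeros((s + 1, s + 1))
    for b in range(s + 1):
        rep = int(np.argmax(counts == b))  # first state with b bonds
        for c in range(s + 1):
            if c != b:
                QTl[c, b] = Q.QT[counts == c, rep].sum()
    np.fill_diagonal(QTl, -QTl.sum(axis=0))
    return QTl


def pcca_memberships(Q: RateMatrix) -> Memberships:
    """Fuzzy 2-state memberships of the binding chain.

    Calorimetry observes how many bonds exist, not which sites carry
    them, and by exact lumpability the observable dynamics is the
    bond-count chain.  ISA therefore runs on the dominant eigenvectors
    of the lumped generator and the memberships are lifted back to the
    full state space (all states with equal bond count share a row).
    For a :class:`RateMatrix` without state-space structure ISA runs on
    the full matrix directly.
    """
    if Q.space is not None and Q.space.s > 1:
        chi_l = _isa_two_state(lumped_generator(Q))
        chi = chi_l[Q.space.bond_counts()]
    else:
        chi = _isa_two_state(Q.QT)
    # orient: first column is the macro state containing the unbound micro
    # state (index 0 by the state-space ordering)
    if chi[0, 1] > chi[0, 0]:
        chi = chi[:, ::-1].copy()
    return Memberships(chi=chi)


def coarse_grain(Q: RateMatrix, chi: Memberships | None = None,
                 pi: np.ndarray | None = None) -> CoarseGrained:
    """Project Q onto the 2-state macro model and read off k_on, k_off."""
    if chi is None:
        chi = pcca_memberships(Q)
    if pi is None:
        pi = stationary_distribution(Q)
    X = chi.chi
    Pi = np.diag(pi)
    G = X.T @ Pi @ X
    if np.linalg.cond(G) > 1e12:
        raise ValueError("collapsed clustering: chi^T Pi chi is singular")
    # project the generator in its row (from-state) convention, where chi
    # spans an invariant subspace, then transpose back
    Qc_T = np.linalg.solve(G, X.T @ Pi @ Q.QT.T @ X).T
    if Q.L_free <= 0:
        raise ValueError("macroscopic on-rate needs [L] > 0")
    k_on = float(Qc_T[1, 0]) / Q.L_free
    k_off = float(Qc_T[0, 1])
    if k_on <= 0 or k_off <= 0:
        raise ValueError("projection produced nonpositive macroscopic rates")
    return CoarseGrained(Qc_T=Qc_T, pi=pi, chi=chi, k_on_macro=k_on,
                         k_off_macro=k_off, L_free=Q.L_free)


def coarse_grain_rate_matrix(rates: MicroRates, L_free: float,
                             space=None) -> CoarseGrained:
    """Build Q at [L] and coarse-grain it in one step."""
    return coarse_grain(build_rate_matrix(rates, L_free, space))


def association_constants(rates: MicroRates, L_series) -> np.ndarray:
    """Macroscopic K_a per titration step along a free-ligand series."""
    L_series = np.asarray(L_series, dtype=float)
    if L_series.ndim != 1 or np.any(L_series <= 0):
        raise ValueError("L_series must be 1-d and positive")
    space = enumerate_binding_states(rates.s)
    return np.array([
        coarse_grain_rate_matrix(rates, L, space).K_a_macro for L in L_series
    ])
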