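"""Equilibrium thermodynamics of dimerization coupled to membrane binding.

A protein exists as monomer or homodimer in each of up to three well-mixed
compartments: the cytoplasm, a plasma-membrane slab of thickness ``a``, and
(optionally) an internal-membrane slab.  Within each compartment the
monomer/dimer split obeys mass action with dissociation constant
``kd_dim``; exchange between compartments is governed by equality of
effective chemical potentials, with dimensionless partition constants
``kd_mem`` (plasma membrane) and ``kd_int`` (internal membranes).

The chemical potential of a compartment at total concentration ``c`` is

    mu/RT = ln(c/c0) - (1/2) ln D(c) + ln K + const,

with D(c) = 1 + 4c/K_dim + sqrt(1 + 8c/K_dim) and K the compartment's
partition constant (1 for the cytoplasm).  The compartment-independent
constants cancel at equilibrium, which therefore reduces to equality of the
*reduced activities* ``a(c) = c / sqrt(D(c))`` weighted by the partition
constants:

    a(c_c) = kd_mem * a(c_m) = kd_int * a(c_n).

D has the exact factorisation D(c) = (1 + sqrt(1 + 8 c/K))^2 / 2, so the
reduced activity inverts in closed form, c = sqrt(2)*a + 4*a^2/K, and the
conservation law c_tot = c_c + a*(psi*c_m + phi*c_n) becomes a quadratic in
the cytoplasmic activity.  Equilibria are therefore solved exactly, with no
iteration.

All concentrations are molar; lengths are metres (``a`` defaults to 5 nm,
``psi`` to 0.174 um^-1 = 1.74e5 m^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "ModelParams",
    "EquilibriumState",
    "dimer_partition",
    "reduced_activity",
    "invert_activity",
    "solve_equilibrium",
    "cooperativity_landscape",
    "compartment_fractions",
    "DEFAULT_CTOT_SWEEP",
]

#: membrane surface-area : cytoplasm-volume ratio of the whole zygote (1/m)
PSI_WHOLE_CELL = 0.174e6
#: the same ratio counting only the posterior half of the plasma membrane
PSI_POSTERIOR = 0.087e6


@dataclass(frozen=True)
class ModelParams:
    """Thermodynamic and geometric constants of the binding model.

    Parameters
    ----------
    kd_dim : float
        Dimer dissociation constant (molar).
    kd_mem : float
        Dimensionless plasma-membrane partition constant; smaller means
        stronger membrane binding.
    c_tot : float
        Total protein concentration (molar, cytoplasm-volume units).
    a : float
        Membrane slab thickness (m); by convention the protein diameter.
    psi : float
        Plasma-membrane surface-area to cytoplasm-volume ratio (1/m).
    kd_int : float, optional
        Internal-membrane partition constant (three-compartment model).
    phi : float, optional
        Internal-membrane surface-to-volume ratio (1/m).

    Notes
    -----
    The reference concentration c0 = 1 M, reference entropy s0, and RT all
    appear in the chemical potentials but are identical across compartments
    and cancel at equilibrium; they are never free parameters.
    """

    kd_dim: float
    kd_mem: float
    c_tot: float
    a: float = 5e-9
    psi: float = PSI_WHOLE_CELL
    kd_int: Optional[float] = None
    phi: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("kd_dim", "kd_mem", "a", "psi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.c_tot < 0:
            raise ValueError("c_tot must be nonnegative")
        if (self.kd_int is None) != (self.phi is None) and self.kd_int is not None and self.kd_int <= 0:
            raise ValueError("kd_int must be strictly positive when set")
        if self.phi is not None and self.phi <= 0:
            raise ValueError("phi must be strictly positive when set")

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class EquilibriumState:
    """Per-compartment totals and monomer/dimer breakdown at equilibrium.

    ``c2`` values are dimer concentrations in monomer-equivalent units, so
    ``c1 + c2`` equals the compartment total exactly.  ``c_n`` fields are
    ``None`` for the two-compartment model.
    """

    c_c: float
    c_m: float
    c_n: Optional[float]
    c_c_monomer: float
    c_c_dimer: float
    c_m_monomer: float
    c_m_dimer: float
    c_n_monomer: Optional[float]
    c_n_dimer: Optional[float]


def _check_nonneg(c, name: str) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError(f"{name} must be nonnegative")
    return c


def dimer_partition(c, kd_dim: float):
    """Split a total concentration into monomer and dimer by mass action.

    Solves 2*c1^2/kd_dim + c1 = c; returns ``(c1, c2)`` with ``c2`` in
    monomer-equivalent units so that ``c1 + c2 == c``.
    """
    c = _check_nonneg(c, "c")
    if kd_dim <= 0:
        raise ValueError("kd_dim must be strictly positive")
    x = 8.0 * c / kd_dim
    root = np.sqrt(1.0 + x)
    # cancellation-free forms: K/4*(root-1) = 2c/(1+root)
    c1 = 2.0 * c / (1.0 + root)
    c2 = c * x / (1.0 + root) ** 2
    if c.ndim == 0:
        return float(c1), float(c2)
    return c1, c2


def reduced_activity(c, kd_dim: float):
    """Reduced activity a(c) = c / sqrt(D(c)), D = 1 + 4c/K + sqrt(1+8c/K).

    This is exp(mu/RT) stripped of the constants common to all compartments;
    equality of partition-weighted reduced activities defines equilibrium.
    Uses the exact factorisation D = (1 + sqrt(1+8c/K))^2 / 2.
    """
    c = _check_nonneg(c, "c")
    if kd_dim <= 0:
        raise ValueError("kd_dim must be strictly positive")
    out = c * np.sqrt(2.0) / (1.0 + np.sqrt(1.0 + 8.0 * c / kd_dim))
    return float(out) if np.ndim(c) == 0 else out


def invert_activity(activity, kd_dim: float):
    """Concentration whose reduced activity equals ``activity`` (exact)."""
    activity = _check_nonneg(activity, "activity")
    out = np.sqrt(2.0) * activity + 4.0 * activity**2 / kd_dim
    return float(out) if np.ndim(activity) == 0 else out


def _solve_activity(c_tot, kd_dim, kd_mem, a, psi, kd_int=None, phi=None):
    """Cytoplasmic reduced activity from the conservation quadratic.

    c_tot = inv(A) + a*psi*inv(A/kd_mem) + a*phi*inv(A/kd_int) with
    inv(x) = sqrt(2) x + 4 x^2 / kd_dim collects into
    beta*A^2 + gamma*A - c_tot = 0.
    """
    gamma = 1.0 + a * psi / kd_mem
    beta = 1.0 + a * psi / kd_mem**2
    if kd_int is not None:
        gamma = gamma + a * phi / kd_int
        beta = beta + a * phi / kd_int**2
    gamma = np.sqrt(2.0) * gamma
    beta = 4.0 * beta / kd_dim
    return 2.0 * c_tot / (gamma + np.sqrt(gamma**2 + 4.0 * beta * c_tot))


def solve_equilibrium(params: ModelParams, n_compartments: int = 2) -> EquilibriumState:
    """Solve the two- or three-compartment binding equilibrium exactly.

    The returned state satisfies the conservation law and the activity
    equalities to machine precision.  ``c_tot = 0`` yields an all-zero
    state.
    """
    if n_compartments not in (2, 3):
        raise ValueError("n_compartments must be 2 or 3")
    three = n_compartments == 3
    if three and (params.kd_int is None or params.phi is None):
        raise ValueError("three-compartment model requires kd_int and phi")
    if params.c_tot == 0.0:
        zero = 0.0
        nz = 0.0 if three else None
        return EquilibriumState(zero, zero, nz, zero, zero, zero, zero,
                                nz, nz)
    A = _solve_activity(
        params.c_tot, params.kd_dim, params.kd_mem, params.a, params.psi,
        params.kd_int if three else None, params.phi if three else None,
    )
    c_c = invert_activity(A, params.kd_dim)
    c_m = invert_activity(A / params.kd_mem, params.kd_dim)
    c_n = invert_activity(A / params.kd_int, params.kd_dim) if three else None
    cc1, cc2 = dimer_partition(c_c, params.kd_dim)
    cm1, cm2 = dimer_partition(c_m, params.kd_dim)
    if three:
        cn1, cn2 = dimer_partition(c_n, params.kd_dim)
    else:
        cn1 = cn2 = None
    return EquilibriumState(c_c, c_m, c_n, cc1, cc2, cm1, cm2, cn1, cn2)


#: the total-protein sweep used for cooperativity scoring: 20 log-spaced
#: points spanning a 100-fold depletion below the wild-type 27 nM estimate
DEFAULT_CTOT_SWEEP = np.geomspace(0.27e-9, 27e-9, 20)


def equilibrium_sweep(params: ModelParams, c_tot_sweep=None):
    """Vectorised two-compartment equilibrium over a total-protein sweep.

    Returns ``(c_c, c_m)`` arrays.
    """
    sweep = DEFAULT_CTOT_SWEEP if c_tot_sweep is None else np.asarray(c_tot_sweep, float)
    A = _solve_activity(sweep, params.kd_dim, params.kd_mem, params.a, params.psi)
    return invert_activity(A, params.kd_dim), invert_activity(A / params.kd_mem, params.kd_dim)


def ctot_sweep_for_cc_range(params: ModelParams, cc_lo: float, cc_hi: float,
                            n: int = 20) -> np.ndarray:
    """Total-protein sweep whose equilibria span a given cytoplasmic range.

    Uses the closed-form conservation law c_tot = c_c + a*psi*c_m(c_c)
    (two-compartment) to map the endpoints, then log-spaces c_tot.
    Useful when an observed cytoplasmic concentration window, rather than
    total protein, defines the regime of interest.
    """
    if not 0 < cc_lo < cc_hi:
        raise ValueError("need 0 < cc_lo < cc_hi")

    def ctot_of_cc(cc):
        a_c = reduced_activity(cc, params.kd_dim)
        c_m = invert_activity(a_c / params.kd_mem, params.kd_dim)
        return cc + params.a * params.psi * c_m

    return np.geomspace(ctot_of_cc(cc_lo), ctot_of_cc(cc_hi), n)


def cooperativity_landscape(kd_dim_grid, kd_mem_grid, params: ModelParams,
                            c_tot_sweep=None) -> np.ndarray:
    """Cooperativity score over a (kd_dim, kd_mem) grid.

    For each grid cell, two-compartment equilibria are solved over the
    total-protein sweep and log10(c_m) is regressed on log10(c_c); the
    slope alpha is the cooperativity score.  Returns an array of shape
    ``(len(kd_dim_grid), len(kd_mem_grid))``.
    """
    kd_dim_grid = np.asarray(kd_dim_grid, float)
    kd_mem_grid = np.asarray(kd_mem_grid, float)
    if np.any(kd_dim_grid <= 0) or np.any(kd_mem_grid <= 0):
        raise ValueError("grids must be strictly positive")
    sweep = DEFAULT_CTOT_SWEEP if c_tot_sweep is None else np.asarray(c_tot_sweep, float)
    kd = kd_dim_grid[:, None, None]
    km = kd_mem_grid[None, :, None]
    ct = sweep[None, None, :]
    A = _solve_activity(ct, kd, km, params.a, params.psi)
    log_cc = np.log10(np.sqrt(2.0) * A + 4.0 * A**2 / kd)
    Am = A / km
    log_cm = np.log10(np.sqrt(2.0) * Am + 4.0 * Am**2 / kd)
    # unweighted OLS slope along the sweep axis
    x = log_cc - log_cc.mean(axis=-1, keepdims=True)
    y = log_cm - log_cm.mean(axis=-1, keepdims=True)
    return (x * y).sum(axis=-1) / (x * x).sum(axis=-1)


def compartment_fractions(state: EquilibriumState, params: ModelParams):
    """Fraction of total protein in cytoplasm / plasma membrane / internal
    membranes, plus the plasma:internal amount ratio (psi*c_m)/(phi*c_n).

    Requires a solved three-compartment state.
    """
    if state.c_n is None:
        raise ValueError("compartment_fractions requires a 3-compartment state")
    amt_c = state.c_c
    amt_m = params.a * params.psi * state.c_m
    amt_n = params.a * params.phi * state.c_n
    tot = amt_c + amt_m + amt_n
    if tot == 0.0:
        return 0.0, 0.0, 0.0, np.nan
    ratio = np.inf if amt_n == 0.0 else (params.psi * state.c_m) / (params.phi * state.c_n)
    return amt_c / tot, amt_m / tot, amt_n / tot, ratio
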