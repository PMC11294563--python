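"""Monomer-dimer model for SEC-MALS weight-average molecular weight.

For a mixture of monomers (weight W_m) and dimers (W_d = 2 W_m) the
weight-average molecular weight is

    Mw = (n_m W_m^2 + n_d W_d^2) / (n_m W_m + n_d W_d)

where the molecule numbers n_m, n_d follow mass-action dimerisation at the
sample concentration.  With W_d = 2 W_m this reduces to
Mw = W_m * (1 + f_d) with f_d the dimer mass fraction, so Mw runs from W_m
(dilute) to W_d (saturating) and depends on concentration only through
c / kd_dim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .thermo import dimer_partition

__all__ = ["MWCurve", "mass_to_molar", "weight_avg_mw", "fit_kdim",
           "MONOMER_KDA"]

#: monomer molecular weight of the PAR-2 RING construct (kDa)
MONOMER_KDA = 9.23474


@dataclass
class MWCurve:
    """Weight-average MW versus input concentration.

    ``conc_mg_ml`` and ``mw_kda`` are parallel arrays; ``w_monomer`` is the
    monomer molecular weight in kDa (dimer = 2x).
    """

    conc_mg_ml: np.ndarray
    mw_kda: np.ndarray
    w_monomer: float = MONOMER_KDA

    def __post_init__(self) -> None:
        self.conc_mg_ml = np.asarray(self.conc_mg_ml, float)
        self.mw_kda = np.asarray(self.mw_kda, float)
        if self.conc_mg_ml.shape != self.mw_kda.shape:
            raise ValueError("concentration and MW arrays must align")
        if np.any(self.conc_mg_ml <= 0):
            raise ValueError("concentrations must be positive")

    @property
    def w_dimer(self) -> float:
        return 2.0 * self.w_monomer

    @classmethod
    def read_csv(cls, path, w_monomer: float = MONOMER_KDA) -> "MWCurve":
        df = pd.read_csv(path)
        return cls(df["conc_mg_ml"].to_numpy(), df["mw_kda"].to_numpy(), w_monomer)

    def to_csv(self, path) -> None:
        pd.DataFrame({"conc_mg_ml": self.conc_mg_ml,
                      "mw_kda": self.mw_kda}).to_csv(path, index=False)


def mass_to_molar(c_mass, w_monomer: float = MONOMER_KDA):
    """mg/ml -> molar (monomer-equivalent): c / (W_m in g/mol)."""
    c_mass = np.asarray(c_mass, float)
    if np.any(c_mass < 0) or w_monomer <= 0:
        raise ValueError("inputs must be nonnegative (w_monomer positive)")
    out = c_mass / (w_monomer * 1e3)
    return float(out) if np.ndim(c_mass) == 0 else out


def weight_avg_mw(c_molar, kd_dim: float, w_monomer: float = MONOMER_KDA):
    """Weight-average MW (kDa) at a monomer-equivalent molar concentration.

    Mass-action dimer split gives dimer mass fraction f_d = c2/c and
    Mw = W_m (1 + f_d), equal to the number-weighted second-moment formula
    (n_m W_m^2 + n_d W_d^2)/(n_m W_m + n_d W_d) for W_d = 2 W_m.
    """
    c_molar = np.asarray(c_molar, float)
    c1, c2 = dimer_partition(c_molar, kd_dim)
    with np.errstate(invalid="ignore"):
        f_d = np.where(c_molar > 0, c2 / np.where(c_molar > 0, c_molar, 1.0), 0.0)
    out = w_monomer * (1.0 + f_d)
    return float(out) if np.ndim(c_molar) == 0 else out


def fit_kdim(curve: MWCurve, fit_dilution_scale: bool = False,
             kd_bounds_log10: tuple = (-8.0, 0.0)):
    """Least-squares dimer dissociation constant from an Mw curve.

    Fits ``Mw(scale * c; kd_dim)`` in linear Mw space.  ``dilution_scale``
    maps input sample concentration to effective on-column concentration;
    it defaults to fixed 1 and is only identifiable jointly with kd up to
    the exact scale collapse Mw(c; kd) = Mw(s c; s kd), so freeing it
    requires external information and is off by default.

    Returns ``(kd_dim, scale)``.
    """
    mw = curve.mw_kda
    span = mw.max() - mw.min()
    if curve.conc_mg_ml.size < 3:
        raise ValueError("need at least 3 points")
    if span < 1e-3 * curve.w_monomer:
        raise ValueError(
            "Mw curve is flat (all monomer or all dimer): kd_dim unidentifiable")
    c_molar = mass_to_molar(curve.conc_mg_ml, curve.w_monomer)

    if not fit_dilution_scale:
        def sse(log_kd):
            r = weight_avg_mw(c_molar, 10.0 ** log_kd, curve.w_monomer) - mw
            return float(r @ r)

        res = optimize.minimize_scalar(sse, bounds=kd_bounds_log10,
                                       method="bounded",
                                       options={"xatol": 1e-10})
        return 10.0 ** res.x, 1.0

    def sse2(x):
        log_kd, log_s = x
        r = weight_avg_mw(10.0 ** log_s * c_molar, 10.0 ** log_kd,
                          curve.w_monomer) - mw
        return float(r @ r)

    res = optimize.minimize(sse2, x0=[np.mean(kd_bounds_log10), 0.0],
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14})
    return 10.0 ** res.x[0], 10.0 ** res.x[1]
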