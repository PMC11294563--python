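"""Synthetic-data generators with known ground truth for every pipeline input.

Each generator draws from the forward models in this package and returns
``(observations, truth)`` (plus its config), so parameter-recovery and
round-trip behaviour can be tested without any experimental data.  Noise
is applied only to observations; the stored truth is noiseless.  All
randomness flows through a mandatory seed and regeneration is
bit-identical.

What is emulated: graded-RNAi depletion series (total protein log-uniform
over a depletion range, equilibrium binding, multiplicative lognormal
measurement noise), straightened-cortex image sets (cytoplasm-only and
polarized, additive Gaussian pixel noise), SEC-MALS weight-average MW
curves, optogenetic before/after calibration pairs, and FRAP traces.
Embryo morphology, optics beyond the profile model, and RNAi biology are
not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cortex_quant as cq
from .cooperativity import RundownDataset
from .secmals import MONOMER_KDA, MWCurve, weight_avg_mw
from .thermo import ModelParams, equilibrium_sweep

__all__ = ["GeneratorConfig", "gen_rundown", "gen_cortex_images",
           "gen_mw_curve", "gen_optogenetic_pair", "gen_frap_trace"]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the wild-type regime: fitted dissociation constants
    (kd_dim 425 nM, kd_mem 10^-2.43), baseline total protein 27 nM depleted
    log-uniformly down to 1%, 40 embryos, 10% lognormal concentration
    noise, 50-pixel cross-sections with 1%-of-plateau Gaussian pixel noise.
    """

    seed: int
    kd_dim: float = 425e-9
    kd_mem: float = 10 ** -2.43
    c_tot_baseline: float = 27e-9
    depletion_range: Tuple[float, float] = (0.01, 1.0)
    n_embryos: int = 40
    noise_cv: float = 0.10
    au_scale_cyt: float = 1.0
    au_scale_mem: float = 1.0
    a: float = 5e-9
    psi: float = 0.174e6
    H: int = 50
    L: int = 100
    pixel_size_um: float = 0.255
    image_noise_sd: float = 0.01
    frap_k_off: float = 0.0073
    frap_bleach_depth: float = 0.8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        if not 0.0 <= self.noise_cv < 1.0:
            raise ValueError("noise_cv must be in [0, 1)")
        if self.n_embryos <= 0:
            raise ValueError("n_embryos must be positive")

    def params(self) -> ModelParams:
        return ModelParams(kd_dim=self.kd_dim, kd_mem=self.kd_mem,
                           c_tot=self.c_tot_baseline, a=self.a, psi=self.psi)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of
    variation ``cv``."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size)


def gen_rundown(config: GeneratorConfig, genotype: str = "wt",
                condition: str = "polarized", units: str = "au"
                ) -> Tuple[RundownDataset, RundownDataset]:
    """Graded-depletion dataset: ``(observed, truth)``.

    Per embryo, total protein is drawn log-uniformly over the depletion
    range, the two-compartment equilibrium is solved for the noiseless
    truth, and independent lognormal noise plus arbitrary-unit scaling is
    applied to each channel of the observation.  With ``units="au"`` the
    membrane channel is additionally multiplied by the slab thickness,
    emulating uncalibrated per-area signal; ``units="molar"`` emits noisy
    molar values directly.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.depletion_range
    c_tot = config.c_tot_baseline * np.exp(
        rng.uniform(np.log(lo), np.log(hi), config.n_embryos))
    c_c, c_m = equilibrium_sweep(config.params(), c_tot)
    truth = RundownDataset.from_arrays(c_c, c_m, genotype=genotype,
                                       condition=condition, units="molar")
    cyt_obs = c_c * _lognormal_factor(rng, config.noise_cv, config.n_embryos)
    mem_obs = c_m * _lognormal_factor(rng, config.noise_cv, config.n_embryos)
    if units == "au":
        cyt_obs = cyt_obs * config.au_scale_cyt
        mem_obs = mem_obs * config.a * config.au_scale_mem
    elif units != "molar":
        raise ValueError("units must be 'au' or 'molar'")
    observed = RundownDataset.from_arrays(cyt_obs, mem_obs, genotype=genotype,
                                          condition=condition, units=units)
    return observed, truth


def _polarized_cmem(L: int, low: float, high: float, width_frac: float = 0.05
                    ) -> np.ndarray:
    """Smooth logistic membrane-concentration step: anterior (arc index 0)
    low, posterior pole (L/2) high."""
    l = np.arange(L)
    # circular distance from the posterior pole at L/2
    dist = np.minimum(np.abs(l - L / 2), L - np.abs(l - L / 2))
    return low + (high - low) / (1.0 + np.exp((dist - L / 4) / (width_frac * L)))


def gen_cortex_images(config: GeneratorConfig,
                      profiles: Optional[cq.SignalProfiles] = None,
                      n_cyt: int = 17, n_pol: int = 10,
                      contrast: float = 8.0):
    """Cytoplasm-only and polarized straightened-cortex image sets.

    Returns ``(cyt_images, pol_images, truth)`` where truth holds the
    generating profiles and per-image concentrations.  ``contrast`` is the
    posterior:anterior membrane concentration ratio; 1 gives uniform
    membrane signal (unidentifiable for profile training, by design).
    """
    rng = np.random.default_rng(config.seed)
    if profiles is None:
        profiles = cq.SignalProfiles(
            s_cyt=cq.default_cyt_profile(config.H),
            s_mem=cq.default_mem_profile(config.H),
            provenance={"source": "synthetic truth"})
    c_cyts = rng.uniform(0.5, 2.0, n_cyt)
    cyt_images = [cq.simulate_cortex_image(
        c, np.zeros(config.L), profiles,
        noise_sd=config.image_noise_sd * c, rng=rng) for c in c_cyts]
    pol_c_cyt = rng.uniform(0.5, 2.0, n_pol)
    pol_c_mem = []
    pol_images = []
    for c in pol_c_cyt:
        low = c * rng.uniform(0.2, 0.6)
        cmem = _polarized_cmem(config.L, low, low * contrast)
        pol_c_mem.append(cmem)
        pol_images.append(cq.simulate_cortex_image(
            c, cmem, profiles, noise_sd=config.image_noise_sd * c, rng=rng))
    truth = {"profiles": profiles, "c_cyt_cyt_images": c_cyts,
             "c_cyt_pol_images": pol_c_cyt, "c_mem_pol_images": pol_c_mem}
    return cyt_images, pol_images, truth


def gen_mw_curve(kd_dim: float, concentrations_mg_ml: Sequence[float],
                 noise_sd_kda: float, seed: int,
                 w_monomer: float = MONOMER_KDA) -> Tuple[MWCurve, MWCurve]:
    """SEC-MALS weight-average MW curve: ``(observed, truth)``."""
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations_mg_ml, float)
    mw_true = weight_avg_mw(conc / (w_monomer * 1e3), kd_dim, w_monomer)
    truth = MWCurve(conc, mw_true, w_monomer)
    observed = MWCurve(conc, mw_true + rng.normal(0.0, noise_sd_kda, conc.size),
                       w_monomer)
    return observed, truth


def gen_optogenetic_pair(true_factor: float, psi: float, noise_cv: float,
                         seed: int, C: float = 100.0, M: float = 50.0,
                         recruited_fraction: float = 0.3
                         ) -> Tuple[cq.CalibrationRecord, cq.CalibrationRecord]:
    """Before/after membrane-recruitment pair: ``(observed, truth)``.

    The truth conserves the total pool T = C + psi*factor*M exactly: a
    fraction of the cytoplasmic signal moves to the membrane.
    """
    rng = np.random.default_rng(seed)
    dC = recruited_fraction * C
    C_post = C - dC
    M_post = M + dC / (psi * true_factor)
    truth = cq.CalibrationRecord(C, C_post, M, M_post, psi)
    f = _lognormal_factor(rng, noise_cv, 4)
    observed = cq.CalibrationRecord(C * f[0], C_post * f[1], M * f[2],
                                    M_post * f[3], psi)
    return observed, truth


def gen_frap_trace(k: float, depth: float, noise_sd: float, seed: int,
                   dt: float = 0.5, n_pre: int = 12, t_end: float = 600.0,
                   control_level: float = 1000.0, drift_per_s: float = 0.0):
    """FRAP bleach/control ROI series pair.

    Returns ``(bleach_roi, control_roi, t, bleach_index)``.  The underlying
    recovery is single-exponential, 1 - depth*exp(-k t) relative to
    prebleach; both ROIs share any acquisition drift so it cancels on
    normalisation.
    """
    rng = np.random.default_rng(seed)
    n_post = int(round(t_end / dt))
    t = np.arange(-n_pre, n_post) * dt
    drift = 1.0 + drift_per_s * (t - t[0])
    rel = np.where(t < 0, 1.0, 1.0 - depth * np.exp(-k * np.maximum(t, 0.0)))
    control = control_level * drift
    bleach = control_level * rel * drift
    if noise_sd > 0:
        bleach = bleach + rng.normal(0.0, noise_sd * control_level, bleach.size)
        control = control + rng.normal(0.0, noise_sd * control_level, control.size)
    return bleach, control, t, n_pre
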