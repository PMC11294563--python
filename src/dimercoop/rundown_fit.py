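"""Fit the binding equilibrium to graded-depletion ("rundown") datasets.

Measured per-embryo (cytoplasm, membrane) pairs — typically from several
genotypes with different dimerisation affinities — are fit to the
two-compartment equilibrium by minimising squared residuals of
log10(membrane slab concentration).  Because both channels are measured,
only the activity equality is needed to predict membrane from cytoplasm;
the conservation law never enters.  The fit shares the membrane partition
constant kd_mem across genotypes and gives each genotype its own kd_dim
(any of which may be fixed, e.g. to an independently measured value).

Raw arbitrary-unit data are first normalised: a single multiplicative
factor puts the reference subset's mean cytoplasmic value at a known
absolute concentration (10.4 nM for wild-type polarized zygotes), and the
membrane channel is additionally divided by the slab thickness ``a`` to
express per-area signal as slab molarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize

from .cooperativity import RundownDataset
from .thermo import invert_activity, reduced_activity

__all__ = ["FitSpec", "FitResult", "normalize_to_molar", "predict_membrane",
           "fit_joint", "bootstrap_fit"]

#: cytoplasmic concentration of the wild-type polarized reference (molar)
REFERENCE_C_C = 10.4e-9


def normalize_to_molar(data: RundownDataset, reference_c_c: float = REFERENCE_C_C,
                       a: float = 5e-9, reference_genotype: str = "wt",
                       reference_condition: Optional[str] = "polarized"
                       ) -> RundownDataset:
    """Convert an arbitrary-unit dataset to molar slab concentrations.

    Both channels are scaled by the single factor that maps the reference
    subset's mean cytoplasmic signal to ``reference_c_c``; the membrane
    channel is then divided by ``a`` to convert per-area signal into slab
    concentration.
    """
    ref = data.subset(genotype=reference_genotype, condition=reference_condition)
    if len(ref) == 0:
        raise ValueError(
            f"no reference records (genotype={reference_genotype!r}, "
            f"condition={reference_condition!r})")
    factor = reference_c_c / ref.df["cyt"].mean()
    df = data.df.copy()
    df["cyt"] = df["cyt"] * factor
    df["mem"] = df["mem"] * factor / a
    df["units"] = "molar"
    return RundownDataset(df)


def predict_membrane(c_c, kd_dim: float, kd_mem: float):
    """Equilibrium membrane slab concentration for given cytoplasmic
    concentration(s), from the activity equality a(c_c) = kd_mem a(c_m)."""
    return invert_activity(reduced_activity(c_c, kd_dim) / kd_mem, kd_dim)


@dataclass
class FitSpec:
    """What to fit and how.

    ``fixed_kd_dim`` maps genotype -> fixed value (molar); genotypes not
    listed get a free kd_dim.  Bounds are in log10 molar (kd_dim) and
    log10 (kd_mem).  ``a`` is the slab thickness used by unit conversion
    upstream; kept here for provenance.
    """

    genotypes: Sequence[str]
    fixed_kd_dim: Dict[str, float] = field(default_factory=dict)
    kd_dim_bounds: tuple = (-9.0, -4.0)     # 1 nM .. 100 uM
    kd_mem_bounds: tuple = (-5.0, 0.0)
    a: float = 5e-9
    n_starts: int = 8
    start_seed: int = 0
    maxiter: int = 2000
    xatol: float = 1e-10
    fatol: float = 1e-12

    def free_genotypes(self):
        return [g for g in self.genotypes if g not in self.fixed_kd_dim]


@dataclass
class FitResult:
    """Joint-fit point estimates, diagnostics, and (optionally) bootstrap CIs."""

    kd_dim: Dict[str, float]
    kd_mem: float
    loss: float
    n_per_genotype: Dict[str, int]
    at_bound: bool = False
    start_losses: Optional[np.ndarray] = None
    fold_change: Optional[Dict[str, float]] = None
    bootstrap: Optional[Dict[str, np.ndarray]] = None
    ci: Optional[Dict[str, tuple]] = None
    n_boot: Optional[int] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        d = {"kd_dim": self.kd_dim, "kd_mem": self.kd_mem, "loss": self.loss,
             "n_per_genotype": self.n_per_genotype, "at_bound": self.at_bound}
        if self.fold_change:
            d["fold_change"] = self.fold_change
        if self.ci:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
            d.update(n_boot=self.n_boot, seed=self.seed)
        return d


def _prepare(datasets: Mapping[str, RundownDataset], spec: FitSpec):
    out = {}
    for g in spec.genotypes:
        if g not in datasets:
            raise ValueError(f"no dataset for genotype {g!r}")
        df = datasets[g].df
        cyt = df["cyt"].to_numpy(float)
        mem = df["mem"].to_numpy(float)
        if np.any(cyt <= 0) or np.any(mem <= 0):
            raise ValueError(f"nonpositive concentrations in genotype {g!r}")
        out[g] = (cyt, np.log10(mem))
    return out


def _loss(theta, arrays, spec: FitSpec):
    """theta = [log10 kd_mem, log10 kd_dim(free genotype 1), ...]."""
    log_km, *log_kds = theta
    km = 10.0 ** log_km
    free = spec.free_genotypes()
    kd_by_g = dict(spec.fixed_kd_dim)
    kd_by_g.update({g: 10.0 ** lk for g, lk in zip(free, log_kds)})
    total = 0.0
    for g, (cyt, log_mem) in arrays.items():
        pred = predict_membrane(cyt, kd_by_g[g], km)
        r = np.log10(pred) - log_mem
        total += float(r @ r)
    return total


def _starts(spec: FitSpec) -> np.ndarray:
    """Deterministic log-uniform multi-start points."""
    rng = np.random.default_rng(spec.start_seed)
    n_free = len(spec.free_genotypes())
    lo = np.array([spec.kd_mem_bounds[0]] + [spec.kd_dim_bounds[0]] * n_free)
    hi = np.array([spec.kd_mem_bounds[1]] + [spec.kd_dim_bounds[1]] * n_free)
    return lo + (hi - lo) * rng.random((spec.n_starts, 1 + n_free))


def _minimize(arrays, spec: FitSpec, starts=None):
    if starts is None:
        starts = _starts(spec)
    results = []
    for x0 in np.atleast_2d(starts):
        res = optimize.minimize(
            _loss, x0, args=(arrays, spec), method="Nelder-Mead",
            options={"maxiter": spec.maxiter, "xatol": spec.xatol,
                     "fatol": spec.fatol})
        results.append(res)
    losses = np.array([r.fun for r in results])
    best_loss = losses.min()
    # equal-loss tie-break: lowest kd_dim of the first free genotype
    tied = [r for r in results if r.fun <= best_loss * (1 + 1e-9) + 1e-300]
    best = min(tied, key=lambda r: tuple(r.x[1:]) if r.x.size > 1 else r.x[0])
    return best, losses


def _unpack(x, spec: FitSpec):
    km = 10.0 ** x[0]
    kd = dict(spec.fixed_kd_dim)
    kd.update({g: 10.0 ** lx for g, lx in zip(spec.free_genotypes(), x[1:])})
    return kd, km


def fit_joint(datasets: Mapping[str, RundownDataset], spec: FitSpec) -> FitResult:
    """Joint fit of per-genotype kd_dim with a shared kd_mem.

    Minimises summed squared log10-membrane residuals with multi-start
    Nelder-Mead; deterministic given ``spec.start_seed``.
    """
    if not spec.free_genotypes() and spec.genotypes and len(spec.fixed_kd_dim) == len(spec.genotypes):
        pass  # kd_mem is still free
    arrays = _prepare(datasets, spec)
    best, losses = _minimize(arrays, spec)
    kd, km = _unpack(best.x, spec)
    at_bound = bool(
        np.any(np.isclose(best.x[0], spec.kd_mem_bounds, atol=0.05)) or
        np.any([np.any(np.isclose(lx, spec.kd_dim_bounds, atol=0.05))
                for lx in best.x[1:]]))
    if at_bound:
        warnings.warn("best fit is near a parameter bound", stacklevel=2)
    fold = None
    if "wt" in kd:
        fold = {g: kd[g] / kd["wt"] for g in kd if g != "wt"}
    return FitResult(kd_dim=kd, kd_mem=km, loss=float(best.fun),
                     n_per_genotype={g: arrays[g][0].size for g in arrays},
                     at_bound=at_bound, start_losses=losses, fold_change=fold)


def bootstrap_fit(datasets: Mapping[str, RundownDataset], spec: FitSpec,
                  n_boot: int = 10_000, seed: Optional[int] = None,
                  ci: float = 95.0) -> FitResult:
    """Joint fit with percentile-bootstrap confidence intervals.

    Embryos are resampled with replacement within each genotype; each
    replicate is refit starting from the full-data optimum (plus the
    multi-start grid on the full data only).  Fold-changes are computed
    replicate-by-replicate.  Deterministic given ``seed``.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible bootstrap")
    point = fit_joint(datasets, spec)
    arrays = _prepare(datasets, spec)
    free = spec.free_genotypes()
    x_point = np.concatenate([[np.log10(point.kd_mem)],
                              [np.log10(point.kd_dim[g]) for g in free]])
    rng = np.random.default_rng(seed)
    names = ["kd_mem"] + [f"kd_dim:{g}" for g in free]
    draws = {n: np.empty(n_boot) for n in names}
    fold_names = [g for g in point.kd_dim if g != "wt"] if "wt" in point.kd_dim else []
    for n in fold_names:
        draws[f"fold:{n}"] = np.empty(n_boot)
    for b in range(n_boot):
        resampled = {}
        for g, (cyt, log_mem) in arrays.items():
            idx = rng.integers(0, cyt.size, size=cyt.size)
            resampled[g] = (cyt[idx], log_mem[idx])
        best, _ = _minimize(resampled, spec, starts=x_point[None, :])
        kd, km = _unpack(best.x, spec)
        draws["kd_mem"][b] = km
        for g in free:
            draws[f"kd_dim:{g}"][b] = kd[g]
        for g in fold_names:
            draws[f"fold:{g}"][b] = kd[g] / kd["wt"]
    q = [(100 - ci) / 2, 100 - (100 - ci) / 2]
    cis = {n: tuple(np.percentile(v, q)) for n, v in draws.items()}
    return FitResult(kd_dim=point.kd_dim, kd_mem=point.kd_mem, loss=point.loss,
                     n_per_genotype=point.n_per_genotype,
                     at_bound=point.at_bound, fold_change=point.fold_change,
                     bootstrap=draws, ci=cis, n_boot=n_boot, seed=seed)
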