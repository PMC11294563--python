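"""Cooperativity scoring: the log-log membrane-vs-cytoplasm slope.

For a molecule exchanging between cytoplasm and membrane, the equilibrium
membrane concentration follows m = beta * c^alpha across a graded series of
total protein levels.  A linear binder (rates independent of concentration)
has alpha = 1; positive cooperativity gives alpha > 1.  If the rate ratio
k_on/k_off scales as m^lambda then alpha = 1/(1 - lambda).  alpha is
estimated as the OLS slope of log10(m) on log10(c), with bootstrap
(resampling embryos with replacement) percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .thermo import ModelParams, equilibrium_sweep

__all__ = ["RundownDataset", "CooperativityResult", "score", "bootstrap_score",
           "score_model"]

COLUMNS = ["embryo_id", "genotype", "condition", "cyt", "mem", "units"]


@dataclass
class RundownDataset:
    """Per-embryo paired cytoplasm/membrane concentration measurements.

    Wraps a tidy DataFrame with columns ``embryo_id, genotype, condition,
    cyt, mem, units``.  ``units`` is ``"au"`` (raw arbitrary units) or
    ``"molar"`` (calibrated).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")

    @classmethod
    def from_arrays(cls, cyt, mem, genotype="wt", condition="polarized",
                    units="au", embryo_id=None) -> "RundownDataset":
        cyt = np.asarray(cyt, float)
        mem = np.asarray(mem, float)
        if embryo_id is None:
            embryo_id = np.arange(cyt.size)
        return cls(pd.DataFrame({
            "embryo_id": embryo_id, "genotype": genotype,
            "condition": condition, "cyt": cyt, "mem": mem, "units": units,
        }))

    @classmethod
    def read_csv(cls, path) -> "RundownDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def subset(self, genotype=None, condition=None) -> "RundownDataset":
        df = self.df
        if genotype is not None:
            df = df[df.genotype == genotype]
        if condition is not None:
            df = df[df.condition == condition]
        return RundownDataset(df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CooperativityResult:
    """Point estimate (and optional bootstrap distribution) of alpha.

    ``beta`` is the intercept in log10 units.  ``lambda_`` is the implied
    rate-ratio exponent 1 - 1/alpha.
    """

    alpha: float
    beta: float
    n: int
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    bootstrap_alphas: Optional[np.ndarray] = None
    n_boot: Optional[int] = None
    n_skipped: int = 0
    seed: Optional[int] = None

    @property
    def lambda_(self) -> float:
        return 1.0 - 1.0 / self.alpha

    def to_dict(self) -> dict:
        d = {"alpha": self.alpha, "beta": self.beta, "n": self.n}
        if self.ci_low is not None:
            d.update(ci_low=self.ci_low, ci_high=self.ci_high,
                     n_boot=self.n_boot, seed=self.seed)
        return d


def _validate(data: RundownDataset):
    cyt = data.df["cyt"].to_numpy(float)
    mem = data.df["mem"].to_numpy(float)
    bad = np.flatnonzero((cyt <= 0) | (mem <= 0) | ~np.isfinite(cyt) | ~np.isfinite(mem))
    if bad.size:
        ids = data.df["embryo_id"].to_numpy()[bad][:10].tolist()
        raise ValueError(
            f"nonpositive/invalid concentrations in {bad.size} record(s); "
            f"embryo ids (first 10): {ids}")
    if cyt.size < 3:
        raise ValueError("need at least 3 records to score cooperativity")
    return np.log10(cyt), np.log10(mem)


def score(data: RundownDataset) -> CooperativityResult:
    """OLS cooperativity score: slope of log10(mem) on log10(cyt)."""
    x, y = _validate(data)
    fit = stats.linregress(x, y)
    return CooperativityResult(alpha=float(fit.slope), beta=float(fit.intercept),
                               n=x.size)


def bootstrap_score(data: RundownDataset, n_boot: int = 10_000,
                    seed: Optional[int] = None,
                    ci: float = 95.0) -> CooperativityResult:
    """Cooperativity score with percentile bootstrap confidence interval.

    Embryos (records) are resampled with replacement; replicates whose
    resample is degenerate (zero variance in log cytoplasm) are skipped and
    counted in ``n_skipped``.  Deterministic for a fixed seed.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible bootstrap")
    x, y = _validate(data)
    rng = np.random.default_rng(seed)
    n = x.size
    alphas = np.empty(n_boot)
    kept = 0
    skipped = 0
    while kept < n_boot:
        idx = rng.integers(0, n, size=n)
        xb = x[idx]
        if np.ptp(xb) == 0.0:
            skipped += 1
            if skipped > 100 * n_boot:
                raise RuntimeError("bootstrap degenerate: cytoplasm values identical")
            continue
        yb = y[idx]
        xc = xb - xb.mean()
        alphas[kept] = (xc @ (yb - yb.mean())) / (xc @ xc)
        kept += 1
    point = score(data)
    lo, hi = np.percentile(alphas, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return CooperativityResult(alpha=point.alpha, beta=point.beta, n=n,
                               ci_low=float(lo), ci_high=float(hi),
                               bootstrap_alphas=alphas, n_boot=n_boot,
                               n_skipped=skipped, seed=seed)


def score_model(params: ModelParams, c_tot_sweep: Optional[Sequence[float]] = None
                ) -> float:
    """Cooperativity of the equilibrium model itself (noise-free).

    Solves two-compartment equilibria over the total-protein sweep and
    returns the log-log regression slope.
    """
    c_c, c_m = equilibrium_sweep(params, c_tot_sweep)
    x = np.log10(c_c)
    y = np.log10(c_m)
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))
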