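"""Orchestration: figure-reproduction presets and the end-to-end run.

Figure presets emit numeric tables (CSV), never rendered plots:

* ``fig3b`` — cooperativity score over a (kd_dim, kd_mem) grid, showing
  the ridge of high cooperativity at intermediate dimerisation strength.
* ``fig5a`` — three-compartment equilibrium fractions versus kd_dim with
  the internal:plasma partition ratio fixed at 5, showing that plasma-
  membrane preference grows with dimerisation strength.
* ``fig5c`` — symmetry-breaking trajectories for weak/intermediate/strong
  dimerisation, with the 600 s snapshot showing kinetic trapping.
* ``fig5d`` — compartment fractions 10 minutes into the transition,
  across a kd_dim sweep.

``run`` executes the synthetic end-to-end pipeline (simulate -> train
profiles -> quantify -> score -> fit) and writes a manifest with seeds and
content hashes for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cortex_quant as cq
from . import kinetics, synthetic_data, thermo
from .cooperativity import bootstrap_score
from .rundown_fit import FitSpec, fit_joint, normalize_to_molar
from .thermo import ModelParams

__all__ = ["RunConfig", "run", "reproduce_model_figures", "FIGURE_PRESETS"]

# shared fig5 preset regime: posterior-half geometry, kd_int/kd_mem fixed at 5
_FIG5 = dict(c_tot=27e-9, a=5e-9, psi=thermo.PSI_POSTERIOR,
             phi=thermo.PSI_POSTERIOR)
_FIG5_KD_MEM = 10 ** -2.43
_FIG5_LAMBDA = kinetics.LAMBDA_PRESETS["figure5"]


def _fig3b(outdir: Path) -> list:
    kd_dim = np.geomspace(1e-9, 1e-3, 25)
    kd_mem = np.geomspace(1e-4, 1e0, 17)
    params = ModelParams(kd_dim=425e-9, kd_mem=1.0, c_tot=27e-9)
    alpha = thermo.cooperativity_landscape(kd_dim, kd_mem, params)
    rows = [(kd, km, alpha[i, j]) for i, kd in enumerate(kd_dim)
            for j, km in enumerate(kd_mem)]
    df = pd.DataFrame(rows, columns=["kd_dim", "kd_mem", "alpha"])
    path = outdir / "fig3b_cooperativity_landscape.csv"
    df.to_csv(path, index=False)
    return [path]


def _fig5a(outdir: Path, kd_dim_grid=None) -> list:
    kds = np.geomspace(1e-9, 1e-3, 25) if kd_dim_grid is None else np.asarray(kd_dim_grid)
    rows = []
    for kd in kds:
        p = ModelParams(kd_dim=kd, kd_mem=_FIG5_KD_MEM,
                        kd_int=5 * _FIG5_KD_MEM, **_FIG5)
        st = thermo.solve_equilibrium(p, 3)
        f_cyt, f_pm, f_im, ratio = thermo.compartment_fractions(st, p)
        rows.append((kd, st.c_c, st.c_m, st.c_n, f_cyt, f_pm, f_im, ratio))
    df = pd.DataFrame(rows, columns=["kd_dim", "c_c", "c_m", "c_n",
                                     "f_cyt", "f_pm", "f_im", "pm_im_ratio"])
    path = outdir / "fig5a_equilibrium_fractions.csv"
    df.to_csv(path, index=False)
    return [path]


def _fig5_trajectory(kd_dim: float, t_end: float = 1e7):
    pre = ModelParams(kd_dim=kd_dim, kd_mem=1.0, kd_int=5 * _FIG5_KD_MEM, **_FIG5)
    post = pre.with_(kd_mem=_FIG5_KD_MEM)
    return kinetics.simulate_symmetry_breaking(pre, post, _FIG5_LAMBDA, t_end=t_end)


# weak / intermediate / strong dimerisation rows for the kinetic panels
_FIG5C_KD_DIMS = (1e-3, 425e-9, 1e-12)


def _fig5c(outdir: Path) -> list:
    paths = []
    snap_rows = []
    for kd in _FIG5C_KD_DIMS:
        traj = _fig5_trajectory(kd)
        f_cyt, f_pm, f_im = traj.fractions()
        df = pd.DataFrame({"t": traj.t, "c_c": traj.c_c, "c_m": traj.c_m,
                           "c_n": traj.c_n, "f_cyt": f_cyt, "f_pm": f_pm,
                           "f_im": f_im})
        path = outdir / f"fig5c_trajectory_kd{kd:.3g}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
        fc, fp, fi, ratio = kinetics.snapshot_metrics(traj, 600.0)
        eq_p = traj.params
        eq = traj.equilibrium
        _, eq_fp, eq_fi, _ = thermo.compartment_fractions(eq, eq_p)
        snap_rows.append((kd, fc, fp, fi, ratio, eq_fp, eq_fi,
                          kinetics.time_to_fraction(traj, 0.5)))
    snap = pd.DataFrame(snap_rows, columns=[
        "kd_dim", "f_cyt_600s", "f_pm_600s", "f_im_600s", "pm_im_ratio_600s",
        "f_pm_equilibrium", "f_im_equilibrium", "t_half_pm"])
    spath = outdir / "fig5c_snapshot_600s.csv"
    snap.to_csv(spath, index=False)
    paths.append(spath)
    return paths


def _fig5d(outdir: Path) -> list:
    kds = np.geomspace(1e-12, 1e-3, 10)
    rows = []
    for kd in kds:
        traj = _fig5_trajectory(kd)
        fc, fp, fi, ratio = kinetics.snapshot_metrics(traj, 600.0)
        rows.append((kd, fc, fp, fi, ratio))
    df = pd.DataFrame(rows, columns=["kd_dim", "f_cyt", "f_pm", "f_im",
                                     "pm_im_ratio"])
    path = outdir / "fig5d_snapshot_10min.csv"
    df.to_csv(path, index=False)
    return [path]


FIGURE_PRESETS = {"fig3b": _fig3b, "fig5a": _fig5a, "fig5c": _fig5c,
                  "fig5d": _fig5d}


def reproduce_model_figures(preset: str, outdir) -> list:
    """Emit the numeric table(s) behind a model figure panel."""
    if preset not in FIGURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: "
                         f"{sorted(FIGURE_PRESETS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return FIGURE_PRESETS[preset](outdir)


@dataclass
class RunConfig:
    """End-to-end synthetic pipeline configuration."""

    seed: int
    outdir: str
    stages: Sequence[str] = ("simulate", "train", "quantify", "score", "fit")
    n_embryos: int = 40
    n_boot: int = 1000
    kd_dim_wt: float = 425e-9
    kd_dim_mut: float = 2550e-9
    kd_mem: float = 10 ** -2.43
    L: int = 100
    n_cyt_images: int = 8
    n_pol_images: int = 6
    max_train_iter: int = 5000


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    Stages: ``simulate`` (rundown tables + cortex images), ``train``
    (profile learning on the simulated images), ``quantify`` (image
    decomposition with the trained profiles), ``score`` (bootstrap
    cooperativity on the simulated rundown), ``fit`` (joint two-genotype
    equilibrium fit).  Later stages regenerate their inputs from the same
    seed if an earlier stage was not requested.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    unknown = set(stages) - {"simulate", "train", "quantify", "score", "fit"}
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outputs: list[Path] = []
    gen_wt = synthetic_data.GeneratorConfig(
        seed=config.seed, kd_dim=config.kd_dim_wt, kd_mem=config.kd_mem,
        n_embryos=config.n_embryos, L=config.L)
    gen_mut = synthetic_data.GeneratorConfig(
        seed=config.seed + 1, kd_dim=config.kd_dim_mut, kd_mem=config.kd_mem,
        n_embryos=config.n_embryos, L=config.L)

    datasets = {}
    for name, gen in (("wt", gen_wt), ("mut", gen_mut)):
        obs, truth = synthetic_data.gen_rundown(gen, genotype=name)
        datasets[name] = obs
        if "simulate" in stages:
            p = outdir / f"rundown_{name}.csv"
            obs.to_csv(p)
            outputs.append(p)

    profiles = None
    cyt_imgs = pol_imgs = None
    if {"simulate", "train", "quantify"} & set(stages):
        cyt_imgs, pol_imgs, img_truth = synthetic_data.gen_cortex_images(
            gen_wt, n_cyt=config.n_cyt_images, n_pol=config.n_pol_images)

    if "train" in stages or "quantify" in stages:
        profiles = cq.train_cyt_profile(cyt_imgs, max_iter=config.max_train_iter)
        profiles = cq.train_mem_profile(pol_imgs, profiles,
                                        max_iter=config.max_train_iter)
        p = outdir / "profiles.json"
        p.write_text(json.dumps({
            "s_cyt": profiles.s_cyt.tolist(), "s_mem": profiles.s_mem.tolist(),
            "provenance": profiles.provenance}, indent=1))
        outputs.append(p)

    if "quantify" in stages:
        rows = []
        for i, img in enumerate(pol_imgs):
            res = cq.quantify(img, profiles)
            m = cq.polarity_metrics(res, factor=1.0, psi=0.174)
            rows.append({"image": i, "c_cyt": res.c_cyt, "loss": res.loss,
                         "posterior_mem_mean": m["posterior_mem_mean"],
                         "posterior_m_to_c": m["posterior_m_to_c"],
                         "fraction_at_pm": m["fraction_at_pm"],
                         "peak_mem": m["peak_mem"]})
        p = outdir / "quantification.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        outputs.append(p)

    if "score" in stages:
        res = bootstrap_score(datasets["wt"], n_boot=config.n_boot,
                              seed=config.seed)
        p = outdir / "cooperativity.json"
        p.write_text(json.dumps(res.to_dict(), indent=1))
        outputs.append(p)

    if "fit" in stages:
        molar = {g: normalize_to_molar(d, reference_genotype=g)
                 for g, d in datasets.items()}
        spec = FitSpec(genotypes=["wt", "mut"])
        fit = fit_joint(molar, spec)
        p = outdir / "fit.json"
        p.write_text(json.dumps(fit.to_dict(), indent=1))
        outputs.append(p)

    manifest = {
        "seed": config.seed,
        "stages": stages,
        "config": asdict(config),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
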