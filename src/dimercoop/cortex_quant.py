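"""Decomposition of straightened-cortex images into membrane and cytoplasm.

A straightened cortex is an H x L intensity array: H pixels across the
membrane (index 0 = extracellular side, index H-1 = cell interior) by L
pixels along the membrane arc.  The forward model is a sum of two tensor
products,

    image[h, l] = c_cyt * s_cyt[h] + c_mem[l] * s_mem[h],

where ``s_cyt`` (a step blurred by the optics, error-function-like) and
``s_mem`` (a blurred line, Gaussian-like) are *global* cross-membrane
signal profiles shared across images, ``c_cyt`` is a single uniform
cytoplasmic concentration per image and ``c_mem`` is a per-arc-position
membrane concentration.  Profiles are learned by gradient descent (Adam,
mean-squared pixel error) in two steps: ``s_cyt`` from cytoplasm-only
images, then ``s_mem`` from polarized images with ``s_cyt`` frozen — the
anterior/posterior membrane contrast together with the uniform-cytoplasm
constraint makes the two profiles separable.  Learned profiles may take
any shape; in practice ``s_mem`` comes out asymmetric, absorbing
out-of-focus membrane signal on the interior side.

With profiles fixed, quantification of a single image is a linear
least-squares problem and is solved in closed form (the gradient-descent
path is also provided and converges to the same optimum).

The model is bilinear, so all gradients used here are exact analytic
expressions; no autodiff framework is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "StraightenedImage", "SignalProfiles", "QuantResult", "CalibrationRecord",
    "default_cyt_profile", "default_mem_profile", "simulate_cortex_image",
    "train_cyt_profile", "train_mem_profile", "quantify", "calibrate_units",
    "polarity_metrics", "normalize_frap", "fit_frap_rate",
]

DEFAULT_H = 50


@dataclass
class StraightenedImage:
    """An H x L straightened-cortex intensity array plus metadata.

    Index 0 of the cross-membrane axis is the extracellular side; arc
    position 0 is the anterior pole, wrapping so the posterior pole sits at
    L/2.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2:
            raise ValueError("image must be 2-D (H x L)")

    @property
    def H(self) -> int:
        return self.data.shape[0]

    @property
    def L(self) -> int:
        return self.data.shape[1]


@dataclass
class SignalProfiles:
    """Learned cross-membrane signal profiles.

    Normalisation convention: the interior plateau of ``s_cyt`` (mean of
    its 5 innermost pixels) is 1, and ``max(s_mem)`` is 1, so recovered
    concentrations read in raw image-intensity units.
    """

    s_cyt: np.ndarray
    s_mem: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s_cyt = np.asarray(self.s_cyt, float)
        self.s_mem = np.asarray(self.s_mem, float)
        if self.s_cyt.shape != self.s_mem.shape or self.s_cyt.ndim != 1:
            raise ValueError("profiles must be 1-D arrays of equal length")


@dataclass
class QuantResult:
    """Recovered concentrations for one image."""

    c_cyt: float
    c_mem: np.ndarray
    loss: float
    units: str = "au"


@dataclass
class CalibrationRecord:
    """Mean signals before/after optogenetic membrane recruitment.

    ``C``/``C_post`` are cytoplasmic and ``M``/``M_post`` membrane means in
    raw model units; ``psi`` is the surface-to-volume ratio (1/um).
    """

    C: float
    C_post: float
    M: float
    M_post: float
    psi: float


def default_cyt_profile(H: int = DEFAULT_H, center: Optional[float] = None,
                        width: float = 2.0) -> np.ndarray:
    """Error-function step rising toward the cell interior (plateau 1)."""
    if center is None:
        center = H / 2.0
    h = np.arange(H)
    return 0.5 * (1.0 + special.erf((h - center) / (width * np.sqrt(2.0))))


def default_mem_profile(H: int = DEFAULT_H, center: Optional[float] = None,
                        sigma: float = 2.0) -> np.ndarray:
    """Unit-peak Gaussian at the membrane position."""
    if center is None:
        center = H / 2.0
    h = np.arange(H)
    return np.exp(-0.5 * ((h - center) / sigma) ** 2)


def simulate_cortex_image(c_cyt: float, c_mem, profiles: SignalProfiles,
                          noise_sd: float = 0.0,
                          rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Forward model: c_cyt x s_cyt + c_mem x s_mem (+ Gaussian noise).

    This is the exact model used in training and quantification; the
    noiseless call is the shared code path.
    """
    c_mem = np.asarray(c_mem, float)
    img = (c_cyt * profiles.s_cyt[:, None]
           + profiles.s_mem[:, None] * c_mem[None, :])
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img


class _Adam:
    """Minimal Adam optimizer over a dict of named numpy arrays."""

    def __init__(self, params: dict, lr: float = 0.005,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _as_stack(images) -> np.ndarray:
    arrs = [im.data if isinstance(im, StraightenedImage) else np.asarray(im, float)
            for im in images]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"images must share one shape, got {shapes}")
    return np.stack(arrs)


def _run_adam(loss_grad, opt: _Adam, max_iter: int, tol: float,
              window: int, what: str, scale: float):
    """Iterate until the relative loss change over ``window`` iterations is
    below ``tol``.  Raises on sustained divergence.

    ``scale`` is the mean squared data value; losses below 1e-12 of it are
    treated as converged-to-zero (Adam jitters at an exact optimum because
    its normalised step has magnitude ~lr regardless of gradient size).
    """
    history = []
    best = np.inf
    floor = 1e-12 * scale
    for it in range(max_iter):
        loss, grads = loss_grad(opt.params)
        history.append(loss)
        best = min(best, loss)
        if loss > 10.0 * max(best, floor) and it > 2 * window:
            raise RuntimeError(
                f"{what}: loss diverged at iteration {it} "
                f"(loss={loss:.3e}, best={best:.3e})")
        if loss <= floor:
            break
        if it >= window:
            prev = history[it - window]
            if prev > 0 and abs(prev - loss) / prev < tol:
                break
        opt.step(grads)
    return history


def train_cyt_profile(images: Sequence, lr: float = 0.005,
                      max_iter: int = 20_000, tol: float = 1e-6,
                      window: int = 100) -> SignalProfiles:
    """Learn the shared cytoplasmic profile from cytoplasm-only images.

    The membrane term is fixed to zero; the shared ``s_cyt`` and one scalar
    ``c_cyt`` per image minimise the mean squared pixel error.  The
    returned profile is normalised to an interior plateau of 1 (mean of
    the 5 innermost pixels); ``s_mem`` is filled with the default Gaussian
    initialiser, to be trained by :func:`train_mem_profile`.
    """
    Y = _as_stack(images)
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 cytoplasm-only images")
    N, H, L = Y.shape
    k = 2.0 / (N * H * L)
    params = {
        "s": default_cyt_profile(H),
        "c": Y[:, -5:, :].mean(axis=(1, 2)),  # plateau estimate
    }

    def loss_grad(p):
        R = p["c"][:, None, None] * p["s"][None, :, None] - Y
        loss = float(np.mean(R * R))
        g_s = k * np.einsum("ihl,i->h", R, p["c"])
        g_c = k * np.einsum("ihl,h->i", R, p["s"])
        return loss, {"s": g_s, "c": g_c}

    history = _run_adam(loss_grad, _Adam(params, lr=lr), max_iter, tol,
                        window, "train_cyt_profile", float(np.mean(Y * Y)))
    s = params["s"]
    plateau = s[-5:].mean()
    if plateau <= 0:
        raise RuntimeError("train_cyt_profile: nonpositive interior plateau")
    s = s / plateau
    return SignalProfiles(
        s_cyt=s, s_mem=default_mem_profile(H),
        provenance={"stage": "cyt", "n_images": N, "iterations": len(history),
                    "final_loss": history[-1],
                    "c_cyt": (params["c"] * plateau).tolist()})


def train_mem_profile(images: Sequence, profiles: SignalProfiles,
                      lr: float = 0.005, max_iter: int = 20_000,
                      tol: float = 1e-6, window: int = 100) -> SignalProfiles:
    """Learn the shared membrane profile from polarized images.

    ``s_cyt`` is frozen to the previously trained profile; ``s_mem``, one
    ``c_cyt`` scalar and one ``c_mem`` array per image are free.  Warns if
    the training images carry no along-membrane contrast, in which case
    ``s_mem`` is confounded with ``s_cyt`` and unidentifiable.  Returned
    ``s_mem`` is normalised to unit peak.
    """
    Y = _as_stack(images)
    N, H, L = Y.shape
    s_cyt = profiles.s_cyt
    if s_cyt.size != H:
        raise ValueError("profile length does not match image height")
    band = Y[:, H // 2 - 3:H // 2 + 4, :].mean(axis=1)  # (N, L) membrane band
    contrast = np.ptp(band, axis=1) / np.maximum(np.abs(Y).mean(axis=(1, 2)), 1e-300)
    if np.all(contrast < 1e-3):
        warnings.warn(
            "training images have no along-membrane contrast; s_mem is "
            "unidentifiable (confounded with s_cyt)", stacklevel=2)
    k = 2.0 / (N * H * L)
    c_cyt0 = Y[:, -5:, :].mean(axis=(1, 2))
    params = {
        "s": default_mem_profile(H),
        "cc": c_cyt0.copy(),
        "cm": np.maximum(band - c_cyt0[:, None] * s_cyt[H // 2 - 3:H // 2 + 4].mean(), 0.0),
    }

    def loss_grad(p):
        R = (p["cc"][:, None, None] * s_cyt[None, :, None]
             + p["s"][None, :, None] * p["cm"][:, None, :] - Y)
        loss = float(np.mean(R * R))
        return loss, {
            "s": k * np.einsum("ihl,il->h", R, p["cm"]),
            "cc": k * np.einsum("ihl,h->i", R, s_cyt),
            "cm": k * np.einsum("ihl,h->il", R, p["s"]),
        }

    history = _run_adam(loss_grad, _Adam(params, lr=lr), max_iter, tol,
                        window, "train_mem_profile", float(np.mean(Y * Y)))
    s = params["s"]
    peak = s.max()
    if peak <= 0:
        raise RuntimeError("train_mem_profile: nonpositive peak")
    return SignalProfiles(
        s_cyt=s_cyt, s_mem=s / peak,
        provenance={**profiles.provenance, "stage": "mem", "n_images_mem": N,
                    "iterations_mem": len(history), "final_loss_mem": history[-1]})


def quantify(image, profiles: SignalProfiles, method: str = "exact",
             lr: float = 0.005, max_iter: int = 20_000, tol: float = 1e-9,
             window: int = 100) -> QuantResult:
    """Recover (c_cyt, c_mem) for one image with profiles fixed.

    The problem is linear: eliminating c_mem column-by-column leaves a
    scalar normal equation for c_cyt, solved exactly (``method="exact"``).
    ``method="gd"`` runs the same Adam descent used in training and
    converges to the same optimum.
    """
    Y = image.data if isinstance(image, StraightenedImage) else np.asarray(image, float)
    H, L = Y.shape
    u, v = profiles.s_cyt, profiles.s_mem
    if u.size != H:
        raise ValueError("profile length does not match image height")
    vv = float(v @ v)
    if vv == 0.0:
        raise ValueError("degenerate membrane profile (all zeros)")
    # projector onto the complement of s_mem
    Pu = u - (u @ v) / vv * v
    denom = float(u @ Pu) * L
    if denom <= 1e-30 * float(u @ u) * L:
        raise ValueError("profiles are collinear; design is singular")

    if method == "exact":
        c_cyt = float(Pu @ Y.sum(axis=1)) / denom
        c_mem = (v @ (Y - c_cyt * u[:, None])) / vv
    elif method == "gd":
        params = {"cc": np.array(float(Y[-5:, :].mean())),
                  "cm": np.maximum(v @ Y / vv, 0.0)}
        k = 2.0 / (H * L)

        def loss_grad(p):
            R = p["cc"] * u[:, None] + v[:, None] * p["cm"][None, :] - Y
            return float(np.mean(R * R)), {
                "cc": k * float(np.einsum("hl,h->", R, u)),
                "cm": k * np.einsum("hl,h->l", R, v),
            }

        # tighter zero-floor than training: oracle-equivalence with the
        # closed form is asserted to ~1e-6 on the concentrations
        _run_adam(loss_grad, _Adam(params, lr=lr), max_iter, tol, window,
                  "quantify", float(np.mean(Y * Y)) * 1e-6)
        c_cyt = float(params["cc"])
        c_mem = params["cm"]
    else:
        raise ValueError(f"unknown method {method!r}")
    R = c_cyt * u[:, None] + v[:, None] * c_mem[None, :] - Y
    return QuantResult(c_cyt=float(c_cyt), c_mem=np.asarray(c_mem, float),
                       loss=float(np.mean(R * R)))


def calibrate_units(record: CalibrationRecord) -> float:
    """Membrane-to-cytoplasm unit conversion from an optogenetic pair.

    Conservation of the total pool T = C + psi*c*M before and after
    recruitment gives c = (C - C') / (psi * (M' - M)), in units of length.
    """
    dM = record.M_post - record.M
    if dM == 0:
        raise ZeroDivisionError(
            "no membrane redistribution (M' == M): cannot calibrate")
    return (record.C - record.C_post) / (record.psi * dM)


def _circular_window_mean(x: np.ndarray, center: int, width: int) -> float:
    idx = (np.arange(center - width // 2, center - width // 2 + width)) % x.size
    return float(x[idx].mean())


def polarity_metrics(result: QuantResult, factor: float, psi: float,
                     window_frac: float = 0.2, posterior_frac: float = 0.5,
                     smooth: int = 21, posterior_index: Optional[int] = None) -> dict:
    """Polarity summary metrics from a quantified image.

    ``factor`` is the unit conversion from :func:`calibrate_units` (1.0 for
    already-consistent units); ``psi`` the surface-to-volume ratio in
    matching length units.  The posterior pole defaults to arc index L/2.
    Membrane means use circular windows; the posterior window covers
    ``window_frac`` of the arc centred on the pole, and the peak value is
    the best such window anywhere on the arc.
    """
    M = result.c_mem * factor
    L = M.size
    w = int(round(window_frac * L))
    if w < 1 or w > L:
        raise ValueError("window_frac out of range for this image")
    pole = L // 2 if posterior_index is None else posterior_index
    post_mem = _circular_window_mean(M, pole, w)
    mem_mean = float(M.mean())
    C = result.c_cyt
    frac_pm = psi * mem_mean / (C + psi * mem_mean) if C + psi * mem_mean != 0 else 0.0
    w50 = int(round(posterior_frac * L))
    post_amount = psi * _circular_window_mean(M, pole, w50) * posterior_frac
    frac_post_pm = post_amount / (C + psi * mem_mean) if C + psi * mem_mean != 0 else 0.0
    peak = max(_circular_window_mean(M, c, w) for c in range(L))
    kernel = np.ones(smooth) / smooth
    local = np.convolve(np.tile(M, 3), kernel, mode="same")[L:2 * L]
    local_mc = local / C if C != 0 else np.full(L, np.nan)
    return {
        "posterior_mem_mean": post_mem,
        "posterior_m_to_c": post_mem / C if C != 0 else np.nan,
        "fraction_at_pm": frac_pm,
        "fraction_at_posterior_pm": frac_post_pm,
        "peak_mem": peak,
        "local_m_to_c": local_mc,
    }


def normalize_frap(bleach_roi, control_roi, bleach_index: int,
                   post_offset: int = 2, n_pre: int = 10) -> np.ndarray:
    """Doubly normalised FRAP recovery curve.

    The bleached-ROI series is divided by the control ROI (cancelling
    acquisition drift), then scaled so the designated postbleach frame
    (``bleach_index + post_offset``; the offset skips the fast initial
    recovery phase) is 0 and the prebleach level (mean of the ``n_pre``
    frames before bleaching) is 1.
    """
    bleach = np.asarray(bleach_roi, float)
    control = np.asarray(control_roi, float)
    if bleach.shape != control.shape:
        raise ValueError("bleach and control series must align")
    if bleach_index < n_pre:
        raise ValueError(f"need at least {n_pre} prebleach frames")
    r = bleach / control
    r_pre = r[bleach_index - n_pre:bleach_index].mean()
    r_post = r[bleach_index + post_offset]
    if abs(r_pre - r_post) < 1e-12 * abs(r_pre):
        raise ValueError("no bleach detected (prebleach equals postbleach)")
    return (r - r_post) / (r_pre - r_post)


def fit_frap_rate(t, recovery) -> float:
    """Single-exponential recovery rate k from 1 - exp(-k t) (1/s)."""
    t = np.asarray(t, float)
    recovery = np.asarray(recovery, float)
    k0 = 1.0 / max(t[-1] / 3.0, 1e-9)
    popt, _ = optimize.curve_fit(lambda tt, k: 1.0 - np.exp(-k * tt),
                                 t, recovery, p0=[k0], maxfev=10_000)
    return float(popt[0])
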