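"""Image-quality metrics: SNR, relative error, SSIM, and FSIM.

SNR here uses *unsquared* Euclidean norms,

    SNR = 10 log10( ||u_ref - mean(u_ref)|| / ||u_ref - u_rec|| )  [dB],

which differs from the common ``20 log10`` convention by a factor of two in
dB; halving the error norm adds ``10 log10 2 ~ 3.01`` dB.  Relative error is
``||u_rec - u_ref|| / ||u_ref|| * 100`` in percent.

SSIM is the standard Wang et al. index (local Gaussian windows, constants
``C1 = (K1 L)^2``, ``C2 = (K2 L)^2``) and is delegated to scikit-image.

FSIM pools two per-pixel similarity maps — phase congruency (PC) and gradient
magnitude (GM) — weighted by the maximal phase congruency:

    S_PC = (2 PC1 PC2 + T1) / (PC1^2 + PC2^2 + T1)
    S_G  = (2 G1 G2 + T2) / (G1^2 + G2^2 + T2)
    FSIM = sum(S_PC^alpha S_G^beta * PCm) / sum(PCm),  PCm = max(PC1, PC2).

Phase congruency is computed with the de-facto standard multi-scale,
multi-orientation log-Gabor construction (quadrature filter energy normalized
by total amplitude, with Rayleigh-statistics noise compensation).

SSIM and FSIM expect both images on the same dynamic range, ``L = 255`` by
default; callers working with unit-intensity images should multiply by 255
first (the pipeline module does).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

__all__ = [
    "SSIMParams",
    "FSIMParams",
    "snr",
    "relative_error",
    "ssim",
    "fsim",
    "fsim_components",
    "phase_congruency",
    "gradient_magnitude",
]

_GRAD_STENCILS = {
    # x-derivative stencils; scharr/16 matches the scaling the FSIM constant
    # T2 = 160 was calibrated for on 8-bit images
    "scharr": np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0,
    "sobel": np.array([[1.0, 0.0, -1.0], [2.0, 0.0, -2.0], [1.0, 0.0, -1.0]]) / 8.0,
    "prewitt": np.array([[1.0, 0.0, -1.0], [1.0, 0.0, -1.0], [1.0, 0.0, -1.0]]) / 6.0,
}


@dataclasses.dataclass(frozen=True)
class SSIMParams:
    K1: float = 0.01
    K2: float = 0.03
    L: float = 255.0
    sigma: float = 1.5
    win_size: int = 11

    def __post_init__(self):
        if self.K1 <= 0 or self.K2 <= 0 or self.L <= 0:
            raise ValueError("K1, K2 and L must be > 0")


@dataclasses.dataclass(frozen=True)
class FSIMParams:
    T1: float = 0.85
    T2: float = 160.0
    alpha: float = 1.0
    beta: float = 1.0
    n_scales: int = 4
    n_orientations: int = 4
    min_wavelength: float = 6.0
    mult: float = 2.0
    sigma_onf: float = 0.5978
    k_noise: float = 2.0
    cut_off: float = 0.5
    cut_off_gain: float = 10.0
    gm_operator: str = "scharr"

    def __post_init__(self):
        if self.T1 <= 0 or self.T2 <= 0:
            raise ValueError("T1 and T2 must be > 0")
        if self.gm_operator not in _GRAD_STENCILS:
            raise ValueError(f"unknown gradient operator {self.gm_operator!r}")


def _pair(ref, rec):
    ref = np.asarray(ref, dtype=float)
    rec = np.asarray(rec, dtype=float)
    if ref.shape != rec.shape:
        raise ValueError(f"image shapes differ: {ref.shape} vs {rec.shape}")
    return ref, rec


def snr(ref: np.ndarray, rec: np.ndarray) -> float:
    """Signal-to-noise ratio in dB with unsquared norms (see module docs)."""
    ref, rec = _pair(ref, rec)
    signal = np.linalg.norm(ref - ref.mean())
    if signal == 0:
        raise ValueError("reference image is constant; SNR is undefined")
    err = np.linalg.norm(ref - rec)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(signal / err))


def relative_error(ref: np.ndarray, rec: np.ndarray) -> float:
    """Percent relative error ``||rec - ref|| / ||ref|| * 100``."""
    ref, rec = _pair(ref, rec)
    denom = np.linalg.norm(ref)
    if denom == 0:
        raise ValueError("reference image has zero norm")
    return float(np.linalg.norm(rec - ref) / denom * 100.0)


def ssim(ref: np.ndarray, rec: np.ndarray, p: SSIMParams | None = None) -> float:
    """Mean structural similarity over local Gaussian windows."""
    from skimage.metrics import structural_similarity

    p = p or SSIMParams()
    ref, rec = _pair(ref, rec)
    if min(ref.shape) < p.win_size:
        raise ValueError(
            f"window of size {p.win_size} larger than image {ref.shape}"
        )
    return float(
        structural_similarity(
            ref,
            rec,
            win_size=p.win_size,
            gaussian_weights=True,
            sigma=p.sigma,
            use_sample_covariance=False,
            K1=p.K1,
            K2=p.K2,
            data_range=p.L,
        )
    )


# ---------------------------------------------------------------------------
# phase congruency (log-Gabor quadrature filter bank)
# ---------------------------------------------------------------------------

_EPS = 1e-4


def _filter_bank(shape, p: FSIMParams):
    rows, cols = shape
    fy = np.fft.fftfreq(rows)
    fx = np.fft.fftfreq(cols)
    u2, u1 = np.meshgrid(fy, fx, indexing="ij")
    radius = np.hypot(u1, u2)
    radius[0, 0] = 1.0
    theta = np.arctan2(-u2, u1)

    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)
    radials = []
    for s in range(p.n_scales):
        f0 = 1.0 / (p.min_wavelength * p.mult**s)
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * np.log(p.sigma_onf) ** 2))
        lg *= lowpass
        lg[0, 0] = 0.0
        radials.append(lg)

    spreads = []
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    theta_sigma = np.pi / p.n_orientations / 1.2
    for o in range(p.n_orientations):
        angl = o * np.pi / p.n_orientations
        ds = sin_t * np.cos(angl) - cos_t * np.sin(angl)
        dc = cos_t * np.cos(angl) + sin_t * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spreads.append(np.exp(-(dtheta**2) / (2.0 * theta_sigma**2)))
    return radials, spreads


def phase_congruency(img: np.ndarray, p: FSIMParams | None = None) -> np.ndarray:
    """Per-pixel phase congruency in [0, 1].

    Quadrature log-Gabor responses are accumulated over scales for each
    orientation; local energy (the component of the responses aligned with
    the mean phase) is noise-compensated using Rayleigh statistics of the
    smallest-scale amplitude and normalized by the total amplitude sum.  The
    measure is dimensionless: invariant to positive affine rescaling of the
    input (up to the numerical stabilization constants).
    """
    p = p or FSIMParams()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if min(img.shape) < 32:
        raise ValueError("image must be at least 32x32 for the filter bank")

    IM = np.fft.fft2(img)
    radials, spreads = _filter_bank(img.shape, p)

    total_energy = np.zeros(img.shape)
    total_amplitude = np.zeros(img.shape)
    for spread in spreads:
        sum_e = np.zeros(img.shape)
        sum_o = np.zeros(img.shape)
        sum_an = np.zeros(img.shape)
        max_an = np.zeros(img.shape)
        responses = []
        tau = 0.0
        for s, radial in enumerate(radials):
            eo = np.fft.ifft2(IM * radial * spread)
            e, o_ = eo.real, eo.imag
            an = np.abs(eo)
            responses.append((e, o_))
            sum_e += e
            sum_o += o_
            sum_an += an
            max_an = np.maximum(max_an, an)
            if s == 0:
                tau = float(np.median(an)) / np.sqrt(np.log(4.0))
        x_energy = np.sqrt(sum_e**2 + sum_o**2) + _EPS
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy
        energy = np.zeros(img.shape)
        for e, o_ in responses:
            energy += e * mean_e + o_ * mean_o - np.abs(e * mean_o - o_ * mean_e)

        # expected noise energy from Rayleigh statistics of the amplitudes
        total_tau = tau * (1.0 - (1.0 / p.mult) ** p.n_scales) / (1.0 - 1.0 / p.mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2.0)
        noise_sigma = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
        energy = np.maximum(energy - (noise_mean + p.k_noise * noise_sigma), 0.0)

        # down-weight orientations with a narrow frequency spread
        width = (sum_an / (max_an + _EPS)) / p.n_scales
        weight = 1.0 / (1.0 + np.exp(p.cut_off_gain * (p.cut_off - width)))
        total_energy += weight * energy
        total_amplitude += sum_an

    pc = total_energy / (total_amplitude + _EPS)
    return np.clip(pc, 0.0, 1.0)


def gradient_magnitude(img: np.ndarray, operator: str = "scharr") -> np.ndarray:
    """``sqrt(Gx^2 + Gy^2)`` with a 3x3 derivative stencil (reflect boundary)."""
    if operator not in _GRAD_STENCILS:
        raise ValueError(f"unknown gradient operator {operator!r}")
    img = np.asarray(img, dtype=float)
    kx = _GRAD_STENCILS[operator]
    gx = ndimage.convolve(img, kx, mode="reflect")
    gy = ndimage.convolve(img, kx.T, mode="reflect")
    return np.hypot(gx, gy)


def _pool_fsim(s_l: np.ndarray, pc_m: np.ndarray) -> float:
    """Phase-congruency-weighted pooling of a similarity map."""
    denom = float(pc_m.sum())
    if denom <= 0:
        return float(np.mean(s_l))
    return float((s_l * pc_m).sum() / denom)


def fsim_components(
    ref: np.ndarray, rec: np.ndarray, p: FSIMParams | None = None
) -> dict:
    """PC/GM maps and similarity maps underlying the FSIM score."""
    p = p or FSIMParams()
    ref, rec = _pair(ref, rec)
    pc1 = phase_congruency(ref, p)
    pc2 = phase_congruency(rec, p)
    g1 = gradient_magnitude(ref, p.gm_operator)
    g2 = gradient_magnitude(rec, p.gm_operator)
    s_pc = (2.0 * pc1 * pc2 + p.T1) / (pc1**2 + pc2**2 + p.T1)
    s_g = (2.0 * g1 * g2 + p.T2) / (g1**2 + g2**2 + p.T2)
    s_l = s_pc**p.alpha * s_g**p.beta
    pc_m = np.maximum(pc1, pc2)
    return {
        "pc1": pc1,
        "pc2": pc2,
        "g1": g1,
        "g2": g2,
        "s_pc": s_pc,
        "s_g": s_g,
        "s_l": s_l,
        "pc_m": pc_m,
    }


def fsim(ref: np.ndarray, rec: np.ndarray, p: FSIMParams | None = None) -> float:
    """Feature similarity index in [0, 1] (1 exactly at identity)."""
    comp = fsim_components(ref, rec, p)
    return _pool_fsim(comp["s_l"], comp["pc_m"])
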