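"""Synthetic phantoms, variable-density k-space sampling, and the forward model.

MRI acquires Fourier coefficients of the image ("k-space").  Compressed
sensing keeps only a random subset of them, preferentially at low spatial
frequencies where most image energy lives.  This module generates ground-truth
phantoms, boolean sampling masks, the partial-Fourier measurement
``v = P F u`` (with a unitary 2D DFT, so the adjoint is the inverse transform
restricted to the mask), Gaussian/Rician noise models, and the zero-filled
baseline reconstruction.

Conventions
-----------
* Images are real 2D ``float64`` arrays with intensities nominally in [0, 1].
* k-space arrays follow the unshifted FFT layout: the DC (zero-frequency)
  coefficient sits at index ``[0, 0]``.
* The DFT is unitary (``norm="ortho"``), so Parseval holds exactly and the
  diagonal of :math:`K^*K` equals the sampling ratio.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.fft import fft2, ifft2
from scipy import ndimage

__all__ = [
    "SamplingMask",
    "KSpaceMeasurement",
    "make_phantom",
    "phantom_labels",
    "make_vardens_mask",
    "forward_measure",
    "add_noise",
    "zero_fill_recon",
]

PHANTOM_KINDS = ("piecewise", "textured", "shepp_logan")


@dataclasses.dataclass(frozen=True)
class SamplingMask:
    """Boolean k-space sampling pattern (True = coefficient acquired).

    ``selected`` uses the unshifted FFT layout (DC at ``[0, 0]``).  ``ratio``
    is the nominal fraction of acquired coefficients; the realized count is
    exactly ``round(ratio * N)``.
    """

    selected: np.ndarray
    ratio: float
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.selected.shape

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def effective_ratio(self) -> float:
        return self.n_selected / self.selected.size


@dataclasses.dataclass(frozen=True)
class KSpaceMeasurement:
    """Acquired k-space data: complex coefficients on a sampling mask.

    Entries off the mask are identically zero and carry no information.
    """

    values: np.ndarray
    mask: SamplingMask
    noise_model: str = "none"
    noise_level: float = 0.0

    def __post_init__(self):
        if self.values.shape != self.mask.selected.shape:
            raise ValueError("k-space values and mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _check_image(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={u.ndim}")
    if not np.all(np.isfinite(u)):
        raise ValueError("image contains non-finite values")
    return u


def _piecewise_regions(size: int) -> np.ndarray:
    """Label map of the piecewise phantom: 0 background, 1 ellipse body,
    2 rectangular insert, 3 small disk."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    labels = np.zeros((size, size), dtype=np.int64)
    # large elliptical body
    body = ((yy - cy) / (0.42 * size)) ** 2 + ((xx - cx) / (0.36 * size)) ** 2 <= 1.0
    labels[body] = 1
    # rectangular insert, upper half
    rect = (
        (yy > 0.22 * size)
        & (yy < 0.44 * size)
        & (xx > 0.30 * size)
        & (xx < 0.70 * size)
    )
    labels[rect & body] = 2
    # small disk, lower half
    disk = (yy - 0.66 * size) ** 2 + (xx - 0.40 * size) ** 2 <= (0.11 * size) ** 2
    labels[disk & body] = 3
    return labels


def make_phantom(kind: str, size: int, seed: int = 0) -> np.ndarray:
    """Generate a deterministic synthetic test image with values in [0, 1].

    Parameters
    ----------
    kind:
        ``"piecewise"`` — piecewise-constant regions (favourable to TV);
        ``"textured"`` — the same geometry with a band-limited pseudo-random
        texture superimposed on two regions, so that texture-preserving
        regularizers can be told apart from local TV;
        ``"shepp_logan"`` — the classic head phantom resampled to ``size``
        (alias ``"shepp_logan-like"`` accepted).
    size:
        Output side length (square image), at least 16.
    seed:
        Seeds the small intensity jitter and the texture field.  The output is
        bit-identical for a fixed ``(kind, size, seed)`` triple.
    """
    if size < 16:
        raise ValueError(f"phantom size must be >= 16, got {size}")
    kind = {"shepp_logan-like": "shepp_logan"}.get(kind, kind)
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; choose from {PHANTOM_KINDS}")

    rng = np.random.default_rng(seed)
    if kind == "shepp_logan":
        from skimage.data import shepp_logan_phantom
        from skimage.transform import resize

        base = shepp_logan_phantom()
        img = resize(base, (size, size), anti_aliasing=True)
        return np.clip(img, 0.0, 1.0)

    labels = _piecewise_regions(size)
    base_levels = np.array([0.05, 0.50, 0.90, 0.30])
    levels = np.clip(base_levels + rng.uniform(-0.03, 0.03, size=4), 0.0, 1.0)
    img = levels[labels]
    if kind == "textured":
        # band-limited texture: low-pass filtered white noise, unit variance,
        # added inside the body and the rectangular insert
        noise = rng.standard_normal((size, size))
        tex = ndimage.gaussian_filter(noise, sigma=1.0)
        tex /= tex.std()
        amp = 0.10
        region = (labels == 1) | (labels == 2)
        img = img + amp * tex * region
    return np.clip(img, 0.0, 1.0)


def phantom_labels(kind: str, size: int, seed: int = 0) -> np.ndarray:
    """Region label map matching :func:`make_phantom` (piecewise/textured only)."""
    kind = {"shepp_logan-like": "shepp_logan"}.get(kind, kind)
    if kind not in ("piecewise", "textured"):
        raise ValueError("labels are only defined for piecewise/textured phantoms")
    if size < 16:
        raise ValueError(f"phantom size must be >= 16, got {size}")
    return _piecewise_regions(size)


def make_vardens_mask(
    size: int,
    ratio: float,
    decay: float = 6.0,
    center_fraction: float = 0.04,
    seed: int = 0,
) -> SamplingMask:
    """Variable-density random sampling mask with a fully sampled center.

    The ``round(center_fraction * size**2)`` lowest-frequency points (and
    always the DC point) are acquired deterministically; the remaining points
    are drawn without replacement with probability proportional to
    ``(1 - r)**decay``, where ``r`` is the distance from DC normalized to
    [0, 1].  Exactly ``round(ratio * size**2)`` points are selected in total.
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    if not 0.0 <= center_fraction < ratio:
        raise ValueError(
            f"center_fraction must satisfy 0 <= center_fraction < ratio, "
            f"got {center_fraction} (ratio {ratio})"
        )
    if decay <= 0:
        raise ValueError(f"decay must be > 0, got {decay}")
    if size < 2:
        raise ValueError("mask size must be >= 2")

    n_total = size * size
    n_sel = int(round(ratio * n_total))
    n_center = max(int(round(center_fraction * n_total)), 1)  # at least DC
    n_sel = max(n_sel, n_center)

    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = size // 2  # DC position in fftshift-centered layout
    dist = np.hypot(yy - cy, xx - cx)
    r = dist / dist.max()

    order = np.argsort(dist.ravel(), kind="stable")
    center_idx = order[:n_center]
    pool = order[n_center:]

    n_draw = n_sel - n_center
    rng = np.random.default_rng(seed)
    chosen = np.empty(0, dtype=np.int64)
    if n_draw > 0:
        p = (1.0 - r.ravel()[pool]) ** decay
        n_pos = int((p > 0).sum())
        if n_draw <= n_pos:
            chosen = rng.choice(pool, size=n_draw, replace=False, p=p / p.sum())
        else:
            # degenerate case (ratio near 1): exhaust the weighted pool, then
            # fill uniformly from the zero-probability remainder
            pos = pool[p > 0]
            zero = pool[p == 0]
            extra = rng.choice(zero, size=n_draw - n_pos, replace=False)
            chosen = np.concatenate([pos, extra])

    flat = np.zeros(n_total, dtype=bool)
    flat[center_idx] = True
    flat[chosen] = True
    selected = np.fft.ifftshift(flat.reshape(size, size))
    assert selected[0, 0], "DC coefficient must always be sampled"
    return SamplingMask(selected=selected, ratio=float(ratio), seed=int(seed))


def forward_measure(u: np.ndarray, mask: SamplingMask) -> KSpaceMeasurement:
    """Measure ``v = P F u`` with a unitary 2D DFT; off-mask entries are zero."""
    u = _check_image(u)
    if u.shape != mask.selected.shape:
        raise ValueError(
            f"image shape {u.shape} does not match mask shape {mask.selected.shape}"
        )
    values = np.where(mask.selected, fft2(u, norm="ortho"), 0.0 + 0.0j)
    return KSpaceMeasurement(values=values, mask=mask)


def add_noise(
    m: KSpaceMeasurement,
    model: str,
    level: float,
    seed: int = 0,
    image: np.ndarray | None = None,
) -> KSpaceMeasurement:
    """Corrupt a measurement with Gaussian (k-space) or Rician (image) noise.

    ``gaussian`` adds i.i.d. complex Gaussian noise with standard deviation
    ``level`` per real/imaginary component on the acquired entries only.

    ``rician`` models magnitude MRI: the ground-truth image (which must be
    passed as ``image``) is corrupted as
    ``u_noisy = sqrt((u + n1)**2 + n2**2)`` with
    ``n1, n2 ~ N(0, (level * max(u))**2)`` (unit scale when the image is
    identically zero), then re-measured through the mask.

    ``level == 0`` returns the input unchanged.
    """
    if level < 0:
        raise ValueError(f"noise level must be >= 0, got {level}")
    if model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model {model!r}")
    if level == 0:
        return m

    rng = np.random.default_rng(seed)
    sel = m.mask.selected
    if model == "gaussian":
        noise = level * (
            rng.standard_normal(m.shape) + 1j * rng.standard_normal(m.shape)
        )
        values = np.where(sel, m.values + noise, 0.0 + 0.0j)
    else:
        if image is None:
            raise ValueError(
                "rician noise corrupts the image domain; pass the ground-truth "
                "image via the `image` argument"
            )
        u = _check_image(image)
        if u.shape != m.shape:
            raise ValueError("image shape does not match measurement shape")
        scale = float(u.max()) if u.max() > 0 else 1.0
        sigma = level * scale
        n1 = rng.normal(0.0, sigma, u.shape)
        n2 = rng.normal(0.0, sigma, u.shape)
        u_noisy = np.sqrt((u + n1) ** 2 + n2**2)
        values = np.where(sel, fft2(u_noisy, norm="ortho"), 0.0 + 0.0j)
    return KSpaceMeasurement(
        values=values, mask=m.mask, noise_model=model, noise_level=float(level)
    )


def rician_corrupt(u: np.ndarray, level: float, seed: int = 0) -> np.ndarray:
    """Magnitude-MRI (Rician) corruption of an image; helper used by tests.

    ``sqrt((u + n1)^2 + n2^2)`` with component std ``level * max(u)`` (unit
    scale for an all-zero image).
    """
    u = _check_image(u)
    if level < 0:
        raise ValueError(f"noise level must be >= 0, got {level}")
    if level == 0:
        return u.copy()
    rng = np.random.default_rng(seed)
    scale = float(u.max()) if u.max() > 0 else 1.0
    sigma = level * scale
    n1 = rng.normal(0.0, sigma, u.shape)
    n2 = rng.normal(0.0, sigma, u.shape)
    return np.sqrt((u + n1) ** 2 + n2**2)


def zero_fill_recon(m: KSpaceMeasurement) -> np.ndarray:
    """Inverse-DFT the measured coefficients with zeros elsewhere (baseline)."""
    return np.real(ifft2(m.values, norm="ortho"))
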