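"""Reading and writing images, masks, and k-space data.

Images travel as PNG/TIFF (8- or 16-bit grayscale, rescaled to [0, 1] on
load) or single-slice NIfTI.  Masks and complex k-space use NumPy's ``.npz``
container with a JSON sidecar (``<file>.json``) recording seeds, ratios,
noise parameters, and a configuration hash, so every artifact is
reproducible from its sidecar alone.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np

from .kspace import KSpaceMeasurement, SamplingMask

__all__ = [
    "load_image",
    "save_image",
    "save_mask",
    "load_mask",
    "save_kspace",
    "load_kspace",
    "write_sidecar",
    "read_sidecar",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: pathlib.Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def load_image(path) -> np.ndarray:
    """Load a grayscale image as float64 in [0, 1].

    Integer PNG/TIFF data are divided by their dtype maximum; float TIFF and
    NIfTI data are min-max rescaled when outside [0, 1].  Multi-slice NIfTI
    volumes contribute their middle slice.
    """
    path = pathlib.Path(path)
    if _is_nifti(path):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
        if data.ndim == 3:
            data = data[..., data.shape[2] // 2]
        if data.ndim != 2:
            raise ValueError(f"cannot interpret {path} as a single 2D slice")
        img = data
    else:
        import imageio.v3 as iio

        raw = iio.imread(path)
        if raw.ndim == 3:  # RGB(A): average channels
            raw = raw[..., :3].mean(axis=2)
        if np.issubdtype(raw.dtype, np.integer):
            return raw.astype(float) / np.iinfo(raw.dtype).max
        img = raw.astype(float)
    lo, hi = float(img.min()), float(img.max())
    if lo < 0.0 or hi > 1.0:
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return img


def save_image(img: np.ndarray, path) -> None:
    """Save a [0, 1] image; 16-bit PNG/TIFF, or float NIfTI."""
    path = pathlib.Path(path)
    img = np.asarray(img, dtype=float)
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(img.astype(np.float32), affine=np.eye(4)), str(path))
        return
    import imageio.v3 as iio

    scaled = np.clip(img, 0.0, 1.0)
    iio.imwrite(path, (scaled * 65535.0 + 0.5).astype(np.uint16))


def write_sidecar(path, info: dict) -> None:
    with open(str(path) + ".json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_sidecar(path) -> dict:
    with open(str(path) + ".json") as fh:
        return json.load(fh)


def save_mask(mask: SamplingMask, path, extra: dict | None = None) -> None:
    path = pathlib.Path(path)
    np.savez(path, selected=mask.selected, ratio=mask.ratio, seed=mask.seed)
    info = {
        "ratio": mask.ratio,
        "seed": mask.seed,
        "n_selected": mask.n_selected,
        "shape": list(mask.shape),
    }
    info.update(extra or {})
    write_sidecar(path.with_suffix(".npz"), info)


def load_mask(path) -> SamplingMask:
    with np.load(path) as z:
        return SamplingMask(
            selected=z["selected"], ratio=float(z["ratio"]), seed=int(z["seed"])
        )


def save_kspace(m: KSpaceMeasurement, path, extra: dict | None = None) -> None:
    path = pathlib.Path(path)
    np.savez(
        path,
        values=m.values,
        selected=m.mask.selected,
        ratio=m.mask.ratio,
        mask_seed=m.mask.seed,
        noise_model=m.noise_model,
        noise_level=m.noise_level,
    )
    info = {
        "mask_ratio": m.mask.ratio,
        "mask_seed": m.mask.seed,
        "n_selected": m.mask.n_selected,
        "noise_model": m.noise_model,
        "noise_level": m.noise_level,
        "shape": list(m.shape),
    }
    info.update(extra or {})
    write_sidecar(path.with_suffix(".npz"), info)


def load_kspace(path) -> KSpaceMeasurement:
    with np.load(path) as z:
        mask = SamplingMask(
            selected=z["selected"], ratio=float(z["ratio"]), seed=int(z["mask_seed"])
        )
        return KSpaceMeasurement(
            values=z["values"],
            mask=mask,
            noise_model=str(z["noise_model"]),
            noise_level=float(z["noise_level"]),
        )
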