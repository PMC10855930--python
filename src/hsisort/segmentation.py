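"""Background removal and per-seed mean-spectrum extraction.

A reflectance cube is reduced to a :class:`~hsisort.containers.SpectrumTable`
in two steps: threshold the band-averaged reflectance image to separate
seeds from the dark acquisition background, then average each connected
component's pixels per band.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .containers import GroundTruth, HyperCube, SpectrumTable


class DegenerateSegmentationError(ValueError):
    """Thresholding produced an all-foreground or all-background mask."""


class EmptyTableError(ValueError):
    """No object survived the minimum-size filter."""


def background_mask(
    cube: HyperCube, method: str = "otsu", threshold: Optional[float] = None
) -> np.ndarray:
    """Foreground mask from the band-averaged reflectance image.

    ``method`` is ``"otsu"`` (parameter-free, default) or ``"fixed"`` with
    an explicit ``threshold`` on mean reflectance.
    """
    if cube.kind != "reflectance":
        raise ValueError("background_mask expects a reflectance cube")
    mean_img = cube.data.mean(axis=2)
    if method == "otsu":
        if np.ptp(mean_img) == 0:
            raise DegenerateSegmentationError("uniform image: no threshold exists")
        thr = threshold_otsu(mean_img)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = mean_img > thr
    n_fg = int(mask.sum())
    if n_fg == 0 or n_fg == mask.size:
        raise DegenerateSegmentationError(
            f"degenerate mask: {n_fg}/{mask.size} foreground pixels "
            f"(threshold {thr:.4g}, image range "
            f"{mean_img.min():.4g}..{mean_img.max():.4g})"
        )
    return mask


def extract_mean_spectra(
    cube: HyperCube,
    mask: np.ndarray,
    min_object_size: int = 20,
    connectivity: int = 8,
    labels: Optional[list] = None,
    truth: Optional[GroundTruth] = None,
) -> SpectrumTable:
    """Mean reflectance spectrum of every connected foreground object.

    Objects smaller than ``min_object_size`` pixels are dropped.  Object
    order is deterministic: row-major by centroid.  If ``truth`` is given,
    each object is labelled with the ground-truth class occupying the
    majority of its pixels (synthetic scenes); alternatively an explicit
    per-object ``labels`` list may be supplied after the fact.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    lab, n = ndimage.label(mask, structure=structure)
    if n == 0:
        raise EmptyTableError("mask contains no foreground component")
    ids = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, ids).astype(int)
    keep = ids[sizes >= min_object_size]
    if keep.size == 0:
        raise EmptyTableError(
            f"all {n} components are below min_object_size={min_object_size}"
        )
    centroids = ndimage.center_of_mass(mask, lab, keep)
    order = np.lexsort(
        (np.array([c[1] for c in centroids]), np.array([c[0] for c in centroids]))
    )
    keep = keep[order]

    spectra = np.empty((keep.size, cube.n_bands))
    for band in range(cube.n_bands):
        spectra[:, band] = ndimage.mean(cube.data[:, :, band], lab, keep)
    pixel_counts = ndimage.sum_labels(np.ones_like(lab), lab, keep).astype(int)

    out_labels = labels
    if truth is not None:
        out_labels = []
        for obj in keep:
            region = truth.label_image[lab == obj]
            region = region[region > 0]
            if region.size == 0:
                out_labels.append("unknown")
            else:
                counts = np.bincount(region)
                out_labels.append(truth.object_classes[int(np.argmax(counts))])
    return SpectrumTable(
        spectra=spectra,
        wavelengths=cube.wavelengths.copy(),
        labels=out_labels,
        object_ids=[int(i) for i in range(1, keep.size + 1)],
        pixel_counts=pixel_counts,
    )
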