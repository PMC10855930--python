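"""Core data containers shared across the pipeline.

The pipeline operates on three kinds of objects: hyperspectral cubes
(rows x cols x bands arrays with a wavelength axis), per-object mean
spectra tables (the feature matrix all statistics run on), and ground
truth for synthetic scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

# The acquisition covers 400-1700 nm at a 5 nm sampling step on a single
# fused VNIR/SWIR axis: 261 bands.
WL_MIN = 400.0
WL_MAX = 1700.0
WL_STEP = 5.0
N_BANDS = 261

LEGUME_CLASSES = frozenset({"broad_bean", "chickpea", "lentil"})
CONTAMINANT_CLASSES = frozenset({"wheat", "oat", "barley", "stone"})


def default_wavelengths() -> np.ndarray:
    """The full candidate wavelength grid (nm)."""
    wl = np.arange(WL_MIN, WL_MAX + WL_STEP / 2, WL_STEP, dtype=float)
    assert wl.size == N_BANDS
    return wl


def is_legume(class_name: str) -> bool:
    if class_name in LEGUME_CLASSES:
        return True
    if class_name in CONTAMINANT_CLASSES:
        return False
    raise ValueError(f"unknown class name: {class_name!r}")


@dataclass
class HyperCube:
    """A hyperspectral image: rows x cols x bands with its wavelength axis.

    ``kind`` flags whether values are raw sensor counts or calibrated
    relative reflectance.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"  # "raw" | "reflectance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"bands dimension {self.data.shape[2]} does not match "
                f"wavelength axis length {self.wavelengths.size}"
            )
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength: float) -> int:
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[idx] - wavelength) > 1e-6:
            raise ValueError(f"wavelength {wavelength} nm not on the cube grid")
        return idx


@dataclass
class ReferenceFrames:
    """Dark and white reference acquisitions used by flat-field calibration.

    References may be full-frame or single-line (rows == 1); single-line
    references are broadcast across the image rows, matching line-scanner
    practice.
    """

    dark: HyperCube
    white: HyperCube

    def __post_init__(self) -> None:
        if self.dark.data.shape != self.white.data.shape:
            raise ValueError("dark and white frames must share a shape")


@dataclass
class GroundTruth:
    """Per-pixel object labels for a synthetic scene (0 = background)."""

    label_image: np.ndarray
    object_classes: dict  # object id -> class name

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        ids = set(np.unique(self.label_image).tolist()) - {0}
        if not ids <= set(self.object_classes):
            raise ValueError("label image contains ids missing from object_classes")

    @property
    def n_objects(self) -> int:
        return len(self.object_classes)


@dataclass
class SpectrumTable:
    """Per-object mean reflectance spectra with class labels.

    Rows are objects (seeds), columns are wavelengths. This is the feature
    table that wavelength selection and classification run on, and the CSV
    interchange object between pipeline stages.
    """

    spectra: np.ndarray  # n_objects x n_bands
    wavelengths: np.ndarray
    labels: Optional[list] = None  # per-object class name, None if unlabelled
    object_ids: Optional[list] = None
    pixel_counts: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)  # per-table annotations

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.shape[1] != self.wavelengths.size:
            raise ValueError("spectra width does not match wavelength axis")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra must be finite")
        n = self.spectra.shape[0]
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length mismatch")
        if self.object_ids is None:
            self.object_ids = list(range(1, n + 1))
        if self.pixel_counts is None:
            self.pixel_counts = np.ones(n, dtype=int)
        else:
            self.pixel_counts = np.asarray(self.pixel_counts, dtype=int)

    def __len__(self) -> int:
        return self.spectra.shape[0]

    def binary_labels(self) -> np.ndarray:
        """+1 for legumes (the accept class), -1 for contaminants."""
        if self.labels is None:
            raise ValueError("table is unlabelled")
        return np.array([1 if is_legume(c) else -1 for c in self.labels])

    def band_index(self, wavelength: float) -> int:
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[idx] - wavelength) > 1e-6:
            raise ValueError(f"wavelength {wavelength} nm not on the table grid")
        return idx

    def restrict(self, wavelengths: Sequence[float]) -> np.ndarray:
        """Feature matrix restricted to the given wavelengths (in order)."""
        cols = [self.band_index(w) for w in wavelengths]
        return self.spectra[:, cols]

    def subset(self, rows: np.ndarray) -> "SpectrumTable":
        rows = np.asarray(rows)
        return SpectrumTable(
            spectra=self.spectra[rows],
            wavelengths=self.wavelengths,
            labels=None if self.labels is None else [self.labels[i] for i in rows],
            object_ids=[self.object_ids[i] for i in rows],
            pixel_counts=self.pixel_counts[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"R{int(round(w)):04d}": self.spectra[:, i]
                for i, w in enumerate(self.wavelengths)}
        df = pd.DataFrame(
            {
                "object_id": self.object_ids,
                "class": self.labels if self.labels is not None else [""] * len(self),
                "pixel_count": self.pixel_counts,
                **cols,
            }
        )
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectrumTable":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c.startswith("R") and c[1:].isdigit()]
        wl = np.array([float(c[1:]) for c in wl_cols])
        labels = df["class"].astype(str).tolist() if "class" in df else None
        if labels is not None and all(l in ("", "nan") for l in labels):
            labels = None
        return cls(
            spectra=df[wl_cols].to_numpy(dtype=float),
            wavelengths=wl,
            labels=labels,
            object_ids=df["object_id"].tolist() if "object_id" in df else None,
            pixel_counts=df["pixel_count"].to_numpy() if "pixel_count" in df else None,
        )
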