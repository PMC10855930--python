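"""Synthetic hyperspectral scenes, reference frames and seed streams.

The generator emulates a line-scan acquisition of legume and cereal seeds
on a dark background over a fused 400-1700 nm axis sampled every 5 nm
(261 bands).  Class endmember spectra are smooth curves that share a
common baseline; class contrast is planted at a small number of known
wavelengths per legume/contaminant pair, so that wavelength selection has
a recoverable ground truth.

Per-seed variation has three components:

* a multiplicative log-normal brightness factor (intact vs. non-intact
  units, illumination geometry);
* a structured spectral fluctuation confined to each pair's planted bands
  and orthogonal to the class-contrast direction.  This models correlated
  surface-chemistry variation and is what makes single planted bands
  insufficient on their own: a classifier needs the full planted set to
  project the fluctuation out;
* additive sensor noise.

A configurable fraction of seeds is "orientation degraded" (the unit
falls profile-on and under-exposes its surface to the optics): its
spectrum is strongly attenuated and flattened, which is the mechanism
behind the small false-negative rate a deployed sorter shows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.ndimage import gaussian_filter1d

from .containers import (
    CONTAMINANT_CLASSES,
    LEGUME_CLASSES,
    WL_STEP,
    GroundTruth,
    HyperCube,
    ReferenceFrames,
    SpectrumTable,
    default_wavelengths,
)

# --------------------------------------------------------------------------
# Generator defaults: these are the study conditions every experiment and
# test runs under (see docs/methods.md for the rationale behind each).
DEFAULT_CONTRAST = 0.2            # reflectance offset planted per band
DEFAULT_SMOOTHNESS = 80.0         # endmember correlation length, nm
DEFAULT_BRIGHTNESS_SIGMA = 0.05   # log-sd of per-seed brightness
DEFAULT_JITTER_SD = 0.095         # base sd of structured per-seed fluctuation
DEFAULT_STREAM_NOISE_SD = 0.01    # additive reflectance noise per seed/band
DEFAULT_ORIENTATION_NOISE = 0.005  # fraction of profile-on (degraded) seeds
DEFAULT_ATTENUATION = (0.1, 0.45)  # exposure factor of degraded seeds
DEFAULT_FLATTEN = (0.0, 0.3)       # spectral flattening of degraded seeds

#: Planted discriminative wavelengths per legume/contaminant pair.  These
#: place the synthetic class contrast at the wavelengths the real
#: acquisition campaign found informative, so selection experiments run
#: against plausible targets.
DEFAULT_PAIR_BANDS: Dict[Tuple[str, str], List[float]] = {
    ("broad_bean", "wheat"): [810.0, 1455.0],
    ("broad_bean", "oat"): [530.0, 655.0, 810.0, 1190.0],
    ("lentil", "wheat"): [615.0, 1015.0],
    ("lentil", "oat"): [575.0, 1265.0],
    ("chickpea", "wheat"): [670.0, 1100.0, 1595.0],
    ("chickpea", "oat"): [845.0, 1075.0, 1310.0, 1510.0, 1660.0],
}


class GridError(ValueError):
    """A planted band does not lie on the 5 nm wavelength grid."""


class RangeError(ValueError):
    """Requested contrasts push endmember reflectance outside [0, 1]."""


class GeometryError(ValueError):
    """Scene objects overlap."""


class InfeasiblePairSystemError(ValueError):
    """The requested pair/band constraints cannot be satisfied jointly."""


@dataclass
class SpectralLibrary:
    """Class endmember spectra plus the planted-contrast bookkeeping."""

    wavelengths: np.ndarray
    endmembers: Dict[str, np.ndarray]
    class_names: List[str]
    informative_bands: Dict[Tuple[str, str], List[float]]
    contrast: Dict[Tuple[str, str], Dict[float, float]]
    # per pair: (planted band indices, smooth full-axis fluctuation curves
    # whose planted-band values form an orthonormal basis of the subspace
    # orthogonal to the class-contrast direction)
    nuisance: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def band_index(self, wavelength: float) -> int:
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[idx] - wavelength) > 1e-6:
            raise GridError(f"wavelength {wavelength} nm is not on the grid")
        return idx

    @property
    def legume_classes(self) -> List[str]:
        return [c for c in self.class_names if c in LEGUME_CLASSES]

    @property
    def contaminant_classes(self) -> List[str]:
        return [c for c in self.class_names if c in CONTAMINANT_CLASSES]


def _smooth_curve(rng: np.random.Generator, n: int, smoothness: float) -> np.ndarray:
    """Unit-amplitude smooth random curve with the given correlation length."""
    sigma = max(smoothness / WL_STEP, 1.0)
    raw = gaussian_filter1d(rng.standard_normal(n + int(6 * sigma)), sigma)
    raw = raw[int(3 * sigma):int(3 * sigma) + n]
    amp = np.max(np.abs(raw))
    return raw / amp if amp > 0 else raw


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _normalise_pair_contrasts(pair_contrasts, wavelengths) -> Dict[tuple, Dict[float, float]]:
    """Accept {pair: {band: contrast}} or {pair: (bands, scalar contrast)}."""
    out: Dict[tuple, Dict[float, float]] = {}
    grid = set(np.round(wavelengths, 6).tolist())
    for pair, val in pair_contrasts.items():
        pair = tuple(pair)
        if len(pair) != 2 or pair[0] == pair[1]:
            raise ValueError(f"invalid class pair {pair!r}")
        if isinstance(val, dict):
            bands = {float(b): float(c) for b, c in val.items()}
        else:
            band_list, c = val
            bands = {float(b): float(c) for b in band_list}
        for b, c in bands.items():
            if round(b, 6) not in grid:
                raise GridError(f"planted band {b} nm is off the 5 nm grid")
            if not (0.0 <= c < 1.0):
                raise RangeError(f"contrast {c} outside [0, 1)")
        out[pair] = bands
    return out


def make_spectral_library(
    pair_contrasts: Dict[tuple, object],
    smoothness: float = DEFAULT_SMOOTHNESS,
    rng_seed: int = 0,
    *,
    include_stone: bool = False,
) -> SpectralLibrary:
    """Build class endmember spectra with contrast planted per class pair.

    ``pair_contrasts`` maps a (class_a, class_b) pair either to
    ``{band_nm: contrast}`` or to ``(band_list, contrast)``.  At every
    planted band the two classes differ by at least the requested contrast;
    at every other band classes constrained by a pair differ by at most a
    fifth of that pair's smallest contrast.  Raises
    :class:`InfeasiblePairSystemError` when the requested pair system has
    contradictory per-band constraints (a class required to both match and
    differ from another through a chain of pairs).
    """
    rng = np.random.default_rng(rng_seed)
    wavelengths = default_wavelengths()
    pairs = _normalise_pair_contrasts(pair_contrasts, wavelengths)
    classes = sorted({c for pair in pairs for c in pair})
    if not classes:
        raise ValueError("at least one class pair is required")

    # Shared smooth baseline keeps all classes spectrally realistic and
    # mutually similar away from planted bands.
    base = 0.5 + 0.12 * _smooth_curve(rng, wavelengths.size, smoothness)

    # Away from planted bands all classes share the baseline exactly: the
    # class signal lives only at the planted wavelengths, mirroring an
    # acquisition where a handful of bands carry the discriminative
    # chemistry (the pair-difference cap of contrast/5 holds trivially).

    # Per planted band, solve the level-assignment problem: pairs planted at
    # the band must differ, pairs not planted there must coincide.
    offsets = {c: np.zeros(wavelengths.size) for c in classes}
    all_planted = sorted({b for bands in pairs.values() for b in bands})
    for j, band in enumerate(all_planted):
        uf = _UnionFind(classes)
        differ = []
        for (a, b), bands in pairs.items():
            if band in bands:
                if bands[band] > 0:
                    differ.append((a, b, bands[band]))
            else:
                uf.union(a, b)
        comp_of = {c: uf.find(c) for c in classes}
        involved = []
        for a, b, c in differ:
            if comp_of[a] == comp_of[b]:
                raise InfeasiblePairSystemError(
                    f"at {band} nm classes {a!r} and {b!r} must differ by {c} "
                    "but are chained equal through other pairs"
                )
            for r in (comp_of[a], comp_of[b]):
                if r not in involved:
                    involved.append(r)
        if not differ:
            continue
        # The first class of a pair takes the high-reflectance side of its
        # planted bands, so the accept class is consistently the brighter
        # one at its signature wavelengths; under-exposed (profile-on)
        # seeds therefore always drift away from the accept signature.
        firsts = {comp_of[a] for a, _, _ in differ}
        involved.sort(key=lambda r: (r not in firsts, r))
        involved.reverse()  # ascending: non-first components lowest
        spacing = max(c for _, _, c in differ)
        positions = {r: i * spacing for i, r in enumerate(involved)}
        centre = (len(involved) - 1) * spacing / 2.0
        idx = int(np.argmin(np.abs(wavelengths - band)))
        for c in classes:
            r = comp_of[c]
            if r in positions:
                offsets[c][idx] = positions[r] - centre

    # Absorption features have finite spectral width: each planted offset
    # gets shoulders one grid step away at a fifth of its height (the cap
    # the off-band contract allows), so a 15 nm broadband window retains
    # most of the class contrast.  Shoulders never touch other planted
    # bands, whose own constraint systems take precedence.
    planted_idx = {int(np.argmin(np.abs(wavelengths - b))) for b in all_planted}
    for c in classes:
        shoulders = np.zeros_like(offsets[c])
        for i in planted_idx:
            for j in (i - 1, i + 1):
                if 0 <= j < wavelengths.size and j not in planted_idx:
                    shoulders[j] += 0.2 * offsets[c][i]
        offsets[c] = offsets[c] + shoulders

    endmembers = {c: base + offsets[c] for c in classes}
    if include_stone:
        endmembers["stone"] = np.full(wavelengths.size, 0.08)
        classes = classes + ["stone"]

    for c, e in endmembers.items():
        if e.min() < 0.0 or e.max() > 1.0:
            raise RangeError(
                f"endmember for {c!r} leaves [0, 1] "
                f"(range {e.min():.3f}..{e.max():.3f})"
            )

    # Verify the planted-contrast contract.
    for (a, b), bands in pairs.items():
        diff = endmembers[a] - endmembers[b]
        for band, c in bands.items():
            idx = int(np.argmin(np.abs(wavelengths - band)))
            if c > 0 and abs(diff[idx]) < c - 1e-9:
                raise InfeasiblePairSystemError(
                    f"planted contrast at {band} nm for {(a, b)} not achieved"
                )

    informative = {pair: sorted(bands) for pair, bands in pairs.items()}
    nuisance = {}
    bump_width = max(smoothness / 2.0, WL_STEP)
    for pair, bands in pairs.items():
        band_list = informative[pair]
        idx = np.array([int(np.argmin(np.abs(wavelengths - b))) for b in band_list])
        delta = (endmembers[pair[0]] - endmembers[pair[1]])[idx]
        if len(idx) >= 2 and np.linalg.norm(delta) > 0:
            dirs = null_space(delta[None, :]).T  # (k-1, k), orthonormal
        else:
            dirs = np.zeros((0, len(idx)))
        # Extend each direction into a smooth curve over the whole axis that
        # interpolates its planted-band values exactly: correlated spectral
        # fluctuation looks like broad wiggle, not isolated spikes.
        centres = wavelengths[idx]
        phi = np.exp(-((wavelengths[:, None] - centres[None, :]) ** 2)
                     / (2 * bump_width**2))  # (n_bands, k)
        m = phi[idx, :]                      # (k, k), near identity
        if dirs.shape[0]:
            coeffs = np.linalg.solve(m.T, dirs.T).T   # rows solve M c = u
            dirs_full = coeffs @ phi.T                # (k-1, n_bands)
            # Amplitude grows with the planted-set size k so that no proper
            # subset of planted bands separates the classes on its own: the
            # least-fluctuation direction within any j < k planted bands
            # keeps enough variance to blur the class contrast.
            dirs_full *= np.sqrt(len(idx) * (len(idx) - 1) / 2.0)
        else:
            dirs_full = np.zeros((0, wavelengths.size))
        nuisance[pair] = (idx, dirs_full)

    return SpectralLibrary(
        wavelengths=wavelengths,
        endmembers=endmembers,
        class_names=classes,
        informative_bands=informative,
        contrast=pairs,
        nuisance=nuisance,
    )


def library_for_pair(
    legume: str,
    contaminant: str,
    contrast: float = DEFAULT_CONTRAST,
    bands: Optional[Sequence[float]] = None,
    rng_seed: int = 0,
    **kwargs,
) -> SpectralLibrary:
    """Two-class library for one legume/contaminant dataset."""
    if bands is None:
        bands = DEFAULT_PAIR_BANDS[(legume, contaminant)]
    return make_spectral_library(
        {(legume, contaminant): (list(bands), contrast)}, rng_seed=rng_seed, **kwargs
    )


def library_for_deployment(
    legume: str,
    contrast: float = DEFAULT_CONTRAST,
    rng_seed: int = 0,
    **kwargs,
) -> SpectralLibrary:
    """Three-class library for the sorter setting: one legume vs both
    contaminants (wheat and oat) simultaneously."""
    pair_contrasts = {
        (legume, "wheat"): (DEFAULT_PAIR_BANDS[(legume, "wheat")], contrast),
        (legume, "oat"): (DEFAULT_PAIR_BANDS[(legume, "oat")], contrast),
    }
    return make_spectral_library(pair_contrasts, rng_seed=rng_seed, **kwargs)


# --------------------------------------------------------------------------
# Scenes


@dataclass
class SceneObject:
    class_name: str
    center: Tuple[float, float]       # (row, col), px
    axes: Tuple[float, float]         # ellipse semi-axes (row, col), px
    brightness_scale: float = 1.0


@dataclass
class SceneSpec:
    """Geometry and acquisition parameters of one synthetic scene."""

    image_shape: Tuple[int, int] = (120, 160)
    objects: List[SceneObject] = field(default_factory=list)
    background_level: float = 100.0        # dark raw-count level
    white_span: float = 4000.0             # white minus dark raw counts
    noise_sd: float = 20.0                 # additive raw-count noise sd
    background_reflectance: float = 0.02
    illumination_profile: Optional[np.ndarray] = None  # per column, > 0
    spectral_jitter_sd: float = 0.0
    brightness_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for obj in self.objects:
            if obj.brightness_scale <= 0:
                raise ValueError("brightness_scale must be > 0")


def _paint_ellipse(label_image: np.ndarray, obj: SceneObject, obj_id: int) -> None:
    rows, cols = label_image.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    inside = (
        ((rr - obj.center[0]) / obj.axes[0]) ** 2
        + ((cc - obj.center[1]) / obj.axes[1]) ** 2
    ) <= 1.0
    if np.any(label_image[inside] != 0):
        raise GeometryError(f"object {obj_id} overlaps a previously placed object")
    label_image[inside] = obj_id


def _pair_jitter(
    rng: np.random.Generator,
    library: SpectralLibrary,
    n: int,
    sd: float,
    n_bands: int,
) -> np.ndarray:
    """Structured per-seed spectral fluctuation (n x n_bands).

    Drawn independently per pair along the orthonormal directions of the
    planted-band subspace orthogonal to the class contrast, so it never
    moves a seed along the discriminative direction itself.
    """
    out = np.zeros((n, n_bands))
    if sd <= 0:
        return out
    for pair in sorted(library.nuisance):
        _, dirs_full = library.nuisance[pair]
        if dirs_full.shape[0] == 0:
            continue
        coeff = rng.normal(0.0, sd, size=(n, dirs_full.shape[0]))
        out += coeff @ dirs_full
    return out


def render_scene(
    spec: SceneSpec, library: SpectralLibrary
) -> Tuple[HyperCube, ReferenceFrames, GroundTruth]:
    """Render a raw-count scene plus matching dark/white reference frames.

    Construction guarantees that flat-field calibration of a noiseless
    scene recovers ``endmember * brightness_scale`` exactly at object
    pixels and ``background_reflectance`` outside.
    """
    for obj in spec.objects:
        if obj.class_name not in library.endmembers:
            raise ValueError(f"class {obj.class_name!r} not in library")
    rng = np.random.default_rng(spec.rng_seed)
    rows, cols = spec.image_shape
    n_bands = library.wavelengths.size

    illum = (
        np.ones(cols)
        if spec.illumination_profile is None
        else np.asarray(spec.illumination_profile, dtype=float)
    )
    if illum.size != cols or np.any(illum <= 0):
        raise ValueError("illumination profile must be positive, one value per column")

    label_image = np.zeros((rows, cols), dtype=np.int32)
    for i, obj in enumerate(spec.objects, start=1):
        _paint_ellipse(label_image, obj, i)

    jitter = _pair_jitter(rng, library, len(spec.objects), spec.spectral_jitter_sd, n_bands)
    if spec.brightness_sigma > 0:
        bright = np.exp(rng.normal(0.0, spec.brightness_sigma, size=len(spec.objects)))
    else:
        bright = np.ones(len(spec.objects))

    refl = np.full((rows, cols, n_bands), spec.background_reflectance)
    for i, obj in enumerate(spec.objects, start=1):
        spectrum = (
            (library.endmembers[obj.class_name] + jitter[i - 1])
            * obj.brightness_scale
            * bright[i - 1]
        )
        refl[label_image == i] = spectrum

    signal = spec.background_level + illum[None, :, None] * refl * spec.white_span
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
    raw = HyperCube(np.clip(signal, 0.0, None), library.wavelengths, kind="raw")

    dark = HyperCube(
        np.full((rows, cols, n_bands), spec.background_level),
        library.wavelengths,
        kind="raw",
    )
    white = HyperCube(
        spec.background_level + illum[None, :, None] * spec.white_span
        * np.ones((rows, cols, n_bands)),
        library.wavelengths,
        kind="raw",
    )
    truth = GroundTruth(
        label_image=label_image,
        object_classes={i + 1: obj.class_name for i, obj in enumerate(spec.objects)},
    )
    return raw, ReferenceFrames(dark=dark, white=white), truth


def random_scene_spec(
    class_counts: Dict[str, int],
    image_shape: Tuple[int, int] = (120, 160),
    rng_seed: int = 0,
    *,
    spectral_jitter_sd: float = DEFAULT_JITTER_SD,
    brightness_sigma: float = DEFAULT_BRIGHTNESS_SIGMA,
    **scene_kwargs,
) -> SceneSpec:
    """Place non-touching elliptical seeds of the requested classes.

    Seed size follows the product: broad beans are large, chickpeas
    intermediate, lentils and cereal kernels small.
    """
    axes_by_class = {
        "broad_bean": (9.0, 6.5),
        "chickpea": (6.0, 5.5),
        "lentil": (4.0, 4.0),
        "wheat": (5.0, 3.0),
        "oat": (6.0, 3.0),
        "barley": (5.5, 3.0),
        "stone": (5.0, 4.5),
    }
    rng = np.random.default_rng(rng_seed)
    rows, cols = image_shape
    objects: List[SceneObject] = []
    placed: List[Tuple[float, float, float, float]] = []
    class_list = [c for c, n in sorted(class_counts.items()) for _ in range(n)]
    rng.shuffle(class_list)
    for cls in class_list:
        ar, ac = axes_by_class.get(cls, (5.0, 4.0))
        ar *= 0.85 + 0.3 * rng.random()
        ac *= 0.85 + 0.3 * rng.random()
        for _ in range(2000):
            r = rng.uniform(ar + 1, rows - ar - 1)
            c = rng.uniform(ac + 1, cols - ac - 1)
            # conservative disjointness: centre distance outside the
            # summed-axes ellipse guarantees the ellipses do not touch
            ok = all(
                ((r - r2) / (ar + ar2 + 1)) ** 2 + ((c - c2) / (ac + ac2 + 1)) ** 2 > 1.0
                for r2, c2, ar2, ac2 in placed
            )
            if ok:
                placed.append((r, c, ar, ac))
                objects.append(SceneObject(cls, (r, c), (ar, ac)))
                break
        else:
            raise GeometryError(
                f"could not place {len(class_list)} objects in a {image_shape} scene"
            )
    return SceneSpec(
        image_shape=image_shape,
        objects=objects,
        rng_seed=rng_seed,
        spectral_jitter_sd=spectral_jitter_sd,
        brightness_sigma=brightness_sigma,
        **scene_kwargs,
    )


# --------------------------------------------------------------------------
# Seed streams


def make_seed_stream(
    n_legumes: int,
    dose: Dict[str, float],
    library: SpectralLibrary,
    orientation_noise: float = DEFAULT_ORIENTATION_NOISE,
    rng_seed: int = 0,
    *,
    legume_class: Optional[str] = None,
    brightness_sigma: float = DEFAULT_BRIGHTNESS_SIGMA,
    spectral_jitter_sd: float = DEFAULT_JITTER_SD,
    noise_sd: float = DEFAULT_STREAM_NOISE_SD,
    attenuation_range: Tuple[float, float] = DEFAULT_ATTENUATION,
    flatten_range: Tuple[float, float] = DEFAULT_FLATTEN,
) -> SpectrumTable:
    """Simulate the per-seed spectra of a contaminated product stream.

    ``n_legumes`` legume seeds are polluted with each contaminant class in
    ``dose`` at the given rate (counts drawn binomially).  With probability
    ``orientation_noise`` a seed falls profile-on: its spectrum is
    attenuated and flattened, degrading the spectral evidence the
    classifier relies on.
    """
    if any(d < 0 for d in dose.values()) or sum(dose.values()) >= 1.0:
        raise ValueError("dose fractions must be >= 0 and sum to < 1")
    if not 0.0 <= orientation_noise <= 1.0:
        raise ValueError("orientation_noise is a probability")
    if legume_class is None:
        legumes = library.legume_classes
        if len(legumes) != 1:
            raise ValueError("legume_class is ambiguous; pass it explicitly")
        legume_class = legumes[0]
    for cls in dose:
        if cls not in library.endmembers:
            raise ValueError(f"dose class {cls!r} not in library")

    rng = np.random.default_rng(rng_seed)
    classes = [legume_class] * n_legumes
    for cls in sorted(dose):
        classes += [cls] * int(rng.binomial(n_legumes, dose[cls]))
    classes = [classes[i] for i in rng.permutation(len(classes))]
    n = len(classes)
    n_bands = library.wavelengths.size

    emat = np.stack([library.endmembers[c] for c in classes])
    emat = emat + _pair_jitter(rng, library, n, spectral_jitter_sd, n_bands)
    if brightness_sigma > 0:
        emat *= np.exp(rng.normal(0.0, brightness_sigma, size=n))[:, None]

    degraded = rng.random(n) < orientation_noise
    if degraded.any():
        k = int(degraded.sum())
        atten = rng.uniform(*attenuation_range, size=k)
        flat = rng.uniform(*flatten_range, size=k)
        sub = emat[degraded]
        mean = sub.mean(axis=1, keepdims=True)
        emat[degraded] = atten[:, None] * ((1 - flat[:, None]) * sub + flat[:, None] * mean)

    if noise_sd > 0:
        emat = emat + rng.normal(0.0, noise_sd, size=emat.shape)
    # negative excursions are kept: flat-field reflectance is not clipped

    return SpectrumTable(
        spectra=emat,
        wavelengths=library.wavelengths.copy(),
        labels=classes,
        meta={"degraded": degraded},
    )


# --------------------------------------------------------------------------
# Scene export (ENVI cube + label image + object table)


def write_scene(
    outdir,
    raw: HyperCube,
    refs: ReferenceFrames,
    truth: GroundTruth,
) -> None:
    """Write a rendered scene as ENVI files plus plain-text ground truth."""
    from .calibration import write_envi

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_envi(raw, outdir / "scene.hdr")
    write_envi(refs.dark, outdir / "dark.hdr")
    write_envi(refs.white, outdir / "white.hdr")
    labels = HyperCube(
        truth.label_image[:, :, None].astype(float), np.array([0.0]), kind="raw"
    )
    write_envi(labels, outdir / "labels.hdr", dtype=np.uint16)
    pd.DataFrame(
        {
            "object_id": sorted(truth.object_classes),
            "class": [truth.object_classes[i] for i in sorted(truth.object_classes)],
        }
    ).to_csv(outdir / "objects.csv", index=False)
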