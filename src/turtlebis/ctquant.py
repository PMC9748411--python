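"""HU-threshold adipose quantification with false-positive removal.

Mirrors the two-step hybrid protocol: (1) per-voxel Hounsfield-unit
thresholding of the attenuation range occupied by adipose tissue, which
leaves negligible false negatives but substantial false positives (skin
folds, air-lung transitions, pericardium, gut contents, the scanner table);
(2) removal of the false positives. The trained segmentation network that
performed step 2 in the original workflow is out of scope here: the module
exposes a pluggable interface with an *oracle* implementation (subtracts the
phantom's ground-truth class masks) and a *rules* implementation
(connected-component and morphology heuristics) standing in for it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, signal

from .errors import ArgumentError, ConsistencyError
from .synthetic import PhantomTruth

__all__ = [
    "CTVolume",
    "HURange",
    "SegmentationMaskSet",
    "CompositionEstimate",
    "DEFAULT_HU_RANGE",
    "estimate_hu_range",
    "threshold_segment",
    "remove_false_positives",
    "quantify",
    "read_volume",
    "write_volume",
    "write_mask_labels",
    "read_mask_labels",
    "MASK_LABELS",
]

#: integer label convention for mask volumes written to NIfTI
MASK_LABELS = {"background": 0, "adipose": 1, "A": 2, "B": 3, "C": 4, "D": 5, "table": 6}

_CONN26 = np.ones((3, 3, 3), bool)


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units with its voxel geometry.

    ``hu`` is indexed (slice, row, col). Spacings are in mm; the voxel volume
    uses the spacing *between* slices, not the slice thickness, because
    overlapping helical reconstructions (1.25 mm thick slices every 0.625 mm)
    would otherwise double-count volume.
    """

    hu: np.ndarray
    in_plane_spacing: float
    slice_spacing: float
    slice_thickness: float

    def __post_init__(self) -> None:
        if self.in_plane_spacing <= 0 or self.slice_spacing <= 0 or self.slice_thickness <= 0:
            raise ArgumentError("spacings must be positive")
        if self.hu.ndim != 3:
            raise ArgumentError("hu grid must be 3-D (slice, row, col)")
        if self.hu.min() < -1024 or self.hu.max() > 3071:
            raise ArgumentError("HU values must lie within [-1024, 3071]")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.in_plane_spacing ** 2 * self.slice_spacing


@dataclass(frozen=True)
class HURange:
    """An attenuation interval [hu_min, hu_max], inclusive on both ends.

    ``fallback`` flags that the estimator could not resolve an adipose mode
    and returned the configured default range.
    """

    hu_min: float
    hu_max: float
    fallback: bool = False

    def __post_init__(self) -> None:
        if not self.hu_min < self.hu_max:
            raise ArgumentError("require hu_min < hu_max")


#: population-mean adipose attenuation range used as the estimator fallback
DEFAULT_HU_RANGE = HURange(-32.2, 10.1, fallback=True)


@dataclass
class SegmentationMaskSet:
    """Candidate mask, per-class removed masks, and the final adipose mask."""

    candidate: np.ndarray
    removed: dict[str, np.ndarray]
    final_adipose: np.ndarray

    def __post_init__(self) -> None:
        removed_union = np.zeros_like(self.candidate)
        for m in self.removed.values():
            removed_union |= m
        expected = self.candidate & ~removed_union
        if not np.array_equal(self.final_adipose, expected):
            raise ConsistencyError("final_adipose must equal candidate minus removals")


@dataclass(frozen=True)
class CompositionEstimate:
    """Adipose volume/fraction/mass accounting for one animal."""

    at_volume_cm3: float
    body_volume_cm3: float
    at_fraction: float
    at_mass_kg: float
    nonat_mass_kg: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def estimate_hu_range(volume: CTVolume, body_mask: np.ndarray, *,
                      prior_center: float = -15.0, mass_quantile: float = 0.95,
                      bin_width: float = 2.0, smooth_sigma_bins: float = 3.0,
                      search_window: tuple[float, float] = (-250.0, 150.0),
                      fallback: HURange = DEFAULT_HU_RANGE) -> HURange:
    """Estimate the adipose attenuation interval from the in-body HU density.

    Works on the in-body voxels inside ``search_window`` (soft-tissue
    attenuations; lung air and bone are physically outside any plausible
    adipose range), smooths their HU histogram, finds its modes, picks the
    mode nearest ``prior_center`` (default -15 HU, the expected adipose
    peak), delimits that mode by the surrounding density valleys, and returns
    the smallest highest-density interval holding at least ``mass_quantile``
    of the mode's voxel mass. Falls back to the configured default range
    (flagged) when the density is unimodal or degenerate.
    """
    if not body_mask.any():
        raise ArgumentError("body_mask is empty")
    vals = np.asarray(volume.hu[body_mask], float)
    vals = vals[(vals >= search_window[0]) & (vals <= search_window[1])]
    if vals.size == 0:
        return fallback
    lo, hi = vals.min(), vals.max()
    if hi - lo < 2 * bin_width:
        return fallback
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    dens = ndimage.gaussian_filter1d(counts.astype(float), smooth_sigma_bins)
    peaks, _ = signal.find_peaks(dens, prominence=0.02 * dens.max())
    if len(peaks) < 2:
        return fallback
    centers = (edges[:-1] + edges[1:]) / 2
    mode = peaks[np.argmin(np.abs(centers[peaks] - prior_center))]
    left_peaks = peaks[peaks < mode]
    right_peaks = peaks[peaks > mode]
    left = 0 if left_peaks.size == 0 else left_peaks.max() + int(
        np.argmin(dens[left_peaks.max():mode + 1]))
    right = len(counts) - 1 if right_peaks.size == 0 else mode + int(
        np.argmin(dens[mode:right_peaks.min() + 1]))
    # highest-density interval: grow from the peak bin toward the denser side
    region_mass = counts[left:right + 1].sum()
    if region_mass == 0:
        return fallback
    a = b = mode
    mass = counts[mode]
    while mass < mass_quantile * region_mass:
        grow_left = a > left and (b >= right or counts[a - 1] >= counts[b + 1])
        if grow_left:
            a -= 1
            mass += counts[a]
        elif b < right:
            b += 1
            mass += counts[b]
        else:
            break
    return HURange(float(edges[a]), float(edges[b + 1]), fallback=False)


def threshold_segment(volume: CTVolume, hu_range: HURange) -> np.ndarray:
    """Per-voxel thresholding: selected iff hu_min <= HU <= hu_max."""
    return (volume.hu >= hu_range.hu_min) & (volume.hu <= hu_range.hu_max)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(np.ones_like(mask, np.int64), labels, range(1, n + 1))
    best = int(np.argmax(sizes)) + 1  # argmax: larger count, then lower index
    return labels == best


def remove_false_positives(candidate: np.ndarray, volume: CTVolume | None = None,
                           mode: str = "oracle", truth: PhantomTruth | None = None,
                           git_region: np.ndarray | None = None,
                           air_dilation: int = 2) -> SegmentationMaskSet:
    """Remove false-positive voxels from a threshold candidate mask.

    ``oracle`` mode subtracts the phantom ground-truth class masks exactly
    (requires ``truth``); it plays the role of a perfectly trained false
    positive classifier. ``rules`` mode (requires ``volume``) applies
    heuristics: candidate components disconnected from the largest body
    component are the scanner table; candidate voxels within ``air_dilation``
    voxels of air pockets inside the body are airway transitions (class B);
    candidate components overlapping ``git_region``, when provided, are gut
    contents (class D). Components matched by no rule are kept. Skin-fold /
    eye / pericardial classes (A, C) need anatomy the rules cannot see and
    are only handled by the oracle.
    """
    if mode == "oracle":
        if truth is None:
            raise ArgumentError("oracle mode requires truth masks")
        removed = {cls: m & candidate for cls, m in truth.class_masks.items()}
    elif mode == "rules":
        if volume is None:
            raise ArgumentError("rules mode requires the CT volume")
        removed = {}
        body_est = _largest_component(volume.hu > -300)
        labels, n = ndimage.label(candidate, structure=_CONN26)
        if n:
            overlap = ndimage.sum_labels(body_est.astype(np.int64), labels,
                                         range(1, n + 1))
            detached = np.isin(labels, np.flatnonzero(overlap == 0) + 1) & candidate
            if detached.any():
                removed["table"] = detached
            if git_region is not None:
                git_overlap = ndimage.sum_labels(git_region.astype(np.int64),
                                                 labels, range(1, n + 1))
                git_comp = np.isin(labels, np.flatnonzero(git_overlap > 0) + 1) & candidate
                if git_comp.any():
                    removed["D"] = git_comp
        air = volume.hu <= -300
        interior_air = air & ~_touching_border_components(air)
        if interior_air.any():
            near_air = ndimage.binary_dilation(interior_air, structure=_CONN26,
                                               iterations=air_dilation)
            mask_b = candidate & near_air & ~interior_air
            if mask_b.any():
                removed["B"] = mask_b
    else:
        raise ArgumentError(f"unknown mode {mode!r} (use 'oracle' or 'rules')")

    union = np.zeros_like(candidate)
    for m in removed.values():
        union |= m
    return SegmentationMaskSet(candidate=candidate, removed=removed,
                               final_adipose=candidate & ~union)


def _touching_border_components(mask: np.ndarray) -> np.ndarray:
    """Components of ``mask`` connected to the volume border (outside air)."""
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return np.zeros_like(mask)
    border = np.zeros_like(mask)
    for ax in range(3):
        sl = [slice(None)] * 3
        for idx in (0, -1):
            sl[ax] = idx
            border[tuple(sl)] = True
    touching = np.unique(labels[border & mask])
    touching = touching[touching > 0]
    return np.isin(labels, touching) & mask


def quantify(masks: SegmentationMaskSet, body_mask: np.ndarray,
             volume: CTVolume, body_mass: float) -> CompositionEstimate:
    """Volume and mass accounting from the final adipose mask.

    Adipose mass is body mass times the voxel-count adipose fraction;
    nonadipose mass is the difference, so the two sum to body mass exactly.
    """
    if body_mass <= 0:
        raise ArgumentError("body_mass must be positive")
    n_body = int(body_mask.sum())
    if n_body == 0:
        raise ArgumentError("body_mask is empty")
    if (masks.final_adipose & ~body_mask).any():
        raise ConsistencyError("final adipose mask extends outside the body mask")
    vox_cm3 = volume.voxel_volume_mm3 / 1000.0
    n_at = int(masks.final_adipose.sum())
    at_fraction = n_at / n_body
    at_mass = body_mass * at_fraction
    # one rounding fixpoint so at + nonat sums to body_mass bit-exactly
    nonat = body_mass - at_mass
    at_mass = body_mass - nonat
    for _ in range(2):
        if at_mass + nonat == body_mass:
            break
        nonat = body_mass - at_mass
    return CompositionEstimate(
        at_volume_cm3=n_at * vox_cm3,
        body_volume_cm3=n_body * vox_cm3,
        at_fraction=at_fraction,
        at_mass_kg=at_mass,
        nonat_mass_kg=nonat,
    )


# ---------------------------------------------------------------------------
# I/O: NIfTI volumes and masks, DICOM series
# ---------------------------------------------------------------------------


def _affine(volume_like) -> np.ndarray:
    # axis 0 is the slice axis
    return np.diag([volume_like.slice_spacing, volume_like.in_plane_spacing,
                    volume_like.in_plane_spacing, 1.0])


def write_volume(volume: CTVolume, path) -> None:
    """Write a CT volume as NIfTI; slice thickness is kept in the header."""
    import nibabel as nib

    img = nib.Nifti1Image(volume.hu.astype(np.int16), _affine(volume))
    img.header["pixdim"][4] = volume.slice_thickness
    img.header["descrip"] = b"turtlebis CT; pixdim[4]=slice thickness mm"
    nib.save(img, str(path))


def read_volume(path) -> CTVolume:
    """Read a CT volume from NIfTI (written by :func:`write_volume`) or a
    DICOM series directory. Errors if spacing metadata is absent."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    if len(zooms) < 3 or not all(z > 0 for z in zooms[:3]):
        raise ArgumentError(f"{path}: missing voxel spacing metadata")
    thickness = float(img.header["pixdim"][4]) or float(zooms[0])
    return CTVolume(
        hu=np.asarray(img.dataobj).astype(np.int16),
        in_plane_spacing=float(zooms[1]),
        slice_spacing=float(zooms[0]),
        slice_thickness=thickness,
    )


def _read_dicom_series(directory: Path) -> CTVolume:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise ArgumentError(f"{directory}: no DICOM series found")
    reader.SetFileNames(files)
    image = reader.Execute()
    sx, sy, sz = image.GetSpacing()
    if not (sx > 0 and sy > 0 and sz > 0):
        raise ArgumentError(f"{directory}: missing spacing metadata")
    if abs(sx - sy) > 1e-6:
        raise ArgumentError(f"{directory}: anisotropic in-plane spacing unsupported")
    hu = sitk.GetArrayFromImage(image)  # (slice, row, col)
    return CTVolume(hu=hu.astype(np.int16), in_plane_spacing=float(sx),
                    slice_spacing=float(sz), slice_thickness=float(sz))


def write_mask_labels(truth: PhantomTruth, volume: CTVolume, path) -> None:
    """Write truth masks as one integer-label NIfTI (see ``MASK_LABELS``)."""
    import nibabel as nib

    labels = np.zeros(truth.body_mask.shape, np.uint8)
    labels[truth.adipose_mask] = MASK_LABELS["adipose"]
    for cls, mask in truth.class_masks.items():
        labels[mask] = MASK_LABELS[cls]
    img = nib.Nifti1Image(labels, _affine(volume))
    nib.save(img, str(path))


def read_mask_labels(path) -> dict[str, np.ndarray]:
    """Read a label NIfTI back into boolean masks keyed by class name."""
    import nibabel as nib

    labels = np.asarray(nib.load(str(path)).dataobj).astype(np.uint8)
    return {name: labels == code for name, code in MASK_LABELS.items() if code > 0}
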