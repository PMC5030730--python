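"""Multi-scale segmentation of single-channel phase-contrast frames.

Phase-contrast images of cells with difficult morphology (iPSCs in
particular) offer no nuclear channel to seed a conventional segmentation.
The approach implemented here runs simple manual-threshold object
identification at several length scales *in parallel* — each scale pairs an
intensity threshold with a typical-diameter window — and then integrates the
per-scale label maps:

1. objects at a smaller scale that overlap an object from any larger scale
   are discarded (largest-object priority);
2. every surviving object is contracted by one pixel, the contracted stack
   is merged and re-segmented by connected components, and the resulting
   labels are expanded back to the original footprint.

The contraction step prevents distinct neighbouring objects from fusing
during the merge while still joining overlapping segmentations of the same
cell.  Clumps of adjacent cells are deliberately segmented as one object:
adjacent cells are indistinguishable in intensity, and clump morphology is
itself an informative, line-specific phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, segmentation as skseg
import tifffile
from PIL import Image

from .errors import InputError, ParameterError

_SQUARE3 = np.ones((3, 3), bool)


@dataclass(frozen=True)
class ScaleConfig:
    """One identification scale: a manual threshold plus a diameter window.

    theta is the threshold applied to the *inverted* normalized frame; d_min
    and d_max bound the equivalent diameter 2*sqrt(area/pi) in pixels.
    """

    theta: float
    d_min: float
    d_max: float
    scale_index: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ParameterError(f"threshold must lie in (0, 1), got {self.theta}")
        if not 0 < self.d_min < self.d_max:
            raise ParameterError(
                f"diameter bounds must satisfy 0 < d_min < d_max, got "
                f"({self.d_min}, {self.d_max})"
            )


#: The three default scales: small/medium/large typical diameters with
#: slightly decreasing thresholds for the larger, dimmer structures.
DEFAULT_SCALES = (
    ScaleConfig(theta=0.78, d_min=5, d_max=20, scale_index=1),
    ScaleConfig(theta=0.75, d_min=21, d_max=40, scale_index=2),
    ScaleConfig(theta=0.74, d_min=41, d_max=65, scale_index=3),
)


@dataclass(frozen=True)
class SegmentationConfig:
    """Global parameters of the multi-scale pipeline.

    scales must be ordered by increasing d_max with non-increasing
    thresholds.  overlap_policy is the overlap fraction above which a
    smaller-scale object is removed; 0.0 means any shared pixel removes it.
    final_d_min/final_d_max form an advisory diameter range for the merged
    objects; it only discards when enforce_final_diameter is set, because
    discarding would delete large clumps.
    """

    scales: tuple[ScaleConfig, ...] = DEFAULT_SCALES
    unify_distance: float = 2.0
    contraction_radius: int = 1
    final_d_min: float = 1.0
    final_d_max: float = 40.0
    enforce_final_diameter: bool = False
    connectivity: int = 8
    discard_border: bool = True
    overlap_policy: float = 0.0

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if self.unify_distance < 0:
            raise ParameterError("unify_distance must be >= 0")
        if self.contraction_radius < 0:
            raise ParameterError("contraction_radius must be >= 0")
        if not 0.0 <= self.overlap_policy < 1.0:
            raise ParameterError("overlap_policy must lie in [0, 1)")
        d_maxes = [s.d_max for s in self.scales]
        if sorted(d_maxes) != d_maxes:
            raise ParameterError("scales must be ordered by increasing d_max")
        thetas = [s.theta for s in self.scales]
        if any(b > a for a, b in zip(thetas, thetas[1:])):
            raise ParameterError("thresholds must be non-increasing with scale size")

    @property
    def _cc(self) -> int:
        # skimage connectivity: 1 = 4-connected, 2 = 8-connected
        return 2 if self.connectivity == 8 else 1

    def to_dict(self) -> dict:
        return {
            "scales": [
                {"theta": s.theta, "d_min": s.d_min, "d_max": s.d_max,
                 "scale_index": s.scale_index}
                for s in self.scales
            ],
            "unify_distance": self.unify_distance,
            "contraction_radius": self.contraction_radius,
            "final_d_min": self.final_d_min,
            "final_d_max": self.final_d_max,
            "enforce_final_diameter": self.enforce_final_diameter,
            "connectivity": self.connectivity,
            "discard_border": self.discard_border,
            "overlap_policy": self.overlap_policy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        d = dict(d)
        if "scales" in d:
            d["scales"] = tuple(ScaleConfig(**s) for s in d["scales"])
        return cls(**d)


def normalize_and_invert(image: np.ndarray) -> np.ndarray:
    """Rescale a raw frame to [0, 1] by its dtype's nominal range and invert.

    Cells are darker than the background in phase contrast; after inversion
    they are the bright structures that thresholding picks out.  Applying the
    operation twice returns the rescaled original.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise InputError(f"expected a 2-D frame, got ndim={image.ndim}")
    if image.dtype == bool:
        scaled = image.astype(float)
    elif np.issubdtype(image.dtype, np.integer):
        scaled = image.astype(float) / np.iinfo(image.dtype).max
    elif np.issubdtype(image.dtype, np.floating):
        scaled = image.astype(float)
        if not np.all(np.isfinite(scaled)):
            raise InputError("float frame contains non-finite values")
        if scaled.size and (scaled.min() < 0.0 or scaled.max() > 1.0):
            raise InputError("float frames must already lie in [0, 1]")
    else:
        raise InputError(f"unsupported frame dtype {image.dtype}")
    return 1.0 - scaled


def foreground_mask(inv: np.ndarray, theta: float) -> np.ndarray:
    """Pixels whose inverted normalized intensity reaches the threshold."""
    if not 0.0 < theta < 1.0:
        raise ParameterError(f"threshold must lie in (0, 1), got {theta}")
    return np.asarray(inv) >= theta


def _relabel_raster(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..N in raster-scan order of each label's first pixel."""
    flat = labels.ravel()
    present, first = np.unique(flat, return_index=True)
    keep = present > 0
    present, first = present[keep], first[keep]
    order = present[np.argsort(first)]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[order] = np.arange(1, len(order) + 1, dtype=np.int32)
    return lut[labels]


def identify_scale_objects(
    mask: np.ndarray, scale: ScaleConfig, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Label a thresholded mask and keep components in the scale's diameter window.

    Components whose equivalent diameter 2*sqrt(area/pi) falls outside
    [d_min, d_max] are removed, as are components touching the frame border
    when the configuration says so.  Surviving labels are renumbered 1..N in
    raster-scan order.
    """
    config = config or SegmentationConfig()
    labels = measure.label(np.asarray(mask, bool), connectivity=config._cc)
    if labels.max() == 0:
        return labels.astype(np.int32)
    keep = np.ones(int(labels.max()) + 1, bool)
    keep[0] = False
    areas = np.bincount(labels.ravel())
    diam = 2.0 * np.sqrt(areas / np.pi)
    keep[1:] &= (diam[1:] >= scale.d_min) & (diam[1:] <= scale.d_max)
    if config.discard_border:
        border = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        keep[border[border > 0]] = False
    labels[~keep[labels]] = 0
    return _relabel_raster(labels)


def unify_by_distance(labels: np.ndarray, max_dist: float) -> np.ndarray:
    """Merge objects whose minimum pixel-to-pixel distance is within max_dist.

    Distances are Euclidean between pixel centers; merging is transitive.
    The merged object keeps the smaller label and labels are renumbered
    contiguously afterwards.
    """
    if max_dist < 0:
        raise ParameterError("max_dist must be >= 0")
    labels = np.asarray(labels)
    n = int(labels.max())
    if n <= 1:
        return labels.copy()
    from scipy.spatial import cKDTree

    coords = np.column_stack(np.nonzero(labels))
    pix_labels = labels[labels > 0]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=max_dist, output_type="ndarray")
    parent = np.arange(n + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    if len(pairs):
        la, lb = pix_labels[pairs[:, 0]], pix_labels[pairs[:, 1]]
        diff = la != lb
        for a, b in set(zip(la[diff].tolist(), lb[diff].tolist())):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(n + 1)])
    # contiguous renumbering, preserving ascending order of surviving labels
    survivors = np.unique(roots[1:])
    lut = np.zeros(n + 1, dtype=np.int32)
    lut[survivors] = np.arange(1, len(survivors) + 1, dtype=np.int32)
    return lut[roots[labels]]


def apply_scale_priority(
    stack: Sequence[np.ndarray], overlap_policy: float = 0.0
) -> list[np.ndarray]:
    """Discard smaller-scale objects overlapping larger-scale ones.

    ``stack`` is ordered small scale to large.  For each scale, an object
    whose overlap fraction with the union of all larger-scale objects exceeds
    ``overlap_policy`` is removed entirely; the largest scale is untouched.
    """
    stack = [np.asarray(m) for m in stack]
    shapes = {m.shape for m in stack}
    if len(shapes) > 1:
        raise InputError(f"label maps have mismatched shapes: {shapes}")
    out: list[np.ndarray] = []
    for s, labels in enumerate(stack):
        larger = np.zeros(labels.shape, bool)
        for bigger in stack[s + 1:]:
            larger |= bigger > 0
        if not larger.any() or labels.max() == 0:
            out.append(labels.copy())
            continue
        areas = np.bincount(labels.ravel())
        inter = np.bincount(labels[larger].ravel(), minlength=len(areas))
        frac = np.zeros(len(areas))
        frac[1:] = inter[1:] / areas[1:]
        removed = frac > overlap_policy
        removed[0] = False
        cleaned = labels.copy()
        cleaned[removed[labels]] = 0
        out.append(_relabel_raster(cleaned))
    return out


def _erode_object(obj: np.ndarray, radius: int) -> np.ndarray:
    """Erode one object's mask; fall back to its ultimate-eroded pixel set."""
    eroded = ndi.binary_erosion(obj, _SQUARE3, iterations=radius)
    if eroded.any():
        return eroded
    dist = ndi.distance_transform_edt(obj)
    return dist == dist.max()


def contract_merge_relabel_expand(
    stack: Sequence[np.ndarray], config: SegmentationConfig | None = None
) -> np.ndarray:
    """Fuse a scale-priority-filtered label stack into one label map.

    Each object is contracted independently by ``contraction_radius`` (3x3
    structuring element); an object that would vanish keeps its ultimate
    eroded pixel set instead.  The contracted binaries are unioned, the union
    is re-segmented by connected components, and every label is expanded back
    over the original (pre-contraction) footprint by nearest-core assignment,
    contested pixels going to the nearest label with ties to the smaller
    label.  Contraction is what keeps distinct touching objects separate
    through the merge.
    """
    config = config or SegmentationConfig()
    stack = [np.asarray(m) for m in stack]
    if not stack:
        raise InputError("empty label stack")
    shape = stack[0].shape
    if any(m.shape != shape for m in stack):
        raise InputError("label maps have mismatched shapes")
    r = config.contraction_radius

    union = np.zeros(shape, bool)
    eroded_union = np.zeros(shape, bool)
    for labels in stack:
        union |= labels > 0
        for region in measure.regionprops(labels):
            sl = tuple(
                slice(max(0, s.start - r), min(dim, s.stop + r))
                for s, dim in zip(region.slice, shape)
            )
            obj = labels[sl] == region.label
            eroded_union[sl] |= _erode_object(obj, r) if r else obj

    cores = measure.label(eroded_union, connectivity=config._cc)
    if cores.max() == 0:
        return np.zeros(shape, np.int32)
    cores = _relabel_raster(cores)

    # Expand each core over the footprint of its union component: per
    # component, assign every footprint pixel to the Euclidean-nearest core.
    final = np.zeros(shape, np.int32)
    comps = measure.label(union, connectivity=config._cc)
    for region in measure.regionprops(comps):
        sl = region.slice
        inside = comps[sl] == region.label
        local_cores = np.where(inside, cores[sl], 0)
        present = np.unique(local_cores)
        present = present[present > 0]
        if len(present) == 0:
            continue
        if len(present) == 1:
            final[sl][inside] = present[0]
            continue
        dists = np.stack([
            ndi.distance_transform_edt(local_cores != lab) for lab in present
        ])
        # argmin returns the first (smallest-label) minimum: ties -> smaller
        nearest = present[np.argmin(dists, axis=0)]
        final[sl][inside] = nearest[inside]
    return _relabel_raster(final)


def segment_frame(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Run the full multi-scale pipeline on one raw frame.

    Composition: normalize/invert, then per scale threshold + identify +
    distance unification, then largest-object priority, then
    contract/merge/relabel/expand.  Deterministic for fixed input and config.
    """
    config = config or SegmentationConfig()
    inv = normalize_and_invert(image)
    stack = []
    for scale in config.scales:
        mask = foreground_mask(inv, scale.theta)
        labels = identify_scale_objects(mask, scale, config)
        labels = unify_by_distance(labels, config.unify_distance)
        stack.append(labels)
    stack = apply_scale_priority(stack, config.overlap_policy)
    final = contract_merge_relabel_expand(stack, config)
    if config.enforce_final_diameter and final.max() > 0:
        areas = np.bincount(final.ravel())
        diam = 2.0 * np.sqrt(areas / np.pi)
        bad = (diam < config.final_d_min) | (diam > config.final_d_max)
        bad[0] = False
        final[bad[final]] = 0
        final = _relabel_raster(final)
    return final


# ---------------------------------------------------------------------------
# Label-map output

def save_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write a label map as 16-bit TIFF."""
    if labels.max() > np.iinfo(np.uint16).max:
        raise InputError("more than 65535 objects; cannot store as 16-bit TIFF")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def load_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def save_outline_overlay(
    image: np.ndarray, labels: np.ndarray, path: str | Path
) -> None:
    """Write the raw frame with object outlines burnt in, as 8-bit RGB PNG."""
    norm = 1.0 - normalize_and_invert(image)
    rgb = np.stack([norm] * 3, axis=-1)
    outlines = skseg.find_boundaries(labels, mode="inner")
    rgb[outlines] = (1.0, 0.0, 0.0)
    Image.fromarray((rgb * 255).round().astype(np.uint8)).save(str(path))
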