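"""Synthetic phase-contrast-like time-lapse plates with ground truth.

The generator emulates the kind of data an automated incubator microscope
produces: hourly single-channel frames over 24 h per well, in which cells
appear as locally contrasted dark blobs with a bright halo ring, spreading
(area growing linearly at a condition-dependent rate) and occasionally
moving into contact to form clumps.  Truth label maps are rendered before
noise; touching cells are — deliberately, matching how a manual count
treats them — one truth object.

This is a geometric emulation, not an optics simulation: no diffraction,
no focus drift, no cell division or death, no intensity inhomogeneity.
Its purpose is to give every stage of the pipeline a fully known gold
standard at desk scale.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from skimage import measure

from .errors import GenerationError, InputError
from .features import FeatureRegistry
from .plate_model import DEFAULT_FRAME_PATTERN, format_frame_name


@dataclass(frozen=True)
class WellAssignment:
    well: str
    cell_line: str
    condition: str


#: Default plate layout: two sibling cultures of one line plus an unrelated
#: line, each over three fibronectin concentrations (ug/mL).
DEFAULT_WELLS = (
    WellAssignment("B2", "LINE-A-P45", "FN1"),
    WellAssignment("B3", "LINE-A-P45", "FN5"),
    WellAssignment("B4", "LINE-A-P45", "FN25"),
    WellAssignment("C2", "LINE-A-P46", "FN1"),
    WellAssignment("C3", "LINE-A-P46", "FN5"),
    WellAssignment("C4", "LINE-A-P46", "FN25"),
    WellAssignment("D2", "LINE-B", "FN1"),
    WellAssignment("D3", "LINE-B", "FN5"),
    WellAssignment("D4", "LINE-B", "FN25"),
)

#: Area growth per condition, px^2/hour: spreading accelerates with matrix
#: concentration.
DEFAULT_GROWTH_RATES = {"FN1": 2.0, "FN5": 4.0, "FN25": 8.0}


@dataclass(frozen=True)
class SyntheticPlateSpec:
    """Conditions of a synthetic plate.

    Defaults follow the emulated acquisition: hourly frames for 24 h,
    ~10 cells per well with initial radii 4-8 px, cells darker than the
    background by ``contrast`` with a bright halo ring, small additive
    Gaussian noise.  The default contrast places the inverted cell
    intensity well above the strictest identification threshold (0.78).
    """

    plate: str = "P1"
    wells: tuple[WellAssignment, ...] = DEFAULT_WELLS
    n_hours: int = 24
    cells_per_well: int = 10
    radius_range: tuple[float, float] = (4.0, 8.0)
    #: optional initial-diameter bands; when set, each cell's diameter is
    #: drawn uniformly from a uniformly chosen band (overrides radius_range)
    diameter_bands: tuple[tuple[float, float], ...] | None = None
    growth_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROWTH_RATES))
    clump_prob: float = 0.05
    background: float = 0.9
    contrast: float = 0.8
    halo_amplitude: float = 0.08
    halo_width: float = 1.5
    noise_sd: float = 0.01
    frame_shape: tuple[int, int] = (360, 360)
    min_separation: float = 12.0
    border_margin: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.clump_prob <= 1.0:
            raise InputError("clump_prob must lie in [0, 1]")
        if self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]:
            raise InputError("radius_range must be positive and ordered")
        if self.n_hours < 1:
            raise InputError("n_hours must be >= 1")

    def growth_rate(self, condition: str) -> float:
        return float(self.growth_rates.get(condition, 0.0))


def _well_rng(spec: SyntheticPlateSpec, well: str, stream: int = 0) -> np.random.Generator:
    """Deterministic per-(seed, well, stream) random generator."""
    return np.random.default_rng(
        [spec.seed & 0x7FFFFFFF, zlib.crc32(well.encode()), stream])


def _final_radius(r0: float, growth: float, n_hours: int) -> float:
    return float(np.sqrt((np.pi * r0**2 + growth * (n_hours - 1)) / np.pi))


@dataclass
class _WellTrajectory:
    """Cell centers per hour plus per-cell radii per hour."""

    positions: np.ndarray  # (n_hours, n_cells, 2) row/col
    radii: np.ndarray      # (n_hours, n_cells)


def _simulate_well(spec: SyntheticPlateSpec, assignment: WellAssignment) -> _WellTrajectory:
    rng = _well_rng(spec, assignment.well)
    n = spec.cells_per_well
    growth = spec.growth_rate(assignment.condition)
    if spec.diameter_bands is not None:
        bands = np.asarray(spec.diameter_bands, float)
        which = rng.integers(0, len(bands), size=n)
        r0 = rng.uniform(bands[which, 0], bands[which, 1]) / 2.0
    else:
        r0 = rng.uniform(*spec.radius_range, size=n)
    r_final = np.array([_final_radius(r, growth, spec.n_hours) for r in r0])

    H, W = spec.frame_shape
    margin = spec.border_margin
    positions = np.empty((n, 2))
    for i in range(n):
        lo_r, hi_r = margin + r_final[i], H - margin - r_final[i]
        lo_c, hi_c = margin + r_final[i], W - margin - r_final[i]
        if lo_r >= hi_r or lo_c >= hi_c:
            raise GenerationError("frame too small for requested cell radii")
        for _ in range(2000):
            cand = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
            d = np.linalg.norm(positions[:i] - cand, axis=1) if i else np.array([np.inf])
            if np.all(d >= r_final[:i] + r_final[i] + spec.min_separation):
                positions[i] = cand
                break
        else:
            raise GenerationError(
                f"could not place {n} cells with separation {spec.min_separation} "
                f"in a {H}x{W} frame"
            )

    pos = np.empty((spec.n_hours, n, 2))
    rad = np.empty((spec.n_hours, n))
    clumped = np.zeros(n, bool)
    cur = positions.copy()
    for h in range(spec.n_hours):
        rad[h] = np.sqrt((np.pi * r0**2 + growth * h) / np.pi)
        if h > 0 and n >= 2 and rng.random() < spec.clump_prob:
            free = np.nonzero(~clumped)[0]
            if len(free) >= 1:
                j = int(rng.choice(free))
                others = [k for k in range(n) if k != j]
                dists = np.linalg.norm(cur[others] - cur[j], axis=1)
                i = others[int(np.argmin(dists))]
                vec = cur[j] - cur[i]
                dist = np.linalg.norm(vec)
                target = rad[h, i] + rad[h, j] - 1.0
                if dist > target > 0:
                    cur[j] = cur[i] + vec / dist * target
                clumped[j] = True
        pos[h] = cur
    return _WellTrajectory(pos, rad)


def _render(
    spec: SyntheticPlateSpec, centers: np.ndarray, radii: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    H, W = spec.frame_shape
    interior = np.zeros((H, W), bool)
    halo = np.zeros((H, W), bool)
    for (cy, cx), r in zip(centers, radii):
        reach = int(np.ceil(r + spec.halo_width)) + 1
        y0, y1 = max(0, int(cy) - reach), min(H, int(cy) + reach + 1)
        x0, x1 = max(0, int(cx) - reach), min(W, int(cx) + reach + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(yy - cy, xx - cx)
        interior[y0:y1, x0:x1] |= d <= r
        halo[y0:y1, x0:x1] |= (d > r) & (d <= r + spec.halo_width)
    halo &= ~interior
    img = np.full((H, W), spec.background)
    img[halo] = spec.background + spec.halo_amplitude
    img[interior] = spec.background - spec.contrast
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    truth = measure.label(interior, connectivity=2).astype(np.int32)
    return img, truth


def generate_frame(
    spec: SyntheticPlateSpec, well: str, hour: int
) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame and its pre-noise truth label map.

    Deterministic in (spec, well, hour): the same call always returns
    bit-identical arrays.
    """
    matches = [w for w in spec.wells if w.well == well]
    if not matches:
        raise InputError(f"well {well!r} not in plate spec")
    if not 0 <= hour < spec.n_hours:
        raise InputError(f"hour {hour} outside 0..{spec.n_hours - 1}")
    traj = _simulate_well(spec, matches[0])
    noise_rng = _well_rng(spec, well, stream=1000 + hour)
    return _render(spec, traj.positions[hour], traj.radii[hour], noise_rng)


def truth_table(spec: SyntheticPlateSpec) -> pd.DataFrame:
    """Per-(well, hour, object) truth: centroid and area of each truth label."""
    rows = []
    for w in spec.wells:
        traj = _simulate_well(spec, w)
        for h in range(spec.n_hours):
            _, truth = _render(spec, traj.positions[h], traj.radii[h],
                               np.random.default_rng(0))
            for region in measure.regionprops(truth):
                rows.append({
                    "plate": spec.plate, "well": w.well, "hour": h,
                    "object_id": int(region.label),
                    "centroid_row": float(region.centroid[0]),
                    "centroid_col": float(region.centroid[1]),
                    "area": float(region.area),
                    "radius": float(region.equivalent_diameter_area / 2.0),
                })
    return pd.DataFrame(rows)


def generate_timelapse(
    spec: SyntheticPlateSpec,
    out_dir: str | Path,
    pattern: str = DEFAULT_FRAME_PATTERN,
    image_format: Literal["png", "tif"] = "png",
) -> tuple[list[Path], pd.DataFrame]:
    """Write a full synthetic plate to disk.

    Frames are written as 8-bit PNG (or 16-bit TIFF) under the plate
    filename template, a ``plate_map.csv`` assigns each well its cell line
    and condition, and ``truth.csv`` records the per-object ground truth.
    Returns the frame paths and the truth table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".png" if image_format == "png" else ".tif"
    paths = []
    for w in spec.wells:
        traj = _simulate_well(spec, w)
        for h in range(spec.n_hours):
            noise_rng = _well_rng(spec, w.well, stream=1000 + h)
            img, _ = _render(spec, traj.positions[h], traj.radii[h], noise_rng)
            name = format_frame_name(spec.plate, w.well, h, pattern, ext)
            path = out_dir / name
            if image_format == "png":
                Image.fromarray((img * 255).round().astype(np.uint8)).save(path)
            else:
                tifffile.imwrite(path, (img * 65535).round().astype(np.uint16))
            paths.append(path)
    plate_map = pd.DataFrame({
        "plate": spec.plate,
        "well": [w.well for w in spec.wells],
        "cell_line": [w.cell_line for w in spec.wells],
        "condition": [w.condition for w in spec.wells],
    })
    plate_map.to_csv(out_dir / "plate_map.csv", index=False)
    truth = truth_table(spec)
    truth.to_csv(out_dir / "truth.csv", index=False, float_format="%.17g")
    return paths, truth


# ---------------------------------------------------------------------------
# Synthetic feature tables (direct harness for the trend-reduction stage)

def generate_feature_table(
    registry: FeatureRegistry,
    slopes: Mapping[str, float] | Sequence[float],
    intercepts: Mapping[str, float] | Sequence[float],
    noise_sd: float = 0.0,
    objects_per_hour: int | Sequence[int] = 50,
    n_hours: int = 24,
    seed: int = 0,
    plate: str = "P1",
    well: str = "B2",
    cell_line: str = "LINE-A",
    condition: str = "FN1",
) -> pd.DataFrame:
    """Object table whose feature values follow designed linear trends.

    Values at hour h are intercept + slope*h + N(0, noise_sd) per object.
    ``objects_per_hour`` may vary by hour; an hour with zero objects is
    simply absent from the table.
    """
    cols = registry.column_names
    if not isinstance(slopes, Mapping):
        slopes = dict(zip(cols, slopes))
    if not isinstance(intercepts, Mapping):
        intercepts = dict(zip(cols, intercepts))
    missing = set(cols) - set(slopes) | set(cols) - set(intercepts)
    if missing:
        raise InputError(f"slopes/intercepts missing for: {sorted(missing)[:5]} ...")
    if isinstance(objects_per_hour, int):
        objects_per_hour = [objects_per_hour] * n_hours
    if len(objects_per_hour) != n_hours:
        raise InputError("objects_per_hour must have one entry per hour")
    rng = np.random.default_rng(seed)
    slope_arr = np.array([slopes[c] for c in cols])
    icpt_arr = np.array([intercepts[c] for c in cols])
    blocks = []
    for h in range(n_hours):
        n = int(objects_per_hour[h])
        if n == 0:
            continue
        values = np.broadcast_to(icpt_arr + slope_arr * h, (n, len(cols))).copy()
        if noise_sd > 0:
            values += rng.normal(0.0, noise_sd, size=(n, len(cols)))
        block = pd.DataFrame(values, columns=list(cols))
        block.insert(0, "plate", plate)
        block.insert(1, "well", well)
        block.insert(2, "hour", h)
        block.insert(3, "object_id", np.arange(1, n + 1))
        block.insert(4, "centroid_row", 0.0)
        block.insert(5, "centroid_col", 0.0)
        block["cell_line"] = cell_line
        block["condition"] = condition
        blocks.append(block)
    columns = ["plate", "well", "hour", "object_id", "centroid_row",
               "centroid_col", *cols, "cell_line", "condition"]
    if not blocks:
        return pd.DataFrame(columns=columns)
    return pd.concat(blocks, ignore_index=True)[columns]


# ---------------------------------------------------------------------------
# Segmentation metrics against ground truth

@dataclass(frozen=True)
class SegmentationMetrics:
    precision: float
    recall: float
    count_error: int
    n_pred: int
    n_truth: int
    n_matched: int


def segmentation_metrics(
    pred: np.ndarray, truth: np.ndarray, iou_threshold: float = 0.5
) -> SegmentationMetrics:
    """Object-level precision/recall by greedy one-to-one IoU matching.

    Candidate (pred, truth) pairs are matched in order of descending
    intersection-over-union (ties broken by label pair for determinism);
    pairs reaching ``iou_threshold`` are true positives.  count_error is
    the signed difference predicted - true object count.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InputError("prediction and truth shapes differ")
    n_pred, n_truth = int(pred.max()), int(truth.max())
    if n_pred == 0 or n_truth == 0:
        return SegmentationMetrics(
            precision=1.0 if n_pred == 0 else 0.0,
            recall=1.0 if n_truth == 0 else 0.0,
            count_error=n_pred - n_truth,
            n_pred=n_pred, n_truth=n_truth, n_matched=0,
        )
    both = (pred > 0) & (truth > 0)
    pair_idx = pred[both].astype(np.int64) * (n_truth + 1) + truth[both]
    inter_counts = np.bincount(pair_idx, minlength=(n_pred + 1) * (n_truth + 1))
    areas_p = np.bincount(pred.ravel(), minlength=n_pred + 1)
    areas_t = np.bincount(truth.ravel(), minlength=n_truth + 1)
    candidates = []
    for idx in np.nonzero(inter_counts)[0]:
        p, t = divmod(int(idx), n_truth + 1)
        inter = int(inter_counts[idx])
        union = int(areas_p[p] + areas_t[t] - inter)
        candidates.append((inter / union, p, t))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    matched = 0
    for iou, p, t in candidates:
        if iou < iou_threshold:
            break
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        matched += 1
    return SegmentationMetrics(
        precision=matched / n_pred,
        recall=matched / n_truth,
        count_error=n_pred - n_truth,
        n_pred=n_pred, n_truth=n_truth, n_matched=matched,
    )
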