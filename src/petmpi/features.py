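"""Lesion segmentation and whole-body PET feature extraction.

The feature set comprises 20 per-patient descriptors computed from a
patient's segmented lesions, grouped into four families:

* global tumor burden — tMTV, tTLG, Intensity_Sum, MeanIntensity_Sum,
  Volume_intensity_sum;
* dominant-lesion descriptors — MTV_Bulk, MTV_Smallest, tSUVmax,
  MaxIntensity_Min;
* inter-lesional heterogeneity — Volume_DiffSum, Bulk_Volume_DiffSum,
  BulkSmallest_Volume_Diff, MaxIntensity_DiffSum,
  HighestLowest_MaxIntensity_Diff, Bulk_MaxIntensity_DiffSum;
* spatial dissemination — DmaxVox, Dmax, BulkDmax,
  BulkCentroidCoor_DistMax, SmallestCentroidCoor_DistMax.

All distances are in millimetres, volumes in millilitres, SUV unitless.
Lesions are segmented from an SUV image with a fixed threshold (default
2.5, strictly above) and 26-connectivity, mirroring common clinical
whole-body PET workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

SUV_THRESHOLD = 2.5

FEATURE_NAMES = [
    # global tumor burden
    "tMTV",
    "tTLG",
    "Intensity_Sum",
    "MeanIntensity_Sum",
    "Volume_intensity_sum",
    # dominant lesion descriptors
    "MTV_Bulk",
    "MTV_Smallest",
    "tSUVmax",
    "MaxIntensity_Min",
    # inter-lesional heterogeneity
    "Volume_DiffSum",
    "Bulk_Volume_DiffSum",
    "BulkSmallest_Volume_Diff",
    "MaxIntensity_DiffSum",
    "HighestLowest_MaxIntensity_Diff",
    "Bulk_MaxIntensity_DiffSum",
    # spatial dissemination
    "DmaxVox",
    "Dmax",
    "BulkDmax",
    "BulkCentroidCoor_DistMax",
    "SmallestCentroidCoor_DistMax",
]

DISSEMINATION_FEATURES = [
    "DmaxVox",
    "Dmax",
    "BulkDmax",
    "BulkCentroidCoor_DistMax",
    "SmallestCentroidCoor_DistMax",
]


class NoDiseaseError(ValueError):
    """Raised when an operation requires at least one lesion."""


@dataclass
class SUVImage:
    """A 3-D standardized-uptake-value image on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        SUV per voxel; must be finite.
    spacing : tuple of float
        Voxel edge length per axis in mm; all entries > 0.
    origin : tuple of float
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("SUVImage requires a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUVImage values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class Lesion:
    """One segmented lesion: voxel-centre world coordinates (mm) + SUVs."""

    lesion_id: int
    coords_mm: np.ndarray  # (n_voxels, 3)
    suv: np.ndarray  # (n_voxels,)

    def __post_init__(self) -> None:
        self.coords_mm = np.atleast_2d(np.asarray(self.coords_mm, dtype=float))
        self.suv = np.atleast_1d(np.asarray(self.suv, dtype=float))
        if self.coords_mm.shape[0] != self.suv.shape[0]:
            raise ValueError("coords_mm and suv length mismatch")
        if self.coords_mm.shape[0] == 0:
            raise ValueError("lesion must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return self.coords_mm.shape[0]


@dataclass
class LesionSet:
    """All segmented lesions of one patient.

    ``lesions`` may be empty only as the explicit "no disease" result of
    segmentation; feature computation requires at least one lesion.
    """

    patient_id: str
    lesions: list[Lesion] = field(default_factory=list)
    voxel_volume_ml: float = 0.064  # 4 x 4 x 4 mm default grid
    threshold: float = SUV_THRESHOLD

    def __post_init__(self) -> None:
        if self.voxel_volume_ml <= 0:
            raise ValueError("voxel_volume_ml must be positive")

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    def all_coords(self) -> np.ndarray:
        if not self.lesions:
            raise NoDiseaseError(f"patient {self.patient_id}: no lesions")
        return np.vstack([l.coords_mm for l in self.lesions])


def segment_lesions(
    image: SUVImage,
    patient_id: str = "patient",
    threshold: float = SUV_THRESHOLD,
    min_voxels: int = 1,
) -> LesionSet:
    """Threshold-segment an SUV image into connected lesions.

    Voxels with SUV strictly above ``threshold`` are grouped into
    26-connected components; components with fewer than ``min_voxels``
    voxels are discarded. World coordinates are voxel centres,
    ``origin + index * spacing``.

    Returns an empty :class:`LesionSet` ("no disease") when no voxel
    exceeds the threshold; the caller decides how to handle it.
    """
    mask = image.values > threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n_components = ndimage.label(mask, structure=structure)

    spacing = np.asarray(image.spacing)
    origin = np.asarray(image.origin)
    lesions: list[Lesion] = []
    lesion_id = 0
    for comp in range(1, n_components + 1):
        idx = np.argwhere(labels == comp)
        if idx.shape[0] < min_voxels:
            continue
        lesion_id += 1
        coords = origin + idx * spacing
        suv = image.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        lesions.append(Lesion(lesion_id=lesion_id, coords_mm=coords, suv=suv))
    return LesionSet(
        patient_id=patient_id,
        lesions=lesions,
        voxel_volume_ml=image.voxel_volume_ml,
        threshold=threshold,
    )


def summarize_lesions(ls: LesionSet) -> pd.DataFrame:
    """Per-lesion summaries: MTV (ml), SUVmean, SUVmax, TLG, summed SUV
    (intensity_sum) and the unweighted voxel-centre centroid (mm).

    TLG = MTV x SUVmean by definition.
    """
    if ls.n_lesions == 0:
        raise NoDiseaseError(f"patient {ls.patient_id}: empty lesion set")
    rows = []
    for lesion in ls.lesions:
        mtv = lesion.n_voxels * ls.voxel_volume_ml
        suv_mean = float(np.mean(lesion.suv))
        suv_max = float(np.max(lesion.suv))
        centroid = lesion.coords_mm.mean(axis=0)
        rows.append(
            {
                "lesion_id": lesion.lesion_id,
                "mtv_ml": mtv,
                "suv_mean": suv_mean,
                "suv_max": suv_max,
                "tlg": mtv * suv_mean,
                "intensity_sum": float(np.sum(lesion.suv)),
                "centroid_x": centroid[0],
                "centroid_y": centroid[1],
                "centroid_z": centroid[2],
            }
        )
    return pd.DataFrame(rows).set_index("lesion_id")


def max_pairwise_distance(points: np.ndarray) -> float:
    """Exact maximum pairwise Euclidean distance (diameter) of a point set.

    Chunked brute force; exact at any input (no convex-hull shortcut, so
    degenerate/collinear sets need no special casing).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < 2:
        return 0.0
    best = 0.0
    chunk = max(1, int(2e6 // max(n, 1)))
    for start in range(0, n, chunk):
        d = cdist(points[start : start + chunk], points)
        best = max(best, float(d.max()))
    return best


def dmax_vox(ls: LesionSet) -> float:
    """Maximum Euclidean distance (mm) between any two tumor voxels,
    pooled across all lesions (within-lesion chords included)."""
    return max_pairwise_distance(ls.all_coords())


def _sum_abs_pairwise_diffs(values: np.ndarray) -> float:
    # sum_{i<j} |v_i - v_j| via the sorted-prefix identity:
    # = sum_k (2k - n - 1) * v_(k), v sorted ascending, k = 1..n
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2:
        return 0.0
    k = np.arange(1, n + 1)
    return float(np.sum((2 * k - n - 1) * v))


def aggregate_features(per_lesion: pd.DataFrame, dmax_vox_value: float) -> pd.Series:
    """Build the 20-feature vector from per-lesion summaries.

    ``per_lesion`` must carry columns mtv_ml, suv_mean, suv_max,
    intensity_sum, centroid_x/y/z (one row per lesion).  ``dmax_vox_value``
    is supplied by the caller because it needs voxel-level (or geometric)
    information the summaries no longer hold.

    The bulk lesion is the one with the largest MTV; ties break toward the
    higher intensity_sum, then the lower lesion_id, so output is
    deterministic.  Bulk_Volume_DiffSum uses signed (bulk - other)
    differences, which are non-negative by the bulk definition; the
    intensity analogue uses absolute differences because the bulk lesion
    need not carry the top SUVmax.
    """
    if per_lesion.shape[0] == 0:
        raise NoDiseaseError("no lesions to aggregate")
    df = per_lesion.sort_index()
    mtv = df["mtv_ml"].to_numpy()
    suv_mean = df["suv_mean"].to_numpy()
    suv_max = df["suv_max"].to_numpy()
    isum = df["intensity_sum"].to_numpy()
    centroids = df[["centroid_x", "centroid_y", "centroid_z"]].to_numpy()
    n = mtv.size

    # deterministic bulk selection: max MTV, then max intensity_sum, then
    # the lowest lesion id (sort order of the index)
    order = np.lexsort((np.arange(n), -isum, -mtv))
    bulk = order[0]
    smallest = int(np.argmin(mtv))

    if n > 1:
        centroid_d = cdist(centroids, centroids)
        dmax = float(centroid_d.max())
        bulk_dmax = float(centroid_d[bulk].max())
        smallest_dmax = float(centroid_d[smallest].max())
    else:
        dmax = bulk_dmax = smallest_dmax = 0.0

    return pd.Series(
        {
            "tMTV": float(mtv.sum()),
            "tTLG": float((mtv * suv_mean).sum()),
            "Intensity_Sum": float(isum.sum()),
            "MeanIntensity_Sum": float(suv_mean.sum()),
            "Volume_intensity_sum": float((mtv * isum).sum()),
            "MTV_Bulk": float(mtv[bulk]),
            "MTV_Smallest": float(mtv[smallest]),
            "tSUVmax": float(suv_max.max()),
            "MaxIntensity_Min": float(suv_max.min()),
            "Volume_DiffSum": _sum_abs_pairwise_diffs(mtv),
            "Bulk_Volume_DiffSum": float(np.sum(mtv[bulk] - np.delete(mtv, bulk))),
            "BulkSmallest_Volume_Diff": float(mtv[bulk] - mtv[smallest]),
            "MaxIntensity_DiffSum": _sum_abs_pairwise_diffs(suv_max),
            "HighestLowest_MaxIntensity_Diff": float(suv_max.max() - suv_max.min()),
            "Bulk_MaxIntensity_DiffSum": float(
                np.abs(suv_max[bulk] - np.delete(suv_max, bulk)).sum()
            ),
            "DmaxVox": float(dmax_vox_value),
            "Dmax": dmax,
            "BulkDmax": bulk_dmax,
            "BulkCentroidCoor_DistMax": bulk_dmax,
            "SmallestCentroidCoor_DistMax": smallest_dmax,
        },
        index=FEATURE_NAMES,
    )


def compute_features(ls: LesionSet) -> pd.Series:
    """The 20-feature vector for one patient's lesion set."""
    per_lesion = summarize_lesions(ls)
    return aggregate_features(per_lesion, dmax_vox(ls))


def compute_feature_matrix(lesion_sets: list[LesionSet]) -> pd.DataFrame:
    """Stack per-patient feature vectors into an n x 20 matrix.

    Patients with empty lesion sets are rejected: exclusion decisions
    belong to the caller, not to feature extraction.
    """
    rows, ids = [], []
    for ls in lesion_sets:
        rows.append(compute_features(ls))
        ids.append(ls.patient_id)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_id in lesion sets")
    fm = pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"))
    fm.attrs["segmentation_threshold"] = lesion_sets[0].threshold if lesion_sets else None
    fm.attrs["voxel_volume_ml"] = lesion_sets[0].voxel_volume_ml if lesion_sets else None
    return fm
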