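"""Synthetic stage-IV small-cell lung cancer cohorts with a known latent
severity axis.

Each patient carries a scalar severity ``s ~ Uniform(0, 1)`` that drives
lesion count, lesion volumes, spatial dissemination, bone-metastasis
probability, 12-month mortality and overall survival, while peak lesion
SUVmax is drawn independently of ``s`` (so that metabolic intensity alone
carries no severity signal).  Lesions are spheres inside a body-like
cylinder (radius 150 mm, height 1000 mm); the first lesion is the bulk
(primary) lesion and is the largest in expectation, metastases are placed
within a severity-dependent radius of it.

Two fidelities are provided:

* a fast path that computes the 20 PET features in closed form from the
  sphere geometry (:func:`geometric_features`), and
* a slow path that rasterizes each patient onto an SUV voxel grid
  (:func:`rasterize`) for end-to-end testing of threshold segmentation.

Default parameters emulate the published cohort scale: n = 83, ~72%
12-month mortality, median overall survival around 6 months,
multi-lesion disease with a median of roughly 4-8 lesions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import SUV_THRESHOLD, SUVImage, aggregate_features

BODY_RADIUS_MM = 150.0
BODY_HEIGHT_MM = 1000.0


class ParameterError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable knobs of the cohort generator.

    Tuple parameters follow the convention (base, slope[, sd]) where the
    severity-dependent location is ``base + slope * s`` (on the log scale
    for log-normal quantities).
    """

    n_patients: int = 83
    seed: int = 0
    #: Poisson rate of extra lesions: L = 1 + Poisson(base + slope * s)
    lesion_rate: tuple[float, float] = (0.5, 14.0)
    #: bulk lesion volume ~ LogNormal(log_base + log_slope * s, log_sd) [ml]
    bulk_volume: tuple[float, float, float] = (math.log(100.0), 1.2, 0.35)
    #: metastasis volume ~ LogNormal(log_base + log_slope * s, log_sd) [ml]
    met_volume: tuple[float, float, float] = (math.log(0.25), 1.0, 0.7)
    #: patient peak SUVmax ~ LogNormal(log_mean, log_sd), independent of s;
    #: the bulk lesion carries the peak, metastases a random fraction of it,
    #: so the cohort-level tSUVmax carries no severity signal
    suvmax_dist: tuple[float, float] = (math.log(15.0), 0.15)
    #: metastasis SUVmax = peak * Uniform(lo, hi)
    met_suv_fraction: tuple[float, float] = (0.35, 1.0)
    #: metastasis placement radius around the bulk centre:
    #: (base + slope * s) * LogNormal(-log_sd^2/2, log_sd) [mm] — the
    #: multiplicative noise keeps dissemination a noisy (not deterministic)
    #: readout of severity, as each single PET feature should be
    dispersion: tuple[float, float, float] = (30.0, 220.0, 0.5)
    #: radial placement profile: met distance = radius_limit * U^exponent.
    #: exponent 1/3 is uniform-in-ball; larger exponents concentrate
    #: metastases near the primary with occasional distant deposits, making
    #: the distance extremes (Dmax, DmaxVox) noisy severity readouts
    placement_exponent: float = 1.0 / 3.0
    #: patient-level growth factor g ~ N(0, 1) shared between the bulk
    #: volume and the dispersion radius (their log-noises are growth_sd * g
    #: each).  This couples volumetric and spatial metrics beyond severity,
    #: reproducing the strong tMTV-DmaxVox collinearity of real cohorts
    #: when set above zero (default: channels independent).
    growth_coupling: float = 0.0
    #: 12-month death: Bernoulli(expit(b0 + b1 * s)); the analytic marginal
    #: over s ~ U(0,1) is 72.4% mortality
    outcome_logit: tuple[float, float] = (-2.7, 10.0)
    #: overall survival: Weibull(shape) with scale [months] and
    #: log-hazard slope in s (proportional hazards)
    survival: tuple[float, float, float] = (1.2, 14.5, 1.5)
    #: bone metastasis: Bernoulli(expit(b0 + b1 * s))
    bone_met_logit: tuple[float, float] = (-0.6, 1.5)
    admin_censor_months: float = 36.0
    voxel_spacing_mm: float = 4.0

    def validate(self) -> None:
        if self.n_patients < 3:
            raise ParameterError("n_patients must be >= 3")
        if self.admin_censor_months < 12:
            raise ParameterError("admin_censor_months must be >= 12")
        for name in ("bulk_volume", "met_volume"):
            if getattr(self, name)[2] <= 0:
                raise ParameterError(f"{name} log-sd must be > 0")
        if self.suvmax_dist[1] <= 0:
            raise ParameterError("suvmax log-sd must be > 0")
        if self.survival[0] <= 0 or self.survival[1] <= 0:
            raise ParameterError("Weibull shape and scale must be > 0")
        if self.lesion_rate[0] < 0 or self.lesion_rate[0] + min(0.0, self.lesion_rate[1]) < 0:
            raise ParameterError("lesion rate must stay non-negative on s in [0,1]")
        if self.dispersion[0] <= 0:
            raise ParameterError("dispersion base must be > 0")
        if self.dispersion[2] <= 0:
            raise ParameterError("dispersion log-sd must be > 0")
        if self.voxel_spacing_mm <= 0:
            raise ParameterError("voxel_spacing_mm must be > 0")

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_spacing_mm**3 / 1000.0


@dataclass(frozen=True)
class LesionGeometry:
    """A spherical lesion: centre (mm), volume (ml), peak SUV."""

    center_mm: tuple[float, float, float]
    volume_ml: float
    suv_max: float

    @property
    def radius_mm(self) -> float:
        return (3.0 * self.volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class PatientTruth:
    patient_id: str
    severity: float
    lesions: tuple[LesionGeometry, ...]
    dead_12mo: int
    time_months: float
    event: int
    bone_met: int


def _sphere_mean_suv(suv_max: float, threshold: float = SUV_THRESHOLD) -> float:
    # linear radial SUV profile threshold..suv_max integrated over the ball:
    # mean = threshold + (suv_max - threshold) / 4
    return threshold + (suv_max - threshold) / 4.0


def _in_cylinder(p: np.ndarray, margin: float) -> bool:
    return (
        p[0] ** 2 + p[1] ** 2 <= (BODY_RADIUS_MM - margin) ** 2
        and margin <= p[2] <= BODY_HEIGHT_MM - margin
    )


def _truncated_weibull(
    rng: np.random.Generator, shape: float, scale: float, rate_mult: float,
    low: float, high: float,
) -> float:
    """Inverse-CDF draw of T ~ Weibull(shape, scale) with hazard multiplier
    ``rate_mult`` (proportional hazards), conditioned on low < T <= high."""

    def cdf(t: float) -> float:
        if t <= 0:
            return 0.0
        if not np.isfinite(t):
            return 1.0
        return 1.0 - math.exp(-((t / scale) ** shape) * rate_mult)

    a, b = cdf(low), cdf(high)
    u = a + rng.uniform() * (b - a)
    u = min(u, 1.0 - 1e-12)
    return scale * (-math.log(1.0 - u) / rate_mult) ** (1.0 / shape)


def _place_metastasis(
    rng: np.random.Generator,
    bulk_center: np.ndarray,
    radius_limit: float,
    lesion_radius: float,
    placed: list[tuple[np.ndarray, float]],
    clearance_mm: float,
    placement_exponent: float = 2.0,
) -> np.ndarray:
    """Radially profiled draw in a ball around the bulk centre, rejected
    until it lies inside the body cylinder and clears every previously
    placed sphere.  The search ball grows every 150 failures so
    pathological parameter combinations still terminate."""
    r_eff = radius_limit
    for attempt in range(2000):
        if attempt and attempt % 150 == 0:
            r_eff *= 1.4
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = r_eff * rng.uniform() ** placement_exponent
        candidate = bulk_center + radius * direction
        if not _in_cylinder(candidate, margin=lesion_radius):
            continue
        ok = all(
            np.linalg.norm(candidate - c) > r + lesion_radius + clearance_mm
            for c, r in placed
        )
        if ok:
            return candidate
    # crowded configuration: deterministic grid scan over the body cylinder
    # (ordered by distance to the bulk centre, so dissemination stays as
    # close to the requested radius profile as the packing allows)
    step = max(2.0 * lesion_radius + clearance_mm, 25.0)
    zs = np.arange(lesion_radius + 1.0, BODY_HEIGHT_MM - lesion_radius, step)
    lat = np.arange(-BODY_RADIUS_MM, BODY_RADIUS_MM + 1, step)
    grid = np.array([(x, y, z) for x in lat for y in lat for z in zs])
    inside = (grid[:, 0] ** 2 + grid[:, 1] ** 2) <= (BODY_RADIUS_MM - lesion_radius) ** 2
    grid = grid[inside]
    order = np.argsort(np.linalg.norm(grid - bulk_center, axis=1))
    for candidate in grid[order]:
        if all(
            np.linalg.norm(candidate - c) > r + lesion_radius + clearance_mm
            for c, r in placed
        ):
            return candidate
    raise RuntimeError("could not place a non-overlapping metastasis")


def sample_patient(
    rng: np.random.Generator, params: GeneratorParams, patient_id: str, severity: float
) -> PatientTruth:
    s = float(severity)
    # clearance > one voxel diagonal keeps rasterized lesions in separate
    # 26-connected components
    clearance = 2.0 * params.voxel_spacing_mm * math.sqrt(3.0)

    n_extra = rng.poisson(params.lesion_rate[0] + params.lesion_rate[1] * s)
    min_vol = 1.5 * params.voxel_volume_ml  # keep every lesion >= one voxel

    # shared growth factor: the same patient-level draw perturbs bulk
    # volume and dispersion radius (collinear "how much disease grew"
    # noise); a residual keeps bulk volume from being a pure g readout
    g = float(rng.normal())
    b0, b1, bsd = params.bulk_volume
    bulk_log_noise = params.growth_coupling * bsd * g + math.sqrt(
        max(1.0 - params.growth_coupling**2, 0.0)
    ) * bsd * float(rng.normal())
    bulk_vol = max(float(np.exp(b0 + b1 * s + bulk_log_noise)), min_vol)
    suv_mu, suv_sd = params.suvmax_dist
    peak_suv = max(float(np.exp(rng.normal(suv_mu, suv_sd))), SUV_THRESHOLD + 1.0)
    frac_lo, frac_hi = params.met_suv_fraction
    met_suv = lambda: max(peak_suv * rng.uniform(frac_lo, frac_hi), SUV_THRESHOLD + 0.5)

    bulk_radius = (3.0 * bulk_vol * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    center = np.array(
        [0.0, 0.0, 0.0]
    )
    # bulk sits in the chest-like upper half of the cylinder
    for _ in range(1000):
        xy = rng.uniform(-BODY_RADIUS_MM, BODY_RADIUS_MM, size=2)
        z = rng.uniform(0.55 * BODY_HEIGHT_MM, 0.85 * BODY_HEIGHT_MM)
        center = np.array([xy[0], xy[1], z])
        if _in_cylinder(center, margin=bulk_radius):
            break
    lesions = [LesionGeometry(tuple(center), bulk_vol, peak_suv)]
    placed = [(center, bulk_radius)]

    m0, m1, msd = params.met_volume
    disp_sd = params.dispersion[2]
    disp_noise = float(
        np.exp(-disp_sd**2 / 2.0 + disp_sd * (params.growth_coupling * g
               + math.sqrt(max(1.0 - params.growth_coupling**2, 0.0)) * float(rng.normal())))
    )
    radius_limit = (params.dispersion[0] + params.dispersion[1] * s) * disp_noise
    # the placement ball must at least clear the bulk sphere
    radius_limit = max(radius_limit, bulk_radius + 1.5 * clearance)
    for _ in range(n_extra):
        vol = max(float(np.exp(rng.normal(m0 + m1 * s, msd))), min_vol)
        lesion_radius = (3.0 * vol * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        pos = _place_metastasis(
            rng, center, radius_limit, lesion_radius, placed, clearance,
            placement_exponent=params.placement_exponent,
        )
        lesions.append(LesionGeometry(tuple(pos), vol, met_suv()))
        placed.append((pos, lesion_radius))

    bone_met = int(rng.uniform() < expit(params.bone_met_logit[0] + params.bone_met_logit[1] * s))

    p_dead = expit(params.outcome_logit[0] + params.outcome_logit[1] * s)
    dead_12mo = int(rng.uniform() < p_dead)
    shape, scale, beta = params.survival
    rate_mult = math.exp(beta * s)
    if dead_12mo:
        time = _truncated_weibull(rng, shape, scale, rate_mult, 0.0, 12.0)
        event = 1
    else:
        time = _truncated_weibull(rng, shape, scale, rate_mult, 12.0, math.inf)
        if time >= params.admin_censor_months:
            time, event = params.admin_censor_months, 0
        else:
            event = 1
    return PatientTruth(
        patient_id=patient_id,
        severity=s,
        lesions=tuple(lesions),
        dead_12mo=dead_12mo,
        time_months=float(time),
        event=event,
        bone_met=bone_met,
    )


def sample_cohort(params: GeneratorParams) -> list[PatientTruth]:
    """Draw a full cohort; deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    severities = rng.uniform(size=params.n_patients)
    width = len(str(params.n_patients))
    return [
        sample_patient(rng, params, f"P{i + 1:0{width}d}", severities[i])
        for i in range(params.n_patients)
    ]


# ---------------------------------------------------------------------------
# fast path: features in closed form from sphere geometry


def geometric_lesion_summaries(patient: PatientTruth, voxel_volume_ml: float) -> pd.DataFrame:
    rows = []
    for i, les in enumerate(patient.lesions, start=1):
        suv_mean = _sphere_mean_suv(les.suv_max)
        n_vox = les.volume_ml / voxel_volume_ml
        rows.append(
            {
                "lesion_id": i,
                "mtv_ml": les.volume_ml,
                "suv_mean": suv_mean,
                "suv_max": les.suv_max,
                "tlg": les.volume_ml * suv_mean,
                "intensity_sum": suv_mean * n_vox,
                "centroid_x": les.center_mm[0],
                "centroid_y": les.center_mm[1],
                "centroid_z": les.center_mm[2],
            }
        )
    return pd.DataFrame(rows).set_index("lesion_id")


def geometric_dmax_vox(patient: PatientTruth) -> float:
    """Surface-to-surface analogue of the voxel-level maximum distance:
    max over lesion pairs (including a lesion with itself) of
    centre distance + both radii."""
    centers = np.array([l.center_mm for l in patient.lesions])
    radii = np.array([l.radius_mm for l in patient.lesions])
    n = len(radii)
    best = 2.0 * float(radii.max())  # within-lesion chord
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(centers[i] - centers[j])) + radii[i] + radii[j]
            best = max(best, d)
    return best


def geometric_features(patient: PatientTruth, voxel_volume_ml: float) -> pd.Series:
    """Closed-form 20-feature vector from sphere geometry (fast path)."""
    per_lesion = geometric_lesion_summaries(patient, voxel_volume_ml)
    return aggregate_features(per_lesion, geometric_dmax_vox(patient))


def cohort_feature_matrix(cohort: list[PatientTruth], params: GeneratorParams) -> pd.DataFrame:
    fm = pd.DataFrame(
        [geometric_features(p, params.voxel_volume_ml) for p in cohort],
        index=pd.Index([p.patient_id for p in cohort], name="patient_id"),
    )
    fm.attrs["segmentation_threshold"] = SUV_THRESHOLD
    fm.attrs["voxel_volume_ml"] = params.voxel_volume_ml
    return fm


def outcomes_frame(cohort: list[PatientTruth]) -> pd.DataFrame:
    """Outcome table (one row per patient) with the latent severity truth."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort],
            "dead_12mo": [p.dead_12mo for p in cohort],
            "time_months": [p.time_months for p in cohort],
            "event": [p.event for p in cohort],
            "bone_met": [p.bone_met for p in cohort],
            "severity": [p.severity for p in cohort],
        }
    ).set_index("patient_id")


def lesion_frame(cohort: list[PatientTruth]) -> pd.DataFrame:
    """Lesion geometry table (one row per lesion)."""
    rows = []
    for p in cohort:
        for i, les in enumerate(p.lesions, start=1):
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "lesion_id": i,
                    "x_mm": les.center_mm[0],
                    "y_mm": les.center_mm[1],
                    "z_mm": les.center_mm[2],
                    "volume_ml": les.volume_ml,
                    "suv_max": les.suv_max,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# slow path: rasterization onto an SUV grid


def rasterize(
    patient: PatientTruth,
    spacing_mm: float = 4.0,
    rng: np.random.Generator | None = None,
    margin_voxels: int = 3,
    origin: tuple[float, float, float] | None = None,
    shape: tuple[int, int, int] | None = None,
) -> SUVImage:
    """Render a patient's spherical lesions onto an SUV voxel grid.

    Each lesion occupies voxel centres strictly inside its sphere, with SUV
    decaying linearly from SUVmax at the centre to just above the 2.5
    segmentation threshold at the boundary; the voxel nearest the lesion
    centre is set to SUVmax exactly.  The background is uniform noise well
    below threshold.  Lesions smaller than one voxel are rendered as a
    single voxel (with a warning).  ``origin``/``shape`` may pin the grid
    explicitly (useful for constructed fixtures); by default the grid is
    the lesion bounding box plus a margin.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    centers = np.array([l.center_mm for l in patient.lesions], dtype=float)
    radii = np.array([l.radius_mm for l in patient.lesions], dtype=float)
    if origin is None:
        lo = (centers - radii[:, None]).min(axis=0) - margin_voxels * spacing_mm
        origin = tuple(lo)
    if shape is None:
        hi = (centers + radii[:, None]).max(axis=0) + margin_voxels * spacing_mm
        shape = tuple(
            int(math.ceil((hi[a] - origin[a]) / spacing_mm)) + 1 for a in range(3)
        )

    values = rng.uniform(0.3, 1.8, size=shape)  # sub-threshold background
    eps = 0.01
    voxel_volume = spacing_mm**3 / 1000.0
    for les, center, radius in zip(patient.lesions, centers, radii):
        if les.volume_ml < voxel_volume:
            warnings.warn(
                f"lesion of {les.volume_ml:.4f} ml below one voxel; rendered as one voxel",
                stacklevel=2,
            )
        lo_idx = np.maximum(0, np.floor((center - radius - np.asarray(origin)) / spacing_mm)).astype(int)
        hi_idx = np.minimum(
            np.asarray(shape) - 1,
            np.ceil((center + radius - np.asarray(origin)) / spacing_mm),
        ).astype(int)
        ax = [np.arange(lo_idx[a], hi_idx[a] + 1) for a in range(3)]
        grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
        coords = np.asarray(origin) + grid * spacing_mm
        dist = np.linalg.norm(coords - center, axis=-1)
        inside = dist < radius
        suv = SUV_THRESHOLD + (les.suv_max - SUV_THRESHOLD) * (1.0 - dist / max(radius, 1e-9))
        suv = np.maximum(suv, SUV_THRESHOLD + eps)
        block = values[
            lo_idx[0] : hi_idx[0] + 1, lo_idx[1] : hi_idx[1] + 1, lo_idx[2] : hi_idx[2] + 1
        ]
        block[inside] = suv[inside]
        # voxel nearest the centre carries SUVmax exactly
        nearest = np.round((center - np.asarray(origin)) / spacing_mm).astype(int)
        nearest = np.clip(nearest, 0, np.asarray(shape) - 1)
        values[tuple(nearest)] = les.suv_max
    return SUVImage(values=values, spacing=(spacing_mm,) * 3, origin=origin)
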