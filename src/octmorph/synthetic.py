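"""Ground-truthed synthetic inputs: vessel phantoms and patient cohorts.

Two levels of synthesis:

* **Vessel phantoms** — 1D line profiles (and 2D cross-section images) of a
  vessel as seen on an OCT B-scan: bright perivascular tissue, two dark wall
  bands, and an intermediate lumen, joined by linear intensity ramps. The
  analytic wall boundaries are the ramp midpoints, which are exactly the
  half-maximum crossings the FWHM algorithm should recover; optional additive
  Gaussian noise emulates acquisition noise.

* **Patient cohorts** — NDR/DR cohorts whose covariates, retinopathy-stage
  distribution and vessel geometry are drawn from the published group
  summaries of the reference study (``table_matched`` preset) or from its
  reduced stage-regression equations (``regression_matched`` preset). Wall
  thickness is sampled and OD derived as LD + 2·WT, which guarantees valid
  geometry. The two presets are deliberately distinct: the printed DR group
  means and the printed stage regressions are not mutually consistent, so
  each preset matches one of the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import reference_tables as ref
from .errors import (
    GeometryDoesNotFit,
    InvalidSpec,
    OctMorphError,
    UnknownPreset,
)
from .fwhm import MeasureParams
from .morphometry import (
    ProfileMeasurement,
    ScanLine,
    aggregate_measurements,
    measure_profile_detailed,
    quality_check,
    wall_cross_sectional_area,
    wall_thickness,
    wall_to_lumen_ratio,
)
from .profile import IntensityProfile
from .stats import PatientRecord, VesselParams

# --------------------------------------------------------------------------
# vessel phantoms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticVesselTruth:
    """Geometry and intensity levels of one synthetic vessel cross-section."""

    center_um: float
    ld_true_um: float
    od_true_um: float
    ramp_halfwidth_um: float = 1.0
    intensity_tissue: float = 200.0
    intensity_wall: float = 50.0
    intensity_lumen: float = 120.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.od_true_um > self.ld_true_um > 0):
            raise InvalidSpec("need od_true > ld_true > 0")
        if self.intensity_wall >= min(self.intensity_tissue, self.intensity_lumen):
            raise InvalidSpec("wall must be darker than tissue and lumen")
        wt = (self.od_true_um - self.ld_true_um) / 2.0
        if not (0 < self.ramp_halfwidth_um < wt / 2.0):
            raise InvalidSpec("ramp halfwidth must be in (0, wall thickness / 2)")
        if self.ramp_halfwidth_um >= self.ld_true_um / 2.0:
            raise InvalidSpec("ramp halfwidth must be below half the lumen")
        if self.noise_sd < 0:
            raise InvalidSpec("noise_sd must be >= 0")

    @property
    def boundaries_um(self) -> tuple[float, float, float, float]:
        """Analytic wall-edge positions (outer, inner, inner, outer), µm."""
        c, ld2, od2 = self.center_um, self.ld_true_um / 2.0, self.od_true_um / 2.0
        return (c - od2, c - ld2, c + ld2, c + od2)


def _phantom_intensity(truth: SyntheticVesselTruth, x_um: np.ndarray) -> np.ndarray:
    """Noise-free phantom intensity at arbitrary positions.

    Piecewise-constant plateaus tissue|wall|lumen|wall|tissue joined by linear
    ramps of half-width ``ramp_halfwidth_um`` centred on the true boundaries.
    """
    b1, b2, b3, b4 = truth.boundaries_um
    r = truth.ramp_halfwidth_um
    ti, wa, lu = truth.intensity_tissue, truth.intensity_wall, truth.intensity_lumen
    knots = np.array([b1 - r, b1 + r, b2 - r, b2 + r, b3 - r, b3 + r, b4 - r, b4 + r])
    levels = np.array([ti, wa, wa, lu, lu, wa, wa, ti])
    return np.interp(x_um, knots, levels, left=ti, right=ti)


def render_profile(
    truth: SyntheticVesselTruth,
    n_samples: int = 0,
    spacing_um: float = 1.0,
    origin_um: float = 0.0,
    rng: np.random.Generator | None = None,
    margin_um: float = 5.0,
) -> tuple[IntensityProfile, tuple[float, float, float, float]]:
    """Render a phantom line profile and return its analytic boundaries.

    With ``n_samples=0`` the window is sized automatically to cover the
    vessel plus ``margin_um`` on each side starting from ``origin_um``. The
    window must contain the whole vessel with at least 5 µm margins.
    """
    b1, _, _, b4 = truth.boundaries_um
    if n_samples <= 0:
        end = b4 + truth.ramp_halfwidth_um + margin_um
        n_samples = int(math.ceil((end - origin_um) / spacing_um)) + 1
    last = origin_um + (n_samples - 1) * spacing_um
    if origin_um > b1 - truth.ramp_halfwidth_um - 5.0 or last < (
        b4 + truth.ramp_halfwidth_um + 5.0
    ):
        raise GeometryDoesNotFit(
            f"window [{origin_um}, {last}] um does not contain the vessel "
            f"[{b1}, {b4}] um with 5 um margins"
        )
    x = origin_um + spacing_um * np.arange(n_samples)
    samples = _phantom_intensity(truth, x)
    if truth.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(truth.seed)
        samples = samples + rng.normal(0.0, truth.noise_sd, samples.size)
        samples = np.clip(samples, 0.0, None)
    prof = IntensityProfile(samples=samples, spacing_um=spacing_um, origin_um=origin_um)
    return prof, truth.boundaries_um


def render_bscan(
    truth: SyntheticVesselTruth,
    width_px: int,
    height_px: int,
    um_per_px: float = 1.0,
    vessel_axis_deg: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, ScanLine]:
    """Render a 2D vessel cross-section image and a centred scan line.

    Concentric-ring model: the radial intensity profile of the phantom is
    revolved about the vessel centre (dark wall annulus, intermediate lumen,
    bright tissue background). The returned scan line runs through the centre
    perpendicular to ``vessel_axis_deg`` (degrees, x-axis = 0).
    """
    cx = (width_px - 1) / 2.0
    cy = (height_px - 1) / 2.0
    r_out = truth.od_true_um / 2.0 + truth.ramp_halfwidth_um
    half_span = min(width_px - 1 - cx, cx, height_px - 1 - cy, cy) * um_per_px
    if r_out + 5.0 > half_span:
        raise GeometryDoesNotFit("vessel plus margins does not fit in the image")

    yy, xx = np.mgrid[0:height_px, 0:width_px]
    rho = np.hypot((xx - cx) * um_per_px, (yy - cy) * um_per_px)
    ld2, od2 = truth.ld_true_um / 2.0, truth.od_true_um / 2.0
    r = truth.ramp_halfwidth_um
    knots = np.array([ld2 - r, ld2 + r, od2 - r, od2 + r])
    levels = np.array(
        [truth.intensity_lumen, truth.intensity_wall, truth.intensity_wall,
         truth.intensity_tissue]
    )
    img = np.interp(rho, knots, levels,
                    left=truth.intensity_lumen, right=truth.intensity_tissue)
    if truth.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(truth.seed)
        img = np.clip(img + rng.normal(0.0, truth.noise_sd, img.shape), 0.0, None)

    theta = math.radians(vessel_axis_deg + 90.0)
    dx, dy = math.cos(theta), math.sin(theta)
    span_px = (r_out + 5.0) / um_per_px
    line = ScanLine(
        p0=(cx - dx * span_px, cy - dy * span_px),
        p1=(cx + dx * span_px, cy + dy * span_px),
        note=f"through vessel centre, perpendicular to axis {vessel_axis_deg} deg",
    )
    return img, line


# --------------------------------------------------------------------------
# cohort specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupDist:
    """Normal(mean, sd) sampling distribution, truncated at ``low``."""

    mean: float
    sd: float
    low: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise InvalidSpec("SD must be > 0")


@dataclass(frozen=True)
class StageLink:
    """Linear link value = intercept + slope * stage + N(0, resid_sd)."""

    intercept: float
    slope: float
    resid_sd: float


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for one synthetic NDR/DR cohort."""

    preset: str
    n_ndr: int
    n_dr: int
    male_fraction: dict  # group -> fraction
    age: dict  # group -> GroupDist
    bmi: dict
    duration: dict
    stage_probs: tuple  # stages I..VI
    artery_ld: dict
    artery_wt: dict
    vein_ld: dict
    vein_wt: dict
    dr_links: dict | None = None  # {"artery_ld": StageLink, ...}
    pi_mode: str = "exact"

    def __post_init__(self) -> None:
        if self.n_ndr < 1 or self.n_dr < 1:
            raise InvalidSpec("both groups must be non-empty")
        if len(self.stage_probs) != 6 or abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise InvalidSpec("stage_probs must be 6 probabilities summing to 1")
        if any(p < 0 for p in self.stage_probs):
            raise InvalidSpec("stage probabilities must be non-negative")
        for grp in ("NDR", "DR"):
            if not (0.0 <= self.male_fraction[grp] <= 1.0):
                raise InvalidSpec("male_fraction must be in [0, 1]")


def _stage_moments(stage_probs) -> tuple[float, float]:
    stages = np.arange(1, 7, dtype=float)
    p = np.asarray(stage_probs, dtype=float)
    mean = float(np.sum(stages * p))
    var = float(np.sum(stages**2 * p) - mean**2)
    return mean, var


def _resid_sd_from_r2(slope: float, stage_var: float, r2: float) -> float:
    """Residual SD making a stage link reproduce a target within-group R²."""
    if not (0 < r2 < 1):
        raise InvalidSpec("R² must be in (0, 1)")
    return abs(slope) * math.sqrt(stage_var * (1.0 - r2) / r2)


def default_cohort_spec(preset: str = "table_matched") -> CohortSpec:
    """Fully-populated cohort spec calibrated to the reference study.

    ``table_matched`` draws vessel LD and WT per group from the published
    group means ± SD; ``regression_matched`` draws the DR group's LD and WT
    from the published stage-regression equations, with residual SDs solved
    from the printed R² values (the NDR group is table-matched in both).
    """
    if preset not in ("table_matched", "regression_matched"):
        raise UnknownPreset(f"unknown preset {preset!r}")
    counts = np.asarray(ref.STAGE_COUNTS, dtype=float)
    stage_probs = tuple(counts / counts.sum())

    def gd(pair, low=0.0):
        return GroupDist(mean=pair[0], sd=pair[1], low=low)

    spec = CohortSpec(
        preset=preset,
        n_ndr=ref.GROUP_SIZES["NDR"],
        n_dr=ref.GROUP_SIZES["DR"],
        male_fraction={
            g: ref.SEX_COUNTS[g][0] / sum(ref.SEX_COUNTS[g]) for g in ("NDR", "DR")
        },
        age={g: gd(ref.AGE_YEARS[g], low=18.0) for g in ("NDR", "DR")},
        bmi={g: gd(ref.BMI[g], low=10.0) for g in ("NDR", "DR")},
        # diabetes duration is not summarised in the reference tables; a
        # plausible T2DM default, truncated at half a year
        duration={g: GroupDist(10.0, 5.0, low=0.5) for g in ("NDR", "DR")},
        stage_probs=stage_probs,
        artery_ld={g: gd(ref.ARTERY[g]["ld"], low=10.0) for g in ("NDR", "DR")},
        artery_wt={g: gd(ref.ARTERY[g]["wt"], low=1.0) for g in ("NDR", "DR")},
        vein_ld={g: gd(ref.VEIN[g]["ld"], low=10.0) for g in ("NDR", "DR")},
        vein_wt={g: gd(ref.VEIN[g]["wt"], low=1.0) for g in ("NDR", "DR")},
    )
    if preset == "regression_matched":
        _, stage_var = _stage_moments(stage_probs)
        links = {}
        for key, (vessel, param) in {
            "artery_ld": ("artery", "ld"),
            "artery_wt": ("artery", "wt"),
            "vein_ld": ("vein", "ld"),
            "vein_wt": ("vein", "wt"),
        }.items():
            pred, a, b, r2, _f = ref.REPORTED_REGRESSIONS[(vessel, param)]
            assert pred == "stage"
            links[key] = StageLink(a, b, _resid_sd_from_r2(b, stage_var, r2))
        spec = replace(spec, dr_links=links)
    return spec


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------


def _trunc_normal(rng: np.random.Generator, dist: GroupDist) -> float:
    """Normal draw resampled until above the truncation bound."""
    for _ in range(1000):
        v = rng.normal(dist.mean, dist.sd)
        if v > dist.low:
            return float(v)
    raise InvalidSpec(
        f"truncated normal({dist.mean}, {dist.sd}) > {dist.low} keeps rejecting"
    )


def _sample_geometry(
    spec: CohortSpec, group: str, stage: int, rng: np.random.Generator, vessel: str
) -> tuple[float, float]:
    """Draw (ld, wt) for one vessel of one patient."""
    ld_dist: GroupDist = getattr(spec, f"{vessel}_ld")[group]
    wt_dist: GroupDist = getattr(spec, f"{vessel}_wt")[group]
    if spec.preset == "regression_matched" and group == "DR":
        links = spec.dr_links
        for _ in range(1000):
            lk: StageLink = links[f"{vessel}_ld"]
            ld = lk.intercept + lk.slope * stage + rng.normal(0.0, lk.resid_sd)
            lk = links[f"{vessel}_wt"]
            wt = lk.intercept + lk.slope * stage + rng.normal(0.0, lk.resid_sd)
            if ld > ld_dist.low and wt > wt_dist.low:
                return ld, wt
        raise InvalidSpec("regression-linked geometry keeps rejecting")
    return _trunc_normal(rng, ld_dist), _trunc_normal(rng, wt_dist)


def sample_patient(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    patient_id: str = "p0",
) -> PatientRecord:
    """Draw one patient record (truth-level morphometry, no rendering)."""
    if group not in ("NDR", "DR"):
        raise InvalidSpec(f"unknown group {group!r}")
    sex = "male" if rng.random() < spec.male_fraction[group] else "female"
    age = _trunc_normal(rng, spec.age[group])
    bmi = _trunc_normal(rng, spec.bmi[group])
    duration = _trunc_normal(rng, spec.duration[group])
    stage = 0
    if group == "DR":
        stage = int(rng.choice(np.arange(1, 7), p=np.asarray(spec.stage_probs)))
    vessels = {}
    for vessel in ("artery", "vein"):
        ld, wt = _sample_geometry(spec, group, stage, rng, vessel)
        od = ld + 2.0 * wt
        vessels[vessel] = VesselParams(
            ld=ld,
            od=od,
            wt=wall_thickness(od, ld),
            wlr=wall_to_lumen_ratio(od, ld),
            wcsa=wall_cross_sectional_area(od, ld, spec.pi_mode),
        )
    return PatientRecord(
        id=patient_id,
        group=group,
        sex=sex,
        age=age,
        bmi=bmi,
        diabetes_duration=duration,
        dr_stage=stage,
        artery=vessels["artery"],
        vein=vessels["vein"],
    )


@dataclass(frozen=True)
class RenderSettings:
    """How per-patient profiles are rendered and measured end-to-end."""

    n_images: int = 5
    n_repeats: int = 3
    noise_sd: float = 5.0
    spacing_um: float = 1.0
    ramp_halfwidth_um: float = 1.0
    intensity_tissue: float = 200.0
    intensity_wall: float = 50.0
    intensity_lumen: float = 120.0
    min_contrast: float = 30.0
    run_length: int = 3


def _measure_vessel_from_profiles(
    truth_ld: float,
    truth_wt: float,
    rs: RenderSettings,
    rng: np.random.Generator,
    vessel_type: str = "artery",
) -> tuple[float, float]:
    """Render n_images x n_repeats noisy profiles of one vessel, measure each
    with the FWHM pipeline, run quality control, and aggregate.

    Each repeat is an independently re-acquired noisy profile of the same
    vessel (re-measurement of a fixed image would be a no-op for a
    deterministic algorithm).
    """
    od = truth_ld + 2.0 * truth_wt
    truth = SyntheticVesselTruth(
        center_um=od / 2.0 + 10.0,
        ld_true_um=truth_ld,
        od_true_um=od,
        ramp_halfwidth_um=min(rs.ramp_halfwidth_um, 0.45 * truth_wt),
        intensity_tissue=rs.intensity_tissue,
        intensity_wall=rs.intensity_wall,
        intensity_lumen=rs.intensity_lumen,
        noise_sd=rs.noise_sd,
    )
    params = MeasureParams(min_contrast=rs.min_contrast, run_length=rs.run_length)
    per_image = []
    for _ in range(rs.n_images):
        repeats = []
        for _ in range(rs.n_repeats):
            prof, _b = render_profile(
                truth, spacing_um=rs.spacing_um, rng=rng
            )
            try:
                outcome: ProfileMeasurement | Exception = measure_profile_detailed(
                    prof, params
                )
            except OctMorphError as exc:
                outcome = exc
            ok, _reason = quality_check(outcome, min_contrast=rs.min_contrast)
            if ok:
                repeats.append(outcome.boundaries)
        per_image.append(repeats)
    # strict only when nothing was rejected; rejected repeats reduce the image
    strict = all(len(r) == 3 for r in per_image) and len(per_image) >= 5
    vm = aggregate_measurements(per_image, vessel_type=vessel_type, strict=strict)
    return vm.ld_um, vm.od_um


def generate_cohort(
    spec: CohortSpec,
    seed: int,
    measure_from_profiles: bool = False,
    render_settings: RenderSettings = RenderSettings(),
) -> list[PatientRecord]:
    """Generate a reproducible cohort of ``n_ndr + n_dr`` patients.

    With ``measure_from_profiles=True`` each vessel's diameters are obtained
    by rendering noisy line profiles and running the full FWHM measurement
    pipeline (5 images × 3 repeats by default) instead of copying the truth
    values, so the cohort statistics exercise every stage.
    """
    # separate streams so the same seed yields identical patient truths
    # whether or not profiles are rendered and measured
    rng = np.random.default_rng([seed, 0])
    render_rng = np.random.default_rng([seed, 1])
    records: list[PatientRecord] = []
    i = 0
    for group, n in (("NDR", spec.n_ndr), ("DR", spec.n_dr)):
        for _ in range(n):
            rec = sample_patient(spec, group, rng, patient_id=f"{group.lower()}{i:03d}")
            if measure_from_profiles:
                vessels = {}
                for vessel in ("artery", "vein"):
                    truth: VesselParams = getattr(rec, vessel)
                    ld, od = _measure_vessel_from_profiles(
                        truth.ld, truth.wt, render_settings, render_rng,
                        vessel_type=vessel,
                    )
                    vessels[vessel] = VesselParams(
                        ld=ld,
                        od=od,
                        wt=wall_thickness(od, ld),
                        wlr=wall_to_lumen_ratio(od, ld),
                        wcsa=wall_cross_sectional_area(od, ld, spec.pi_mode),
                    )
                rec = replace(rec, artery=vessels["artery"], vein=vessels["vein"])
            records.append(rec)
            i += 1
    return records
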