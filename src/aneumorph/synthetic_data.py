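"""Vessel+dome phantoms with analytic truth, and simulated rater tables.

The clinical data the statistics were designed for (CTA scans of saccular
intracranial aneurysms sized by several human raters) is private, so this
module supplies two synthetic substitutes:

* **Phantoms** — the voxel union of a cylindrical parent vessel and a
  spherical dome attached at a neck, emitted as a binary mask with a
  ground-truth record carrying the analytic maximum dome diameter
  (2 x dome radius), the dome centre, and a neck plane separating dome
  from vessel. Every phantom has a closed-form truth by construction.

* **Rater simulators** — measurements generated from the additive model

      m = s_true + bias_r + eps,   eps ~ Normal(0, (sd_r * kappa^[ruptured])^2)

  truncated below at 0.1 mm. ``bias_r`` captures systematic offsets, most
  importantly the undersizing of manual 2D-plane measurements relative to
  the 3D truth (modelled as a negative bias, default calibration -3.0 mm);
  ``sd_r`` is the rater's random error, inflated by ``kappa >= 1`` for
  ruptured cases where adjacent blood obscures the dome boundary.

Default rater calibrations mirror the magnitudes reported for a senior
neuroradiologist (SD ~1.2 mm unruptured / ~1.7 mm ruptured) and junior
raters (SD ~1.7-2.7 mm unruptured / ~2.7-5.1 mm ruptured); they are
simulation defaults, not estimates from any accessible dataset.

Randomness contract: every simulator takes one root seed and derives
independent per-rater streams from it deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from aneumorph.errors import ResolutionError, ValidationError
from aneumorph.growth_monitoring import classify_interval
from aneumorph.io_formats import BinaryVolume, MeasurementRecord, MeasurementTable
from aneumorph.mesh_geometry import SurfaceMesh


@dataclass
class GroundTruth:
    """Analytic truth for one phantom aneurysm."""

    case_id: str
    dome_center: np.ndarray  # world mm
    true_max_diameter_mm: float
    neck_plane: tuple[np.ndarray, np.ndarray]  # (point, unit normal), dome on +normal side
    rupture_status: str = "unruptured"

    def __post_init__(self) -> None:
        self.dome_center = np.asarray(self.dome_center, dtype=float)
        point, normal = (np.asarray(x, dtype=float) for x in self.neck_plane)
        n = np.linalg.norm(normal)
        if n == 0:
            raise ValidationError("neck plane normal must be non-zero")
        self.neck_plane = (point, normal / n)
        if self.true_max_diameter_mm <= 0:
            raise ValidationError("true diameter must be positive")


@dataclass
class RaterProfile:
    """Generative error parameters of one (real or simulated) rater."""

    rater_id: str
    bias_mm: float = 0.0
    sd_mm: float = 1.0
    ruptured_sd_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_mm <= 0:
            raise ValidationError("sd_mm must be positive")
        if self.ruptured_sd_multiplier < 1:
            raise ValidationError("ruptured_sd_multiplier must be >= 1")


#: Simulation defaults calibrated to the magnitudes reported for a senior
#: rater and four junior raters (unruptured SD, ruptured multiplier), with
#: the manual-vs-3D undersizing as a -3.0 mm bias. Defaults only — never
#: used as test oracles.
DEFAULT_PROFILES: tuple[RaterProfile, ...] = (
    RaterProfile("senior", bias_mm=-3.0, sd_mm=1.23, ruptured_sd_multiplier=1.73 / 1.23),
    RaterProfile("junior1", bias_mm=-3.0, sd_mm=1.67, ruptured_sd_multiplier=3.80 / 1.67),
    RaterProfile("junior2", bias_mm=-3.0, sd_mm=1.65, ruptured_sd_multiplier=3.07 / 1.65),
    RaterProfile("junior3", bias_mm=-3.0, sd_mm=2.68, ruptured_sd_multiplier=5.12 / 2.68),
    RaterProfile("junior4", bias_mm=-3.0, sd_mm=1.87, ruptured_sd_multiplier=2.72 / 1.87),
    RaterProfile("computerized", bias_mm=0.0, sd_mm=0.3, ruptured_sd_multiplier=1.0),
)

MIN_SIZE_MM = 0.1  # truncation floor keeping simulated sizes positive


def make_sphere_mesh(radius_mm: float, subdivisions: int = 2) -> SurfaceMesh:
    """Icosphere: subdivided icosahedron with vertices projected to the radius.

    Centrally symmetric, so the vertex-set diameter is exactly 2 r; vertex
    count is 10 * 4^n + 2 at subdivision level n.
    """
    if radius_mm <= 0:
        raise ValidationError("radius must be positive")
    if subdivisions < 0:
        raise ValidationError("subdivisions must be >= 0")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    return SurfaceMesh(vertices=np.asarray(ico.vertices, float), faces=np.asarray(ico.faces))


def make_vessel_phantom(
    dome_radius_mm: float = 3.0,
    tube_radius_mm: float = 1.5,
    tube_length_mm: float = 20.0,
    neck_offset_mm: float = 1.0,
    spacing: float | tuple[float, float, float] = 0.3,
    rupture_status: str = "unruptured",
    case_id: str = "phantom",
    branch_length_mm: float = 0.0,
) -> tuple[BinaryVolume, GroundTruth]:
    """Voxelized parent vessel (cylinder along x) with a spherical dome.

    The dome sphere of radius ``r_d`` sits above the tube, its centre at
    height ``z_c = tube_radius + r_d - neck_offset`` so the two overlap by
    ``neck_offset`` (the neck). The ground-truth maximum diameter is
    ``2 r_d``; the neck plane is horizontal, halfway between the tube top
    and the sphere centre, which cuts the sphere in a circle clear of the
    tube while keeping the dome cap larger than a hemisphere (so the cap
    still realizes the full diameter at its equator).

    ``branch_length_mm > 0`` adds a perpendicular side branch at the far
    tube end — geodesically remote from the dome — for ROI-exclusion tests.
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), 3).copy()
    if np.any(spacing <= 0):
        raise ValidationError("spacing must be positive")
    if dome_radius_mm <= 0 or tube_radius_mm <= 0:
        raise ValidationError("radii must be positive")
    if not 0 < neck_offset_mm < dome_radius_mm:
        raise ValidationError("neck_offset_mm must be in (0, dome_radius_mm)")
    if 2 * dome_radius_mm / spacing.max() < 4:
        raise ResolutionError(
            f"spacing {spacing.max()} too coarse: fewer than 4 voxels across the "
            f"{2 * dome_radius_mm} mm dome"
        )
    z_center = tube_radius_mm + dome_radius_mm - neck_offset_mm
    margin = 2.0 * spacing.max()
    lo = np.array(
        [
            -tube_length_mm / 2 - margin,
            -max(tube_radius_mm, dome_radius_mm) - branch_length_mm - margin,
            -tube_radius_mm - margin,
        ]
    )
    hi = np.array(
        [
            tube_length_mm / 2 + margin,
            max(tube_radius_mm, dome_radius_mm) + margin,
            z_center + dome_radius_mm + margin,
        ]
    )
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    idx = np.indices(shape, dtype=float)
    x = lo[0] + idx[0] * spacing[0]
    y = lo[1] + idx[1] * spacing[1]
    z = lo[2] + idx[2] * spacing[2]
    tube = (y**2 + z**2 <= tube_radius_mm**2) & (np.abs(x) <= tube_length_mm / 2)
    dome = x**2 + y**2 + (z - z_center) ** 2 <= dome_radius_mm**2
    mask = tube | dome
    if branch_length_mm > 0:
        bx = tube_length_mm / 2 - tube_radius_mm
        branch = ((x - bx) ** 2 + z**2 <= tube_radius_mm**2) & (y <= 0) & (y >= -branch_length_mm)
        mask |= branch
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = lo
    volume = BinaryVolume(voxels=mask.astype(np.uint8), affine=affine)
    truth = GroundTruth(
        case_id=case_id,
        dome_center=np.array([0.0, 0.0, z_center]),
        true_max_diameter_mm=2.0 * dome_radius_mm,
        neck_plane=(
            np.array([0.0, 0.0, (tube_radius_mm + z_center) / 2.0]),
            np.array([0.0, 0.0, 1.0]),
        ),
        rupture_status=rupture_status,
    )
    return volume, truth


def _profile_streams(profiles, seed: int) -> list[np.random.Generator]:
    root = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in root.spawn(len(profiles))]


def simulate_rater_measurements(
    truths,
    profiles,
    sessions_per_rater: int = 1,
    seed: int = 0,
    timepoint: int = 0,
) -> MeasurementTable:
    """One simulated measurement per (truth x profile x session).

    Sizes follow the additive truncated-Gaussian model documented at module
    level; output is reproducible given the same root seed.
    """
    truths = list(truths)
    profiles = list(profiles)
    if not truths:
        raise ValidationError("no ground truths given")
    if not profiles:
        raise ValidationError("no rater profiles given")
    records = []
    for profile, rng in zip(profiles, _profile_streams(profiles, seed)):
        for truth in truths:
            sd = profile.sd_mm * (
                profile.ruptured_sd_multiplier if truth.rupture_status == "ruptured" else 1.0
            )
            noise = rng.normal(0.0, sd, size=sessions_per_rater)
            for s in range(sessions_per_rater):
                size = max(truth.true_max_diameter_mm + profile.bias_mm + noise[s], MIN_SIZE_MM)
                records.append(
                    MeasurementRecord(
                        case_id=truth.case_id,
                        rater_id=profile.rater_id,
                        session=s + 1,
                        timepoint=timepoint,
                        size_mm=float(size),
                        rupture_status=truth.rupture_status,
                    )
                )
    return MeasurementTable(records)


def simulate_longitudinal_cohort(
    n_cases: int,
    timepoints: int,
    growth_rates_mm,
    profiles,
    seed: int = 0,
    baseline_median_mm: float = 3.38,
    baseline_log_sd: float = 0.5,
    ruptured_fraction: float = 201.0 / 358.0,
    threshold_mm: float = 1.0,
) -> tuple[MeasurementTable, dict[tuple[str, tuple[int, int]], str]]:
    """Follow-up cohort with known per-interval growth and noisy raters.

    True baseline sizes are log-normal around a 3.38 mm median (the typical
    size scale of incidentally found aneurysms); each case then grows by
    its ``growth_rates_mm`` (scalar or per-case array) per interval. The
    true interval statuses come from the >= threshold rule applied to the
    noiseless sizes; the returned table holds the noisy rater measurements
    for every timepoint.
    """
    if timepoints < 2:
        raise ValidationError("need at least 2 timepoints")
    if n_cases < 1:
        raise ValidationError("need at least 1 case")
    profiles = list(profiles)
    rates = np.broadcast_to(np.asarray(growth_rates_mm, dtype=float), n_cases).copy()
    root = np.random.SeedSequence(seed)
    case_seed, meas_seed = root.spawn(2)
    rng = np.random.default_rng(case_seed)
    base = np.exp(np.log(baseline_median_mm) + baseline_log_sd * rng.standard_normal(n_cases))
    ruptured = rng.random(n_cases) < ruptured_fraction
    true_status: dict[tuple[str, tuple[int, int]], str] = {}
    all_records: list[MeasurementRecord] = []
    meas_children = meas_seed.spawn(timepoints)
    for t in range(timepoints):
        truths = []
        for i in range(n_cases):
            size = max(base[i] + t * rates[i], MIN_SIZE_MM)
            truths.append(
                GroundTruth(
                    case_id=f"case{i:04d}",
                    dome_center=np.zeros(3),
                    true_max_diameter_mm=size,
                    neck_plane=(np.zeros(3), np.array([0.0, 0.0, 1.0])),
                    rupture_status="ruptured" if ruptured[i] else "unruptured",
                )
            )
            if t > 0:
                prev = max(base[i] + (t - 1) * rates[i], MIN_SIZE_MM)
                a = classify_interval(prev, size, threshold_mm, case_id=truths[-1].case_id,
                                      interval=(t - 1, t))
                true_status[(a.case_id, a.interval)] = a.status
        table_t = simulate_rater_measurements(
            truths,
            profiles,
            sessions_per_rater=1,
            seed=int(meas_children[t].generate_state(1)[0] % (2**31)),
            timepoint=t,
        )
        all_records.extend(table_t.records)
    return MeasurementTable(all_records), true_status
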