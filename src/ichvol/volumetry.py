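"""ICH volumetry on labeled masks: voxel reference, ABC/2 and a simulated
automated segmenter.

Three measurement routes, mirroring clinical practice:

* ``voxel_volume_mL`` — voxel counting, the digital idealization of
  semi-automatic threshold segmentation; used as the reference standard.
* ``abc2_measure`` — the bedside ABC/2 estimator: largest axial diameter A,
  largest perpendicular diameter B on the same slice, and a weighted slice
  count C, combined as A*B*C/2 (exact for an ellipsoid up to pi/6 vs 1/2).
* ``simulate_auto_segmentation`` — a parametric error model of fully
  automated segmentation with the documented failure modes: missed small
  haematomas (logistic detection in log-volume), inclusion of
  intraventricular blood, partial segmentation, inclusion of distractor
  hyperdensities, and multiplicative measurement noise.

Intraventricular haemorrhage is never counted as ICH: every ICH volume here
is computed from label 1 alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.special import expit

from .phantoms import ICH, LabeledVolume, PhantomRecord

__all__ = [
    "ABC2Measurement",
    "MeasurementRecord",
    "AutoSegErrorModel",
    "voxel_volume_mL",
    "abc2_measure",
    "simulate_auto_segmentation",
    "simulate_abc2_reader",
    "measure_reference",
    "records_to_frame",
    "write_measurements_csv",
    "read_measurements_csv",
    "MEASUREMENT_COLUMNS",
]

MEASUREMENT_COLUMNS = [
    "case_id", "method", "reader_id", "volume_mL",
    "missed", "partial", "ivh_included", "distractor_included",
]


@dataclass(frozen=True)
class ABC2Measurement:
    """One ABC/2 reading: diameters in cm and the resulting volume in mL."""

    A_cm: float
    B_cm: float
    C_cm: float
    volume_mL: float
    reference_slice_index: int
    slice_thickness_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.B_cm > self.A_cm + 1e-12:
            raise ValueError("B must not exceed A")
        if abs(self.volume_mL - self.A_cm * self.B_cm * self.C_cm / 2.0) > 1e-9:
            raise ValueError("volume_mL must equal A*B*C/2")


@dataclass(frozen=True)
class MeasurementRecord:
    """One volume measurement by one method/reader, with failure-event flags."""

    case_id: str
    method: str  # reference_voxel | abc2 | auto_sim
    reader_id: str | None = None
    volume_mL: float | None = None
    missed: bool = False
    partial: bool = False
    ivh_included: bool = False
    distractor_included: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("reference_voxel", "abc2", "auto_sim"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.missed and self.volume_mL is not None:
            raise ValueError("a missed case must have no volume")
        if not self.missed and self.volume_mL is None:
            raise ValueError("a non-missed case must carry a volume")
        if self.method == "reference_voxel" and (
            self.partial or self.ivh_included or self.distractor_included or self.missed
        ):
            raise ValueError("the voxel reference carries no failure flags")


@dataclass
class AutoSegErrorModel:
    """Parametric failure model of a fully automated ICH segmenter.

    Detection follows a logistic model in log-volume:
    ``P(detect) = expit(detect_intercept + detect_slope * ln V)``.  Detected
    cases get multiplicative log-normal noise and may additionally include
    the full IVH volume, drop a fraction of the haematoma (partial
    segmentation) or include a distractor hyperdensity.

    The defaults are calibrated so that, on a cohort with log-normal volumes
    of median 26.0 mL and IQR 9.3-59.2 mL, about 83% of haematomas are
    detected and the missed ones are predominantly small (median ~5 mL) —
    the behaviour reported for commercial automated software.  Event
    probabilities follow the observed event counts: IVH included in 131/148
    IVH cases, partial segmentation in 55/250 detected cases.
    """

    detect_intercept: float = -2.9803
    detect_slope: float = 1.8221
    p_ivh_include: float = 131.0 / 148.0
    p_partial: float = 55.0 / 250.0
    partial_fraction_range: tuple[float, float] = (0.2, 0.6)
    p_distractor_include: float = 0.4
    distractor_volume_mL_range: tuple[float, float] = (0.5, 3.0)
    multiplicative_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        for name in ("p_ivh_include", "p_partial", "p_distractor_include"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.partial_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError("partial_fraction_range must lie within (0, 1)")
        if self.multiplicative_noise_sd < 0:
            raise ValueError("multiplicative_noise_sd must be >= 0")

    @classmethod
    def error_free(cls) -> "AutoSegErrorModel":
        """A degenerate model: always detects, reproduces the truth exactly."""
        return cls(
            detect_intercept=50.0,
            detect_slope=0.0,
            p_ivh_include=0.0,
            p_partial=0.0,
            p_distractor_include=0.0,
            multiplicative_noise_sd=0.0,
        )


# ---------------------------------------------------------------------------
# voxel reference
# ---------------------------------------------------------------------------

def voxel_volume_mL(volume: LabeledVolume, label: int = ICH) -> float:
    """Voxel-count volume of one label in mL; 0.0 when the label is absent."""
    if label not in (1, 2, 3):
        raise ValueError("label must be 1 (ICH), 2 (IVH) or 3 (distractor)")
    return volume.label_volume_mL(label)


def measure_reference(volume: LabeledVolume, case_id: str) -> MeasurementRecord:
    return MeasurementRecord(
        case_id=case_id, method="reference_voxel",
        volume_mL=voxel_volume_mL(volume, ICH),
    )


# ---------------------------------------------------------------------------
# ABC/2
# ---------------------------------------------------------------------------

def _perimeter_centers(mask2d: np.ndarray, sx: float, sy: float) -> np.ndarray:
    """Centre points (mm) of the perimeter voxels of a 2D mask."""
    perim = mask2d & ~ndimage.binary_erosion(mask2d)
    return (np.argwhere(perim) + 0.5) * (sx, sy)


def _feret(points: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Maximum pairwise (Feret) distance, its direction and the hull vertices.

    Measured between voxel centres: the digital analog of placing a ruler
    across the lesion on a viewer.
    """
    if len(points) > 4:
        hull = ConvexHull(points)
        pts = points[hull.vertices]
    else:
        pts = points
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    direction = pts[i] - pts[j]
    norm = np.linalg.norm(direction)
    if norm == 0:  # single voxel: caliper reduces to the footprint itself
        return 0.0, np.array([1.0, 0.0]), pts
    return float(norm), direction / norm, pts


def abc2_measure(volume: LabeledVolume, c_rule: str = "kothari_weighted") -> ABC2Measurement:
    """ABC/2 volume estimate from a labeled mask.

    The reference slice is the axial slice with the largest ICH area.  A is
    the maximal caliper (Feret) diameter of the ICH footprint on that slice,
    B the maximal extent perpendicular to A on the same slice, both in cm.

    C depends on the slice-count rule:

    * ``kothari_weighted`` — slices with area > 75% of the reference slice
      count fully, those between 25% and 75% count half, smaller ones not at
      all; C = weighted count x slice thickness (cm).
    * ``full_extent`` — every slice containing ICH counts fully.
    """
    if c_rule not in ("kothari_weighted", "full_extent"):
        raise ValueError(f"unknown c_rule {c_rule!r}")
    mask = volume.labels == ICH
    if not mask.any():
        raise ValueError("abc2_measure requires a nonempty ICH region")
    sx, sy, sz = volume.spacing_mm
    areas = mask.sum(axis=(0, 1))
    ref = int(np.argmax(areas))

    points = _perimeter_centers(mask[:, :, ref], sx, sy)
    a_mm, a_dir, hull_pts = _feret(points)
    perp = np.array([-a_dir[1], a_dir[0]])
    proj = hull_pts @ perp
    b_mm = float(proj.max() - proj.min())

    thickness_cm = sz / 10.0
    if c_rule == "full_extent":
        n_weighted = float(np.count_nonzero(areas > 0))
    else:
        frac = areas / areas[ref]
        weights = np.where(frac > 0.75, 1.0, np.where(frac >= 0.25, 0.5, 0.0))
        n_weighted = float(weights.sum())
    c_cm = thickness_cm * n_weighted

    a_cm, b_cm = a_mm / 10.0, b_mm / 10.0
    if b_cm > a_cm:  # guard against float jitter; A is the Feret maximum
        a_cm, b_cm = b_cm, a_cm
    return ABC2Measurement(
        A_cm=a_cm, B_cm=b_cm, C_cm=c_cm,
        volume_mL=a_cm * b_cm * c_cm / 2.0,
        reference_slice_index=ref,
        slice_thickness_cm=thickness_cm,
    )


# ---------------------------------------------------------------------------
# simulated automated segmentation
# ---------------------------------------------------------------------------

def simulate_auto_segmentation(
    volume: LabeledVolume | None,
    record: PhantomRecord,
    model: AutoSegErrorModel,
    seed: int,
) -> MeasurementRecord:
    """Simulate one automated-segmentation measurement of a phantom.

    The simulator is parametric in the case's true volumes, so ``volume``
    may be None; it is accepted for signature symmetry with the mask-based
    methods.  All random draws are made in a fixed order so that results are
    reproducible from ``seed`` regardless of which events fire.
    """
    rng = np.random.default_rng(seed)
    u_detect = rng.random()
    eps = rng.normal()
    u_partial = rng.random()
    pf = rng.uniform(*model.partial_fraction_range)
    u_ivh = rng.random()
    u_distr = rng.random()
    dvol = rng.uniform(*model.distractor_volume_mL_range)

    v_true = record.true_ich_volume_mL
    if v_true <= 0:
        raise ValueError(f"{record.case_id}: true ICH volume must be positive")
    p_detect = float(expit(model.detect_intercept + model.detect_slope * np.log(v_true)))
    if u_detect >= p_detect:
        return MeasurementRecord(case_id=record.case_id, method="auto_sim", missed=True)

    measured = v_true * float(np.exp(model.multiplicative_noise_sd * eps))
    partial = u_partial < model.p_partial
    if partial:
        measured *= 1.0 - pf
    ivh_included = record.ivh_present and u_ivh < model.p_ivh_include
    if ivh_included:
        measured += record.true_ivh_volume_mL
    distractor_included = u_distr < model.p_distractor_include
    if distractor_included:
        measured += dvol
    return MeasurementRecord(
        case_id=record.case_id, method="auto_sim", volume_mL=measured,
        partial=partial, ivh_included=ivh_included,
        distractor_included=distractor_included,
    )


def simulate_abc2_reader(
    measurement: ABC2Measurement,
    reader_sd: float,
    seed: int,
    case_id: str = "",
    reader_id: str | None = None,
) -> MeasurementRecord:
    """Perturb an ABC/2 reading to emulate inter-observer variability.

    A and B are each scaled by ``exp(eps)`` with ``eps ~ N(0, reader_sd)``;
    C is jittered by one half-weight slice step with probability
    ``min(1, 4 * reader_sd)``.  ``reader_sd = 0`` reproduces the input
    exactly.
    """
    if reader_sd < 0:
        raise ValueError("reader_sd must be >= 0")
    if reader_sd == 0:
        return MeasurementRecord(
            case_id=case_id, method="abc2", reader_id=reader_id,
            volume_mL=measurement.volume_mL,
        )
    rng = np.random.default_rng(seed)
    e1, e2 = rng.normal(size=2)
    u_jit = rng.random()
    sign = 1.0 if rng.random() < 0.5 else -1.0

    a = measurement.A_cm * float(np.exp(reader_sd * e1))
    b = measurement.B_cm * float(np.exp(reader_sd * e2))
    if b > a:
        a, b = b, a
    c = measurement.C_cm
    step = 0.5 * measurement.slice_thickness_cm
    if reader_sd > 0 and step > 0 and u_jit < min(1.0, 4.0 * reader_sd):
        c = max(step, c + sign * step)
    return MeasurementRecord(
        case_id=case_id, method="abc2", reader_id=reader_id,
        volume_mL=a * b * c / 2.0,
    )


# ---------------------------------------------------------------------------
# long-format measurement tables
# ---------------------------------------------------------------------------

def records_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    rows = [
        dict(
            case_id=r.case_id, method=r.method, reader_id=r.reader_id,
            volume_mL=r.volume_mL, missed=r.missed, partial=r.partial,
            ivh_included=r.ivh_included, distractor_included=r.distractor_included,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurements_csv(records: list[MeasurementRecord] | pd.DataFrame,
                           path) -> None:
    """Long-format CSV with missing volumes encoded as empty fields."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def read_measurements_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"case_id": str, "method": str})
    for col in ("missed", "partial", "ivh_included", "distractor_included"):
        df[col] = df[col].astype(bool)
    return df
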