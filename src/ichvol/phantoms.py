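"""Synthetic 3D haematoma phantoms on CT-like voxel grids.

Generates labeled voxel volumes that mimic the geometry of spontaneous
supratentorial intracerebral haemorrhage (ICH) as seen on non-contrast CT:
an ellipsoid-like parenchymal haematoma (label 1), optional intraventricular
extension (IVH, label 2) abutting it, and optional distractor hyperdensities
(label 3) standing in for dura, skull base or calcifications.  Cohorts are
sampled with the statistical structure of a consecutive ICH population:
log-normal volumes calibrated by median and IQR, ~50% IVH prevalence and a
basal-ganglia/thalamus majority.

Coordinate convention: voxel indices are 0-based, the centre of voxel ``i``
along an axis with spacing ``s`` lies at ``(i + 0.5) * s`` mm, and the third
axis is the axial (slice) direction.  No affine rotation is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

__all__ = [
    "BACKGROUND",
    "ICH",
    "IVH",
    "DISTRACTOR",
    "LabeledVolume",
    "PhantomRecord",
    "CohortConfig",
    "make_ellipsoid_mask",
    "perturb_mask",
    "add_ivh_component",
    "add_distractors",
    "reslice_axial",
    "sample_true_volumes",
    "lognormal_params_from_quantiles",
    "sample_cohort",
    "save_labeled_volume",
    "load_labeled_volume",
]

BACKGROUND = 0
ICH = 1
IVH = 2
DISTRACTOR = 3

#: 75th percentile of the standard normal; converts an IQR ratio to a
#: log-normal sigma via sigma = ln(q75/q25) / (2 * Z75).
Z75 = 0.6744897501960817

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class LabeledVolume:
    """A 3D integer label grid with per-axis voxel spacing in mm.

    Labels: 0 background, 1 ICH, 2 IVH, 3 distractor hyperdensity.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if self.labels.size and (
            int(self.labels.max()) > 3
            or (self.labels.dtype.kind != "u" and int(self.labels.min()) < 0)
        ):
            raise ValueError("label codes must lie in {0, 1, 2, 3}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def label_volume_mL(self, label: int) -> float:
        """Voxel-count volume of one label in mL."""
        return float(np.count_nonzero(self.labels == label)) * self.voxel_volume_mm3 / 1000.0

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(self.labels.copy(), self.spacing_mm)


@dataclass(frozen=True)
class PhantomRecord:
    """Per-case ground truth for one synthetic haematoma."""

    case_id: str
    true_ich_volume_mL: float
    true_ivh_volume_mL: float
    location: str  # "lobar" or "basal_ganglia_thalamus"
    ivh_present: bool
    irregularity: float
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        if self.ivh_present != (self.true_ivh_volume_mL > 0):
            raise ValueError(
                f"{self.case_id}: ivh_present must mirror true_ivh_volume_mL > 0"
            )
        if self.location not in ("lobar", "basal_ganglia_thalamus"):
            raise ValueError(f"unknown location {self.location!r}")


@dataclass
class CohortConfig:
    """Cohort-level generative settings.

    Defaults reproduce the study population this package emulates: log-normal
    ICH volumes with median 26.0 mL and IQR 9.3-59.2 mL, IVH prevalence 0.5,
    66% basal-ganglia/thalamus location, and CT slice thickness of 1, 3 or
    5 mm.
    """

    n_cases: int = 300
    volume_median_mL: float = 26.0
    volume_iqr_mL: tuple[float, float] = (9.3, 59.2)
    ivh_prevalence: float = 0.5
    basal_ganglia_fraction: float = 0.66
    irregularity_range: tuple[float, float] = (0.1, 0.8)
    slice_thickness_mm: float = 1.0
    seed: int = 0
    #: fraction of ICH volume occupied by the IVH component when present
    ivh_fraction_range: tuple[float, float] = (0.05, 0.40)
    #: in-plane / through-plane spacing of the generated master grids (mm)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: fixed grid shape; None sizes each case's grid to fit its haematoma
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        q25, q75 = self.volume_iqr_mL
        if not (q25 < self.volume_median_mL < q75):
            raise ValueError("volume IQR must bracket the median")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not 0 <= self.ivh_prevalence <= 1:
            raise ValueError("ivh_prevalence must lie in [0, 1]")
        if self.slice_thickness_mm not in (1, 3, 5):
            raise ValueError("slice_thickness_mm must be one of 1, 3, 5")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("volume_iqr_mL", "irregularity_range", "ivh_fraction_range",
                    "spacing_mm", "grid_shape"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# mask primitives
# ---------------------------------------------------------------------------

def _center_coords(shape: tuple[int, int, int],
                   spacing: tuple[float, float, float]) -> list[np.ndarray]:
    """Per-axis voxel-centre coordinates in mm."""
    return [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]


def make_ellipsoid_mask(
    semi_axes_mm: tuple[float, float, float],
    spacing_mm: tuple[float, float, float],
    grid_shape: tuple[int, int, int],
    center_mm: tuple[float, float, float] | None = None,
) -> LabeledVolume:
    """Digitize an axis-aligned ellipsoid as a label-1 mask.

    A voxel belongs to the ellipsoid when its centre satisfies
    ``sum(((x_i - c_i) / a_i)**2) <= 1``.  The ellipsoid must fit inside the
    grid with at least one voxel of margin on every side.
    """
    semi = np.asarray(semi_axes_mm, dtype=float)
    spacing = np.asarray(spacing_mm, dtype=float)
    shape = tuple(int(n) for n in grid_shape)
    if np.any(semi <= 0) or np.any(spacing <= 0):
        raise ValueError("semi-axes and spacing must be positive")
    extent = np.array(shape) * spacing
    if center_mm is None:
        center = extent / 2.0
    else:
        center = np.asarray(center_mm, dtype=float)
    lo = center - semi
    hi = center + semi
    if np.any(lo < spacing) or np.any(hi > extent - spacing):
        raise ValueError(
            f"ellipsoid with semi-axes {tuple(semi)} mm at centre {tuple(center)} "
            f"does not fit in grid {shape} at spacing {tuple(spacing)} "
            "with a one-voxel margin"
        )
    # evaluate the quadratic only inside the ellipsoid's bounding box
    lo_i = np.maximum(np.floor(lo / spacing).astype(int), 0)
    hi_i = np.minimum(np.ceil(hi / spacing).astype(int) + 1, shape)
    axes = [
        ((np.arange(l, h) + 0.5) * s - c) / a
        for l, h, s, c, a in zip(lo_i, hi_i, spacing, center, semi)
    ]
    q = (
        (axes[0] ** 2)[:, None, None]
        + (axes[1] ** 2)[None, :, None]
        + (axes[2] ** 2)[None, None, :]
    )
    labels = np.zeros(shape, dtype=np.uint8)
    labels[tuple(slice(l, h) for l, h in zip(lo_i, hi_i))] = np.where(
        q <= 1.0, ICH, BACKGROUND
    )
    return LabeledVolume(labels, tuple(spacing))


def _angular_noise(rng: np.random.Generator, n_waves: int = 12,
                   freq_range: tuple[float, float] = (3.0, 8.0)):
    """Band-limited random field on the unit sphere, unit RMS.

    Superposition of plane-wave cosines restricted to the sphere; smooth,
    cheap to evaluate and with angular wavelength set by ``freq_range``.
    """
    dirs = rng.normal(size=(n_waves, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    freqs = rng.uniform(*freq_range, size=n_waves)
    waves = dirs * freqs[:, None]
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    amps = rng.normal(size=n_waves)
    rms = np.sqrt(np.sum(amps**2) / 2.0)

    def f(u: np.ndarray) -> np.ndarray:
        # u: (..., 3) unit directions
        acc = np.zeros(u.shape[:-1])
        for w, ph, a in zip(waves, phases, amps):
            acc += a * np.cos(u @ w + ph)
        return acc / rms

    return f


def perturb_mask(volume: LabeledVolume, irregularity: float, seed: int) -> LabeledVolume:
    """Deform the ICH boundary by a smooth random radial warp.

    The label-1 region is radially rescaled about its centroid by
    ``1 + 0.3 * irregularity * f(direction)`` where ``f`` is a band-limited
    angular noise field with unit RMS.  ``irregularity = 0`` returns the
    input unchanged; the output ICH region is a single connected component.
    Other labels are left untouched.
    """
    if not 0 <= irregularity <= 1:
        raise ValueError("irregularity must lie in [0, 1]")
    ich = volume.labels == ICH
    if not ich.any():
        raise ValueError("perturb_mask requires a nonempty ICH (label 1) region")
    if irregularity == 0:
        return volume.copy()

    rng = np.random.default_rng(seed)
    noise = _angular_noise(rng)
    amp = 0.3 * irregularity

    # bound the realized field by probing a dense deterministic direction set;
    # clipping g at that bound guarantees the warp stays inside the padded box
    k = np.arange(2048)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    zp = 1.0 - 2.0 * (k + 0.5) / 2048
    rp = np.sqrt(1.0 - zp**2)
    probe = np.stack([rp * np.cos(golden * k), rp * np.sin(golden * k), zp], axis=1)
    f_bound = min(3.5, float(np.abs(noise(probe)).max()) * 1.1 + 0.1)

    spacing = np.asarray(volume.spacing_mm)
    idx = np.argwhere(ich)
    centroid = (idx.mean(axis=0) + 0.5) * spacing  # mm

    gmax = 1.0 + amp * f_bound
    lo_idx = idx.min(axis=0)
    hi_idx = idx.max(axis=0)
    half = np.maximum((hi_idx - lo_idx + 1) * spacing / 2.0, spacing)
    c_idx = (lo_idx + hi_idx) / 2.0
    pad = np.ceil(half * (gmax - 1.0) / spacing).astype(int) + 2
    lo = np.maximum(lo_idx - pad, 0)
    hi = np.minimum(hi_idx + pad + 1, np.array(volume.shape))

    sub_shape = tuple(hi - lo)
    coords = np.meshgrid(
        *[(np.arange(l, h) + 0.5) * s for l, h, s in zip(lo, hi, spacing)],
        indexing="ij",
    )
    rel = np.stack(coords, axis=-1) - centroid  # (..., 3) mm
    r = np.sqrt(np.einsum("...k,...k->...", rel, rel))

    # radial pre-classification: voxels whose source radius is certainly
    # inside (outside) the ICH for any admissible warp skip the noise field
    diag = float(np.linalg.norm(spacing))
    ich_sub = ich[tuple(slice(l, h) for l, h in zip(lo, hi))]
    r_ich = r[ich_sub]
    perim = ich_sub & ~ndimage.binary_erosion(ich_sub)
    r_perim = r[perim]
    rmax_in = float(r_ich.max()) + diag
    rmin_in = max(float(r_perim.min()) - diag, 0.0)
    gmin = 1.0 - amp * f_bound
    warped = r <= rmin_in * gmin
    shell = ~warped & (r < rmax_in * gmax)

    rel_s = rel[shell]
    r_s = r[shell]
    u = rel_s / np.maximum(r_s, 1e-12)[:, None]
    g = 1.0 + amp * np.clip(noise(u), -f_bound, f_bound)
    src = centroid + rel_s / g[:, None]
    src_idx = np.floor(src / spacing).astype(int)
    inside = np.all((src_idx >= 0) & (src_idx < np.array(volume.shape)), axis=-1)
    hit = np.zeros(len(src_idx), dtype=bool)
    ii = src_idx[inside]
    hit[inside] = ich[ii[:, 0], ii[:, 1], ii[:, 2]]
    warped[shell] = hit

    # keep the largest connected component: digitization can shave off slivers
    lab, n = ndimage.label(warped, structure=_STRUCT26)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        warped = lab == (int(np.argmax(sizes)) + 1)

    out = volume.labels.copy()
    region = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub = out[region]
    sub[sub == ICH] = BACKGROUND
    sub[warped & (sub == BACKGROUND)] = ICH
    out[region] = sub
    if not (out == ICH).any():
        raise RuntimeError("perturbation removed the entire ICH region")
    return LabeledVolume(out, volume.spacing_mm)


def add_ivh_component(volume: LabeledVolume, target_ivh_volume_mL: float,
                      seed: int) -> LabeledVolume:
    """Attach a contiguous IVH (label 2) region abutting the ICH.

    The region is grown outward from a randomly chosen background voxel
    face-adjacent to the ICH surface, filling the nearest background voxels
    until the target volume is reached (within 10%).  Label-1 voxels are
    never modified.
    """
    if target_ivh_volume_mL <= 0:
        raise ValueError("target IVH volume must be positive")
    ich = volume.labels == ICH
    if not ich.any():
        raise ValueError("add_ivh_component requires a nonempty ICH region")
    rng = np.random.default_rng(seed)

    k = max(1, int(round(target_ivh_volume_mL * 1000.0 / volume.voxel_volume_mm3)))
    bg = volume.labels == BACKGROUND
    if int(bg.sum()) < k:
        raise ValueError(
            f"target IVH volume {target_ivh_volume_mL} mL exceeds remaining grid capacity"
        )

    # candidate contact points: background voxels face-adjacent to ICH
    dilated = ndimage.binary_dilation(ich)  # 6-connectivity default
    contact_candidates = np.argwhere(dilated & bg)
    if contact_candidates.size == 0:
        raise ValueError("no background voxel adjacent to the ICH surface")
    contact = contact_candidates[rng.integers(len(contact_candidates))]

    spacing = np.asarray(volume.spacing_mm)
    # local window large enough for a ball of k voxels grown into a half-space
    r_mm = 1.6 * (3.0 * k * volume.voxel_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    pad = np.ceil(r_mm / spacing).astype(int) + 2
    lo = np.maximum(contact - pad, 0)
    hi = np.minimum(contact + pad + 1, np.array(volume.shape))
    region = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub_bg = bg[region]
    coords = np.meshgrid(
        *[(np.arange(l, h) - c) * s for l, h, c, s in zip(lo, hi, contact, spacing)],
        indexing="ij",
    )
    dist = np.sqrt(sum(c**2 for c in coords))
    dist = np.where(sub_bg, dist, np.inf)
    flat = np.argsort(dist, axis=None, kind="stable")
    n_avail = int(np.isfinite(dist).sum())
    if n_avail < k:
        raise ValueError("target IVH volume exceeds local grid capacity")
    sel = np.zeros(dist.shape, dtype=bool)
    sel.ravel()[flat[:k]] = True
    # the k nearest background voxels form a clipped ball; keep the component
    # containing the contact voxel and top up if clipping disconnected it
    lab, n = ndimage.label(sel, structure=_STRUCT26)
    cc = lab[tuple(contact - lo)]
    if n > 1 and cc > 0:
        sel = lab == cc
        extra = flat[k:n_avail]
        i = 0
        while sel.sum() < k and i < extra.size:
            sel.ravel()[extra[i]] = True
            i += 1

    out = volume.labels.copy()
    sub = out[region]
    sub[sel & (sub == BACKGROUND)] = IVH
    out[region] = sub
    result = LabeledVolume(out, volume.spacing_mm)
    got = result.label_volume_mL(IVH)
    if abs(got - target_ivh_volume_mL) > 0.1 * target_ivh_volume_mL + volume.voxel_volume_mm3 / 1000.0:
        raise RuntimeError(
            f"IVH growth reached {got:.2f} mL, outside 10% of target {target_ivh_volume_mL:.2f} mL"
        )
    return result


def add_distractors(volume: LabeledVolume, n_blobs: int, rim: bool,
                    seed: int) -> LabeledVolume:
    """Add label-3 distractor hyperdensities.

    ``n_blobs`` small ellipsoidal blobs (1-2 mL each) are placed on background
    away from the ICH/IVH; with ``rim`` a one-voxel label-3 shell is painted on
    the grid boundary, mimicking dura/skull-base hyperdensity.  Labels 1 and 2
    are never modified.  No-op when ``n_blobs == 0 and not rim``.
    """
    if n_blobs < 0:
        raise ValueError("n_blobs must be >= 0")
    if n_blobs == 0 and not rim:
        return volume.copy()
    rng = np.random.default_rng(seed)
    out = volume.labels.copy()
    spacing = np.asarray(volume.spacing_mm)
    shape = np.array(volume.shape)
    occupied = ndimage.binary_dilation(out != BACKGROUND, iterations=2)
    xs, ys, zs = _center_coords(volume.shape, volume.spacing_mm)

    placed = 0
    attempts = 0
    while placed < n_blobs and attempts < 200 * max(n_blobs, 1):
        attempts += 1
        vol_mL = rng.uniform(1.0, 2.0)
        # oblate blob with mild anisotropy
        ratios = rng.uniform(0.7, 1.3, size=3)
        s3 = vol_mL * 1000.0 * 3.0 / (4.0 * np.pi * np.prod(ratios))
        semi = ratios * s3 ** (1.0 / 3.0)
        margin = semi + 2 * spacing
        lo_c = margin
        hi_c = shape * spacing - margin
        if np.any(hi_c <= lo_c):
            continue
        center = rng.uniform(lo_c, hi_c)
        q = (
            ((xs - center[0]) / semi[0])[:, None, None] ** 2
            + (((ys - center[1]) / semi[1]) ** 2)[None, :, None]
            + (((zs - center[2]) / semi[2]) ** 2)[None, None, :]
        )
        blob = q <= 1.0
        # reject placements touching anything that is not plain background
        near = ndimage.binary_dilation(blob)
        if (occupied & near).any() or (out[near] != BACKGROUND).any():
            continue
        out[blob] = DISTRACTOR
        occupied |= ndimage.binary_dilation(blob, iterations=2)
        placed += 1
    if placed < n_blobs:
        raise ValueError(
            f"could only place {placed} of {n_blobs} distractor blobs on this grid"
        )
    if rim:
        shell = np.zeros(volume.shape, dtype=bool)
        shell[[0, -1], :, :] = True
        shell[:, [0, -1], :] = True
        shell[:, :, [0, -1]] = True
        out[shell & (out == BACKGROUND)] = DISTRACTOR
    return LabeledVolume(out, volume.spacing_mm)


def reslice_axial(volume: LabeledVolume, new_thickness_mm: float) -> LabeledVolume:
    """Aggregate axial slices to a coarser slice thickness by majority label.

    The new thickness must be an integer multiple of the current z-spacing.
    Within each slab the most frequent label wins; ties break toward the
    priority order 1 > 2 > 3 > 0, preserving the ICH (the measurand).
    """
    sx, sy, sz = volume.spacing_mm
    ratio = new_thickness_mm / sz
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"new thickness {new_thickness_mm} mm is not an integer multiple of "
            f"current z-spacing {sz} mm"
        )
    if factor == 1:
        return volume.copy()
    labels = volume.labels
    nx, ny, nz = labels.shape
    n_slabs = -(-nz // factor)
    padded = np.zeros((nx, ny, n_slabs * factor), dtype=labels.dtype)
    padded[:, :, :nz] = labels
    blocks = padded.reshape(nx, ny, n_slabs, factor)
    priority = (ICH, IVH, DISTRACTOR, BACKGROUND)
    counts = np.stack([(blocks == l).sum(axis=3) for l in priority])
    winner = np.argmax(counts, axis=0)  # first max -> highest priority
    out = np.asarray(priority, dtype=labels.dtype)[winner]
    return LabeledVolume(out, (sx, sy, new_thickness_mm))


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def lognormal_params_from_quantiles(median: float,
                                    iqr: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and IQR.

    mu = ln(median); sigma = ln(q75/q25) / (2 * Z75) where Z75 = 0.67449 is
    the standard-normal 75th percentile.
    """
    q25, q75 = iqr
    if not (0 < q25 < median < q75):
        raise ValueError("require 0 < q25 < median < q75")
    return float(np.log(median)), float(np.log(q75 / q25) / (2.0 * Z75))


def sample_true_volumes(config: CohortConfig, n: int | None = None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw true ICH volumes (mL) from the configured log-normal."""
    mu, sigma = lognormal_params_from_quantiles(
        config.volume_median_mL, config.volume_iqr_mL
    )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return np.exp(rng.normal(mu, sigma, size=n if n is not None else config.n_cases))


def _case_grid(semi: np.ndarray, irregularity: float, ivh_mL: float,
               spacing: np.ndarray) -> tuple[int, int, int]:
    """Smallest grid that holds the (warped) ellipsoid plus any IVH ball."""
    warp = 1.0 + 0.3 * irregularity * 3.5
    half = semi * warp
    ivh_r = 0.0
    if ivh_mL > 0:
        ivh_r = 1.6 * (3.0 * ivh_mL * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half_ext = half + 2.0 * ivh_r + 4.0 * spacing
    return tuple(int(np.ceil(2 * h / s)) for h, s in zip(half_ext, spacing))


def sample_cohort(
    config: CohortConfig,
    build_masks: bool = True,
) -> tuple[list[tuple[LabeledVolume | None, PhantomRecord]], pd.DataFrame]:
    """Sample a synthetic ICH cohort.

    Returns per-case ``(mask, record)`` pairs and a ground-truth table.  Masks
    are generated at ``config.spacing_mm``; downstream measurement reslices to
    the acquisition thickness recorded per case.  With ``build_masks=False``
    only the statistical ground truth is produced (records carry the sampled
    analytic volumes), which is orders of magnitude faster and sufficient for
    purely parametric simulations.

    Recorded true volumes equal the voxel-count volumes of the corresponding
    mask labels (exact by construction when masks are built).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    target_vols = sample_true_volumes(config, n, rng)
    is_bg = rng.random(n) < config.basal_ganglia_fraction
    has_ivh = rng.random(n) < config.ivh_prevalence
    ivh_frac = rng.uniform(*config.ivh_fraction_range, size=n)
    lo, hi = config.irregularity_range
    mid = (lo + hi) / 2.0
    # basal ganglia/thalamus haematomas tend to the regular end of the range
    irregularity = np.where(
        is_bg, rng.uniform(lo, mid, size=n), rng.uniform(mid, hi, size=n)
    )
    aspect = rng.uniform([1.15, 1.0, 0.65], [1.45, 1.0, 0.85], size=(n, 3))
    case_seeds = rng.integers(0, 2**31 - 1, size=(n, 2))

    spacing = np.asarray(config.spacing_mm)
    cases: list[tuple[LabeledVolume | None, PhantomRecord]] = []
    rows = []
    for i in range(n):
        case_id = f"case_{i:04d}"
        v_target = float(target_vols[i])
        ivh_target = float(ivh_frac[i] * v_target) if has_ivh[i] else 0.0
        location = "basal_ganglia_thalamus" if is_bg[i] else "lobar"
        irr = float(irregularity[i])

        if build_masks:
            scale = (v_target * 1000.0 * 3.0 / (4.0 * np.pi * np.prod(aspect[i]))) ** (1 / 3)
            semi = aspect[i] * scale
            if config.grid_shape is not None:
                grid = config.grid_shape
                extent = np.asarray(grid) * spacing
                if np.any(2 * semi * (1 + 0.3 * irr * 3.5) > extent - 4 * spacing):
                    raise ValueError(
                        f"{case_id}: haematoma of {v_target:.1f} mL does not fit "
                        f"the configured grid {grid}"
                    )
            else:
                grid = _case_grid(semi, irr, ivh_target, spacing)
            vol = make_ellipsoid_mask(tuple(semi), tuple(spacing), grid)
            vol = perturb_mask(vol, irr, int(case_seeds[i, 0]))
            if ivh_target > 0:
                vol = add_ivh_component(vol, ivh_target, int(case_seeds[i, 1]))
            true_ich = vol.label_volume_mL(ICH)
            true_ivh = vol.label_volume_mL(IVH)
        else:
            vol = None
            true_ich = v_target
            true_ivh = ivh_target

        rec = PhantomRecord(
            case_id=case_id,
            true_ich_volume_mL=true_ich,
            true_ivh_volume_mL=true_ivh,
            location=location,
            ivh_present=bool(has_ivh[i]),
            irregularity=irr,
            slice_thickness_mm=float(config.slice_thickness_mm),
        )
        cases.append((vol, rec))
        rows.append(
            dict(
                case_id=case_id,
                true_ich_volume_mL=true_ich,
                true_ivh_volume_mL=true_ivh,
                location=location,
                ivh_present=bool(has_ivh[i]),
                irregularity=irr,
                slice_thickness_mm=float(config.slice_thickness_mm),
            )
        )
    truth = pd.DataFrame(rows)
    return cases, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_labeled_volume(volume: LabeledVolume, path: str | Path) -> None:
    """Write a mask as integer NIfTI with a diagonal affine carrying spacing."""
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(volume.labels.astype(np.uint8), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def load_labeled_volume(path: str | Path) -> LabeledVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    labels = np.asarray(img.dataobj).astype(np.uint8)
    return LabeledVolume(labels, spacing)
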