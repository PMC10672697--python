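"""Static and dynamic 3D bone morphometry, overlays, and agreement metrics.

Static morphometry follows standard HR-pQCT trabecular outcomes: bone volume
fraction (Tb.BV/TV, %), thickness (Tb.Th, mm) and separation (Tb.Sp, mm) by
the Hildebrand-Ruegsegger sphere-fitting local-thickness method, and
trabecular number (Tb.N, 1/mm) from mid-axis spacing.

Dynamic morphometry derives from three-valued overlays of two registered
binaries (resorbed / formed / quiescent): formation and resorption rates
(BFR, BRR, %/day), mineral apposition and resorption rates (MAR, MRR,
um/day) as the sphere-fitting thickness of the formed/resorbed voxel sets
per day, and mineralizing/eroding surface fractions (MS, ES, %).

Agreement metrics are the Dice coefficient and the mean symmetric surface
distance (um).

Connectivity conventions: 26-connectivity for bone components,
6-connectivity (voxel faces) for surface detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .core_geometry import DegenerateInputError, Volume3D

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)

# Overlay voxel codes
BACKGROUND, RESORBED, FORMED, QUIESCENT = 0, 1, 2, 3


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class OverlayVolume:
    """Three-valued formed/resorbed/quiescent overlay of two binaries."""

    data: np.ndarray  # {0 background, 1 resorbed, 2 formed, 3 quiescent}
    spacing: float
    days: float

    def counts(self) -> dict[str, int]:
        return {
            "resorbed": int(np.count_nonzero(self.data == RESORBED)),
            "formed": int(np.count_nonzero(self.data == FORMED)),
            "quiescent": int(np.count_nonzero(self.data == QUIESCENT)),
        }

    def baseline_bone(self) -> np.ndarray:
        return (self.data == RESORBED) | (self.data == QUIESCENT)

    def followup_bone(self) -> np.ndarray:
        return (self.data == FORMED) | (self.data == QUIESCENT)


@dataclass
class StaticMorphometry:
    bvtv: float          # %
    tb_th: float         # mm
    tb_sp: float         # mm
    tb_n: float          # 1/mm
    flags: set = field(default_factory=set)


@dataclass
class DynamicMorphometry:
    bfr: float   # %/day
    brr: float   # %/day
    mar: float   # um/day
    mrr: float   # um/day
    ms: float    # %
    es: float    # %
    flags: set = field(default_factory=set)


@dataclass
class EmbeddingMetrics:
    dice: float                 # dimensionless in [0, 1]
    symmetric_distance: float   # um


# --------------------------------------------------------------------------
# Binarization
# --------------------------------------------------------------------------

def binarize(
    gray: Volume3D,
    mask: Volume3D,
    sigma: float = 0.8,
    support: float = 1.0,
    threshold: float = 320.0,
) -> Volume3D:
    """Gaussian smooth, fixed threshold, mask, largest connected component.

    ``sigma`` and ``support`` are in voxels (the kernel is truncated
    ``support`` voxels beyond its center); ``threshold`` in mg HA/cm^3.
    """
    if gray.shape != mask.shape:
        raise ValueError("gray and mask shapes differ")
    m = mask.data.astype(bool)
    if not m.any():
        raise DegenerateInputError("empty mask")
    smoothed = ndimage.gaussian_filter(
        gray.data.astype(np.float64), sigma=sigma, truncate=support / sigma
    )
    bone = (smoothed >= threshold) & m
    bone = _largest_component(bone)
    return Volume3D(data=bone.astype(np.uint8), spacing=gray.spacing, mask=m.astype(np.uint8))


def common_voi(masks: list[Volume3D], mode: str = "intersection") -> Volume3D:
    """Common volume of interest across registered scans.

    ``intersection`` keeps only voxels present in every mask — the region
    actually measured at all time points and the default for longitudinal
    comparisons; ``union`` is offered because some processing chains define
    the common region that way.
    """
    if not masks:
        raise ValueError("need at least one mask")
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError("mask shapes differ")
    stack = np.stack([m.data.astype(bool) for m in masks])
    if mode == "intersection":
        out = stack.all(axis=0)
    elif mode == "union":
        out = stack.any(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Volume3D(out.astype(np.uint8), masks[0].spacing)


def _largest_component(bone: np.ndarray) -> np.ndarray:
    if not bone.any():
        return bone
    labels, n = ndimage.label(bone, structure=_STRUCT26)
    if n <= 1:
        return bone
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


# --------------------------------------------------------------------------
# Local thickness (sphere fitting)
# --------------------------------------------------------------------------

def local_thickness(binary: Volume3D, phase: str = "bone") -> np.ndarray:
    """Hildebrand-Ruegsegger local thickness, um.

    tau(x) = diameter of the largest sphere fully inside the selected phase
    that contains x.  Computed by a descending-radius sweep: voxels whose
    distance map reaches radius r seed a sphere of that radius; any voxel
    within r of a seed and not yet assigned receives diameter 2r.  Radii are
    binned at 0.5 voxel, the method's placement resolution.
    """
    if phase == "bone":
        ph = binary.data.astype(bool)
    elif phase == "background":
        ph = ~binary.data.astype(bool)
        if binary.mask is not None:
            ph &= binary.mask.astype(bool)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    if not ph.any():
        raise DegenerateInputError(f"empty {phase} phase")

    dist = ndimage.distance_transform_edt(ph)  # voxel units
    tau = np.zeros(binary.shape, dtype=np.float64)
    r_max = dist.max()
    edges = np.arange(np.ceil(r_max / 0.5) * 0.5, 0.0, -0.5)
    for r_lo in edges:
        seeds = dist >= r_lo
        if not seeds.any():
            continue
        r_mid = r_lo + 0.25
        reach = ndimage.distance_transform_edt(~seeds) <= r_mid
        newly = ph & reach & (tau == 0)
        tau[newly] = 2.0 * r_mid
    # any uncovered phase voxels (thin single-voxel features)
    tau[ph & (tau == 0)] = 1.0
    tau[~ph] = 0.0
    return tau * binary.spacing


# --------------------------------------------------------------------------
# Static morphometry
# --------------------------------------------------------------------------

def static_morphometry(
    binary: Volume3D,
    mask: Volume3D | None = None,
    tbn_model: str = "mid-axis",
) -> StaticMorphometry:
    """Tb.BV/TV (%), Tb.Th (mm), Tb.Sp (mm), Tb.N (1/mm) of a binary volume.

    Tb.N uses the mid-axis (skeleton spacing) direct method by default:
    1 / mean sphere-fitting thickness of the non-skeleton phase; the
    ``inverse-sum`` model computes 1 / (Tb.Th + Tb.Sp) instead.
    """
    if mask is None:
        if binary.mask is not None:
            mask = Volume3D(binary.mask, binary.spacing)
        else:
            mask = Volume3D(np.ones(binary.shape, dtype=np.uint8), binary.spacing)
    m = mask.data.astype(bool)
    if not m.any():
        raise DegenerateInputError("empty mask")
    bone = binary.data.astype(bool) & m
    flags: set = set()
    bvtv = 100.0 * bone.sum() / m.sum()

    if not bone.any():
        return StaticMorphometry(bvtv=0.0, tb_th=np.nan, tb_sp=np.nan, tb_n=np.nan,
                                 flags={"empty_bone"})
    masked = Volume3D(bone.astype(np.uint8), binary.spacing, mask=m.astype(np.uint8))
    tau_bone = local_thickness(masked, "bone")
    tb_th = tau_bone[bone].mean() / 1000.0  # mm

    bg = (~bone) & m
    if bg.any():
        tau_bg = local_thickness(masked, "background")
        tb_sp = tau_bg[bg].mean() / 1000.0
    else:
        tb_sp = np.nan
        flags.add("no_background")

    if tbn_model == "inverse-sum":
        tb_n = 1.0 / (tb_th + tb_sp) if np.isfinite(tb_sp) else np.nan
    elif tbn_model == "mid-axis":
        skel = skeletonize(bone).astype(bool)
        if skel.any() and (~skel & m).any():
            nonskel = Volume3D(skel.astype(np.uint8), binary.spacing, mask=m.astype(np.uint8))
            tau_ns = local_thickness(nonskel, "background")
            sel = ~skel & m
            tb_n = 1000.0 / tau_ns[sel].mean()  # 1/mm
        else:
            tb_n = np.nan
            flags.add("degenerate_skeleton")
    else:
        raise ValueError(f"unknown tbn_model {tbn_model!r}")
    return StaticMorphometry(bvtv=bvtv, tb_th=tb_th, tb_sp=tb_sp, tb_n=tb_n, flags=flags)


# --------------------------------------------------------------------------
# Overlays and dynamic morphometry
# --------------------------------------------------------------------------

def overlay(baseline: Volume3D, followup: Volume3D, days: float) -> OverlayVolume:
    """Three-valued overlay: voxels only in the baseline are resorbed, only
    in the follow-up formed, in both quiescent."""
    if baseline.shape != followup.shape:
        raise ValueError("baseline and followup shapes differ")
    if days <= 0:
        raise ValueError(f"days must be positive, got {days}")
    b0 = baseline.data.astype(bool)
    b1 = followup.data.astype(bool)
    data = np.zeros(b0.shape, dtype=np.uint8)
    data[b0 & ~b1] = RESORBED
    data[~b0 & b1] = FORMED
    data[b0 & b1] = QUIESCENT
    return OverlayVolume(data=data, spacing=baseline.spacing, days=days)


def _surface_voxels(bone: np.ndarray) -> np.ndarray:
    """Bone voxels with at least one face-adjacent background voxel."""
    eroded = ndimage.binary_erosion(bone, structure=_STRUCT6, border_value=1)
    return bone & ~eroded


def dynamic_morphometry(ov: OverlayVolume) -> DynamicMorphometry:
    """BFR/BRR (%/day), MAR/MRR (um/day), MS/ES (%) from an overlay.

    MS and ES use the surface of the union volume, the only surface set that
    contains both formed (follow-up-only) and resorbed (baseline-only)
    voxels.  Empty formed (resorbed) sets give MAR (MRR) = 0 with a flag.
    """
    baseline = ov.baseline_bone()
    n_baseline = int(baseline.sum())
    if n_baseline == 0:
        raise DegenerateInputError("zero baseline bone volume")
    formed = ov.data == FORMED
    resorbed = ov.data == RESORBED
    flags: set = set()

    bfr = 100.0 * formed.sum() / n_baseline / ov.days
    brr = 100.0 * resorbed.sum() / n_baseline / ov.days

    def _set_thickness(sel: np.ndarray) -> float:
        vol = Volume3D(sel.astype(np.uint8), ov.spacing)
        tau = local_thickness(vol, "bone")
        return float(tau[sel].mean())

    if formed.any():
        mar = _set_thickness(formed) / ov.days
    else:
        mar = 0.0
        flags.add("no_formed")
    if resorbed.any():
        mrr = _set_thickness(resorbed) / ov.days
    else:
        mrr = 0.0
        flags.add("no_resorbed")

    union = baseline | formed
    surface = _surface_voxels(union)
    n_surf = int(surface.sum())
    if n_surf == 0:
        ms = es = 0.0
        flags.add("no_surface")
    else:
        ms = 100.0 * (surface & formed).sum() / n_surf
        es = 100.0 * (surface & resorbed).sum() / n_surf
    return DynamicMorphometry(bfr=bfr, brr=brr, mar=mar, mrr=mrr, ms=ms, es=es, flags=flags)


# --------------------------------------------------------------------------
# Agreement metrics
# --------------------------------------------------------------------------

def dice(b1: Volume3D, b2: Volume3D) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|); two empty volumes give 1."""
    if b1.shape != b2.shape:
        raise ValueError("volume shapes differ")
    a = b1.data.astype(bool)
    b = b2.data.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        warnings.warn("dice of two empty volumes; defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * (a & b).sum() / denom


def symmetric_distance(b1: Volume3D, b2: Volume3D) -> float:
    """Mean symmetric surface distance between two binary volumes, um.

    Mean over surface voxels of each volume of the Euclidean distance to the
    other volume's surface, averaged over both directions.
    """
    if b1.shape != b2.shape:
        raise ValueError("volume shapes differ")
    out = []
    surfaces = []
    for v in (b1, b2):
        bone = v.data.astype(bool)
        if not bone.any() or bone.all():
            raise DegenerateInputError("symmetric_distance requires two-phase volumes")
        surfaces.append(_surface_voxels(bone))
    for s_from, s_to in ((surfaces[0], surfaces[1]), (surfaces[1], surfaces[0])):
        d_to = ndimage.distance_transform_edt(~s_to, sampling=b1.spacing)
        out.append(d_to[s_from].mean())
    return 0.5 * (out[0] + out[1])


def embedding_metrics(b1: Volume3D, b2: Volume3D) -> EmbeddingMetrics:
    return EmbeddingMetrics(dice=dice(b1, b2), symmetric_distance=symmetric_distance(b1, b2))
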