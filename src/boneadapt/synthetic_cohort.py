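"""Synthetic trabecular structures, analytic phantoms, and longitudinal cohorts.

In vivo HR-pQCT data for the population this model targets are not publicly
available, so the study pipeline is exercised on synthetic stand-ins:

* Gaussian-random-field (GRF) structures — smooth correlated noise
  thresholded at the quantile giving a target bone volume fraction — have
  controllable BV/TV and strut thickness and are standard surrogates for
  trabecular microarchitecture.
* Analytic phantoms (sphere, plate, rod, gyroid) provide exact oracles for
  the solvers and morphometry.
* Longitudinal cohorts are generated by running the forward model with known
  per-participant, per-interval parameters (ground truth by construction),
  arranged as N participants x 2 sites x 4 time points (L, R+0, R+6, R+12)
  with approximately six-month intervals.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_geometry import Volume3D, signed_distance
from .forward_solver import EvolutionConfig, ModelParams, simulate
from .inverse_solver import FitResult

#: Default per-interval mean advection rates (um/day).  Anchored to reported
#: in vivo median adaptation rates of roughly -96, -89 and -87 um/year for
#: the in-flight and two recovery intervals.
_DEFAULT_THETA = {
    "a_mean": (-0.264, -0.243, -0.238),
    "a_participant_sd": 0.04,
    "a_interval_sd": 0.03,
    "b_mean": (30.0, 30.0, 30.0),
    "b_participant_sd": 10.0,
    "b_interval_sd": 8.0,
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic cohort."""

    n_participants: int = 16
    n_sites: int = 2
    timepoints: tuple = ("L", "R+0", "R+6", "R+12")
    interval_days: tuple = (180.0, 182.0, 183.0)
    volume_shape: tuple = (96, 96, 96)
    spacing: float = 61.0
    target_bvtv: float = 25.0
    correlation_length: float = 260.0
    theta_distributions: dict = field(default_factory=lambda: dict(_DEFAULT_THETA))
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_sites < 1:
            raise ValueError("participant and site counts must be >= 1")
        if len(self.interval_days) != len(self.timepoints) - 1:
            raise ValueError("need one interval per consecutive timepoint pair")
        if any(d <= 0 for d in self.interval_days):
            raise ValueError("interval_days must be positive")
        if not 0 <= self.noise <= 0.05:
            raise ValueError(f"noise must be in [0, 0.05], got {self.noise}")

    @property
    def n_intervals(self) -> int:
        return len(self.interval_days)


@dataclass
class CohortRecord:
    """One participant x site x interval unit of analysis."""

    participant: str
    site: str
    interval: str          # e.g. "L-R+0"
    interval_index: int    # 1-based
    baseline: Volume3D
    followup: Volume3D
    days: float
    theta_true: ModelParams | None = None
    fit: FitResult | None = None
    corrupted: bool = False


# --------------------------------------------------------------------------
# Structures and phantoms
# --------------------------------------------------------------------------

def _largest_component_periodic(bone: np.ndarray) -> np.ndarray:
    """Largest 26-connected component under periodic boundary conditions.

    The GRF is generated with periodic (wrap) convolution, so strut pieces
    touching through opposite faces belong to one component in the infinite
    medium; labeling a 2x2x2 tiling unifies them before the base cell is
    extracted.  Small volumes would otherwise shed boundary fragments.
    """
    tiled = np.tile(bone, (2, 2, 2))
    labels, n = ndimage.label(tiled, structure=np.ones((3, 3, 3), bool))
    if n <= 1:
        return bone
    nx, ny, nz = bone.shape
    base = labels[:nx, :ny, :nz]
    counts = np.bincount(base.ravel())
    counts[0] = 0
    return base == counts.argmax()


_SPECK_VOXELS = 30


def _remove_specks(bone: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(bone, structure=np.ones((3, 3, 3), bool))
    if n <= 1:
        return bone
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = np.flatnonzero(counts >= _SPECK_VOXELS)
    return np.isin(labels, keep)


def grf_structure(
    shape: tuple,
    spacing: float,
    target_bvtv: float,
    correlation_length: float,
    seed: int,
    max_retries: int = 5,
    min_retention: float = 0.9,
) -> Volume3D:
    """Trabecular-like binary structure from a thresholded Gaussian random field.

    White noise is convolved (periodically) with a Gaussian of standard
    deviation ``correlation_length / (2 * spacing)`` voxels and thresholded
    at the quantile giving ``target_bvtv`` percent bone, then the largest
    connected component is kept (26-connectivity, periodic to match the
    field).  Seeds whose largest component holds less than 90% of the
    thresholded volume are retried with the next seed.
    """
    if not 5 < target_bvtv < 60:
        raise ValueError(f"target_bvtv must be in (5, 60), got {target_bvtv}")
    if correlation_length < 2 * spacing:
        raise ValueError("correlation_length must be >= 2 * spacing")
    sigma_vox = correlation_length / (2.0 * spacing)
    for attempt in range(max_retries):
        rng = np.random.default_rng([int(seed) + attempt, 0x5EED])
        noise = rng.standard_normal(shape)
        fieldv = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
        thr = np.quantile(fieldv, 1.0 - target_bvtv / 100.0)
        bone = fieldv >= thr
        n_thr = bone.sum()
        bone = _largest_component_periodic(bone)
        if bone.sum() >= min_retention * n_thr:
            return Volume3D(data=bone.astype(np.uint8), spacing=spacing)
    raise RuntimeError(
        f"no connected GRF structure in {max_retries} attempts from seed {seed}"
    )


def phantom(kind: str, shape: tuple, spacing: float, **geometry) -> Volume3D:
    """Exact voxelization of an analytic solid (voxel center inside => bone).

    Kinds and geometry parameters (all lengths in voxels):
      sphere: radius, optional center (defaults to domain center)
      plate:  thickness (spans the domain normal to axis 0), optional offset
      rod:    radius (axis of the cylinder along axis 0)
      gyroid: period, optional threshold (default 0)
    """
    shape = tuple(int(s) for s in shape)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    center = geometry.get("center", tuple((s - 1) / 2.0 for s in shape))

    if kind == "sphere":
        r = float(geometry["radius"])
        if any(c - r < 3 or c + r > s - 4 for c, s in zip(center, shape)):
            raise ValueError("sphere must fit inside the domain with a 3-voxel margin")
        dist = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
        bone = dist <= r
    elif kind == "plate":
        t = float(geometry["thickness"])
        off = float(geometry.get("offset", (shape[0] - t) / 2.0))
        if t >= shape[0]:
            raise ValueError("plate thickness exceeds the domain")
        bone = (grids[0] >= off) & (grids[0] < off + t)
    elif kind == "rod":
        r = float(geometry["radius"])
        if any(c - r < 3 or c + r > s - 4 for c, s in zip(center[1:], shape[1:])):
            raise ValueError("rod must fit inside the domain cross-section with a 3-voxel margin")
        dist = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids[1:], center[1:])))
        bone = dist <= r
    elif kind == "gyroid":
        period = float(geometry["period"])
        thr = float(geometry.get("threshold", 0.0))
        w = 2.0 * np.pi / period
        x, y, z = (w * g for g in grids)
        g = np.sin(x) * np.cos(y) + np.sin(y) * np.cos(z) + np.sin(z) * np.cos(x)
        bone = g >= thr
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return Volume3D(data=bone.astype(np.uint8), spacing=spacing)


# --------------------------------------------------------------------------
# Longitudinal generation
# --------------------------------------------------------------------------

def longitudinal_series(
    initial: Volume3D,
    thetas: list[ModelParams],
    interval_days: list[float],
    noise: float = 0.0,
    seed: int | None = None,
    config: EvolutionConfig = EvolutionConfig(),
) -> list[Volume3D]:
    """Forward-generate a volume series with known per-interval parameters.

    Optional voxel noise flips band voxels (within one voxel spacing of the
    surface) at the given rate, emulating segmentation and registration
    jitter, followed by speck cleanup: connected components smaller than
    ``_SPECK_VOXELS`` are removed (noise debris), while larger fragments a
    flip may have severed are kept — amputating them would change far more
    voxels than the noise itself.
    """
    if len(thetas) != len(interval_days):
        raise ValueError("thetas and interval_days must have the same length")
    rng = np.random.default_rng(seed)
    series = [initial]
    current = initial
    for theta, days in zip(thetas, interval_days):
        nxt, _ = simulate(current, theta, days, config)
        if noise > 0 and nxt.bone_voxels() not in (0, nxt.data.size):
            phi = signed_distance(nxt).phi
            band = np.abs(phi) <= nxt.spacing
            flips = band & (rng.random(nxt.shape) < noise)
            data = nxt.data.astype(bool) ^ flips
            data = _remove_specks(data)
            nxt = Volume3D(data=data.astype(np.uint8), spacing=nxt.spacing)
        series.append(nxt)
        current = nxt
    return series


def _draw_thetas(spec: CohortSpec, rng: np.random.Generator) -> list[ModelParams]:
    """Per-interval parameters: interval mean + participant random effect
    + interval-level draw (between-subject variance is the premise of
    participant-specific modeling)."""
    td = spec.theta_distributions
    u_a = rng.normal(0.0, td["a_participant_sd"])
    u_b = rng.normal(0.0, td["b_participant_sd"])
    out = []
    for i in range(spec.n_intervals):
        a = td["a_mean"][i] + u_a + rng.normal(0.0, td["a_interval_sd"])
        b = td["b_mean"][i] + u_b + rng.normal(0.0, td["b_interval_sd"])
        out.append(ModelParams(a=a, b=max(b, 0.0)))
    return out


def cohort_generate(
    spec: CohortSpec,
    config: EvolutionConfig = EvolutionConfig(),
):
    """Generate a full synthetic cohort.

    Returns ``(records, manifest)``: one CohortRecord per participant x site
    x interval (volumes and true thetas only; fits are added by the study
    pipeline) and a manifest DataFrame. Deterministic for a fixed spec seed.
    """
    records: list[CohortRecord] = []
    rows = []
    for p in range(spec.n_participants):
        for s in range(spec.n_sites):
            site = ("left", "right")[s % 2] if spec.n_sites <= 2 else f"site{s}"
            struct_seed = int(np.random.default_rng([spec.seed, p, s]).integers(2**31))
            baseline = grf_structure(
                spec.volume_shape, spec.spacing, spec.target_bvtv,
                spec.correlation_length, seed=struct_seed,
            )
            theta_rng = np.random.default_rng([spec.seed, p, s, 1])
            thetas = _draw_thetas(spec, theta_rng)
            noise_seed = int(np.random.default_rng([spec.seed, p, s, 2]).integers(2**31))
            series = longitudinal_series(
                baseline, thetas, list(spec.interval_days),
                noise=spec.noise, seed=noise_seed, config=config,
            )
            pid = f"P{p + 1:02d}"
            for i in range(spec.n_intervals):
                label = f"{spec.timepoints[i]}-{spec.timepoints[i + 1]}"
                rec = CohortRecord(
                    participant=pid, site=site, interval=label, interval_index=i + 1,
                    baseline=series[i], followup=series[i + 1],
                    days=float(spec.interval_days[i]), theta_true=thetas[i],
                )
                records.append(rec)
                rows.append({
                    "participant": pid, "site": site, "interval": label,
                    "interval_index": i + 1, "days": rec.days,
                    "true_a": thetas[i].a, "true_b": thetas[i].b,
                    "baseline_bone_voxels": series[i].bone_voxels(),
                    "followup_bone_voxels": series[i + 1].bone_voxels(),
                })
    return records, pd.DataFrame(rows)


def corrupt_followups(
    records: list[CohortRecord],
    fraction: float,
    seed: int = 0,
) -> list[CohortRecord]:
    """Replace a fraction of follow-ups with independent GRF structures.

    The corrupted pairs violate the adaptation model by construction; a
    sound pipeline must land them in its exclusion ledger (non-converged or
    distance-rejected), mirroring the bookkeeping of in vivo fits that fail.
    Returns a new record list; originals are not modified.
    """
    rng = np.random.default_rng([seed, 0xC0])
    n = max(1, int(round(fraction * len(records)))) if fraction > 0 else 0
    idx = rng.choice(len(records), size=n, replace=False) if n else []
    out = list(records)
    for i in idx:
        rec = records[i]
        shape = rec.baseline.shape
        indep = grf_structure(
            shape, rec.baseline.spacing,
            float(np.clip(100.0 * rec.baseline.bone_voxels() / rec.baseline.data.size,
                          15.0, 45.0)),
            correlation_length=4.3 * rec.baseline.spacing,
            seed=int(rng.integers(2**31)),
            min_retention=0.0,  # connectivity is irrelevant for a model-violating stand-in
        )
        out[i] = replace(rec, followup=indep, corrupted=True, theta_true=None)
    return out


def reduced_spec(spec: CohortSpec, shape: tuple = (32, 32, 32)) -> CohortSpec:
    """A desk-scale variant of a cohort spec (smaller volumes, same design)."""
    return replace(spec, volume_shape=tuple(shape))
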