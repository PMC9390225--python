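"""Synthetic thoracic CT phantoms with paired masks and known ground truth.

The phantom is deliberately schematic — ellipsoidal body (40 HU) and lungs
(-800 HU) — but reproduces the radiological structure of pleural
collections that the feature extractor measures:

* dependent effusions as posterior crescents draping the lung (concave,
  low solidity) and loculated effusions as lens-shaped collections abutting
  the lung laterally/posteriorly, which yields the obtuse contact angle by
  construction (convex, high solidity);
* hyperdense inclusions (> 30 HU) as depth-core layers of the collection,
  so a requested inclusion no larger than the cavity partition lies fully
  inside it;
* smooth pleural rim thickening of parameterized physical width;
* gas as intrapleural bubbles (-1000 HU inside the pleura label) and
  pneumothorax as an anterior gas pocket between lung and chest wall,
  face-adjacent to the lung but outside lung/pleura and disconnected from
  the airway;
* an optional cylindrical airway (label 3) so the bronchial-exclusion rule
  of the gas features is exercisable;
* additive Gaussian HU noise on the CT only, never on the mask.

Structure volumes are matched to their requested values by bisection on a
single geometric parameter, so realized mask volumes track requests to
well under 2% for structures >= 2 mL; ground truth records the realized
(voxelized) volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import CTVolume, LabelMask, CaseTable, DEFAULT_LABEL_MAP
from .features import FeatureConfig, extract_all, LUNG, PLEURA, AIRWAY

logger = logging.getLogger(__name__)

__all__ = [
    "SideSpec",
    "PhantomSpec",
    "GroundTruth",
    "InfeasibleGeometryError",
    "generate_phantom",
    "generate_cohort",
    "sample_phantom_spec",
    "CLINICAL_PREVALENCES",
]

SOFT_TISSUE_HU = 40.0
LUNG_HU = -800.0
AIR_HU = -1000.0

#: default per-feature prevalences, emulating a thoracocentesis-referred
#: clinical cohort enriched for complex effusions (17/335 hyperdense,
#: 95/335 thickening, 100/335 gas, 128/335 loculated)
CLINICAL_PREVALENCES = {
    "hyperdense_fluid": 17 / 335,
    "pleural_thickening": 95 / 335,
    "gas": 100 / 335,
    "loculation": 128 / 335,
}


class InfeasibleGeometryError(ValueError):
    """Requested structure volumes exceed the hemithorax capacity."""


@dataclass
class SideSpec:
    """Generative parameters for one hemithorax."""

    effusion_ml: float = 0.0
    density_hu: float = 10.0
    geometry: str = "dependent_crescent"  # or "loculated_lens"
    #: list of (volume_ml, density_hu, location) with location cavity|rim
    inclusions: list = field(default_factory=list)
    rim_width_mm: float = 0.0
    rim_density_hu: float = 60.0
    gas_bubbles_ml: list = field(default_factory=list)
    pneumothorax_ml: float = 0.0

    def validate(self):
        if self.effusion_ml < 0 or self.pneumothorax_ml < 0:
            raise ValueError("volumes must be >= 0")
        if any(v < 0 for v, *_ in self.inclusions):
            raise ValueError("inclusion volumes must be >= 0")
        if any(v < 0 for v in self.gas_bubbles_ml):
            raise ValueError("bubble volumes must be >= 0")
        if self.geometry not in ("dependent_crescent", "loculated_lens"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        for _, _, loc in self.inclusions:
            if loc not in ("cavity", "rim"):
                raise ValueError(f"inclusion location must be cavity|rim, got {loc!r}")


@dataclass
class PhantomSpec:
    """Full generative specification of one phantom case.

    Geometry defaults scale with the physical grid extent; all distances
    are millimetres, all densities Hounsfield units.
    """

    shape: tuple[int, int, int] = (96, 88, 72)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    left: SideSpec | None = None
    right: SideSpec | None = None
    airway: bool = True
    rim_partition_mm: float = 4.0  # used only to size cavity inclusions
    noise_sigma_hu: float = 10.0
    seed: int = 0

    def validate(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.noise_sigma_hu < 0:
            raise ValueError("noise sigma must be >= 0")
        for s in (self.left, self.right):
            if s is not None:
                s.validate()

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)


@dataclass
class GroundTruth:
    """Realized (voxelized) volumes and the binary labels they imply."""

    per_side: dict  # side -> dict of realized volumes (mL)
    labels: dict  # binary complexity labels + 'complex'
    diagnosis: str

    def to_dict(self) -> dict:
        return {"per_side": self.per_side, "labels": self.labels,
                "diagnosis": self.diagnosis}


# ---------------------------------------------------------------------------
# geometry helpers

def _grids(shape, spacing):
    ax = [(np.arange(s) - (s - 1) / 2.0) * sp for s, sp in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij")


def _ellipsoid(X, Y, Z, c, a):
    return (
        ((X - c[0]) / a[0]) ** 2
        + ((Y - c[1]) / a[1]) ** 2
        + ((Z - c[2]) / a[2]) ** 2
        <= 1.0
    )


def _bisect_volume(fn, target_vox, lo, hi, tol_frac=0.002, iters=60):
    """Find parameter t such that fn(t).sum() ~= target_vox; fn monotone."""
    hi_count = int(fn(hi).sum())
    if hi_count < target_vox:
        raise InfeasibleGeometryError(
            f"requested structure needs {target_vox:.0f} voxels but at most "
            f"{hi_count} fit the available region"
        )
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        c = int(fn(mid).sum())
        if abs(c - target_vox) <= tol_frac * target_vox:
            return mid
        if c < target_vox:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class _Anatomy:
    """Fixed body/lung/airway geometry derived from the grid extent."""

    def __init__(self, spec: PhantomSpec):
        self.X, self.Y, self.Z = _grids(spec.shape, spec.spacing)
        ex = spec.extent_mm
        self.body_a = (0.47 * ex[0], 0.47 * ex[1], 0.48 * ex[2])
        self.body = _ellipsoid(self.X, self.Y, self.Z, (0, 0, 0), self.body_a)
        self.body_inner = _ellipsoid(
            self.X, self.Y, self.Z, (0, 0, 0), tuple(0.96 * a for a in self.body_a)
        )
        self.lung_a = (0.165 * ex[0], 0.26 * ex[1], 0.375 * ex[2])
        self.lung_cx = 0.23 * ex[0]
        self.lungs = {}
        for side, sgn in (("left", -1), ("right", +1)):
            c = (sgn * self.lung_cx, 0.0, 0.0)
            self.lungs[side] = (c, _ellipsoid(self.X, self.Y, self.Z, c, self.lung_a))
        # trachea: vertical cylinder between the lungs, upper half of grid
        r_aw = min(4.5, 0.055 * ex[0])
        self.airway = (
            (self.X**2 + (self.Y + 0.08 * ex[1]) ** 2 <= r_aw**2)
            & (self.Z >= 0)
            & self.body_inner
        )


def _crescent(an: _Anatomy, side: str, t: float, shift_frac: float = 0.6):
    c, lung = an.lungs[side]
    dy = shift_frac * an.lung_a[1] * (t - 1.0)
    outer = _ellipsoid(
        an.X, an.Y, an.Z, (c[0], c[1] + dy, c[2]), tuple(a * t for a in an.lung_a)
    )
    return outer & ~lung & (an.Y > c[1]) & an.body_inner & ~an.airway


def _lens(an: _Anatomy, side: str, r: float):
    c, lung = an.lungs[side]
    sgn = -1 if side == "left" else +1
    cc = (c[0] + 0.45 * an.lung_a[0] * sgn, c[1] + 0.90 * an.lung_a[1], c[2])
    ball = (an.X - cc[0]) ** 2 + (an.Y - cc[1]) ** 2 + (an.Z - cc[2]) ** 2 <= r * r
    return ball & ~lung & an.body_inner & ~an.airway


def _pneumo_pocket(an: _Anatomy, side: str, t: float):
    c, lung = an.lungs[side]
    sgn = -1 if side == "left" else +1
    outer = _ellipsoid(an.X, an.Y, an.Z, c, tuple(a * t for a in an.lung_a))
    return (
        outer
        & ~lung
        & (an.Y < c[1])
        & ((an.X - c[0]) * sgn >= 0)
        & an.body_inner
        & ~an.airway
    )


def _take_top(region, score, target_vox):
    """Exact-count subset of a region: the target_vox voxels of highest
    score (deterministic tie-break by array order)."""
    n = int(round(target_vox))
    idx = np.flatnonzero(region.ravel())
    if n > idx.size:
        raise InfeasibleGeometryError(
            f"structure needs {n} voxels but only {idx.size} are available"
        )
    order = np.argsort(-score.ravel()[idx], kind="stable")[:n]
    out = np.zeros(region.size, dtype=bool)
    out[idx[order]] = True
    return out.reshape(region.shape)


def _core_layer(effusion, edt, target_vox):
    """Deepest-core subset of a collection with an exact target volume."""
    return _take_top(effusion, edt, target_vox)


def _ball_patch(region, X, Y, Z, center, target_vox, r_max=None):
    """Region voxels nearest a centre, with an exact target volume."""
    cx, cy, cz = center
    d2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
    return _take_top(region, -d2, target_vox)


# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec):
    """Generate (CTVolume, LabelMask, GroundTruth) from a PhantomSpec.

    Deterministic for a fixed spec (seed included); noise is added to the
    CT only. Ground truth reflects realized voxel volumes after all
    structures are painted, not the requested volumes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    an = _Anatomy(spec)
    vox_mm3 = float(np.prod(spec.spacing))

    ct = np.full(spec.shape, AIR_HU, dtype=np.float32)
    ct[an.body] = SOFT_TISSUE_HU
    mask = np.zeros(spec.shape, dtype=np.uint8)
    for _, (_, lung) in an.lungs.items():
        ct[lung] = LUNG_HU
        mask[lung] = LUNG
    if spec.airway:
        ct[an.airway] = AIR_HU
        mask[an.airway] = AIRWAY

    per_side: dict[str, dict] = {}
    struct_masks: dict[str, dict] = {}
    for side in ("left", "right"):
        sspec = getattr(spec, side)
        info = {
            "effusion_ml": 0.0,
            "hyperdense_ml": 0.0,
            "gas_ml": 0.0,
            "pneumothorax_ml": 0.0,
            "rim_ml": 0.0,
            "geometry": None,
            "inclusion_realized": [],
            "bubble_realized": [],
        }
        structs = {"effusion": None, "inclusions": [], "bubbles": [],
                   "rim": None, "pneumo": None}
        if sspec is not None and sspec.effusion_ml > 0:
            target = sspec.effusion_ml * 1000.0 / vox_mm3
            if sspec.geometry == "dependent_crescent":
                t = _bisect_volume(
                    lambda t: _crescent(an, side, t), target, 1.0, 2.6
                )
                eff = _crescent(an, side, t)
            else:
                t = _bisect_volume(
                    lambda r: _lens(an, side, r), target, 0.5,
                    0.9 * float(min(an.body_a)),
                )
                eff = _lens(an, side, t)
            eff &= mask == 0  # never overwrite lung or airway
            structs["effusion"] = eff
            mask[eff] = PLEURA
            ct[eff] = sspec.density_hu
            info["effusion_ml"] = eff.sum() * vox_mm3 / 1000.0
            info["geometry"] = sspec.geometry

            edt = ndi.distance_transform_edt(eff, sampling=spec.spacing)
            rim_part = eff & (edt <= spec.rim_partition_mm)

            if sspec.rim_width_mm > 0:
                rim_paint = eff & (edt <= sspec.rim_width_mm)
                ct[rim_paint] = sspec.rim_density_hu
                structs["rim"] = rim_paint
                info["rim_ml"] = rim_paint.sum() * vox_mm3 / 1000.0

            used = np.zeros_like(eff)
            for vol_ml, hu, location in sspec.inclusions:
                tv = vol_ml * 1000.0 / vox_mm3
                if location == "cavity":
                    inc = _core_layer(eff, edt, tv)
                else:  # rim patch around the outermost rim voxel
                    ridx = np.argwhere(rim_part)
                    center_idx = ridx[np.argmax(ridx[:, 1])]
                    cc = (
                        an.X[tuple(center_idx)],
                        an.Y[tuple(center_idx)],
                        an.Z[tuple(center_idx)],
                    )
                    inc = _ball_patch(
                        rim_part, an.X, an.Y, an.Z, cc, tv,
                        2.0 * float(max(an.body_a)),
                    )
                ct[inc] = hu
                used |= inc
                structs["inclusions"].append((inc, hu))
            for vol_ml in sspec.gas_bubbles_ml:
                tv = vol_ml * 1000.0 / vox_mm3
                avail = eff & ~ndi.binary_dilation(used, iterations=2)
                edt_av = np.where(avail, edt, 0.0)
                center_idx = np.unravel_index(np.argmax(edt_av), edt.shape)
                cc = (
                    an.X[center_idx], an.Y[center_idx], an.Z[center_idx]
                )
                bub = _ball_patch(
                    eff & ~used, an.X, an.Y, an.Z, cc, tv,
                    2.0 * float(max(an.body_a)),
                )
                ct[bub] = AIR_HU
                used |= bub
                structs["bubbles"].append(bub)

        if sspec is not None and sspec.pneumothorax_ml > 0:
            target = sspec.pneumothorax_ml * 1000.0 / vox_mm3
            t = _bisect_volume(
                lambda t: _pneumo_pocket(an, side, t) & (mask == 0),
                target, 1.0, 3.5,
            )
            pocket = _pneumo_pocket(an, side, t) & (mask == 0)
            ct[pocket] = AIR_HU
            structs["pneumo"] = pocket
            info["pneumothorax_ml"] = pocket.sum() * vox_mm3 / 1000.0

        per_side[side] = info
        struct_masks[side] = structs

    # realized volumes: recompute from the final CT paint (later structures
    # may have overwritten earlier ones)
    min_ml = 2.0
    labels = dict.fromkeys(
        ("hyperdense_fluid", "pleural_thickening", "gas", "loculation"), 0
    )
    for side in ("left", "right"):
        structs = struct_masks[side]
        info = per_side[side]
        sspec = getattr(spec, side)
        gas_total = 0.0
        for inc, hu in structs["inclusions"]:
            realized = inc & np.isin(
                mask, [PLEURA]
            ) & (ct > 30.0) if hu > 30.0 else np.zeros_like(inc)
            # noise not yet added: paint is exact here
            ml = realized.sum() * vox_mm3 / 1000.0
            info["inclusion_realized"].append(ml)
            info["hyperdense_ml"] += ml
            if ml >= min_ml and hu > 30.0:
                labels["hyperdense_fluid"] = 1
        if structs["rim"] is not None:
            rim_now = structs["rim"] & (ct == sspec.rim_density_hu)
            info["rim_ml"] = rim_now.sum() * vox_mm3 / 1000.0
            if info["rim_ml"] >= min_ml and sspec.rim_density_hu > 30.0:
                labels["pleural_thickening"] = 1
        for bub in structs["bubbles"]:
            ml = bub.sum() * vox_mm3 / 1000.0
            info["bubble_realized"].append(ml)
            gas_total += ml
            if ml >= min_ml:
                labels["gas"] = 1
        info["gas_ml"] = gas_total
        # all painted material above the hyperdensity cutoff, i.e. what a
        # >30 HU measurement should recover in total
        info["hyperdense_total_ml"] = info["hyperdense_ml"] + (
            info["rim_ml"]
            if sspec is not None and sspec.rim_density_hu > 30.0 else 0.0
        )
        if info["pneumothorax_ml"] >= min_ml:
            labels["gas"] = 1
        if (
            info["geometry"] == "loculated_lens"
            and info["effusion_ml"] >= min_ml
        ):
            labels["loculation"] = 1

    labels["complex"] = int(any(labels.values()))
    if labels["complex"] == 0:
        diagnosis = "serous"
    elif labels["pleural_thickening"] or labels["gas"] or labels["hyperdense_fluid"]:
        diagnosis = "empyema"
    else:
        diagnosis = "carcinomatosis"

    if spec.noise_sigma_hu > 0:
        ct = ct + rng.normal(0.0, spec.noise_sigma_hu, size=ct.shape).astype(
            np.float32
        )

    volume = CTVolume(ct, spec.spacing)
    label_map = dict(DEFAULT_LABEL_MAP)
    mask_obj = LabelMask(mask, spec.spacing, label_map=label_map)
    gt = GroundTruth(per_side=per_side, labels=labels, diagnosis=diagnosis)
    return volume, mask_obj, gt


# ---------------------------------------------------------------------------
# cohort generation

def _sample_side_spec(rng, labels: dict) -> SideSpec:
    """Draw generative parameters consistent with requested binary labels.

    Volume ranges are sized to the default grid so that every requested
    structure is geometrically feasible and its label is recoverable from
    the extracted features (cavity inclusions >= ~2.6 mL, bubbles >= 2.6
    mL, crescents up to ~85 mL, lenses up to ~28 mL).
    """
    loculated = bool(labels["loculation"])
    hyperdense = bool(labels["hyperdense_fluid"])
    thickening = bool(labels["pleural_thickening"])
    gas = bool(labels["gas"])

    geometry = "loculated_lens" if loculated else "dependent_crescent"
    if loculated:
        eff = rng.uniform(19.0, 28.0) if hyperdense else rng.uniform(12.0, 28.0)
    else:
        if hyperdense:
            eff = rng.uniform(56.0, 80.0)
        elif gas:
            eff = rng.uniform(30.0, 80.0)
        else:
            eff = rng.uniform(15.0, 80.0)

    sspec = SideSpec(
        effusion_ml=float(eff),
        density_hu=float(rng.uniform(0.0, 12.0)),
        geometry=geometry,
    )
    if thickening:
        sspec.rim_width_mm = 4.0
        sspec.rim_density_hu = 60.0
    if hyperdense:
        hi = 4.5 if loculated else 6.0
        sspec.inclusions.append(
            (float(rng.uniform(2.8, hi)), 60.0, "cavity")
        )
    if gas:
        mode = rng.random()
        want_bubble = mode < 0.8
        want_pneumo = mode >= 0.6
        if want_bubble:
            cap = min(4.5, 0.2 * eff)
            sspec.gas_bubbles_ml.append(float(rng.uniform(2.6, max(2.7, cap))))
        if want_pneumo:
            sspec.pneumothorax_ml = float(rng.uniform(10.0, 20.0))
    return sspec


def sample_phantom_spec(
    case_seed: int,
    prevalences: dict[str, float] | None = None,
    shape: tuple[int, int, int] = (96, 88, 72),
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5),
    noise_sigma_hu: float = 10.0,
):
    """Draw one random unilateral case spec; returns (spec, side).

    The case's binary complexity labels are drawn independently per
    feature from ``prevalences`` (clinical-cohort defaults) and the
    generative parameters are sampled to realize them.
    """
    prev = dict(CLINICAL_PREVALENCES)
    if prevalences is not None:
        prev.update(prevalences)
    bad = {k: v for k, v in prev.items() if not 0.0 <= v <= 1.0}
    if bad:
        raise ValueError(f"prevalences must be in [0, 1]: {bad}")
    crng = np.random.default_rng(case_seed)
    req = {k: int(crng.random() < prev[k]) for k in CLINICAL_PREVALENCES}
    side = "left" if crng.random() < 0.5 else "right"
    sspec = _sample_side_spec(crng, req)
    spec = PhantomSpec(
        shape=shape, spacing=spacing, noise_sigma_hu=noise_sigma_hu,
        seed=case_seed,
    )
    setattr(spec, side, sspec)
    return spec, side


def generate_cohort(
    n_cases: int,
    prevalences: dict[str, float] | None = None,
    seed: int = 0,
    shape: tuple[int, int, int] = (96, 88, 72),
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5),
    noise_sigma_hu: float = 10.0,
    config: FeatureConfig = FeatureConfig(),
    radiomics: str = "builtin",
):
    """Generate a cohort of phantoms and its extracted feature table.

    Each case carries one unilateral effusion whose complexity labels are
    drawn independently per feature from ``prevalences`` (defaults follow
    the clinical classification cohort). Returns
    ``(ground_truths, CaseTable)`` with one table row per case holding the
    extracted features of the effusion side plus the ground-truth labels.
    """
    if n_cases < 2:
        raise ValueError("n_cases must be >= 2")
    rng = np.random.default_rng(seed)
    records, gts = [], []
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec, side = sample_phantom_spec(
            case_seed, prevalences=prevalences, shape=shape, spacing=spacing,
            noise_sigma_hu=noise_sigma_hu,
        )
        ct, mask, gt = generate_phantom(spec)
        gts.append(gt)
        featuresets = extract_all(ct, mask, config, radiomics=radiomics)
        fs = featuresets[side]
        row = {"case_id": f"case_{i:04d}", "side": side}
        row.update(fs.to_dict())
        row.pop("side", None)
        row["side"] = side
        row.update(gt.labels)
        row["diagnosis"] = gt.diagnosis
        records.append(row)
    table = CaseTable(pd.DataFrame.from_records(records))
    return gts, table
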