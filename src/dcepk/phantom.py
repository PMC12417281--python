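"""Digital reference objects: glioma-like PK phantoms rendered to 4-D DCE.

The generator stands in for a patient cohort: each synthetic subject has a
brain disc, a small arterial vessel, and a three-layer ellipsoidal tumor
(enhancing rim, necrotic core, non-enhancing infiltration) whose voxelwise
(ktrans, ve, vp) are drawn from truncated log-normal class distributions.
Binary labels (WHO grade low/high, IDH mutant/wildtype) act on the tumor-rim
distribution medians, so all label information is carried by the PK maps.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from dcepk.io import DCESeries
from dcepk.physics import (
    AcquisitionParams,
    AIFCurve,
    PKMaps,
    TimeGrid,
    concentration_to_signal,
    population_aif,
    tofts_forward_maps,
)

__all__ = [
    "PhantomSpec",
    "CohortEffects",
    "SyntheticSubject",
    "build_phantom",
    "render_dce",
    "generate_cohort",
]

#: blood plasma fraction (1 - hematocrit); vessel voxels carry vp at this value
BLOOD_PLASMA_FRACTION = 0.58

#: per-class log-normal (median, log-sd) for (ktrans [1/min], ve, vp).
#: Synthetic calibration values, chosen to emulate treatment-naive glioma
#: DCE contrast between normal brain, enhancing rim, necrotic core and
#: non-enhancing infiltration; the rim defaults are the low-grade centres.
DEFAULT_CLASS_PARAMS = {
    "normal": {"ktrans": (0.01, 0.15), "ve": (0.05, 0.15), "vp": (0.01, 0.15)},
    "tumor_rim": {"ktrans": (0.05, 0.15), "ve": (0.20, 0.15), "vp": (0.025, 0.15)},
    "tumor_core": {"ktrans": (0.004, 0.15), "ve": (0.35, 0.15), "vp": (0.006, 0.15)},
    "nonenhancing_infiltration": {"ktrans": (0.02, 0.15), "ve": (0.15, 0.15), "vp": (0.015, 0.15)},
}

TRUNCATION = {"ktrans": (0.0, 5.0), "ve": (1e-3, 0.95), "vp": (1e-4, 0.5)}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, class distributions and degradation settings for one phantom.

    ``tumor_radius`` is the in-plane semi-axis range in voxels (0 disables the
    tumor); ``noise_sd`` is the Rician sigma in signal units; ``motion`` is
    ``"none"`` or ``"shift"`` (seeded per-frame integer shifts).
    """

    shape: tuple = (32, 32, 1)
    class_params: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_PARAMS.items()})
    tumor_radius: tuple = (5.0, 8.0)
    core_fraction: float = 0.5
    infiltration_factor: float = 1.35
    noise_sd: float = 2.0
    motion: str = "none"
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or self.shape[0] < 16 or self.shape[1] < 16 or self.shape[2] < 1:
            raise ValueError("phantom shape must be at least (16, 16, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.motion not in ("none", "shift"):
            raise ValueError(f"unknown motion mode {self.motion!r}")
        if max(self.tumor_radius) * self.infiltration_factor > min(self.shape[:2]):
            raise ValueError("tumor larger than the volume")


@dataclass(frozen=True)
class CohortEffects:
    """Class-conditional effect specification.

    Shifts are additive on the log-median of the tumor-rim distributions
    (high-grade and IDH-wildtype directions); ``sigma_subject_log`` is the
    between-subject log-sd shared by all rim parameters (independently drawn
    per parameter).  Infiltration receives half of each shift.
    """

    sigma_subject_log: float = 0.6
    grade_shift: dict = field(
        default_factory=lambda: {"ktrans": math.log(3.0), "ve": math.log(1.75), "vp": math.log(2.4)}
    )
    idh_shift: dict = field(
        default_factory=lambda: {"ktrans": math.log(2.0), "ve": math.log(1.3), "vp": math.log(2.0)}
    )

    @classmethod
    def null(cls, sigma_subject_log: float = 0.6) -> "CohortEffects":
        """Zero-shift effects: labels carry no PK information (AUROC ~ 0.5)."""
        zero = {"ktrans": 0.0, "ve": 0.0, "vp": 0.0}
        return cls(sigma_subject_log=sigma_subject_log, grade_shift=dict(zero), idh_shift=dict(zero))


@dataclass
class SyntheticSubject:
    subject_id: str
    gt_maps: PKMaps
    masks: dict
    label_idh: str  # "wildtype" | "mutant"
    label_grade: str  # "low" | "high"
    seed: int
    dce: DCESeries | None = None
    class_map: np.ndarray | None = None


def _ellipsoid(shape, center, radii):
    idx = np.indices(shape).astype(float)
    r = np.zeros(shape)
    for ax in range(3):
        if radii[ax] > 0:
            r += ((idx[ax] - center[ax]) / radii[ax]) ** 2
        else:
            r += np.where(idx[ax] == center[ax], 0.0, np.inf)
    return r <= 1.0


def _draw_class(rng, params, n):
    """Truncated log-normal draws respecting the joint ve + vp <= 1 invariant."""
    out = {}
    for name in ("ktrans", "ve", "vp"):
        med, sig = params[name]
        if med <= 0:
            out[name] = np.zeros(n)
        else:
            lo, hi = TRUNCATION[name]
            out[name] = np.clip(med * rng.lognormal(0.0, sig, size=n), lo, hi)
    s = out["ve"] + out["vp"]
    over = s > 0.999
    if over.any():
        f = 0.999 / s[over]
        out["ve"][over] *= f
        out["vp"][over] *= f
    return out


def build_phantom(spec: PhantomSpec):
    """Ground-truth maps and masks for one phantom; deterministic per seed.

    Returns ``(PKMaps, masks, class_map)`` where ``masks`` holds ``brain``,
    ``vessel``, ``enhancing_tumor``, ``whole_tumor`` boolean arrays and
    ``class_map`` is an integer tissue-class label volume.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    brain = _ellipsoid(shape, (cx, cy, cz), (0.44 * nx, 0.44 * ny, max(nz, 1e9)))

    class_map = np.zeros(shape, dtype=np.int8)  # 0 background
    class_map[brain] = 1  # normal

    r_lo, r_hi = spec.tumor_radius
    has_tumor = r_hi > 0
    tumor = np.zeros(shape, dtype=bool)
    core = np.zeros(shape, dtype=bool)
    infiltration = np.zeros(shape, dtype=bool)
    if has_tumor:
        radii = rng.uniform(r_lo, r_hi, size=2)
        off_lim = 0.44 * nx - spec.infiltration_factor * radii.max() - 1
        off_lim = max(off_lim, 0.0)
        center = (
            cx + rng.uniform(-off_lim, off_lim),
            cy + rng.uniform(-off_lim, off_lim),
            cz,
        )
        rz = max(nz, 1e9)
        tumor = _ellipsoid(shape, center, (radii[0], radii[1], rz)) & brain
        core = _ellipsoid(
            shape, center, (spec.core_fraction * radii[0], spec.core_fraction * radii[1], rz)
        ) & brain
        infil_full = _ellipsoid(
            shape, center,
            (spec.infiltration_factor * radii[0], spec.infiltration_factor * radii[1], rz),
        ) & brain
        infiltration = infil_full & ~tumor
        rim = tumor & ~core
        class_map[infiltration] = 2
        class_map[rim] = 3
        class_map[core] = 4

    # vessel: small block near the anterior brain margin, overwrites tumor
    vx = int(round(cx))
    vy = int(round(0.1 * ny + 2))
    vessel = np.zeros(shape, dtype=bool)
    vessel[vx - 1 : vx + 1, vy : vy + 2, :] = True
    vessel &= brain
    class_map[vessel] = 5

    names = {1: "normal", 2: "nonenhancing_infiltration", 3: "tumor_rim", 4: "tumor_core"}
    maps = {k: np.zeros(shape) for k in ("ktrans", "ve", "vp")}
    for code, cname in names.items():
        sel = class_map == code
        n = int(sel.sum())
        if n == 0:
            continue
        draws = _draw_class(rng, spec.class_params[cname], n)
        for k in maps:
            maps[k][sel] = draws[k]
    vsel = class_map == 5
    maps["ktrans"][vsel] = 0.0
    maps["ve"][vsel] = 0.0
    maps["vp"][vsel] = BLOOD_PLASMA_FRACTION

    masks = {
        "brain": brain,
        "vessel": vessel,
        "enhancing_tumor": (class_map == 3),
        "whole_tumor": (class_map == 2) | (class_map == 3) | (class_map == 4),
    }
    return PKMaps(**maps), masks, class_map


def render_dce(
    gt_maps: PKMaps,
    masks: dict,
    aif: AIFCurve,
    acq: AcquisitionParams | None = None,
    noise_sd: float = 2.0,
    motion: str = "none",
    seed: int = 0,
    subject_id: str = "subject-0",
) -> DCESeries:
    """Render ground-truth maps to a noisy 4-D signal series.

    Per voxel: extended Tofts forward -> SPGR signal; vessel voxels carry the
    AIF through their plasma fraction.  Rician noise is applied at signal
    scale (magnitude of a complex Gaussian perturbation); optional seeded
    per-frame integer shifts emulate motion.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    acq = acq or AcquisitionParams()
    if gt_maps.shape != masks["brain"].shape:
        raise ValueError("maps and masks are not aligned")
    ct = tofts_forward_maps(gt_maps, aif)
    sig = concentration_to_signal(ct, acq)
    rng = np.random.default_rng(seed)
    if motion == "shift":
        for t in range(aif.grid.n_baseline, aif.grid.n_frames):
            if rng.random() < 0.3:
                dx, dy = rng.integers(-1, 2, size=2)
                sig[..., t] = np.roll(sig[..., t], (dx, dy), axis=(0, 1))
    elif motion != "none":
        raise ValueError(f"unknown motion mode {motion!r}")
    if noise_sd > 0:
        e1 = rng.normal(0.0, noise_sd, sig.shape)
        e2 = rng.normal(0.0, noise_sd, sig.shape)
        sig = np.sqrt((sig + e1) ** 2 + e2**2)
    return DCESeries(data=sig, grid=aif.grid, acq=acq, subject_id=subject_id)


def _subject_spec(base: PhantomSpec, effects: CohortEffects, grade: str, idh: str, rng, seed: int) -> PhantomSpec:
    """Per-subject spec: label shifts + subject-level log-normal factors on the rim."""
    cp = {k: dict(v) for k, v in base.class_params.items()}
    for param in ("ktrans", "ve", "vp"):
        shift = rng.normal(0.0, effects.sigma_subject_log)
        if grade == "high":
            shift += effects.grade_shift[param]
        if idh == "wildtype":
            shift += effects.idh_shift[param]
        med, sig = cp["tumor_rim"][param]
        cp["tumor_rim"][param] = (med * math.exp(shift), sig)
        med_i, sig_i = cp["nonenhancing_infiltration"][param]
        cp["nonenhancing_infiltration"][param] = (med_i * math.exp(0.5 * shift), sig_i)
    return replace(base, class_params=cp, seed=seed)


def generate_cohort(
    n_subjects: int,
    class_mix: float = 0.5,
    idh_mix: float = 0.5,
    effects: CohortEffects | None = None,
    split: tuple = (0.6, 0.2, 0.2),
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    acq: AcquisitionParams | None = None,
    grid: TimeGrid | None = None,
    render: bool = True,
):
    """Generate a labelled synthetic cohort with a reproducible manifest.

    ``class_mix`` is P(high grade); ``idh_mix`` is P(wildtype); ``split``
    fractions (train, valid, test) must sum to 1.  All randomness derives from
    ``seed`` through a per-subject seed recorded in the manifest.  With
    ``render=False`` only ground-truth maps and labels are produced (fast path
    for statistics experiments).

    Returns ``(subjects, manifest)`` with ``manifest`` a pandas DataFrame of
    (subject_id, label_idh, label_grade, split, seed).
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_splits = sum(1 for f in split if f > 0)
    if n_subjects < n_splits:
        raise ValueError(f"n_subjects={n_subjects} too small for a {n_splits}-way split")
    effects = effects or CohortEffects()
    base_spec = base_spec or PhantomSpec()
    acq = acq or AcquisitionParams()
    grid = grid or TimeGrid.uniform()
    aif = population_aif(grid)

    master = np.random.default_rng(seed)
    n_train = int(round(split[0] * n_subjects))
    n_valid = int(round(split[1] * n_subjects))
    labels = ["train"] * n_train + ["valid"] * n_valid + ["test"] * (n_subjects - n_train - n_valid)
    order = master.permutation(n_subjects)
    split_of = {int(order[i]): labels[i] for i in range(n_subjects)}

    subjects, rows = [], []
    for i in range(n_subjects):
        sseed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] & 0x7FFFFFFF)
        rng = np.random.default_rng(sseed)
        grade = "high" if rng.random() < class_mix else "low"
        idh = "wildtype" if rng.random() < idh_mix else "mutant"
        spec = _subject_spec(base_spec, effects, grade, idh, rng, seed=sseed)
        gt, masks, class_map = build_phantom(spec)
        sid = f"sub-{i:04d}"
        dce = None
        if render:
            dce = render_dce(
                gt, masks, aif, acq,
                noise_sd=spec.noise_sd, motion=spec.motion,
                seed=sseed + 1, subject_id=sid,
            )
        subjects.append(
            SyntheticSubject(
                subject_id=sid, gt_maps=gt, masks=masks,
                label_idh=idh, label_grade=grade, seed=sseed,
                dce=dce, class_map=class_map,
            )
        )
        rows.append(
            {"subject_id": sid, "label_idh": idh, "label_grade": grade,
             "split": split_of[i], "seed": sseed}
        )
    manifest = pd.DataFrame(rows)
    return subjects, manifest
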