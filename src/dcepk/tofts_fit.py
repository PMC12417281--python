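"""Conventional pathway: semi-automatic AIF extraction and voxelwise
extended-Tofts least-squares fitting.

This is the "ground-truth" route the network is trained toward and compared
against; its run-to-run variability is driven entirely by the AIF selection,
which :func:`extract_aif` can perturb with a seeded rater-jitter model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from dcepk.physics import (
    AIFCurve,
    PKMaps,
    PKParams,
    exp_conv,
    signal_to_concentration,
)

__all__ = ["AIFSelection", "FitResult", "FitOptions", "extract_aif", "fit_voxel", "fit_volume"]

#: physiologic parameter bounds: ktrans [min^-1], ve, vp [fraction]
DEFAULT_BOUNDS = {"ktrans": (0.0, 5.0), "ve": (1e-4, 1.0), "vp": (0.0, 1.0)}


@dataclass(frozen=True)
class AIFSelection:
    """An AIF extracted from a set of candidate vessel voxels."""

    voxel_indices: tuple
    aif: AIFCurve
    rater_id: str = "rater-0"


@dataclass
class FitResult:
    params: PKParams
    rss: float
    converged: bool
    n_iter: int
    bounds_hit: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FitOptions:
    """Voxel fit settings.

    ``n_starts`` seeded initialisations (the first is a variable-projection
    scan over a kep grid, the rest random within bounds); best residual sum of
    squares wins, ties broken toward the smaller ktrans.  The joint constraint
    ve + vp <= 1 is enforced by a residual penalty.
    """

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_starts: int = 3
    seed: int = 0
    kep_grid_size: int = 48
    penalty: float = 1e3
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12


def _varpro_init(ct, cp, dt, bounds, kep_grid_size):
    """Best (ktrans, ve, vp) on a kep grid, solving the linear subproblem.

    For fixed kep the model is linear in (ktrans, vp):
    Ct = ktrans * conv_kep + vp * Cp.  Solve the 2x2 normal equations for each
    kep on a log grid, clip to bounds, keep the lowest rss.
    """
    kep_hi = bounds["ktrans"][1] / bounds["ve"][0]
    keps = np.geomspace(1e-3, min(kep_hi, 50.0), kep_grid_size)
    basis = exp_conv(cp, dt, keps)  # (K, T)
    g11 = np.einsum("kt,kt->k", basis, basis)
    g12 = basis @ cp
    g22 = float(cp @ cp)
    b1 = basis @ ct
    b2 = float(cp @ ct)
    det = g11 * g22 - g12**2
    det = np.where(np.abs(det) < 1e-300, np.inf, det)
    kt = (b1 * g22 - b2 * g12) / det
    vp = (g11 * b2 - g12 * b1) / det
    kt = np.clip(kt, *bounds["ktrans"])
    vp = np.clip(vp, *bounds["vp"])
    resid = ct[None, :] - kt[:, None] * basis - vp[:, None] * cp[None, :]
    rss = np.einsum("kt,kt->k", resid, resid)
    k = int(np.argmin(rss))
    ve = np.clip(kt[k] / keps[k] if kt[k] > 0 else bounds["ve"][0], *bounds["ve"])
    return np.array([kt[k], ve, vp[k]])


def fit_voxel(ct: np.ndarray, aif: AIFCurve, options: FitOptions | None = None) -> FitResult:
    """Bounded trust-region least-squares fit of one concentration curve.

    Minimises ``sum((Ct - ExtendedTofts(theta, Cp))^2)`` over
    theta = (ktrans, ve, vp) within ``options.bounds``.  Deterministic for a
    given seed.  NaN frames are dropped if at least 75% of frames are valid.
    """
    options = options or FitOptions()
    ct = np.asarray(ct, dtype=float)
    cp = np.asarray(aif.cp, dtype=float)
    if not np.all(np.isfinite(cp)):
        raise ValueError("AIF contains non-finite values")
    valid = np.isfinite(ct)
    if not valid.any():
        raise ValueError("all-NaN concentration curve")
    dt = aif.grid.dt
    bounds = options.bounds
    lo = np.array([bounds["ktrans"][0], bounds["ve"][0], bounds["vp"][0]])
    hi = np.array([bounds["ktrans"][1], bounds["ve"][1], bounds["vp"][1]])

    ctv = np.where(valid, ct, 0.0)
    # degenerate all-zero curve: unidentifiable by convention
    if np.max(np.abs(ctv)) < 1e-12:
        params = PKParams(0.0, bounds["ve"][0], 0.0)
        return FitResult(params, 0.0, True, 0, {"ve": True, "ktrans": True, "vp": True})

    scale = max(np.max(np.abs(ctv)), 1e-6)

    def residual(theta):
        kt, ve, vp = theta
        model = vp * cp + kt * exp_conv(cp, dt, kt / ve)
        r = np.where(valid, ct - model, 0.0)
        pen = options.penalty * scale * max(0.0, ve + vp - 1.0)
        return np.concatenate([r, [pen]])

    rng = np.random.default_rng(options.seed)
    inits = [_varpro_init(ctv * valid, cp, dt, bounds, options.kep_grid_size)]
    for _ in range(options.n_starts - 1):
        inits.append(lo + rng.random(3) * (hi - lo))

    best = None
    for s, x0 in enumerate(inits):
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        sol = least_squares(
            residual, x0, bounds=(lo, hi), method="trf",
            xtol=options.xtol, ftol=options.ftol, gtol=options.gtol,
            max_nfev=None if s == 0 else 60,
        )
        rss = float(np.sum(sol.fun[:-1] ** 2))
        cand = (rss, float(sol.x[0]), sol)
        if best is None or (cand[0], cand[1]) < (best[0], best[1]):
            best = cand
    rss, _, sol = best
    kt, ve, vp = sol.x
    atol = 1e-9
    bounds_hit = {
        "ktrans": bool(kt <= lo[0] + atol or kt >= hi[0] - atol),
        "ve": bool(ve <= lo[1] + atol or ve >= hi[1] - atol),
        "vp": bool(vp <= lo[2] + atol or vp >= hi[2] - atol),
    }
    if kt <= atol:  # unidentifiable ve at ktrans = 0
        kt = 0.0
    vp = float(min(vp, 1.0))
    ve = float(min(ve, 1.0 - vp))  # the penalty leaves ve + vp <= 1 only softly
    params = PKParams(float(kt), ve, vp)
    return FitResult(params, rss, bool(sol.status > 0), int(sol.nfev), bounds_hit)


def fit_volume(dce, aif: AIFCurve, mask: np.ndarray, options: FitOptions | None = None):
    """Voxelwise extended-Tofts fit over a 4-D series.

    ``dce`` is a :class:`dcepk.io.DCESeries`.  Signal is converted to
    concentration first (baseline-calibrated); voxels outside ``mask`` are
    zero.  Voxels with fewer than 75% invertible frames are skipped and
    QC-flagged.  Results do not depend on voxel iteration order.

    Volume fits default to a single start: the variable-projection
    initialisation already scans the full kep range, so the extra random
    multistarts only cost time at this scale (pass options to override).

    Returns ``(PKMaps, qc)`` with ``qc`` holding rss / converged / skipped maps.
    """
    options = options or FitOptions(n_starts=1)
    data = dce.data
    if data.shape[-1] != aif.grid.n_frames:
        raise ValueError("dce and aif grids do not match")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape does not match volume")
    shape = data.shape[:3]
    out = {k: np.zeros(shape) for k in ("ktrans", "ve", "vp")}
    qc = {
        "rss": np.zeros(shape),
        "converged": np.zeros(shape, dtype=bool),
        "skipped": np.zeros(shape, dtype=bool),
    }
    idx = np.argwhere(mask)
    if idx.size == 0:
        return PKMaps(**out), qc
    ct_all, invalid = signal_to_concentration(data[mask], dce.acq, aif.grid.n_baseline)
    frac_valid = 1.0 - invalid.mean(axis=-1)
    for row, (i, j, k) in enumerate(idx):
        if frac_valid[row] < 0.75:
            qc["skipped"][i, j, k] = True
            continue
        ct = np.where(invalid[row], np.nan, ct_all[row])
        res = fit_voxel(ct, aif, options)
        out["ktrans"][i, j, k] = res.params.ktrans
        out["ve"][i, j, k] = res.params.ve
        out["vp"][i, j, k] = res.params.vp
        qc["rss"][i, j, k] = res.rss
        qc["converged"][i, j, k] = res.converged
    return PKMaps(**out), qc


def extract_aif(
    dce,
    candidate_mask: np.ndarray,
    rater_seed: int | None = None,
    top_k: int = 5,
    enhancement_floor: float = 0.1,
    scale_jitter: float = 0.10,
    plasma_fraction: float = 0.58,
    rater_id: str | None = None,
) -> AIFSelection:
    """Semi-automatic AIF selection from vessel-candidate voxels.

    Candidates are ranked by (peak concentration, early arrival); the top
    ``top_k`` curves are averaged and divided by ``plasma_fraction``
    (1 - hematocrit) to convert whole-blood to plasma concentration.  With ``rater_seed`` set, a seeded jitter
    re-ranks candidates (lognormal score noise), then applies a multiplicative
    scale within ``+/- scale_jitter`` and a one-frame delay in {-1, 0, +1},
    emulating inter-rater AIF selection variability.

    Raises if no candidate peak exceeds ``enhancement_floor`` (mM).
    """
    candidate_mask = np.asarray(candidate_mask, dtype=bool)
    if not candidate_mask.any():
        raise ValueError("candidate mask is empty")
    idx = np.argwhere(candidate_mask)
    curves, _ = signal_to_concentration(
        dce.data[candidate_mask], dce.acq, dce.grid.n_baseline
    )
    peaks = curves.max(axis=-1)
    if peaks.max() < enhancement_floor:
        raise ValueError(
            f"no candidate voxel exceeds the enhancement floor ({enhancement_floor} mM)"
        )
    arrival = np.argmax(curves >= 0.5 * peaks[:, None], axis=-1)
    scores = peaks.copy()
    scale, delay = 1.0, 0
    provenance = "extracted"
    if rater_seed is not None:
        rng = np.random.default_rng(rater_seed)
        scores = peaks * rng.lognormal(0.0, 0.25, size=peaks.shape)
        scale = 1.0 + rng.uniform(-scale_jitter, scale_jitter)
        delay = int(rng.integers(-1, 2))
        provenance = "perturbed"
    order = np.lexsort((arrival, -scores))
    chosen = order[: min(top_k, order.size)]
    cp = curves[chosen].mean(axis=0) / plasma_fraction
    cp = np.maximum(cp, 0.0)
    cp[: dce.grid.n_baseline] = 0.0
    aif = AIFCurve(cp=cp, grid=dce.grid, provenance="extracted")
    if rater_seed is not None:
        aif = aif.perturbed(scale, delay)
        cp = np.maximum(aif.cp, 0.0)
        cp[: dce.grid.n_baseline] = 0.0
        aif = AIFCurve(cp=cp, grid=dce.grid, provenance=provenance)
    if rater_id is None:
        rater_id = "rater-none" if rater_seed is None else f"rater-{rater_seed}"
    return AIFSelection(tuple(map(tuple, idx[chosen])), aif, rater_id)
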