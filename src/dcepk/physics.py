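"""Tracer-kinetic physics shared by the simulator, the fitter and the tests.

Units are fixed throughout the package: time in **minutes**, ``ktrans`` and
``kep`` in **min^-1**, contrast concentration in **mM**, TR and T1 in
**seconds** (converted internally).  Mixing minutes and seconds is the classic
DCE bug; every function states its units.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.signal import lfilter

__all__ = [
    "TimeGrid",
    "PKParams",
    "PKMaps",
    "AIFCurve",
    "AcquisitionParams",
    "aif_model_coefficients",
    "population_aif",
    "exp_conv",
    "tofts_forward",
    "concentration_to_signal",
    "signal_to_concentration",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform acquisition time grid.

    ``times`` are frame midpoints in minutes, starting at 0; the first
    ``n_baseline`` frames are pre-contrast.
    """

    times: np.ndarray
    n_baseline: int = 5

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("times must be a 1-D array with >= 2 frames")
        dt = np.diff(t)
        if not np.all(dt > 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
            raise ValueError("times must be uniformly spaced")
        if not (1 <= self.n_baseline < t.size):
            raise ValueError("n_baseline must be >= 1 and < n_frames")

    @classmethod
    def uniform(cls, n_frames: int = 60, dt: float = 1.0 / 12.0, n_baseline: int = 5) -> "TimeGrid":
        """Grid of ``n_frames`` frames spaced ``dt`` minutes (default 5 s)."""
        return cls(times=np.arange(n_frames) * float(dt), n_baseline=n_baseline)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PKParams:
    """Extended Tofts parameter triplet for one voxel.

    ktrans : volume transfer constant, min^-1
    ve     : extravascular extracellular volume fraction (dimensionless)
    vp     : plasma volume fraction (dimensionless)
    """

    ktrans: float
    ve: float
    vp: float

    def __post_init__(self):
        if self.ktrans < 0:
            raise ValueError(f"ktrans must be >= 0, got {self.ktrans}")
        if self.ktrans > 0 and not (0 < self.ve <= 1):
            raise ValueError(f"ve must be in (0, 1] when ktrans > 0, got {self.ve}")
        if not (0 <= self.ve <= 1):
            raise ValueError(f"ve must be in [0, 1], got {self.ve}")
        if not (0 <= self.vp <= 1):
            raise ValueError(f"vp must be in [0, 1], got {self.vp}")
        if self.ve + self.vp > 1 + 1e-12:
            raise ValueError(f"ve + vp must be <= 1, got {self.ve + self.vp}")

    @property
    def kep(self) -> float:
        """Efflux rate ktrans/ve in min^-1; 0 by convention for ktrans = ve = 0."""
        if self.ktrans == 0:
            return 0.0
        return self.ktrans / self.ve


@dataclass
class PKMaps:
    """Voxelwise parameter maps (each 3-D, aligned)."""

    ktrans: np.ndarray
    ve: np.ndarray
    vp: np.ndarray

    PARAMS = ("ktrans", "ve", "vp")

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.PARAMS:
            raise KeyError(name)
        return getattr(self, name)

    def stack(self) -> np.ndarray:
        """(3, ...) array in (ktrans, ve, vp) order."""
        return np.stack([self.ktrans, self.ve, self.vp])

    @classmethod
    def from_stack(cls, arr: np.ndarray) -> "PKMaps":
        return cls(ktrans=np.asarray(arr[0]), ve=np.asarray(arr[1]), vp=np.asarray(arr[2]))

    @property
    def shape(self):
        return self.ktrans.shape


@dataclass(frozen=True)
class AIFCurve:
    """Plasma contrast concentration Cp(t) in mM on a :class:`TimeGrid`."""

    cp: np.ndarray
    grid: TimeGrid
    provenance: str = "population-model"

    def __post_init__(self):
        cp = np.asarray(self.cp, dtype=float)
        object.__setattr__(self, "cp", cp)
        if cp.shape != self.grid.times.shape:
            raise ValueError("cp and grid must have the same length")
        if np.any(cp < -1e-12):
            raise ValueError("AIF concentrations must be non-negative")

    def perturbed(self, scale: float, delay_frames: int, provenance: str = "perturbed") -> "AIFCurve":
        """Multiplicative scale and integer-frame delay (zero-padded)."""
        cp = np.asarray(self.cp) * float(scale)
        if delay_frames > 0:
            cp = np.concatenate([np.zeros(delay_frames), cp[:-delay_frames]])
        elif delay_frames < 0:
            d = -delay_frames
            cp = np.concatenate([cp[d:], np.full(d, cp[-1])])
        return AIFCurve(cp=cp, grid=self.grid, provenance=provenance)


@dataclass(frozen=True)
class AcquisitionParams:
    """SPGR acquisition settings.

    tr_s       : repetition time in seconds
    flip_deg   : flip angle in degrees, (0, 90]
    r1         : contrast agent longitudinal relaxivity, s^-1 mM^-1
    t10_s      : pre-contrast tissue T1 in seconds
    s0_scale   : equilibrium-magnetisation signal scale (arbitrary units)
    """

    tr_s: float = 0.0028
    flip_deg: float = 10.0
    r1: float = 3.3
    t10_s: float = 1.5
    s0_scale: float = 5000.0

    def __post_init__(self):
        for name in ("tr_s", "flip_deg", "r1", "t10_s", "s0_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.flip_deg > 90:
            raise ValueError("flip_deg must be in (0, 90]")

    @classmethod
    def from_sidecar(cls, sidecar: dict) -> "AcquisitionParams":
        return cls(
            tr_s=sidecar["tr_s"],
            flip_deg=sidecar["flip_deg"],
            r1=sidecar["r1"],
            t10_s=sidecar["t10_s"],
            s0_scale=sidecar.get("s0_scale", 5000.0),
        )


# ---------------------------------------------------------------------------
# Arterial input function models
# ---------------------------------------------------------------------------

def aif_model_coefficients(model: str, path=None) -> dict:
    """Named AIF coefficient sets from the packaged YAML config."""
    if path is None:
        ref = importlib.resources.files("dcepk.data") / "aif_models.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = yaml.safe_load(text)
    if model not in table:
        raise ValueError(f"unknown AIF model {model!r}; available: {sorted(table)}")
    return table[model]


def _aif_biexponential(t, c):
    """Weinmann-style biexponential decay (no first-pass peak), mM."""
    return c["dose"] * (c["a1"] * np.exp(-c["m1"] * t) + c["a2"] * np.exp(-c["m2"] * t))


def _aif_mixed_gaussian_sigmoid(t, c):
    """Two Gaussian bolus passes plus an exponential-decay sigmoid washout, mM."""
    out = np.zeros_like(t)
    for a, mu, sig in ((c["a1"], c["t1"], c["sigma1"]), (c["a2"], c["t2"], c["sigma2"])):
        out = out + a / (sig * np.sqrt(2 * np.pi)) * np.exp(-((t - mu) ** 2) / (2 * sig**2))
    out = out + c["alpha"] * np.exp(-c["beta"] * t) / (1 + np.exp(-c["s"] * (t - c["tau"])))
    return out

_AIF_MODELS = {
    "biexponential": _aif_biexponential,
    "mixed_gaussian_sigmoid": _aif_mixed_gaussian_sigmoid,
}

_AIF_ARITY = {
    "biexponential": {"dose", "a1", "a2", "m1", "m2"},
    "mixed_gaussian_sigmoid": {"a1", "a2", "t1", "t2", "sigma1", "sigma2", "alpha", "beta", "s", "tau"},
}


def population_aif(
    grid: TimeGrid,
    model: str = "mixed_gaussian_sigmoid",
    params: dict | None = None,
    onset: float | None = None,
) -> AIFCurve:
    """Population AIF sampled on ``grid``.

    ``onset`` (minutes) is the bolus-arrival time; it must not precede the last
    baseline frame, and the curve is exactly zero before it.  ``params``
    defaults to the packaged coefficient set for ``model``.
    """
    if model not in _AIF_MODELS:
        raise ValueError(f"unknown AIF model {model!r}")
    if params is None:
        params = aif_model_coefficients(model)
    missing = _AIF_ARITY[model] - set(params)
    extra = set(params) - _AIF_ARITY[model]
    if missing or extra:
        raise ValueError(f"bad coefficients for {model}: missing {sorted(missing)}, extra {sorted(extra)}")
    t_base = grid.times[grid.n_baseline - 1]
    if onset is None:
        onset = grid.times[grid.n_baseline] if grid.n_baseline < grid.n_frames else t_base
    if onset < t_base - 1e-12:
        raise ValueError("onset must not precede the last baseline frame")
    tp = grid.times - onset
    cp = np.where(tp >= 0, _AIF_MODELS[model](np.maximum(tp, 0.0), params), 0.0)
    cp = np.maximum(cp, 0.0)
    return AIFCurve(cp=cp, grid=grid, provenance="population-model")


# ---------------------------------------------------------------------------
# Extended Tofts forward model
# ---------------------------------------------------------------------------

def _exp_conv_weights(kep, dt):
    """Interval weights for the exponential-kernel trapezoid.

    For Cp linear on [0, dt] and kernel exp(-kep (dt - s)):
        contribution = A * cp_left + B * cp_right,  E = exp(-kep dt).
    Exact for piecewise-linear Cp; series used for kep*dt -> 0.
    """
    kep = np.asarray(kep, dtype=float)
    x = kep * dt
    small = x < 1e-4
    xs = np.where(small, 1.0, x)  # avoid 0/0 in the exact branch
    E = np.exp(-x)
    with np.errstate(divide="ignore", invalid="ignore"):
        one_minus_E_over_k = -np.expm1(-x) / np.where(small, 1.0, kep)
        B_exact = (1.0 - (-np.expm1(-x)) / xs) / np.where(small, 1.0, kep)
    A_exact = one_minus_E_over_k - B_exact
    # Taylor in x: A = dt(1/2 - x/3 + x^2/8), B = dt(1/2 - x/6 + x^2/24)
    A_ser = dt * (0.5 - x / 3.0 + x**2 / 8.0)
    B_ser = dt * (0.5 - x / 6.0 + x**2 / 24.0)
    A = np.where(small, A_ser, A_exact)
    B = np.where(small, B_ser, B_exact)
    return E, A, B


def exp_conv(cp: np.ndarray, dt: float, kep) -> np.ndarray:
    """Discrete convolution  I(t_i) = int_0^{t_i} Cp(tau) exp(-kep (t_i - tau)) dtau.

    Cp is interpreted as piecewise linear between frames; the exponential
    kernel is integrated exactly over each interval (recursion
    ``I_{i+1} = E I_i + A cp_i + B cp_{i+1}``), giving O(dt^2) accuracy for
    smooth Cp and machine accuracy for piecewise-linear Cp.

    Either ``kep`` is a scalar (``cp`` of any shape, time last) or ``cp`` is
    1-D (``kep`` of any shape); the output has shape ``kep.shape + (T,)`` in
    the latter case and ``cp.shape`` in the former.
    """
    cp = np.asarray(cp, dtype=float)
    kep_arr = np.asarray(kep, dtype=float)
    if kep_arr.ndim > 0 and cp.ndim > 1:
        raise ValueError("either kep must be scalar or cp must be 1-D")
    E, A, B = _exp_conv_weights(kep_arr, dt)
    if kep_arr.ndim == 0:
        # scalar kep: the recursion is an order-1 IIR filter along time
        zi_shape = cp.shape[:-1] + (1,)
        out, _ = lfilter(
            [float(B), float(A)], [1.0, -float(E)], cp, axis=-1,
            zi=np.broadcast_to(-float(B) * cp[..., :1], zi_shape).copy(),
        )
        return out
    n = cp.shape[-1]
    out = np.zeros(kep_arr.shape + cp.shape, dtype=float)
    acc = np.zeros(out.shape[:-1], dtype=float)
    for i in range(1, n):
        acc = E * acc + A * cp[..., i - 1] + B * cp[..., i]
        out[..., i] = acc
    return out


def tofts_forward(params: PKParams, aif: AIFCurve) -> np.ndarray:
    """Tissue concentration Ct(t) in mM under the extended Tofts model:

        Ct(t) = vp Cp(t) + ktrans int_0^t Cp(tau) exp(-kep (t - tau)) dtau
    """
    if params.ve == 0 and params.ktrans > 0:
        raise ValueError("ve = 0 with ktrans > 0: kep undefined")
    ct = params.vp * aif.cp
    if params.ktrans > 0:
        ct = ct + params.ktrans * exp_conv(aif.cp, aif.grid.dt, params.kep)
    return ct


def tofts_forward_maps(maps: PKMaps, aif: AIFCurve) -> np.ndarray:
    """Vectorised extended Tofts over voxel maps; returns shape ``maps.shape + (T,)``.

    Voxels with ktrans > 0 must have ve > 0 (enforced).
    """
    kt = np.asarray(maps.ktrans, dtype=float)
    ve = np.asarray(maps.ve, dtype=float)
    vp = np.asarray(maps.vp, dtype=float)
    if np.any((kt > 0) & (ve <= 0)):
        raise ValueError("ve = 0 with ktrans > 0 in maps")
    kep = np.where(kt > 0, kt / np.where(ve > 0, ve, 1.0), 0.0)
    conv = exp_conv(aif.cp, aif.grid.dt, kep)
    return vp[..., None] * aif.cp + kt[..., None] * conv


# ---------------------------------------------------------------------------
# SPGR signal model
# ---------------------------------------------------------------------------

def concentration_to_signal(ct: np.ndarray, acq: AcquisitionParams) -> np.ndarray:
    """Spoiled gradient-echo steady-state signal for concentration ``ct`` (mM).

    R1(t) = 1/T10 + r1 Ct(t)  (s^-1);  S = S0 sin(a) (1 - E1) / (1 - E1 cos(a)),
    E1 = exp(-TR R1).  Strictly increasing in Ct for flip angles in (0, 90].
    """
    ct = np.asarray(ct, dtype=float)
    if np.any(ct < -1e-9):
        raise ValueError("ct must be non-negative")
    a = np.deg2rad(acq.flip_deg)
    r1t = 1.0 / acq.t10_s + acq.r1 * np.maximum(ct, 0.0)
    e1 = np.exp(-acq.tr_s * r1t)
    return acq.s0_scale * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))


def signal_to_concentration(
    si: np.ndarray, acq: AcquisitionParams, n_baseline: int
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the SPGR equation; baseline frames calibrate the signal scale.

    Returns ``(ct, invalid)`` where ``invalid`` flags frames whose signal could
    not be inverted (implied E1 outside (0, 1)); such frames are clamped to
    Ct = 0.  On noiseless data this is the exact inverse of
    :func:`concentration_to_signal` and Ct is identically 0 over baseline.
    """
    si = np.asarray(si, dtype=float)
    if n_baseline < 1:
        raise ValueError("need at least one baseline frame")
    base = si[..., :n_baseline].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("baseline mean signal must be positive")
    a = np.deg2rad(acq.flip_deg)
    cos_a, sin_a = np.cos(a), np.sin(a)
    e10 = np.exp(-acq.tr_s / acq.t10_s)
    f0 = sin_a * (1 - e10) / (1 - e10 * cos_a)
    s0 = base / f0  # per-voxel effective equilibrium scale
    sp = si / (s0 * sin_a)
    denom = 1 - sp * cos_a
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (1 - sp) / denom
    invalid = ~np.isfinite(e1) | (e1 <= 0) | (e1 >= 1)
    e1 = np.clip(np.where(invalid, e10, e1), 1e-12, 1 - 1e-12)
    r1t = -np.log(e1) / acq.tr_s
    ct = (r1t - 1.0 / acq.t10_s) / acq.r1
    ct = np.where(invalid, 0.0, ct)
    return ct, invalid
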