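"""Choroid plexus perfusion from pCASL: surround subtraction, slice-delay
correction, and inversion of the third (post-bolus) component of the Buxton
kinetic model.

The forward model for the control-label difference signal at readout time
t = tau + PLD (labeling duration tau, post-label delay PLD) is

    dM = 2 alpha M0_blood f T1app * exp(-dt/T1b) * exp(-(t - tau - dt)/T1app)
         * (1 - exp(-tau/T1app))
    1/T1app = 1/T1_tissue + f/lambda

with f carried internally in mL g^-1 s^-1 (divide mL/100 g/min by 6000) so
that f/lambda shares units with 1/T1. Perfusion is recovered by bracketed
root finding on f in [0, 300] mL/100 g/min after a numeric monotonicity
check of the forward curve.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import AlignmentError, DomainError, StructureError
from .geometry import PhantomGeometry

#: mL/100 g/min -> mL g^-1 s^-1
F_UNIT = 6000.0

#: Search interval for inversion, mL/100 g/min.
F_MAX = 300.0

#: Quantification floor, mL/100 g/min: voxels below are treated as noise.
PERFUSION_THRESHOLD = 10.0


@dataclass(frozen=True)
class ASLParams:
    """Kinetic constants of the Buxton third-component model (times in ms)."""

    alpha: float = 0.8            # labeling efficiency (dual background suppression)
    lambda_bbp: float = 0.9       # blood-brain partition coefficient, mL blood/g
    tau: float = 1800.0           # labeling duration
    pld: float = 2000.0           # post-label delay
    delta_t: float = 1240.0       # choroid plexus bolus arrival time
    t1_blood: float = 1624.0      # blood T1 at 3 T
    t1_tissue: float = 2500.0     # choroid plexus T1
    slice_time: float = 0.0       # per-slice acquisition delay (2-D readout)
    slice_order: tuple | None = None  # acquisition position per slice (None: ascending)

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise DomainError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.lambda_bbp <= 0:
            raise DomainError("lambda_bbp must be positive")
        for name in ("tau", "pld", "delta_t", "t1_blood", "t1_tissue"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.slice_time < 0:
            raise DomainError("slice_time must be non-negative")


@dataclass
class ASLSeries:
    """Alternating control/label 4-D series plus the equilibrium M0 volume."""

    volumes: np.ndarray
    m0: np.ndarray
    geometry: PhantomGeometry
    order_flag: str = "control_first"

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.m0 = np.asarray(self.m0, dtype=float)
        if self.volumes.ndim != 4:
            raise StructureError("ASL volumes must be 4-D")
        if self.volumes.shape[3] % 2 != 0:
            raise StructureError("ASL series must contain an even number of volumes")
        if self.m0.shape != self.volumes.shape[:3]:
            raise AlignmentError("M0 volume geometry differs from the series")
        if self.order_flag not in ("control_first", "label_first"):
            raise ValueError(f"unknown order_flag {self.order_flag!r}")

    @property
    def n_pairs(self) -> int:
        return self.volumes.shape[3] // 2


@dataclass
class SurroundResult:
    """Time-averaged control-label difference with edge-handling bookkeeping."""

    delta_m: np.ndarray
    n_terms: int
    n_edges_dropped: int
    single_pair_fallback: bool = False


@dataclass
class PerfusionMap:
    """Voxelwise perfusion (mL/100 g/min) and the above-threshold valid mask."""

    f: np.ndarray
    valid_mask: np.ndarray
    threshold: float = PERFUSION_THRESHOLD
    n_clamped_negative: int = 0
    n_out_of_range: int = 0


def surround_subtract(series: ASLSeries, include_edges: bool = False) -> SurroundResult:
    """Surround-subtracted, time-averaged difference signal dM = control - label.

    Each interior volume is differenced against the mean of its two temporal
    neighbors (which belong to the other condition), so a signal drift common
    to both conditions and linear in time cancels exactly. Edge volumes have
    only one neighbor; by default they are dropped from the average (counted
    in ``n_edges_dropped``); ``include_edges=True`` switches to one-sided
    subtraction at the edges instead. A single control/label pair falls back
    to plain subtraction.
    """
    v = series.volumes
    n = v.shape[3]
    control_first = series.order_flag == "control_first"
    is_control = np.arange(n) % 2 == (0 if control_first else 1)
    if n == 2:
        dm = v[..., is_control.argmax()] - v[..., (~is_control).argmax()]
        return SurroundResult(delta_m=dm, n_terms=1, n_edges_dropped=0,
                              single_pair_fallback=True)
    diffs = []
    for i in range(1, n - 1):
        neigh = 0.5 * (v[..., i - 1] + v[..., i + 1])
        d = v[..., i] - neigh
        diffs.append(d if is_control[i] else -d)
    edges = 0
    if include_edges:
        d0 = v[..., 0] - v[..., 1]
        diffs.append(d0 if is_control[0] else -d0)
        dn = v[..., n - 1] - v[..., n - 2]
        diffs.append(dn if is_control[n - 1] else -dn)
    else:
        edges = 2
    dm = np.mean(diffs, axis=0)
    return SurroundResult(delta_m=dm, n_terms=len(diffs), n_edges_dropped=edges)


def effective_pld(params: ASLParams, slice_index: int) -> float:
    """Post-label delay seen by one slice of an ascending 2-D readout (ms).

    With ``params.slice_order`` set, that vector gives each slice's position
    in the acquisition order instead of the ascending default.
    """
    if slice_index < 0:
        raise ValueError("slice_index must be >= 0")
    pos = slice_index
    if params.slice_order is not None:
        pos = params.slice_order[slice_index]
    return params.pld + pos * params.slice_time


def buxton_forward(f, params: ASLParams, m0_blood, slice_index: int = 0):
    """Difference signal dM for perfusion f (mL/100 g/min); vectorized in f."""
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise DomainError("perfusion f must be non-negative")
    f_si = f_arr / F_UNIT                       # mL g^-1 s^-1
    tau = params.tau / 1e3
    pld = effective_pld(params, slice_index) / 1e3
    dt = params.delta_t / 1e3
    t1b = params.t1_blood / 1e3
    t1t = params.t1_tissue / 1e3
    t1app = 1.0 / (1.0 / t1t + f_si / params.lambda_bbp)
    t = tau + pld
    dm = (2.0 * params.alpha * np.asarray(m0_blood, dtype=float) * f_si * t1app
          * np.exp(-dt / t1b)
          * np.exp(-(t - tau - dt) / t1app)
          * (1.0 - np.exp(-tau / t1app)))
    return dm if dm.shape else float(dm)


def verify_forward_monotone(params: ASLParams, m0_blood: float = 1.0,
                            slice_index: int = 0, n: int = 3001) -> bool:
    """Numeric check that dM(f) is strictly increasing on [0, F_MAX]."""
    fs = np.linspace(0.0, F_MAX, n)
    dm = buxton_forward(fs, params, m0_blood, slice_index)
    return bool(np.all(np.diff(dm) > 0))


def invert_perfusion(delta_m: float, params: ASLParams, m0_blood: float,
                     slice_index: int = 0, check_monotone: bool = True) -> tuple[float, str]:
    """Solve buxton_forward(f) = delta_m for f on [0, 300] mL/100 g/min.

    Returns (f, flag); flag is '' for a clean bracketed solve,
    'clamped_negative' when delta_m < 0 (f set to 0), 'out_of_range' when
    delta_m exceeds the forward value at f = 300 (f reported at the bound).
    """
    if m0_blood <= 0:
        raise DomainError("m0_blood must be positive")
    if delta_m <= 0.0:
        return 0.0, ("" if delta_m == 0.0 else "clamped_negative")
    hi = buxton_forward(F_MAX, params, m0_blood, slice_index)
    if delta_m > hi:
        return F_MAX, "out_of_range"
    if check_monotone and not verify_forward_monotone(params, m0_blood, slice_index, n=301):
        raise DomainError("forward model is not monotone on [0, 300]; cannot invert")
    f = brentq(lambda x: buxton_forward(x, params, m0_blood, slice_index) - delta_m,
               0.0, F_MAX, xtol=1e-6)
    return float(f), ""


def quantify_perfusion_map(delta_m_volume: np.ndarray, m0_volume: np.ndarray,
                           params: ASLParams, brain_mask: np.ndarray,
                           threshold: float = PERFUSION_THRESHOLD,
                           blood_water_factor: float = 1.0) -> PerfusionMap:
    """Voxelwise inversion with slice-specific PLD and noise-floor threshold.

    M0_blood is taken voxelwise from the M0 volume scaled by
    ``blood_water_factor``. Voxels with f below ``threshold`` (default
    10 mL/100 g/min) are excluded from ``valid_mask``.
    """
    dm = np.asarray(delta_m_volume, dtype=float)
    m0 = np.asarray(m0_volume, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    if not (dm.shape == m0.shape == mask.shape):
        raise AlignmentError("delta-M, M0 and mask geometries differ")
    if np.any(m0[mask] <= 0):
        raise DomainError("M0 must be strictly positive inside the brain mask")
    f = np.full(dm.shape, np.nan)
    clamped = out_of_range = 0
    for z in range(dm.shape[2]):
        sl = mask[..., z]
        if not sl.any():
            continue
        if not verify_forward_monotone(params, 1.0, z, n=301):
            raise DomainError(f"forward model not monotone for slice {z}")
        for i, j in np.argwhere(sl):
            fv, flag = invert_perfusion(dm[i, j, z], params,
                                        m0[i, j, z] * blood_water_factor, z,
                                        check_monotone=False)
            f[i, j, z] = fv
            clamped += flag == "clamped_negative"
            out_of_range += flag == "out_of_range"
    valid = np.isfinite(f) & (f >= threshold)
    return PerfusionMap(f=f, valid_mask=valid, threshold=threshold,
                        n_clamped_negative=int(clamped), n_out_of_range=int(out_of_range))


def roi_perfusion(pmap: PerfusionMap, roi_mask: np.ndarray) -> tuple[float, float, int]:
    """Mean, SD and count of perfusion over valid voxels inside one ROI."""
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != pmap.f.shape:
        raise AlignmentError("ROI mask and perfusion map geometries differ")
    vals = pmap.f[roi & pmap.valid_mask]
    if vals.size == 0:
        return np.nan, np.nan, 0
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, int(vals.size)
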