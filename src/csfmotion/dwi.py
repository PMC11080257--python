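"""Noise-floor-corrected exponential decay fitting for low b-value DWI.

The signal model is

    S(b) = S0 * exp(-b * D) + Nfloor

where D (mm^2/s) is the apparent decay rate of the direction-averaged (trace)
signal and Nfloor absorbs the Rician magnitude-noise floor that flattens the
decay at high b. The "standard" model omits Nfloor. Fits are bounded
nonlinear least squares with an analytic initialization, a coarse
variable-projection scan over D to avoid bad local minima, and a final
nonnegative linear polish of (S0, Nfloor) at the fitted D.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .errors import AlignmentError, MaskError, StructureError, UnderDeterminedError
from .geometry import PhantomGeometry
from .masks import ROIMask, TISSUE_CLASSES

#: Protocol b-values (s/mm^2) of the multi-shell low-to-intermediate scheme.
DEFAULT_BVALUES = (0.0, 50.0, 100.0, 200.0, 300.0, 700.0, 1000.0)

#: Upper bound on the fitted decay rate, mm^2/s. Free CSF motion in the
#: cisterns gives apparent rates ~0.002-0.01 mm^2/s; 0.05 is far above any
#: physically plausible value at these b-values.
D_MAX = 0.05

#: b-value cutoff (s/mm^2) used for the log-linear slope initialization and
#: the default low-range ablation subset.
LOW_B_CUTOFF = 300.0

_RAYLEIGH_MEDIAN = np.sqrt(2.0 * np.log(2.0))  # median of |n| at unit sigma
_RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)          # mean of |n| at unit sigma


@dataclass
class DWISeries:
    """A 4-D magnitude series indexed by (b-value, direction).

    ``volumes`` has shape (x, y, z, n_volumes); ``bvalues`` and
    ``direction_index`` give the b-value (s/mm^2) and diffusion-direction
    index of each volume (direction index 0 for b=0 volumes).
    """

    volumes: np.ndarray
    bvalues: np.ndarray
    direction_index: np.ndarray
    geometry: PhantomGeometry

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes)
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        self.direction_index = np.asarray(self.direction_index, dtype=int)
        if self.volumes.ndim != 4:
            raise StructureError("DWISeries volumes must be 4-D (x, y, z, volume)")
        n = self.volumes.shape[3]
        if len(self.bvalues) != n or len(self.direction_index) != n:
            raise StructureError("one b-value and direction index required per volume")
        if np.unique(self.bvalues).size < 2:
            raise StructureError("at least two distinct b-values required")
        if np.any(self.bvalues < 0):
            raise StructureError("b-values must be non-negative")

    @property
    def unique_bvalues(self) -> np.ndarray:
        return np.unique(self.bvalues)


@dataclass
class DecayFit:
    """Per-curve estimates of (S0, D, Nfloor) with fit diagnostics."""

    S0: float
    D: float
    Nfloor: float | None
    model_kind: str
    rss: float
    r2: float
    aic: float
    rmse: float
    n_points: int
    converged: bool
    degenerate: bool = False

    def params(self) -> tuple:
        if self.model_kind == "noise_modeled":
            return (self.S0, self.D, self.Nfloor)
        return (self.S0, self.D)


@dataclass
class DecayMap:
    """Voxelwise decay-fit maps; NaN marks voxels outside the analysis mask."""

    D: np.ndarray
    S0: np.ndarray
    Nfloor: np.ndarray
    r2: np.ndarray
    converged: np.ndarray
    mask: np.ndarray
    geometry: PhantomGeometry
    model_kind: str = "noise_modeled"
    n_skipped: int = 0


@dataclass
class NoiseEstimate:
    """Rician channel noise sigma and the implied magnitude floor level."""

    sigma: float
    floor: float
    n_voxels: int


def trace_signal(series: DWISeries) -> DWISeries:
    """Collapse directions into one trace volume per b-value.

    For b > 0 the voxelwise geometric mean over directions is used (the
    trace-weighted convention, insensitive to anisotropy); b = 0 volumes are
    averaged arithmetically. Set ``trace_signal.geometric = False`` is not an
    option here: use :func:`trace_signal_arithmetic` for the arithmetic
    variant.
    """
    return _trace(series, geometric=True)


def trace_signal_arithmetic(series: DWISeries) -> DWISeries:
    """Arithmetic-mean variant of :func:`trace_signal`."""
    return _trace(series, geometric=False)


def _trace(series: DWISeries, geometric: bool) -> DWISeries:
    ubs = series.unique_bvalues
    n_dirs = None
    for b in ubs[ubs > 0]:
        cnt = int(np.sum(series.bvalues == b))
        if n_dirs is None:
            n_dirs = cnt
        elif cnt != n_dirs:
            raise StructureError(
                f"inconsistent direction counts across b-values ({cnt} vs {n_dirs})"
            )
    out = np.empty(series.volumes.shape[:3] + (len(ubs),), dtype=float)
    for i, b in enumerate(ubs):
        sel = series.volumes[..., series.bvalues == b].astype(float)
        if b == 0 or not geometric:
            out[..., i] = sel.mean(axis=-1)
        else:
            # geometric mean; exact zeros propagate to a zero trace value
            with np.errstate(divide="ignore"):
                out[..., i] = np.exp(np.mean(np.log(np.maximum(sel, 1e-300)), axis=-1))
            out[..., i][np.any(sel == 0, axis=-1)] = 0.0
    return DWISeries(out, ubs, np.zeros(len(ubs), dtype=int), series.geometry)


def estimate_noise_sigma(highb_volume: np.ndarray, fluid_mask: np.ndarray) -> NoiseEstimate:
    """Estimate the Rician channel sigma from a signal-suppressed region.

    In a region where the true signal is fully attenuated (here the high
    b = 1000 s/mm^2 image inside free fluid), the magnitude is Rayleigh
    distributed; its median is sigma*sqrt(2 ln 2), so the median magnitude
    divided by that constant is a robust, consistent estimate of sigma. The
    implied noise-floor level (the expected magnitude at zero signal,
    sigma*sqrt(pi/2)) is returned alongside and is used only to seed the
    Nfloor initialization -- Nfloor remains a free fitted parameter.
    """
    vol = np.asarray(highb_volume, dtype=float)
    m = np.asarray(fluid_mask, dtype=bool)
    if vol.shape != m.shape:
        raise AlignmentError("volume and mask shapes differ")
    vals = vol[m]
    if vals.size == 0:
        raise MaskError("noise-estimation mask is empty")
    sigma = float(np.median(vals) / _RAYLEIGH_MEDIAN)
    return NoiseEstimate(sigma=sigma, floor=sigma * _RAYLEIGH_MEAN, n_voxels=int(vals.size))


# ---------------------------------------------------------------------------
# curve fitting

def _profiled_linear(e: np.ndarray, s: np.ndarray, smax: float, with_floor: bool):
    """Best (S0, Nfloor) for a fixed decay factor e = exp(-b*D), bounded below at 0."""
    if with_floor:
        # exact 2-variable nonnegative least squares, solved in closed form
        n = len(s)
        ee = float(e @ e)
        e1 = float(e.sum())
        es = float(e @ s)
        s1 = float(s.sum())
        det = ee * n - e1 * e1
        s0 = nf = -1.0
        if det > 1e-30:
            s0 = (es * n - e1 * s1) / det
            nf = (ee * s1 - e1 * es) / det
        if s0 < 0.0 or nf < 0.0:
            a1 = max(es / ee, 0.0) if ee > 0 else 0.0   # Nfloor pinned at 0
            c1 = max(s1 / n, 0.0)                        # S0 pinned at 0
            r1 = s - a1 * e
            r2 = s - c1
            s0, nf = (a1, 0.0) if float(r1 @ r1) <= float(r2 @ r2) else (0.0, c1)
        s0 = min(s0, 2.0 * smax)
        nf = min(nf, smax)
        resid = s - (s0 * e + nf)
    else:
        ee = float(e @ e)
        s0 = max(float(e @ s) / ee, 0.0) if ee > 0 else 0.0
        s0 = min(s0, 2.0 * smax)
        nf = 0.0
        resid = s - s0 * e
    return s0, nf, float(resid @ resid)


#: Scan grid over D: fine at low D, where near-collinearity of the decay
#: column with the constant makes the profiled objective sharply featured,
#: coarser above (features there have width ~1/b_max).
_D_SCAN = np.unique(np.concatenate([
    np.linspace(0.0, 0.004, 41),          # 1e-4 spacing
    np.linspace(0.004, D_MAX, 47),        # ~1e-3 spacing
    np.array([2.5e-5, 5e-5]),
]))


def _grid_scan(b: np.ndarray, s: np.ndarray, smax: float, with_floor: bool) -> float:
    """Coarse variable-projection scan over D; returns the best grid D."""
    ds = _D_SCAN
    E = np.exp(-np.outer(ds, b))  # (n_grid, n_b)
    n = len(s)
    if with_floor:
        # unconstrained 2x2 normal-equation solve per grid point, then clamp
        ee = np.einsum("ij,ij->i", E, E)
        e1 = E.sum(axis=1)
        es = E @ s
        s1 = float(s.sum())
        det = ee * n - e1 * e1
        det = np.where(np.abs(det) < 1e-30, 1e-30, det)
        s0 = (es * n - e1 * s1) / det
        nf = (ee * s1 - e1 * es) / det
        # clamp negative solutions to the admissible edge cases
        neg_nf = nf < 0
        s0 = np.where(neg_nf, np.maximum(es / np.maximum(ee, 1e-30), 0.0), s0)
        nf = np.where(neg_nf, 0.0, nf)
        neg_s0 = s0 < 0
        s0 = np.where(neg_s0, 0.0, s0)
        nf = np.where(neg_s0, np.maximum(s1 / n, 0.0), nf)
        s0 = np.clip(s0, 0.0, 2.0 * smax)
        nf = np.clip(nf, 0.0, smax)
        resid = s[None, :] - (s0[:, None] * E + nf[:, None])
    else:
        ee = np.einsum("ij,ij->i", E, E)
        s0 = np.clip(E @ s / np.maximum(ee, 1e-30), 0.0, 2.0 * smax)
        resid = s[None, :] - s0[:, None] * E
    rss = np.einsum("ij,ij->i", resid, resid)
    return float(ds[int(np.argmin(rss))])


def _default_init(b: np.ndarray, s: np.ndarray, with_floor: bool):
    nf0 = max(float(np.min(s)), 0.0) if with_floor else 0.0
    s00 = max(float(np.max(s)) - nf0, 1e-6)
    low = (b <= LOW_B_CUTOFF) & (s - nf0 > 0)
    if np.sum(low) >= 2 and np.ptp(b[low]) > 0:
        slope = np.polyfit(b[low], np.log(s[low] - nf0), 1)[0]
        d0 = float(np.clip(-slope, 1e-6, D_MAX - 1e-6))
    else:
        d0 = 1e-3
    return s00, d0, nf0


def fit_decay_curve(signal: Sequence[float], bvalues: Sequence[float],
                    model_kind: str = "noise_modeled",
                    init: tuple | None = None,
                    bounds: dict | None = None) -> DecayFit:
    """Fit S(b) = S0 exp(-b D) [+ Nfloor] to one decay curve.

    Bounded trust-region least squares; default bounds D in [0, 0.05] mm^2/s,
    Nfloor in [0, max signal], S0 in (0, 2 max signal]. Non-convergence is
    reported through ``converged=False`` with the best iterate, never an
    exception. Diagnostics: rss, r2 = 1 - rss/TSS, the least-squares AIC
    n*ln(rss/n) + 2k, and rmse = sqrt(rss/n).
    """
    if model_kind not in ("standard", "noise_modeled"):
        raise ValueError(f"unknown model_kind {model_kind!r}")
    s = np.asarray(signal, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    if s.shape != b.shape or s.ndim != 1:
        raise ValueError("signal and bvalues must be matching 1-D arrays")
    if not np.all(np.isfinite(s)) or np.any(s < 0):
        raise ValueError("signal must be finite and non-negative")
    with_floor = model_kind == "noise_modeled"
    k = 3 if with_floor else 2
    n_distinct = np.unique(b).size
    if n_distinct < k:
        raise UnderDeterminedError(
            f"{model_kind} model needs >= {k} distinct b-values, got {n_distinct}"
        )
    n = len(s)
    smax = float(np.max(s))
    tss = float(np.sum((s - s.mean()) ** 2))

    # flat curve: rss is flat in D; tie-break at D = 0 with the constant in
    # S0 + Nfloor (Nfloor at its initialization, i.e. min(signal))
    if np.ptp(s) == 0.0:
        nf = float(s[0]) if with_floor else 0.0
        s0 = float(s[0]) - nf
        return DecayFit(S0=s0, D=0.0, Nfloor=nf if with_floor else None,
                        model_kind=model_kind, rss=0.0, r2=1.0,
                        aic=_aic(0.0, n, k), rmse=0.0, n_points=n,
                        converged=True, degenerate=True)

    s00, d0, nf0 = _default_init(b, s, with_floor)
    if init is not None:
        s00, d0 = float(init[0]), float(init[1])
        if with_floor and len(init) > 2:
            nf0 = float(init[2])
    d_grid = _grid_scan(b, s, smax, with_floor)

    bnd = {"D": (0.0, D_MAX), "S0": (1e-12, 2.0 * smax), "Nfloor": (0.0, smax)}
    if bounds:
        bnd.update(bounds)

    def pack(s0, d, nf):
        x = [s0, d] + ([nf] if with_floor else [])
        lo = [bnd["S0"][0], bnd["D"][0]] + ([bnd["Nfloor"][0]] if with_floor else [])
        hi = [bnd["S0"][1], bnd["D"][1]] + ([bnd["Nfloor"][1]] if with_floor else [])
        return (np.clip(x, np.asarray(lo) + 1e-15, np.asarray(hi) - 1e-15),
                np.asarray(lo), np.asarray(hi))

    def resid(x):
        m = x[0] * np.exp(-b * x[1])
        if with_floor:
            m = m + x[2]
        return m - s

    def jac(x):
        e = np.exp(-b * x[1])
        cols = [e, -x[0] * b * e]
        if with_floor:
            cols.append(np.ones_like(b))
        return np.column_stack(cols)

    # pick the better of the analytic init and the grid-scan start (compared
    # on the profiled objective, which is cheap), then one trust-region run
    def prof_at(d):
        return _profiled_linear(np.exp(-b * d), s, smax, with_floor)

    start = (s00, d0, nf0)
    if abs(d_grid - d0) > 1e-4:
        if prof_at(d_grid)[2] < prof_at(d0)[2]:
            s0g, nfg, _ = prof_at(d_grid)
            start = (max(s0g, 1e-9), d_grid, nfg)
    x0, lo, hi = pack(*start)
    try:
        res = least_squares(resid, x0, jac=jac, bounds=(lo, hi),
                            method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
                            max_nfev=100)
        rss, x, converged = float(res.cost) * 2.0, res.x, res.status > 0
    except Exception:
        rss, x, converged = float(np.sum(resid(x0) ** 2)), x0, False

    # polish: exact nonnegative linear solve of (S0, Nfloor) at the fitted D,
    # then a short bounded 1-D refinement of D with the linear part profiled
    d_hat = float(x[1])
    if prof_at(d_grid)[2] < prof_at(d_hat)[2]:
        d_hat = d_grid

    def prof_rss(d):
        return prof_at(d)[2]

    lo_d = max(bnd["D"][0], d_hat - 2e-3)
    hi_d = min(bnd["D"][1], d_hat + 2e-3)
    try:
        r = minimize_scalar(prof_rss, bounds=(lo_d, hi_d), method="bounded",
                            options={"xatol": 1e-13})
        if r.fun < rss + 1e-12:
            d_hat = float(r.x)
    except Exception:
        pass
    s0_hat, nf_hat, rss_hat = _profiled_linear(np.exp(-b * d_hat), s, smax, with_floor)
    if with_floor and 0.0 < nf_hat < 1e-7 * smax:
        # numerically indistinguishable from the Nfloor = 0 boundary
        e = np.exp(-b * d_hat)
        s0_pin = min(max(float(e @ s) / float(e @ e), 0.0), 2.0 * smax)
        r_pin = s - s0_pin * e
        rss_pin = float(r_pin @ r_pin)
        if rss_pin <= rss_hat + 1e-10 * max(rss_hat, 1.0):
            s0_hat, nf_hat, rss_hat = s0_pin, 0.0, rss_pin
    if rss_hat <= rss * (1.0 + 1e-9) + 1e-12:
        rss = rss_hat
    else:  # keep the trust-region solution if the polish did not help
        s0_hat, d_hat = float(x[0]), float(x[1])
        nf_hat = float(x[2]) if with_floor else 0.0

    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss <= 1e-12 else np.nan)
    return DecayFit(S0=s0_hat, D=d_hat, Nfloor=nf_hat if with_floor else None,
                    model_kind=model_kind, rss=rss, r2=r2, aic=_aic(rss, n, k),
                    rmse=float(np.sqrt(rss / n)), n_points=n, converged=bool(converged))


def _aic(rss: float, n: int, k: int) -> float:
    return n * float(np.log(max(rss, 1e-300) / n)) + 2 * k


def fit_both_models(signal: Sequence[float], bvalues: Sequence[float]) -> dict:
    """Fit the standard and noise-floor models to the same curve.

    The models are nested (Nfloor = 0 recovers the standard model), so the
    noise-modeled residual can never exceed the standard one at the true
    optimum; if the independent searches ever disagree with that ordering,
    the noise-floor fit is re-profiled at the standard model's decay rate,
    which restores it by construction. Returns
    ``{"standard": DecayFit, "noise_modeled": DecayFit}``.
    """
    s = np.asarray(signal, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    std = fit_decay_curve(s, b, model_kind="standard")
    nm = fit_decay_curve(s, b, model_kind="noise_modeled")
    if nm.rss > std.rss:
        smax = float(np.max(s))
        s0, nf, rss = _profiled_linear(np.exp(-b * std.D), s, smax, with_floor=True)
        n = len(s)
        tss = float(np.sum((s - s.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss <= 1e-12 else np.nan)
        nm = DecayFit(S0=s0, D=std.D, Nfloor=nf, model_kind="noise_modeled",
                      rss=rss, r2=r2, aic=_aic(rss, n, 3),
                      rmse=float(np.sqrt(rss / n)), n_points=n,
                      converged=nm.converged)
    return {"standard": std, "noise_modeled": nm}


def fit_decay_map(series: DWISeries, mask: np.ndarray,
                  model_kind: str = "noise_modeled") -> DecayMap:
    """Apply :func:`fit_decay_curve` voxelwise inside ``mask``.

    Non-finite or all-zero curves are skipped (counted in ``n_skipped``),
    not errored. Deterministic given inputs.
    """
    m = np.asarray(mask, dtype=bool)
    if m.shape != series.volumes.shape[:3]:
        raise AlignmentError("mask and series geometry differ")
    shp = m.shape
    nanvol = lambda: np.full(shp, np.nan)
    out = DecayMap(D=nanvol(), S0=nanvol(), Nfloor=nanvol(), r2=nanvol(),
                   converged=np.zeros(shp, dtype=bool), mask=m,
                   geometry=series.geometry, model_kind=model_kind)
    b = series.bvalues
    idx = np.argwhere(m)
    skipped = 0
    for i, j, z in idx:
        curve = series.volumes[i, j, z, :].astype(float)
        if not np.all(np.isfinite(curve)) or np.all(curve == 0):
            skipped += 1
            continue
        fit = fit_decay_curve(curve, b, model_kind=model_kind)
        out.D[i, j, z] = fit.D
        out.S0[i, j, z] = fit.S0
        out.Nfloor[i, j, z] = fit.Nfloor if fit.Nfloor is not None else 0.0
        out.r2[i, j, z] = fit.r2
        out.converged[i, j, z] = fit.converged and not fit.degenerate
    out.n_skipped = skipped
    return out


def ablation_fit(signal: Sequence[float], bvalues: Sequence[float],
                 subsets: list[tuple[str, Sequence[float]]] | None = None,
                 model_kinds: str | list[str] = "noise_modeled"):
    """Refit one curve over several b-value subsets.

    Default subsets: all b-values, and the low range b <= 300 s/mm^2 (the
    range adequate for cisternal fluid). ``rmse`` normalizes the residual per
    point so fit quality is comparable across subsets of different size.
    Returns a pandas DataFrame with one row per subset.
    """
    import pandas as pd

    s = np.asarray(signal, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    if subsets is None:
        subsets = [("all", tuple(np.unique(b))),
                   ("low_b", tuple(np.unique(b[b <= LOW_B_CUTOFF])))]
    if isinstance(model_kinds, str):
        model_kinds = [model_kinds] * len(subsets)
    if len(model_kinds) != len(subsets):
        raise ValueError("one model_kind required per subset")
    rows = []
    for (name, bs), kind in zip(subsets, model_kinds):
        sel = np.isin(b, np.asarray(bs, dtype=float))
        if np.unique(b[sel]).size < 2:
            raise UnderDeterminedError(f"subset {name!r} has fewer than 2 b-values")
        fit = fit_decay_curve(s[sel], b[sel], model_kind=kind)
        rows.append({"subset": name, "model_kind": kind, "S0": fit.S0, "D": fit.D,
                     "Nfloor": fit.Nfloor, "rss": fit.rss, "rmse": fit.rmse,
                     "r2": fit.r2, "aic": fit.aic, "n_points": fit.n_points,
                     "converged": fit.converged})
    return pd.DataFrame(rows)


def roi_summary(decay_map: DecayMap, masks: ROIMask):
    """Per-tissue-class mean, SD and voxel count of the fitted D map.

    Only converged voxels contribute; excluded voxels are counted. Classes
    absent from the analysis mask get count 0 and NaN summaries.
    """
    import pandas as pd

    if tuple(masks.labels.shape) != tuple(decay_map.D.shape):
        raise AlignmentError("decay map and ROI mask geometry differ")
    rows = []
    for cls in TISSUE_CLASSES:
        region = masks.region(cls) & decay_map.mask
        good = region & decay_map.converged & np.isfinite(decay_map.D)
        vals = decay_map.D[good]
        rows.append({
            "roi": cls,
            "mean_D": float(vals.mean()) if vals.size else np.nan,
            "sd_D": float(vals.std(ddof=1)) if vals.size > 1 else (0.0 if vals.size == 1 else np.nan),
            "n_voxels": int(vals.size),
            "n_excluded": int(region.sum() - vals.size),
        })
    return pd.DataFrame(rows)
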