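"""Seeded synthetic phantoms and cohorts.

Generates NIfTI-ready DWI/pCASL/mask volumes and participant tables carrying
the statistical structure the downstream analysis assumes: per-tissue
exponential signal decay with Rician magnitude noise, Buxton-model ASL
difference signal, two cohorts with group-specific decay-rate distributions,
and a tunable rank coupling between choroid plexus perfusion and suprasellar
decay rate.

Tissue decay-rate means and between-subject SDs default to the normative
group values of the study cohorts (control group as baseline; the PD group
is expressed as additive shifts). Phantom anatomy is deliberately schematic:
disjoint parametric solids, since registration and segmentation are out of
scope and only the signal statistics matter downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .asl import ASLParams, ASLSeries, buxton_forward
from .dwi import DEFAULT_BVALUES, DWISeries
from .errors import DomainError, LabelingError, SizingError
from .geometry import PhantomGeometry
from .masks import (BACKGROUND, CHOROID_PLEXUS, GRAY_MATTER, LABELS, OPTIC_NERVE,
                    ROIMask, SUPRASELLAR_CSF, TISSUE_CLASSES, VENTRICULAR_CSF,
                    WHITE_MATTER)


@dataclass(frozen=True)
class TissueParams:
    """Signal model of one tissue class.

    ``D_sd_between_subject`` is the between-subject SD of the class decay
    rate; ``d_sd_voxel`` is the within-ROI voxelwise dispersion (no normative
    value exists for it, default 0: a uniform ROI).
    """

    label: str
    S0_mean: float
    D_mean: float               # mm^2/s
    D_sd_between_subject: float = 0.0
    noise_sigma: float = 15.0   # Rician channel noise, signal units
    d_sd_voxel: float = 0.0

    def __post_init__(self):
        if self.label not in LABELS:
            raise LabelingError(f"unknown tissue class {self.label!r}")
        if self.D_mean < 0:
            raise ValueError("D_mean must be >= 0")
        if self.S0_mean <= 0:
            raise ValueError("S0_mean must be > 0")
        if self.noise_sigma < 0 or self.D_sd_between_subject < 0 or self.d_sd_voxel < 0:
            raise ValueError("dispersions must be >= 0")


def default_tissue_params(noise_sigma: float = 15.0,
                          d_sd_voxel: float = 0.0) -> dict[str, TissueParams]:
    """Control-group tissue parameters (decay rates in mm^2/s).

    S0 values reflect a T2-weighted EPI contrast (CSF bright, parenchyma
    intermediate). The choroid plexus decay rate is not part of the normative
    table; a value intermediate between parenchyma and ventricular CSF is
    used for this partly fluid, highly vascular structure.
    """
    mk = lambda lbl, s0, d, sd: TissueParams(lbl, s0, d, sd,
                                             noise_sigma=noise_sigma,
                                             d_sd_voxel=d_sd_voxel)
    return {
        BACKGROUND: TissueParams(BACKGROUND, 1e-3, 0.003, 0.0,
                                 noise_sigma=noise_sigma, d_sd_voxel=0.0),
        GRAY_MATTER: mk(GRAY_MATTER, 500.0, 0.00209, 0.00009),
        WHITE_MATTER: mk(WHITE_MATTER, 450.0, 0.00210, 0.00010),
        VENTRICULAR_CSF: mk(VENTRICULAR_CSF, 1000.0, 0.00253, 0.00019),
        SUPRASELLAR_CSF: mk(SUPRASELLAR_CSF, 1000.0, 0.00673, 0.00213),
        OPTIC_NERVE: mk(OPTIC_NERVE, 600.0, 0.00453, 0.00249),
        CHOROID_PLEXUS: mk(CHOROID_PLEXUS, 700.0, 0.0030, 0.0004),
    }


#: Additive decay-rate shifts (mm^2/s) applied to the PD group, equal to the
#: normative PD-minus-control group differences per class.
PD_GROUP_EFFECTS: dict[str, float] = {
    GRAY_MATTER: 0.00002,
    WHITE_MATTER: 0.00002,
    VENTRICULAR_CSF: 0.00014,
    SUPRASELLAR_CSF: -0.00156,
    OPTIC_NERVE: -0.00090,
    CHOROID_PLEXUS: 0.0,
}

#: PD-group between-subject SDs where they differ from control.
PD_GROUP_SDS: dict[str, float] = {
    GRAY_MATTER: 0.00016,
    WHITE_MATTER: 0.00015,
    VENTRICULAR_CSF: 0.00028,
    SUPRASELLAR_CSF: 0.00110,
    OPTIC_NERVE: 0.00108,
}


@dataclass
class CohortConfig:
    """Cohort simulation settings (defaults are the study conditions)."""

    n_control: int = 32
    n_pd: int = 27
    group_effects: dict[str, float] = field(default_factory=lambda: dict(PD_GROUP_EFFECTS))
    pd_group_sds: dict[str, float] = field(default_factory=lambda: dict(PD_GROUP_SDS))
    perfusion_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (32.7, 6.1), "pd": (32.8, 8.2)})
    coupling_rho: float = -0.312   # target pooled Spearman(perfusion, suprasellar D)
    seed: int = 0
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (67.6, 9.0), "pd": (66.0, 6.8)})
    moca_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (26.5, 2.8), "pd": (24.3, 3.9)})
    updrs_mean_sd: tuple[float, float] = (32.4, 12.5)
    noise_sigma: float = 15.0
    d_sd_voxel: float = 0.0
    bvalues: tuple = DEFAULT_BVALUES
    n_directions: int = 6
    asl_params: ASLParams = field(default_factory=ASLParams)
    n_asl_pairs: int = 8
    asl_noise_sigma: float = 0.0005
    m0_blood: float = 1.0

    def validate(self):
        if self.n_control < 0 or self.n_pd < 0:
            raise DomainError("cohort sizes must be non-negative")
        if abs(self.coupling_rho) > 1:
            raise DomainError(f"|coupling_rho| must be <= 1, got {self.coupling_rho}")


# ---------------------------------------------------------------------------
# phantom masks

# fractional (center, half-extent) placements; ellipsoids except the optic
# nerve, which is an axis-aligned box (a schematic nerve segment)
_PLACEMENTS = {
    GRAY_MATTER: ("ellipsoid", (0.22, 0.30, 0.55), (0.07, 0.08, 0.12)),
    WHITE_MATTER: ("ellipsoid", (0.78, 0.30, 0.55), (0.07, 0.08, 0.12)),
    VENTRICULAR_CSF: ("ellipsoid", (0.38, 0.72, 0.60), (0.07, 0.08, 0.12)),
    CHOROID_PLEXUS: ("ellipsoid", (0.66, 0.72, 0.60), (0.05, 0.05, 0.09)),
    SUPRASELLAR_CSF: ("ellipsoid", (0.50, 0.46, 0.22), (0.08, 0.07, 0.12)),
    OPTIC_NERVE: ("box", (0.50, 0.18, 0.22), (0.08, 0.025, 0.05)),
}

_MIN_REGION_VOXELS = 8


def make_phantom_masks(geometry: PhantomGeometry, seed: int) -> ROIMask:
    """Place one disjoint parametric solid per tissue class.

    Placement is deterministic given the seed (the seed jitters each region
    center by at most one voxel). Raises :class:`SizingError` when the matrix
    is too small to hold every region disjointly with at least
    ``_MIN_REGION_VOXELS`` voxels each.
    """
    rng = np.random.default_rng(seed)
    shape = np.asarray(geometry.shape, dtype=float)
    labels = np.zeros(geometry.shape, dtype=np.int16)
    grid = np.indices(geometry.shape).astype(float)
    for cls in TISSUE_CLASSES:
        kind, center, half = _PLACEMENTS[cls]
        jitter = rng.integers(-1, 2, size=3)
        c = np.asarray(center) * (shape - 1) + jitter
        h = np.maximum(np.asarray(half) * shape, 1e-9)
        d = [(grid[a] - c[a]) / h[a] for a in range(3)]
        if kind == "ellipsoid":
            inside = d[0] ** 2 + d[1] ** 2 + d[2] ** 2 <= 1.0
        else:
            inside = (np.abs(d[0]) <= 1.0) & (np.abs(d[1]) <= 1.0) & (np.abs(d[2]) <= 1.0)
        if int(inside.sum()) < _MIN_REGION_VOXELS:
            raise SizingError(
                f"matrix {geometry.shape} too small to place region {cls!r}")
        if np.any(labels[inside] != 0):
            raise SizingError(
                f"matrix {geometry.shape} too small to keep region {cls!r} disjoint")
        labels[inside] = LABELS[cls]
    return ROIMask(labels=labels, geometry=geometry)


# ---------------------------------------------------------------------------
# signal simulators

def _class_maps(masks: ROIMask, params: dict[str, TissueParams], rng=None):
    """Per-voxel S0 and D maps from class parameters (voxelwise D dispersion optional)."""
    present = set(np.unique(masks.labels))
    covered = {LABELS[name] for name in params}
    missing = present - covered
    if missing:
        raise LabelingError(f"mask labels {sorted(missing)} have no tissue parameters")
    s0 = np.zeros(masks.labels.shape)
    d = np.zeros(masks.labels.shape)
    for name, p in params.items():
        sel = masks.labels == LABELS[name]
        if not sel.any():
            continue
        s0[sel] = p.S0_mean
        dv = np.full(int(sel.sum()), p.D_mean)
        if p.d_sd_voxel > 0 and rng is not None:
            dv = np.maximum(dv + rng.normal(0.0, p.d_sd_voxel, dv.size), 1e-6)
        d[sel] = dv
    return s0, d


def _rician(clean: np.ndarray, sigma: np.ndarray, rng) -> np.ndarray:
    """Magnitude of (clean + n1) + i*n2 with independent Gaussian channels."""
    n1 = rng.normal(0.0, 1.0, clean.shape) * sigma
    n2 = rng.normal(0.0, 1.0, clean.shape) * sigma
    return np.hypot(clean + n1, n2)


def simulate_dwi(masks: ROIMask, params: dict[str, TissueParams],
                 bvalues=DEFAULT_BVALUES, n_directions: int = 6,
                 seed: int = 0) -> DWISeries:
    """Forward-simulate a multi-shell DWI series with Rician magnitude noise.

    The noise-free voxel signal is S0*exp(-b*D) for the voxel's class (the
    phantom is isotropic, so all directions share the same expectation); each
    b > 0 shell is acquired along ``n_directions`` directions and b = 0 once.
    Noise is drawn independently per voxel, b-value and direction.
    """
    b = np.asarray(bvalues, dtype=float)
    if np.any(b < 0) or np.unique(b).size < 2:
        raise ValueError("need >= 2 distinct non-negative b-values")
    rng = np.random.default_rng(seed)
    s0, d = _class_maps(masks, params, rng)
    sigma = np.zeros(masks.labels.shape)
    for name, p in params.items():
        sigma[masks.labels == LABELS[name]] = p.noise_sigma
    vols, bs, dirs = [], [], []
    for bv in b:
        clean = s0 * np.exp(-bv * d)
        reps = 1 if bv == 0 else n_directions
        for k in range(reps):
            vols.append(_rician(clean, sigma, rng))
            bs.append(bv)
            dirs.append(k)
    return DWISeries(np.stack(vols, axis=-1), np.asarray(bs),
                     np.asarray(dirs, dtype=int), masks.geometry)


def simulate_asl(masks: ROIMask, f_map: np.ndarray, asl_params: ASLParams,
                 m0_blood: float = 1.0, n_pairs: int = 8,
                 noise_sigma: float = 0.0, seed: int = 0,
                 baseline_fraction: float = 0.05) -> ASLSeries:
    """Forward-simulate an alternating control/label pCASL series plus M0.

    The expected control-label difference at each voxel equals the Buxton
    forward model at that voxel's perfusion (with slice-specific PLD);
    control volumes carry a background-suppressed static baseline
    (``baseline_fraction`` of M0) and labels subtract the difference signal.
    Additive Gaussian noise per volume.
    """
    f = np.asarray(f_map, dtype=float)
    if f.shape != tuple(masks.geometry.shape):
        raise ValueError("f_map shape must match the mask geometry")
    if np.any(f < 0):
        raise DomainError("perfusion map must be non-negative")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    brain = masks.labels > 0
    m0 = np.where(brain, m0_blood, 1e-3 * m0_blood)
    dm = np.zeros_like(f)
    for z in range(f.shape[2]):
        dm[..., z] = buxton_forward(f[..., z], asl_params, m0_blood, slice_index=z)
    base = baseline_fraction * m0
    vols = []
    for _ in range(n_pairs):
        for signal in (base, base - dm):   # control, label
            noise = rng.normal(0.0, noise_sigma, f.shape) if noise_sigma > 0 else 0.0
            vols.append(signal + noise)
    return ASLSeries(np.stack(vols, axis=-1), m0=m0, geometry=masks.geometry,
                     order_flag="control_first")


# ---------------------------------------------------------------------------
# cohorts

def simulate_cohort_table(config: CohortConfig) -> pd.DataFrame:
    """Draw the per-subject ground truth table (no images).

    Suprasellar decay rates come from each group's normal law (truncated at
    zero); perfusion is rank-coupled to the pooled suprasellar D sample
    through a Gaussian copula targeting a pooled Spearman correlation of
    ``coupling_rho``, then mapped through the subject's group-specific
    perfusion marginal.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_control + config.n_pd
    groups = ["control"] * config.n_control + ["pd"] * config.n_pd

    tissues = default_tissue_params()
    true_d = {}
    for cls in TISSUE_CLASSES:
        if cls == BACKGROUND:
            continue
        base = tissues[cls]
        mean_c, sd_c = base.D_mean, base.D_sd_between_subject
        mean_p = mean_c + config.group_effects.get(cls, 0.0)
        sd_p = config.pd_group_sds.get(cls, sd_c)
        draws = np.where(
            np.arange(n) < config.n_control,
            rng.normal(mean_c, sd_c, n),
            rng.normal(mean_p, sd_p, n),
        )
        true_d[cls] = np.maximum(draws, 1e-6)

    # Gaussian copula on pooled normal scores of the realized suprasellar D
    d_ss = true_d[SUPRASELLAR_CSF]
    rho_lat = 2.0 * np.sin(np.pi * config.coupling_rho / 6.0)
    scores = sps.norm.ppf((sps.rankdata(d_ss) - 0.5) / n)
    z_perf = rho_lat * scores + np.sqrt(1.0 - rho_lat ** 2) * rng.standard_normal(n)
    perf = np.empty(n)
    for g in ("control", "pd"):
        sel = np.asarray(groups) == g
        mu, sd = config.perfusion_mean_sd[g]
        perf[sel] = mu + sd * z_perf[sel]
    perf = np.maximum(perf, 1e-3)

    age = np.empty(n)
    moca = np.empty(n)
    for g in ("control", "pd"):
        sel = np.asarray(groups) == g
        age[sel] = rng.normal(*config.age_mean_sd[g], size=int(sel.sum()))
        moca[sel] = rng.normal(*config.moca_mean_sd[g], size=int(sel.sum()))
    sex = rng.choice(["F", "M"], size=n)
    updrs = np.full(n, np.nan)
    updrs[config.n_control:] = np.maximum(
        rng.normal(*config.updrs_mean_sd, size=config.n_pd), 0.0)

    table = pd.DataFrame({
        "subject_id": [f"sub-{i:03d}" for i in range(n)],
        "group": groups,
        "age": np.round(np.maximum(age, 30.0), 1),
        "sex": sex,
        "true_D_suprasellar": d_ss,
        "true_perfusion": perf,
        "updrs": np.round(updrs, 0),
        "moca": np.round(np.clip(moca, 0, 30), 0),
    })
    for cls in (VENTRICULAR_CSF, GRAY_MATTER, WHITE_MATTER, OPTIC_NERVE, CHOROID_PLEXUS):
        table[f"true_D_{cls}"] = true_d[cls]
    return table


@dataclass
class SubjectData:
    """One synthetic participant's imaging bundle."""

    subject_id: str
    masks: ROIMask
    dwi: DWISeries
    asl: ASLSeries


def iter_cohort_subjects(config: CohortConfig, geometry: PhantomGeometry,
                         table: pd.DataFrame | None = None):
    """Yield per-subject imaging one participant at a time (memory-light)."""
    config.validate()
    if table is None:
        table = simulate_cohort_table(config)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(table))
    tissues = default_tissue_params(noise_sigma=config.noise_sigma,
                                    d_sd_voxel=config.d_sd_voxel)
    for (idx, row), child in zip(table.iterrows(), children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        masks = make_phantom_masks(geometry, seed=sub_seed)
        params = dict(tissues)
        params[SUPRASELLAR_CSF] = replace(params[SUPRASELLAR_CSF],
                                          D_mean=float(row["true_D_suprasellar"]))
        for cls in (VENTRICULAR_CSF, GRAY_MATTER, WHITE_MATTER, OPTIC_NERVE,
                    CHOROID_PLEXUS):
            params[cls] = replace(params[cls], D_mean=float(row[f"true_D_{cls}"]))
        dwi = simulate_dwi(masks, params, bvalues=config.bvalues,
                           n_directions=config.n_directions, seed=sub_seed + 1)
        f_map = np.where(masks.region(CHOROID_PLEXUS), float(row["true_perfusion"]), 0.0)
        asl = simulate_asl(masks, f_map, config.asl_params,
                           m0_blood=config.m0_blood, n_pairs=config.n_asl_pairs,
                           noise_sigma=config.asl_noise_sigma, seed=sub_seed + 2)
        yield SubjectData(subject_id=row["subject_id"], masks=masks, dwi=dwi, asl=asl)


def simulate_cohort(config: CohortConfig, geometry: PhantomGeometry):
    """Materialized variant of :func:`iter_cohort_subjects`.

    Returns (subjects, table). Note the memory cost: prefer the iterator for
    full-size cohorts at full matrix size.
    """
    table = simulate_cohort_table(config)
    subjects = list(iter_cohort_subjects(config, geometry, table=table))
    return subjects, table
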