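"""Cohort statistics: nonparametric contrasts, perfusion-decay correlation,
covariate regressions, and a voxelwise group-difference map with cluster
extraction.

Small samples get exact enumeration (rank-sum for total n <= 12, Spearman
for n <= 8); larger samples use the tie-corrected normal / t approximations.
Midranks are used everywhere. The voxelwise map applies a per-voxel rank-sum
test inside a region of interest, Benjamini-Hochberg control at q (default
0.10), and 26-connectivity clustering of surviving voxels; this transparent
procedure stands in for atlas-based cluster inference and is labeled as such
in the output metadata.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import CSFMotionError
from .masks import SUPRASELLAR_CSF

EXACT_RANKSUM_MAX_N = 12   # total sample size for exhaustive enumeration
EXACT_SPEARMAN_MAX_N = 8   # paired sample size for full permutation


@dataclass
class TestResult:
    """Outcome of one hypothesis test (two-sided unless stated otherwise)."""

    statistic: float
    p_value: float
    method: str
    n_per_group: tuple
    effect_summary: dict = field(default_factory=dict)
    degenerate: bool = False


@dataclass
class ClusterMap:
    """Connected clusters of group-different voxels after FDR control."""

    label_volume: np.ndarray
    clusters: list[dict]
    alpha_fdr: float
    min_extent: int
    method: str = ("voxelwise Wilcoxon rank-sum, Benjamini-Hochberg FDR, "
                   "26-connectivity clustering")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


# ---------------------------------------------------------------------------
# elementary tests

def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def rank_sum_test(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration of the permutation null for total n <= 12 (two-sided
    p = P(|W - E[W]| >= |observed - E[W]|) over all assignments); otherwise
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample must contain at least one value")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    eff = {"mean_x": float(x.mean()), "sd_x": float(x.std(ddof=1)) if nx > 1 else 0.0,
           "mean_y": float(y.mean()), "sd_y": float(y.std(ddof=1)) if ny > 1 else 0.0}
    if np.ptp(pooled) == 0.0:
        return TestResult(statistic=float(nx * (n + 1) / 2.0), p_value=1.0,
                          method="rank-sum (degenerate)", n_per_group=(nx, ny),
                          effect_summary=eff, degenerate=True)
    ranks = _midranks(pooled)
    w_obs = float(ranks[:nx].sum())
    e_w = nx * (n + 1) / 2.0
    if n <= EXACT_RANKSUM_MAX_N:
        dev = abs(w_obs - e_w)
        hits = total = 0
        for idx in itertools.combinations(range(n), nx):
            w = ranks[list(idx)].sum()
            hits += abs(w - e_w) >= dev - 1e-12
            total += 1
        p = hits / total
        method = "rank-sum (exact enumeration)"
    else:
        # tie-corrected normal approximation on W
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts ** 3 - counts))
        var_w = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var_w <= 0:
            return TestResult(statistic=w_obs, p_value=1.0,
                              method="rank-sum (degenerate)", n_per_group=(nx, ny),
                              effect_summary=eff, degenerate=True)
        z = (w_obs - e_w) / np.sqrt(var_w)
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "rank-sum (normal approximation, tie-corrected)"
    return TestResult(statistic=w_obs, p_value=min(p, 1.0), method=method,
                      n_per_group=(nx, ny), effect_summary=eff)


def chi_squared_test(table) -> TestResult:
    """Pearson chi-squared on a 2 x k contingency table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    row_m, col_m = t.sum(axis=1), t.sum(axis=0)
    if np.any(row_m == 0) or np.any(col_m == 0):
        return TestResult(statistic=0.0, p_value=1.0,
                          method="chi-squared (degenerate margin)",
                          n_per_group=tuple(int(v) for v in row_m), degenerate=True)
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(statistic=float(stat), p_value=float(p),
                      method=f"chi-squared (df={dof})",
                      n_per_group=tuple(int(v) for v in row_m))


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation with midrank ties.

    Exact permutation p for n <= 8 (two-sided on |r|), t-approximation
    otherwise. Zero variance in either variable is flagged undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("paired samples with n >= 3 required")
    n = x.size
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return TestResult(statistic=np.nan, p_value=np.nan,
                          method="spearman (undefined: zero variance)",
                          n_per_group=(n,), degenerate=True)
    rx, ry = _midranks(x), _midranks(y)
    r_obs = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c @ rx_c) * (ry_c @ ry_c))
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            r = float(rx_c @ ry_c[list(perm)]) / denom
            hits += abs(r) >= abs(r_obs) - 1e-12
            total += 1
        p = hits / total
        method = "spearman (exact permutation)"
    else:
        t = r_obs * np.sqrt((n - 2) / max(1.0 - r_obs ** 2, 1e-300))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        method = "spearman (t approximation)"
    return TestResult(statistic=r_obs, p_value=min(p, 1.0), method=method,
                      n_per_group=(n,))


# ---------------------------------------------------------------------------
# regressions

def covariate_regression(dependent, covariates: pd.DataFrame,
                         combined: bool = False) -> pd.DataFrame:
    """OLS of the decay rate on cohort/age/sex, one covariate at a time.

    ``covariates`` holds any subset of columns {group, age, sex}; categorical
    columns are coded as a two-level indicator and the reported row is the
    contrast for that indicator. ``combined=True`` adds a joint model with
    all covariates. Returns one row per (model, covariate) with the
    coefficient and its two-sided p-value.
    """
    import statsmodels.api as sm

    y = np.asarray(dependent, dtype=float)
    cov = covariates.copy()
    if len(cov) != y.size:
        raise ValueError("dependent and covariates must have equal length")

    def design(cols):
        X = pd.DataFrame(index=cov.index)
        names = []
        for c in cols:
            col = cov[c]
            if col.dtype == object or str(col.dtype) == "category":
                levels = sorted(col.unique())
                if len(levels) != 2:
                    raise ValueError(f"covariate {c!r} must have two levels")
                X[f"{c}[{levels[1]}]"] = (col == levels[1]).astype(float)
                names.append(f"{c}[{levels[1]}]")
            else:
                X[c] = col.astype(float)
                names.append(c)
        return sm.add_constant(X), names

    def fit_one(cols, model_name):
        X, names = design(cols)
        if y.size <= X.shape[1] + 1:
            raise ValueError("too few observations for the number of coefficients")
        if np.linalg.matrix_rank(X.values) < X.shape[1]:
            raise CSFMotionError("rank-deficient design matrix")
        res = sm.OLS(y, X).fit()
        return [{"model": model_name, "covariate": nm,
                 "coef": float(res.params[nm]), "p_value": float(res.pvalues[nm]),
                 "n": int(y.size)} for nm in names]

    rows = []
    for c in cov.columns:
        rows.extend(fit_one([c], f"separate:{c}"))
    if combined and len(cov.columns) > 1:
        rows.extend(fit_one(list(cov.columns), "combined"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# voxelwise group difference

def voxelwise_group_map(d_maps: np.ndarray, groups, roi_mask: np.ndarray,
                        alpha_fdr: float = 0.10, min_extent: int = 1) -> ClusterMap:
    """Voxelwise rank-sum map with FDR control and cluster extraction.

    ``d_maps`` is (n_subjects, x, y, z); ``groups`` labels each subject
    ('control'/'pd' or any two labels). Voxels inside ``roi_mask`` with
    finite values for every subject are tested; Benjamini-Hochberg keeps the
    expected false-discovery proportion at ``alpha_fdr``; surviving voxels
    are grouped by 26-connectivity and clusters below ``min_extent`` voxels
    are dropped. Per-cluster sizes and group mean decay rates are reported.
    """
    maps = np.asarray(d_maps, dtype=float)
    groups = np.asarray(groups)
    if maps.ndim != 4 or maps.shape[0] != groups.size:
        raise ValueError("d_maps must be (n_subjects, x, y, z) matching groups")
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("exactly two group labels required")
    g1 = groups == levels[0]
    if g1.sum() < 2 or (~g1).sum() < 2:
        raise ValueError("need >= 2 subjects per group")
    roi = np.asarray(roi_mask, dtype=bool)
    testable = roi & np.all(np.isfinite(maps), axis=0)
    coords = np.argwhere(testable)
    label_vol = np.zeros(roi.shape, dtype=np.int32)
    if coords.shape[0] == 0:
        return ClusterMap(label_volume=label_vol, clusters=[],
                          alpha_fdr=alpha_fdr, min_extent=min_extent)
    pvals = np.empty(coords.shape[0])
    for k, (i, j, z) in enumerate(coords):
        vals = maps[:, i, j, z]
        pvals[k] = rank_sum_test(vals[g1], vals[~g1]).p_value
    reject, _, _, _ = multipletests(pvals, alpha=alpha_fdr, method="fdr_bh")
    surviving = np.zeros(roi.shape, dtype=bool)
    surviving[tuple(coords[reject].T)] = True
    labeled, n_raw = ndimage.label(surviving, structure=np.ones((3, 3, 3), dtype=int))
    clusters = []
    next_id = 0
    for cid in range(1, n_raw + 1):
        sel = labeled == cid
        size = int(sel.sum())
        if size < min_extent:
            continue
        next_id += 1
        label_vol[sel] = next_id
        clusters.append({
            "cluster_id": next_id,
            "size": size,
            f"mean_D_{levels[0]}": float(maps[g1][:, sel].mean()),
            f"mean_D_{levels[1]}": float(maps[~g1][:, sel].mean()),
        })
    return ClusterMap(label_volume=label_vol, clusters=clusters,
                      alpha_fdr=alpha_fdr, min_extent=min_extent)


# ---------------------------------------------------------------------------
# cohort report

#: ROI decay-rate columns summarized by the report, in display order.
REPORT_ROIS = ("ventricular_csf", "gray_matter", "white_matter",
               SUPRASELLAR_CSF, "optic_nerve")


def cohort_report(table: pd.DataFrame, roi_list=REPORT_ROIS,
                  d_column_prefix: str = "D_",
                  perfusion_column: str = "perfusion",
                  stratified_correlation: bool = False):
    """Summary of the cohort contrast table.

    One row per measure: group mean +/- SD and the rank-sum p (continuous
    measures), chi-squared for sex, and the pooled Spearman correlation of
    perfusion against suprasellar decay rate (stratified per group when
    ``stratified_correlation``). Returns (DataFrame, fixed-width text).
    """
    ctrl = table[table["group"] == "control"]
    pd_grp = table[table["group"] == "pd"]

    def summarize(vals):
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            return np.nan, np.nan, 0
        return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0, int(v.size)

    def contrast_row(name, col):
        mc, sc, n_c = summarize(ctrl[col]) if col in ctrl else (np.nan, np.nan, 0)
        mp, sp_, n_p = summarize(pd_grp[col]) if col in pd_grp else (np.nan, np.nan, 0)
        if n_c and n_p:
            xc = ctrl[col].dropna().to_numpy(dtype=float)
            xp = pd_grp[col].dropna().to_numpy(dtype=float)
            p = rank_sum_test(xc, xp).p_value
        else:
            p = np.nan
        return {"measure": name, "control_mean": mc, "control_sd": sc,
                "pd_mean": mp, "pd_sd": sp_, "p_value": p, "test": "rank-sum"}

    rows = [{"measure": "N", "control_mean": float(len(ctrl)), "control_sd": np.nan,
             "pd_mean": float(len(pd_grp)), "pd_sd": np.nan,
             "p_value": np.nan, "test": ""}]
    rows.append(contrast_row("age_years", "age"))
    if len(ctrl) and len(pd_grp) and "sex" in table:
        counts = pd.crosstab(table["group"], table["sex"]).to_numpy()
        sex_res = chi_squared_test(counts)
        rows.append({"measure": "sex", "control_mean": np.nan, "control_sd": np.nan,
                     "pd_mean": np.nan, "pd_sd": np.nan,
                     "p_value": sex_res.p_value, "test": "chi-squared"})
    if "moca" in table:
        rows.append(contrast_row("moca", "moca"))
    if "updrs" in table:
        mu, su, nu = summarize(pd_grp["updrs"]) if len(pd_grp) else (np.nan, np.nan, 0)
        rows.append({"measure": "updrs_pd_only", "control_mean": np.nan,
                     "control_sd": np.nan, "pd_mean": mu, "pd_sd": su,
                     "p_value": np.nan, "test": ""})
    for roi in roi_list:
        col = d_column_prefix + roi
        if col in table:
            rows.append(contrast_row(f"decay_rate_{roi}", col))
    if perfusion_column in table:
        rows.append(contrast_row("choroid_plexus_perfusion", perfusion_column))
        d_col = d_column_prefix + SUPRASELLAR_CSF
        if d_col in table:
            if stratified_correlation:
                for gname, grp in (("control", ctrl), ("pd", pd_grp)):
                    sub = grp[[d_col, perfusion_column]].dropna()
                    if len(sub) >= 3:
                        res = spearman_corr(sub[perfusion_column], sub[d_col])
                        rows.append({"measure": f"spearman_perfusion_vs_D_{gname}",
                                     "control_mean": np.nan, "control_sd": np.nan,
                                     "pd_mean": np.nan, "pd_sd": np.nan,
                                     "p_value": res.p_value, "test": f"spearman r={res.statistic:.3f}"})
            sub = table[[d_col, perfusion_column]].dropna()
            if len(sub) >= 3:
                res = spearman_corr(sub[perfusion_column], sub[d_col])
                rows.append({"measure": "spearman_perfusion_vs_D_pooled",
                             "control_mean": np.nan, "control_sd": np.nan,
                             "pd_mean": np.nan, "pd_sd": np.nan,
                             "p_value": res.p_value,
                             "test": f"spearman r={res.statistic:.3f}"})
    report = pd.DataFrame(rows)
    return report, _render_report(report)


def _render_report(report: pd.DataFrame) -> str:
    lines = [f"{'measure':<34}{'control':>24}{'pd':>24}{'p':>10}  test",
             "-" * 102]
    for _, r in report.iterrows():
        def ms(m, s):
            if not np.isfinite(m):
                return "--"
            if not np.isfinite(s):
                return f"{m:g}"
            return f"{m:.5g} ± {s:.3g}"
        p = f"{r['p_value']:.3g}" if np.isfinite(r["p_value"]) else "--"
        lines.append(f"{r['measure']:<34}{ms(r['control_mean'], r['control_sd']):>24}"
                     f"{ms(r['pd_mean'], r['pd_sd']):>24}{p:>10}  {r['test']}")
    return "\n".join(lines)
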