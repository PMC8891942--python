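"""Mass-univariate group analysis and summary-statistics tests.

Voxel-wise covariate-adjusted group comparison (partial F), two-group
post-hoc t maps, step-up false-discovery-rate control, connected-cluster
extraction, and the classical summary tests (ANOVA / pooled t /
chi-square) used for demographics tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io_core import BrainMask, PasymError, SubjectTable, ValidationError

DEFAULT_COVARIATES = ("age", "gender", "education", "mean_fd")

#: pairwise contrasts reported for the three-group design, in output order
CONTRASTS = (("GI_MDD", "NGI_MDD"), ("GI_MDD", "HC"), ("NGI_MDD", "HC"))


@dataclass
class DesignMatrix:
    """Full (group + covariates) and reduced (covariates only) designs."""

    X: np.ndarray
    names: list
    X_reduced: np.ndarray
    group_columns: list  # column indices of group indicators in X
    groups: tuple
    reference: str
    row_index: np.ndarray  # positions of retained subjects in the source table

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class StatMap:
    """Per-voxel statistic with p, BH-adjusted q, and significance flags."""

    stat: np.ndarray
    p: np.ndarray
    df: tuple
    kind: str  # "F" or "t"
    q: np.ndarray | None = None
    significant: np.ndarray | None = None
    degenerate: np.ndarray | None = None  # zero-residual-variance voxels

    def apply_fdr(self, alpha: float) -> "StatMap":
        self.q, self.significant = fdr_bh(self.p, alpha)
        return self


@dataclass
class ClusterRecord:
    """One supra-threshold connected component."""

    cluster_id: int
    sign: int
    n_voxels: int
    peak_voxel: int  # in-mask voxel index
    peak_ijk: tuple
    peak_mm: tuple
    peak_stat: float
    subject_means: np.ndarray | None = None
    voxel_members: np.ndarray | None = None  # in-mask voxel indices


@dataclass
class SummaryGroup:
    """Printed-table style summary: size, mean, sample SD (n-1)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("summary group needs n >= 2")
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")


# ---------------------------------------------------------------------------
# design construction and voxel-wise models
# ---------------------------------------------------------------------------


def build_design(
    table: SubjectTable,
    groups: Sequence[str] | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    reference: str | None = None,
) -> DesignMatrix:
    """Reduced-rank-safe design: intercept, group indicators (reference
    dropped), and mean-centered covariates. Gender is coded male=0 female=1.
    """
    df = table.df
    present = [g for g in dict.fromkeys(df["group"])]
    groups = list(groups) if groups is not None else present
    keep = df["group"].isin(groups).to_numpy()
    rows = np.flatnonzero(keep)
    sub = df.iloc[rows]
    used_groups = [g for g in groups if (sub["group"] == g).any()]
    if len(used_groups) < 1:
        raise ValidationError("no subjects left after group filtering")
    table.subset(used_groups).require_covariates(
        [c for c in covariates if c != "gender"]
    )
    if reference is None:
        reference = "HC" if "HC" in used_groups else used_groups[-1]
    if reference not in used_groups:
        raise ValidationError(f"reference group {reference!r} not among {used_groups}")

    n = len(sub)
    cols = [np.ones(n)]
    names = ["intercept"]
    group_columns = []
    for g in used_groups:
        if g == reference:
            continue
        group_columns.append(len(cols))
        cols.append((sub["group"] == g).to_numpy(float))
        names.append(f"group[{g}]")
    for cov in covariates:
        if cov == "gender":
            vals = (sub["gender"] == "female").to_numpy(float)
        else:
            vals = sub[cov].to_numpy(float)
        cols.append(vals - vals.mean())
        names.append(cov)
    X = np.column_stack(cols)
    reduced_cols = [i for i in range(X.shape[1]) if i not in group_columns]
    X_reduced = X[:, reduced_cols]

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            f"design is rank deficient; check columns {names} for collinearity"
        )
    return DesignMatrix(
        X=X,
        names=names,
        X_reduced=X_reduced,
        group_columns=group_columns,
        groups=tuple(used_groups),
        reference=reference,
        row_index=rows,
    )


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid**2).sum(axis=0)


def ancova_f_map(pas_stack: np.ndarray, design: DesignMatrix) -> StatMap:
    """Partial F for the group factor at every voxel."""
    Y = np.asarray(pas_stack, dtype=float)
    if Y.shape[0] != design.n:
        raise PasymError("stack rows do not align with the design")
    ddf = len(design.group_columns)
    if ddf == 0:
        raise PasymError("design contains no group indicators")
    df_resid = design.n - design.X.shape[1]
    if df_resid < 1:
        raise PasymError("non-positive residual degrees of freedom")
    rss_full = _rss(design.X, Y)
    rss_red = _rss(design.X_reduced, Y)
    num = np.maximum(rss_red - rss_full, 0.0) / ddf
    degenerate = rss_full <= 0
    den = np.where(degenerate, 1.0, rss_full / df_resid)
    F = np.where(degenerate, np.inf, num / den)
    p = np.where(degenerate, 0.0, stats.f.sf(np.where(degenerate, 0, F), ddf, df_resid))
    # identical-response voxels: no group signal at all
    flat = rss_red <= 0
    F = np.where(flat, 0.0, F)
    p = np.where(flat, 1.0, p)
    return StatMap(stat=F, p=p, df=(ddf, df_resid), kind="F",
                   degenerate=degenerate & ~flat)


def posthoc_t_map(pas_stack: np.ndarray, design: DesignMatrix) -> StatMap:
    """Covariate-adjusted two-group t map.

    The design must hold exactly two groups; the sign convention is
    positive when the non-reference (first-listed) group is higher.
    """
    if len(design.group_columns) != 1:
        raise PasymError("post-hoc t requires a design with exactly two groups")
    Y = np.asarray(pas_stack, dtype=float)
    if Y.shape[0] != design.n:
        raise PasymError("stack rows do not align with the design")
    X = design.X
    n, p_cols = X.shape
    df_resid = n - p_cols
    if df_resid < 1:
        raise PasymError("non-positive residual degrees of freedom")
    g = design.group_columns[0]
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df_resid
    degenerate = sigma2 <= 0
    se = np.sqrt(np.where(degenerate, 1.0, sigma2) * xtx_inv[g, g])
    t = np.where(degenerate, np.sign(beta[g]) * np.inf, beta[g] / se)
    t = np.where(degenerate & (beta[g] == 0), 0.0, t)
    p = np.where(
        np.isinf(t), 0.0, 2 * stats.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df_resid)
    )
    p = np.where((t == 0) & degenerate, 1.0, p)
    return StatMap(stat=t, p=p, df=(df_resid,), kind="t", degenerate=degenerate)


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q_i = min_{j>=i} m*p_(j)/j, clipped at 1.

    Rejection uses strict q < alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise PasymError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q < alpha


# ---------------------------------------------------------------------------
# cluster extraction
# ---------------------------------------------------------------------------

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_clusters(
    stat_map: StatMap,
    mask: BrainMask,
    voxel_index: np.ndarray,
    connectivity: int = 26,
    min_extent: int = 0,
    pas_stack: np.ndarray | None = None,
) -> list[ClusterRecord]:
    """Connected components of significant voxels, split by effect sign.

    ``voxel_index`` maps stat-map entries to in-mask voxel positions.
    The peak is the maximum |statistic|, ties broken by the lowest
    row-major voxel index.  When ``pas_stack`` is given (aligned with the
    stat map columns), each record carries per-subject cluster means.
    """
    if stat_map.significant is None:
        raise PasymError("apply FDR before extracting clusters")
    if connectivity not in _STRUCTURES:
        raise PasymError("connectivity must be 6, 18 or 26")
    coords = mask.voxel_coords[voxel_index]
    stat_vol = np.zeros(mask.shape)
    col_vol = np.full(mask.shape, -1, dtype=np.int64)
    stat_vol[tuple(coords.T)] = stat_map.stat
    col_vol[tuple(coords.T)] = np.arange(voxel_index.size)

    records: list[ClusterRecord] = []
    cluster_id = 0
    for sign in (1, -1):
        flags = np.zeros(mask.shape, dtype=bool)
        sig = stat_map.significant & (np.sign(stat_map.stat) == sign if stat_map.kind == "t"
                                      else np.ones_like(stat_map.significant))
        if stat_map.kind == "F" and sign == -1:
            continue  # F maps are one-signed
        flags[tuple(coords[sig].T)] = True
        labels, n_labels = ndimage.label(flags, structure=_STRUCTURES[connectivity])
        for lab in range(1, n_labels + 1):
            where = np.argwhere(labels == lab)
            if len(where) < max(min_extent, 1):
                continue
            # row-major argwhere order makes the first maximal |stat| the tiebreak winner
            vals = stat_vol[tuple(where.T)]
            peak_pos = int(np.argmax(np.abs(vals)))
            peak_ijk = tuple(int(v) for v in where[peak_pos])
            peak_mm = tuple(
                float(v) for v in (mask.affine @ np.array(peak_ijk + (1,)))[:3]
            )
            cols = col_vol[tuple(where.T)]
            subject_means = None
            if pas_stack is not None:
                subject_means = np.asarray(pas_stack, float)[:, cols].mean(axis=1)
            cluster_id += 1
            records.append(
                ClusterRecord(
                    cluster_id=cluster_id,
                    sign=sign if stat_map.kind == "t" else 1,
                    n_voxels=len(where),
                    peak_voxel=int(voxel_index[cols[peak_pos]]),
                    peak_ijk=peak_ijk,
                    peak_mm=peak_mm,
                    peak_stat=float(vals[peak_pos]),
                    subject_means=subject_means,
                    voxel_members=np.sort(voxel_index[cols]),
                )
            )
    records.sort(key=lambda r: (-r.n_voxels, r.peak_voxel))
    for i, rec in enumerate(records, start=1):
        rec.cluster_id = i
    return records


def clusters_to_frame(records: list[ClusterRecord]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": r.cluster_id,
            "sign": r.sign,
            "n_voxels": r.n_voxels,
            "peak_x_mm": r.peak_mm[0],
            "peak_y_mm": r.peak_mm[1],
            "peak_z_mm": r.peak_mm[2],
            "peak_stat": r.peak_stat,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "sign", "n_voxels",
            "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_stat",
        ],
    )


# ---------------------------------------------------------------------------
# summary-statistics tests (demographics tables)
# ---------------------------------------------------------------------------


def anova_from_summary(groups: Sequence[SummaryGroup]) -> tuple[float, int, int]:
    """One-way ANOVA F reconstructed from per-group n/mean/SD."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    N = ns.sum()
    k = len(groups)
    grand = (ns * means).sum() / N
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df1, df2 = k - 1, int(N - k)
    if ssw <= 0:
        return (np.inf if ssb > 0 else 0.0), df1, df2
    F = (ssb / df1) / (ssw / df2)
    return float(F), df1, df2


def ttest_from_summary(a: SummaryGroup, b: SummaryGroup) -> tuple[float, int]:
    """Pooled-variance two-sample t from summaries; df = n_a + n_b - 2."""
    df = a.n + b.n - 2
    pooled = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = np.sqrt(pooled * (1 / a.n + 1 / b.n))
    if se == 0:
        return (0.0 if a.mean == b.mean else np.inf * np.sign(a.mean - b.mean)), df
    return float((a.mean - b.mean) / se), df


def chi_square_independence(counts) -> tuple[float, int]:
    """Pearson chi-square of independence, no continuity correction."""
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2:
        raise ValidationError("counts must be a 2-way table")
    if (obs < 0).any():
        raise ValidationError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValidationError("table has a zero marginal")
    expected = row @ col / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df


def summarize(values) -> SummaryGroup:
    """n / mean / sample-SD summary of a raw vector (n-1 convention)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return SummaryGroup(n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))


def table_one(table: SubjectTable) -> pd.DataFrame:
    """Demographics/clinical summary with the matching omnibus statistic."""
    df = table.df
    by = {g: df[df["group"] == g] for g in df["group"].unique()}
    rows = []

    def fmt(sub, col):
        v = sub[col].dropna().to_numpy(float)
        if len(v) == 0:
            return ""
        if len(v) == 1:
            return f"{v[0]:.2f}"
        return f"{np.mean(v):.2f} ± {np.std(v, ddof=1):.2f}"

    continuous_all = ["age", "education", "hrsd17_total", "anxiety_somatization",
                      "weight_loss", "cognitive_disturbance", "retardation",
                      "sleep_disturbance"]
    for col in continuous_all:
        if col not in df.columns:
            continue
        summaries = []
        for g, sub in by.items():
            v = sub[col].dropna().to_numpy(float)
            if len(v) >= 2 and np.std(v, ddof=1) >= 0:
                summaries.append(summarize(v))
        stat = ""
        if len(summaries) >= 2:
            try:
                F, *_ = anova_from_summary(summaries)
                stat = f"{F:.3f}"
            except ValidationError:
                stat = ""
        rows.append({"variable": col, "test": "ANOVA F", "statistic": stat,
                     **{g: fmt(sub, col) for g, sub in by.items()}})

    if "gender" in df.columns:
        tab = pd.crosstab(df["gender"], df["group"])
        try:
            chi2, _ = chi_square_independence(tab.to_numpy())
            stat = f"{chi2:.3f}"
        except ValidationError:
            stat = ""
        rows.append({"variable": "gender (male/female)", "test": "chi-square",
                     "statistic": stat,
                     **{g: f"{int((sub['gender'] == 'male').sum())}/"
                           f"{int((sub['gender'] == 'female').sum())}"
                        for g, sub in by.items()}})

    if "illness_duration" in df.columns:
        pats = [summarize(by[g]["illness_duration"].dropna())
                for g in ("GI_MDD", "NGI_MDD") if g in by
                and by[g]["illness_duration"].notna().sum() >= 2]
        if len(pats) == 2:
            t, _ = ttest_from_summary(*pats)
            rows.append({"variable": "illness_duration", "test": "two-sample t",
                         "statistic": f"{abs(t):.3f}",
                         **{g: fmt(sub, "illness_duration") for g, sub in by.items()}})
    return pd.DataFrame(rows)
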