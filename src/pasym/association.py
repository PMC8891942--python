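"""Rank correlation between cluster-mean asymmetry scores and clinical
variables, with Benjamini-Hochberg control over the tested family."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import PasymError, SubjectTable
from .inference import fdr_bh

PATIENT_GROUPS = ("GI_MDD", "NGI_MDD")


@dataclass
class CorrelationResult:
    cluster: str
    variable: str
    rho: float
    p: float
    n: int
    valid: bool
    q: float = float("nan")
    significant: bool = False


def spearman(x, y) -> tuple[float, float]:
    """Rank correlation with mid-ranks for ties; p from the t approximation
    t = rho * sqrt((n-2) / (1-rho^2)).

    Raises on constant input (zero rank variance); callers building a BH
    family should catch and flag such pairs instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise PasymError(f"need at least 3 complete pairs, got {n}")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise PasymError("constant input: rank correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, p


def correlation_grid(
    cluster_means: pd.DataFrame,
    table: SubjectTable,
    variables: Sequence[str],
    groups: Sequence[str] = PATIENT_GROUPS,
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """One rank correlation per (cluster, variable) pair over the chosen
    subject groups, BH-corrected across all valid pairs in the grid.

    ``cluster_means`` is subject-by-cluster and must align row-wise with
    the subject table.
    """
    if len(variables) == 0:
        raise PasymError("empty variable list")
    if len(cluster_means) != len(table):
        raise PasymError("cluster means do not align with the subject table")
    keep = table.df["group"].isin(groups).to_numpy()
    sub = table.df.loc[keep]
    means = cluster_means.loc[keep]
    if keep.sum() < 3:
        raise PasymError("need at least 3 subjects after group filtering")

    results: list[CorrelationResult] = []
    for cluster in cluster_means.columns:
        for var in variables:
            if var not in sub.columns:
                raise PasymError(f"unknown clinical variable: {var}")
            x = means[cluster].to_numpy(float)
            y = sub[var].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            try:
                rho, p = spearman(x[ok], y[ok])
                results.append(CorrelationResult(cluster, var, rho, p,
                                                 int(ok.sum()), True))
            except PasymError:
                results.append(CorrelationResult(cluster, var, float("nan"),
                                                 float("nan"), int(ok.sum()), False))

    valid = [r for r in results if r.valid]
    if valid:
        q, rej = fdr_bh([r.p for r in valid], alpha)
        for r, qi, ri in zip(valid, q, rej):
            r.q = float(qi)
            r.significant = bool(ri)
    return results


def grid_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster": r.cluster,
                "variable": r.variable,
                "rho": r.rho,
                "p": r.p,
                "q": r.q,
                "n": r.n,
                "significant": r.significant,
                "valid": r.valid,
            }
            for r in results
        ]
    )
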