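"""Expression-array preprocessing and differential expression.

Probe-level log2 intensity matrices are screened for outlier samples with PCA,
quantile-normalized, and summarized per probeset with Tukey median polish.
Differential expression between groups reuses the moderated-t machinery of
:mod:`methlink.methylation` with a single group-difference contrast; a
transcript passes at adjusted p <= fdr and fold change >= min_fc.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy import stats as sps

from .methylation import InferenceError, fit_probe_models, moderate_statistics

__all__ = [
    "pca_outlier_detect",
    "median_polish",
    "median_polish_summarize",
    "differential_expression",
    "combine_de",
]


def pca_outlier_detect(
    matrix: pd.DataFrame, groups: pd.Series, k_mad: float = 3.0
) -> list[str]:
    """Flag samples far from their group centroid in the first two PCs.

    Samples (columns of ``matrix``) are projected onto the first two principal
    components of the column-centered matrix; a sample is flagged when its
    Euclidean distance to its group centroid exceeds
    median + ``k_mad`` x MAD of the pooled within-group distances.  Flags are
    advisory: exclusion is the caller's decision.
    """
    n = matrix.shape[1]
    if n < 4:
        raise InferenceError("PCA outlier detection needs >= 4 samples")
    X = matrix.to_numpy(dtype=float).T  # samples x probes
    X = X - X.mean(axis=0)
    # two right singular vectors suffice; avoids forming the probe covariance
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    proj = X @ vt[:2].T
    groups = groups.loc[matrix.columns]
    dists = np.zeros(n)
    for g in pd.unique(groups):
        idx = np.asarray(groups.values == g)
        centroid = proj[idx].mean(axis=0)
        dists[idx] = np.linalg.norm(proj[idx] - centroid, axis=1)
    if not np.isfinite(k_mad):
        return []
    med = float(np.median(dists))
    mad = float(sps.median_abs_deviation(dists, scale=1.0))
    cutoff = med + k_mad * mad
    return [s for s, d in zip(matrix.columns, dists) if d > cutoff]


def median_polish(
    X: np.ndarray, max_iter: int = 10, tol: float = 0.01
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish: X ~ overall + row + col + residual.

    Alternating row/column median sweeps (rows first) until the sum of
    absolute residuals changes by less than ``tol`` or ``max_iter`` full
    sweeps.  Returns (overall, row_effects, col_effects, residuals).
    """
    R = np.asarray(X, dtype=float).copy()
    nr, nc = R.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    prev_sar = np.abs(R).sum()
    for _ in range(max_iter):
        rmed = np.median(R, axis=1)
        R -= rmed[:, None]
        row += rmed
        cmed_of_row = np.median(row)
        row -= cmed_of_row
        overall += cmed_of_row
        cmed = np.median(R, axis=0)
        R -= cmed[None, :]
        col += cmed
        rmed_of_col = np.median(col)
        col -= rmed_of_col
        overall += rmed_of_col
        sar = np.abs(R).sum()
        if abs(prev_sar - sar) < tol:
            break
        prev_sar = sar
    return overall, row, col, R


def median_polish_summarize(
    matrix: pd.DataFrame,
    probeset_map: pd.Series,
    max_iter: int = 10,
    tol: float = 0.01,
) -> pd.DataFrame:
    """Summarize probe-level log2 intensities to one value per probeset per sample.

    For each probeset the probe x sample submatrix is decomposed by median
    polish and the summary for sample j is overall + column effect j (the
    RMA-style summary, robust to outlier probes).  Empty probesets are skipped
    with a warning.
    """
    all_probesets = set(probeset_map.unique())
    probeset_map = probeset_map.loc[probeset_map.index.intersection(matrix.index)]
    for tid in sorted(all_probesets - set(probeset_map.unique())):
        warnings.warn(f"probeset {tid} has no probes in the matrix; skipped",
                      RuntimeWarning)
    out_rows = {}
    for tid, probe_ids in probeset_map.groupby(probeset_map).groups.items():
        sub = matrix.loc[probe_ids].to_numpy(dtype=float)
        overall, _, col, _ = median_polish(sub, max_iter=max_iter, tol=tol)
        out_rows[tid] = overall + col
    out = pd.DataFrame.from_dict(out_rows, orient="index", columns=matrix.columns)
    out.index.name = "transcript_id"
    return out.sort_index()


def differential_expression(
    expr: pd.DataFrame,
    groups: pd.Series,
    fdr: float = 0.05,
    min_fc: float = 1.25,
    reference: str = "normal",
    treatment: str = "asthma",
) -> pd.DataFrame:
    """Moderated-t differential expression on a transcript x sample matrix.

    The single contrast is treatment minus reference (log2 scale).  Returns a
    table with one row per transcript: log2fc, moderated_t, p_raw, p_adj,
    direction (up/down), and a ``passes`` flag at (fdr, min_fc):
    passes <=> p_adj <= fdr and |log2fc| >= log2(min_fc).
    """
    fit = fit_probe_models(expr, groups)
    if set(fit.means.columns) != {reference, treatment}:
        raise InferenceError(
            f"expected groups {{{reference}, {treatment}}}, got {set(fit.means.columns)}"
        )
    results, _ = moderate_statistics(
        fit, contrasts={"log2fc": {treatment: 1.0, reference: -1.0}}
    )
    de = results.rename(columns={"probe_id": "transcript_id", "estimate": "log2fc"})
    de = de.drop(columns=["contrast"])
    de["direction"] = np.where(de["log2fc"] >= 0, "up", "down")
    de["passes"] = (de["p_adj"] <= fdr) & (de["log2fc"].abs() >= np.log2(min_fc))
    return de.set_index("transcript_id")


def combine_de(
    de1: pd.DataFrame, de2: pd.DataFrame, mode: str = "intersection"
) -> pd.DataFrame:
    """Merge DE tables from two independent datasets by transcript id.

    ``intersection`` (default): a transcript passes only if it passes in both
    datasets with agreeing direction; the merged log2fc is the mean and the
    merged p_adj the maximum (conservative).  ``union``: passes in either
    dataset; on a direction conflict between two passing calls the transcript
    is demoted to non-passing.
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown combine mode {mode!r}")
    merged = de1.join(de2, how="outer", lsuffix="_1", rsuffix="_2")
    both = merged["log2fc_1"].notna() & merged["log2fc_2"].notna()
    log2fc = merged[["log2fc_1", "log2fc_2"]].mean(axis=1)
    p_adj = merged[["p_adj_1", "p_adj_2"]].max(axis=1)
    pass1 = merged["passes_1"].fillna(False).astype(bool)
    pass2 = merged["passes_2"].fillna(False).astype(bool)
    agree = merged["direction_1"] == merged["direction_2"]
    if mode == "intersection":
        passes = both & pass1 & pass2 & agree
    else:
        conflict = pass1 & pass2 & ~agree
        passes = (pass1 | pass2) & ~conflict
    direction = np.where(log2fc >= 0, "up", "down")
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_adj": p_adj,
            "direction": direction,
            "passes": passes,
            "in_both_sets": both,
        },
        index=merged.index,
    )
    out.index.name = "transcript_id"
    return out
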