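"""Differential methylation from two-color methylation-sensitive restriction arrays.

The assay hybridizes endonuclease-treated (Cy3) and untreated (Cy5) DNA from the
same sample on one chip.  An unmethylated probe is cut by the enzyme, so its
treated-channel signal drops and its M-value, defined here as

    M = log2(untreated) - log2(treated),

is positive; a methylated (protected) probe and a control spot have expected
M = 0.  The analysis chain is: MA transform -> IQR-based chip QC -> within-array
loess normalization anchored on control spots -> between-array quantile
normalization -> per-probe two-group linear model with three contrasts
(mean M in each group, and their difference) -> empirical-Bayes moderated t ->
Benjamini-Hochberg adjustment -> unmethylated calls and the two-stage DMR filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TwoColorArray",
    "MaValues",
    "ModelFit",
    "EBayesPrior",
    "DmrSet",
    "QcReport",
    "DataError",
    "InferenceError",
    "compute_ma",
    "qc_exclude_low_iqr",
    "normalize_within_control_loess",
    "quantile_normalize",
    "fit_probe_models",
    "moderate_statistics",
    "bh_adjust",
    "call_unmethylated",
    "filter_dmrs",
    "METHYLATION_CONTRASTS",
    "HYPER_IN_ASTHMA",
    "HYPO_IN_ASTHMA",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class InferenceError(RuntimeError):
    """The statistical model cannot be fitted on the given design."""


# Direction vocabulary, asserted in one place so sign conventions cannot drift:
# a probe unmethylated in the normal group only is *hypermethylated in asthma*.
HYPER_IN_ASTHMA = "unmeth_normal_meth_asthma"
HYPO_IN_ASTHMA = "unmeth_asthma_meth_normal"


@dataclass
class TwoColorArray:
    """One chip: per-probe treated (Cy3) and untreated (Cy5) intensities."""

    array_id: str
    group: str
    probe_ids: np.ndarray
    treated: np.ndarray
    untreated: np.ndarray
    is_control: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.probe_ids)
        if not (len(self.treated) == len(self.untreated) == len(self.is_control) == n):
            raise DataError(f"array {self.array_id}: ragged probe columns")


@dataclass
class MaValues:
    """M and A per probe per array, plus array group labels and control flags.

    M and A are DataFrames indexed by probe_id with one column per array_id.
    """

    M: pd.DataFrame
    A: pd.DataFrame
    groups: pd.Series
    is_control: pd.Series

    def subset_arrays(self, array_ids: list[str]) -> "MaValues":
        return MaValues(
            M=self.M[array_ids],
            A=self.A[array_ids],
            groups=self.groups.loc[array_ids],
            is_control=self.is_control,
        )


@dataclass
class QcReport:
    """Per-array IQR of raw M and the exclusion decision."""

    table: pd.DataFrame  # columns: array_id, group, iqr, excluded
    threshold: float


@dataclass
class ModelFit:
    """Per-probe group means and pooled residual variance for a two-group model."""

    means: pd.DataFrame  # one column per group
    sigma_sq: pd.Series
    residual_df: int
    n_per_group: dict[str, int]

    @property
    def probe_ids(self) -> pd.Index:
        return self.means.index


@dataclass
class EBayesPrior:
    """Empirical-Bayes prior for residual variances: d0 prior df, s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("prior degrees of freedom must be >= 0")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance must be positive")


@dataclass
class DmrSet:
    """Probes unmethylated in exactly one group that survived the two-stage filter."""

    direction: str  # HYPER_IN_ASTHMA or HYPO_IN_ASTHMA
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # table columns: probe_id, lfc_normal, lfc_asthma, delta_lfc

    @property
    def probe_ids(self) -> list[str]:
        if self.table.empty:
            return []
        return list(self.table["probe_id"])


def compute_ma(arrays: list[TwoColorArray], floor: float = 1.0) -> MaValues:
    """MA transform: M = log2(untreated/treated), A = mean log2 intensity.

    Intensities below ``floor`` are raised to ``floor`` before taking logs so
    that near-zero scanner readings do not produce infinities; bright probes
    are unaffected.
    """
    if not arrays:
        raise DataError("no arrays supplied")
    ref = arrays[0]
    probe_index = pd.Index(ref.probe_ids, name="probe_id")
    if probe_index.has_duplicates:
        dupes = probe_index[probe_index.duplicated()][:3].tolist()
        raise DataError(f"duplicate probe ids: {dupes}")
    M, A, groups = {}, {}, {}
    for arr in arrays:
        if not np.array_equal(arr.probe_ids, ref.probe_ids):
            raise DataError(
                f"array {arr.array_id}: probe list differs from array {ref.array_id}"
            )
        t = np.maximum(np.asarray(arr.treated, dtype=float), floor)
        u = np.maximum(np.asarray(arr.untreated, dtype=float), floor)
        for name, v in (("treated", t), ("untreated", u)):
            if np.any(v <= 0):
                bad = probe_index[np.asarray(v <= 0)][0]
                raise DataError(
                    f"array {arr.array_id}, probe {bad}: non-positive {name} "
                    f"intensity after flooring at {floor}"
                )
        lt, lu = np.log2(t), np.log2(u)
        M[arr.array_id] = lu - lt
        A[arr.array_id] = (lu + lt) / 2.0
        groups[arr.array_id] = arr.group
    return MaValues(
        M=pd.DataFrame(M, index=probe_index),
        A=pd.DataFrame(A, index=probe_index),
        groups=pd.Series(groups, name="group"),
        is_control=pd.Series(np.asarray(ref.is_control, dtype=bool), index=probe_index,
                             name="is_control"),
    )


def qc_exclude_low_iqr(ma: MaValues, min_iqr_ratio: float = 0.5) -> tuple[MaValues, QcReport]:
    """Exclude arrays whose raw-M interquartile range has collapsed.

    Endonuclease treatment failure leaves treated ~ untreated for every probe,
    so the M distribution loses the long unmethylated tail and its IQR drops
    far below that of working chips.  An array is excluded when its IQR is
    below ``min_iqr_ratio`` times the median IQR across arrays.
    """
    if ma.M.shape[1] < 3:
        raise InferenceError("IQR-based QC requires at least 3 arrays")
    q75 = ma.M.quantile(0.75)
    q25 = ma.M.quantile(0.25)
    iqr = q75 - q25
    threshold = min_iqr_ratio * float(iqr.median())
    excluded = iqr < threshold
    report = QcReport(
        table=pd.DataFrame(
            {
                "array_id": iqr.index,
                "group": ma.groups.loc[iqr.index].values,
                "iqr": iqr.values,
                "excluded": excluded.values,
            }
        ),
        threshold=threshold,
    )
    keep = [a for a in ma.M.columns if not excluded[a]]
    if not keep:
        raise InferenceError(
            "all arrays excluded by IQR QC; report:\n" + report.table.to_string()
        )
    return ma.subset_arrays(keep), report


def normalize_within_control_loess(
    ma: MaValues,
    span: float = 0.3,
    min_controls: int = 50,
    fallback_global: bool = False,
) -> MaValues:
    """Within-array normalization: subtract a loess M~A trend fitted on control spots.

    Control probes are expected not to change with treatment (M = 0), so any
    systematic M~A trend among them is a dye/intensity artifact.  The trend is
    fitted per array on controls only and its prediction at each probe's A is
    subtracted from that probe's M; predictions outside the control A-range use
    the boundary fitted values.  A unchanged.
    """
    ctrl = ma.is_control.values
    n_ctrl = int(ctrl.sum())
    if n_ctrl < min_controls:
        if not fallback_global:
            raise DataError(
                f"only {n_ctrl} control probes (< {min_controls}); pass "
                "fallback_global=True to fit the loess on all probes instead"
            )
        ctrl = np.ones(len(ma.is_control), dtype=bool)
    M_out = {}
    for aid in ma.M.columns:
        m = ma.M[aid].values
        a = ma.A[aid].values
        fitted = lowess(m[ctrl], a[ctrl], frac=span, return_sorted=True)
        xs, ys = fitted[:, 0], fitted[:, 1]
        # np.interp clamps to the first/last fitted value outside the range
        trend = np.interp(a, xs, ys)
        M_out[aid] = m - trend
    return MaValues(
        M=pd.DataFrame(M_out, index=ma.M.index),
        A=ma.A.copy(),
        groups=ma.groups,
        is_control=ma.is_control,
    )


def quantile_normalize(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Force every column onto the mean distribution of the column order statistics.

    After the transform each column's sorted values equal the across-column
    mean of order statistics; ranks within a column are preserved.  Tied values
    receive the mean of the reference values for the order-statistic positions
    they span, so the transform is well defined and idempotent.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise DataError("quantile normalization expects a 2-D matrix")
    if np.isnan(X).any():
        raise DataError("missing values are not allowed in quantile normalization")
    order = np.argsort(X, axis=0, kind="stable")
    X_sorted = np.take_along_axis(X, order, axis=0)
    target = X_sorted.mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col_target = np.empty(X.shape[0])
        col_target[order[:, j]] = target
        # average target values over runs of tied input values
        s = pd.Series(col_target)
        out[:, j] = s.groupby(X[:, j]).transform("mean").to_numpy()
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def fit_probe_models(M: pd.DataFrame, groups: pd.Series) -> ModelFit:
    """Per-probe two-group means model with pooled residual variance.

    ``groups`` maps each column of ``M`` to its group label (exactly two
    groups).  Residual df is n - 2, pooled over both groups.
    """
    groups = groups.loc[M.columns]
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise InferenceError(f"expected exactly 2 groups, got {labels}")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise InferenceError(f"each group needs >= 2 arrays, got {counts.to_dict()}")
    X = M.to_numpy(dtype=float)
    means = {}
    rss = np.zeros(X.shape[0])
    for g in labels:
        cols = np.asarray(groups.values == g)
        sub = X[:, cols]
        mu = sub.mean(axis=1)
        means[g] = mu
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
    df = X.shape[1] - 2
    sigma_sq = rss / df
    return ModelFit(
        means=pd.DataFrame(means, index=M.index),
        sigma_sq=pd.Series(sigma_sq, index=M.index, name="sigma_sq"),
        residual_df=df,
        n_per_group={g: int(counts[g]) for g in labels},
    )


# contrast name -> {group label: coefficient}; keyed by name so the fitted
# column order can never flip a sign
METHYLATION_CONTRASTS: dict[str, dict[str, float]] = {
    "meth_normal": {"normal": 1.0},
    "meth_asthma": {"asthma": 1.0},
    "difference": {"normal": 1.0, "asthma": -1.0},
}


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_ebayes_prior(sigma_sq: np.ndarray, residual_df: float) -> EBayesPrior:
    """Moment-match an inverse-chi-square prior to the observed variance spread.

    On the log scale, log s^2 for a probe with true variance s0^2 has known
    mean/variance offsets given by digamma/trigamma of the half-df; the excess
    spread of log s^2 across probes beyond the chi-square sampling component
    identifies the prior df d0, and the centred mean identifies s0^2.  When the
    observed spread does not exceed the sampling component, d0 is infinite and
    all probes share one variance.
    """
    s2 = np.asarray(sigma_sq, dtype=float)
    pos = s2 > 0
    if not pos.any():
        warnings.warn(
            "all residual variances are zero; using a degenerate prior "
            "(d0=inf, machine-floor s0_sq)",
            RuntimeWarning,
        )
        return EBayesPrior(d0=np.inf, s0_sq=np.finfo(float).tiny)
    z = np.log(s2[pos])
    half_df = residual_df / 2.0
    e = z - special.digamma(half_df) + np.log(half_df)
    emean = float(e.mean())
    if len(e) > 1:
        evar = float(e.var(ddof=1)) - float(special.polygamma(1, half_df))
    else:
        evar = 0.0
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread beyond chi-square sampling: one shared variance,
        # estimated by the arithmetic mean
        d0 = np.inf
        s0_sq = float(np.mean(s2))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def moderate_statistics(
    fit: ModelFit,
    contrasts: dict[str, dict[str, float]] | None = None,
    prior: EBayesPrior | None = None,
) -> tuple[pd.DataFrame, EBayesPrior]:
    """Moderated t-statistics for each contrast, with BH-adjusted p-values.

    The posterior variance shrinks each probe's residual variance toward the
    empirical-Bayes prior:  s~^2 = (d0*s0^2 + df*s^2) / (d0 + df); the t
    statistic uses s~ in its denominator and gains d0 extra degrees of freedom
    (a normal reference when d0 is infinite).  Returns a long-format table with
    one row per probe per contrast and the prior actually used.
    """
    if contrasts is None:
        contrasts = METHYLATION_CONTRASTS
    if fit.residual_df < 1:
        raise InferenceError("residual df < 1: cannot moderate variances")
    s2 = fit.sigma_sq.to_numpy()
    df = float(fit.residual_df)
    if prior is None:
        prior = estimate_ebayes_prior(s2, df)
    d0, s0 = prior.d0, prior.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df
    n = fit.n_per_group
    rows = []
    for cname, coef in contrasts.items():
        unknown = set(coef) - set(fit.means.columns)
        if unknown:
            raise InferenceError(f"contrast {cname}: unknown groups {unknown}")
        est = np.zeros(len(fit.means))
        unscaled_sq = 0.0
        for g, c in coef.items():
            if c != 0.0:
                est = est + c * fit.means[g].to_numpy()
                unscaled_sq += c * c / n[g]
        unscaled = np.sqrt(unscaled_sq)
        se_post = np.sqrt(s2_post) * unscaled
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se_post > 0, est / se_post, np.where(est == 0, 0.0, np.inf * np.sign(est)))
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        rows.append(
            pd.DataFrame(
                {
                    "probe_id": fit.probe_ids,
                    "contrast": cname,
                    "estimate": est,
                    "stderr": np.sqrt(np.maximum(s2, 0)) * unscaled,
                    "residual_df": fit.residual_df,
                    "moderated_t": t,
                    "p_raw": p,
                    "p_adj": bh_adjust(p),
                }
            )
        )
    return pd.concat(rows, ignore_index=True), prior


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_unmethylated(
    results: pd.DataFrame, fdr: float = 0.05, min_lfc: float = 0.5
) -> dict[str, set[str]]:
    """Call a probe unmethylated in a group when adj-p <= fdr and its group M >= min_lfc.

    Returns sets ``normal_only``, ``asthma_only``, ``both`` plus the raw
    per-group call sets ``unmeth_normal`` / ``unmeth_asthma``.
    """
    needed = {"meth_normal", "meth_asthma"}
    present = set(results["contrast"].unique())
    if not needed <= present:
        raise InferenceError(f"results missing contrasts {needed - present}")
    sets = {}
    for cname, key in (("meth_normal", "unmeth_normal"), ("meth_asthma", "unmeth_asthma")):
        sub = results[results["contrast"] == cname]
        hit = sub[(sub["p_adj"] <= fdr) & (sub["estimate"] >= min_lfc)]
        sets[key] = set(hit["probe_id"])
    sets["normal_only"] = sets["unmeth_normal"] - sets["unmeth_asthma"]
    sets["asthma_only"] = sets["unmeth_asthma"] - sets["unmeth_normal"]
    sets["both"] = sets["unmeth_normal"] & sets["unmeth_asthma"]
    return sets


def filter_dmrs(
    calls: dict[str, set[str]],
    results: pd.DataFrame,
    max_meth_lfc: float = 0.5,
    min_group_diff: float = 0.3,
) -> tuple[DmrSet, DmrSet]:
    """Two-stage DMR filter on single-group unmethylated calls.

    A probe unmethylated only in group A is kept when (1) the *other* group's
    log2 fold change is below ``max_meth_lfc`` — i.e. the methylated group
    really looks methylated — and (2) the absolute between-group difference in
    log2 fold change exceeds ``min_group_diff``.  Returns the pair
    (hypermethylated-in-asthma, hypomethylated-in-asthma).
    """
    lfc = results.pivot_table(index="probe_id", columns="contrast", values="estimate")
    out = []
    for only_key, direction, meth_group in (
        ("normal_only", HYPER_IN_ASTHMA, "meth_asthma"),
        ("asthma_only", HYPO_IN_ASTHMA, "meth_normal"),
    ):
        ids = sorted(calls[only_key])
        if ids:
            sub = lfc.loc[ids]
            delta = (sub["meth_normal"] - sub["meth_asthma"]).abs()
            keep = (sub[meth_group] < max_meth_lfc) & (delta > min_group_diff)
            table = pd.DataFrame(
                {
                    "probe_id": sub.index[keep],
                    "lfc_normal": sub.loc[keep, "meth_normal"].values,
                    "lfc_asthma": sub.loc[keep, "meth_asthma"].values,
                    "delta_lfc": delta[keep].values,
                }
            ).reset_index(drop=True)
        else:
            table = pd.DataFrame(columns=["probe_id", "lfc_normal", "lfc_asthma", "delta_lfc"])
        out.append(DmrSet(direction=direction, table=table))
    return out[0], out[1]
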