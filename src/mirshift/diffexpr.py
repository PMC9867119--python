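"""Normalization and differential-expression calling for count tables.

The differential-expression convention follows the study design this package
analyses: two groups (sham vs TAC), small replicate numbers (duplicate mRNA
libraries, quadruplicate miRNA libraries), equal-variance Student's t-test
on normalized abundances, and hard cut-offs on fold change and raw p-value
(fold change > 2.0 / p < 0.05 for mRNA; > 1.70 / p < 0.05 for miRNA), with
an abundance pre-filter (FPKM > 2 for genes, mean count > 100 for miRNAs).

Fold change is the ratio of pseudocounted group means, taken in whichever
direction makes it >= 1; the cut-off is a strict inequality.  Benjamini-
Hochberg q-values are reported as an informational extra column; the status
call itself uses the raw p-value, matching the stated cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError

GROUP_CONTROL = "sham"
GROUP_CASE = "TAC"


@dataclass
class CountMatrix:
    """Nonnegative feature x sample abundance table with group labels.

    Parameters
    ----------
    values
        DataFrame, rows = features, columns = samples.
    groups
        Series mapping sample id -> group name (``sham`` or ``TAC``).
    lengths
        Optional Series of feature lengths in nt, required for FPKM.
    """

    values: pd.DataFrame
    groups: pd.Series
    lengths: pd.Series | None = None

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise DataError(f"duplicate feature ids: {dups[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise DataError("negative abundance values")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise DataError(f"samples without a group assignment: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        present = set(self.groups)
        for g in (GROUP_CONTROL, GROUP_CASE):
            if g not in present:
                raise DataError(f"group {g!r} has no samples")
        if self.lengths is not None:
            self.lengths = self.lengths.loc[self.values.index]
            if (self.lengths <= 0).any():
                raise DataError("feature lengths must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def with_values(self, values: pd.DataFrame) -> "CountMatrix":
        return replace(self, values=values)


def normalize_total_counts(m: CountMatrix) -> CountMatrix:
    """Scale each sample to the mean library size across samples.

    Library size is the column sum; after normalization all column sums are
    equal, and within-sample relative order of features is preserved.
    """
    totals = m.values.sum(axis=0)
    if (totals <= 0).any():
        zero = list(totals.index[totals <= 0])
        raise DataError(f"samples with non-positive total counts: {zero}")
    target = totals.mean()
    return m.with_values(m.values * (target / totals))


def fpkm(m: CountMatrix) -> CountMatrix:
    """Fragments per kilobase per million mapped fragments.

    value = count * 1e9 / (feature_length * sample_total).
    """
    if m.lengths is None:
        raise DataError("feature lengths are required to compute FPKM")
    totals = m.values.sum(axis=0)
    if (totals <= 0).any():
        raise DataError("cannot compute FPKM with a zero-total sample")
    out = m.values * 1e9
    out = out.div(totals, axis=1).div(m.lengths, axis=0)
    return m.with_values(out)


def normalize_by_references(m: CountMatrix, ref_ids: list[str]) -> CountMatrix:
    """Normalize each sample by its reference-feature geometric mean.

    Each sample is multiplied by (grand geometric mean of all reference
    counts) / (geometric mean of that sample's reference counts).  After
    normalization the per-sample reference geometric means are equal.  This
    mirrors small-RNA normalization against invariant miRNAs
    (miR-126a-3p and miR-19b-3p in the heart-failure study design).
    """
    missing = [r for r in ref_ids if r not in m.values.index]
    if missing:
        raise DataError(f"reference features absent from matrix: {missing}")
    refs = m.values.loc[list(ref_ids)]
    if (refs.to_numpy() <= 0).any():
        raise DataError("reference features must have positive counts in every sample")
    log_refs = np.log(refs.to_numpy())
    sample_gm = np.exp(log_refs.mean(axis=0))
    grand_gm = np.exp(log_refs.mean())
    factors = grand_gm / sample_gm
    return m.with_values(m.values * factors)


def two_sample_t(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test (Student's by default, Welch by flag).

    Degenerate inputs: if the pooled variance is zero the statistic is 0
    with p = 1 when the means are equal, and +/-inf with p = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        d = x.mean() - y.mean()
        if d == 0.0:
            return 0.0, 1.0
        return float(np.sign(d) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (informational)."""
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def call_de(
    m: CountMatrix,
    filter_metric: str = "count",
    filter_threshold: float = 100.0,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    filter_mode: str = "mean",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Call differentially expressed features between sham and TAC.

    Features failing the abundance filter get status ``filtered`` and are
    not tested.  For the rest, fold change is the larger of the two ratios
    of pseudocounted group means; a feature is ``up``/``down`` iff
    fold_change > fc_threshold (strict) and p < alpha (strict), else
    ``unchanged``.

    Parameters
    ----------
    filter_metric
        ``"count"`` filters on the matrix values themselves; ``"FPKM"``
        filters on FPKM computed from the matrix (requires lengths).
    filter_mode
        ``"mean"`` (default) or ``"min"`` across samples.

    Returns a DataFrame indexed by feature id with columns mean_sham,
    mean_tac, fold_change, direction, log2fc, p_value, q_value, status.
    """
    if fc_threshold <= 0 or filter_threshold <= 0:
        raise ParameterError("thresholds must be positive")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    sham = m.samples_of(GROUP_CONTROL)
    tac = m.samples_of(GROUP_CASE)
    if len(sham) < 2 or len(tac) < 2:
        raise DataError("each group needs at least 2 replicates for the t-test")

    if filter_metric.lower() == "fpkm":
        fmat = fpkm(m).values
    elif filter_metric == "count":
        fmat = m.values
    else:
        raise ParameterError(f"unknown filter metric {filter_metric!r}")
    if filter_mode == "mean":
        fstat = fmat.mean(axis=1)
    elif filter_mode == "min":
        fstat = fmat.min(axis=1)
    else:
        raise ParameterError(f"unknown filter mode {filter_mode!r}")
    passing = fstat > filter_threshold

    xs = m.values[sham].to_numpy(dtype=float)
    ys = m.values[tac].to_numpy(dtype=float)
    mean_s = xs.mean(axis=1)
    mean_t = ys.mean(axis=1)
    ps = mean_s + pseudocount
    pt = mean_t + pseudocount
    fold = np.maximum(pt / ps, ps / pt)
    direction = np.where(pt >= ps, "up", "down")
    log2fc = np.log2(pt / ps)

    # vectorized Student's t with the same degenerate-case policy as
    # two_sample_t (checked for agreement in the test suite)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = stats.ttest_ind(xs, ys, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(tstat)
    if degenerate.any():
        same = degenerate & (mean_s == mean_t)
        diff = degenerate & (mean_s != mean_t)
        with np.errstate(invalid="ignore"):
            tstat = np.where(same, 0.0, tstat)
            pval = np.where(same, 1.0, pval)
            tstat = np.where(diff, np.sign(mean_s - mean_t) * np.inf, tstat)
            pval = np.where(diff, 0.0, pval)

    qval = np.full_like(pval, np.nan)
    qval[passing] = _bh_qvalues(pval[passing])

    status = np.full(m.values.shape[0], "unchanged", dtype=object)
    sig = passing & (fold > fc_threshold) & (pval < alpha)
    status[sig] = direction[sig]
    status[~passing] = "filtered"

    return pd.DataFrame(
        {
            "mean_sham": mean_s,
            "mean_tac": mean_t,
            "fold_change": fold,
            "direction": direction,
            "log2fc": log2fc,
            "p_value": pval,
            "q_value": qval,
            "status": status,
        },
        index=m.values.index.rename("feature_id"),
    )


def asymmetry_summary(results: pd.DataFrame) -> tuple[int, int, float]:
    """Count up/down calls and the down/up ratio.

    The ratio is inf when there are down calls but no up calls, and NaN
    when there are no significant calls at all.
    """
    n_up = int((results["status"] == "up").sum())
    n_down = int((results["status"] == "down").sum())
    if n_up == 0:
        ratio = float("nan") if n_down == 0 else float("inf")
    else:
        ratio = n_down / n_up
    return n_up, n_down, ratio
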