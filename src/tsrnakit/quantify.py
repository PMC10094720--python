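"""CPM normalisation, differential screening, and qPCR relative quantification.

Abundance is expressed as counts per million of total aligned reads (CPM):
``cpm = count / aligned_total * 1e6``, where the denominator counts every
aligned read in the sample, classified or not. Differential fragments are
screened with a fold-change gate on CPM group means (pseudocount 1) combined
with a two-sided Welch t-test on log2(CPM+1); the default gates are
fold change >= 1.5 in either direction and p <= 0.05, without multiple-testing
correction (Benjamini-Hochberg is available behind ``adjust=True``). The test
is pluggable so an exact negative-binomial test can be substituted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_P_THRESHOLD = 0.05
CPM_PSEUDOCOUNT = 1.0


@dataclass
class CountMatrix:
    """Fragment x sample count matrix with CPM denominators.

    ``aligned_totals`` may exceed the per-sample column sums: unclassified
    aligned reads contribute to the denominator but have no row.
    """

    counts: pd.DataFrame
    aligned_totals: pd.Series
    conditions: pd.Series

    def validate(self) -> None:
        if list(self.counts.columns) != list(self.aligned_totals.index):
            raise ValueError("counts columns and aligned_totals index differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        short = self.aligned_totals < self.counts.sum(axis=0)
        if short.any():
            raise ValueError(
                f"aligned_totals below classified column sums for: "
                f"{list(self.aligned_totals.index[short])}"
            )

    def cpm(self) -> pd.DataFrame:
        return cpm(self.counts, self.aligned_totals)


def cpm(counts: pd.DataFrame, aligned_totals: pd.Series) -> pd.DataFrame:
    """Counts per million of total aligned reads, per sample."""
    totals = aligned_totals.reindex(counts.columns)
    if totals.isna().any():
        missing = [s for s in counts.columns if s not in aligned_totals.index]
        raise ValueError(f"no aligned total for samples: {missing}")
    bad = totals[totals <= 0]
    if len(bad):
        raise ValueError(f"zero aligned total for samples: {list(bad.index)}")
    return counts.div(totals, axis=1) * 1e6


def welch_log_t(log_a: np.ndarray, log_b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test p-values per row of two log-expression blocks."""
    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    return np.asarray(result.pvalue)


def differential(
    cpm_df: pd.DataFrame,
    groups: Mapping[str, str],
    condition_a: str,
    condition_b: str,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    adjust: bool = False,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] = welch_log_t,
) -> pd.DataFrame:
    """Screen fragments differential between two conditions (B over A).

    Fold change is ``(mean_cpm_B + 1) / (mean_cpm_A + 1)``; a fragment is
    significant iff the fold change in either direction reaches
    ``fc_threshold`` and the test p-value is within ``p_threshold``. Rows
    absent (zero CPM) in every sample are excluded with a log entry. Groups
    with zero within-group variance but unequal means get p = 0 (degenerate t,
    deterministic and conservative for simulated fixtures); equal constant
    groups get p = 1.
    """
    a_cols = [s for s in cpm_df.columns if groups[s] == condition_a]
    b_cols = [s for s in cpm_df.columns if groups[s] == condition_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("differential screening needs >= 2 replicates per group")

    present = cpm_df[a_cols + b_cols].sum(axis=1) > 0
    dropped = int((~present).sum())
    if dropped:
        logger.info("differential: excluded %d all-zero fragments", dropped)
    data = cpm_df.loc[present]

    A = data[a_cols].to_numpy(dtype=float)
    B = data[b_cols].to_numpy(dtype=float)
    log_a = np.log2(A + 1.0)
    log_b = np.log2(B + 1.0)
    p_values = test(log_a, log_b)

    var_a = log_a.var(axis=1)
    var_b = log_b.var(axis=1)
    degenerate = (var_a == 0) & (var_b == 0)
    mean_diff = log_b.mean(axis=1) - log_a.mean(axis=1)
    n_forced = int((degenerate & (mean_diff != 0)).sum())
    if n_forced:
        logger.warning(
            "differential: %d fragments with zero within-group variance and "
            "unequal means; p set to 0",
            n_forced,
        )
    p_values = np.where(degenerate, np.where(mean_diff == 0, 1.0, 0.0), p_values)

    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    fc = (mean_b + CPM_PSEUDOCOUNT) / (mean_a + CPM_PSEUDOCOUNT)
    log2fc = np.log2(fc)
    fc_magnitude = np.maximum(fc, 1.0 / fc)

    p_screen = p_values
    out = pd.DataFrame(
        {
            "name": data.index,
            "mean_cpm_a": mean_a,
            "mean_cpm_b": mean_b,
            "log2fc": log2fc,
            "p_value": p_values,
        }
    ).set_index("name")
    if adjust:
        out["p_adjusted"] = stats.false_discovery_control(np.clip(p_values, 0, 1))
        p_screen = out["p_adjusted"].to_numpy()
    significant = (fc_magnitude >= fc_threshold) & (p_screen <= p_threshold)
    out["significant"] = significant
    out["direction"] = np.where(
        ~significant, "ns", np.where(log2fc > 0, "up", "down")
    )
    return out


def expressed_set(
    cpm_df: pd.DataFrame,
    samples: Sequence[str],
    min_cpm: float = 1.0,
    min_replicates: Optional[int] = None,
) -> set:
    """Fragments expressed in a condition: CPM >= ``min_cpm`` in at least
    ``min_replicates`` of its samples (default: a majority)."""
    if not samples:
        raise ValueError("expressed_set needs at least one sample")
    if min_replicates is None:
        min_replicates = math.ceil(len(samples) / 2)
    sub = cpm_df[list(samples)]
    enough = (sub >= min_cpm).sum(axis=1) >= min_replicates
    return set(sub.index[enough])


def ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl).
    """
    for value in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(value):
            raise ValueError("Ct values must be finite")
    delta_delta = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-delta_delta)
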