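"""Cohort-level comparison of co-localization between two groups.

Two readouts, mirroring how such cohorts are scored:

* frequency of co-localization — the fraction of nuclei with a positive
  binary call, compared between groups with a two-sided Fisher's exact
  test on the 2x2 contingency table;
* mean per-nucleus PCC, compared with a classic equal-variance two-sample
  Student's t-test (df = n_a + n_b - 2).

Both tests are two-sided and evaluated at alpha = 0.01 by default. Nuclei
with an undefined PCC stay in the frequency counts but are excluded from
the mean-PCC comparison; nuclei whose segmentation failed are excluded
from both (they contribute no measurement). No multiple-testing
correction is applied — comparisons are single pairwise contrasts and raw
p-values are reported alongside the significance flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ParameterError
from .metrics import STATUS_SEGMENTATION_FAILED, ColocRecord

__all__ = [
    "GroupComparison",
    "fisher_exact_2x2",
    "students_t_two_sample",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupComparison:
    """Frequencies, mean PCCs and both significance tests for one contrast.

    ``pcc_test_available`` is False when either group has fewer than two
    defined PCC values (or zero pooled variance); the frequency comparison
    is still reported.
    """

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    k_a: int
    k_b: int
    freq_a: float
    freq_b: float
    fisher_p: float
    alpha: float
    significant_freq: bool
    pcc_test_available: bool
    mean_pcc_a: float = math.nan
    mean_pcc_b: float = math.nan
    sd_pcc_a: float = math.nan
    sd_pcc_b: float = math.nan
    t_stat: float = math.nan
    t_p: float = math.nan
    significant_pcc: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def fisher_exact_2x2(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    """Two-sided Fisher's exact p for co-localized counts k out of n.

    Uses the standard two-sided convention: the p-value sums the
    hypergeometric probabilities (margins fixed) of every table at most as
    probable as the observed one.
    """
    for name, k, n in (("a", k_a, n_a), ("b", k_b, n_b)):
        if n < 1:
            raise ParameterError(f"n_{name}: must be >= 1")
        if not (0 <= k <= n):
            raise ParameterError(f"k_{name}: must satisfy 0 <= k <= n")
    table = [[k_a, n_a - k_a], [k_b, n_b - k_b]]
    p = sps.fisher_exact(table, alternative="two-sided").pvalue
    return float(min(p, 1.0))


def students_t_two_sample(
    pcc_a: Sequence[float], pcc_b: Sequence[float]
) -> tuple[float, float]:
    """Equal-variance two-sample t-test on per-nucleus PCC values.

    Returns (t statistic, two-sided p) with df = n_a + n_b - 2. Swapping
    the groups negates t and leaves p unchanged.
    """
    a = np.asarray(pcc_a, dtype=float)
    b = np.asarray(pcc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("students_t_two_sample: need >= 2 values per group")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
    if pooled == 0.0:
        raise ParameterError("students_t_two_sample: zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _defined_pccs(records: Sequence[ColocRecord]) -> list[float]:
    return [r.pcc for r in records if r.pcc is not None]


def compare_groups(
    records: Sequence[ColocRecord],
    group_a: str,
    group_b: str,
    alpha: float = 0.01,
) -> GroupComparison:
    """Assemble counts and run both tests for one two-group contrast."""
    if not (0 < alpha < 1):
        raise ParameterError("alpha: must be in (0, 1)")
    groups: dict[str, list[ColocRecord]] = {group_a: [], group_b: []}
    for rec in records:
        if rec.group_label in groups and rec.status != STATUS_SEGMENTATION_FAILED:
            groups[rec.group_label].append(rec)
    for label in (group_a, group_b):
        if not groups[label]:
            raise ParameterError(
                f"group label {label!r}: no analyzable records in input"
            )

    recs_a, recs_b = groups[group_a], groups[group_b]
    n_a, n_b = len(recs_a), len(recs_b)
    k_a = sum(r.coloc_call for r in recs_a)
    k_b = sum(r.coloc_call for r in recs_b)
    fisher_p = fisher_exact_2x2(k_a, n_a, k_b, n_b)

    pcc_a, pcc_b = _defined_pccs(recs_a), _defined_pccs(recs_b)
    fields = dict(
        group_a=group_a, group_b=group_b,
        n_a=n_a, n_b=n_b, k_a=k_a, k_b=k_b,
        freq_a=k_a / n_a, freq_b=k_b / n_b,
        fisher_p=fisher_p, alpha=alpha,
        significant_freq=fisher_p < alpha,
        pcc_test_available=False,
    )
    if len(pcc_a) >= 1:
        fields["mean_pcc_a"] = float(np.mean(pcc_a))
        fields["sd_pcc_a"] = float(np.std(pcc_a, ddof=1)) if len(pcc_a) > 1 else math.nan
    if len(pcc_b) >= 1:
        fields["mean_pcc_b"] = float(np.mean(pcc_b))
        fields["sd_pcc_b"] = float(np.std(pcc_b, ddof=1)) if len(pcc_b) > 1 else math.nan
    if len(pcc_a) >= 2 and len(pcc_b) >= 2:
        try:
            t_stat, t_p = students_t_two_sample(pcc_a, pcc_b)
        except ParameterError:
            pass  # zero pooled variance: PCC comparison unavailable
        else:
            fields.update(
                pcc_test_available=True,
                t_stat=t_stat, t_p=t_p,
                significant_pcc=t_p < alpha,
            )
    return GroupComparison(**fields)
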