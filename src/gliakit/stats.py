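"""Two-level comparison scheme for nested culture experiments.

Observations come in two layers: technical replicates (individual cells or
image fields within a culture) and independent experiments (donors).  The
scheme implemented here mirrors common practice for such data:

* technical level — a normality-gated two-group test (Shapiro-Wilk on each
  group with the asymmetric gate p < 0.1; both normal → two-sample t-test,
  otherwise Mann-Whitney), plain Wilcoxon rank-sum for multi-group pairwise
  contrasts, and a 2×2 chi-square for responder proportions;
* donor level — per-donor medians of each group compared with a paired
  t-test across donors, which respects the nesting without a mixed model.

Mann-Whitney and "Wilcoxon rank-sum" are the same test (tie-corrected,
exact for small samples via scipy's automatic method selection).  Pairwise
contrasts are reported unadjusted by default; Holm adjustment is available
but off, and the choice is recorded in the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
NORMALITY_GATE_P = 0.1


@dataclass
class GroupSample:
    """Observations of one group, optionally tagged with donor ids."""

    label: str
    values: np.ndarray
    donor_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError(f"group {self.label!r} has no observations")
        if self.donor_ids is not None:
            self.donor_ids = np.asarray(self.donor_ids)
            if len(self.donor_ids) != len(self.values):
                raise ValueError("donor_ids must align with values")

    def donor_medians(self) -> pd.Series:
        if self.donor_ids is None:
            raise ValueError(f"group {self.label!r} carries no donor ids")
        return pd.Series(self.values).groupby(pd.Series(self.donor_ids)).median()


@dataclass
class TestResult:
    """One group contrast: statistic, p-value, and bookkeeping."""

    contrast: str
    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    details: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)


def _clean(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def rank_sum_test(a: GroupSample, b: GroupSample) -> TestResult:
    """Wilcoxon rank-sum / Mann-Whitney U, two-sided, tie-corrected.

    scipy selects the exact null distribution for small untied samples and
    the tie-corrected normal approximation otherwise.
    """
    x, y = _clean(a.values), _clean(b.values)
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(
        contrast=f"{a.label} vs {b.label}",
        test_name="Mann-Whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(x), len(y)),
    )


def two_group_test(a: GroupSample, b: GroupSample, gate_p: float = NORMALITY_GATE_P) -> TestResult:
    """Normality-gated two-group comparison.

    Shapiro-Wilk is run on each group; when both yield p > ``gate_p``
    (default 0.1) the groups are treated as normal and a two-sample t-test
    is used, otherwise Mann-Whitney.  The gate decision and both normality
    p-values are recorded in ``details``.
    """
    x, y = _clean(a.values), _clean(b.values)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 observations for the normality gate")
    sw_a = sps.shapiro(x)
    sw_b = sps.shapiro(y)
    normal = sw_a.pvalue > gate_p and sw_b.pvalue > gate_p
    if normal:
        res = sps.ttest_ind(x, y)
        name = "two-sample t"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        name = "Mann-Whitney"
    return TestResult(
        contrast=f"{a.label} vs {b.label}",
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(x), len(y)),
        details={
            "shapiro_p": (float(sw_a.pvalue), float(sw_b.pvalue)),
            "normality_gate_p": gate_p,
            "gate_selected": "t" if normal else "rank",
        },
    )


def pairwise_rank_sum(
    groups: list[GroupSample] | dict[str, GroupSample],
    contrasts: list[tuple[str, str]],
    holm: bool = False,
) -> list[TestResult]:
    """Rank-sum test for each named contrast.

    P-values are unadjusted by default, matching the convention of
    reporting each contrast on its own; pass ``holm=True`` for a Holm
    step-down adjustment (adjusted p stored next to the raw one).
    """
    by_label = (
        {g.label: g for g in groups} if not isinstance(groups, dict) else dict(groups)
    )
    results = []
    for first, second in contrasts:
        for label in (first, second):
            if label not in by_label:
                raise KeyError(f"contrast references unknown group {label!r}")
        results.append(rank_sum_test(by_label[first], by_label[second]))
    if holm:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.p_value for r in results], method="holm")[1]
        for r, p_adj in zip(results, adj):
            r.details["p_holm"] = float(p_adj)
            r.details["adjustment"] = "holm"
    else:
        for r in results:
            r.details["adjustment"] = "none"
    return results


def proportion_chi_square(
    k1: int, n1: int, k2: int, n2: int, correction: bool = False
) -> TestResult:
    """Chi-square test on a 2×2 responder table.

    ``correction`` toggles the Yates continuity correction; the default is
    the plain Pearson chi-square, which is calibrated at these sample sizes
    (Yates is conservative).  Tables with a zero margin have undefined
    expected frequencies and raise.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined for a table with a zero margin")
    res = sps.chi2_contingency(table, correction=correction)
    return TestResult(
        contrast="proportions",
        test_name="chi-square",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(n1, n2),
        details={"k": (k1, k2), "yates_correction": correction},
    )


def donor_level_paired_test(a: GroupSample, b: GroupSample) -> TestResult:
    """Paired t-test on per-donor medians.

    Each donor contributes one median per group; the paired t-test across
    donors is the donor-level comparison.  Donors present in only one group
    make pairing impossible and raise (naming the donor).  The medians are
    returned in ``details`` for plotting.
    """
    med_a, med_b = a.donor_medians(), b.donor_medians()
    missing = set(med_a.index).symmetric_difference(med_b.index)
    if missing:
        raise ValueError(f"donor(s) {sorted(map(str, missing))} missing from one group")
    if len(med_a) < 2:
        raise ValueError("paired t-test needs at least 2 donors")
    donors = sorted(med_a.index)
    x, y = med_a[donors].to_numpy(), med_b[donors].to_numpy()
    if np.allclose(x, y):
        t_stat, p = 0.0, 1.0
    else:
        res = sps.ttest_rel(x, y)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return TestResult(
        contrast=f"{a.label} vs {b.label}",
        test_name="paired t",
        statistic=t_stat,
        p_value=p,
        n=(len(donors),),
        details={
            "donors": [str(d) for d in donors],
            "medians": {a.label: x.tolist(), b.label: y.tolist()},
        },
    )


def percent_change(reference: float, treated: float) -> float:
    """Signed percent change from ``reference`` to ``treated``, one decimal."""
    if reference == 0:
        raise ValueError("percent change undefined for a zero reference")
    return round((treated - reference) / reference * 100.0, 1)


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contrast": r.contrast,
                "test": r.test_name,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.significant,
                "n": "/".join(map(str, r.n)),
                **{k: v for k, v in r.details.items() if np.isscalar(v)},
            }
            for r in results
        ]
    )
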