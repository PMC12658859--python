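"""Cross-instrument statistical comparison layer.

Replicate medians from the two modes are compared with a two-sided
two-sample Student's t test (pooled variance; Welch by flag), and the full
per-cell mass distributions with the Mann–Whitney U test — exact
enumeration for small samples, tie-corrected normal approximation
otherwise — with optional Tukey 1.5*IQR outlier removal per sample.
``build_report`` assembles both views, the mean of medians and box-plot
summary data into one reproducible report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CellQuantResult, mean_of_medians

EXACT_LIMIT = 8  # exact Mann–Whitney enumeration up to this per-group size


def tukey_outlier_mask(x: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean mask of points inside [Q1 - k*IQR, Q3 + k*IQR]."""
    x = np.asarray(x, dtype=float)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x >= q1 - k * iqr) & (x <= q3 + k * iqr)


def _apply_policy(x: np.ndarray, policy: str) -> np.ndarray:
    if policy == "none":
        return np.asarray(x, dtype=float)
    if policy == "tukey_1.5iqr":
        x = np.asarray(x, dtype=float)
        return x[tukey_outlier_mask(x)]
    raise ValueError(f"unknown outlier policy {policy!r}")


def t_test_medians(
    medians_a: Sequence[float],
    medians_b: Sequence[float],
    equal_var: bool = True,
    paired: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t test on replicate medians.

    Pooled-variance (classic Student's) by default; Welch with
    ``equal_var=False``; paired for matched replicates.
    """
    a = np.asarray(medians_a, dtype=float)
    b = np.asarray(medians_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if paired:
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t) and np.mean(a) == np.mean(b):
        # zero variance in both groups with equal means: no difference
        t, p = 0.0, 1.0
    return t, p


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    outlier_policy: str = "none",
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U on full per-cell distributions.

    Exact null enumeration when both groups have at most ``EXACT_LIMIT``
    observations and no ties; tie-corrected normal approximation (with
    continuity correction) otherwise.  ``outlier_policy`` is applied per
    sample before testing ('none' or 'tukey_1.5iqr').
    """
    a = _apply_policy(np.asarray(sample_a, dtype=float), outlier_policy)
    b = _apply_policy(np.asarray(sample_b, dtype=float), outlier_policy)
    if a.size == 0 or b.size == 0:
        raise ValueError("sample empty after outlier removal")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size <= EXACT_LIMIT and b.size <= EXACT_LIMIT and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def boxplot_summary(x: np.ndarray) -> dict[str, float]:
    """Quartiles and Tukey whiskers for box-plot rendering."""
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    inside = x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]
    return {
        "q1": float(q1), "median": float(med), "q3": float(q3),
        "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
        "n": int(x.size),
    }


@dataclass
class ComparisonReport:
    """Cross-mode comparison of per-cell element masses."""

    element: str
    medians_sc: list[float]
    medians_cytof: list[float]
    mean_of_medians_sc: float
    mean_of_medians_cytof: float
    n_events_sc: int
    n_events_cytof: int
    outlier_policy: str
    t_statistic: float | None
    t_pvalue: float | None
    u_statistic: float
    u_pvalue: float
    u_statistic_outliers_removed: float
    u_pvalue_outliers_removed: float
    alpha: float = 0.05
    boxplot: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_markdown(self) -> str:
        lines = [
            f"# Cross-mode comparison — {self.element}",
            "",
            f"| quantity | SC-ICP-MS | CyTOF |",
            f"|---|---|---|",
            f"| replicates | {len(self.medians_sc)} | {len(self.medians_cytof)} |",
            f"| events | {self.n_events_sc} | {self.n_events_cytof} |",
            f"| mean of medians (fg) | {self.mean_of_medians_sc:.4g} | "
            f"{self.mean_of_medians_cytof:.4g} |",
            "",
        ]
        if self.t_pvalue is not None:
            verdict = "significant" if self.t_pvalue < self.alpha else "not significant"
            lines.append(f"Student's t on replicate medians: t = {self.t_statistic:.3g}, "
                         f"p = {self.t_pvalue:.3g} ({verdict} at {self.alpha:.0%}).")
        else:
            lines.append("Student's t on replicate medians: not applicable "
                         "(fewer than 2 replicates per mode).")
        verdict = "significant" if self.u_pvalue < self.alpha else "not significant"
        lines.append(f"Mann–Whitney U on full distributions: U = {self.u_statistic:.4g}, "
                     f"p = {self.u_pvalue:.3g} ({verdict}).")
        verdict = ("significant" if self.u_pvalue_outliers_removed < self.alpha
                   else "not significant")
        lines.append(f"After outlier removal ({self.outlier_policy}): "
                     f"U = {self.u_statistic_outliers_removed:.4g}, "
                     f"p = {self.u_pvalue_outliers_removed:.3g} ({verdict}).")
        for note in self.notes:
            lines.append(f"_{note}_")
        return "\n".join(lines)

    def boxplot_csv(self) -> str:
        df = pd.DataFrame(self.boxplot).T
        df.index.name = "mode"
        return df.to_csv()


def build_report(
    sc: Sequence[CellQuantResult],
    cytof: Sequence[CellQuantResult],
    outlier_policy: str = "tukey_1.5iqr",
    alpha: float = 0.05,
    paired: bool = False,
    equal_var: bool = True,
) -> ComparisonReport:
    """Assemble the full cross-instrument comparison for one element.

    Requires at least one replicate per mode; the t test on medians is
    skipped (with a note) when either mode has a single replicate.  The
    U test is run on the pooled full distributions both as-is and after
    per-sample outlier removal.
    """
    if not sc or not cytof:
        raise ValueError("need at least one replicate per mode")
    elements = {r.element for r in sc} | {r.element for r in cytof}
    if len(elements) != 1:
        raise ValueError(f"element label mismatch between modes: {sorted(elements)}")
    element = elements.pop()

    med_sc = [r.median_fg for r in sc]
    med_cy = [r.median_fg for r in cytof]
    all_sc = np.concatenate([r.masses_fg for r in sc])
    all_cy = np.concatenate([r.masses_fg for r in cytof])

    notes: list[str] = []
    if len(med_sc) >= 2 and len(med_cy) >= 2:
        t_stat, t_p = t_test_medians(med_sc, med_cy, equal_var=equal_var, paired=paired)
    else:
        t_stat = t_p = None
        notes.append("t test on medians not applicable with a single replicate")

    u_stat, u_p = mann_whitney_u(all_sc, all_cy, outlier_policy="none")
    u_stat_clean, u_p_clean = mann_whitney_u(all_sc, all_cy, outlier_policy=outlier_policy)

    return ComparisonReport(
        element=element,
        medians_sc=med_sc,
        medians_cytof=med_cy,
        mean_of_medians_sc=mean_of_medians(sc),
        mean_of_medians_cytof=mean_of_medians(cytof),
        n_events_sc=int(all_sc.size),
        n_events_cytof=int(all_cy.size),
        outlier_policy=outlier_policy,
        t_statistic=t_stat,
        t_pvalue=t_p,
        u_statistic=u_stat,
        u_pvalue=u_p,
        u_statistic_outliers_removed=u_stat_clean,
        u_pvalue_outliers_removed=u_p_clean,
        alpha=alpha,
        boxplot={"sc_icpms": boxplot_summary(all_sc), "cytof": boxplot_summary(all_cy)},
        notes=notes,
    )
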