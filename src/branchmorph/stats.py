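"""Group-comparison decision tree and correlation reporting.

The selection procedure: Shapiro–Wilk normality on each group (on the
paired differences for paired designs); any non-normal group routes to
the Wilcoxon rank-sum (unpaired) or signed-rank (paired) test; normal
unpaired data is gated by Levene's test into Student's t (equal
variances) or Welch's t; normal paired data uses the paired t test.
Bonferroni correction multiplies p by the number of comparisons, capped
at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .datatypes import InputError, ParameterError

__all__ = ["ComparisonResult", "compare_groups", "pearson_fit"]


@dataclass
class ComparisonResult:
    chosen_test: str
    statistic: float
    p_value: float
    p_adjusted: float
    n_comparisons: int
    normality_p: dict[str, float]
    variance_p: float | None
    decisions: list[str] = field(default_factory=list)


def _is_degenerate(x: np.ndarray) -> bool:
    return np.allclose(x, x[0])


def compare_groups(
    x,
    y,
    paired: bool = False,
    alpha_gate: float = 0.05,
    n_comparisons: int = 1,
) -> ComparisonResult:
    """Compare two samples with the normality/variance decision tree."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise InputError("each sample needs n >= 3")
    if paired and x.size != y.size:
        raise InputError("paired comparison needs equal sample sizes")
    if not 0 < alpha_gate < 1:
        raise ParameterError("alpha_gate must be in (0, 1)")
    if n_comparisons < 1:
        raise ParameterError("n_comparisons must be >= 1")

    log: list[str] = []
    normality: dict[str, float] = {}
    variance_p: float | None = None

    if paired:
        diffs = x - y
        if _is_degenerate(diffs):
            log.append("paired differences degenerate -> forced nonparametric")
            normal = False
            normality["differences"] = float("nan")
        else:
            p_norm = float(sps.shapiro(diffs).pvalue)
            normality["differences"] = p_norm
            normal = p_norm >= alpha_gate
            log.append(
                f"shapiro(differences) p={p_norm:.4g} -> "
                f"{'normal' if normal else 'non-normal'}"
            )
        if normal:
            chosen = "paired_t"
            res = sps.ttest_rel(x, y)
        else:
            chosen = "wilcoxon_signed_rank"
            if np.allclose(x, y):
                res = type("R", (), {"statistic": 0.0, "pvalue": 1.0})
                log.append("identical paired samples -> p = 1")
            else:
                res = sps.wilcoxon(x, y)
    else:
        degenerate = _is_degenerate(x) or _is_degenerate(y)
        if degenerate:
            log.append("constant sample -> forced nonparametric")
            normal = False
            normality["x"] = normality["y"] = float("nan")
        else:
            px = float(sps.shapiro(x).pvalue)
            py = float(sps.shapiro(y).pvalue)
            normality["x"], normality["y"] = px, py
            normal = (px >= alpha_gate) and (py >= alpha_gate)
            log.append(
                f"shapiro p=({px:.4g}, {py:.4g}) -> "
                f"{'both normal' if normal else 'non-normal'}"
            )
        if normal:
            variance_p = float(sps.levene(x, y).pvalue)
            equal_var = variance_p >= alpha_gate
            log.append(
                f"levene p={variance_p:.4g} -> "
                f"{'equal' if equal_var else 'unequal'} variances"
            )
            if equal_var:
                chosen = "student_t"
                res = sps.ttest_ind(x, y, equal_var=True)
            else:
                chosen = "welch_t"
                res = sps.ttest_ind(x, y, equal_var=False)
        else:
            chosen = "wilcoxon_rank_sum"
            if np.array_equal(np.sort(x), np.sort(y)):
                res = type("R", (), {"statistic": 0.0, "pvalue": 1.0})
                log.append("identical samples -> p = 1")
            else:
                res = sps.ranksums(x, y)

    p = float(res.pvalue)
    p_adj = min(1.0, n_comparisons * p)
    log.append(f"chosen {chosen}; p={p:.4g}, bonferroni m={n_comparisons} -> {p_adj:.4g}")
    return ComparisonResult(
        chosen_test=chosen,
        statistic=float(res.statistic),
        p_value=p,
        p_adjusted=p_adj,
        n_comparisons=n_comparisons,
        normality_p=normality,
        variance_p=variance_p,
        decisions=log,
    )


def pearson_fit(x, y) -> dict:
    """Pearson correlation plus a least-squares linear fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise InputError("need matched samples with n >= 3")
    if _is_degenerate(x) or _is_degenerate(y):
        raise InputError("constant input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return {
        "R": float(r),
        "p_value": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": int(x.size),
    }
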