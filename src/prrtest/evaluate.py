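"""False-positive-rate and power metrics for differential-abundance tests.

Given one p-value per taxon and the simulation truth ``y*`` (1 for the taxa
with injected signal), four summaries describe a test's operating
characteristics:

* FPR and TPR at a fixed threshold ``gamma`` (0.05 by default), using strict
  inequality ``p < gamma``;
* power@0.05: the TPR at the largest threshold whose *empirical* FPR does
  not exceed 0.05 -- the power a practitioner would get if the threshold
  could be calibrated against the (normally unknowable) truth;
* AUC@0.10: the area under the ROC curve up to FPR = 0.10.  The default
  normalization divides by the maximum attainable area ``max_fpr``, so a
  perfect test scores 1 and a chance-level ranking ``max_fpr / 2`` = 0.05;
  a McClish-standardized variant that instead maps chance to 0.5 is
  available via ``standardized=True``.

``summarize_repetitions`` aggregates per-repetition metrics into the
mean (+/- standard error) rows of a model-comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = [
    "MetricsResult",
    "fpr_tpr",
    "power_at_fpr",
    "auc_at_fpr",
    "compute_metrics",
    "summarize_repetitions",
]


@dataclass
class MetricsResult:
    """The four operating-characteristic summaries for one p-value vector."""

    fpr: float
    tpr: float
    power_at_fpr05: float
    auc_at_fpr10: float
    gamma: float
    n_null: int
    n_da: int


def _validate(pvalues, truth):
    p = np.asarray(pvalues, dtype=float)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("pvalues and truth must have equal length")
    if not np.isin(t, (0, 1)).all():
        raise ValueError("truth must be binary")
    keep = np.isfinite(p)
    return p[keep], t[keep].astype(bool)


def fpr_tpr(pvalues, truth, gamma: float = 0.05) -> tuple[float, float]:
    """Fractions of null / truly-DA taxa with ``p < gamma``.

    With no null (or no DA) taxa the corresponding rate is undefined and
    reported as NaN rather than zero.  Taxa with missing (NaN) p-values --
    skipped or failed tests -- are excluded from both denominators.
    """
    if not (0.0 < gamma < 1.0):
        raise ValueError("gamma must be in (0, 1)")
    p, t = _validate(pvalues, truth)
    rej = p < gamma
    n_null = int((~t).sum())
    n_da = int(t.sum())
    fpr = float(rej[~t].sum() / n_null) if n_null else float("nan")
    tpr = float(rej[t].sum() / n_da) if n_da else float("nan")
    return fpr, tpr


def power_at_fpr(pvalues, truth, target_fpr: float = 0.05) -> float:
    """TPR at the largest threshold whose empirical FPR stays <= target.

    Achievable thresholds are the sorted null p-values: with strict
    rejection ``p < gamma`` the threshold is set just above the k-th
    smallest null p-value, ``k = floor(target * n_null)``, admitting at
    most k null rejections (ties resolve toward the smaller threshold).
    """
    p, t = _validate(pvalues, truth)
    if not t.any() or t.all():
        raise ValueError("need at least one null and one DA taxon")
    null_p = np.sort(p[~t])
    k = int(np.floor(target_fpr * null_p.size))
    gamma = np.inf if k >= null_p.size else null_p[k]
    return float(np.mean(p[t] < gamma))


def auc_at_fpr(
    pvalues, truth, max_fpr: float = 0.10, standardized: bool = False
) -> float:
    """Partial area under the ROC curve over FPR in [0, max_fpr].

    The ROC is traced by thresholding the p-values (smaller = more
    significant) and the area integrated by the trapezoidal rule with the
    curve interpolated at ``max_fpr``.  Default normalization divides by
    ``max_fpr`` (the maximum attainable area); ``standardized=True`` applies
    the McClish transformation instead, mapping a chance-level ranking to
    0.5 and a perfect one to 1.
    """
    p, t = _validate(pvalues, truth)
    if not t.any() or t.all():
        raise ValueError("need at least one null and one DA taxon")
    fpr, tpr, _ = roc_curve(t.astype(int), -p)
    cut = np.searchsorted(fpr, max_fpr, side="right")
    fx = np.concatenate([fpr[:cut], [max_fpr]])
    tx = np.concatenate([tpr[:cut], [np.interp(max_fpr, fpr, tpr)]])
    area = float(np.trapezoid(tx, fx))
    if not standardized:
        return area / max_fpr
    # McClish (1989) standardization of the partial area
    a_min = max_fpr**2 / 2.0
    a_max = max_fpr
    return 0.5 * (1.0 + (area - a_min) / (a_max - a_min))


def compute_metrics(pvalues, truth, gamma: float = 0.05) -> MetricsResult:
    """All four metrics for one p-value vector."""
    p, t = _validate(pvalues, truth)
    fpr, tpr = fpr_tpr(p, t, gamma)
    return MetricsResult(
        fpr=fpr,
        tpr=tpr,
        power_at_fpr05=power_at_fpr(p, t, 0.05),
        auc_at_fpr10=auc_at_fpr(p, t, 0.10),
        gamma=gamma,
        n_null=int((~t).sum()),
        n_da=int(t.sum()),
    )


def summarize_repetitions(
    results: Sequence[MetricsResult],
    family: Optional[str] = None,
    test_type: Optional[str] = None,
) -> dict:
    """Mean and standard error of each metric over repetitions.

    Returns one table row: ``power``, ``fpr``, ``power_at_0.05`` and
    ``auc_at_0.10`` formatted "mean (+/-se)" to two decimals, plus the raw
    means/SEs for programmatic use.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 repetitions for a standard error")

    def agg(values):
        v = np.asarray(values, dtype=float)
        mean = float(np.nanmean(v))
        se = float(np.nanstd(v, ddof=1) / np.sqrt(np.sum(np.isfinite(v))))
        return mean, se

    row: dict = {}
    if family is not None:
        row["family"] = family
    if test_type is not None:
        row["test_type"] = test_type
    for label, attr in (
        ("power", "tpr"),
        ("fpr", "fpr"),
        ("power_at_0.05", "power_at_fpr05"),
        ("auc_at_0.10", "auc_at_fpr10"),
    ):
        mean, se = agg([getattr(r, attr) for r in results])
        row[label] = f"{mean:.2f} (±{se:.2f})"
        row[f"{label}_mean"] = mean
        row[f"{label}_se"] = se
    return row
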