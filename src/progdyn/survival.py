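"""Score-tertile survival analysis.

Subjects are split into low / intermediate / high groups at the empirical
tertiles of a per-subject enrichment score; survival is summarized by
Kaplan–Meier curves, compared by the k-group log-rank test, and modelled by
Cox proportional hazards (Efron tie handling) in univariate or
covariate-adjusted form. Median follow-up is reported by the reverse
Kaplan–Meier method (censoring-indicator KM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .containers import ValidationError

TERTILE_LABELS = ("low", "intermediate", "high")


def tertile_groups(scores: Sequence[float]) -> pd.Series:
    """Assign each subject to a score tertile (low / intermediate / high).

    Cut points are the empirical 1/3 and 2/3 quantiles (linear-interpolation
    definition); scores ≤ q1 go to 'low', ≤ q2 to 'intermediate', else
    'high' — ties at a cut point fall to the lower group.
    """
    s = pd.Series(scores, dtype=float) if not isinstance(scores, pd.Series) else scores.astype(float)
    if len(s) < 3:
        raise ValidationError("tertiles need at least 3 subjects")
    if s.nunique() == 1:
        raise ValidationError("all scores identical; tertiles undefined")
    q1, q2 = np.quantile(s.to_numpy(), [1 / 3, 2 / 3])
    out = pd.Series(
        np.where(s <= q1, "low", np.where(s <= q2, "intermediate", "high")),
        index=s.index, name="tertile",
    )
    return out


def validate_survival_table(table: pd.DataFrame,
                            time_col: str = "time", event_col: str = "event") -> None:
    for col in (time_col, event_col):
        if col not in table.columns:
            raise ValidationError(f"survival table missing column {col!r}")
    if (table[time_col] <= 0).any():
        raise ValidationError("survival times must be > 0")
    if not table[event_col].isin([0, 1]).all():
        raise ValidationError("event indicator must be 0/1")


@dataclass
class KMLogrankResult:
    curves: Mapping[str, pd.DataFrame]  # group -> KM step function (timeline, survival)
    chi2: float
    p: float
    df: int
    median_followup: float


def km_logrank(table: pd.DataFrame, groups: pd.Series,
               time_col: str = "time", event_col: str = "event") -> KMLogrankResult:
    """Kaplan–Meier curves per group plus the k-group log-rank test.

    The log-rank statistic is the usual observed-minus-expected quadratic
    form with hypergeometric variance, chi-square with k − 1 df. Median
    follow-up uses the reverse Kaplan–Meier estimator (events censored,
    censorings treated as events).
    """
    validate_survival_table(table, time_col, event_col)
    groups = groups.loc[table.index]
    levels = [g for g in pd.unique(groups)]
    if len(levels) < 2:
        raise ValidationError("log-rank needs at least 2 non-empty groups")

    curves = {}
    for level in levels:
        mask = groups == level
        if not mask.any():
            raise ValidationError(f"group {level!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(table.loc[mask, time_col], table.loc[mask, event_col], label=str(level))
        curves[level] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", str(level): "survival"})

    res = multivariate_logrank_test(table[time_col], groups, table[event_col])

    rkm = KaplanMeierFitter()
    rkm.fit(table[time_col], 1 - table[event_col])
    median_fu = float(rkm.median_survival_time_)
    return KMLogrankResult(curves=curves, chi2=float(res.test_statistic),
                           p=float(res.p_value), df=len(levels) - 1,
                           median_followup=median_fu)


def cox_fit(table: pd.DataFrame, covariates: Sequence[str],
            ref_levels: Mapping[str, str] = None,
            time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
    """Cox proportional-hazards fit with Efron tie handling.

    Categorical covariates (object / categorical dtype) are dummy-coded
    against their declared reference level (``ref_levels``, e.g.
    ``{"tertile": "low"}`` so hazard ratios read high-vs-low and
    intermediate-vs-low); numeric covariates enter as-is. Returns one row
    per model term: ``HR``, ``ci_low``, ``ci_high`` (95%, from the observed
    information), ``coef``, ``se``, ``p`` (Wald), and the model's
    likelihood-ratio p in ``global_p``.
    """
    validate_survival_table(table, time_col, event_col)
    if (table[event_col] == 1).sum() < 1:
        raise ValidationError("Cox model needs at least one event")
    ref_levels = dict(ref_levels or {})
    design = table[[time_col, event_col]].copy()
    for cov in covariates:
        if cov not in table.columns:
            raise ValidationError(f"survival table missing covariate {cov!r}")
        col = table[cov]
        if col.dtype.kind in "if":
            design[cov] = col.astype(float)
        else:
            levels = list(pd.unique(col.astype(str)))
            ref = ref_levels.get(cov, sorted(levels)[0])
            if ref not in levels:
                raise ValidationError(f"reference level {ref!r} absent from {cov!r}")
            for level in levels:
                if level == ref:
                    continue
                design[f"{cov}_{level}_vs_{ref}"] = (col.astype(str) == level).astype(float)

    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ValidationError(f"Cox model failed to converge: {exc}") from exc

    summary = cph.summary
    out = pd.DataFrame({
        "term": summary.index,
        "coef": summary["coef"].to_numpy(),
        "se": summary["se(coef)"].to_numpy(),
        "HR": summary["exp(coef)"].to_numpy(),
        "ci_low": summary["exp(coef) lower 95%"].to_numpy(),
        "ci_high": summary["exp(coef) upper 95%"].to_numpy(),
        "p": summary["p"].to_numpy(),
    }).set_index("term")
    out["global_p"] = float(cph.log_likelihood_ratio_test().p_value)
    return out
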