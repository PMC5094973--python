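"""The step-wise enrichment-rate statistic of tumor-progression dynamics.

For a gene set scored per sample (ssGSEA), the stage-level score is the mean
enrichment score over that stage's samples. The enrichment rate at step k
(stage_k vs stage_{k-1}) is

    rate_k = |score(stage_k) - score(stage_{k-1})| / |score(tumor) - score(normal)|,

i.e. the fraction of the total tumor-vs-normal enrichment change acquired at
that step. Rates are reported unnormalized: on a non-monotone stage course
individual rates may exceed 1 and need not sum to 1, although the signed
per-step deltas always telescope exactly to the total delta.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import StageDesign, ValidationError


def enrichment_rate(es: pd.Series, design: StageDesign) -> pd.DataFrame:
    """Per-step enrichment rates of one gene set's per-sample ES.

    Parameters
    ----------
    es
        Per-sample enrichment scores of a single gene set (index = sample
        ids covering every stage of the design).
    design
        Ordered stage design; stage-level scores are replicate means.

    Returns
    -------
    DataFrame with one row per step: ``step``, ``signed_delta``, ``rate``,
    ``total_delta``.
    """
    stage_scores = {}
    for stage in design.stages:
        samples = [s for s in design.samples_for(stage) if s in es.index]
        if not samples:
            raise ValidationError(f"stage {stage!r} has no scored samples")
        stage_scores[stage] = float(es.loc[samples].mean())
    total = stage_scores[design.stages[-1]] - stage_scores[design.stages[0]]
    if total == 0:
        raise ValidationError(
            f"total tumor-vs-normal ES delta is zero for {es.name!r}; "
            "enrichment rates are undefined"
        )
    rows = []
    for later, earlier in design.steps:
        delta = stage_scores[later] - stage_scores[earlier]
        rows.append({
            "step": f"{later}_vs_{earlier}",
            "signed_delta": delta,
            "rate": abs(delta) / abs(total),
            "total_delta": total,
        })
    return pd.DataFrame(rows)


def rate_profile(es_matrix: pd.DataFrame, design: StageDesign,
                 set_names=None) -> pd.DataFrame:
    """Enrichment-rate table for several gene sets scored on the same samples.

    ``es_matrix`` is sets × samples (e.g. the combined EGS/IGS/LGS/PGS
    scores). The step achieving each set's maximal rate is flagged in the
    ``is_max`` column.
    """
    if set_names is None:
        set_names = list(es_matrix.index)
    missing = [n for n in set_names if n not in es_matrix.index]
    if missing:
        raise ValidationError(f"ES matrix missing set(s): {missing}")
    tables = []
    for name in set_names:
        tab = enrichment_rate(es_matrix.loc[name], design)
        tab.insert(0, "set", name)
        tab["is_max"] = tab["rate"] == tab["rate"].max()
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)
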