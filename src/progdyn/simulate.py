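"""Synthetic data generators with the statistical structure the analysis assumes.

The generators emulate, at desk scale, the study designs the pipeline targets:

* a 4-stage (normal → hyperplasia → dysplasia → tumor) × 3-replicate
  expression matrix with planted early / intermediate / late / progressive /
  null genes (``generate_stage_course``);
* a human-like cohort with normal / dysplasia / tumor class labels in which a
  given gene set separates tumor from normal (``generate_cohort``);
* exponential proportional-hazards survival times whose hazard depends on a
  per-subject score (``generate_survival``);
* log-IC50 drug-response vectors with a controlled negative correlation to a
  per-cell-line score (``generate_drug_response``).

All noise is Gaussian on the log2 scale, independent per gene × sample, and
every generator is deterministic given its seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet, StageDesign, ValidationError

#: The ordered histological stages of the stage-course generator.
STAGES = ("normal", "hyperplasia", "dysplasia", "tumor")

ARCHETYPES = ("early", "intermediate", "late", "progressive", "null")

#: Stage-mean profile of each archetype as a multiple of the full effect at
#: stage k = 0..3. Early genes shift fully from hyperplasia onward,
#: intermediate from dysplasia, late at tumor only; progressive genes
#: accumulate linearly (k/3 of the effect), so no single step reaches the
#: full effect.
_ARCHETYPE_PROFILE = {
    "early": np.array([0.0, 1.0, 1.0, 1.0]),
    "intermediate": np.array([0.0, 0.0, 1.0, 1.0]),
    "late": np.array([0.0, 0.0, 0.0, 1.0]),
    "progressive": np.array([0.0, 1 / 3, 2 / 3, 1.0]),
    "null": np.array([0.0, 0.0, 0.0, 0.0]),
}


def _normalize_counts(n_per_archetype: Union[int, Mapping[str, int]]) -> dict:
    if isinstance(n_per_archetype, int):
        counts = {a: n_per_archetype for a in ARCHETYPES}
    else:
        counts = {a: int(n_per_archetype.get(a, 0)) for a in ARCHETYPES}
    for a, n in counts.items():
        if n < 0:
            raise ValidationError(f"negative gene count for archetype {a!r}: {n}")
    return counts


def generate_stage_course(
    n_per_archetype: Union[int, Mapping[str, int]] = 200,
    effect: float = 2.0,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    baseline_range: tuple = (5.0, 10.0),
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a stage-course expression matrix with planted dynamics.

    Parameters
    ----------
    n_per_archetype
        Genes per archetype (int applied to all five, or a mapping).
    effect
        Full tumor-vs-normal shift in log2 units for every non-null gene.
    noise_sd
        SD of the Gaussian noise added independently per gene × sample.
    n_replicates
        Samples per stage (the emulated design uses 3).
    baseline_range
        Per-gene baselines are drawn uniformly from this log2 range.

    Returns
    -------
    (ExpressionMatrix, truth)
        ``truth`` is a DataFrame indexed by gene id with columns
        ``archetype`` and ``direction`` ('up'/'dn', empty for null genes).
    """
    if effect <= 0:
        raise ValidationError("effect must be > 0")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    counts = _normalize_counts(n_per_archetype)
    rng = np.random.default_rng(seed)

    gene_ids, archetypes, signs = [], [], []
    for arch in ARCHETYPES:
        n = counts[arch]
        for i in range(n):
            gene_ids.append(f"{arch}_{i:04d}")
            archetypes.append(arch)
            if arch == "null":
                signs.append(0)
            else:
                signs.append(1 if i < (n + 1) // 2 else -1)  # half up, half dn
    n_genes = len(gene_ids)
    if n_genes == 0:
        raise ValidationError("no genes requested")

    sample_ids = [f"{stage}_{r + 1}" for stage in STAGES for r in range(n_replicates)]
    stage_of_sample = [stage for stage in STAGES for _ in range(n_replicates)]

    baseline = rng.uniform(*baseline_range, size=n_genes)
    profile = np.stack([_ARCHETYPE_PROFILE[a] for a in archetypes])  # genes × 4
    sign = np.asarray(signs, dtype=float)
    stage_means = baseline[:, None] + sign[:, None] * effect * profile  # genes × 4

    stage_index = {s: k for k, s in enumerate(STAGES)}
    mean_matrix = stage_means[:, [stage_index[s] for s in stage_of_sample]]
    noise = rng.normal(0.0, noise_sd, size=mean_matrix.shape) if noise_sd > 0 else 0.0
    values = pd.DataFrame(mean_matrix + noise, index=gene_ids, columns=sample_ids)

    annotation = pd.Series(stage_of_sample, index=sample_ids, name="label")
    truth = pd.DataFrame(
        {
            "archetype": archetypes,
            "direction": ["up" if s > 0 else ("dn" if s < 0 else "") for s in signs],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ExpressionMatrix(values, annotation), truth


def stage_course_design(matrix: ExpressionMatrix) -> StageDesign:
    """The StageDesign implied by a generate_stage_course annotation."""
    return StageDesign(STAGES, matrix.annotation)


def generate_cohort(
    n_normal: int = 45,
    n_dysplasia: int = 17,
    n_tumor: int = 169,
    gene_sets: Union[GeneSet, Sequence[GeneSet]] = None,
    effect: float = 3.0,
    noise_sd: float = 0.5,
    n_background: int = 500,
    seed: int = 0,
    baseline: float = 7.0,
) -> ExpressionMatrix:
    """Simulate a normal/dysplasia/tumor cohort separated by a gene set.

    Member genes of the supplied set(s) are shifted by ±``effect`` in tumor
    samples (sign from the set direction, up if undirected), by half that in
    dysplasia, and not at all in normal samples; ``n_background`` extra null
    genes are appended. Default class sizes mirror a public OSCC cohort
    (45 normal / 17 dysplasia / 169 tumor).
    """
    if gene_sets is None:
        raise ValidationError("gene_sets is required (pass a GeneSet or a sequence)")
    if isinstance(gene_sets, GeneSet):
        gene_sets = [gene_sets]
    members: dict = {}
    for gs in gene_sets:
        s = -1.0 if gs.direction == "dn" else 1.0
        for g in gs.members:
            members[g] = s
    if not members:
        raise ValidationError("gene set has no members")
    for n, lab in ((n_normal, "n_normal"), (n_dysplasia, "n_dysplasia"), (n_tumor, "n_tumor")):
        if n < 0:
            raise ValidationError(f"{lab} must be >= 0")

    rng = np.random.default_rng(seed)
    member_ids = sorted(members)
    gene_ids = member_ids + [f"bg_{i:04d}" for i in range(n_background)]
    sign = np.array([members[g] for g in member_ids] + [0.0] * n_background)

    labels = ["normal"] * n_normal + ["dysplasia"] * n_dysplasia + ["tumor"] * n_tumor
    class_frac = {"normal": 0.0, "dysplasia": 0.5, "tumor": 1.0}
    shift = np.array([class_frac[c] for c in labels])
    sample_ids = [f"{c}_{i + 1}" for c in ("normal", "dysplasia", "tumor")
                  for i in range({"normal": n_normal, "dysplasia": n_dysplasia,
                                  "tumor": n_tumor}[c])]

    mean = baseline + sign[:, None] * effect * shift[None, :]
    noise = rng.normal(0.0, noise_sd, size=mean.shape) if noise_sd > 0 else 0.0
    values = pd.DataFrame(mean + noise, index=gene_ids, columns=sample_ids)
    annotation = pd.Series(labels, index=sample_ids, name="label")
    return ExpressionMatrix(values, annotation)


def generate_survival(
    scores: Sequence[float],
    hr_per_unit: float = 3.0,
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw survival times from an exponential proportional-hazards model.

    Each subject's event hazard is ``baseline_hazard * hr_per_unit**score``;
    censoring is independent exponential at ``censor_rate`` (0 disables it).
    Returns a DataFrame with columns ``time``, ``event``, ``score``.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    if hr_per_unit <= 0:
        raise ValidationError("hr_per_unit must be > 0")
    if baseline_hazard <= 0:
        raise ValidationError("baseline_hazard must be > 0")
    if censor_rate < 0:
        raise ValidationError("censor_rate must be >= 0")
    rng = np.random.default_rng(seed)
    hazard = baseline_hazard * hr_per_unit ** scores
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=len(scores))
    else:
        censor_time = np.full(len(scores), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {"time": time, "event": event, "score": scores},
        index=pd.Index([f"subj_{i + 1}" for i in range(len(scores))], name="subject_id"),
    )


def generate_drug_response(
    scores: Sequence[float],
    r_target: float = 0.6,
    seed: int = 0,
) -> pd.Series:
    """Simulate log-IC50 values negatively correlated with a sample score.

    log-IC50 = -r_target * z(score) + sqrt(1 - r_target^2) * N(0, 1), so the
    expected Pearson correlation with the score is ``-r_target`` (lower IC50
    for higher scores: score-associated drug sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 3:
        raise ValidationError("need at least 3 scores")
    if abs(r_target) > 1:
        raise ValidationError("|r_target| must be <= 1")
    sd = scores.std(ddof=0)
    if sd == 0:
        raise ValidationError("scores are constant; correlation target undefined")
    z = (scores - scores.mean()) / sd
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=len(scores))
    ic50 = -r_target * z + np.sqrt(1.0 - r_target ** 2) * noise
    return pd.Series(ic50, index=[f"cell_{i + 1}" for i in range(len(scores))],
                     name="log_ic50")
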