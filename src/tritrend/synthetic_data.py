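"""Synthetic three-condition proteome datasets with planted trend classes.

Emulates the study design the pipeline targets: three pooled replicate
experiments per condition (healthy H, non-lesional NL, lesional L; each pool
combining three donors), quantified on two channels — log-normal MS1
intensities and overdispersed (negative-binomial) spectral counts — with
completely-at-random missing values.  Every protein is assigned a trend
class and its true per-contrast log2 fold changes are returned alongside the
matrices, so downstream stages can be scored against ground truth.

Planted condition means on the log2 scale (H is the reference; the change
direction is a random sign per protein):

==============  =================================================
null            H = NL = L
lesion_only     H = NL; L shifted by ``effect_log2fc``
intermediate    L shifted by ``effect_log2fc``; NL at
                ``intermediate_position`` of the H-to-L span
group_I         NL = L, both shifted by ``effect_log2fc``
group_II        NL shifted by ``effect_log2fc``; H = L
group_III       NL shifted by ``-effect_log2fc/2`` and L by
                ``+effect_log2fc/2`` (opposite directions)
==============  =================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import AbundanceMatrix, SampleDesign, TriContrast, ContrastCall
from .trend_classify import TrendFlags, classify_trend

CLASS_NAMES = ("null", "intermediate", "group_I", "group_II", "group_III", "lesion_only")

_DEFAULT_PROPORTIONS = {
    "null": 0.30,
    "intermediate": 0.40,
    "group_I": 0.075,
    "group_II": 0.075,
    "group_III": 0.075,
    "lesion_only": 0.075,
}


@dataclass
class SimulationConfig:
    """Parameters of the generator; defaults mirror the emulated study design.

    ``n_replicates`` defaults to 3 (three pooled extraction experiments per
    condition).  ``effect_log2fc`` is the planted |log2 fold change| for the
    differentially expressed classes.  ``noise_sd_log2`` is the replicate
    noise standard deviation on log2 intensities; ``count_dispersion`` is the
    negative-binomial size parameter for spectral counts (smaller = more
    overdispersed).  ``count_scale`` sets the mean spectral count of a
    baseline-abundance protein.
    """

    n_proteins: int = 1000
    n_replicates: int = 3
    class_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    base_abundance: float = 16.0
    baseline_sd_log2: float = 1.5
    effect_log2fc: float = 2.0
    intermediate_position: float = 0.5
    noise_sd_log2: float = 0.3
    count_dispersion: float = 5.0
    count_scale: float = 20.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0 or self.n_replicates <= 0:
            raise ValueError("n_proteins and n_replicates must be positive")
        unknown = set(self.class_proportions) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown class name(s): {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be nonnegative")
        for name in ("baseline_sd_log2", "noise_sd_log2", "count_dispersion",
                     "count_scale", "base_abundance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be nonnegative")
        if not (0 < self.intermediate_position < 1):
            raise ValueError("intermediate_position must be in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one simulated protein."""

    protein_id: str
    trend_class: str
    log2fc_LH: float
    log2fc_NLH: float
    log2fc_NLL: float


def _class_offsets(trend_class: str, effect: float, position: float, sign: float):
    """(H, NL, L) log2 offsets for a planted class."""
    e = sign * effect
    if trend_class == "null":
        return 0.0, 0.0, 0.0
    if trend_class == "lesion_only":
        return 0.0, 0.0, e
    if trend_class == "intermediate":
        return 0.0, position * e, e
    if trend_class == "group_I":
        return 0.0, e, e
    if trend_class == "group_II":
        return 0.0, e, 0.0
    if trend_class == "group_III":
        return 0.0, -e / 2.0, e / 2.0
    raise ValueError(f"unknown class {trend_class!r}")


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[AbundanceMatrix, AbundanceMatrix, list[PlantedTruth]]:
    """Draw one dataset: (intensity matrix, spectral-count matrix, truths).

    Deterministic given ``config.seed``; identical configs produce identical
    matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, r = config.n_proteins, config.n_replicates
    conditions = ("H", "NL", "L")

    names = list(config.class_proportions.keys())
    probs = np.array([config.class_proportions[c] for c in names])
    classes = rng.choice(names, size=n, p=probs)
    signs = rng.choice([-1.0, 1.0], size=n)
    protein_ids = [f"P{str(i + 1).zfill(len(str(n)))}" for i in range(n)]

    baselines = config.base_abundance + rng.normal(0.0, config.baseline_sd_log2, n)

    truths: list[PlantedTruth] = []
    mean_log2 = np.zeros((n, 3))
    for i in range(n):
        h, nl, l = _class_offsets(
            classes[i], config.effect_log2fc, config.intermediate_position, signs[i]
        )
        mean_log2[i] = (h, nl, l)
        truths.append(
            PlantedTruth(
                protein_id=protein_ids[i],
                trend_class=str(classes[i]),
                log2fc_LH=l - h,
                log2fc_NLH=nl - h,
                log2fc_NLL=nl - l,
            )
        )

    sample_ids = [f"{cond}_{j + 1}" for cond in conditions for j in range(r)]
    cond_labels = [cond for cond in conditions for _ in range(r)]
    rep_labels = [f"rep{j + 1}" for _ in conditions for j in range(r)]

    # log2 intensities: baseline + condition offset + replicate noise
    cond_idx = {c: i for i, c in enumerate(conditions)}
    log2_int = np.empty((n, 3 * r))
    for col, cond in enumerate(cond_labels):
        log2_int[:, col] = (
            baselines
            + mean_log2[:, cond_idx[cond]]
            + rng.normal(0.0, config.noise_sd_log2, n)
        )
    intensity = np.power(2.0, log2_int)

    # spectral counts: NB around a mean proportional to the planted abundance
    rel = np.empty((n, 3 * r))
    for col, cond in enumerate(cond_labels):
        rel[:, col] = baselines - config.base_abundance + mean_log2[:, cond_idx[cond]]
    mu = config.count_scale * np.power(2.0, rel)
    size = config.count_dispersion
    counts = rng.negative_binomial(size, size / (size + mu)).astype(float)

    if config.missing_rate > 0:
        intensity[rng.random((n, 3 * r)) < config.missing_rate] = np.nan
        counts[rng.random((n, 3 * r)) < config.missing_rate] = np.nan

    def build(values: np.ndarray, channel: str) -> AbundanceMatrix:
        design = SampleDesign(
            sample_ids=tuple(sample_ids),
            conditions=tuple(cond_labels),
            replicate_ids=tuple(rep_labels),
            channel=channel,
        )
        df = pd.DataFrame(values, index=protein_ids, columns=sample_ids)
        df.index.name = "protein_id"
        return AbundanceMatrix(values=df, design=design)

    return build(intensity, "intensity"), build(counts, "spectral_count"), truths


def truth_to_tricontrast(truth: PlantedTruth, fc_threshold: float = 2.0) -> TriContrast:
    """The contrast triplet a planted protein converges to with many replicates.

    In the infinite-replicate limit every nonzero planted effect reaches an
    arbitrarily small p-value, so the composite significance reduces to the
    fold gate: |log2fc| >= log2(fc_threshold) (inclusive, matching the
    "at least two-fold or higher" rule).
    """
    T = math.log2(fc_threshold)

    def call(l2: float) -> ContrastCall:
        return ContrastCall(fc_ratio=float(2.0**l2), significant=bool(abs(l2) >= T))

    return TriContrast(
        protein_id=truth.protein_id,
        lh=call(truth.log2fc_LH),
        nlh=call(truth.log2fc_NLH),
        nll=call(truth.log2fc_NLL),
    )


def truth_to_expected_flags(truth: PlantedTruth, fc_threshold: float = 2.0) -> TrendFlags:
    """Expected classifier output for a planted truth (noise-free limit).

    Applies exactly the same predicates as the classifier to the planted
    log2 fold changes, with significance given by the inclusive fold gate.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    return classify_trend(truth_to_tricontrast(truth, fc_threshold), fc_threshold)


def expected_flags_frame(
    truths: list[PlantedTruth], fc_threshold: float = 2.0
) -> pd.DataFrame:
    """Expected flag table for a list of planted truths."""
    rows = [truth_to_expected_flags(t, fc_threshold).as_dict() for t in truths]
    return pd.DataFrame(rows).set_index("protein_id")


def flag_precision_recall(
    observed: pd.DataFrame, expected: pd.DataFrame
) -> pd.DataFrame:
    """Per-flag precision/recall of an observed flag table against truth.

    Rows are aligned on protein id; ``None`` flags count as False.  Precision
    and recall are NaN when undefined (no calls / no support).
    """
    expected = expected.loc[observed.index]
    records = []
    for col in ("de_LH", "de_NLH", "de_NLL", "intermediate", "group_I",
                "group_II", "group_III", "lesion_only", "unclassified_divergent"):
        o = observed[col] == True  # noqa: E712
        e = expected[col] == True  # noqa: E712
        tp = int((o & e).sum())
        fp = int((o & ~e).sum())
        fn = int((~o & e).sum())
        records.append(
            {
                "flag": col,
                "support": int(e.sum()),
                "called": int(o.sum()),
                "precision": tp / (tp + fp) if tp + fp else float("nan"),
                "recall": tp / (tp + fn) if tp + fn else float("nan"),
            }
        )
    return pd.DataFrame(records).set_index("flag")


def truths_to_frame(truths: list[PlantedTruth]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "protein_id": [t.protein_id for t in truths],
            "trend_class": [t.trend_class for t in truths],
            "log2fc_LH": [t.log2fc_LH for t in truths],
            "log2fc_NLH": [t.log2fc_NLH for t in truths],
            "log2fc_NLL": [t.log2fc_NLL for t in truths],
        }
    ).set_index("protein_id")
    return df
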