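"""Grid search over rejection-policy parameters and reproducibility scoring.

The harness scores a policy by how well the group-level statistical
inferences it yields (one-tailed one-sample t-tests of region-of-interest
activation, α = 0.025) reproduce a set of expected outcomes — e.g. null
activation before drug administration and after placebo, significant
activation after medication, and a significant medication-minus-placebo
contrast. *Independent* optimization scores every grid cell on every
dataset; *sequential* optimization keeps only the policies optimal on the
training dataset and re-scores those on the validation datasets (a policy is
robust when one threshold set reproduces everything everywhere). Rejection
accuracy against reference labels (e.g. visual inspection, or synthetic
ground truth) breaks ties.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .criteria import Criterion1Config, Criterion2Config, Criterion3Config
from .design import EpochSet
from .power import TestConfig, activation_ttest, epoch_activation
from .reject import UNLIMITED, RejectionPolicy, apply_rejection

__all__ = [
    "ParameterGrid",
    "StatTarget",
    "CohortDataset",
    "synthetic_cohort",
    "reproducibility_score",
    "rejection_accuracy",
    "grid_search",
]

CONDITIONS = ("premedication", "postmedication", "preplacebo", "postplacebo")


@dataclass(frozen=True)
class ParameterGrid:
    """Threshold and policy grid.

    The full published ranges are 0.01–0.05 (step 0.001) for criteria 1 and
    2 and 0–3×IQR (step 0.1) for criterion 3; ``coarse`` thins each range by
    an integer factor for desk-scale runs.
    """

    acceptance_rates: tuple[int | None, ...] = (3, 4, UNLIMITED)
    criteria_subsets: tuple[tuple[int, ...], ...] = tuple(
        s for r in range(0, 4) for s in itertools.combinations((1, 2, 3), r)
    )
    c1_thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.01, 0.0501, 0.001), 3))
    c2_thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.01, 0.0501, 0.001), 3))
    c3_thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.0, 3.01, 0.1), 1))
    coarse: int = 1

    def __post_init__(self) -> None:
        if self.coarse < 1:
            raise ValueError("coarse factor must be >= 1")
        for name in ("c1_thresholds", "c2_thresholds", "c3_thresholds"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} is empty")

    def _thin(self, values: tuple[float, ...]) -> tuple[float, ...]:
        return values[:: self.coarse]

    def n_cells(self) -> int:
        """Exact cell count: |acceptance| x sum over subsets of products."""
        sizes = {1: len(self._thin(self.c1_thresholds)),
                 2: len(self._thin(self.c2_thresholds)),
                 3: len(self._thin(self.c3_thresholds))}
        total = 0
        for subset in self.criteria_subsets:
            prod = 1
            for c in subset:
                prod *= sizes[c]
            total += prod
        return len(self.acceptance_rates) * total

    def policies(self):
        """Yield every RejectionPolicy in the grid."""
        axes = {1: self._thin(self.c1_thresholds),
                2: self._thin(self.c2_thresholds),
                3: self._thin(self.c3_thresholds)}
        for acc in self.acceptance_rates:
            for subset in self.criteria_subsets:
                for combo in itertools.product(*(axes[c] for c in subset)):
                    configs = []
                    for c, thr in zip(subset, combo):
                        if c == 1:
                            configs.append(Criterion1Config(jump_threshold=thr))
                        elif c == 2:
                            configs.append(Criterion2Config(slope_threshold=thr))
                        else:
                            configs.append(Criterion3Config(k_iqr=thr))
                    yield RejectionPolicy(criteria=tuple(configs),
                                          acceptance_rate=acc)


@dataclass(frozen=True)
class StatTarget:
    """One expected group-level inference."""

    group: str  # e.g. "preadministration", "postmedication", "intermedication"
    expected: str  # "significant" | "not_significant"
    alpha: float = 0.025
    tail: str = "one"

    def __post_init__(self) -> None:
        if self.expected not in ("significant", "not_significant"):
            raise ValueError("expected must be 'significant' or 'not_significant'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class CohortDataset:
    """One study dataset: per-subject epoch sets per condition.

    ``subjects`` maps subject id -> {condition -> EpochSet} where the epoch
    sets hold the ROI-pooled signal, already preprocessed and
    baseline-normalized. ``reference`` optionally holds per-subject boolean
    rejection labels (per condition) for accuracy scoring.
    """

    name: str
    subjects: dict[str, dict[str, EpochSet]]
    task: str = "OB"
    reference: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def conditions(self) -> set[str]:
        return {c for conds in self.subjects.values() for c in conds}


def synthetic_cohort(name: str = "training",
                     condition_means: Mapping[str, float] | None = None,
                     n_subjects: int = 8,
                     *,
                     ratio: float = 2.0,
                     snr_db: float = 10.0,
                     with_noise: bool = False,
                     task: str = "OB",
                     seed: int = 0) -> CohortDataset:
    """Build a synthetic cohort with known per-condition activation means.

    ``condition_means`` maps condition name -> boxcar amplitude mean (0 for a
    null condition, where the amplitude draw is degenerate at zero). The
    default emulates a medication study: null pre-administration and
    post-placebo activation, positive post-medication activation. Epoch sets
    come out preprocessed and baseline-normalized, with ground-truth noisy
    trials stored as reference labels when ``with_noise`` is set.
    """
    from dataclasses import replace as _dc_replace

    from .power import _simulate_epochs
    from .preprocess import PreprocessConfig
    from .synth import BoxcarParams, HRFParams, NoiseModelParams
    from .design import BlockDesign

    if condition_means is None:
        condition_means = {"premedication": 0.0, "preplacebo": 0.0,
                           "postplacebo": 0.0, "postmedication": 0.25}
    design = BlockDesign()
    hrf = HRFParams()
    pre = PreprocessConfig()
    subjects: dict[str, dict[str, EpochSet]] = {}
    reference: dict[tuple[str, str], np.ndarray] = {}
    for s in range(n_subjects):
        sid = f"S{s:02d}"
        subjects[sid] = {}
        for c, (cond, mean) in enumerate(condition_means.items()):
            rng = np.random.default_rng(np.random.SeedSequence((seed, s, c)))
            box = (BoxcarParams(mean_amp=mean, ratio=ratio) if mean > 0
                   else BoxcarParams(mean_amp=0.0, sd_amp=0.0))
            noise = _dc_replace(NoiseModelParams(), snr_db=snr_db)
            es, truth = _simulate_epochs(design, box, hrf, noise, with_noise,
                                         rng, pre)
            subjects[sid][cond] = es
            if with_noise:
                reference[(sid, cond)] = ~truth.clean
    return CohortDataset(name=name, subjects=subjects, task=task,
                         reference=reference)


def _subject_activation(epoch_set: EpochSet, policy: RejectionPolicy
                        ) -> tuple[float, np.ndarray]:
    """Activation of one subject-condition: mean of retained epoch values.

    NaN when the policy (unlimited mode) rejected every epoch — the
    subject-condition then carries no datum.
    """
    result = apply_rejection(epoch_set, policy)
    if not result.retained:
        return float("nan"), ~result.retained_mask
    kept = epoch_set.with_retained(result.retained)
    return float(epoch_activation(kept).mean()), ~result.retained_mask


def _group_values(cohort: CohortDataset, policy: RejectionPolicy,
                  groups: Sequence[str]) -> tuple[dict[str, np.ndarray],
                                                  dict[tuple[str, str], np.ndarray]]:
    """Per-subject group values and the rejection masks produced on the way."""
    acts: dict[str, dict[str, float]] = {}
    rejections: dict[tuple[str, str], np.ndarray] = {}
    for subject, conds in cohort.subjects.items():
        acts[subject] = {}
        for cond, es in conds.items():
            a, rej = _subject_activation(es, policy)
            acts[subject][cond] = a
            rejections[(subject, cond)] = rej
    out: dict[str, np.ndarray] = {}
    for group in groups:
        vals = []
        for subject, a in acts.items():
            try:
                if group == "preadministration":
                    vals.append((a["premedication"] + a["preplacebo"]) / 2.0)
                elif group == "postmedication":
                    vals.append(a["postmedication"])
                elif group == "postplacebo":
                    vals.append(a["postplacebo"])
                elif group == "intermedication":
                    # medicated-minus-placebo effect, per subject, before testing
                    vals.append((a["postmedication"] - a["premedication"])
                                - (a["postplacebo"] - a["preplacebo"]))
                elif group in a:
                    vals.append(a[group])
                else:
                    raise KeyError(group)
            except KeyError as exc:
                raise ValueError(
                    f"dataset {cohort.name!r}: subject {subject!r} lacks the "
                    f"conditions needed for group {group!r}") from exc
        out[group] = np.asarray(vals)
    return out, rejections


def reproducibility_score(cohort: CohortDataset, policy: RejectionPolicy,
                          targets: Sequence[StatTarget]) -> float:
    """Fraction of expected statistical inferences the policy reproduces.

    Vacuously 1.0 for an empty target list.
    """
    if not targets:
        return 1.0
    groups = [t.group for t in targets]
    values, _ = _group_values(cohort, policy, groups)
    satisfied = sum(_target_satisfied(t, values[t.group]) for t in targets)
    return satisfied / len(targets)


def _target_satisfied(target: StatTarget, values: np.ndarray) -> bool:
    """One group inference vs its expectation.

    Subjects without a datum (all epochs rejected) are dropped; if fewer
    than two remain the inference is unavailable and the target unmet.
    """
    values = values[np.isfinite(values)]
    if values.size < 2:
        return False
    _, _, significant = activation_ttest(
        values, TestConfig(alpha=target.alpha, tail=target.tail))
    return significant == (target.expected == "significant")


def rejection_accuracy(predicted, reference) -> float:
    """(TP + TN) / total between two rejection labelings (positive=rejected).

    Accepts boolean arrays or mappings of aligned boolean arrays; raises on
    misaligned shapes or key sets.
    """
    if isinstance(predicted, Mapping) != isinstance(reference, Mapping):
        raise ValueError("predicted and reference must be of the same kind")
    if isinstance(predicted, Mapping):
        if set(predicted) != set(reference):
            raise ValueError("predicted and reference keys differ")
        pred = np.concatenate([np.asarray(predicted[k], dtype=bool).ravel()
                               for k in sorted(predicted)])
        ref = np.concatenate([np.asarray(reference[k], dtype=bool).ravel()
                              for k in sorted(reference)])
    else:
        pred = np.asarray(predicted, dtype=bool).ravel()
        ref = np.asarray(reference, dtype=bool).ravel()
    if pred.shape != ref.shape:
        raise ValueError(f"misaligned labels: {pred.shape} vs {ref.shape}")
    if pred.size == 0:
        raise ValueError("empty labels")
    return float((pred == ref).mean())


def _policy_row(policy: RejectionPolicy) -> dict:
    row = {"acceptance": "unlimited" if policy.acceptance_rate is None
           else policy.acceptance_rate,
           "criteria": "+".join(str(c) for c in policy.order) or "none",
           "c1": np.nan, "c2": np.nan, "c3": np.nan}
    for cfg in policy.criteria:
        if isinstance(cfg, Criterion1Config):
            row["c1"] = cfg.jump_threshold
        elif isinstance(cfg, Criterion2Config):
            row["c2"] = cfg.slope_threshold
        elif isinstance(cfg, Criterion3Config):
            row["c3"] = cfg.k_iqr
    return row


def grid_search(datasets: Sequence[tuple[CohortDataset, Sequence[StatTarget]]],
                grid: ParameterGrid,
                mode: str = "independent") -> pd.DataFrame:
    """Score every policy on every dataset; rank lexicographically.

    ``datasets`` pairs each cohort with its targets; in ``sequential`` mode
    the first pair is the training dataset and only its optimal policies are
    scored on the rest (their rows carry ``sequential=True``). The returned
    table has one row per policy with per-dataset scores, the cumulative
    reproducibility, and — where any cohort carries reference labels — the
    mean rejection accuracy; it is sorted best-first.
    """
    if mode not in ("independent", "sequential"):
        raise ValueError("mode must be 'independent' or 'sequential'")
    if not datasets:
        raise ValueError("need at least one dataset")
    if mode == "sequential" and len(datasets) < 2:
        raise ValueError("sequential mode needs a training and >=1 validation dataset")
    policies = list(grid.policies())
    if not policies:
        raise ValueError("empty grid")

    def evaluate(policy: RejectionPolicy) -> dict:
        row = _policy_row(policy)
        total = 0.0
        accs = []
        for cohort, targets in datasets:
            groups = [t.group for t in targets]
            values, rejections = _group_values(cohort, policy, groups)
            if targets:
                score = sum(_target_satisfied(t, values[t.group])
                            for t in targets) / len(targets)
            else:
                score = 1.0
            row[f"score_{cohort.name}"] = score
            total += score
            if cohort.reference:
                keys = set(cohort.reference)
                pred = {k: rejections[k] for k in keys}
                accs.append(rejection_accuracy(pred, cohort.reference))
        row["cumulative"] = total
        row["accuracy"] = float(np.mean(accs)) if accs else np.nan
        return row

    if mode == "independent":
        rows = [evaluate(p) for p in policies]
        table = pd.DataFrame(rows)
    else:
        train_cohort, train_targets = datasets[0]
        train_scores = np.array([
            reproducibility_score(train_cohort, p, train_targets) for p in policies
        ])
        best = train_scores.max()
        keep = [p for p, s in zip(policies, train_scores) if s == best]
        rows = [evaluate(p) for p in keep]
        table = pd.DataFrame(rows)
        table["sequential"] = True
    sort_cols = ["cumulative"]
    if table["accuracy"].notna().any():
        sort_cols.append("accuracy")
    return table.sort_values(sort_cols, ascending=False, kind="mergesort"
                             ).reset_index(drop=True)
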