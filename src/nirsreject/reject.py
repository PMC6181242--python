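"""Acceptance-rate-controlled sequential rejection with noise-level ranking.

The engine runs the noise criteria in a configured order, each on the epochs
that survived the previous stages. A stage rejects *all* of its newly flagged
epochs only when doing so leaves at least ``acceptance_rate`` epochs (the
floor — the minimum expected number of remaining epochs); otherwise it
rejects none and merely records the flags. After all stages, epochs are
ranked by *noise level* — the count of recorded-but-unacted flags — and the
noisiest are trimmed one by one until the floor is reached or no flagged
epoch remains. With an unlimited acceptance rate (no floor) the engine
degenerates to conventional unconditional rejection and the ranking never
fires.

The engine is fully deterministic: ties in the ranking break first by the
sum of within-criterion severity ranks, then by lower epoch index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sstats
from sklearn.base import BaseEstimator, OutlierMixin

from .criteria import (
    Criterion1Config,
    Criterion2Config,
    Criterion3Config,
    NoiseFlag,
    detect_amplitude_jump,
    detect_baseline_drift,
    detect_low_correlation,
)
from .design import EpochSet

__all__ = [
    "UNLIMITED",
    "RejectionPolicy",
    "NoiseRecord",
    "RejectionResult",
    "run_rejection",
    "apply_rejection",
    "rank_and_trim",
    "propagate_rejection",
    "AdaptiveEpochRejector",
]

#: Sentinel acceptance rate: no floor (conventional unconditional rejection).
UNLIMITED = None

CriterionConfig = Criterion1Config | Criterion2Config | Criterion3Config
StageDetector = Callable[[Sequence[int]], list[NoiseFlag]]


@dataclass(frozen=True)
class RejectionPolicy:
    """Ordered criteria plus the acceptance rate (floor) or ``UNLIMITED``."""

    criteria: tuple[CriterionConfig, ...] = (
        Criterion1Config(), Criterion2Config(), Criterion3Config(),
    )
    acceptance_rate: int | None = 3

    def __post_init__(self) -> None:
        if self.acceptance_rate is not None and self.acceptance_rate < 1:
            raise ValueError("acceptance_rate must be >= 1 or UNLIMITED")

    @property
    def order(self) -> tuple[int, ...]:
        return tuple(c.criterion for c in self.criteria)


@dataclass(frozen=True)
class NoiseRecord:
    """Ledger entry: a flag, the stage that raised it, and its fate."""

    flag: NoiseFlag
    stage: int  # 0-based position in the policy's criterion order
    action: str  # "rejected" (stage), "recorded", or "rank_rejected" (trim)


@dataclass
class RejectionResult:
    """Outcome of one engine run over a single epoch set."""

    n_epochs: int
    retained: list[int]
    rejected: dict[int, str]  # epoch -> cause ("criterion_k" | "ranking")
    ledger: list[NoiseRecord] = field(default_factory=list)
    acceptance_rate: int | None = None

    def __post_init__(self) -> None:
        all_epochs = set(self.retained) | set(self.rejected)
        if all_epochs != set(range(self.n_epochs)):
            raise ValueError("retained and rejected must partition the epochs")
        if self.acceptance_rate is not None and len(self.retained) < self.acceptance_rate:
            raise AssertionError(
                f"floor violated: {len(self.retained)} retained < "
                f"acceptance rate {self.acceptance_rate}"
            )

    @property
    def retained_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_epochs, dtype=bool)
        mask[self.retained] = True
        return mask

    def recorded_flags(self) -> list[NoiseRecord]:
        return [r for r in self.ledger if r.action == "recorded"]


def _severity_rank_sums(records: Sequence[NoiseRecord],
                        candidates: Sequence[int]) -> dict[int, float]:
    """Per-epoch sum of within-criterion severity ranks (average-tie ranks)."""
    sums = {e: 0.0 for e in candidates}
    by_criterion: dict[int, list[NoiseRecord]] = {}
    cand = set(candidates)
    for r in records:
        if r.flag.epoch_index in cand:
            by_criterion.setdefault(r.flag.criterion, []).append(r)
    for recs in by_criterion.values():
        ranks = sstats.rankdata([r.flag.severity for r in recs], method="average")
        for r, rank in zip(recs, ranks):
            sums[r.flag.epoch_index] += float(rank)
    return sums


def rank_and_trim(retained: Sequence[int], ledger: Sequence[NoiseRecord],
                  acceptance_rate: int | None) -> tuple[list[int], dict[int, str], list[NoiseRecord]]:
    """Final trim by noise-level ranking (single pass over recorded flags).

    Noise level of an epoch = number of recorded (unacted) flags on it. While
    the retained count exceeds the floor and some retained epoch is flagged,
    the noisiest epoch is rejected; recorded severities are not recomputed
    between trims. Returns the updated retained list, the trim rejections,
    and the ledger entries marking acted-on records.
    """
    retained = sorted(retained)
    if acceptance_rate is None:
        return retained, {}, []
    recorded = [r for r in ledger if r.action == "recorded"
                and r.flag.epoch_index in set(retained)]
    levels: dict[int, int] = {}
    for r in recorded:
        levels[r.flag.epoch_index] = levels.get(r.flag.epoch_index, 0) + 1
    if not levels:
        return retained, {}, []
    rank_sums = _severity_rank_sums(recorded, list(levels))
    # noisiest first: level desc, severity-rank sum desc, index asc
    queue = sorted(levels, key=lambda e: (-levels[e], -rank_sums[e], e))
    rejected: dict[int, str] = {}
    trim_records: list[NoiseRecord] = []
    for epoch in queue:
        if len(retained) <= acceptance_rate:
            break
        retained.remove(epoch)
        rejected[epoch] = "ranking"
        trim_records.extend(
            replace(r, action="rank_rejected") for r in recorded
            if r.flag.epoch_index == epoch
        )
    return retained, rejected, trim_records


def run_rejection(n_epochs: int, stages: Sequence[StageDetector],
                  acceptance_rate: int | None,
                  stage_criteria: Sequence[int] | None = None) -> RejectionResult:
    """Core engine over abstract stage detectors.

    ``stages[k]`` receives the currently retained epoch indices and returns
    the flags it raises among them. This indirection lets the same engine run
    the real criteria or enumerated flag patterns (for exhaustive checking).
    """
    if acceptance_rate is not None and acceptance_rate > n_epochs:
        raise ValueError(
            f"acceptance_rate {acceptance_rate} exceeds {n_epochs} epochs")
    retained = list(range(n_epochs))
    rejected: dict[int, str] = {}
    ledger: list[NoiseRecord] = []
    if stage_criteria is None:
        stage_criteria = list(range(1, len(stages) + 1))
    for stage, detect in enumerate(stages):
        flags = detect(tuple(retained))
        newly = sorted({f.epoch_index for f in flags})
        floor = 0 if acceptance_rate is None else acceptance_rate
        if len(retained) - len(newly) >= floor:
            action = "rejected"
            for e in newly:
                retained.remove(e)
                rejected[e] = f"criterion_{stage_criteria[stage]}"
        else:
            action = "recorded"
        ledger.extend(NoiseRecord(flag=f, stage=stage, action=action) for f in flags)
    retained, trim_rejected, trim_records = rank_and_trim(
        retained, ledger, acceptance_rate)
    # mark acted-on records in place of their recorded entries
    acted = {(r.flag.epoch_index, r.flag.criterion, r.stage) for r in trim_records}
    ledger = [
        replace(r, action="rank_rejected")
        if (r.flag.epoch_index, r.flag.criterion, r.stage) in acted else r
        for r in ledger
    ]
    rejected.update(trim_rejected)
    return RejectionResult(n_epochs=n_epochs, retained=retained,
                           rejected=rejected, ledger=ledger,
                           acceptance_rate=acceptance_rate)


def _stage_for(cfg: CriterionConfig, epoch_set: EpochSet) -> StageDetector:
    dt = epoch_set.dt
    if isinstance(cfg, Criterion1Config):
        def stage(retained: Sequence[int]) -> list[NoiseFlag]:
            out: list[NoiseFlag] = []
            for e in retained:
                out.extend(detect_amplitude_jump(epoch_set.values[e], dt, cfg,
                                                 epoch_index=e))
            return out
    elif isinstance(cfg, Criterion2Config):
        def stage(retained: Sequence[int]) -> list[NoiseFlag]:
            out = []
            for e in retained:
                out.extend(detect_baseline_drift(epoch_set.values[e],
                                                 epoch_set.times, cfg,
                                                 epoch_index=e))
            return out
    elif isinstance(cfg, Criterion3Config):
        def stage(retained: Sequence[int]) -> list[NoiseFlag]:
            idx = list(retained)
            return detect_low_correlation(epoch_set.values[idx], cfg,
                                          epoch_indices=idx)
    else:  # pragma: no cover
        raise TypeError(f"unknown criterion config {cfg!r}")
    return stage


def apply_rejection(epoch_set: EpochSet,
                    policy: RejectionPolicy = RejectionPolicy()) -> RejectionResult:
    """Run the full adaptive rejection process on one epoch set."""
    if epoch_set.n_epochs == 0:
        raise ValueError("epoch set is empty")
    stages = [_stage_for(cfg, epoch_set) for cfg in policy.criteria]
    return run_rejection(epoch_set.n_epochs, stages, policy.acceptance_rate,
                         stage_criteria=policy.order)


def propagate_rejection(result: RejectionResult,
                        other_sets: Mapping[str, EpochSet] | Sequence[EpochSet]
                        ) -> list[EpochSet]:
    """Apply one result's retained/rejected split to other signal types.

    Mirrors the practice of deciding rejection on the oxy-hemoglobin signal
    and carrying the decision to HHb / total-Hb epochs of the same trials.
    Idempotent; raises on trial-count mismatch.
    """
    sets = list(other_sets.values()) if isinstance(other_sets, Mapping) else list(other_sets)
    out = []
    for es in sets:
        if es.n_epochs != result.n_epochs:
            raise ValueError(
                f"trial count mismatch: {es.n_epochs} != {result.n_epochs}")
        out.append(es.with_retained(result.retained))
    return out


class AdaptiveEpochRejector(OutlierMixin, BaseEstimator):
    """Scikit-learn-style front end to the rejection engine.

    ``X`` is an ``(n_epochs, n_samples)`` matrix of one channel's epochs on a
    uniform grid starting ``pre_s`` seconds before stimulus onset.

    Parameters mirror the criterion thresholds (defaults are the optimized
    operating point: 0.047 mM·mm amplitude change, 0.029 mM·mm/s baseline
    slope, 0.6×IQR correlation fence) plus the criterion order and the
    acceptance rate (``None`` for unlimited/conventional mode).

    Attributes
    ----------
    result_ : RejectionResult
    retained_ : ndarray of retained epoch indices
    labels_ : ndarray, +1 retained / -1 rejected (outlier-detector convention)
    ledger_ : list of NoiseRecord
    """

    def __init__(self, jump_threshold: float = 0.047, base_window_s: float = 1.0,
                 recovery_threshold: float = 0.2, slope_threshold: float = 0.029,
                 k_iqr: float = 0.6, criteria: tuple[int, ...] = (1, 2, 3),
                 acceptance_rate: int | None = 3, dt: float = 0.1,
                 pre_s: float = 13.0):
        self.jump_threshold = jump_threshold
        self.base_window_s = base_window_s
        self.recovery_threshold = recovery_threshold
        self.slope_threshold = slope_threshold
        self.k_iqr = k_iqr
        self.criteria = criteria
        self.acceptance_rate = acceptance_rate
        self.dt = dt
        self.pre_s = pre_s

    def _policy(self) -> RejectionPolicy:
        configs = {
            1: Criterion1Config(jump_threshold=self.jump_threshold,
                                base_window_s=self.base_window_s,
                                recovery_threshold=self.recovery_threshold),
            2: Criterion2Config(slope_threshold=self.slope_threshold),
            3: Criterion3Config(k_iqr=self.k_iqr),
        }
        return RejectionPolicy(criteria=tuple(configs[c] for c in self.criteria),
                               acceptance_rate=self.acceptance_rate)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_epochs, n_samples)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        n_pre = int(round(self.pre_s / self.dt))
        times = (np.arange(X.shape[1]) - n_pre) * self.dt
        from .design import BlockDesign  # local import to avoid cycle at module load

        design = BlockDesign(n_trials=X.shape[0], pre_s=self.pre_s)
        epoch_set = EpochSet(design=design, channel="X", signal_type="O2Hb",
                             times=times, values=X)
        self.result_ = apply_rejection(epoch_set, self._policy())
        self.retained_ = np.asarray(self.result_.retained, dtype=int)
        self.labels_ = np.where(self.result_.retained_mask, 1, -1)
        self.ledger_ = self.result_.ledger
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X=None):
        """Labels of the fitted epochs (+1 retained, -1 rejected)."""
        if not hasattr(self, "labels_"):
            raise AttributeError("rejector is not fitted")
        return self.labels_

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
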