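"""Readers, writers, run configuration, and on-disk fixtures.

Canonical formats are plain text: recordings as CSV with a ``time_s`` column
and ``<channel>_<signaltype>`` columns (mM·mm), events as ``trial,onset_s``
CSV, rejection reports as ``channel,epoch,retained,cause,stage,severity``
CSV, labels as ``subject,channel,epoch,rejected`` CSV, configuration as
YAML, ground truth and run manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import SIGNAL_TYPES, BlockDesign, ContinuousRecording, SamplingGrid
from .preprocess import PreprocessConfig
from .reject import RejectionPolicy, RejectionResult
from .synth import (
    BoxcarParams,
    GroundTruth,
    HRFParams,
    NoiseModelParams,
    generate_recording,
)

__all__ = [
    "RunConfig",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "write_report",
    "read_labels",
    "write_labels",
    "write_ground_truth",
    "read_ground_truth",
    "write_manifest",
    "make_fixture",
    "FIXTURE_PROFILES",
]

FIXTURE_PROFILES = ("clean", "spiky", "drifty", "mixed", "cohort")


@dataclass
class RunConfig:
    """Serializable bundle of every tunable a run depends on."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    policy: RejectionPolicy = field(default_factory=RejectionPolicy)
    design: BlockDesign = field(default_factory=BlockDesign)
    hrf: HRFParams = field(default_factory=HRFParams)
    box: BoxcarParams = field(default_factory=BoxcarParams)
    noise: NoiseModelParams = field(default_factory=NoiseModelParams)
    seed: int = 0

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        d = {name: enc(getattr(self, name))
             for name in ("preprocess", "design", "hrf", "box", "noise")}
        d["seed"] = self.seed
        d["policy"] = {
            "acceptance_rate": self.policy.acceptance_rate,
            "order": list(self.policy.order),
            "criteria": {},
        }
        for cfg in self.policy.criteria:
            key = f"c{cfg.criterion}"
            d["policy"]["criteria"][key] = enc(cfg)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        from .criteria import Criterion1Config, Criterion2Config, Criterion3Config

        def build(klass, payload):
            payload = dict(payload or {})
            for k, v in payload.items():
                if isinstance(v, list):
                    payload[k] = tuple(v)
            return klass(**payload)

        pol = d.get("policy", {})
        by_num = {1: Criterion1Config, 2: Criterion2Config, 3: Criterion3Config}
        criteria = tuple(
            build(by_num[num], pol.get("criteria", {}).get(f"c{num}", {}))
            for num in pol.get("order", (1, 2, 3))
        )
        return cls(
            preprocess=build(PreprocessConfig, d.get("preprocess")),
            policy=RejectionPolicy(criteria=criteria,
                                   acceptance_rate=pol.get("acceptance_rate", 3)),
            design=build(BlockDesign, d.get("design")),
            hrf=build(HRFParams, d.get("hrf")),
            box=build(BoxcarParams, d.get("box")),
            noise=build(NoiseModelParams, d.get("noise")),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# recordings and events


def write_recording(recordings: ContinuousRecording | Sequence[ContinuousRecording],
                    path: str | Path) -> None:
    """Write one or several same-grid recordings to the CSV dialect."""
    if isinstance(recordings, ContinuousRecording):
        recordings = [recordings]
    grid = recordings[0].grid
    data = {"time_s": grid.times}
    for rec in recordings:
        if rec.grid != grid:
            raise ValueError("all recordings must share one grid")
        for ci, ch in enumerate(rec.channels):
            data[f"{ch}_{rec.signal_type}"] = rec.values[ci]
    pd.DataFrame(data).to_csv(path, index=False)


def read_recording(path: str | Path,
                   trial_onsets: np.ndarray | None = None
                   ) -> dict[str, ContinuousRecording]:
    """Read a recording CSV into one ContinuousRecording per signal type.

    The grid is inferred from the ``time_s`` column, which must be uniform
    within 1e-6 s; headers must match ``<channel>_<signaltype>``.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    steps = np.diff(t)
    if np.any(np.abs(steps - steps[0]) > 1e-6):
        bad = int(np.argmax(np.abs(steps - steps[0]) > 1e-6)) + 2
        raise ValueError(f"{path}: non-uniform time step at line {bad}")
    grid = SamplingGrid(dt=float(steps[0]), n_samples=t.size)
    by_type: dict[str, tuple[list[str], list[np.ndarray]]] = {}
    for col in df.columns:
        if col == "time_s":
            continue
        parts = col.rsplit("_", 1)
        if len(parts) != 2 or parts[1] not in SIGNAL_TYPES:
            raise ValueError(
                f"{path}: header {col!r} does not match '<channel>_<signaltype>'")
        ch, st = parts
        by_type.setdefault(st, ([], []))
        by_type[st][0].append(ch)
        by_type[st][1].append(df[col].to_numpy(dtype=float))
    onsets = trial_onsets if trial_onsets is not None else np.array([])
    return {
        st: ContinuousRecording(grid=grid, channels=chs, signal_type=st,
                                values=np.vstack(vals), trial_onsets=onsets)
        for st, (chs, vals) in by_type.items()
    }


def write_events(onsets: Sequence[float], path: str | Path) -> None:
    pd.DataFrame({"trial": np.arange(len(onsets)),
                  "onset_s": np.asarray(onsets, dtype=float)}
                 ).to_csv(path, index=False)


def read_events(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("trial", "onset_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df.sort_values("trial")["onset_s"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# reports, labels, ground truth


def write_report(results: Mapping[str, RejectionResult], path: str | Path) -> None:
    """Rejection report: one row per (channel, epoch)."""
    rows = []
    for channel, result in results.items():
        severities = {}
        for rec in result.ledger:
            e = rec.flag.epoch_index
            severities.setdefault(e, []).append(rec)
        for epoch in range(result.n_epochs):
            retained = epoch in result.retained
            cause = result.rejected.get(epoch, "")
            recs = severities.get(epoch, [])
            rows.append({
                "channel": channel,
                "epoch": epoch,
                "retained": retained,
                "cause": cause,
                "stage": recs[0].stage if recs else "",
                "severity": max((r.flag.severity for r in recs), default=""),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_labels(labels: Mapping[tuple[str, str], Sequence[bool]],
                 path: str | Path) -> None:
    rows = [
        {"subject": subj, "channel": ch, "epoch": e, "rejected": bool(r)}
        for (subj, ch), rej in labels.items()
        for e, r in enumerate(rej)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels(path: str | Path) -> dict[tuple[str, str], np.ndarray]:
    df = pd.read_csv(path)
    expected = {"subject", "channel", "epoch", "rejected"}
    unknown = set(df.columns) - expected
    if unknown:
        raise ValueError(f"{path}: unknown column(s) {sorted(unknown)}")
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[tuple[str, str], np.ndarray] = {}
    for (subj, ch), grp in df.groupby(["subject", "channel"]):
        grp = grp.sort_values("epoch")
        out[(str(subj), str(ch))] = grp["rejected"].to_numpy(dtype=bool)
    return out


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "events": [dataclasses.asdict(e) for e in truth.events],
        "clean": truth.clean.tolist(),
        "amplitudes": truth.amplitudes.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_manifest(path: str | Path, *, command: str, seed: int | None,
                   config: Mapping | None = None, **extra) -> None:
    """Machine-readable run manifest written beside every CLI output."""
    payload = {"package": "nirsreject", "version": __version__,
               "command": command, "seed": seed, "config": config or {}}
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# fixtures


def _profile_params(profile: str) -> tuple[NoiseModelParams, bool, int | None]:
    noise = NoiseModelParams()
    if profile == "clean":
        return noise, False, None
    if profile == "spiky":
        return dataclasses.replace(noise, event_types=("spike", "nonrecovery_spike")), True, 3
    if profile == "drifty":
        return dataclasses.replace(noise, event_types=("baseline_shift",)), True, 3
    if profile == "mixed":
        return noise, True, None
    raise ValueError(f"unknown profile {profile!r}; choose from {FIXTURE_PROFILES}")


def make_fixture(profile: str, seed: int, out_dir: str | Path) -> Path:
    """Write a small synthetic dataset for tests and documentation.

    Profiles: ``clean`` (no events), ``spiky`` (spikes only), ``drifty``
    (baseline shifts only), ``mixed`` (all event types), ``cohort`` (a
    two-group study with a known activation contrast: group A positive
    activation, group B null). Deterministic for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = BlockDesign()
    if profile == "cohort":
        groups = {"groupA": 0.25, "groupB": 0.0}
        for gi, (group, mean) in enumerate(groups.items()):
            for s in range(4):
                rng = np.random.default_rng(np.random.SeedSequence((seed, gi, s)))
                box = (BoxcarParams(mean_amp=mean, ratio=2.0) if mean > 0
                       else BoxcarParams(mean_amp=0.0, sd_amp=0.0))
                rec, truth = generate_recording(design, box, seed=rng)
                stem = out / f"{group}_S{s:02d}"
                write_recording(rec, stem.with_suffix(".csv"))
                write_events(rec.trial_onsets, Path(f"{stem}_events.csv"))
                write_ground_truth(truth, Path(f"{stem}_truth.json"))
        write_manifest(out / "manifest.json", command="fixture", seed=seed,
                       profile=profile, groups={g: m for g, m in groups.items()})
        return out
    noise, with_noise, n_events = _profile_params(profile)
    rng = np.random.default_rng(seed)
    rec, truth = generate_recording(design, BoxcarParams(mean_amp=0.22, ratio=2.0),
                                    noise=noise, with_synthetic_noise=with_noise,
                                    seed=rng, n_events=n_events)
    write_recording(rec, out / "recording.csv")
    write_events(rec.trial_onsets, out / "events.csv")
    write_ground_truth(truth, out / "ground_truth.json")
    write_manifest(out / "manifest.json", command="fixture", seed=seed,
                   profile=profile)
    return out
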