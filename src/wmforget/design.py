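"""Experiment structure: phases, trial types, timing grids and rosters.

The paradigm has three phases.  Phase 1 is simple delayed recognition of
single face or scene pictures (classifier training data).  Phase 2 is a
retro-cued stay/switch task holding one face and one scene in working
memory; on switch trials a cue redirects attention from the scene to the
face.  Phase 3 is a surprise old/new recognition test for the Phase 2
scenes.  Everything here is integer-second arithmetic on a TR-aligned
grid (TR = 2 s); analysis windows are half-open ``[a, b)`` so the 4-12 s
pre-switch window at TR = 2 contains exactly the scans at 4, 6, 8, 10 s.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DesignError(ValueError):
    """Raised for malformed trial types, misaligned windows or bad rosters."""


#: Canonical trial segment structure (name, seconds).
CANONICAL_SEGMENTS: dict[str, tuple[tuple[str, int], ...]] = {
    "p1_face": (("target", 1), ("delay", 7), ("probe", 2), ("blank", 6)),
    "p1_scene": (("target", 1), ("delay", 7), ("probe", 2), ("blank", 6)),
    "stay": (("target", 4), ("delay", 8), ("probe", 2), ("blank", 6)),
    "switch": (("target", 4), ("delay", 8), ("switch_delay", 8), ("probe", 2), ("blank", 6)),
}

PHASE_OF_TRIAL = {"p1_face": "P1", "p1_scene": "P1", "stay": "P2", "switch": "P2"}


@dataclass(frozen=True)
class TrialSpec:
    """One trial type: its phase and ordered segment durations (seconds)."""

    phase: str
    trial_type: str
    segment_durations: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.phase not in ("P1", "P2"):
            raise DesignError(f"unknown phase {self.phase!r}")
        for name, dur in self.segment_durations:
            if not (isinstance(dur, (int, np.integer)) and dur > 0):
                raise DesignError(f"segment {name!r} duration must be a positive whole second, got {dur!r}")


def trial_spec(trial_type: str) -> TrialSpec:
    """Return the canonical :class:`TrialSpec` for one of the four trial types."""
    try:
        segments = CANONICAL_SEGMENTS[trial_type]
    except KeyError:
        raise DesignError(f"unknown trial type {trial_type!r}; expected one of {sorted(CANONICAL_SEGMENTS)}") from None
    return TrialSpec(PHASE_OF_TRIAL[trial_type], trial_type, segments)


def trial_duration(spec: TrialSpec | str) -> int:
    """Total trial duration in seconds (sum of segment durations).

    Accepts a :class:`TrialSpec` or a canonical trial-type name.  The
    result is always divisible by the TR for the canonical types.
    """
    if isinstance(spec, str):
        spec = trial_spec(spec)
    return int(sum(dur for _, dur in spec.segment_durations))


@dataclass
class ExperimentDesign:
    """Counts, timings and analysis windows of the two scanned phases.

    Defaults encode the canonical design: four 20-trial Phase 1 blocks
    (even face/scene split), six 18-trial Phase 2 blocks (12 stay, 6
    switch), 20 s of dummy pulses per block, a 6-s label shift for
    classifier training, and the three per-trial evidence windows
    (seconds from trial onset, half-open).
    """

    tr_seconds: int = 2
    p1_blocks: int = 4
    p1_trials_per_block: int = 20
    p2_blocks: int = 6
    p2_stay_per_block: int = 12
    p2_switch_per_block: int = 6
    dummy_seconds_per_block: int = 20
    label_shift_seconds: int = 6
    training_window_seconds: int = 6
    windows: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"pre_switch": (4, 12), "post_switch": (16, 20), "probe": (20, 24)}
    )

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise DesignError("tr_seconds must be positive")
        if self.p1_trials_per_block % 2:
            raise DesignError("p1_trials_per_block must split evenly into face and scene trials")
        for cnt in (self.p1_blocks, self.p2_blocks, self.p2_stay_per_block, self.p2_switch_per_block):
            if cnt < 0:
                raise DesignError("block/trial counts must be non-negative")
        spans = sorted(self.windows.values())
        for (a, b) in spans:
            if a % self.tr_seconds or b % self.tr_seconds:
                raise DesignError(f"window [{a}, {b}) is not aligned to the TR grid")
            if b <= a:
                raise DesignError(f"window [{a}, {b}) is empty or reversed")
        for (_, b0), (a1, _) in zip(spans, spans[1:]):
            if a1 < b0:
                raise DesignError("analysis windows overlap")

    @property
    def p2_trials_per_block(self) -> int:
        return self.p2_stay_per_block + self.p2_switch_per_block

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = {k: list(v) for k, v in self.windows.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        d = dict(d)
        if "windows" in d:
            d["windows"] = {k: tuple(v) for k, v in d["windows"].items()}
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ExperimentDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def block_duration(design: ExperimentDesign, phase: str) -> int:
    """Duration of one block in seconds: summed trial durations plus dummies.

    Canonical values: P1 = 340 s (5 min 40 s), P2 = 428 s (7 min 8 s).
    """
    if phase == "P1":
        trials = design.p1_trials_per_block * trial_duration("p1_face")
    elif phase == "P2":
        trials = (
            design.p2_stay_per_block * trial_duration("stay")
            + design.p2_switch_per_block * trial_duration("switch")
        )
    else:
        raise DesignError(f"unknown phase {phase!r}")
    return int(trials + design.dummy_seconds_per_block)


def session_scan_time(design: ExperimentDesign) -> int:
    """Total functional scan time over Phases 1 and 2 (canonical: 3,928 s)."""
    total = 0
    if design.p1_blocks:
        total += design.p1_blocks * block_duration(design, "P1")
    if design.p2_blocks:
        total += design.p2_blocks * block_duration(design, "P2")
    return int(total)


def training_label_counts(design: ExperimentDesign) -> dict[str, int]:
    """Per-class classifier-training scan counts for Phase 1.

    Face and scene counts come from the final ``training_window_seconds``
    of each trial's delay period (one scan per TR); rest scans are
    subsampled per block from the intertrial intervals to match, so all
    three classes are balanced by contract (canonical: 120 each).
    """
    if design.training_window_seconds % design.tr_seconds:
        raise DesignError("training window is not aligned to the TR grid")
    scans_per_trial = design.training_window_seconds // design.tr_seconds
    face_trials = design.p1_blocks * (design.p1_trials_per_block // 2)
    n = int(face_trials * scans_per_trial)
    return {"face": n, "scene": n, "rest": n}


def phase3_roster(trials, lure_pool=None, rng=None) -> tuple[list, list]:
    """Old/new item lists for the Phase 3 surprise recognition test.

    ``trials`` is a DataFrame (or records coercible to one) with columns
    ``scene_id``, ``trial_type`` (stay/switch) and ``scene_probed``
    (whether the scene target reappeared in that trial's probe stream).
    Old items are every switch-trial scene (never re-probed, to avoid
    repetition-based enhancement) plus stay-trial scenes that were not
    re-probed.  The new list matches the old list in length, sampled
    from ``lure_pool`` if given, otherwise synthesized as ``new_####``.
    """
    trials = pd.DataFrame(trials, columns=["scene_id", "trial_type", "scene_probed"] if len(trials) == 0 else None)
    if len(trials) == 0:
        return [], []
    if trials["scene_id"].duplicated().any():
        dupes = trials.loc[trials["scene_id"].duplicated(), "scene_id"].tolist()
        raise DesignError(f"duplicate scene ids across trials: {dupes[:5]}")
    is_old = (trials["trial_type"] == "switch") | (
        (trials["trial_type"] == "stay") & ~trials["scene_probed"].astype(bool)
    )
    old = trials.loc[is_old, "scene_id"].tolist()
    rng = np.random.default_rng(0) if rng is None else rng
    if lure_pool is not None:
        pool = [s for s in lure_pool if s not in set(trials["scene_id"])]
        if len(pool) < len(old):
            raise DesignError("lure pool too small for a matched new-item list")
        new = list(rng.choice(np.asarray(pool, dtype=object), size=len(old), replace=False))
    else:
        new = [f"new_{i:04d}" for i in range(len(old))]
    return old, new


# -- events tables -------------------------------------------------------

EVENTS_COLUMNS = ["onset", "duration", "trial_type", "block", "stimulus_id"]


def phase1_events(design: ExperimentDesign, rng) -> pd.DataFrame:
    """Trial roster for Phase 1: balanced face/scene trials per block.

    Onsets are seconds from the start of the phase (blocks concatenated,
    each beginning with its dummy period); one row per trial, in the
    BIDS-events dialect (onset, duration, trial_type, block, stimulus_id).
    """
    rows = []
    dur = trial_duration("p1_face")
    blk = block_duration(design, "P1")
    half = design.p1_trials_per_block // 2
    counter = 0
    for b in range(design.p1_blocks):
        cats = np.array(["p1_face"] * half + ["p1_scene"] * half, dtype=object)
        rng.shuffle(cats)
        for i, cat in enumerate(cats):
            onset = b * blk + design.dummy_seconds_per_block + i * dur
            stim = f"{'face' if cat == 'p1_face' else 'scene'}_p1_{counter:03d}"
            rows.append((onset, dur, cat, b, stim))
            counter += 1
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)


def phase2_events(design: ExperimentDesign, rng, switch_only: bool = False) -> pd.DataFrame:
    """Trial roster for Phase 2 (stay/switch shuffled within block).

    With ``switch_only`` the roster contains just the switch trials (the
    substrate of every subsequent-memory analysis); block durations then
    shrink accordingly.
    """
    rows = []
    counter = 0
    for b in range(design.p2_blocks):
        if switch_only:
            types = np.array(["switch"] * design.p2_switch_per_block, dtype=object)
        else:
            types = np.array(
                ["stay"] * design.p2_stay_per_block + ["switch"] * design.p2_switch_per_block, dtype=object
            )
            rng.shuffle(types)
        durations = [trial_duration(t) for t in types]
        blk = design.dummy_seconds_per_block + int(sum(durations))
        t = design.dummy_seconds_per_block
        for ttype, dur in zip(types, durations):
            rows.append((sum_block_offset(b, blk) + t, dur, ttype, b, f"scene_p2_{counter:03d}"))
            t += dur
            counter += 1
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)


def sum_block_offset(block: int, block_seconds: int) -> int:
    """Onset of a block in the concatenated phase timeline."""
    return block * block_seconds


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
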