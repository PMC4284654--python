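"""Supersubject assembly, permutation null and participant bootstrap.

Per-participant switch-trial counts are too small to estimate a
nonlinear brain-behaviour curve within subject, so all participants'
items are pooled into one "supersubject" and inference runs on the
pool.  Two resampling procedures qualify the pooled estimate:

* a permutation test — outcomes shuffled across the pooled items
  (evidence fixed), the full curve-induction analysis re-run per
  permutation, and the observed log Bayes factor referred to the null
  distribution with the matched-or-exceeded (>=) convention;
* a participant bootstrap — participants resampled with replacement
  (duplicated participants contribute duplicated items), the analysis
  re-run per replicate, and population-level reliability reported as
  the fraction of replicates with a positive log Bayes factor.

Evidence rescaling to [-1, 1] happens inside each analysis over that
replicate's pooled scores, so it tracks the bootstrap pool (whose
min/max change) and is automatically unchanged under permutation
(which leaves the evidence values alone).  Every replicate derives its
RNG substream from (seed, replicate index), so replicates are
independent and individually reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pcit import PcitError, fit_pcit


class ResamplingError(ValueError):
    """Raised for empty pools, duplicate items and bad replicate counts."""


@dataclass
class SuperSubject:
    """All participants' items pooled, with provenance retained."""

    items: pd.DataFrame
    participant_index: dict

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_participants(self) -> int:
        return len(self.participant_index)


def build_supersubject(per_participant) -> SuperSubject:
    """Pool per-participant item tables into one supersubject.

    Accepts a mapping participant -> DataFrame or a single DataFrame
    with a ``participant_id`` column.  Item ids must be globally
    unique; each item belongs to exactly one participant.
    """
    if isinstance(per_participant, dict):
        if not per_participant:
            raise ResamplingError("no participants supplied")
        frames = []
        for pid, df in per_participant.items():
            df = df.copy()
            df["participant_id"] = pid
            frames.append(df)
        items = pd.concat(frames, ignore_index=True)
    else:
        items = pd.DataFrame(per_participant).reset_index(drop=True)
        if len(items) == 0:
            raise ResamplingError("no items supplied")
    if "item_id" in items.columns and items["item_id"].duplicated().any():
        raise ResamplingError("duplicate item ids across participants")
    index = {pid: grp.index.to_numpy() for pid, grp in items.groupby("participant_id", sort=True)}
    return SuperSubject(items=items, participant_index=index)


@dataclass
class PermutationResult:
    observed_log_bf: float
    null_log_bfs: list
    fraction_geq: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class BootstrapResult:
    log_bfs: list
    fraction_positive: float
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _replicate_rng(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(k),)))


def permutation_test(
    supersubject: SuperSubject | pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
    within_participant: bool = False,
    observed=None,
    **pcit_kwargs,
) -> PermutationResult:
    """Null distribution of the log Bayes factor under outcome shuffling.

    Outcomes are permuted uniformly across all pooled items by default
    (``within_participant`` restricts shuffles to each participant's
    own items); the full curve-induction analysis is re-run per
    permutation with a fresh curve sample from its own substream.
    ``fraction_geq`` counts null values that matched or exceeded the
    observed statistic.
    """
    if n_perm < 1:
        raise ResamplingError("n_perm must be at least 1")
    items = supersubject.items if isinstance(supersubject, SuperSubject) else supersubject
    pcit_kwargs.setdefault("summarize", False)
    if observed is None:
        observed = fit_pcit(items, rng=_replicate_rng(seed, 0), **pcit_kwargs).log_bayes_factor
    nulls = []
    for k in range(1, n_perm + 1):
        rng = _replicate_rng(seed, k)
        perm_items = items.copy()
        if within_participant:
            out = perm_items["outcome"].to_numpy().copy()
            for pid, idx in items.groupby("participant_id", sort=True).indices.items():
                out[idx] = out[rng.permutation(idx)]
            perm_items["outcome"] = out
        else:
            perm_items["outcome"] = perm_items["outcome"].to_numpy()[rng.permutation(len(perm_items))]
        nulls.append(fit_pcit(perm_items, rng=rng, **pcit_kwargs).log_bayes_factor)
    nulls_arr = np.asarray(nulls)
    return PermutationResult(
        observed_log_bf=float(observed),
        null_log_bfs=[float(v) for v in nulls],
        fraction_geq=float(np.mean(nulls_arr >= observed)),
        n_perm=int(n_perm),
        seed=int(seed),
    )


def bootstrap_reliability(
    supersubject: SuperSubject,
    n_boot: int = 200,
    seed: int = 0,
    **pcit_kwargs,
) -> BootstrapResult:
    """Participant-level bootstrap of the log Bayes factor.

    Each replicate draws N participants with replacement, pools their
    items (duplicates included), and re-runs the analysis.  Reports the
    fraction of replicates with log Bayes factor > 0.
    """
    if not isinstance(supersubject, SuperSubject):
        supersubject = build_supersubject(supersubject)
    if n_boot < 1:
        raise ResamplingError("n_boot must be at least 1")
    if supersubject.n_participants < 2:
        raise ResamplingError("participant bootstrap requires at least 2 participants")
    pcit_kwargs.setdefault("summarize", False)
    pids = sorted(supersubject.participant_index)
    log_bfs = []
    for k in range(1, n_boot + 1):
        rng = _replicate_rng(seed, k)
        draw = rng.integers(0, len(pids), size=len(pids))
        idx = np.concatenate([supersubject.participant_index[pids[j]] for j in draw])
        rep = supersubject.items.loc[idx].reset_index(drop=True)
        log_bfs.append(fit_pcit(rep, rng=rng, **pcit_kwargs).log_bayes_factor)
    arr = np.asarray(log_bfs)
    return BootstrapResult(
        log_bfs=[float(v) for v in log_bfs],
        fraction_positive=float(np.mean(arr > 0)),
        n_boot=int(n_boot),
        seed=int(seed),
    )
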