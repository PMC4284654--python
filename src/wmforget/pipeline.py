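"""End-to-end orchestration: generate, decode, analyze, resample, report.

The pipeline composes the other modules into one reproducible run:
synthetic generation (or externally supplied evidence/behaviour
tables), per-participant decoding, item assembly, the five
curve-induction variants (combined, pre-only, post-only, and the two
partialing-out analyses), permutation and bootstrap inference, the
working-memory logistic regression and the recognition ROC.  One
master seed drives documented substreams per stage; reports are
JSON-compatible and tables are tab-separated, with timestamps isolated
to the manifest so result files are diffable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import design as dsg
from . import behavior as beh
from . import mvpa, resampling, synth
from .pcit import fit_pcit, partial_out

logger = logging.getLogger("wmforget")

VARIANTS = ("combined", "pre_only", "post_only", "post_partial_pre", "pre_partial_post")

#: Documented defaults filled in by validate_config.
DEFAULTS = {
    "mode": "synthetic",
    "lam": 50.0,
    "alpha": 0.05,
    "n_samples": 100_000,
    "chi2_df": 1,
    "cap": 10.0,
    "n_perm": 200,
    "n_boot": 200,
    "wm_n_boot": 1000,
    "variants": list(VARIANTS),
    "resampling_variants": ["combined"],
    "seed": 0,
}


class ConfigError(ValueError):
    """Raised with the full list of config violations."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class RunConfig:
    """Normalized pipeline configuration (see ``validate_config``)."""

    mode: str = "synthetic"
    ground_truth: synth.GroundTruthConfig = field(default_factory=synth.GroundTruthConfig)
    design: dsg.ExperimentDesign = field(default_factory=dsg.ExperimentDesign)
    items_path: str | None = None
    wm_path: str | None = None
    lam: float = 50.0
    alpha: float = 0.05
    n_samples: int = 100_000
    chi2_df: int = 1
    cap: float = 10.0
    n_perm: int = 200
    n_boot: int = 200
    wm_n_boot: int = 1000
    variants: list = field(default_factory=lambda: list(VARIANTS))
    resampling_variants: list = field(default_factory=lambda: ["combined"])
    seed: int = 0
    output_dir: str = "wmforget_run"


def validate_config(raw: dict) -> RunConfig:
    """Fill documented defaults and report all violations at once.

    Exactly one input mode is allowed: ``synthetic`` (the generator
    runs) or ``tables`` (``items_path`` points at a per-trial evidence
    + outcome table).  Raises :class:`ConfigError` listing every
    violation; never returns a partially normalized config.
    """
    raw = dict(raw or {})
    errors = []
    merged = {**DEFAULTS, **{k: v for k, v in raw.items() if v is not None}}

    mode = merged["mode"]
    if mode not in ("synthetic", "tables"):
        errors.append(f"unknown input mode {mode!r}")
    if raw.get("items_path") and mode == "synthetic" and "mode" in raw:
        errors.append("both input modes set: mode='synthetic' but items_path given")
    if mode == "tables" and not raw.get("items_path"):
        errors.append("tables mode requires items_path")
    if merged["lam"] < 0:
        errors.append(f"negative penalty lam={merged['lam']}")
    if not (0 < merged["alpha"] <= 1):
        errors.append(f"alpha must be in (0, 1], got {merged['alpha']}")
    for key in ("n_samples", "n_perm", "n_boot", "wm_n_boot"):
        if int(merged[key]) < 1:
            errors.append(f"{key} must be positive, got {merged[key]}")
    for v in merged["variants"]:
        if v not in VARIANTS:
            errors.append(f"unknown analysis variant {v!r}")
    for v in merged["resampling_variants"]:
        if v not in VARIANTS:
            errors.append(f"unknown resampling variant {v!r}")
    gt_raw = raw.get("ground_truth", {})
    gt = None
    if isinstance(gt_raw, synth.GroundTruthConfig):
        gt = gt_raw
    else:
        try:
            gt = synth.GroundTruthConfig(**gt_raw)
        except (TypeError, synth.SynthError) as exc:
            errors.append(f"ground_truth: {exc}")
    des_raw = raw.get("design", {})
    des = None
    if isinstance(des_raw, dsg.ExperimentDesign):
        des = des_raw
    else:
        try:
            des = dsg.ExperimentDesign.from_dict(des_raw)
        except (TypeError, dsg.DesignError) as exc:
            errors.append(f"design: {exc}")
    if errors:
        raise ConfigError(errors)
    return RunConfig(
        mode=mode,
        ground_truth=gt,
        design=des,
        items_path=raw.get("items_path"),
        wm_path=raw.get("wm_path"),
        lam=float(merged["lam"]),
        alpha=float(merged["alpha"]),
        n_samples=int(merged["n_samples"]),
        chi2_df=int(merged["chi2_df"]),
        cap=float(merged["cap"]),
        n_perm=int(merged["n_perm"]),
        n_boot=int(merged["n_boot"]),
        wm_n_boot=int(merged["wm_n_boot"]),
        variants=list(merged["variants"]),
        resampling_variants=list(merged["resampling_variants"]),
        seed=int(merged["seed"]),
        output_dir=str(raw.get("output_dir", "wmforget_run")),
    )


# -- stages --------------------------------------------------------------


def decode_study(study: synth.SyntheticStudy, lam: float = 50.0, alpha: float = 0.05) -> pd.DataFrame:
    """Train on Phase 1 and decode Phase 2 for every participant.

    Feature selection and training use all Phase 1 blocks (the final
    model, as distinct from the per-fold models of cross-validation);
    decoded Phase 2 timecourses are window-averaged into one row per
    switch trial.
    """
    frames = []
    windows = study.design.windows
    for part in study.participants:
        lab = part.phase1.labels.labels
        mask = mvpa.select_features(part.phase1.ts.data, lab, alpha=alpha)
        model = mvpa.train(part.phase1.ts.data, lab, lam=lam, feature_mask=mask)
        ev = mvpa.decode(model, part.phase2.ts)
        te = mvpa.window_average(ev, part.phase2.trials, windows, tr_seconds=study.design.tr_seconds)
        frames.append(te)
    return pd.concat(frames, ignore_index=True)


def build_items(trial_evidence: pd.DataFrame, behavior_df: pd.DataFrame) -> pd.DataFrame:
    """Join decoded trial evidence with recognition outcomes into item records."""
    items = trial_evidence.merge(behavior_df[["trial_id", "outcome"]], on="trial_id", validate="1:1")
    out = pd.DataFrame(
        {
            "item_id": items["scene_id"],
            "participant_id": items["participant_id"],
            "ev_pre": items["pre_switch_scene_minus_face"],
            "ev_post": items["post_switch_scene_minus_face"],
            "outcome": items["outcome"],
        }
    )
    return out


def variant_items(items: pd.DataFrame, variant: str) -> tuple[pd.DataFrame, tuple[str, ...], bool]:
    """Item table, event columns and rescale flag for one analysis variant.

    The partialing variants residualize one interval's evidence on the
    other (OLS with intercept over the pooled supersubject items) and
    are already rescaled by ``partial_out``.
    """
    if variant == "combined":
        return items, ("ev_pre", "ev_post"), True
    if variant == "pre_only":
        return items, ("ev_pre",), True
    if variant == "post_only":
        return items, ("ev_post",), True
    if variant == "post_partial_pre":
        out = items.copy()
        out["ev"] = partial_out(items["ev_post"], items["ev_pre"])
        return out, ("ev",), False
    if variant == "pre_partial_post":
        out = items.copy()
        out["ev"] = partial_out(items["ev_pre"], items["ev_post"])
        return out, ("ev",), False
    raise ConfigError([f"unknown analysis variant {variant!r}"])


def analyze_items(items: pd.DataFrame, config: RunConfig, seed: int) -> dict:
    """Run every configured curve-induction variant on the pooled items."""
    results = {}
    for i, variant in enumerate(config.variants):
        vitems, cols, rescale = variant_items(items, variant)
        results[variant] = fit_pcit(
            vitems,
            event_cols=cols,
            n_samples=config.n_samples,
            seed=np.random.SeedSequence(entropy=seed, spawn_key=(i,)),
            rescale=rescale,
            cap=config.cap,
            chi2_df=config.chi2_df,
        )
    return results


def run(config: RunConfig, output_dir=None) -> dict:
    """Execute the full pipeline and write a report bundle.

    Writes per-stage outputs (evidence table, item records, per-variant
    posterior summaries, permutation and bootstrap results, the WM
    regression and recognition report) plus a run manifest.  Returns
    the in-memory report dictionary.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"variants": {}}
    seeds = {
        "master": config.seed,
        "analysis": config.seed,
        "permutation": config.seed + 1,
        "bootstrap": config.seed + 2,
        "wm": config.seed + 3,
    }

    try:
        if config.mode == "synthetic":
            logger.info("generating synthetic study")
            study = synth.generate_dataset(config.ground_truth, config.design)
            logger.info("decoding %d participants", len(study.participants))
            trial_evidence = decode_study(study, lam=config.lam, alpha=config.alpha)
            items = build_items(trial_evidence, study.behavior)
            trial_evidence.to_csv(out / "trial_evidence.tsv", sep="\t", index=False)
            wm_evidence = trial_evidence["probe_face"].to_numpy()
            wm_accuracy = study.behavior["wm_accuracy"].to_numpy()
            old_scores = study.behavior["outcome"].to_numpy()
            new_scores = study.new_items["outcome"].to_numpy()
        else:
            logger.info("loading item table from %s", config.items_path)
            items = pd.read_csv(config.items_path, sep="\t")
            wm_evidence = wm_accuracy = old_scores = new_scores = None
        items.to_csv(out / "items.tsv", sep="\t", index=False)

        supersubject = resampling.build_supersubject(items)
        logger.info("curve induction on %d pooled items", supersubject.n_items)
        pcit_results = analyze_items(supersubject.items, config, seeds["analysis"])
        for variant, res in pcit_results.items():
            report["variants"][variant] = res.to_dict()
            res.curve_table().to_csv(out / f"curve_{variant}.tsv", sep="\t", index=False)

        for variant in config.resampling_variants:
            vitems, cols, rescale = variant_items(supersubject.items, variant)
            kwargs = dict(
                event_cols=cols, rescale=rescale, n_samples=config.n_samples,
                cap=config.cap, chi2_df=config.chi2_df,
            )
            logger.info("permutation test (%s, %d permutations)", variant, config.n_perm)
            perm = resampling.permutation_test(
                vitems, n_perm=config.n_perm, seed=seeds["permutation"],
                observed=pcit_results[variant].log_bayes_factor, **kwargs,
            )
            report["variants"][variant]["permutation"] = perm.to_dict()
            logger.info("participant bootstrap (%s, %d replicates)", variant, config.n_boot)
            boot = resampling.bootstrap_reliability(
                resampling.build_supersubject(vitems), n_boot=config.n_boot,
                seed=seeds["bootstrap"], **kwargs,
            )
            report["variants"][variant]["bootstrap"] = boot.to_dict()

        if wm_evidence is not None:
            logger.info("working-memory logistic regression")
            wm = beh.wm_logistic(
                wm_evidence, wm_accuracy, n_boot=config.wm_n_boot,
                seed=seeds["wm"], predictor_name="probe_face",
            )
            report["wm_regression"] = wm.to_dict()
            report["recognition"] = {
                "auc": beh.roc_auc(old_scores, new_scores),
                "hit_rate": float(np.mean(old_scores > 0.5)),
                "n_old": int(old_scores.size),
                "n_new": int(new_scores.size),
            }
    except Exception as exc:  # pragma: no cover - error path exercised in tests
        logger.error("pipeline aborted: %s", exc)
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    manifest = {
        "config": _config_dict(config),
        "seeds": seeds,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["ground_truth"] = config.ground_truth.to_dict()
    d["design"] = config.design.to_dict()
    d["ground_truth"]["true_curve"] = {
        "knot_x": list(config.ground_truth.true_curve.knot_x),
        "knot_y": list(config.ground_truth.true_curve.knot_y),
    }
    return d
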