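"""Synthetic studies with known ground truth.

Generates complete data for the three-phase paradigm — ROI voxel
timeseries for classifier training (Phase 1) and for the retro-cued
switch task (Phase 2), plus behavioural outcomes (Phase 2 probe
accuracy, Phase 3 graded recognition) — so every downstream stage is
testable without any acquisition.

Signal model
------------
Each participant has a face template and a scene template: unit-norm
loading vectors over a shared set of informative voxels.  A trial's
neural state is a pair of (scene, face) amplitudes multiplying the two
templates; haemodynamics are a pure onset shift of the amplitude boxcar
(an optional double-gamma HRF convolution is available behind a config
flag), and i.i.d. Gaussian noise is added to every voxel and scan.
Phase 2 switch trials draw independent per-trial amplitude pairs for
the pre-switch state (scene-dominant by default) and post-switch state
(face-dominant), so the scene-minus-face evidence axis is well sampled
across trials — the variability the curve-induction stage needs to
resolve curve shape.

Behaviour is generated from a known ground-truth plasticity curve f*:
the pre- and post-switch latent evidence values (rescaled to [-1, 1]
over the pooled study) are separate learning events whose effects sum,
``p = expit(beta0 + f*(e_pre) + f*(e_post))``; a noisy copy of p is
binned at fixed thresholds into the four graded recognition responses.
Working-memory probe accuracy is Bernoulli in the latent probe-window
face amplitude.  The noise-free latent evidence is retained for
recovery tests but never consumed by the analysis stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import design as dsg
from . import mvpa
from .pcit import PcitError, PlasticityCurve, rescale_evidence


class SynthError(ValueError):
    """Raised for inconsistent generator configurations."""


#: U-shaped ground truth: drops below its start, then rises above its minimum.
DEFAULT_TRUE_CURVE = PlasticityCurve((-1.0, -0.25, 0.25, 1.0), (0.0, -0.85, -0.25, 0.9))

#: Monotone-increasing ground truth for negative controls.
MONOTONE_CURVE = PlasticityCurve((-1.0, -0.3, 0.3, 1.0), (-0.9, -0.3, 0.3, 0.9))

#: Flat ground truth (no evidence-memory relationship).
FLAT_CURVE = PlasticityCurve((-1.0, -0.3, 0.3, 1.0), (0.0, 0.0, 0.0, 0.0))

RESPONSE_LABELS = ("sure_new", "unsure_new", "unsure_old", "sure_old")
#: Fixed thresholds binning the noisy latent strength into graded responses.
RESPONSE_BINS = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class MixtureSpec:
    """Per-trial (scene, face) amplitude distribution.

    The scene-minus-face contrast is drawn uniformly over
    ``[contrast_lo, contrast_hi]`` and the total activation
    ``scene + face`` from a normal around ``total_mean``; amplitudes
    are ``(total + c) / 2`` and ``(total - c) / 2``, clipped at zero.
    The bounded uniform contrast samples the evidence axis densely out
    to its edges, which is what lets the curve-induction stage resolve
    curve shape near the extremes.
    """

    contrast_lo: float
    contrast_hi: float
    total_mean: float = 1.4
    total_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.contrast_lo > self.contrast_hi:
            raise SynthError("contrast_lo must not exceed contrast_hi")

    @property
    def contrast_mean(self) -> float:
        return 0.5 * (self.contrast_lo + self.contrast_hi)

    def draw(
        self, rng: np.random.Generator, n: int, contrast_offset: float = 0.0, total_offset: float = 0.0
    ) -> tuple[np.ndarray, np.ndarray]:
        c = rng.uniform(self.contrast_lo, self.contrast_hi, size=n) + contrast_offset
        total = rng.normal(self.total_mean + total_offset, self.total_sd, size=n) if self.total_sd > 0 else np.full(n, self.total_mean + total_offset)
        s = np.clip((total + c) / 2.0, 0.0, None)
        f = np.clip((total - c) / 2.0, 0.0, None)
        return s, f


@dataclass
class GroundTruthConfig:
    """Everything the generator needs; defaults are the study conditions.

    21 participants, 200 ROI voxels of which 60 are informative, unit
    category amplitude against voxel noise sd 0.3 (calibrated so
    block-wise cross-validated face/scene decoding is comfortably
    above 90%, the separability regime the analysis assumes for
    ventral temporal category evidence).  Pre-switch amplitude
    contrasts are scene-dominant (uniform on [-0.3, 1.2]) and
    post-switch face-dominant (uniform on [-1.2, 0.3]), so the pooled
    scene-minus-face axis is sampled densely from full face dominance
    through close competition to full scene dominance.  The
    phase-1 haemodynamic lag (6 s) matches the classifier label shift;
    the phase-2 state lag defaults to 4 s, matching how the analysis
    windows are positioned relative to trial events.
    """

    n_participants: int = 21
    n_voxels: int = 200
    n_informative: int = 60
    p1_amplitude: float = 1.0
    noise_sd: float = 0.3
    pre_mix: MixtureSpec = field(default_factory=lambda: MixtureSpec(-0.3, 1.2))
    post_mix: MixtureSpec = field(default_factory=lambda: MixtureSpec(-1.2, 0.3))
    true_curve: PlasticityCurve = DEFAULT_TRUE_CURVE
    beta0_mem: float = 1.0
    response_noise_sd: float = 0.05
    new_item_delta: float = -2.2
    gamma0: float = -0.3
    gamma1: float = 2.0
    participant_sd: float = 0.08
    phase1_lag_seconds: int = 6
    phase2_lag_seconds: int = 4
    hrf: str = "shift"  # "shift" (pure onset delay) or "double_gamma"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_voxels:
            raise SynthError("n_informative cannot exceed n_voxels")
        if self.noise_sd < 0 or self.response_noise_sd < 0:
            raise SynthError("noise standard deviations must be non-negative")
        if self.hrf not in ("shift", "double_gamma"):
            raise SynthError("hrf must be 'shift' or 'double_gamma'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_curve"] = {"knot_x": list(self.true_curve.knot_x), "knot_y": list(self.true_curve.knot_y)}
        return d


@dataclass
class PhaseData:
    """One phase's decoding substrate for one participant."""

    ts: mvpa.RoiTimeseries
    events: pd.DataFrame
    labels: mvpa.LabelSeries | None = None
    trials: pd.DataFrame | None = None


@dataclass
class ParticipantData:
    participant_id: int
    phase1: PhaseData
    phase2: PhaseData
    template_face: np.ndarray
    template_scene: np.ndarray


@dataclass
class SyntheticStudy:
    """A full synthetic study plus its generating ground truth."""

    participants: list[ParticipantData]
    latent: pd.DataFrame
    behavior: pd.DataFrame
    new_items: pd.DataFrame
    config: GroundTruthConfig
    design: dsg.ExperimentDesign


def _double_gamma_hrf(tr_seconds: int, duration: float = 30.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR, peak-normalized."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration, tr_seconds, dtype=float)
    h = gamma_dist.pdf(t, 6) - 1.0 / 6.0 * gamma_dist.pdf(t, 16)
    return h / h.max()


def _bold(neural: np.ndarray, lag_scans: int, kernel: np.ndarray | None) -> np.ndarray:
    """Haemodynamic transform of a neural amplitude series (per block)."""
    if kernel is not None:
        return np.convolve(neural, kernel)[: neural.size]
    if lag_scans == 0:
        return neural.copy()
    out = np.zeros_like(neural)
    out[lag_scans:] = neural[:-lag_scans]
    return out


def _make_templates(cfg: GroundTruthConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.choice(cfg.n_voxels, size=cfg.n_informative, replace=False)
    templates = []
    for _ in range(2):
        t = np.zeros(cfg.n_voxels)
        load = rng.normal(size=cfg.n_informative)
        t[idx] = load / np.linalg.norm(load)
        templates.append(t)
    return templates[0], templates[1]


def generate_phase1(
    cfg: GroundTruthConfig,
    design: dsg.ExperimentDesign,
    rng: np.random.Generator,
    templates: tuple[np.ndarray, np.ndarray],
) -> PhaseData:
    """One participant's Phase 1 run: data, label events, balanced labels.

    Category signal occupies the final ``training_window_seconds`` of
    each trial's delay period, shifted by the phase-1 lag; rest labels
    come from the intertrial blank, subsampled per block with the
    provided RNG so all three classes have equal counts (the
    rest-matching contract of the design module).
    """
    tmpl_face, tmpl_scene = templates
    tr = design.tr_seconds
    lag = cfg.phase1_lag_seconds
    if lag % tr:
        raise SynthError("phase-1 lag must be a multiple of the TR")
    kernel = _double_gamma_hrf(tr) if cfg.hrf == "double_gamma" else None
    events = dsg.phase1_events(design, rng)
    blk = dsg.block_duration(design, "P1")
    scans_per_block = blk // tr
    p1_dur = dsg.trial_duration("p1_face")
    delay_end = 1 + 7  # target(1) + delay(7)
    neural_on = delay_end - design.training_window_seconds

    data_blocks, onset_blocks, block_ids = [], [], []
    label_rows = []
    for b in range(design.p1_blocks):
        onsets = b * blk + np.arange(scans_per_block) * tr
        face_n = np.zeros(scans_per_block)
        scene_n = np.zeros(scans_per_block)
        for _, ev in events[events["block"] == b].iterrows():
            rel = (ev["onset"] - b * blk) // tr
            a = rel + neural_on // tr
            z = rel + delay_end // tr
            tgt = face_n if ev["trial_type"] == "p1_face" else scene_n
            tgt[a:z] = cfg.p1_amplitude
            label_rows.append(
                {"onset": ev["onset"] + neural_on, "duration": design.training_window_seconds,
                 "label": "face" if ev["trial_type"] == "p1_face" else "scene"}
            )
            label_rows.append({"onset": ev["onset"] + p1_dur - 6, "duration": 6, "label": "rest"})
        face_b = _bold(face_n, lag // tr, kernel)
        scene_b = _bold(scene_n, lag // tr, kernel)
        signal = np.outer(tmpl_face, face_b) + np.outer(tmpl_scene, scene_b)
        noise = rng.normal(0.0, cfg.noise_sd, size=signal.shape) if cfg.noise_sd > 0 else 0.0
        data_blocks.append(signal + noise)
        onset_blocks.append(onsets)
        block_ids.append(np.full(scans_per_block, b))

    ts = mvpa.RoiTimeseries(
        data=np.concatenate(data_blocks, axis=1),
        tr_seconds=tr,
        scan_onsets=np.concatenate(onset_blocks),
        block_id=np.concatenate(block_ids),
        phase="P1",
    )
    label_events = pd.DataFrame(label_rows)
    labels = mvpa.shift_labels(label_events, ts.scan_onsets, design.label_shift_seconds, tr)
    labels = _balance_rest(labels, ts.block_id, rng)
    return PhaseData(ts=ts, events=events, labels=labels)


def _balance_rest(labels: mvpa.LabelSeries, block_id: np.ndarray, rng: np.random.Generator) -> mvpa.LabelSeries:
    """Subsample rest-labeled scans per block to match the category count."""
    lab = labels.labels.copy()
    for b in np.unique(block_id):
        in_b = block_id == b
        n_face = int(np.sum((lab == "face") & in_b))
        rest_idx = np.flatnonzero((lab == "rest") & in_b)
        if rest_idx.size < n_face:
            raise SynthError(f"block {b}: only {rest_idx.size} rest scans for {n_face} per-class targets")
        drop = rng.permutation(rest_idx)[n_face:]
        lab[drop] = mvpa.UNLABELED
    return mvpa.LabelSeries(labels=lab, shift_applied=labels.shift_applied)


def generate_phase2_switch(
    cfg: GroundTruthConfig,
    design: dsg.ExperimentDesign,
    rng: np.random.Generator,
    templates: tuple[np.ndarray, np.ndarray],
    participant_id: int = 0,
    offsets: np.ndarray | None = None,
) -> tuple[PhaseData, pd.DataFrame]:
    """One participant's Phase 2 switch trials plus their latent evidence.

    Each 28-s trial mixes both templates: the pre-switch state (target +
    first delay, 0-12 s) uses a pre_mix amplitude draw and the
    post-switch state (switch delay + probe, 12-22 s) a post_mix draw,
    both lag-shifted.  The latent table records the noise-free
    scene-minus-face mixture per analysis window.
    """
    tmpl_face, tmpl_scene = templates
    tr = design.tr_seconds
    lag = cfg.phase2_lag_seconds
    if lag % tr:
        raise SynthError("phase-2 lag must be a multiple of the TR")
    kernel = _double_gamma_hrf(tr) if cfg.hrf == "double_gamma" else None
    off = np.zeros(4) if offsets is None else np.asarray(offsets, float)

    n_blocks = design.p2_blocks
    per_block = design.p2_switch_per_block
    switch_dur = dsg.trial_duration("switch")
    blk = design.dummy_seconds_per_block + per_block * switch_dur
    scans_per_block = blk // tr

    data_blocks, onset_blocks, block_ids = [], [], []
    trial_rows, latent_rows = [], []
    for b in range(n_blocks):
        onsets = b * blk + np.arange(scans_per_block) * tr
        s_neural = np.zeros(scans_per_block)
        f_neural = np.zeros(scans_per_block)
        s1, f1 = cfg.pre_mix.draw(rng, per_block, contrast_offset=off[0], total_offset=off[1])
        s2, f2 = cfg.post_mix.draw(rng, per_block, contrast_offset=off[2], total_offset=off[3])
        for i in range(per_block):
            t0 = design.dummy_seconds_per_block + i * switch_dur
            rel = t0 // tr
            s_neural[rel : rel + 12 // tr] = s1[i]
            f_neural[rel : rel + 12 // tr] = f1[i]
            s_neural[rel + 12 // tr : rel + 22 // tr] = s2[i]
            f_neural[rel + 12 // tr : rel + 22 // tr] = f2[i]
            trial_id = f"sub{participant_id:02d}_b{b}_t{i}"
            trial_rows.append(
                {
                    "trial_id": trial_id,
                    "participant_id": participant_id,
                    "block": b,
                    "onset": b * blk + t0,
                    "duration": switch_dur,
                    "trial_type": "switch",
                    "scene_id": f"scene_{trial_id}",
                }
            )
            latent_rows.append(
                {
                    "trial_id": trial_id,
                    "participant_id": participant_id,
                    "scene_amp_pre": s1[i],
                    "face_amp_pre": f1[i],
                    "scene_amp_post": s2[i],
                    "face_amp_post": f2[i],
                    "ev_pre": s1[i] - f1[i],
                    "ev_post": s2[i] - f2[i],
                    "ev_probe": s2[i] - f2[i],
                    "face_probe": f2[i],
                }
            )
        s_bold = _bold(s_neural, lag // tr, kernel)
        f_bold = _bold(f_neural, lag // tr, kernel)
        signal = np.outer(tmpl_scene, s_bold) + np.outer(tmpl_face, f_bold)
        noise = rng.normal(0.0, cfg.noise_sd, size=signal.shape) if cfg.noise_sd > 0 else 0.0
        data_blocks.append(signal + noise)
        onset_blocks.append(onsets)
        block_ids.append(np.full(scans_per_block, b))

    ts = mvpa.RoiTimeseries(
        data=np.concatenate(data_blocks, axis=1),
        tr_seconds=tr,
        scan_onsets=np.concatenate(onset_blocks),
        block_id=np.concatenate(block_ids),
        phase="P2",
    )
    trials = pd.DataFrame(trial_rows)
    return PhaseData(ts=ts, events=trials, trials=trials), pd.DataFrame(latent_rows)


def generate_behavior(
    cfg: GroundTruthConfig,
    latent: pd.DataFrame,
    rng: np.random.Generator,
    rescale: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Behavioural outcomes from the latent evidence and ground-truth curve.

    Recognition: the pre/post latent values are rescaled to [-1, 1] over
    the pooled study (unless ``rescale=False``, in which case they must
    already lie in the domain — a violation raises), the ground-truth
    curve is applied to each learning event, effects are summed into a
    logistic memory probability, and a noisy copy is binned at fixed
    thresholds into the four graded responses.  New (lure) items get a
    baseline probability ``expit(beta0_mem + new_item_delta)``.
    Working memory: probe accuracy is Bernoulli in the latent
    probe-window face amplitude via ``expit(gamma0 + gamma1 * f)``.
    """
    n = len(latent)
    if n == 0:
        raise SynthError("latent evidence table is empty")
    ev = np.concatenate([latent["ev_pre"].to_numpy(float), latent["ev_post"].to_numpy(float)])
    if rescale:
        if np.ptp(ev) == 0:
            scaled = np.zeros_like(ev)
        else:
            scaled = rescale_evidence(ev)
    else:
        scaled = ev  # curve call below raises PcitError outside [-1, 1]
    e_pre, e_post = scaled[:n], scaled[n:]
    f = cfg.true_curve
    delta = f(e_pre) + f(e_post)
    p_mem = expit(cfg.beta0_mem + delta)
    noise = rng.normal(0.0, cfg.response_noise_sd, size=n) if cfg.response_noise_sd > 0 else 0.0
    s = np.clip(p_mem + noise, 0.0, 1.0)
    bins = np.digitize(s, RESPONSE_BINS)
    strength = bins / 3.0
    response = np.asarray(RESPONSE_LABELS, dtype=object)[bins]

    p_acc = expit(cfg.gamma0 + cfg.gamma1 * latent["face_probe"].to_numpy(float))
    accuracy = (rng.random(n) < p_acc).astype(int)

    behavior = pd.DataFrame(
        {
            "trial_id": latent["trial_id"],
            "participant_id": latent["participant_id"],
            "p_mem": p_mem,
            "outcome": strength,
            "response": response,
            "wm_accuracy": accuracy,
            "is_old_item": True,
        }
    )

    p_new = expit(cfg.beta0_mem + cfg.new_item_delta)
    s_new = np.clip(p_new + (rng.normal(0.0, cfg.response_noise_sd, size=n) if cfg.response_noise_sd > 0 else 0.0), 0.0, 1.0)
    nb = np.digitize(s_new, RESPONSE_BINS)
    new_items = pd.DataFrame(
        {
            "item_id": [f"new_{i:04d}" for i in range(n)],
            "participant_id": latent["participant_id"].to_numpy(),
            "outcome": nb / 3.0,
            "response": np.asarray(RESPONSE_LABELS, dtype=object)[nb],
            "is_old_item": False,
        }
    )
    return behavior, new_items


def export_nifti(ts: mvpa.RoiTimeseries, path) -> None:
    """Optional NIfTI export: voxels reshaped onto a dummy 3-D grid.

    Requires nibabel.  The spatial arrangement is arbitrary (the ROI is
    a flat voxel list); the 4th axis is scan time at the TR.
    """
    import nibabel as nib

    n_vox = ts.n_voxels
    side = int(np.ceil(n_vox ** (1 / 3)))
    vol = np.zeros((side, side, side, ts.n_scans))
    vol.reshape(-1, ts.n_scans)[:n_vox] = ts.data
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header["pixdim"][4] = ts.tr_seconds
    nib.save(img, str(path))


def generate_dataset(cfg: GroundTruthConfig, design: dsg.ExperimentDesign | None = None) -> SyntheticStudy:
    """Compose the generators into a full study.

    One master seed governs everything: per-participant RNG substreams
    (templates, heterogeneity offsets, both phases' noise) plus one
    behaviour substream are spawned from ``SeedSequence(cfg.seed)``, so
    identical configs give byte-identical studies.
    """
    if design is None:
        design = dsg.ExperimentDesign()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_participants + 1)
    behavior_rng = np.random.default_rng(children[0])

    participants = []
    latents = []
    for pid in range(cfg.n_participants):
        rng = np.random.default_rng(children[pid + 1])
        templates = _make_templates(cfg, rng)
        offsets = rng.normal(0.0, cfg.participant_sd, size=4) if cfg.participant_sd > 0 else np.zeros(4)
        phase1 = generate_phase1(cfg, design, rng, templates)
        phase2, latent = generate_phase2_switch(cfg, design, rng, templates, participant_id=pid, offsets=offsets)
        participants.append(
            ParticipantData(
                participant_id=pid,
                phase1=phase1,
                phase2=phase2,
                template_face=templates[0],
                template_scene=templates[1],
            )
        )
        latents.append(latent)
    latent = pd.concat(latents, ignore_index=True)
    behavior, new_items = generate_behavior(cfg, latent, behavior_rng)
    return SyntheticStudy(
        participants=participants,
        latent=latent,
        behavior=behavior,
        new_items=new_items,
        config=cfg,
        design=design,
    )
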