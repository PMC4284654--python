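"""Multivoxel pattern analysis: decoding face/scene/rest evidence.

Three independent one-vs-other L2-penalized logistic detectors (face,
scene, rest; penalty lambda = 50 by default) are trained on individual
2-s scans, after a one-way ANOVA feature selection and a 6-s forward
shift of the trial labels to account for haemodynamic lag.  Each
detector's output is a per-scan evidence value in [0, 1]; the scene
minus face difference tracks the competitive balance between the two
held representations.  Cross-validation is block-wise (train on k-1
blocks, test on the held-out block), with feature selection re-run
inside each fold's training set so the accuracy estimate never leaks.

Evidence outputs are the raw per-detector logistic values, not softmax
normalized across detectors: the three detectors are trained
independently and their outputs need not sum to one.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import f_oneway
from sklearn.linear_model import LogisticRegression


class MvpaError(ValueError):
    """Raised for shape mismatches, misaligned shifts and degenerate folds."""


#: Fixed detector order; ties in the accuracy argmax break toward the first.
CLASS_ORDER = ("face", "scene", "rest")

UNLABELED = "unlabeled"


@dataclass
class RoiTimeseries:
    """ROI voxel-by-scan matrix with its acquisition grid.

    ``data`` is (n_voxels, n_scans); ``scan_onsets`` are seconds from
    the start of the phase timeline; ``block_id`` maps each scan to its
    acquisition run.
    """

    data: np.ndarray
    tr_seconds: int
    scan_onsets: np.ndarray
    block_id: np.ndarray
    phase: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.scan_onsets = np.asarray(self.scan_onsets)
        self.block_id = np.asarray(self.block_id)
        if self.data.ndim != 2:
            raise MvpaError("data must be a voxels x scans matrix")
        n = self.data.shape[1]
        if self.scan_onsets.shape != (n,) or self.block_id.shape != (n,):
            raise MvpaError("scan_onsets and block_id must have one entry per scan")
        if np.isnan(self.data).any():
            raise MvpaError("timeseries contains missing values")
        for b in np.unique(self.block_id):
            on = self.scan_onsets[self.block_id == b]
            if np.any(np.diff(on) <= 0):
                raise MvpaError("scans must be time-ordered within block")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_scans(self) -> int:
        return self.data.shape[1]

    def save(self, prefix) -> None:
        """Write the matrix as TSV plus a JSON sidecar (TR, grid, blocks)."""
        np.savetxt(f"{prefix}_data.tsv", self.data, delimiter="\t")
        with open(f"{prefix}_sidecar.json", "w") as fh:
            json.dump(
                {
                    "tr_seconds": int(self.tr_seconds),
                    "scan_onsets": self.scan_onsets.tolist(),
                    "block_id": self.block_id.tolist(),
                    "phase": self.phase,
                },
                fh,
            )

    @classmethod
    def load(cls, prefix) -> "RoiTimeseries":
        data = np.loadtxt(f"{prefix}_data.tsv", delimiter="\t", ndmin=2)
        with open(f"{prefix}_sidecar.json") as fh:
            side = json.load(fh)
        return cls(
            data=data,
            tr_seconds=side["tr_seconds"],
            scan_onsets=np.asarray(side["scan_onsets"]),
            block_id=np.asarray(side["block_id"]),
            phase=side.get("phase", ""),
        )


@dataclass
class LabelSeries:
    """Per-scan training labels (face/scene/rest/unlabeled) and the shift applied."""

    labels: np.ndarray
    shift_applied: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)


def shift_labels(events: pd.DataFrame, scan_onsets, shift_seconds: int = 6, tr_seconds: int = 2) -> LabelSeries:
    """Assign event labels to scans after a forward haemodynamic shift.

    A scan at time ``t`` takes the label of the event active at
    ``t - shift``; scans before the first shifted event (or in gaps)
    are unlabeled.  ``events`` needs columns onset, duration, label.
    """
    if shift_seconds % tr_seconds:
        raise MvpaError("label shift must be a multiple of the TR")
    scan_onsets = np.asarray(scan_onsets)
    labels = np.full(scan_onsets.shape, UNLABELED, dtype=object)
    src = scan_onsets - shift_seconds
    for _, ev in events.iterrows():
        mask = (src >= ev["onset"]) & (src < ev["onset"] + ev["duration"])
        labels[mask] = ev["label"]
    return LabelSeries(labels=labels, shift_applied=int(shift_seconds))


def select_features(data: np.ndarray, labels, alpha: float = 0.05) -> np.ndarray:
    """Voxel mask from a one-way three-group ANOVA on the training scans.

    Keeps voxels whose activity differs across face/scene/rest at
    ``p < alpha``.  Zero-variance voxels yield an undefined F and are
    excluded, not an error.
    """
    labels = np.asarray(labels, dtype=object)
    groups = []
    for cls in CLASS_ORDER:
        idx = labels == cls
        if idx.sum() < 2:
            raise MvpaError(f"need at least 2 scans per class; class {cls!r} has {int(idx.sum())}")
        groups.append(data[:, idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = f_oneway(*groups, axis=1)
    p = np.where(np.isfinite(p), p, 1.0)
    return p < alpha


@dataclass
class ClassifierModel:
    """Three one-vs-other detectors over a feature-selected voxel set."""

    weights: np.ndarray  # (3, n_features) in CLASS_ORDER
    intercepts: np.ndarray  # (3,)
    lam: float
    feature_mask: np.ndarray  # boolean over the full voxel space
    classes: tuple[str, ...] = CLASS_ORDER

    @property
    def n_voxels_total(self) -> int:
        return int(self.feature_mask.size)


def train(
    data: np.ndarray,
    labels,
    lam: float = 50.0,
    feature_mask: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> ClassifierModel:
    """Fit the three one-vs-other penalized logistic detectors.

    The objective per detector is the summed logistic loss plus
    ``(lam / 2) ||w||^2`` (intercept unpenalized); with scikit-learn's
    parameterization this is ``C = 1 / lam``.  Only labeled scans
    (face/scene/rest) enter the fits; per-class balance is the caller's
    (design-module) contract.
    """
    if lam < 0:
        raise MvpaError("penalty lambda must be non-negative")
    labels = np.asarray(labels, dtype=object)
    if feature_mask is None:
        feature_mask = np.ones(data.shape[0], dtype=bool)
    if not np.any(feature_mask):
        raise MvpaError("feature mask selects no voxels")
    labeled = np.isin(labels, CLASS_ORDER)
    X = data[np.ix_(feature_mask, labeled)].T
    y_all = labels[labeled]
    weights = np.empty((3, X.shape[1]))
    intercepts = np.empty(3)
    for k, cls in enumerate(CLASS_ORDER):
        y = (y_all == cls).astype(int)
        if y.sum() == 0 or y.sum() == y.size:
            raise MvpaError(f"class {cls!r} is empty (or exhaustive) in the training labels")
        C = np.inf if lam == 0 else 1.0 / lam
        clf = LogisticRegression(C=C, solver="lbfgs", tol=tol, max_iter=max_iter)
        clf.fit(X, y)
        weights[k] = clf.coef_[0]
        intercepts[k] = clf.intercept_[0]
    return ClassifierModel(weights=weights, intercepts=intercepts, lam=float(lam), feature_mask=feature_mask)


def penalized_objective(weights: np.ndarray, intercept: float, X: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Summed logistic loss plus (lam/2)||w||^2; the quantity ``train`` minimizes."""
    z = X @ weights + intercept
    # log(1 + exp(-z*yq)) with yq in {-1, +1}, numerically stable
    yq = 2.0 * y - 1.0
    loss = np.logaddexp(0.0, -yq * z).sum()
    return float(loss + 0.5 * lam * np.dot(weights, weights))


def decode(model: ClassifierModel, ts: RoiTimeseries) -> pd.DataFrame:
    """Per-scan evidence timecourse for each detector plus scene - face.

    Returns a DataFrame with onset, block and the four evidence columns;
    each detector value is ``expit(w.x + b)``, guaranteed in [0, 1].
    """
    if ts.n_voxels != model.n_voxels_total:
        raise MvpaError(
            f"timeseries has {ts.n_voxels} voxels but the model was built over {model.n_voxels_total}"
        )
    X = ts.data[model.feature_mask].T
    ev = expit(X @ model.weights.T + model.intercepts)
    out = pd.DataFrame(
        {
            "onset": ts.scan_onsets,
            "block": ts.block_id,
            "face": ev[:, 0],
            "scene": ev[:, 1],
            "rest": ev[:, 2],
        }
    )
    out["scene_minus_face"] = out["scene"] - out["face"]
    return out


@dataclass
class CvResult:
    """Block-wise cross-validation output."""

    evidence: pd.DataFrame  # labeled test scans only, with label/predicted columns
    fold_accuracies: dict
    accuracy: float
    face_scene_accuracy: float
    fold_models: dict = field(default_factory=dict, repr=False)


def _argmax_class(ev: np.ndarray) -> np.ndarray:
    # np.argmax takes the first maximum, which is exactly the documented
    # fixed-order (face, scene, rest) tie-break.
    idx = np.argmax(ev, axis=1)
    return np.asarray(CLASS_ORDER, dtype=object)[idx]


def crossvalidate(
    ts: RoiTimeseries,
    labels: LabelSeries,
    lam: float = 50.0,
    alpha: float = 0.05,
    reselect_per_fold: bool = True,
) -> CvResult:
    """k-fold cross-validation with one fold per acquisition block.

    Each block is scored exactly once by a model never trained on it.
    By default feature selection is re-run within each fold's training
    scans (a deliberate strictness; a single whole-phase selection is
    available via ``reselect_per_fold=False``).  Accuracy is the
    fraction of labeled test scans whose class attains the maximum
    evidence.
    """
    blocks = np.unique(ts.block_id)
    if blocks.size < 2:
        raise MvpaError("cross-validation requires at least 2 blocks")
    lab = labels.labels
    if not reselect_per_fold:
        global_mask = select_features(ts.data[:, np.isin(lab, CLASS_ORDER)], lab[np.isin(lab, CLASS_ORDER)], alpha)
    frames = []
    fold_acc = {}
    fold_models = {}
    for b in blocks:
        test = ts.block_id == b
        train_idx = ~test
        train_lab = lab[train_idx]
        for cls in CLASS_ORDER:
            if (train_lab == cls).sum() == 0 or ((lab[test] == cls).sum() == 0):
                raise MvpaError(f"fold {b}: class {cls!r} missing from train or test scans")
        if reselect_per_fold:
            sel_scans = train_idx & np.isin(lab, CLASS_ORDER)
            mask = select_features(ts.data[:, sel_scans], lab[sel_scans], alpha)
        else:
            mask = global_mask
        model = train(ts.data[:, train_idx], train_lab, lam=lam, feature_mask=mask)
        fold_models[b] = model
        test_labeled = test & np.isin(lab, CLASS_ORDER)
        X = ts.data[np.ix_(mask, test_labeled)].T
        ev = expit(X @ model.weights.T + model.intercepts)
        pred = _argmax_class(ev)
        true = lab[test_labeled]
        frame = pd.DataFrame(
            {
                "onset": ts.scan_onsets[test_labeled],
                "block": ts.block_id[test_labeled],
                "face": ev[:, 0],
                "scene": ev[:, 1],
                "rest": ev[:, 2],
                "label": true,
                "predicted": pred,
            }
        )
        frame["scene_minus_face"] = frame["scene"] - frame["face"]
        frames.append(frame)
        fold_acc[int(b)] = float(np.mean(pred == true))
    evidence = pd.concat(frames, ignore_index=True)
    correct = evidence["predicted"] == evidence["label"]
    fs = evidence["label"].isin(["face", "scene"])
    return CvResult(
        evidence=evidence,
        fold_accuracies=fold_acc,
        accuracy=float(correct.mean()),
        face_scene_accuracy=float(correct[fs].mean()),
        fold_models=fold_models,
    )


def window_average(
    evidence: pd.DataFrame,
    trials: pd.DataFrame,
    windows: dict[str, tuple[int, int]],
    tr_seconds: int = 2,
) -> pd.DataFrame:
    """Per-trial evidence means over trial-relative windows.

    ``trials`` needs onset and duration columns (plus any identifier
    columns, which are carried through).  Windows are half-open
    ``[a, b)`` in seconds from trial onset and must be TR-aligned and
    lie inside the trial.  Output columns are ``{window}_{quantity}``
    for face, scene, rest and scene_minus_face.
    """
    onsets = evidence["onset"].to_numpy()
    rows = []
    carry = [c for c in trials.columns if c not in ("onset", "duration")]
    for _, tr in trials.iterrows():
        row = {c: tr[c] for c in carry}
        t0, dur = tr["onset"], tr["duration"]
        for name, (a, b) in windows.items():
            if a % tr_seconds or b % tr_seconds:
                raise MvpaError(f"window {name} is not TR-aligned")
            if a < 0 or b > dur:
                raise MvpaError(f"window {name} [{a}, {b}) lies outside the {dur}-s trial")
            mask = (onsets >= t0 + a) & (onsets < t0 + b)
            expected = (b - a) // tr_seconds
            if mask.sum() != expected:
                raise MvpaError(
                    f"window {name}: expected {expected} scans in [{t0 + a}, {t0 + b}), found {int(mask.sum())}"
                )
            for col in ("face", "scene", "rest", "scene_minus_face"):
                row[f"{name}_{col}"] = float(evidence.loc[mask, col].mean())
        rows.append(row)
    return pd.DataFrame(rows)
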