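"""Channel-ablation classifier grid with cross-validated AUC.

The experimental logic: four binary condition tests (isALS, isOXIDATIVE,
isHEAT, isOSMOTIC) crossed with 13 channel combinations (DAPI, BIII, one
per RBP, DAPI:BIII, and DAPI:BIII:RBP per RBP) give 52 classifiers.  Each
is evaluated by stratified 10-fold cross-validation repeated over 5
subsets, yielding 50 AUC points per classifier; comparing those AUC
distributions across combinations reveals which marker carries the
phenotype.

Classifiers are trained with SGD on the cross-entropy loss (learning rate
0.001, batch size 32, 10 epochs by default).  Training images receive the
sixfold dihedral augmentation; evaluation images never do.  Crop-level
probabilities are averaged to field-image level and then to culture level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import nn
from .preprocessing import (BIII, DAPI, ChannelCombination, IMAGENET,
                            NormalizationConstants, augment, preprocess_field)

logger = logging.getLogger(__name__)

TESTS = ("isALS", "isOXIDATIVE", "isHEAT", "isOSMOTIC")

_TEST_POSITIVE = {"isALS": "mutant", "isOXIDATIVE": "oxidative",
                  "isHEAT": "heat", "isOSMOTIC": "osmotic"}


@dataclass(frozen=True)
class ClassifierConfig:
    """Training hyperparameters; defaults follow the reference protocol."""

    backbone: str = "scratch_small_cnn"
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 10
    momentum: float = 0.9
    n_classes: int = 2
    seed: int = 0
    cnn_channels: tuple[int, ...] = (8, 16, 32, 32)
    dtype: str = "float32"  # training precision; float32 halves CPU time

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_classes != 2:
            raise ValueError("binary classification only: n_classes must be 2")


def enumerate_channel_combinations(rbp_markers: Sequence[str]) -> list[ChannelCombination]:
    """The legal channel combinations, in deterministic order:
    [DAPI], [BIII], one single-RBP per marker, [DAPI:BIII], and one
    [DAPI:BIII:RBP] per marker.  Five RBPs give the canonical 13."""
    if len(set(rbp_markers)) != len(rbp_markers):
        raise ValueError(f"duplicate RBP markers: {list(rbp_markers)}")
    for m in rbp_markers:
        if m in (DAPI, BIII):
            raise ValueError(f"{m} is not an RBP marker")
    combos = [ChannelCombination((DAPI,)), ChannelCombination((BIII,))]
    combos += [ChannelCombination((m,)) for m in rbp_markers]
    combos.append(ChannelCombination((DAPI, BIII)))
    combos += [ChannelCombination((DAPI, BIII, m)) for m in rbp_markers]
    return combos


def make_stratified_folds(labels: Sequence[int], k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each item to one of ``k`` stratified folds (per-fold class
    counts within 1 of n_class / k); returns an int array of fold ids."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    small = counts < k
    if small.any():
        raise ValueError(f"class(es) {classes[small].tolist()} have fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def roc_auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """P(score_pos > score_neg) + 0.5 * P(tie), computed from midranks."""
    a = np.asarray(scores_pos, dtype=float)
    b = np.asarray(scores_neg, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[:a.size].sum() - a.size * (a.size + 1) / 2
    return float(u / (a.size * b.size))


# --------------------------------------------------------------------------
# dataset plumbing

@dataclass
class FieldRecord:
    """One field of view, MIP-ready: marker -> z-stack, plus lineage keys."""

    channels: dict[str, np.ndarray]
    image_id: str
    culture: str
    condition: str
    cell_line: str
    experiment: str


class FieldDataset:
    """A list of `FieldRecord` with helpers for test selection."""

    def __init__(self, records: list[FieldRecord]):
        self.records = records

    @classmethod
    def from_plate(cls, fields) -> "FieldDataset":
        """Build from `synthetic.generate_plate` output, renaming the
        generic RBP channel to its marker name."""
        records = []
        for fs, _gt in fields:
            md = fs.metadata
            rbp = md.get("rbp_marker", "RBP")
            channels = {(rbp if m == "RBP" else m): z for m, z in fs.channels.items()}
            culture = f"{md['experiment']}|{md.get('plate', 'P1')}|{md['well']}"
            records.append(FieldRecord(
                channels=channels,
                image_id=f"{culture}|f{md['field']}",
                culture=culture, condition=md["condition"],
                cell_line=md["cell_line"], experiment=md["experiment"]))
        return cls(records)

    @property
    def markers(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out |= set(r.channels)
        return out

    def select_for_test(self, test: str) -> tuple[list[FieldRecord], np.ndarray]:
        """Records relevant to a binary test plus 0/1 labels.

        Positives: cultures in the test's condition (for isALS, also any
        culture from a MUT* line).  Negatives: untreated control-line
        cultures.  Everything else is excluded.
        """
        if test not in _TEST_POSITIVE:
            raise ValueError(f"unknown test {test!r}; known: {list(TESTS)}")
        pos_cond = _TEST_POSITIVE[test]
        records, labels = [], []
        for r in self.records:
            mutant_line = r.cell_line.upper().startswith("MUT")
            if test == "isALS":
                if r.condition == "mutant" or (mutant_line and r.condition == "control"):
                    lab = 1
                elif r.condition == "control" and not mutant_line:
                    lab = 0
                else:
                    continue
            else:
                if r.condition == pos_cond:
                    lab = 1
                elif r.condition == "control":
                    lab = 0
                else:
                    continue
            records.append(r)
            labels.append(lab)
        return records, np.asarray(labels, dtype=int)


# --------------------------------------------------------------------------
# training

class TrainedClassifier:
    """A trained network bound to its channel combination and preprocessing
    geometry; callable on preprocessed crops or raw field records."""

    def __init__(self, net: nn.Sequential, combo: ChannelCombination,
                 config: ClassifierConfig, input_size: int,
                 tile_size: int, constants: NormalizationConstants = IMAGENET):
        self.net = net
        self.combo = combo
        self.config = config
        self.input_size = input_size
        self.tile_size = tile_size
        self.constants = constants

    def predict_proba(self, crops: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Probability of the positive class for (N, H, W, 3) crops."""
        crops = np.asarray(crops)
        dtype = np.dtype(self.config.dtype)
        out = np.empty(len(crops))
        for i in range(0, len(crops), batch_size):
            x = np.ascontiguousarray(crops[i:i + batch_size].transpose(0, 3, 1, 2),
                                     dtype=dtype)
            out[i:i + batch_size] = nn.softmax(self.net.forward(x).astype(np.float64))[:, 1]
        return out

    def logit_and_input_gradient(self, crop: np.ndarray,
                                 class_index: int | None = None) -> tuple[float, int, np.ndarray]:
        """Predicted-class logit and its gradient w.r.t. one (H, W, 3) crop."""
        x = np.asarray(crop)[None].transpose(0, 3, 1, 2)
        logits = self.net.forward(x)[0]
        if class_index is None:
            class_index = int(np.argmax(logits))
        dx = self.net.input_gradient(x, class_index)
        return float(logits[class_index]), class_index, dx[0].transpose(1, 2, 0)


def _build_net(config: ClassifierConfig, input_shape: tuple[int, int, int],
               rng: np.random.Generator) -> nn.Sequential:
    if config.backbone == "scratch_small_cnn":
        return nn.SmallCNN(rng, in_ch=input_shape[0], channels=config.cnn_channels,
                           n_classes=config.n_classes)
    if config.backbone == "linear":
        return nn.LinearNet(rng, input_shape, n_classes=config.n_classes)
    if config.backbone == "pretrained_mobilenet_v2":
        raise NotImplementedError(
            "the pretrained MobileNetV2 backbone requires a deep-learning "
            "framework with published weights; use backbone='scratch_small_cnn'")
    raise ValueError(f"unknown backbone {config.backbone!r}")


def train_classifier(train_images: np.ndarray, labels: Sequence[int],
                     config: ClassifierConfig, augment_training: bool = True,
                     combo: ChannelCombination | None = None,
                     tile_size: int = 270) -> TrainedClassifier:
    """Train a binary classifier on normalized (N, H, W, 3) images.

    Training images receive the sixfold dihedral augmentation before
    shuffling into SGD batches; given the same config seed and data the
    run is deterministic.
    """
    labels = np.asarray(labels, dtype=int)
    x = np.asarray(train_images)
    if x.ndim != 4 or x.shape[3] != 3:
        raise ValueError(f"expected (N, H, W, 3) images, got shape {x.shape}")
    if np.unique(labels).size < 2:
        raise ValueError("training set contains a single class; need both")
    if augment_training:
        xs, ys = [], []
        for img, lab in zip(x, labels):
            for aug in augment(img):
                xs.append(aug)
                ys.append(lab)
        x = np.stack(xs)
        labels = np.asarray(ys)
    dtype = np.dtype(config.dtype)
    x = np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=dtype)

    ss = np.random.SeedSequence(config.seed & 0x7FFFFFFF)
    rng_init, rng_order = (np.random.default_rng(c) for c in ss.spawn(2))
    net = _build_net(config, x.shape[1:], rng_init)
    for layer in net.layers:
        for name in ("W", "b", "dW", "db"):
            if hasattr(layer, name):
                setattr(layer, name, getattr(layer, name).astype(dtype))
    velocity = None
    n = len(x)
    for _epoch in range(config.epochs):
        order = rng_order.permutation(n)
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            net.zero_grad()
            logits = net.forward(x[idx])
            _loss, dlogits = nn.cross_entropy_grad(logits, labels[idx])
            net.backward(dlogits.astype(dtype))
            velocity = nn.sgd_step(net, config.learning_rate, config.momentum, velocity)
    return TrainedClassifier(net, combo or ChannelCombination((DAPI,)), config,
                             input_size=x.shape[2], tile_size=tile_size)


# --------------------------------------------------------------------------
# cross-validation grid

def _crops_for_records(records: Iterable[FieldRecord], combo: ChannelCombination,
                       input_size: int, tile_size: int,
                       cutoff_percent: float = 0.1) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Preprocess all fields for one combination; returns stacked crops and
    per-crop (image_id, culture) lineage."""
    crops, lineage = [], []
    for r in records:
        tiles = preprocess_field(r.channels, combo, cutoff_percent=cutoff_percent,
                                 tile_size=tile_size, size=input_size)
        for t_idx, t in enumerate(tiles):
            crops.append(t)
            lineage.append((r.image_id, r.culture))
    return np.stack(crops), lineage


def run_cv_grid(dataset: FieldDataset, tests: Sequence[str] = TESTS,
                combinations: Sequence[ChannelCombination] | None = None,
                n_subsets: int = 5, k: int = 10,
                config: ClassifierConfig | None = None,
                input_size: int = 224, tile_size: int = 270,
                split_level: str = "image",
                return_predictions: bool = False):
    """Repeated stratified k-fold CV over the (test, combination) grid.

    For every grid cell: ``n_subsets`` independent shuffles x ``k`` folds,
    training on the augmented train folds and scoring the never-augmented
    held-out fold; one AUC row per (test, combination, subset, fold).

    ``split_level='image'`` keeps all 16 crops of a field together across
    the train/test boundary (leakage-free default); ``'crop'`` shuffles
    crops independently, mirroring a crop-level protocol.

    Returns the fold-AUC table (and, if requested, the held-out crop-level
    prediction rows from the first subset for downstream aggregation).
    """
    config = config or ClassifierConfig()
    if combinations is None:
        rbps = sorted(dataset.markers - {DAPI, BIII})
        combinations = enumerate_channel_combinations(rbps)
    if split_level not in ("image", "crop"):
        raise ValueError("split_level must be 'image' or 'crop'")
    rows = []
    pred_rows = []
    for t_idx, test in enumerate(tests):
        records, labels = dataset.select_for_test(test)
        for c_idx, combo in enumerate(combinations):
            if not set(combo.members) <= dataset.markers:
                logger.warning("skipping (%s, %s): marker(s) %s absent",
                               test, combo.name,
                               sorted(set(combo.members) - dataset.markers))
                continue
            usable = [i for i, r in enumerate(records) if set(combo.members) <= set(r.channels)]
            recs = [records[i] for i in usable]
            labs = labels[usable]
            crops, lineage = _crops_for_records(recs, combo, input_size, tile_size)
            crops_per_field = len(crops) // len(recs)
            crop_labels = np.repeat(labs, crops_per_field)
            for subset in range(n_subsets):
                # deterministic per-(cell, subset) seed derived from the grid coords
                fold_seed = (config.seed * 1_000_003 + t_idx * 10_007
                             + c_idx * 101 + subset) % (2 ** 31)
                if split_level == "image":
                    folds_f = make_stratified_folds(labs, k=k, seed=fold_seed)
                    crop_folds = np.repeat(folds_f, crops_per_field)
                else:
                    crop_folds = make_stratified_folds(crop_labels, k=k, seed=fold_seed)
                for fold in range(k):
                    test_mask = crop_folds == fold
                    clf = train_classifier(crops[~test_mask], crop_labels[~test_mask],
                                           replace(config, seed=fold_seed + fold),
                                           combo=combo, tile_size=tile_size)
                    p = clf.predict_proba(crops[test_mask])
                    y = crop_labels[test_mask]
                    rows.append({"test": test, "combination": combo.name,
                                 "subset": subset, "fold": fold,
                                 "auc": roc_auc(p[y == 1], p[y == 0])})
                    if return_predictions and subset == 0:
                        for (img, cult), prob, lab in zip(
                                [lineage[i] for i in np.nonzero(test_mask)[0]], p, y):
                            pred_rows.append({"test": test, "combination": combo.name,
                                              "image": img, "culture": cult,
                                              "label": int(lab), "p": float(prob)})
    table = pd.DataFrame(rows, columns=["test", "combination", "subset", "fold", "auc"])
    if return_predictions:
        return table, pd.DataFrame(pred_rows)
    return table


# --------------------------------------------------------------------------
# prediction aggregation

@dataclass
class PredictionTable:
    """Class probabilities at crop, field-image and culture level, with the
    averaging lineage preserved (image p = mean of its crops; culture p =
    mean of its images)."""

    crops: pd.DataFrame     # columns: crop, image, culture, p
    images: pd.DataFrame    # columns: image, culture, p, n_crops
    cultures: pd.DataFrame  # columns: culture, p, n_images


def aggregate_predictions(crop_probs: pd.DataFrame) -> PredictionTable:
    """Average crop probabilities to image level, then image probabilities
    to culture level (plain arithmetic means at each stage)."""
    required = {"crop", "image", "culture", "p"}
    missing = required - set(crop_probs.columns)
    if missing:
        raise ValueError(f"crop table missing column(s) {sorted(missing)}")
    orphan = crop_probs["image"].isna() | crop_probs["culture"].isna()
    if orphan.any():
        bad = crop_probs.loc[orphan, "crop"].tolist()[:5]
        raise ValueError(f"orphan crop(s) without lineage: {bad}")
    images = (crop_probs.groupby(["image", "culture"], sort=True)["p"]
              .agg(["mean", "size"]).reset_index()
              .rename(columns={"mean": "p", "size": "n_crops"}))
    cultures = (images.groupby("culture", sort=True)["p"]
                .agg(["mean", "size"]).reset_index()
                .rename(columns={"mean": "p", "size": "n_images"}))
    return PredictionTable(crops=crop_probs.copy(), images=images, cultures=cultures)


def apply_classifier(clf: TrainedClassifier, dataset: FieldDataset,
                     conditions: Sequence[str] | None = None) -> PredictionTable:
    """Score any dataset with a trained model (cross-condition transfer):
    preprocess with the model's own combination and geometry, predict every
    crop, and aggregate crop -> image -> culture."""
    records = dataset.records
    if conditions is not None:
        records = [r for r in records if r.condition in conditions]
    missing = set(clf.combo.members) - {m for r in records for m in r.channels}
    if missing:
        raise ValueError(f"dataset lacks marker(s) {sorted(missing)} "
                         f"required by combination {clf.combo.name!r}")
    crops, lineage = _crops_for_records(records, clf.combo, clf.input_size, clf.tile_size)
    p = clf.predict_proba(crops)
    meta = {r.culture: r for r in records}
    table = pd.DataFrame({
        "crop": [f"{img}|c{i}" for i, (img, _) in enumerate(lineage)],
        "image": [img for img, _ in lineage],
        "culture": [cult for _, cult in lineage],
        "p": p,
    })
    pt = aggregate_predictions(table)
    pt.cultures["condition"] = [meta[c].condition for c in pt.cultures["culture"]]
    pt.cultures["cell_line"] = [meta[c].cell_line for c in pt.cultures["culture"]]
    pt.cultures["experiment"] = [meta[c].experiment for c in pt.cultures["culture"]]
    return pt
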