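"""Training, cross-validation, volume-level prediction and evaluation.

Patient-level data handling follows the no-leakage rule: a fraction of
patients is held out as the test set, the remainder partitioned into
stratified folds (stratum = tumour-volume half relative to the cohort
median), and no patient ever appears on both sides of a boundary.

Training uses Adam on the hybrid Dice/BCE/boundary loss. A batch is always
a window of consecutive slices from ONE study, never mixed across patients,
because the inter-slice attention reads the batch axis as adjacent slices.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import nn
from .net import RST2G, RST2GConfig, build_variant, VARIANTS, save_checkpoint
from .objectives import LossWeights, dsc, ji, rvd, total_loss
from .volumes_io import (DCEStudy, SliceBatch, ValidationError, Volume,
                         assemble_slice_batches)

__all__ = [
    "TrainConfig", "FoldSplit", "split_patients", "train", "predict_volume",
    "stitch_predictions", "evaluate", "evaluate_model", "run_ablation",
]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 4
    epochs: int = 20
    seed: int = 0
    patience: int = 10          # early stopping on validation DSC
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay <= 0:
            raise ValueError("learning rate and weight decay must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclasses.dataclass(frozen=True)
class FoldSplit:
    """Patient-level partition: disjoint folds plus a held-out test set."""

    folds: tuple[tuple[str, ...], ...]
    test_ids: tuple[str, ...]
    strata: dict[str, int]

    def __post_init__(self):
        seen: set[str] = set()
        for fold in self.folds:
            overlap = seen & set(fold)
            if overlap:
                raise ValidationError(f"patients in more than one fold: {overlap}")
            seen |= set(fold)
        if seen & set(self.test_ids):
            raise ValidationError("test patients overlap the training folds")

    @property
    def train_ids(self) -> tuple[str, ...]:
        return tuple(pid for fold in self.folds for pid in fold)


def split_patients(studies: Sequence[DCEStudy], k: int = 5,
                   test_frac: float = 0.3, seed: int = 0) -> FoldSplit:
    """Hold out ``test_frac`` of patients, stratified k-fold the rest.

    Stratum = tumour volume above/below the cohort median. Both the hold-out
    draw and the fold assignment are round-robin within each stratum after a
    seeded shuffle, so every fold receives a balanced volume mix and the
    split is deterministic per seed.
    """
    ids = [s.patient_id for s in studies]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate patient ids in cohort")
    volumes = {s.patient_id: s.tumor_volume_voxels for s in studies}
    median = float(np.median(list(volumes.values())))
    strata = {pid: int(volumes[pid] > median) for pid in ids}

    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    train_ids: list[str] = []
    for stratum in (0, 1):
        members = sorted(pid for pid in ids if strata[pid] == stratum)
        rng.shuffle(members)
        n_test = int(round(test_frac * len(members)))
        test_ids += members[:n_test]
        train_ids += members[n_test:]
    if len(train_ids) < k:
        raise ValidationError(
            f"only {len(train_ids)} training patients for k={k} folds")

    folds: list[list[str]] = [[] for _ in range(k)]
    cursor = 0
    for stratum in (0, 1):
        for pid in [p for p in train_ids if strata[p] == stratum]:
            folds[cursor % k].append(pid)
            cursor += 1
    return FoldSplit(folds=tuple(tuple(f) for f in folds),
                     test_ids=tuple(test_ids), strata=strata)


def _study_batches(studies: Sequence[DCEStudy], batch_size: int
                   ) -> list[SliceBatch]:
    batches: list[SliceBatch] = []
    for study in studies:
        batches.extend(assemble_slice_batches(study, batch_size))
    return batches


def _mask_target(study_lookup: dict[int, DCEStudy], batch: SliceBatch,
                 masks: dict[int, np.ndarray], key: int) -> np.ndarray:
    mask = masks[key]
    return mask[list(batch.slice_indices)][:, None, :, :]


def train(model: RST2G, studies: Sequence[DCEStudy], cfg: TrainConfig,
          val_studies: Sequence[DCEStudy] = (),
          ) -> tuple[RST2G, dict]:
    """Optimise the model on a cohort; returns (model, history).

    history: per-step losses, per-epoch means, and per-epoch validation DSC
    when validation studies are supplied (early stopping with the configured
    patience restores the best weights). Aborts on a non-finite loss.
    """
    weights = LossWeights(lam=model.cfg.lam, beta=model.cfg.beta)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate,
                  weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)

    per_study = [(s, assemble_slice_batches(s, cfg.batch_size)) for s in studies]
    masks = {id(s): s.mask.voxels for s, _ in per_study}
    pairs = [(id(s), b) for s, batch_list in per_study for b in batch_list]

    history: dict = {"step_loss": [], "epoch_loss": [], "val_dsc": []}
    best = {"dsc": -1.0, "state": None, "epoch": -1}
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        model.train()
        epoch_losses = []
        for j in order:
            key, batch = pairs[j]
            target = masks[key][list(batch.slice_indices)][:, None, :, :]
            logits = model.training_logits(batch)
            probs = logits.sigmoid()
            loss, _ = total_loss(probs, nn.Tensor(target), weights)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {value}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            history["step_loss"].append(value)
            epoch_losses.append(value)
        history["epoch_loss"].append(float(np.mean(epoch_losses)))

        if val_studies:
            scores = [dsc(predict_volume(model, s, cfg.batch_size,
                                         model.cfg.threshold).voxels,
                          s.mask.voxels) for s in val_studies]
            val = float(np.mean(scores))
            history["val_dsc"].append(val)
            if val > best["dsc"]:
                best = {"dsc": val, "state": model.state_dict(), "epoch": epoch}
            elif epoch - best["epoch"] >= cfg.patience:
                break
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    if cfg.checkpoint_path:
        save_checkpoint(model, cfg.checkpoint_path)
    return model, history


def predict_volume(model: RST2G, study: DCEStudy, batch_size: int = 4,
                   threshold: float | None = None) -> Volume:
    """Segment a whole study: batch, forward, drop padding, stitch, threshold."""
    threshold = model.cfg.threshold if threshold is None else threshold
    batches = assemble_slice_batches(study, batch_size)
    model.eval()
    prob_slices = []
    with nn.no_grad():
        for batch in batches:
            out = model.forward(batch)
            probs = out.probabilities[:, 0]
            keep = batch.batch_size - batch.n_padded
            prob_slices.append(probs[:keep])
    probs = np.concatenate(prob_slices, axis=0)
    mask = (probs >= threshold).astype(np.float32)
    return Volume(mask, study.pre.spacing, study.patient_id)


def stitch_predictions(batches: Sequence[SliceBatch],
                       per_batch_maps: Sequence[np.ndarray]) -> np.ndarray:
    """Reassemble per-batch (B,H,W) maps into a volume, dropping padding.

    Batches must come from :func:`assemble_slice_batches` in order.
    """
    slabs = []
    for batch, maps in zip(batches, per_batch_maps):
        keep = batch.batch_size - batch.n_padded
        slabs.append(np.asarray(maps)[:keep])
    return np.concatenate(slabs, axis=0)


def evaluate(studies: Sequence[DCEStudy],
             predict_fn: Callable[[DCEStudy], np.ndarray],
             csv_path: str | Path | None = None) -> pd.DataFrame:
    """Per-study DSC/JI/RVD plus cohort mean and SD rows.

    Studies with an empty ground-truth mask are skipped with a warning row
    (RVD is undefined there). SD of a single study is reported as 0.
    """
    rows = []
    for study in studies:
        if study.mask.voxels.sum() == 0:
            import warnings
            warnings.warn(f"skipping {study.patient_id}: empty ground truth")
            continue
        pred = np.asarray(predict_fn(study))
        rows.append({"patient_id": study.patient_id,
                     "dsc": dsc(pred, study.mask.voxels),
                     "ji": ji(pred, study.mask.voxels),
                     "rvd": rvd(pred, study.mask.voxels)})
    if not rows:
        raise ValidationError("no evaluable studies (all ground truths empty)")
    table = pd.DataFrame(rows)
    summary = pd.DataFrame([
        {"patient_id": "mean", "dsc": table["dsc"].mean(),
         "ji": table["ji"].mean(), "rvd": table["rvd"].mean()},
        {"patient_id": "sd", "dsc": table["dsc"].std(ddof=0),
         "ji": table["ji"].std(ddof=0), "rvd": table["rvd"].std(ddof=0)},
    ])
    table = pd.concat([table, summary], ignore_index=True)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    return table


def evaluate_model(model: RST2G, studies: Sequence[DCEStudy],
                   batch_size: int = 4,
                   csv_path: str | Path | None = None) -> pd.DataFrame:
    return evaluate(
        studies,
        lambda s: predict_volume(model, s, batch_size).voxels,
        csv_path=csv_path)


def run_ablation(studies: Sequence[DCEStudy], base_cfg: RST2GConfig,
                 train_cfg: TrainConfig,
                 variants: Sequence[str] = VARIANTS,
                 test_frac: float = 0.3,
                 csv_path: str | Path | None = None) -> pd.DataFrame:
    """Train and evaluate each structural variant under identical data/seed.

    One row per variant: held-out mean/SD DSC and JI plus parameter count.
    """
    unknown = set(variants) - set(VARIANTS)
    if unknown:
        raise ValueError(f"unknown variants: {sorted(unknown)}")
    n_train = len(studies) - int(round(test_frac * len(studies)))
    split = split_patients(studies, k=max(2, min(5, n_train)),
                           test_frac=test_frac, seed=train_cfg.seed)
    by_id = {s.patient_id: s for s in studies}
    train_set = [by_id[p] for p in split.train_ids]
    test_set = [by_id[p] for p in split.test_ids]

    rows = []
    for name in variants:
        model = build_variant(base_cfg, name)
        model, _ = train(model, train_set, train_cfg)
        table = evaluate_model(model, test_set, train_cfg.batch_size)
        mean = table[table.patient_id == "mean"].iloc[0]
        sd = table[table.patient_id == "sd"].iloc[0]
        rows.append({"variant": name, "dsc_mean": mean.dsc, "dsc_sd": sd.dsc,
                     "ji_mean": mean.ji, "ji_sd": sd.ji,
                     "n_parameters": model.num_parameters()})
    table = pd.DataFrame(rows)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    return table
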