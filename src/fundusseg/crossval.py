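"""Label-stratified ordered cross-validation and the evaluation loop.

Folds follow the convention of grouping samples by class in their
original order and dealing each class's run of samples into k contiguous
blocks, so fold membership is reproducible from the dataset ordering
alone (no shuffling).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import evaluate_masks
from .network import NetworkConfig
from .pipeline import crop_resize, detect_roi, resize_image, resize_mask, segment_fundus
from .training import MMLMConfig, TrainingPair, train_alm, train_mlm, train_mmlm

__all__ = ["kfold_splits", "run_crossval"]

_TRAINERS = {"alm": train_alm, "mlm": train_mlm, "mmlm": train_mmlm}


def kfold_splits(labels, k: int = 5):
    """Ordered, label-grouped k-fold assignment.

    ``labels`` is one label per item (use a constant for unlabelled
    data).  Within each label, items keep their original order and are
    split into k contiguous blocks; fold f unions block f of every
    label.  Returns a list of ``(train_indices, test_indices)`` pairs.
    A label with fewer than k items concentrates in the early folds.
    """
    labels = list(labels)
    n = len(labels)
    if n < k:
        raise ValueError("need at least k items")
    fold_of = np.empty(n, dtype=int)
    seen = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    for lab in seen:
        idx = [i for i, l in enumerate(labels) if l == lab]
        blocks = np.array_split(np.asarray(idx), k)
        for f, block in enumerate(blocks):
            fold_of[block] = f
    splits = []
    everything = np.arange(n)
    for f in range(k):
        test = everything[fold_of == f]
        train = everything[fold_of != f]
        splits.append((train.tolist(), test.tolist()))
    return splits


def _roi_training_pairs(samples, indices, oc_side, margin):
    """Stage-2 pairs: ground-truth-disc ROI crops of image and cup mask."""
    pairs = []
    for i in indices:
        s = samples[i]
        roi = detect_roi(s.od_mask, margin=margin)
        img = crop_resize(s.image, roi, out_side=oc_side, kind="image")
        msk = crop_resize(s.oc_mask, roi, out_side=oc_side, kind="mask")
        pairs.append(TrainingPair(image=img, mask=msk, index=i))
    return pairs


def run_crossval(
    samples,
    od_cfg: NetworkConfig,
    oc_cfg: NetworkConfig,
    train_cfg: MMLMConfig,
    strategy: str = "mmlm",
    k: int = 5,
    margin: float = 0.5,
):
    """Train and evaluate the two-stage pipeline with k-fold cross-validation.

    ``samples`` provide ``image``, ``od_mask``, ``oc_mask`` and ``label``
    attributes (e.g. phantom samples or manifest-backed records).  Each
    fold trains a disc network on full images and a cup network on
    ground-truth-disc ROI crops, then evaluates the full two-stage
    pipeline on the held-out fold.

    Returns ``(od_table, oc_table)`` DataFrames with one row per image
    (columns: index, fold, f_score, iou, sensitivity, specificity) plus
    fold means and the grand mean accessible via groupby.
    """
    if strategy not in _TRAINERS:
        raise ValueError(f"strategy must be one of {sorted(_TRAINERS)}")
    trainer = _TRAINERS[strategy]
    labels = [getattr(s, "label", 0) for s in samples]
    od_rows, oc_rows = [], []
    for fold, (train_idx, test_idx) in enumerate(kfold_splits(labels, k=k)):
        od_train = [
            TrainingPair(
                image=resize_image(samples[i].image, (od_cfg.input_side, od_cfg.input_side)),
                mask=resize_mask(samples[i].od_mask, (od_cfg.input_side, od_cfg.input_side)),
                index=i,
            )
            for i in train_idx
        ]
        oc_train = _roi_training_pairs(samples, train_idx, oc_cfg.input_side, margin)
        od_net, _ = trainer(od_train, od_cfg, train_cfg)
        oc_net, _ = trainer(oc_train, oc_cfg, train_cfg)
        for i in test_idx:
            s = samples[i]
            od_mask, oc_mask = segment_fundus(s.image, od_net, oc_net, margin=margin)
            for rows, pred, true in ((od_rows, od_mask, s.od_mask), (oc_rows, oc_mask, s.oc_mask)):
                sc = evaluate_masks(pred, true)
                rows.append(
                    dict(
                        index=i,
                        fold=fold,
                        f_score=sc.f_score,
                        iou=sc.iou,
                        sensitivity=sc.sensitivity,
                        specificity=sc.specificity,
                    )
                )
    return pd.DataFrame(od_rows), pd.DataFrame(oc_rows)
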