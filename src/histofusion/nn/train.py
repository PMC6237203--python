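"""Two-stage momentum-SGD training of the fusion model and biomarker
extraction.

Stage 1 trains the patch CNN on individual patches with the multitask
Gleason loss.  Stage 2 freezes the CNN (configurable), precomputes per-patch
image features, and trains the genomic MLP, the fusion FC and the LSTM on
chunked patch sequences with the same loss.  The learning rate starts at
``config.lr`` and is annealed by ``config.anneal_factor`` after every
anneal interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (FusionConfig, FusionModel, chunk_sequence, multitask_loss,
                    one_hot, sequence_biomarker)


@dataclass
class PatientSample:
    """Prepared inputs for one patient: ordered patch images + labels."""

    patient_id: str
    images: np.ndarray            # (n_patches, C, H, W) float in [0,1]
    primary: int                  # primary Gleason pattern
    gleason_sum: int              # primary + secondary
    scores: np.ndarray | None = None  # pathway score vector


class SGDMomentum:
    """Momentum SGD with decoupled-from-nothing classic weight decay."""

    def __init__(self, params, momentum: float, weight_decay: float):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float):
        for p in self.params:
            g = p.grad + self.weight_decay * p.value
            p.vel = self.momentum * p.vel - lr * g
            p.value += p.vel


def lr_at(iteration: int, lr0: float, anneal: float, interval: int) -> float:
    """Step-decay schedule: lr0 * anneal^(iteration // interval)."""
    return lr0 * anneal ** (iteration // interval)


def _check_classes(labels, classes, what: str):
    present = set(labels)
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(
            f"{what} classes {missing} absent from training labels; "
            "adjust the configured class sets")


def images_to_array(images) -> np.ndarray:
    """uint8 HWC patch images -> float NCHW in [0, 1]."""
    arr = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    if arr.ndim == 3:
        arr = arr[:, :, :, None]
    arr = arr / 255.0 if arr.max() > 1.5 else arr
    return arr.transpose(0, 3, 1, 2)


def train(samples: list[PatientSample], config: FusionConfig,
          train_ids: list[str] | None = None
          ) -> tuple[FusionModel, pd.DataFrame]:
    """Run both training stages; returns the model and a per-iteration log."""
    rng = np.random.default_rng(config.seed)
    model = FusionModel(config, rng)
    train_ids = set(train_ids) if train_ids is not None \
        else {s.patient_id for s in samples}
    tr = [s for s in samples if s.patient_id in train_ids]
    if not tr:
        raise ValueError("no training samples")

    _check_classes([s.primary for s in tr], config.primary_classes, "primary")
    _check_classes([s.gleason_sum for s in tr], config.sum_classes, "sum")
    if model.use_genomic:
        missing = [s.patient_id for s in tr if s.scores is None]
        if missing:
            raise ValueError(f"fusion mode: missing pathway scores for "
                             f"{missing[:3]}...")
        S = np.stack([s.scores for s in tr])
        model.score_mean = S.mean(axis=0)
        model.score_sd = np.where(S.std(axis=0) == 0, 1.0, S.std(axis=0))

    log = []

    # ---- stage 1: CNN on individual patches ------------------------------
    X = np.concatenate([s.images for s in tr])
    yp = np.concatenate([[s.primary] * len(s.images) for s in tr])
    ys = np.concatenate([[s.gleason_sum] * len(s.images) for s in tr])
    Tp = one_hot(yp, config.primary_classes)
    Ts = one_hot(ys, config.sum_classes)
    opt1 = SGDMomentum(model.stage1_params(), config.momentum,
                       config.weight_decay)
    n = len(X)
    for it in range(config.iters_cnn):
        lr = lr_at(it, config.lr, config.anneal_factor,
                   config.anneal_interval_cnn)
        idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
        pred_p, pred_s = model.forward_patches(X[idx])
        loss = multitask_loss(pred_p, pred_s, Tp[idx], Ts[idx],
                              reduction=config.loss_reduction)
        opt1.zero_grad()
        scale = 1.0 / len(idx) if config.loss_reduction == "mean" else 1.0
        model.backward_patches(pred_p * scale, pred_s * scale,
                               Tp[idx] * scale, Ts[idx] * scale)
        opt1.step(lr)
        log.append({"stage": 1, "iteration": it, "lr": lr, "loss": loss})

    # ---- stage 2: MLP + fusion FC + LSTM on chunked sequences ------------
    chunks, masks, cTp, cTs, cscores = [], [], [], [], []
    for s in tr:
        feats = model.cnn.features(s.images)
        ch, mk = chunk_sequence(feats, config.unroll_length)
        for k in range(len(ch)):
            chunks.append(ch[k])
            masks.append(mk[k])
            cTp.append(one_hot([s.primary], config.primary_classes)[0])
            cTs.append(one_hot([s.gleason_sum], config.sum_classes)[0])
            if model.use_genomic:
                cscores.append((s.scores - model.score_mean) / model.score_sd)
    chunks = np.stack(chunks)
    masks = np.stack(masks)
    cTp, cTs = np.stack(cTp), np.stack(cTs)
    cscores = np.stack(cscores) if cscores else None

    opt2 = SGDMomentum(model.stage2_params(include_cnn=not config.freeze_cnn),
                       config.momentum, config.weight_decay)
    n = len(chunks)
    for it in range(config.iters_lstm):
        lr = lr_at(it, config.lr, config.anneal_factor,
                   config.anneal_interval_lstm)
        idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
        sc = cscores[idx] if cscores is not None else None
        pred_p, pred_s, _ = model.forward_sequence(chunks[idx], masks[idx], sc)
        loss = multitask_loss(pred_p, pred_s, cTp[idx], cTs[idx],
                              reduction=config.loss_reduction)
        opt2.zero_grad()
        scale = 1.0 / len(idx) if config.loss_reduction == "mean" else 1.0
        model.backward_sequence(pred_p * scale, pred_s * scale,
                                cTp[idx] * scale, cTs[idx] * scale)
        opt2.step(lr)
        log.append({"stage": 2, "iteration": it, "lr": lr, "loss": loss})

    return model, pd.DataFrame(log)


def extract_biomarkers(model: FusionModel,
                       samples: list[PatientSample]) -> pd.DataFrame:
    """Pooled-LSTM biomarker vector per patient (deterministic inference)."""
    rows = {}
    for s in samples:
        feats = model.cnn.features(s.images)
        sc = None
        if model.use_genomic:
            if s.scores is None:
                raise ValueError(
                    f"patient {s.patient_id}: pathway scores required in "
                    "fusion mode")
            sc = (s.scores - model.score_mean) / model.score_sd
        rows[s.patient_id] = sequence_biomarker(model, feats, sc)
    df = pd.DataFrame(rows).T
    df.columns = [f"v{j}" for j in range(df.shape[1])]
    df.index.name = "patient_id"
    return df


def extract_cnn_biomarkers(model: FusionModel,
                           samples: list[PatientSample]) -> pd.DataFrame:
    """CNN-only biomarkers: mean penultimate-layer feature over patches."""
    rows = {s.patient_id: model.cnn.features(s.images).mean(axis=0)
            for s in samples}
    df = pd.DataFrame(rows).T
    df.columns = [f"v{j}" for j in range(df.shape[1])]
    df.index.name = "patient_id"
    return df
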