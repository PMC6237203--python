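"""The fusion biomarker model: patch CNN, pathway-score MLP, fusion FC,
peephole LSTM over the spatial patch sequence, average pooling, and the
multitask Gleason loss.

The model predicts, for every slide (or chunk of its patch sequence), the
primary Gleason pattern and the Gleason sum; the supervised signal forces
the pooled LSTM output — the "computational biomarker" vector — to encode
the pattern composition of the slide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .layers import Conv2d, Flatten, Linear, MaxPool2, ReLU, Sequential, softmax
from .lstm import PeepholeLSTM

EPS = 1e-12


@dataclass
class FusionConfig:
    """Architecture and optimization settings.

    Defaults follow the full-scale design (AlexNet-style CNN on 256-px
    patches, 1024-unit LSTM, 50k/5k iteration schedule); ``desk_config``
    returns a reduced configuration sized for CPU-scale synthetic runs.
    """

    cnn_arch: str = "alexnet-style"
    patch_px: int = 256
    in_channels: int = 3
    mlp_hidden: tuple[int, ...] = (1024, 512, 256)
    lstm_hidden: int = 1024
    unroll_length: int = 7
    fusion_fc_dim: int = 1024
    primary_classes: tuple[int, ...] = (3, 4)
    sum_classes: tuple[int, ...] = (6, 7, 8)
    n_signatures: int | None = None  # None => image-only (no MLP branch)
    batch_size: int = 32
    momentum: float = 0.9
    weight_decay: float = 5e-5
    lr: float = 1e-3
    anneal_factor: float = 0.1
    anneal_interval_cnn: int = 10_000
    anneal_interval_lstm: int = 2_000
    iters_cnn: int = 50_000
    iters_lstm: int = 5_000
    freeze_cnn: bool = True
    loss_reduction: str = "sum"
    seed: int = 0

    def __post_init__(self):
        if self.unroll_length < 1:
            raise ValueError("unroll length must be >= 1")
        if not 0 < self.anneal_factor < 1:
            raise ValueError("anneal factor must be in (0,1)")
        for d in (*self.mlp_hidden, self.lstm_hidden, self.fusion_fc_dim):
            if d < 1:
                raise ValueError("all layer dims must be >= 1")

    @property
    def n_primary(self) -> int:
        return len(self.primary_classes)

    @property
    def n_sum(self) -> int:
        return len(self.sum_classes)


def desk_config(**overrides) -> FusionConfig:
    """CPU-scale configuration: small CNN on 64-px patches, 128-unit LSTM."""
    base = dict(cnn_arch="small-cnn", patch_px=64,
                mlp_hidden=(64, 32, 16), lstm_hidden=128,
                fusion_fc_dim=32, iters_cnn=300, iters_lstm=300,
                anneal_interval_cnn=120, anneal_interval_lstm=120,
                batch_size=32)
    base.update(overrides)
    return FusionConfig(**base)


# conv specs: (out_channels, kernel, stride, pad); "M" = 2x2 max pool
_ARCHS = {
    # reduced 4-conv-block network for 64-px desk-scale patches
    "small-cnn": {
        "convs": [(8, 3, 1, 1), "M", (16, 3, 1, 1), "M",
                  (32, 3, 1, 1), "M", (32, 3, 1, 1), "M"],
        "fc": 128,
    },
    # AlexNet-like stack for 256-px patches (2x2 pools in place of 3x3/2)
    "alexnet-style": {
        "convs": [(96, 11, 4, 2), "M", (256, 5, 1, 2), "M",
                  (384, 3, 1, 1), (384, 3, 1, 1), (256, 3, 1, 1), "M"],
        "fc": 4096,
    },
}


class PatchCNN:
    """Convolutional patch encoder with a penultimate FC feature layer.

    ``features`` returns the activations of the second-to-last layer (the
    penultimate FC), which serve as the per-patch image features.
    """

    def __init__(self, config: FusionConfig, rng: np.random.Generator):
        if config.cnn_arch not in _ARCHS:
            raise ValueError(f"unknown cnn arch {config.cnn_arch!r}")
        spec = _ARCHS[config.cnn_arch]
        layers = []
        c, edge = config.in_channels, config.patch_px
        for item in spec["convs"]:
            if item == "M":
                layers.append(MaxPool2())
                edge //= 2
            else:
                c_out, k, s, p = item
                layers.append(Conv2d(c, c_out, k, rng, stride=s, pad=p))
                layers.append(ReLU())
                edge = (edge + 2 * p - k) // s + 1
                c = c_out
        layers.append(Flatten())
        flat = c * edge * edge
        self.trunk = Sequential(*layers)
        self.fc = Linear(flat, spec["fc"], rng)
        self.fc_relu = ReLU()
        self.feature_dim = spec["fc"]
        self.in_shape = (config.in_channels, config.patch_px, config.patch_px)

    def features(self, images: np.ndarray) -> np.ndarray:
        """Penultimate-layer features for a batch of NCHW images."""
        if images.shape[1:] != self.in_shape:
            raise ValueError(
                f"expected images of shape {self.in_shape}, "
                f"got {images.shape[1:]}")
        return self.fc_relu.forward(self.fc.forward(
            self.trunk.forward(images)))

    def backward_features(self, dfeat: np.ndarray) -> np.ndarray:
        return self.trunk.backward(self.fc.backward(
            self.fc_relu.backward(dfeat)))

    def params(self):
        return self.trunk.params() + self.fc.params()


class GenomicMLP:
    """Three-FC-layer perceptron turning pathway scores into genomic features."""

    def __init__(self, n_in: int, hidden: tuple[int, ...],
                 rng: np.random.Generator):
        layers = []
        d = n_in
        for h in hidden:
            layers.append(Linear(d, h, rng))
            layers.append(ReLU())
            d = h
        self.net = Sequential(*layers)
        self.out_dim = d
        self.n_in = n_in

    def forward(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(scores)
        if scores.shape[1] != self.n_in:
            raise ValueError(
                f"score vector length {scores.shape[1]} != panel size "
                f"{self.n_in}")
        return self.net.forward(scores)

    def backward(self, dout):
        return self.net.backward(dout)

    def params(self):
        return self.net.params()


def multitask_loss(pred_p: np.ndarray, pred_s: np.ndarray,
                   t_p: np.ndarray, t_s: np.ndarray,
                   reduction: str = "sum") -> float:
    """Multitask cross-entropy over primary-pattern and Gleason-sum heads.

    L = -sum_i t_i^p . log t-hat_i^p  -  sum_i t_i^s . log t-hat_i^s
    with natural logs and batch-sum reduction (``reduction="mean"`` divides
    by the batch size).  Predicted probabilities are clamped at 1e-12.
    """
    pred_p, pred_s = np.atleast_2d(pred_p), np.atleast_2d(pred_s)
    t_p, t_s = np.atleast_2d(t_p), np.atleast_2d(t_s)
    if (pred_p.min() < EPS and (t_p[pred_p < EPS] > 0).any()) or \
       (pred_s.min() < EPS and (t_s[pred_s < EPS] > 0).any()):
        warnings.warn("predicted probability ~0 at a true class; clamped",
                      stacklevel=2)
    lp = -(t_p * np.log(np.clip(pred_p, EPS, None))).sum()
    ls = -(t_s * np.log(np.clip(pred_s, EPS, None))).sum()
    total = lp + ls
    if reduction == "mean":
        total /= pred_p.shape[0]
    return float(total)


def one_hot(labels: np.ndarray, classes: tuple[int, ...]) -> np.ndarray:
    idx = {c: k for k, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for r, lab in enumerate(labels):
        if lab not in idx:
            raise ValueError(f"label {lab} not in classes {classes}")
        out[r, idx[lab]] = 1.0
    return out


class FusionModel:
    """CNN + MLP + fusion FC + peephole LSTM + average pooling + two heads.

    In fusion mode the per-patch CNN features are concatenated with the
    patient's genomic features (MLP output, repeated at every step); in
    image-only mode the fusion FC sees the image features alone.
    """

    def __init__(self, config: FusionConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        self.cnn = PatchCNN(config, rng)
        self.use_genomic = config.n_signatures is not None
        if self.use_genomic:
            self.mlp = GenomicMLP(config.n_signatures, config.mlp_hidden, rng)
            fuse_in = self.cnn.feature_dim + self.mlp.out_dim
        else:
            self.mlp = None
            fuse_in = self.cnn.feature_dim
        self.fusion_fc = Linear(fuse_in, config.fusion_fc_dim, rng)
        self.fusion_relu = ReLU()
        self.lstm = PeepholeLSTM(config.fusion_fc_dim, config.lstm_hidden, rng)
        # stage-1 heads read the CNN feature layer directly
        self.head1_p = Linear(self.cnn.feature_dim, config.n_primary, rng)
        self.head1_s = Linear(self.cnn.feature_dim, config.n_sum, rng)
        # stage-2 heads read the pooled LSTM output
        self.head2_p = Linear(config.lstm_hidden, config.n_primary, rng)
        self.head2_s = Linear(config.lstm_hidden, config.n_sum, rng)
        # training-set standardization of pathway scores (filled by trainer)
        self.score_mean: np.ndarray | None = None
        self.score_sd: np.ndarray | None = None
        self._cache = None

    # ---- stage 1: per-patch classification -------------------------------
    def forward_patches(self, images: np.ndarray):
        feat = self.cnn.features(images)
        return softmax(self.head1_p.forward(feat)), \
            softmax(self.head1_s.forward(feat))

    def backward_patches(self, pred_p, pred_s, t_p, t_s):
        dfeat = self.head1_p.backward(pred_p - t_p) \
            + self.head1_s.backward(pred_s - t_s)
        self.cnn.backward_features(dfeat)

    # ---- fusion of per-step image features with genomic features ---------
    def fuse(self, image_feats: np.ndarray,
             genomic_feats: np.ndarray | None) -> np.ndarray:
        """Concatenate image and genomic features and project for the LSTM."""
        if self.use_genomic:
            if genomic_feats is None:
                raise ValueError("fusion mode requires genomic features")
            z = np.concatenate([image_feats, genomic_feats], axis=-1)
        else:
            z = image_feats
        return self.fusion_relu.forward(self.fusion_fc.forward(z))

    # ---- stage 2: sequence-level classification --------------------------
    def forward_sequence(self, feats: np.ndarray, mask: np.ndarray,
                         scores: np.ndarray | None):
        """feats: (B, T, cnn_dim) frozen CNN features; scores: (B, S) or None.

        Returns (pred_p, pred_s, pooled) where pooled is the biomarker
        vector (mean of hidden outputs over valid steps).
        """
        B, T, D = feats.shape
        if self.use_genomic:
            g = self.mlp.forward(scores)  # B, G
            g_rep = np.repeat(g[:, None, :], T, axis=1)
            z = np.concatenate([feats, g_rep], axis=-1)
        else:
            z = feats
        flat = z.reshape(B * T, -1)
        u = self.fusion_relu.forward(self.fusion_fc.forward(flat))
        X = u.reshape(B, T, -1)
        H = self.lstm.forward(X, mask)
        valid = mask.sum(axis=1, keepdims=True)
        pooled = H.sum(axis=1) / valid
        pred_p = softmax(self.head2_p.forward(pooled))
        pred_s = softmax(self.head2_s.forward(pooled))
        self._cache = (B, T, mask, valid)
        self._last_H = H
        return pred_p, pred_s, pooled

    def backward_sequence(self, pred_p, pred_s, t_p, t_s):
        B, T, mask, valid = self._cache
        dpooled = self.head2_p.backward(pred_p - t_p) \
            + self.head2_s.backward(pred_s - t_s)
        dH = np.repeat((dpooled / valid)[:, None, :], T, axis=1) \
            * mask[:, :, None]
        dX = self.lstm.backward(dH)
        du = dX.reshape(B * T, -1)
        dz = self.fusion_fc.backward(self.fusion_relu.backward(du))
        if self.use_genomic:
            dz = dz.reshape(B, T, -1)
            dg = dz[:, :, self.cnn.feature_dim:].sum(axis=1)
            self.mlp.backward(dg)

    # ---- parameter groups -------------------------------------------------
    def stage1_params(self):
        return self.cnn.params() + self.head1_p.params() + \
            self.head1_s.params()

    def stage2_params(self, include_cnn: bool = False):
        p = self.fusion_fc.params() + self.lstm.params() + \
            self.head2_p.params() + self.head2_s.params()
        if self.use_genomic:
            p += self.mlp.params()
        if include_cnn:
            p += self.cnn.params()
        return p


def chunk_sequence(feats: np.ndarray, T: int):
    """Split an (n, D) step sequence into (ceil(n/T), T, D) chunks + mask.

    The final short chunk is kept and padded with zeros; the mask marks
    real steps.
    """
    n, D = feats.shape
    if n == 0:
        raise ValueError("empty sequence")
    n_chunks = -(-n // T)
    out = np.zeros((n_chunks, T, D))
    mask = np.zeros((n_chunks, T))
    for k in range(n_chunks):
        part = feats[k * T:(k + 1) * T]
        out[k, :len(part)] = part
        mask[k, :len(part)] = 1.0
    return out, mask


def sequence_biomarker(model: FusionModel, feats: np.ndarray,
                       scores: np.ndarray | None) -> np.ndarray:
    """Pooled LSTM output over all chunks of one patient's patch sequence.

    The biomarker is the mean of the per-step hidden outputs across every
    chunk (padded steps excluded), giving one vector of length
    ``lstm_hidden`` per patient.
    """
    T = model.config.unroll_length
    chunks, mask = chunk_sequence(feats, T)
    B = chunks.shape[0]
    sc = None
    if model.use_genomic:
        if scores is None:
            raise ValueError("fusion model requires pathway scores")
        sc = np.repeat(np.atleast_2d(scores), B, axis=0)
    model.forward_sequence(chunks, mask, sc)
    H = model._last_H  # (n_chunks, T, hidden), zero at padded steps
    return H.sum(axis=(0, 1)) / mask.sum()
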