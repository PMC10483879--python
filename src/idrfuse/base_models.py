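"""The five sequence-labelling base predictors.

Each predictor consumes the assembled per-residue feature matrix (width
103, or 97 for the hierarchical-attention model) and emits one disorder
probability per residue. The architectures realize five complementary
mechanisms borrowed from natural-language sequence modelling:

* ``CAN`` — convolution stack with attention pooling over a local window;
  trained on SDR proteins only, so it specializes in short disorder.
* ``HAN`` — hierarchical (residue -> segment -> sequence) attention;
  trained on LDR proteins only, specializing in long disorder.
* ``SEQ2SEQ`` — bidirectional encoder with a decoder attending over all
  encoder states (global, non-local context).
* ``CNN_LSTM`` — convolutions (local motifs) feeding a bidirectional
  LSTM (long-range context).
* ``LSTM_CNN`` — the reverse stacking order.

These are reference implementations at configurable desk scale: depths
and widths live in :class:`BaseModelSpec`, and training uses per-residue
binary cross-entropy with class weighting and early stopping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Tensor, concat, softmax
from .errors import ContractError, DataError, ParameterError
from .features import FULLY_ORDERED, LDR_PROTEIN, SDR_PROTEIN, classify_protein
from .layers import Adam, BiLSTMSeq, Conv1dSeq, Dense, Module, bce_loss, sliding_stack
from .types import FULL_CONFIG, HAN_CONFIG, FeatureConfig, PredictionTrack

KINDS = ("CAN", "HAN", "SEQ2SEQ", "CNN_LSTM", "LSTM_CNN")

#: Training regime per kind: the SDR specialist sees only SDR proteins,
#: the LDR specialist only LDR proteins, the rest the full mixture.
REGIMES = {
    "CAN": "SDR_only",
    "HAN": "LDR_only",
    "SEQ2SEQ": "mixed",
    "CNN_LSTM": "mixed",
    "LSTM_CNN": "mixed",
}


@dataclass(frozen=True)
class BaseModelSpec:
    kind: str
    hidden: int = 8
    channels: int = 8
    kernel: int = 5
    attention_window: int = 7
    segment_length: int = 20
    features: FeatureConfig | None = None  # validated against the kind's fixed config

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ParameterError(f"unknown base-model kind {self.kind!r}")
        for name in ("hidden", "channels", "kernel", "attention_window", "segment_length"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.features is not None and self.features != self.feature_config:
            raise ContractError(
                f"{self.kind} is bound to a width-{self.feature_config.width} feature "
                f"configuration; got width {self.features.width}"
            )

    @property
    def feature_config(self) -> FeatureConfig:
        return HAN_CONFIG if self.kind == "HAN" else FULL_CONFIG

    @property
    def regime(self) -> str:
        return REGIMES[self.kind]


@dataclass
class TrainConfig:
    epochs: int = 25
    lr: float = 2e-2
    patience: int = 5
    val_fraction: float = 0.2
    max_pos_weight: float = 10.0
    seed: int = 0


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------


class _CAN(Module):
    def __init__(self, rng, spec: BaseModelSpec):
        super().__init__()
        d, c, w = spec.feature_config.width, spec.channels, spec.attention_window
        self.w = w
        self.conv1 = self.add_child("conv1", Conv1dSeq(rng, d, c, spec.kernel))
        self.conv2 = self.add_child("conv2", Conv1dSeq(rng, c, c, spec.kernel))
        self.score = self.add_child("score", Dense(rng, c, 1))
        self.head = self.add_child("head", Dense(rng, 2 * c, 1))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu()).relu()
        scores = self.score(h)
        h_views = sliding_stack(h, self.w)
        s_views = sliding_stack(scores, self.w)
        weights = softmax(concat(s_views, axis=1), axis=1)  # (L, w)
        context = weights[:, 0:1] * h_views[0]
        for j in range(1, self.w):
            context = context + weights[:, j : j + 1] * h_views[j]
        return self.head(concat([h, context], axis=1)).sigmoid()


class _HAN(Module):
    def __init__(self, rng, spec: BaseModelSpec):
        super().__init__()
        d, c = spec.feature_config.width, spec.channels
        self.seg = spec.segment_length
        self.encoder = self.add_child("encoder", Conv1dSeq(rng, d, c, spec.kernel))
        self.res_score = self.add_child("res_score", Dense(rng, c, 1))
        self.seg_score = self.add_child("seg_score", Dense(rng, c, 1))
        self.head = self.add_child("head", Dense(rng, 3 * c, 1))

    def __call__(self, x: Tensor) -> Tensor:
        L, _ = x.shape
        c = self.encoder.W.shape[2]
        seg = self.seg
        n_seg = -(-L // seg)
        pad = n_seg * seg - L
        h = self.encoder(x).relu()  # (L, c)

        scores = self.res_score(h)  # (L, 1)
        if pad:
            h_p = concat([h, Tensor(np.zeros((pad, c)))], axis=0)
            s_p = concat([scores, Tensor(np.full((pad, 1), -1e9))], axis=0)
        else:
            h_p, s_p = h, scores
        weights = softmax(s_p.reshape(n_seg, seg, 1), axis=1)
        h3 = h_p.reshape(n_seg, seg, c)
        seg_vecs = (weights * h3).sum(axis=1)  # (n_seg, c)

        seq_weights = softmax(self.seg_score(seg_vecs), axis=0)  # (n_seg, 1)
        doc = (seq_weights * seg_vecs).sum(axis=0, keepdims=True)  # (1, c)

        seg_ctx = (seg_vecs.reshape(n_seg, 1, c) + Tensor(np.zeros((n_seg, seg, c))))
        seg_ctx = seg_ctx.reshape(n_seg * seg, c)[:L, :]
        doc_ctx = doc + Tensor(np.zeros((L, c)))
        return self.head(concat([h, seg_ctx, doc_ctx], axis=1)).sigmoid()


class _Seq2Seq(Module):
    def __init__(self, rng, spec: BaseModelSpec):
        super().__init__()
        d, hdim = spec.feature_config.width, spec.hidden
        self.encoder = self.add_child("encoder", BiLSTMSeq(rng, d, hdim))
        self.decoder = self.add_child("decoder", Conv1dSeq(rng, 2 * hdim, hdim, 1))
        self.attn = self.add_child("attn", Dense(rng, hdim, 2 * hdim))
        self.head = self.add_child("head", Dense(rng, 3 * hdim, 1))

    def __call__(self, x: Tensor) -> Tensor:
        enc = self.encoder(x)  # (L, 2H)
        dec = self.decoder(enc).tanh()  # (L, H)
        scores = self.attn(dec) @ enc.transpose(1, 0)  # (L, L)
        attention = softmax(scores, axis=1)
        context = attention @ enc  # (L, 2H)
        return self.head(concat([dec, context], axis=1)).sigmoid()


class _CnnLstm(Module):
    def __init__(self, rng, spec: BaseModelSpec):
        super().__init__()
        d, c, hdim = spec.feature_config.width, spec.channels, spec.hidden
        self.conv1 = self.add_child("conv1", Conv1dSeq(rng, d, c, spec.kernel))
        self.conv2 = self.add_child("conv2", Conv1dSeq(rng, c, c, spec.kernel))
        self.lstm = self.add_child("lstm", BiLSTMSeq(rng, c, hdim))
        self.head = self.add_child("head", Dense(rng, 2 * hdim, 1))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu()).relu()
        return self.head(self.lstm(h)).sigmoid()


class _LstmCnn(Module):
    def __init__(self, rng, spec: BaseModelSpec):
        super().__init__()
        d, c, hdim = spec.feature_config.width, spec.channels, spec.hidden
        self.lstm = self.add_child("lstm", BiLSTMSeq(rng, d, hdim))
        self.conv1 = self.add_child("conv1", Conv1dSeq(rng, 2 * hdim, c, spec.kernel))
        self.head = self.add_child("head", Dense(rng, c, 1))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(self.lstm(x)).relu()
        return self.head(h).sigmoid()


_ARCHITECTURES = {
    "CAN": _CAN,
    "HAN": _HAN,
    "SEQ2SEQ": _Seq2Seq,
    "CNN_LSTM": _CnnLstm,
    "LSTM_CNN": _LstmCnn,
}


@dataclass
class TrainedBaseModel:
    spec: BaseModelSpec
    network: Module
    training_log: list = field(default_factory=list)

    def save(self, path) -> None:
        """Checkpoint spec + parameters + training log to a ``.npz`` archive."""
        state = self.network.state_dict()
        spec_fields = {k: v for k, v in asdict(self.spec).items() if k != "features"}
        np.savez(
            path,
            __spec__=json.dumps(spec_fields),
            __log__=json.dumps(self.training_log),
            **state,
        )

    @classmethod
    def load(cls, path) -> "TrainedBaseModel":
        archive = np.load(path, allow_pickle=False)
        spec = BaseModelSpec(**json.loads(str(archive["__spec__"])))
        model = build_base_model(spec, seed=0)
        state = {k: archive[k] for k in archive.files if not k.startswith("__")}
        model.network.load_state_dict(state)
        model.training_log = json.loads(str(archive["__log__"]))
        return model


def build_base_model(spec: BaseModelSpec, seed: int) -> TrainedBaseModel:
    """Instantiate an (untrained) base predictor; identical seeds yield
    byte-identical initial parameters."""
    rng = np.random.default_rng(seed)
    network = _ARCHITECTURES[spec.kind](rng, spec)
    return TrainedBaseModel(spec=spec, network=network)


def filter_regime(dataset, regime: str):
    """Restrict (features, labels) pairs to the protein classes a regime
    trains on."""
    wanted = {
        "SDR_only": {SDR_PROTEIN},
        "LDR_only": {LDR_PROTEIN},
        "mixed": {SDR_PROTEIN, LDR_PROTEIN, FULLY_ORDERED},
    }[regime]
    return [(X, y) for X, y in dataset if classify_protein(y) in wanted]


def train_base_model(model: TrainedBaseModel, dataset, config: TrainConfig | None = None
                     ) -> TrainedBaseModel:
    """Train a base predictor on (features, labels) pairs.

    The dataset is first filtered to the model's training regime; a
    held-out fraction is used for early stopping and the per-epoch mean
    training loss is recorded in ``training_log``.
    """
    config = config or TrainConfig()
    data = filter_regime(dataset, model.spec.regime)
    if not data:
        raise DataError(
            f"no proteins left after filtering to regime {model.spec.regime!r}"
        )
    width = model.spec.feature_config.width
    for X, _ in data:
        if X.shape[1] != width:
            raise ContractError(
                f"feature width {X.shape[1]} does not match the "
                f"{model.spec.kind} configuration ({width})"
            )

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(data))
    n_val = max(1, int(round(config.val_fraction * len(data)))) if len(data) > 1 else 0
    val = [data[i] for i in order[:n_val]]
    train = [data[i] for i in order[n_val:]] or val

    n_pos = sum(int(np.sum(y)) for _, y in train)
    n_res = sum(len(y) for _, y in train)
    pos_weight = 1.0
    if 0 < n_pos < n_res:
        pos_weight = min((n_res - n_pos) / n_pos, config.max_pos_weight)

    params = model.network.parameters()
    optim = Adam(params, lr=config.lr)
    best_val, best_state, stale = np.inf, model.network.state_dict(), 0
    for epoch in range(config.epochs):
        epoch_order = rng.permutation(len(train))
        losses = []
        for idx in epoch_order:
            X, y = train[idx]
            optim.zero_grad()
            loss = bce_loss(model.network(Tensor(X)), y, pos_weight=pos_weight)
            loss.backward()
            optim.step()
            losses.append(loss.item())
        val_losses = [
            bce_loss(model.network(Tensor(X)), y, pos_weight=pos_weight).item()
            for X, y in val
        ]
        val_loss = float(np.mean(val_losses)) if val_losses else float(np.mean(losses))
        model.training_log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss}
        )
        if val_loss < best_val - 1e-6:
            best_val, best_state, stale = val_loss, model.network.state_dict(), 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.network.load_state_dict(best_state)
    return model


def predict_base(model: TrainedBaseModel, features: np.ndarray,
                 record_id: str = "prediction") -> PredictionTrack:
    """Per-residue disorder probabilities for one feature matrix."""
    features = np.asarray(features, dtype=float)
    width = model.spec.feature_config.width
    if features.ndim != 2 or features.shape[1] != width:
        raise ContractError(
            f"expected L x {width} features for {model.spec.kind}, got {features.shape}"
        )
    probs = model.network(Tensor(features)).data.reshape(-1)
    return PredictionTrack(id=record_id, probabilities=np.clip(probs, 0.0, 1.0))
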