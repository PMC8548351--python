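"""The ESIDEN torsion-angle network: parallel LSTM/BiLSTM regression.

Topology: the L x 232 feature matrix feeds a unidirectional LSTM and a
bidirectional LSTM in parallel; their per-position outputs are
concatenated and passed to a second bidirectional LSTM, then a
256-unit ReLU layer with heavy (p = 0.8) dropout, and finally four
sigmoid outputs per residue encoding (sin phi, cos phi, sin psi,
cos psi).  Angles are decoded with the two-argument arctangent.

Default hidden sizes (352 per LSTM direction) put the learnable
parameter count at 6,620,292 — about 6.6M.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .feature_assembly import FULL_WIDTH, FeatureMatrix
from .nn import Adam, BiLSTMLayer, Dropout, DenseLayer, LSTMLayer, masked_mse, sigmoid
from .rama_potential import TorsionSeries, wrap_angle


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Hidden sizes are per direction.  The defaults reproduce the ~6.6M
    learnable-parameter budget; tests use much smaller ("toy") sizes.
    """

    input_width: int = FULL_WIDTH
    lstm1_hidden: int = 352
    bilstm_hidden: int = 352
    bilstm2_hidden: int = 352
    fc1_units: int = 256
    fc1_dropout: float = 0.8
    output_units: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = (self.input_width, self.lstm1_hidden, self.bilstm_hidden,
                 self.bilstm2_hidden, self.fc1_units)
        if any(s <= 0 for s in sizes):
            raise ValueError("all layer sizes must be positive")
        if self.output_units != 4:
            raise ValueError("the network predicts exactly 4 outputs "
                             "(sin/cos of phi and psi)")
        if not (0.0 <= self.fc1_dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


# ---------------------------------------------------------------------------
# Target encoding / decoding


@dataclass
class AngleEncoding:
    """Sigmoid-range sin/cos targets for (phi, psi), with masks.

    Columns are (sin phi, cos phi, sin psi, cos psi), each mapped from
    [-1, 1] to [0, 1] via t = (x + 1) / 2 so the sigmoid output layer can
    reach them.  Masked entries (terminal angles, chain breaks) hold 0.5
    and are excluded from the loss.
    """

    targets: np.ndarray  # (L, 4) in [0, 1]
    masks: np.ndarray    # (L, 4) bool


def encode_targets(torsions: TorsionSeries) -> AngleEncoding:
    phi = np.radians(torsions.phi)
    psi = np.radians(torsions.psi)
    raw = np.stack([np.sin(phi), np.cos(phi), np.sin(psi), np.cos(psi)], axis=1)
    targets = (raw + 1.0) / 2.0
    masks = np.stack([torsions.phi_mask, torsions.phi_mask,
                      torsions.psi_mask, torsions.psi_mask], axis=1)
    targets[~masks] = 0.5
    return AngleEncoding(targets=targets, masks=masks)


def decode_predictions(outputs: np.ndarray, eps: float = 1e-6) -> TorsionSeries:
    """Invert the affine map and recover angles with atan2.

    The printed decoding arctan(sin/cos) is quadrant-ambiguous; the
    two-argument form restores the full [-180, 180) range.  Positions
    where both sin and cos are within ``eps`` of zero are masked.
    """
    outputs = np.asarray(outputs, dtype=float)
    if outputs.ndim != 2 or outputs.shape[1] != 4:
        raise ValueError("expected an (L, 4) output array")
    xy = 2.0 * outputs - 1.0
    sin_phi, cos_phi, sin_psi, cos_psi = xy.T
    phi = wrap_angle(np.degrees(np.arctan2(sin_phi, cos_phi)))
    psi = wrap_angle(np.degrees(np.arctan2(sin_psi, cos_psi)))
    phi_ok = np.hypot(sin_phi, cos_phi) > eps
    psi_ok = np.hypot(sin_psi, cos_psi) > eps
    if not (phi_ok.all() and psi_ok.all()):
        warnings.warn("near-zero (sin, cos) pairs decoded as masked positions",
                      stacklevel=2)
    L = len(phi)
    phi_mask = phi_ok.copy()
    psi_mask = psi_ok.copy()
    if L:
        phi_mask[0] = False
        psi_mask[-1] = False
    phi = np.where(phi_mask, phi, 0.0)
    psi = np.where(psi_mask, psi, 0.0)
    return TorsionSeries(phi=phi, psi=psi, phi_mask=phi_mask, psi_mask=psi_mask)


# ---------------------------------------------------------------------------
# Model


class EsidenNet:
    """Numpy implementation of the parallel LSTM/BiLSTM architecture."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        I = config.input_width
        self.lstm1 = LSTMLayer(I, config.lstm1_hidden, rng, name="lstm1")
        self.lstm2 = BiLSTMLayer(I, config.bilstm_hidden, rng, name="lstm2")
        mid = config.lstm1_hidden + 2 * config.bilstm_hidden
        self.bilstm2 = BiLSTMLayer(mid, config.bilstm2_hidden, rng, name="bilstm2")
        self.fc1 = DenseLayer(2 * config.bilstm2_hidden, config.fc1_units, rng,
                              relu=True, name="fc1")
        self.dropout = Dropout(config.fc1_dropout)
        self.fc2 = DenseLayer(config.fc1_units, config.output_units, rng,
                              relu=False, name="fc2")

    # -- plumbing ----------------------------------------------------------

    def _layers(self):
        return [self.lstm1, self.lstm2.fwd, self.lstm2.bwd,
                self.bilstm2.fwd, self.bilstm2.bwd, self.fc1, self.fc2]

    def parameter_triples(self):
        """(owner, param_attr, grad_attr) triples for the optimizer."""
        triples = []
        for layer in self._layers():
            if isinstance(layer, LSTMLayer):
                triples += [(layer, "W", "dW"), (layer, "U", "dU"), (layer, "b", "db")]
            else:
                triples += [(layer, "W", "dW"), (layer, "b", "db")]
        return triples

    def zero_grads(self):
        for layer in self._layers():
            layer.zero_grads()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self._layers():
            for attr in ("W", "U", "b"):
                if hasattr(layer, attr):
                    out[f"{layer.name}.{attr}"] = getattr(layer, attr).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for layer in self._layers():
            for attr in ("W", "U", "b"):
                if hasattr(layer, attr):
                    key = f"{layer.name}.{attr}"
                    current = getattr(layer, attr)
                    if state[key].shape != current.shape:
                        raise ValueError(f"shape mismatch for {key}")
                    setattr(layer, attr, state[key].copy())

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, mask: np.ndarray,
                dropout_rng: np.random.Generator | None = None) -> np.ndarray:
        """x: (B, T, input_width); mask: (B, T). Returns sigmoid outputs (B, T, 4).

        Pass a generator to enable dropout (training); omit it for
        deterministic inference.
        """
        if x.shape[2] != self.config.input_width:
            raise ValueError(
                f"feature width {x.shape[2]} != configured "
                f"{self.config.input_width}")
        h1 = self.lstm1.forward(x, mask)
        h2 = self.lstm2.forward(x, mask)
        u = np.concatenate([h1, h2], axis=2)
        h3 = self.bilstm2.forward(u, mask)
        f1 = self.fc1.forward(h3)
        f1 = self.dropout.forward(f1, dropout_rng)
        self._logits = self.fc2.forward(f1)
        self._out = sigmoid(self._logits)
        return self._out

    def backward(self, dout: np.ndarray) -> None:
        dlogits = dout * self._out * (1.0 - self._out)
        d = self.fc2.backward(dlogits)
        d = self.dropout.backward(d)
        d = self.fc1.backward(d)
        d = self.bilstm2.backward(d)
        H1 = self.config.lstm1_hidden
        d1 = self.lstm1.backward(d[:, :, :H1])
        d2 = self.lstm2.backward(d[:, :, H1:])
        # input gradient d1 + d2 is discarded (features are not learned)


def build_model(config: ModelConfig) -> EsidenNet:
    return EsidenNet(config)


def count_parameters(model: EsidenNet) -> int:
    """Exact learnable scalar count (4(I+H+1)H per LSTM direction + FC)."""
    return sum(layer.n_params() for layer in model._layers())


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    """Optimisation settings (Adam, lr 0.001, batch 32, <= 5000 steps)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_steps: int = 5000
    eval_every: int = 50
    patience: int | None = None  # eval rounds without val improvement
    target_loss: float | None = None  # stop once training MSE reaches this
    shuffle_seed: int = 0
    dropout_seed: int = 1


@dataclass
class TrainState:
    """Loss/validation histories and the best-checkpoint bookkeeping."""

    loss_history: list[float] = field(default_factory=list)
    val_history: list[tuple[int, float]] = field(default_factory=list)
    best_step: int = -1
    best_val_mae: float = np.inf
    best_params: dict | None = None
    config: TrainConfig | None = None


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.asarray(features, dtype=float)


def _pad_batch(items):
    """Stack variable-length (features, encoding) pairs with trailing padding."""
    feats = [_as_array(f) for f, _ in items]
    encs = [e for _, e in items]
    B = len(items)
    T = max(f.shape[0] for f in feats)
    C = feats[0].shape[1]
    x = np.zeros((B, T, C))
    mask = np.zeros((B, T))
    targets = np.full((B, T, 4), 0.5)
    tmask = np.zeros((B, T, 4), dtype=bool)
    for k, (f, e) in enumerate(zip(feats, encs)):
        L = f.shape[0]
        x[k, :L] = f
        mask[k, :L] = 1.0
        targets[k, :L] = e.targets
        tmask[k, :L] = e.masks
    return x, mask, targets, tmask


def _validation_mae(model: EsidenNet, dataset) -> float:
    """Mean of wrap-aware phi and psi MAE over a dataset (no dropout)."""
    from .eval_and_fixtures import mae  # local import: avoid cycle

    preds, refs = [], []
    for features, enc in dataset:
        f = _as_array(features)
        out = model.forward(f[None], np.ones((1, f.shape[0])))
        pred = decode_predictions(out[0])
        with warnings.catch_warnings():
            # masked target entries hold the (0.5, 0.5) sentinel on purpose
            warnings.simplefilter("ignore")
            ref = decode_predictions(enc.targets)
        # only score positions that are real targets
        ref.phi_mask &= enc.masks[:, 0]
        ref.psi_mask &= enc.masks[:, 2]
        pred.phi_mask = ref.phi_mask.copy()
        pred.psi_mask = ref.psi_mask.copy()
        preds.append(pred)
        refs.append(ref)
    report = mae(preds, refs)
    return 0.5 * (report.mae_phi + report.mae_psi)


def train_model(
    model: EsidenNet,
    dataset: list,
    train_config: TrainConfig | None = None,
    validation: list | None = None,
) -> TrainState:
    """Fit the network with Adam on masked MSE over sin/cos targets.

    ``dataset`` (and optional ``validation``) are lists of
    (FeatureMatrix | ndarray, AngleEncoding) pairs.  Batches of up to
    ``batch_size`` chains are padded to their longest member; padding
    and masked targets contribute zero loss and zero gradient.  The best
    checkpoint by validation MAE is restored before returning.  Fully
    reproducible given the config seeds.
    """
    cfg = train_config or TrainConfig()
    if not dataset:
        raise ValueError("empty training dataset")
    if not any(e.masks.any() for _, e in dataset):
        raise ValueError("dataset has no unmasked target entries")
    rng = np.random.default_rng(cfg.shuffle_seed)
    drop_rng = np.random.default_rng(cfg.dropout_seed)
    optim = Adam(model.parameter_triples(), lr=cfg.learning_rate)
    state = TrainState(config=cfg)

    order: list[int] = []
    bad_rounds = 0
    for step in range(cfg.max_steps):
        if len(order) < cfg.batch_size:
            perm = rng.permutation(len(dataset)).tolist()
            order.extend(perm)
        batch_idx = [order.pop(0) for _ in range(min(cfg.batch_size, len(order)))]
        batch = [dataset[i] for i in batch_idx]
        x, mask, targets, tmask = _pad_batch(batch)
        model.zero_grads()
        out = model.forward(x, mask, dropout_rng=drop_rng)
        loss, dout = masked_mse(out, targets, tmask)
        model.backward(dout)
        optim.step()
        state.loss_history.append(loss)

        last = step == cfg.max_steps - 1
        if cfg.target_loss is not None and loss <= cfg.target_loss:
            last = True
        if validation is not None and ((step + 1) % cfg.eval_every == 0 or last):
            val = _validation_mae(model, validation)
            state.val_history.append((step + 1, val))
            if val < state.best_val_mae:
                state.best_val_mae = val
                state.best_step = step + 1
                state.best_params = model.state_dict()
                bad_rounds = 0
            else:
                bad_rounds += 1
                if cfg.patience is not None and bad_rounds > cfg.patience:
                    break
        if cfg.target_loss is not None and loss <= cfg.target_loss:
            break
    if state.best_params is not None:
        model.load_state_dict(state.best_params)
    return state


def predict(model: EsidenNet, features) -> TorsionSeries:
    """Predict (phi, psi) for one chain; terminal angles are masked."""
    f = _as_array(features)
    if f.ndim != 2 or f.shape[1] != model.config.input_width:
        raise ValueError(
            f"features must be (L, {model.config.input_width}); got {f.shape}")
    out = model.forward(f[None], np.ones((1, f.shape[0])))
    return decode_predictions(out[0])


# ---------------------------------------------------------------------------
# Checkpoints


def save_model(model: EsidenNet, path: str | Path, scaler=None) -> None:
    """Versioned checkpoint: weights + config (+ optional feature scaler)."""
    cfg = model.config
    meta = {"version": 1, "config": cfg.__dict__}
    if scaler is not None:
        meta["scaler"] = scaler.to_dict()
    np.savez_compressed(path, __meta__=np.array(json.dumps(meta)),
                        **model.state_dict())


def load_model(path: str | Path):
    """Returns (model, scaler-or-None)."""
    from .feature_assembly import ChannelScaler

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = EsidenNet(ModelConfig(**meta["config"]))
    model.load_state_dict(state)
    scaler = ChannelScaler.from_dict(meta["scaler"]) if "scaler" in meta else None
    return model, scaler
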