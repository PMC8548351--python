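"""Angle encoding, network topology, gradients, training and prediction."""

import numpy as np
import pytest

from esiden import (
    ModelConfig, TorsionSeries, TrainConfig, build_model, count_parameters,
    decode_predictions, encode_targets, load_model, predict, save_model,
    train_model,
)
from esiden.nn import DenseLayer, LSTMLayer, masked_mse

TOY = dict(input_width=6, lstm1_hidden=5, bilstm_hidden=4, bilstm2_hidden=3,
           fc1_units=8, fc1_dropout=0.0)


def _torsions(phi, psi):
    L = len(phi)
    phi_mask = np.ones(L, bool)
    psi_mask = np.ones(L, bool)
    phi_mask[0] = False
    psi_mask[-1] = False
    return TorsionSeries(phi=np.where(phi_mask, phi, 0.0),
                         psi=np.where(psi_mask, psi, 0.0),
                         phi_mask=phi_mask, psi_mask=psi_mask)


# ---------------------------------------------------------------------------
# encoding / decoding


def test_encode_maps_sin_cos_to_unit_interval():
    t = _torsions(np.array([0.0, 90.0, 0.0]), np.array([0.0, 0.0, 0.0]))
    enc = encode_targets(t)
    # phi = 90: (sin, cos) = (1, 0) -> (1.0, 0.5)
    np.testing.assert_allclose(enc.targets[1, :2], [1.0, 0.5], atol=1e-12)
    # psi = 0 -> (0.5, 1.0)
    np.testing.assert_allclose(enc.targets[1, 2:], [0.5, 1.0], atol=1e-12)


def test_encode_masks_terminal_angles():
    t = _torsions(np.full(4, -60.0), np.full(4, -45.0))
    enc = encode_targets(t)
    assert not enc.masks[0, 0] and not enc.masks[0, 1]   # phi at N-terminus
    assert not enc.masks[-1, 2] and not enc.masks[-1, 3]  # psi at C-terminus
    assert enc.masks[1:, :2].all() and enc.masks[:-1, 2:].all()
    np.testing.assert_allclose(enc.targets[0, :2], 0.5)  # sentinel


def test_decode_quadrants():
    out = np.array([[1.0, 0.5, 0.5, 0.0],    # phi=90, psi=atan2(0,-1)=180->-180
                    [0.5, 1.0, 0.0, 0.5]])   # phi=0,  psi=-90
    t = decode_predictions(out)
    assert t.psi[0] == pytest.approx(-180.0)
    assert t.phi[1] == pytest.approx(0.0)
    assert t.psi[0] >= -180.0 and t.psi[0] < 180.0


@pytest.mark.filterwarnings("ignore:near-zero")
def test_encode_decode_round_trip(rng):
    theta = rng.uniform(-180.0, 180.0 - 1e-9, size=1000)
    t = _torsions(theta, theta[::-1].copy())
    dec = decode_predictions(encode_targets(t).targets)
    np.testing.assert_allclose(dec.phi[t.phi_mask], t.phi[t.phi_mask], atol=1e-6)
    np.testing.assert_allclose(dec.psi[t.psi_mask], t.psi[t.psi_mask], atol=1e-6)


def test_decode_near_zero_pair_masks_position():
    out = np.full((3, 4), 0.9)
    out[1, :2] = 0.5  # sin = cos = 0 for phi
    with pytest.warns(UserWarning):
        t = decode_predictions(out)
    assert not t.phi_mask[1]


# ---------------------------------------------------------------------------
# topology / parameter count


def test_output_shape_and_range(rng):
    model = build_model(ModelConfig(**TOY, seed=0))
    x = rng.normal(size=(2, 9, 6))
    out = model.forward(x, np.ones((2, 9)))
    assert out.shape == (2, 9, 4)
    assert (out > 0).all() and (out < 1).all()


def test_padding_invariance(rng):
    model = build_model(ModelConfig(**TOY, seed=0))
    L = 12
    x = rng.normal(size=(1, L, 6))
    mask_s = np.ones((1, L))
    out_s = model.forward(x, mask_s)
    for pad_to in (50, 500):
        xp = np.zeros((1, pad_to, 6))
        xp[:, :L] = x
        xp[:, L:] = rng.normal(size=(1, pad_to - L, 6))  # junk in the padding
        mask_p = np.zeros((1, pad_to))
        mask_p[:, :L] = 1.0
        out_p = model.forward(xp, mask_p)
        np.testing.assert_allclose(out_p[:, :L], out_s, atol=1e-6)


def test_lstm_parameter_count_formula(rng):
    # standard gate formula: 4 (I + H + 1) H
    layer = LSTMLayer(2, 1, np.random.default_rng(0))
    assert layer.n_params() == 16
    fc = DenseLayer(256, 4, np.random.default_rng(0))
    assert fc.n_params() == 1028


def test_model_count_matches_analytic_formula():
    cfg = ModelConfig(**TOY, seed=3)
    model = build_model(cfg)

    def lstm(i, h):
        return 4 * (i + h + 1) * h

    expected = (
        lstm(6, 5) + 2 * lstm(6, 4)
        + 2 * lstm(5 + 2 * 4, 3)
        + (2 * 3) * 8 + 8
        + 8 * 4 + 4
    )
    assert count_parameters(model) == expected


def test_default_config_has_about_6_6M_parameters():
    n = count_parameters(build_model(ModelConfig()))
    assert n == 6_620_292
    assert abs(n - 6.6e6) / 6.6e6 < 0.01


def test_count_invariant_across_seeds():
    cfg = dict(**TOY)
    assert (count_parameters(build_model(ModelConfig(**cfg, seed=1)))
            == count_parameters(build_model(ModelConfig(**cfg, seed=99))))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ModelConfig(lstm1_hidden=0)
    with pytest.raises(ValueError):
        ModelConfig(output_units=2)


# ---------------------------------------------------------------------------
# gradients / loss masking


def test_gradients_match_finite_differences(rng):
    model = build_model(ModelConfig(input_width=4, lstm1_hidden=3,
                                    bilstm_hidden=3, bilstm2_hidden=2,
                                    fc1_units=5, fc1_dropout=0.0, seed=1))
    B, T = 2, 5
    x = rng.normal(size=(B, T, 4))
    mask = np.ones((B, T))
    mask[1, 3:] = 0
    targets = rng.random((B, T, 4))
    tmask = rng.random((B, T, 4)) < 0.7
    tmask[1, 3:] = False

    model.zero_grads()
    out = model.forward(x, mask)
    _, dout = masked_mse(out, targets, tmask)
    model.backward(dout)

    eps = 1e-6
    for owner, p_attr, g_attr in model.parameter_triples():
        P = getattr(owner, p_attr)
        G = getattr(owner, g_attr)
        idx = tuple(rng.integers(0, s) for s in P.shape)
        orig = P[idx]
        P[idx] = orig + eps
        lp = masked_mse(model.forward(x, mask), targets, tmask)[0]
        P[idx] = orig - eps
        lm = masked_mse(model.forward(x, mask), targets, tmask)[0]
        P[idx] = orig
        num = (lp - lm) / (2 * eps)
        assert num == pytest.approx(G[idx], abs=1e-6, rel=1e-4)


def test_masked_positions_have_zero_gradient_and_loss(rng):
    model = build_model(ModelConfig(**TOY, seed=2))
    L = 8
    x = np.zeros((1, 20, 6))
    x[0, :L] = rng.normal(size=(L, 6))
    mask = np.zeros((1, 20))
    mask[0, :L] = 1.0
    targets = rng.random((1, 20, 4))
    tmask = np.zeros((1, 20, 4), bool)
    tmask[0, :L] = True
    out = model.forward(x, mask)
    loss1, _ = masked_mse(out, targets, tmask)
    # junk in the padding region must not change the loss
    x2 = x.copy()
    x2[0, L:] = 1e3
    loss2, _ = masked_mse(model.forward(x2, mask), targets, tmask)
    assert loss1 == pytest.approx(loss2, abs=1e-12)


def test_masked_mse_requires_unmasked_entries(rng):
    with pytest.raises(ValueError):
        masked_mse(rng.random((1, 3, 4)), rng.random((1, 3, 4)),
                   np.zeros((1, 3, 4), bool))


# ---------------------------------------------------------------------------
# training / prediction


def _tiny_dataset(rng, n=4, L=10, width=6):
    from esiden import encode_targets as enc
    out = []
    for _ in range(n):
        feats = rng.uniform(-1, 1, size=(L, width))
        phi = rng.uniform(-180, 179, size=L)
        psi = rng.uniform(-180, 179, size=L)
        out.append((feats, enc(_torsions(phi, psi))))
    return out


def test_training_is_deterministic(rng):
    data = _tiny_dataset(rng)
    histories = []
    for _ in range(2):
        model = build_model(ModelConfig(**TOY, seed=7))
        cfg = TrainConfig(batch_size=2, max_steps=30, shuffle_seed=5,
                          dropout_seed=6)
        state = train_model(model, data, cfg)
        histories.append(state.loss_history)
    np.testing.assert_array_equal(histories[0], histories[1])


def test_training_rejects_fully_masked_dataset(rng):
    from esiden import AngleEncoding
    feats = rng.normal(size=(5, 6))
    enc = AngleEncoding(targets=np.full((5, 4), 0.5),
                        masks=np.zeros((5, 4), bool))
    with pytest.raises(ValueError):
        train_model(build_model(ModelConfig(**TOY, seed=0)), [(feats, enc)])


def test_prediction_contract(rng):
    model = build_model(ModelConfig(**TOY, seed=0))
    feats = rng.uniform(-1, 1, size=(30, 6))
    t = predict(model, feats)
    assert len(t) == 30
    assert not t.phi_mask[0] and not t.psi_mask[-1]
    assert (t.phi >= -180).all() and (t.phi < 180).all()
    assert (t.psi >= -180).all() and (t.psi < 180).all()
    # dropout inactive at prediction: repeated calls identical
    t2 = predict(model, feats)
    np.testing.assert_array_equal(t.phi, t2.phi)
    np.testing.assert_array_equal(t.psi, t2.psi)


def test_predict_rejects_wrong_width(rng):
    model = build_model(ModelConfig(**TOY, seed=0))
    with pytest.raises(ValueError):
        predict(model, rng.normal(size=(10, 5)))


def test_checkpoint_round_trip(tmp_path, rng):
    from esiden import fit_scaler
    model = build_model(ModelConfig(**TOY, seed=4))
    scaler = fit_scaler([rng.normal(size=(20, 6))])
    path = tmp_path / "model.ckpt.npz"
    save_model(model, path, scaler=scaler)
    again, scaler2 = load_model(path)
    feats = rng.uniform(-1, 1, size=(15, 6))
    t1 = predict(model, feats)
    t2 = predict(again, feats)
    np.testing.assert_array_equal(t1.phi, t2.phi)
    np.testing.assert_array_equal(t1.psi, t2.psi)
    np.testing.assert_array_equal(scaler2.mins, scaler.mins)
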