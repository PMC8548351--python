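"""Dihedral geometry, torsion extraction, and the basin potential."""

import numpy as np
import pytest

from esiden import (
    Sequence, backbone_from_torsions, build_basin_potential, dihedral_angle,
    extract_torsions, load_potential, rbp_features, reduce_basins,
    save_potential, torsion_records, wrap_angle,
)
from esiden.rama_potential import GLOBAL_KEY, angle_bin


def brute_force_dihedral(p1, p2, p3, p4):
    """Independent oracle: plane-normal arccos with a separately computed sign."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return float(wrap_angle(ang))


# ---------------------------------------------------------------------------
# dihedral


def test_dihedral_cis_is_zero():
    assert dihedral_angle((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(0.0)


def test_dihedral_trans_is_minus_180():
    # +/-180 normalises to -180 under the [-180, 180) range rule
    ang = dihedral_angle((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0))
    assert ang == pytest.approx(-180.0)


def test_dihedral_rigid_motion_invariance(rng):
    pts = rng.normal(size=(4, 3))
    ref = dihedral_angle(*pts)
    # random rotation (QR of a Gaussian matrix, det forced positive) + shift
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    moved = pts @ q.T + rng.normal(size=3)
    assert dihedral_angle(*moved) == pytest.approx(ref, abs=1e-9)


def test_dihedral_mirror_flips_sign(rng):
    pts = rng.normal(size=(4, 3))
    ref = dihedral_angle(*pts)
    mirrored = pts * np.array([1.0, 1.0, -1.0])
    if abs(abs(ref) - 180.0) > 1e-6 and abs(ref) > 1e-6:
        assert dihedral_angle(*mirrored) == pytest.approx(-ref, abs=1e-9)
    assert abs(dihedral_angle(*mirrored)) == pytest.approx(
        abs(wrap_angle(-ref)), abs=1e-9)


def test_dihedral_against_brute_force_oracle(rng):
    for _ in range(1000):
        pts = rng.normal(size=(4, 3))
        assert dihedral_angle(*pts) == pytest.approx(
            brute_force_dihedral(*pts), abs=1e-9)


def test_dihedral_degenerate_geometry_rejected():
    with pytest.raises(ValueError):
        dihedral_angle((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
    with pytest.raises(ValueError):
        # three collinear points: parallel consecutive bonds
        dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0))


# ---------------------------------------------------------------------------
# torsion extraction


def test_terminal_angles_are_masked():
    chain = backbone_from_torsions("AAA", np.full(3, -60.0), np.full(3, -45.0))
    t = extract_torsions(chain)
    assert not t.phi_mask[0] and t.phi_mask[1:].all()
    assert not t.psi_mask[-1] and t.psi_mask[:-1].all()


def test_build_then_extract_round_trip(rng):
    L = 25
    phi = rng.uniform(-180.0, 179.0, size=L)
    psi = rng.uniform(-180.0, 179.0, size=L)
    chain = backbone_from_torsions("A" * L, phi, psi)
    t = extract_torsions(chain)
    np.testing.assert_allclose(t.phi[1:], phi[1:], atol=1e-3)
    np.testing.assert_allclose(t.psi[:-1], psi[:-1], atol=1e-3)


def test_chain_break_masks_spanning_angles():
    chain = backbone_from_torsions("AAAAA", np.full(5, -60.0), np.full(5, -45.0))
    # open a 5 A gap in the peptide bond between residues 2 and 3 (1-based)
    shift = np.array([5.0, 0.0, 0.0])
    for arr in (chain.n, chain.ca, chain.c):
        arr[2:] += shift
    t = extract_torsions(chain)
    assert not t.phi_mask[2]   # phi of residue 3
    assert not t.psi_mask[1]   # psi of residue 2
    assert t.phi_mask[1] and t.phi_mask[3]
    assert t.psi_mask[0] and t.psi_mask[2]


def test_incomplete_residue_masks_dependent_angles():
    chain = backbone_from_torsions("AAAA", np.full(4, -60.0), np.full(4, -45.0))
    chain.complete[1] = False
    t = extract_torsions(chain)
    assert not t.phi_mask[1] and not t.psi_mask[1]
    assert not t.phi_mask[2] and not t.psi_mask[0]


def test_too_few_complete_residues_rejected():
    chain = backbone_from_torsions("AAA", np.zeros(3), np.zeros(3))
    chain.complete[:2] = False
    with pytest.raises(ValueError):
        extract_torsions(chain)


# ---------------------------------------------------------------------------
# basin potential


def test_single_record_lands_in_expected_bin():
    pot = build_basin_potential([("A", "N", "C", -60.0, -45.0)],
                                pseudocount=0.0, min_triplet_count=1)
    m = pot.normalized(("A", "N", "C"))
    assert m[24, 27] == pytest.approx(1.0)
    assert m.sum() == pytest.approx(1.0)
    assert angle_bin(-60.0) == 24 and angle_bin(-45.0) == 27


def test_bin_convention_wraps_180():
    assert angle_bin(180.0) == 0
    assert angle_bin(-180.0) == 0
    assert angle_bin(179.999) == 71


def test_maps_are_probability_distributions(rng):
    records = [("A", "N", "C", rng.uniform(-180, 180), rng.uniform(-180, 180))
               for _ in range(50)]
    pot = build_basin_potential(records)
    for key in pot.keys():
        assert pot.normalized(key).sum() == pytest.approx(1.0, abs=1e-9)


def test_sparse_triplet_backs_off_to_center_map():
    records = [("A", "N", "C", -60.0, -45.0)] * 30 + [("G", "N", "G", 60.0, 60.0)]
    pot = build_basin_potential(records, min_triplet_count=20)
    np.testing.assert_array_equal(pot.normalized(("G", "N", "G")),
                                  pot.normalized("N"))
    # the dense triplet keeps its own map
    assert pot.normalized(("A", "N", "C"))[24, 27] > pot.normalized("N")[24, 27]


def test_backoff_is_count_weighted_mixture_when_unsmoothed(rng):
    records = []
    for trip, n in [(("A", "N", "C"), 30), (("G", "N", "G"), 50)]:
        for _ in range(n):
            records.append((*trip, rng.uniform(-180, 180), rng.uniform(-180, 180)))
    pot = build_basin_potential(records, pseudocount=0.0, min_triplet_count=1)
    mix = (30 * pot.normalized(("A", "N", "C"))
           + 50 * pot.normalized(("G", "N", "G"))) / 80
    np.testing.assert_allclose(pot.normalized("N"), mix, atol=1e-12)


def test_empty_record_stream_rejected():
    with pytest.raises(ValueError):
        build_basin_potential([])


# ---------------------------------------------------------------------------
# reduction + RBP feature


def _toy_potential(rng, n=400):
    records = []
    for _ in range(n):
        trip = tuple(rng.choice(list("ARNCFGD"), size=3))
        records.append((*trip, rng.uniform(-180, 180), rng.uniform(-180, 180)))
    return build_basin_potential(records, min_triplet_count=10)


def test_reduced_shape_and_determinism(rng):
    pot = _toy_potential(rng)
    red1 = reduce_basins(pot, method="pca", seed=13)
    red2 = reduce_basins(pot, method="pca", seed=13)
    for key, emb in red1.embeddings.items():
        assert emb.shape == (72, 2)
        np.testing.assert_array_equal(emb, red2.embeddings[key])


def test_identical_map_rows_embed_coincidentally():
    # two identical phi-rows must land on the same PCA point
    records = [("A", "A", "A", -60.0, -45.0), ("A", "A", "A", -65.0, -45.0)]
    pot = build_basin_potential(records, min_triplet_count=1)
    red = reduce_basins(pot, method="pca", seed=0)
    emb = red.embeddings[("A", "A", "A")]
    m = pot.normalized(("A", "A", "A"))
    i, j = 0, 1  # rows 0 and 1 are both pure pseudocount -> identical
    np.testing.assert_array_equal(m[i], m[j])
    np.testing.assert_allclose(emb[i], emb[j], atol=1e-9)


def test_unknown_reduction_method_rejected(rng):
    with pytest.raises(ValueError):
        reduce_basins(_toy_potential(rng, 50), method="umap", seed=0)


def test_rbp_uses_neighbor_triplet_key(rng):
    # residue N in ARNCFGD is keyed by its neighbours (R, N, C)
    records = [("R", "N", "C", -60.0, -45.0)] * 25
    records += [(l, c, r, rng.uniform(-180, 180), rng.uniform(-180, 180))
                for l, c, r in [("A", "R", "N"), ("N", "C", "F"), ("C", "F", "G"),
                                ("F", "G", "D"), ("D", "A", "R")] for _ in range(3)]
    pot = build_basin_potential(records, min_triplet_count=20)
    red = reduce_basins(pot, method="pca", seed=1)
    feats = rbp_features(Sequence("q", "ARNCFGD"), red)
    assert feats.values.shape == (7, 144)
    np.testing.assert_array_equal(
        feats.values[2], red.embeddings[("R", "N", "C")].reshape(-1))
    # first residue has no left neighbour: center backoff
    np.testing.assert_array_equal(
        feats.values[0], red.embeddings["A"].reshape(-1))


def test_rbp_unseen_center_uses_global_backoff(rng):
    pot = _toy_potential(rng, 100)
    red = reduce_basins(pot, method="pca", seed=2)
    feats = rbp_features(Sequence("q", "WWW"), red)  # W never observed
    np.testing.assert_array_equal(
        feats.values[0], red.embeddings[GLOBAL_KEY].reshape(-1))


def test_potential_serialization_round_trip(tmp_path, rng):
    pot = _toy_potential(rng, 200)
    red = reduce_basins(pot, method="pca", seed=5)
    path = tmp_path / "potential.npz"
    save_potential(pot, red, path)
    pot2, red2 = load_potential(path)
    assert pot2.min_triplet_count == pot.min_triplet_count
    assert red2.method == "pca" and red2.seed == 5
    for key in pot.keys():
        np.testing.assert_array_equal(pot.normalized(key), pot2.normalized(key))
        np.testing.assert_array_equal(red.embeddings[key], red2.embeddings[key])


def test_torsion_records_skip_masked_and_terminal():
    chain = backbone_from_torsions("ARNCF", np.full(5, -60.0), np.full(5, -45.0))
    t = extract_torsions(chain)
    recs = list(torsion_records(chain, t))
    # residues 2..4 (1-based) have both angles and both neighbours
    assert [r[:3] for r in recs] == [("A", "R", "N"), ("R", "N", "C"), ("N", "C", "F")]
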