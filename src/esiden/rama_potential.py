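"""Backbone torsions and the triplet-conditioned Ramachandran basin potential.

The potential is a set of probability maps over the Ramachandran plane,
binned into 72 x 72 cells of 5 x 5 degrees, conditioned on a residue and
its two sequence neighbours (left, center, right).  Sparse triplets back
off to a map conditioned on the center residue alone.  Secondary
structure is not conditioned on.  Each map is reduced from 72 x 72 to
72 x 2 (t-SNE, or PCA as a deterministic alternative) and flattened to a
144-vector per residue — the RBP feature block.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .io_formats import BackboneChain, Sequence

N_BINS = 72
BIN_WIDTH = 5.0
#: peptide-bond C(i)-N(i+1) distance above which the chain is broken
CHAIN_BREAK_CUTOFF = 2.0
#: default Laplace mass per bin (1 / 72^2)
DEFAULT_PSEUDOCOUNT = 1.0 / (N_BINS * N_BINS)

#: key of the global (all observations pooled) backoff map
GLOBAL_KEY = "*"


@dataclass
class TorsionSeries:
    """Per-residue (phi, psi) in degrees in [-180, 180) with validity masks.

    ``phi_mask[0]`` and ``psi_mask[-1]`` are always False (the terminal
    torsions do not exist).  Masked entries hold the sentinel 0.0 and
    must never enter statistics.
    """

    phi: np.ndarray
    psi: np.ndarray
    phi_mask: np.ndarray
    psi_mask: np.ndarray

    def __post_init__(self) -> None:
        for name in ("phi", "psi"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("phi_mask", "psi_mask"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        L = len(self.phi)
        if not (len(self.psi) == len(self.phi_mask) == len(self.psi_mask) == L):
            raise ValueError("phi/psi/masks must share one length")
        if L:
            if self.phi_mask[0]:
                raise ValueError("phi is undefined at the N-terminal residue")
            if self.psi_mask[-1]:
                raise ValueError("psi is undefined at the C-terminal residue")

    def __len__(self) -> int:
        return len(self.phi)


def wrap_angle(deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (degrees) into [-180, 180); +180 maps to -180."""
    return (np.asarray(deg) + 180.0) % 360.0 - 180.0


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral (degrees, IUPAC sign convention) of four points.

    Computed with the quadrant-aware two-argument arctangent; raises on
    degenerate geometry (coincident points or parallel consecutive
    bonds), where the torsion is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-9:
            raise ValueError("coincident consecutive points: dihedral undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("parallel consecutive bonds: dihedral undefined")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def extract_torsions(chain: BackboneChain) -> TorsionSeries:
    """Extract (phi, psi) from backbone coordinates.

    phi_i uses C(i-1)-N(i)-CA(i)-C(i); psi_i uses N(i)-CA(i)-C(i)-N(i+1).
    Angles spanning an incomplete residue or a broken peptide bond
    (C-N distance > 2 A) are masked.
    """
    L = len(chain)
    if int(chain.complete.sum()) < 2:
        raise ValueError("need at least 2 complete residues to define torsions")
    phi = np.zeros(L)
    psi = np.zeros(L)
    phi_mask = np.zeros(L, dtype=bool)
    psi_mask = np.zeros(L, dtype=bool)

    def bonded(i: int) -> bool:
        """Is the peptide bond C(i)-N(i+1) intact?"""
        if not (chain.complete[i] and chain.complete[i + 1]):
            return False
        d = np.linalg.norm(chain.n[i + 1] - chain.c[i])
        return bool(d <= CHAIN_BREAK_CUTOFF)

    for i in range(L):
        if i > 0 and bonded(i - 1):
            phi[i] = dihedral_angle(chain.c[i - 1], chain.n[i], chain.ca[i], chain.c[i])
            phi_mask[i] = True
        if i < L - 1 and bonded(i):
            psi[i] = dihedral_angle(chain.n[i], chain.ca[i], chain.c[i], chain.n[i + 1])
            psi_mask[i] = True
    return TorsionSeries(phi=phi, psi=psi, phi_mask=phi_mask, psi_mask=psi_mask)


def angle_bin(deg: float) -> int:
    """5-degree bin index in [0, 72): floor((angle + 180) / 5)."""
    return int(np.floor((wrap_angle(deg) + 180.0) / BIN_WIDTH))


@dataclass
class BasinPotential:
    """Raw (phi, psi) bin counts keyed by residue triplets, with backoffs.

    ``triplet_counts[(l, c, r)]`` and ``center_counts[c]`` are 72 x 72
    count matrices; ``normalized(key)`` returns the probability map with
    backoff (sparse triplet -> center map; unseen center -> global map)
    and pseudocount smoothing applied.
    """

    triplet_counts: dict[tuple[str, str, str], np.ndarray]
    center_counts: dict[str, np.ndarray]
    global_counts: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    min_triplet_count: int = 20
    bin_width: float = BIN_WIDTH
    ss_mode: str = "A"  # secondary structure not conditioned

    def _normalize(self, counts: np.ndarray) -> np.ndarray:
        m = counts + self.pseudocount
        total = m.sum()
        if total == 0:
            raise ValueError("empty count map with zero pseudocount")
        return m / total

    def center_map(self, center: str) -> np.ndarray:
        counts = self.center_counts.get(center)
        if counts is None or (counts.sum() == 0 and self.pseudocount == 0):
            return self._normalize(self.global_counts)
        return self._normalize(counts)

    def normalized(self, key) -> np.ndarray:
        """Probability map for a triplet key, a center letter, or '*'."""
        if key == GLOBAL_KEY:
            return self._normalize(self.global_counts)
        if isinstance(key, str):
            return self.center_map(key)
        left, center, right = key
        counts = self.triplet_counts.get((left, center, right))
        if counts is None or counts.sum() < self.min_triplet_count:
            return self.center_map(center)
        return self._normalize(counts)

    def keys(self) -> list:
        """All keys with a distinct map: '*', every center, dense triplets."""
        ks: list = [GLOBAL_KEY]
        ks.extend(sorted(self.center_counts))
        ks.extend(sorted(k for k, v in self.triplet_counts.items()
                         if v.sum() >= self.min_triplet_count))
        return ks


def build_basin_potential(
    records,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_triplet_count: int = 20,
) -> BasinPotential:
    """Accumulate (left, center, right, phi, psi) observations into maps.

    ``records`` is an iterable of tuples; angles must be valid torsions in
    degrees.  Center maps exist for every amino acid seen; residues whose
    center was never observed back off to the pooled global map.
    """
    triplet: dict[tuple[str, str, str], np.ndarray] = {}
    center: dict[str, np.ndarray] = {}
    glob = np.zeros((N_BINS, N_BINS))
    n = 0
    for left, c, right, phi, psi in records:
        i, j = angle_bin(phi), angle_bin(psi)
        key = (left, c, right)
        if key not in triplet:
            triplet[key] = np.zeros((N_BINS, N_BINS))
        if c not in center:
            center[c] = np.zeros((N_BINS, N_BINS))
        triplet[key][i, j] += 1
        center[c][i, j] += 1
        glob[i, j] += 1
        n += 1
    if n == 0:
        raise ValueError("no torsion observations supplied")
    return BasinPotential(
        triplet_counts=triplet,
        center_counts=center,
        global_counts=glob,
        pseudocount=pseudocount,
        min_triplet_count=min_triplet_count,
    )


def torsion_records(chain: BackboneChain, torsions: TorsionSeries):
    """Yield (left, center, right, phi, psi) for residues with both angles."""
    seq = chain.residues
    L = len(seq)
    for i in range(L):
        if torsions.phi_mask[i] and torsions.psi_mask[i]:
            left = seq[i - 1] if i > 0 else None
            right = seq[i + 1] if i < L - 1 else None
            if left is None or right is None:
                continue
            yield left, seq[i], right, torsions.phi[i], torsions.psi[i]


def _pca_embed(map2d: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic 2-component PCA of the 72 phi-rows (sign-fixed)."""
    pca = PCA(n_components=2, svd_solver="full", random_state=seed)
    emb = pca.fit_transform(map2d)
    # fix component signs so the embedding is reproducible across runs
    for k in range(emb.shape[1]):
        col = pca.components_[k]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            emb[:, k] = -emb[:, k]
    return emb


def _tsne_embed(map2d: np.ndarray, seed: int) -> np.ndarray:
    tsne = TSNE(
        n_components=2,
        perplexity=30.0,
        init="pca",
        random_state=seed,
        max_iter=500,
    )
    return tsne.fit_transform(map2d.astype(np.float64))


@dataclass
class ReducedBasinSet:
    """72 x 2 embeddings per potential key, plus the reduction provenance."""

    embeddings: dict
    method: str
    seed: int

    def get(self, key):
        return self.embeddings.get(key)


def reduce_basins(
    potential: BasinPotential, method: str = "pca", seed: int = 0
) -> ReducedBasinSet:
    """Embed every 72 x 72 map to 72 x 2.

    Each map is treated as 72 points (the phi-rows) in 72 dimensions (the
    psi-bins) and embedded independently per key.  ``pca`` is exactly
    reproducible; ``tsne`` is reproducible for a fixed seed.
    """
    if method not in ("pca", "tsne"):
        raise ValueError(f"unknown reduction method {method!r}")
    embed = _pca_embed if method == "pca" else _tsne_embed
    embeddings = {}
    for key in potential.keys():
        emb = embed(potential.normalized(key), seed)
        embeddings[key] = np.asarray(emb, dtype=np.float64)
    return ReducedBasinSet(embeddings=embeddings, method=method, seed=seed)


@dataclass
class RbpMatrix:
    """The flattened per-residue RBP feature block, shape (L, 144)."""

    values: np.ndarray


def rbp_features(seq: Sequence, reduced: ReducedBasinSet) -> RbpMatrix:
    """Per-residue 144-vector from the reduced basin of (left, self, right).

    Terminal residues and unseen triplets use the center-residue backoff;
    residues with no center map (e.g. 'X') use the global map.  Rows are
    the row-major flattening of the 72 x 2 embedding.
    """
    s = seq.residues
    L = len(s)
    out = np.zeros((L, 2 * N_BINS))
    for i in range(L):
        emb = None
        if 0 < i < L - 1:
            emb = reduced.get((s[i - 1], s[i], s[i + 1]))
        if emb is None:
            emb = reduced.get(s[i])
        if emb is None:
            emb = reduced.get(GLOBAL_KEY)
        if emb is None:
            raise KeyError(
                f"no basin embedding for residue {s[i]!r} at position {i} "
                "and no global backoff present"
            )
        out[i] = emb.reshape(-1)
    return RbpMatrix(values=out)


# ---------------------------------------------------------------------------
# Serialization (runtime artifact; .npz container + metadata)


def save_potential(potential: BasinPotential, reduced: ReducedBasinSet,
                   path: str | Path) -> None:
    arrays: dict[str, np.ndarray] = {"__global__": potential.global_counts}
    for c, v in potential.center_counts.items():
        arrays[f"c:{c}"] = v
    for (l, c, r), v in potential.triplet_counts.items():
        arrays[f"t:{l}{c}{r}"] = v
    for key, emb in reduced.embeddings.items():
        name = "*" if key == GLOBAL_KEY else (key if isinstance(key, str) else "".join(key))
        arrays[f"e:{name}"] = emb
    meta = np.array([potential.pseudocount, potential.min_triplet_count,
                     potential.bin_width, reduced.seed])
    np.savez_compressed(path, __meta__=meta,
                        __method__=np.array(reduced.method), **arrays)


def load_potential(path: str | Path) -> tuple[BasinPotential, ReducedBasinSet]:
    with np.load(path, allow_pickle=False) as data:
        meta = data["__meta__"]
        method = str(data["__method__"])
        triplet, center, embeddings = {}, {}, {}
        glob = data["__global__"]
        for name in data.files:
            if name.startswith("c:"):
                center[name[2:]] = data[name]
            elif name.startswith("t:"):
                l, c, r = name[2:]
                triplet[(l, c, r)] = data[name]
            elif name.startswith("e:"):
                raw = name[2:]
                key = GLOBAL_KEY if raw == "*" else (raw if len(raw) == 1 else tuple(raw))
                embeddings[key] = data[name]
    potential = BasinPotential(
        triplet_counts=triplet, center_counts=center, global_counts=glob,
        pseudocount=float(meta[0]), min_triplet_count=int(meta[1]),
        bin_width=float(meta[2]),
    )
    reduced = ReducedBasinSet(embeddings=embeddings, method=method,
                              seed=int(meta[3]))
    return potential, reduced
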