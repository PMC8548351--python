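"""Classic per-residue features and assembly of the L x 232 network input.

Block order is fixed: AA(20) | PP(7) | PSSM(20) | RE(20) | DC(1) |
PSSP(20) | RBP(144) = 232 channels.  The classic blocks alone
(AA | PP | PSSM) form the L x 47 matrix.  All channels are min-max
scaled into [-1, 1] with bounds learned on a training set; one-hot and
constant channels pass through unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .alphabet import AA_INDEX, physchem_table
from .io_formats import Sequence

logger = logging.getLogger(__name__)

#: fixed block order and widths
BLOCK_WIDTHS: dict[str, int] = {
    "AA": 20, "PP": 7, "PSSM": 20, "RE": 20, "DC": 1, "PSSP": 20, "RBP": 144,
}
CLASSIC_BLOCKS = ("AA", "PP", "PSSM")
FULL_WIDTH = sum(BLOCK_WIDTHS.values())  # 232
CLASSIC_WIDTH = sum(BLOCK_WIDTHS[b] for b in CLASSIC_BLOCKS)  # 47


def aa_onehot(seq: Sequence) -> np.ndarray:
    """One-hot residue encoding, columns alphabetical; 'X' rows all-zero."""
    out = np.zeros((len(seq), 20))
    for i, c in enumerate(seq.residues):
        j = AA_INDEX.get(c)
        if j is not None:
            out[i, j] = 1.0
    return out


def physchem_features(seq: Sequence) -> np.ndarray:
    """Seven physicochemical descriptors per residue (steric parameter,
    polarizability, van der Waals volume, hydrophobicity, isoelectric
    point, helix and sheet probability).  'X' rows take the per-property
    mean over the 20 amino acids."""
    table = physchem_table()
    means = table.mean(axis=0)
    out = np.empty((len(seq), 7))
    for i, c in enumerate(seq.residues):
        j = AA_INDEX.get(c)
        out[i] = table[j] if j is not None else means
    return out


@dataclass
class ChannelScaler:
    """Per-channel affine map onto [-1, 1] with persisted bounds.

    Channels whose training values are all in {0, 1} (one-hot) are
    flagged identity, as are constant channels (with a warning: they
    carry no signal and are left unchanged).
    """

    mins: np.ndarray
    maxs: np.ndarray
    identity: np.ndarray  # bool per channel

    @property
    def n_channels(self) -> int:
        return len(self.mins)

    def transform(self, values: np.ndarray, clip: bool = True) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape[1] != self.n_channels:
            raise ValueError(
                f"expected {self.n_channels} channels, got {values.shape[1]}"
            )
        out = values.copy()
        act = ~self.identity
        span = self.maxs[act] - self.mins[act]
        out[:, act] = 2.0 * (values[:, act] - self.mins[act]) / span - 1.0
        if clip:
            out = np.clip(out, -1.0, 1.0)
        return out

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        scaled = np.asarray(scaled, dtype=float)
        out = scaled.copy()
        act = ~self.identity
        span = self.maxs[act] - self.mins[act]
        out[:, act] = (scaled[:, act] + 1.0) / 2.0 * span + self.mins[act]
        return out

    def to_dict(self) -> dict:
        return {
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "identity": self.identity.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelScaler":
        return cls(
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
            identity=np.asarray(d["identity"], dtype=bool),
        )

    @classmethod
    def identity_scaler(cls, n_channels: int) -> "ChannelScaler":
        return cls(
            mins=np.full(n_channels, -1.0),
            maxs=np.full(n_channels, 1.0),
            identity=np.ones(n_channels, dtype=bool),
        )


def fit_scaler(matrices: list[np.ndarray]) -> ChannelScaler:
    """Learn per-channel [min, max] bounds from a list of (L_i, C) blocks."""
    if not matrices:
        raise ValueError("need at least one matrix to fit the scaler")
    stacked = np.vstack([np.asarray(m, dtype=float) for m in matrices])
    mins = stacked.min(axis=0)
    maxs = stacked.max(axis=0)
    onehot = np.array([set(np.unique(stacked[:, j])) <= {0.0, 1.0}
                       for j in range(stacked.shape[1])])
    constant = mins == maxs
    n_const = int((constant & ~onehot).sum())
    if n_const:
        msg = f"{n_const} constant feature channel(s) left unscaled"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return ChannelScaler(mins=mins, maxs=maxs, identity=onehot | constant)


@dataclass
class FeatureMatrix:
    """Assembled per-residue feature matrix with named block slices."""

    values: np.ndarray
    blocks: dict[str, slice]
    scaled: bool

    def block(self, name: str) -> np.ndarray:
        return self.values[:, self.blocks[name]]

    def __len__(self) -> int:
        return len(self.values)


def assemble_features(
    seq: Sequence,
    pp: np.ndarray | None = None,
    pssm: np.ndarray | None = None,
    re: np.ndarray | None = None,
    dc: np.ndarray | None = None,
    pssp: np.ndarray | None = None,
    rbp: np.ndarray | None = None,
    scaler: ChannelScaler | None = None,
) -> FeatureMatrix:
    """Concatenate feature blocks in the fixed order and apply the scaler.

    ``pp`` and ``pssm`` default to the packaged physicochemical table and
    are required for the classic L x 47 block; passing the four
    evolutionary blocks as well yields the full L x 232 matrix.  DC may
    be (L,) or (L, 1).  A length mismatch raises, naming the blocks.
    """
    L = len(seq)
    aa = aa_onehot(seq)
    if pp is None:
        pp = physchem_features(seq)
    provided = {"AA": aa, "PP": pp, "PSSM": pssm, "RE": re, "DC": dc,
                "PSSP": pssp, "RBP": rbp}
    evo = [provided[b] is not None for b in ("RE", "DC", "PSSP", "RBP")]
    if any(evo) and not all(evo):
        raise ValueError("provide all of RE, DC, PSSP, RBP or none of them")
    if provided["PSSM"] is None:
        raise ValueError("the PSSM block is required")
    names = list(BLOCK_WIDTHS) if all(evo) else list(CLASSIC_BLOCKS)

    blocks: dict[str, slice] = {}
    parts = []
    offset = 0
    for name in names:
        arr = np.asarray(provided[name], dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape != (L, BLOCK_WIDTHS[name]):
            raise ValueError(
                f"block {name} has shape {arr.shape}, expected "
                f"({L}, {BLOCK_WIDTHS[name]}) to match block AA"
            )
        blocks[name] = slice(offset, offset + BLOCK_WIDTHS[name])
        offset += BLOCK_WIDTHS[name]
        parts.append(arr)
    values = np.hstack(parts)
    scaled = False
    if scaler is not None:
        values = scaler.transform(values, clip=True)
        scaled = True
    return FeatureMatrix(values=values, blocks=blocks, scaled=scaled)
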