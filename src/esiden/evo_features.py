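"""MSA-derived evolutionary features: RE, DC and PSSP.

Three per-residue signals are computed from a trimmed multiple sequence
alignment:

* **relative entropy (RE)** — for each position i and amino acid a, the
  binary Kullback-Leibler divergence between the observed column
  frequency f_i^a and a background probability p^a:

      RE_i^a = f ln(f/p) + (1-f) ln((1-f)/(1-p))

* **degree of conservation (DC)** — the per-position sum of RE over the
  20 amino acids; a scalar conservation score per column.

* **position-specific substitution probabilities (PSSP)** — derived from
  the site terms h_i of an evolutionary statistical (Potts-type) energy
  E = sum_ij e_ij + sum_i h_i.  Pairwise couplings e_ij are not used;
  with independent sites the maximum-likelihood h_i is the log of the
  (smoothed) column frequency up to an additive gauge constant, and the
  PSSP is softmax(h_i) per position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, background_frequencies
from .io_formats import AlignedMSA


@dataclass
class ColumnProfile:
    """Per-column amino-acid frequencies plus a background distribution."""

    freqs: np.ndarray           # (L, 20), rows sum to 1 over non-gap mass
    background: np.ndarray      # (20,), sums to 1
    effective_depth: np.ndarray  # (L,) non-gap observations per column

    def __post_init__(self) -> None:
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("column frequency rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if (self.freqs < 0).any() or (self.background < 0).any():
            raise ValueError("probabilities must be non-negative")


@dataclass
class EvoFeatureSet:
    """RE (L x 20) and DC (L,) computed from one profile."""

    re: np.ndarray
    dc: np.ndarray


@dataclass
class SiteFields:
    """Site-specific bias terms h_i, gauge-fixed to zero row sums."""

    h: np.ndarray        # (L, 20)
    pseudocount: float

    def __post_init__(self) -> None:
        if not np.allclose(self.h.sum(axis=1), 0.0, atol=1e-6):
            raise ValueError("site fields must be gauge-fixed to zero row sums")


def trim_msa(msa: AlignedMSA, max_row_gap_fraction: float = 0.5) -> AlignedMSA:
    """Remove alignment rows whose gap fraction exceeds a threshold.

    The query row is always retained.  ``max_row_gap_fraction = 1`` is the
    identity.
    """
    if not (0.0 < max_row_gap_fraction <= 1.0):
        raise ValueError("max_row_gap_fraction must be in (0, 1]")
    L = len(msa.query)
    kept = [msa.rows[0]]
    for row in msa.rows[1:]:
        if row.count("-") / L <= max_row_gap_fraction:
            kept.append(row)
    return AlignedMSA(query=msa.query, rows=kept)


def column_frequencies(
    msa: AlignedMSA,
    background_mode: str = "fixed_table",
    pseudocount: float = 0.0,
) -> ColumnProfile:
    """Per-column amino-acid frequencies with gaps excluded.

    Counts (plus ``pseudocount`` per amino acid) are renormalised per
    column.  'X' residues contribute no counts.  The background is either
    the packaged standard table (``fixed_table``) or the frequencies
    pooled over all columns of this MSA (``pooled``).
    """
    if background_mode not in ("fixed_table", "pooled"):
        raise ValueError(f"unknown background_mode {background_mode!r}")
    L = len(msa.query)
    counts = np.zeros((L, 20))
    for row in msa.rows:
        for i, c in enumerate(row):
            j = AA_INDEX.get(c)
            if j is not None:
                counts[i, j] += 1
    depth = counts.sum(axis=1)
    if pseudocount == 0.0 and (depth == 0).any():
        bad = int(np.argmax(depth == 0))
        raise ValueError(
            f"column {bad} has no amino-acid observations and pseudocount is 0"
        )
    smoothed = counts + pseudocount
    freqs = smoothed / smoothed.sum(axis=1, keepdims=True)
    if background_mode == "pooled":
        pooled = counts.sum(axis=0) + pseudocount
        if pooled.sum() == 0:
            raise ValueError("cannot pool background from an empty MSA")
        background = pooled / pooled.sum()
    else:
        background = background_frequencies()
    return ColumnProfile(freqs=freqs, background=background,
                         effective_depth=depth)


def relative_entropy(profile: ColumnProfile) -> np.ndarray:
    """Binary KL divergence per (position, amino acid); shape (L, 20).

    Uses the convention 0 ln 0 := 0, so fully absent and fully conserved
    frequencies are well defined.  Background entries must lie strictly
    inside (0, 1).
    """
    p = profile.background
    if (p <= 0).any() or (p >= 1).any():
        raise ValueError("background probabilities must lie strictly in (0, 1)")
    f = profile.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(f > 0, f * np.log(f / p), 0.0)
        term2 = np.where(f < 1, (1 - f) * np.log((1 - f) / (1 - p)), 0.0)
    return term1 + term2


def degree_of_conservation(re: np.ndarray) -> np.ndarray:
    """Per-position conservation: the exact row sum of RE; shape (L,)."""
    re = np.asarray(re)
    if re.ndim != 2 or re.shape[1] != 20:
        raise ValueError("RE must be an L x 20 array")
    return re.sum(axis=1)


def compute_evo_features(profile: ColumnProfile) -> EvoFeatureSet:
    re = relative_entropy(profile)
    return EvoFeatureSet(re=re, dc=degree_of_conservation(re))


def fit_site_fields(profile: ColumnProfile, pseudocount: float = 1.0) -> SiteFields:
    """Independent-site maximum-likelihood fit of the Potts site terms h_i.

    With couplings ignored the likelihood factorises per column and the
    optimum is h_i(a) = ln f~_i(a) + const, where f~ are the lambda-smoothed
    frequencies; the zero-sum gauge fixes the constant.  By construction
    softmax(h_i) reproduces f~_i exactly.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    depth = profile.effective_depth[:, None]
    smoothed = profile.freqs * depth + pseudocount
    smoothed = smoothed / smoothed.sum(axis=1, keepdims=True)
    if (smoothed <= 0).any():
        raise ValueError(
            "smoothed frequencies must be strictly positive; "
            "increase the pseudocount"
        )
    log_f = np.log(smoothed)
    h = log_f - log_f.mean(axis=1, keepdims=True)
    return SiteFields(h=h, pseudocount=float(pseudocount))


def pssp_from_fields(fields: SiteFields) -> np.ndarray:
    """Per-position substitution probabilities: row softmax of h; (L, 20)."""
    h = fields.h
    z = h - h.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
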