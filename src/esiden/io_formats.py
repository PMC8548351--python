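"""Readers and writers for the standard formats the toolkit touches.

FASTA and aligned-FASTA parsing go through Biopython; A3M projection
(dropping lowercase insertion states so every row matches the query
length) is applied on top.  PDB backbone extraction keeps only the three
mainchain atoms N/CA/C that define the phi/psi torsions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser

from .alphabet import AMINO_ACIDS, PSIBLAST_ORDER, THREE_TO_ONE, canonicalize


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


@dataclass
class Sequence:
    """A named protein sequence over the 20 one-letter codes plus 'X'."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        self.residues = canonicalize(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignedMSA:
    """An MSA projected onto query (match) columns.

    Row 0 is the ungapped query; every row has exactly ``len(query)``
    columns and uses '-' for gaps.
    """

    query: Sequence
    rows: list[str]

    def __post_init__(self) -> None:
        L = len(self.query)
        for k, row in enumerate(self.rows):
            if len(row) != L:
                raise FormatError(
                    f"MSA row {k} has {len(row)} columns, query has {L}"
                )
        if self.rows and "-" in self.rows[0]:
            raise FormatError("query row of an aligned MSA may not contain gaps")

    @property
    def depth(self) -> int:
        return len(self.rows)

    def __len__(self) -> int:
        return len(self.query)


@dataclass
class BackboneChain:
    """Backbone N/CA/C coordinates for one chain, indexed 1..L.

    ``complete[i]`` is False when any of the three atoms is missing at
    residue i; such coordinates are NaN and must not enter statistics.
    ``author_numbers`` retains the file's own residue numbering.
    """

    chain_id: str
    residues: str
    n: np.ndarray        # (L, 3) angstroms
    ca: np.ndarray       # (L, 3)
    c: np.ndarray        # (L, 3)
    complete: np.ndarray  # (L,) bool
    author_numbers: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PssmProfile:
    """PSI-BLAST log-odds scores, remapped to AMINO_ACIDS column order."""

    query: Sequence
    scores: np.ndarray  # (L, 20) int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.shape != (len(self.query), 20):
            raise FormatError(
                f"PSSM shape {self.scores.shape} does not match query length "
                f"{len(self.query)}"
            )


# ---------------------------------------------------------------------------
# FASTA / MSA


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file into a list of :class:`Sequence`.

    Wrapped sequence lines are concatenated; the record id is the header
    text up to the first whitespace.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path}: line {lineno}: expected FASTA header")
        break
    else:
        raise FormatError(f"{path}: empty FASTA file")
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return [Sequence(rec.id, str(rec.seq)) for rec in records]


def write_fasta(seqs: list[Sequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def _project_a3m(row: str) -> str:
    """Drop lowercase insertion characters; normalise '.' to '-'."""
    return "".join("-" if c == "." else c for c in row if not c.islower())


def read_msa(path: str | Path, format: str = "afa") -> AlignedMSA:
    """Read an alignment whose first record is the query.

    ``afa`` rows must all share the query length.  ``a3m`` rows carry
    lowercase insertion characters which are removed so that every row
    projects onto the query's match columns.
    """
    if format not in ("afa", "a3m"):
        raise ValueError(f"unknown MSA format {format!r}")
    path = Path(path)
    text = path.read_text()
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise FormatError(f"{path}: no alignment records")
    raw = [str(r.seq) for r in records]
    if format == "a3m":
        raw = [_project_a3m(r) for r in raw]
    else:
        width = len(raw[0])
        for k, row in enumerate(raw):
            if len(row) != width:
                raise FormatError(
                    f"{path}: record {records[k].id!r} has {len(row)} columns, "
                    f"expected {width}"
                )
        # columns where the query is gapped are insertions, not match columns
        keep = [j for j, c in enumerate(raw[0]) if c not in "-."]
        raw = ["".join(row[j] for j in keep) for row in raw]
    query = Sequence(records[0].id, raw[0])
    L = len(query)
    rows = []
    for k, row in enumerate(raw):
        row = canonicalize_row(row)
        if len(row) != L:
            raise FormatError(
                f"{path}: record {records[k].id!r} projects to {len(row)} "
                f"columns, query has {L}"
            )
        rows.append(row)
    rows[0] = query.residues
    return AlignedMSA(query=query, rows=rows)


def canonicalize_row(row: str) -> str:
    """Canonicalize an alignment row, keeping gap characters."""
    return "".join("-" if c in "-." else c if c in AMINO_ACIDS else "X"
                   for c in row.upper())


def write_msa(msa: AlignedMSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{msa.query.id}\n{msa.rows[0]}\n")
        for k, row in enumerate(msa.rows[1:], start=1):
            fh.write(f">row{k}\n{row}\n")


# ---------------------------------------------------------------------------
# PDB backbone


def read_pdb_backbone(path: str | Path, chain: str) -> BackboneChain:
    """Extract per-residue N/CA/C coordinates for one chain.

    First model only; for disordered atoms the highest-occupancy altloc
    wins (ties by label order).  Nonstandard residues map to their parent
    one-letter code where known (MSE -> M) and to 'X' otherwise.
    Residues missing any of N/CA/C are flagged incomplete.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chain_ids = [c.id for c in model]
    if chain not in chain_ids:
        raise KeyError(f"chain {chain!r} not found (available: {chain_ids})")
    ch = model[chain]

    letters: list[str] = []
    numbers: list[int] = []
    coords = {"N": [], "CA": [], "C": []}
    complete: list[bool] = []
    for res in ch:
        hetflag, resseq, _icode = res.id
        resname = res.get_resname().strip()
        if hetflag != " " and resname not in THREE_TO_ONE:
            continue  # skip waters/ligands, keep MSE-like residues
        letters.append(THREE_TO_ONE.get(resname, "X"))
        numbers.append(resseq)
        ok = True
        for atom_name in ("N", "CA", "C"):
            if atom_name in res:
                atom = res[atom_name]  # DisorderedAtom resolves by occupancy
                coords[atom_name].append(np.asarray(atom.get_coord(), dtype=float))
            else:
                coords[atom_name].append(np.full(3, np.nan))
                ok = False
        complete.append(ok)
    if not letters:
        raise FormatError(f"chain {chain!r} contains no amino-acid residues")
    return BackboneChain(
        chain_id=chain,
        residues="".join(letters),
        n=np.vstack(coords["N"]),
        ca=np.vstack(coords["CA"]),
        c=np.vstack(coords["C"]),
        complete=np.asarray(complete, dtype=bool),
        author_numbers=numbers,
    )


_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}


def write_pdb_backbone(chain: BackboneChain, path: str | Path) -> None:
    """Write backbone N/CA/C ATOM records (complete residues only)."""
    serial = 1
    with open(path, "w") as fh:
        for i in range(len(chain)):
            if not chain.complete[i]:
                continue
            resname = _ONE_TO_THREE.get(chain.residues[i], "UNK")
            for name, xyz in (("N", chain.n[i]), ("CA", chain.ca[i]), ("C", chain.c[i])):
                fh.write(
                    f"ATOM  {serial:5d} {name:^4s} {resname:3s} {chain.chain_id:1s}"
                    f"{i + 1:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}\n"
                )
                serial += 1
        fh.write("TER\nEND\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_psiblast_pssm(path: str | Path) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM into an L x 20 signed-integer matrix.

    Only the first 20 columns (log-odds scores) are kept; columns are
    remapped from PSI-BLAST order to the package's alphabetical order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    residues: list[str] = []
    rows: list[list[int]] = []
    started = False
    for lineno, line in enumerate(lines, start=1):
        toks = line.split()
        if not started:
            # the column-header line lists the 20 residues (twice)
            if len(toks) >= 20 and all(t in PSIBLAST_ORDER for t in toks[:20]):
                started = True
            continue
        if len(toks) < 2 or not toks[0].isdigit():
            if rows:
                break  # footer (statistics block)
            continue
        if len(toks) < 22:
            raise FormatError(f"{path}: line {lineno}: truncated PSSM row")
        try:
            scores = [int(t) for t in toks[2:22]]
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-integer score") from exc
        residues.append(toks[1])
        rows.append(scores)
    if not rows:
        raise FormatError(f"{path}: no PSSM rows found")
    query = Sequence(path.stem, "".join(residues))
    raw = np.asarray(rows, dtype=int)
    remap = [PSIBLAST_ORDER.index(a) for a in AMINO_ACIDS]
    return PssmProfile(query=query, scores=raw[:, remap])


# ---------------------------------------------------------------------------
# Angle tables


def write_torsion_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-residue torsion table (chain, resi, aa, phi, psi, masks)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_torsion_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chain", "resi", "aa", "phi", "psi", "phi_mask", "psi_mask"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
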