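"""Reading, validation and normalization of protein PSSM profiles.

A position-specific scoring matrix (PSSM) summarizes the evolutionary
substitution preferences of every residue position of one protein as an
L x 20 matrix of log-odds scores, one column per standard amino acid in
PSI-BLAST column order (A R N D C Q E G H I L K M F P S T W Y V).  This
module parses the ASCII dump produced by ``psiblast -out_ascii_pssm``,
normalizes raw scores into probability-like values, and round-trips
matrices through a plain TSV dump used for fixtures.

Running PSI-BLAST itself (typically e-value 0.001, 3 iterations against a
large non-redundant database) is outside the scope of this package; only
its output files are consumed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Union

import numpy as np
from Bio import SeqIO
from scipy.special import expit

#: PSI-BLAST amino-acid column order.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Residue letters tolerated in sequences (20 standard + ambiguity codes).
ALLOWED_RESIDUES = set(AA_ORDER) | set("XBZU")

NORMALIZATIONS = ("raw", "sigmoid", "rowsum")


class PSSMParseError(ValueError):
    """Raised when a PSI-BLAST ASCII PSSM file cannot be parsed."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its identifier."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.protein_id}: sequence must be non-empty")
        bad = set(self.sequence.upper()) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"{self.protein_id}: unexpected residue letters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PSSM:
    """An L x 20 position-specific scoring matrix for one protein.

    ``scores`` holds one row per residue; columns follow :data:`AA_ORDER`.
    ``normalization`` records whether the entries are raw PSI-BLAST
    log-odds (``raw``), element-wise logistic transforms in (0, 1)
    (``sigmoid``), or per-row shifted relative frequencies summing to one
    (``rowsum``).
    """

    protein_id: str
    scores: np.ndarray
    sequence: str = ""
    normalization: str = "raw"
    column_order: str = field(default=AA_ORDER, repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"{self.protein_id}: PSSM must have exactly 20 columns, "
                f"got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"{self.protein_id}: PSSM must have at least one row")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.sequence and len(self.sequence) != self.scores.shape[0]:
            raise ValueError(
                f"{self.protein_id}: sequence length {len(self.sequence)} "
                f"!= number of score rows {self.scores.shape[0]}"
            )
        if self.normalization == "sigmoid":
            if not np.all((self.scores > 0.0) & (self.scores < 1.0)):
                raise ValueError("sigmoid-normalized entries must lie in (0, 1)")
        elif self.normalization == "rowsum":
            if not np.allclose(self.scores.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("rowsum-normalized rows must each sum to 1")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def _looks_like_matrix_header(tokens: List[str]) -> bool:
    # The score header line lists single amino-acid letters (20 for the
    # log-odds block, usually repeated for the percentage block).
    letters = [t for t in tokens if len(t) == 1 and t.isalpha()]
    return len(letters) >= 20 and len(letters) == len(tokens)


def parse_psiblast_pssm(path: Union[str, Path]) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a raw :class:`PSSM`.

    Only the first block of 20 integer columns (the log-odds scores) is
    kept; the percentage block and the two trailing per-row statistics are
    ignored.  Rows for nonstandard residues (X/B/Z/U) are retained so that
    the matrix length matches the query sequence length.

    Raises
    ------
    PSSMParseError
        If the file is empty, the matrix header is missing, or any residue
        row does not carry 20 integer scores.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise PSSMParseError(f"{path}: empty PSSM file")

    lines = text.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if _looks_like_matrix_header(line.split()):
            header_idx = i
            break
    if header_idx is None:
        raise PSSMParseError(f"{path}: no PSSM matrix header line found")

    rows: List[List[int]] = []
    residues: List[str] = []
    expected_pos = 1
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            break  # blank line terminates the matrix block
        if not tokens[0].lstrip("-").isdigit():
            break  # footer (Lambda/K statistics)
        if len(tokens) < 2 or len(tokens[1]) != 1 or not tokens[1].isalpha():
            raise PSSMParseError(
                f"{path}:{lineno}: expected '<pos> <residue> <20 scores...>', "
                f"got: {line.strip()!r}"
            )
        if len(tokens) < 22:
            raise PSSMParseError(
                f"{path}:{lineno}: residue row has fewer than 20 score columns"
            )
        try:
            scores = [int(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise PSSMParseError(
                f"{path}:{lineno}: non-integer score in log-odds block: {exc}"
            ) from None
        if int(tokens[0]) != expected_pos:
            raise PSSMParseError(
                f"{path}:{lineno}: position {tokens[0]} out of order "
                f"(expected {expected_pos})"
            )
        expected_pos += 1
        rows.append(scores)
        residues.append(tokens[1].upper())

    if not rows:
        raise PSSMParseError(f"{path}: no residue rows found after matrix header")

    return PSSM(
        protein_id=path.stem,
        scores=np.array(rows, dtype=float),
        sequence="".join(residues),
        normalization="raw",
    )


def normalize_pssm(p: PSSM, mode: str) -> PSSM:
    """Return a new PSSM with entries normalized per ``mode``.

    ``sigmoid`` maps every log-odds score s to 1/(1+exp(-s)), giving a
    probability-like value in (0, 1).  ``rowsum`` first shifts each row by
    its minimum (raw log-odds rows may sum to <= 0) and then divides by the
    row sum; an all-constant row maps to the uniform distribution (each
    entry 1/20).  ``raw`` returns an identity copy.
    """
    if p.normalization != "raw":
        raise ValueError(
            f"cannot re-normalize a PSSM already in {p.normalization!r} state"
        )
    if mode not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization mode {mode!r}")

    if mode == "raw":
        return replace(p, scores=p.scores.copy())
    if mode == "sigmoid":
        return replace(p, scores=expit(p.scores), normalization="sigmoid")

    shifted = p.scores - p.scores.min(axis=1, keepdims=True)
    sums = shifted.sum(axis=1, keepdims=True)
    flat = (sums[:, 0] == 0)  # all-constant rows -> uniform
    shifted[flat] = 1.0
    sums[flat] = 20.0
    return replace(p, scores=shifted / sums, normalization="rowsum")


def write_pssm_tsv(p: PSSM, path: Union[str, Path]) -> None:
    """Dump a PSSM to the internal TSV fixture format."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#protein_id\t{p.protein_id}\n")
        if p.sequence:
            fh.write(f"#sequence\t{p.sequence}\n")
        fh.write(f"#normalization\t{p.normalization}\n")
        for row in p.scores:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def read_pssm_tsv(path: Union[str, Path]) -> PSSM:
    """Read a PSSM from the internal TSV dump written by :func:`write_pssm_tsv`."""
    path = Path(path)
    protein_id, sequence, normalization = path.stem, "", "raw"
    rows: List[List[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("\t")
            if key == "protein_id":
                protein_id = value
            elif key == "sequence":
                sequence = value
            elif key == "normalization":
                normalization = value
            continue
        values = line.split("\t")
        if len(values) != 20:
            raise PSSMParseError(f"{path}:{lineno}: expected 20 columns")
        rows.append([float(v) for v in values])
    if not rows:
        raise PSSMParseError(f"{path}: no score rows")
    return PSSM(
        protein_id=protein_id,
        scores=np.array(rows),
        sequence=sequence,
        normalization=normalization,
    )


def read_fasta(path: Union[str, Path]) -> List[ProteinRecord]:
    """Read protein records from a FASTA file (identifier bookkeeping only)."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(protein_id=rec.id, sequence=str(rec.seq).upper()))
    return records
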