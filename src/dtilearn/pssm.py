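"""Reading, validating and normalizing position-specific scoring matrices.

A PSSM is the N x 20 log-odds profile PSI-BLAST emits for a protein of N
residues: entry (i, j) scores substitution of residue i by the j-th amino
acid.  Only the ASCII ``-out_ascii_pssm`` output format is handled here;
running PSI-BLAST itself is out of scope.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

# Canonical residue alphabet in the order PSI-BLAST prints it.
DEFAULT_ALPHABET: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

#: Ambiguity / non-standard residue letters tolerated in sequences.  They are
#: retained verbatim in ProteinRecord.sequence but never influence scores,
#: which always come from the file's numeric columns.
AMBIGUITY_RESIDUES: frozenset[str] = frozenset("XBZUJO*-")

N_AMINO_ACIDS = 20


class PSSMParseError(ValueError):
    """Raised when a PSI-BLAST ASCII PSSM file cannot be parsed."""


class ConfigurationError(ValueError):
    """Raised for unrecognized option values."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier with its (optional) amino-acid sequence."""

    protein_id: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            allowed = set("".join(DEFAULT_ALPHABET)) | AMBIGUITY_RESIDUES
            bad = set(self.sequence.upper()) - allowed
            if bad:
                raise ValueError(
                    f"sequence of {self.protein_id!r} contains unsupported "
                    f"residue letters: {sorted(bad)}"
                )


@dataclass
class PSSM:
    """An N x 20 profile of real-valued substitution scores.

    Attributes
    ----------
    protein_id:
        Opaque identifier (file stem in batch mode).
    scores:
        Array of shape (N, 20), row order equals residue order.
    column_alphabet:
        Ordered amino-acid letters of the 20 score columns, as read from the
        source file header (not assumed).
    record:
        The residue letters of the profile rows, when available.
    """

    protein_id: str
    scores: np.ndarray
    column_alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    record: ProteinRecord | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != N_AMINO_ACIDS:
            raise ValueError(
                f"PSSM must have exactly {N_AMINO_ACIDS} columns, got shape "
                f"{self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError("PSSM must have at least one row")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("PSSM entries must all be finite")
        if len(self.column_alphabet) != N_AMINO_ACIDS:
            raise ValueError("column alphabet must list 20 letters")

    @property
    def n_residues(self) -> int:
        return int(self.scores.shape[0])


_ROW_RE = re.compile(r"^\s*(\d+)\s+(\S)\s+(.*)$")


def _looks_like_alphabet_header(tokens: list[str]) -> bool:
    if len(tokens) not in (N_AMINO_ACIDS, 2 * N_AMINO_ACIDS):
        return False
    return all(len(t) == 1 and t.isalpha() for t in tokens)


def parse_psiblast_pssm(stream, protein_id: str = "") -> PSSM:
    """Parse one PSI-BLAST ``-out_ascii_pssm`` file into a :class:`PSSM`.

    Both the 20-column (scores only) and 40-column (scores plus weighted
    observed percentages) dialects are accepted; only the first 20 integer
    score columns are kept.  Trailing per-row statistics and the
    Lambda/K footer are ignored.

    Parameters
    ----------
    stream:
        Text content, a text file object, or a path to the file.
    protein_id:
        Identifier to attach; defaults to the file stem when a path is given.

    Raises
    ------
    PSSMParseError
        On a truncated file, a row with other than 20 parseable score
        columns, or a non-numeric score; the message names the line number.
    """
    if isinstance(stream, (str, Path)) and "\n" not in str(stream):
        path = Path(stream)
        text = path.read_text()
        protein_id = protein_id or path.stem
    elif isinstance(stream, str):
        text = stream
    else:
        text = stream.read()

    # Line-ending independence (LF vs CRLF).
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")

    alphabet: tuple[str, ...] | None = None
    rows: list[list[float]] = []
    letters: list[str] = []
    in_block = False

    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if alphabet is None:
            tokens = stripped.split()
            if _looks_like_alphabet_header(tokens):
                alphabet = tuple(t.upper() for t in tokens[:N_AMINO_ACIDS])
                in_block = True
            continue
        if not in_block:
            continue
        if not stripped:
            # Blank line terminates the score block (footer follows).
            if rows:
                break
            continue
        m = _ROW_RE.match(line)
        if m is None:
            # Footer text (Lambda/K statistics) ends the block.
            if rows:
                break
            raise PSSMParseError(
                f"line {lineno}: expected a score row, got {stripped!r}"
            )
        _, residue, rest = m.groups()
        tokens = rest.split()
        if len(tokens) < N_AMINO_ACIDS:
            raise PSSMParseError(
                f"line {lineno}: expected at least {N_AMINO_ACIDS} score "
                f"columns, found {len(tokens)}"
            )
        values: list[float] = []
        for k, tok in enumerate(tokens[:N_AMINO_ACIDS]):
            try:
                values.append(float(tok))
            except ValueError:
                raise PSSMParseError(
                    f"line {lineno}: non-numeric score {tok!r} in column {k + 1}"
                ) from None
        rows.append(values)
        letters.append(residue.upper())

    if alphabet is None:
        raise PSSMParseError("no amino-acid column header found (truncated file?)")
    if not rows:
        raise PSSMParseError("no score rows found after the column header")

    record = ProteinRecord(protein_id=protein_id, sequence="".join(letters))
    return PSSM(
        protein_id=protein_id,
        scores=np.array(rows, dtype=float),
        column_alphabet=alphabet,
        record=record,
    )


def write_psiblast_pssm(pssm: PSSM, path=None) -> str:
    """Serialize a PSSM back to the 20-column ASCII dialect.

    Round-trips exactly through :func:`parse_psiblast_pssm` for integer
    scores (the format PSI-BLAST emits).
    """
    out = io.StringIO()
    out.write("Last position-specific scoring matrix computed\n\n")
    out.write("            " + "  ".join(pssm.column_alphabet) + "\n")
    seq = pssm.record.sequence if pssm.record and pssm.record.sequence else None
    for i, row in enumerate(pssm.scores):
        letter = seq[i] if seq else "X"
        cells = " ".join(f"{v:6g}" for v in row)
        out.write(f"{i + 1:5d} {letter}  {cells}\n")
    out.write("\n")
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def load_pssm_directory(directory) -> dict[str, PSSM]:
    """Parse every ``*.pssm`` (or any) file in *directory*; id = file stem."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"PSSM directory not found: {directory}")
    result: dict[str, PSSM] = {}
    for path in sorted(directory.iterdir()):
        if path.is_file():
            result[path.stem] = parse_psiblast_pssm(path)
    if not result:
        raise PSSMParseError(f"no PSSM files found in {directory}")
    return result


NORMALIZATION_METHODS = ("minmax", "sigmoid", "none")


def normalize_pssm(pssm: PSSM | np.ndarray, method: str = "minmax") -> np.ndarray:
    """Rescale raw PSSM scores prior to moment computation.

    ``minmax`` affinely maps the global [min, max] of the matrix onto [0, 1]
    (a constant matrix maps to all 0.5); ``sigmoid`` applies the entrywise
    logistic 1/(1+e^-x); ``none`` is the identity.  The default pipeline uses
    minmax so that moment magnitudes are comparable across proteins.
    """
    if method not in NORMALIZATION_METHODS:
        raise ConfigurationError(
            f"unknown normalization {method!r}; choose from {NORMALIZATION_METHODS}"
        )
    scores = pssm.scores if isinstance(pssm, PSSM) else np.asarray(pssm, dtype=float)
    if method == "none":
        return scores.copy()
    if method == "sigmoid":
        return 1.0 / (1.0 + np.exp(-scores))
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.full_like(scores, 0.5)
    return (scores - lo) / (hi - lo)


def pssm_to_tsv(pssm: PSSM) -> str:
    """TSV export: N rows x 20 columns, header = column alphabet."""
    lines = ["\t".join(pssm.column_alphabet)]
    for row in pssm.scores:
        lines.append("\t".join(f"{v:g}" for v in row))
    return "\n".join(lines) + "\n"
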