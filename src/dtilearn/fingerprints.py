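"""881-bit PubChem substructure fingerprints for drug molecules.

Each drug is a Boolean vector over the 881 substructure keys of the PubChem
fingerprint dictionary: bit k (zero-based) records presence of key k.
Computing the keys from chemical structures (SMARTS matching) is delegated
to external toolkits; this module represents, validates, reads and writes
precomputed fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

FINGERPRINT_LENGTH = 881

__all__ = [
    "FINGERPRINT_LENGTH",
    "SubstructureFingerprint",
    "encode_from_key_indices",
    "parse_fingerprint_table",
    "write_fingerprint_table",
]


class FingerprintParseError(ValueError):
    """Raised when a fingerprint table cannot be parsed."""


@dataclass
class SubstructureFingerprint:
    """Presence/absence vector over the 881 PubChem substructure keys."""

    drug_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8).ravel()
        if self.bits.size != FINGERPRINT_LENGTH:
            raise ValueError(
                f"fingerprint of {self.drug_id!r} has length {self.bits.size}; "
                f"expected {FINGERPRINT_LENGTH}"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError(f"fingerprint of {self.drug_id!r} has non-binary entries")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


def encode_from_key_indices(drug_id: str, present_keys: Iterable[int]) -> SubstructureFingerprint:
    """Build a fingerprint from the set of present substructure key indices.

    Keys are zero-based; valid range [0, 880].
    """
    bits = np.zeros(FINGERPRINT_LENGTH, dtype=np.int8)
    for k in present_keys:
        k = int(k)
        if k < 0 or k >= FINGERPRINT_LENGTH:
            raise ValueError(
                f"substructure key {k} out of range [0, {FINGERPRINT_LENGTH - 1}]"
            )
        bits[k] = 1
    return SubstructureFingerprint(drug_id=drug_id, bits=bits)


def _parse_bitstring(drug_id: str, s: str, row: int) -> SubstructureFingerprint:
    if len(s) != FINGERPRINT_LENGTH:
        raise FingerprintParseError(
            f"row {row}: bitstring of {drug_id!r} has length {len(s)}; "
            f"expected {FINGERPRINT_LENGTH}"
        )
    if set(s) - {"0", "1"}:
        raise FingerprintParseError(
            f"row {row}: bitstring of {drug_id!r} contains non-binary characters"
        )
    return SubstructureFingerprint(drug_id, np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))


def parse_fingerprint_table(stream) -> list[SubstructureFingerprint]:
    """Read fingerprints from a TSV bitstring table or a wide CSV.

    Two dialects are accepted:

    * TSV, no header: ``drug_id<TAB>881-character 0/1 string`` per row;
    * CSV with header: a ``drug_id`` column followed by 881 binary columns.

    Duplicate drug ids, wrong lengths and non-binary values raise
    :class:`FingerprintParseError` naming the offending row.
    """
    if isinstance(stream, (str, Path)) and "\n" not in str(stream):
        text = Path(stream).read_text()
    elif isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    lines = [ln for ln in text.replace("\r\n", "\n").split("\n") if ln.strip()]
    if not lines:
        raise FingerprintParseError("empty fingerprint table")

    fingerprints: list[SubstructureFingerprint] = []
    seen: set[str] = set()

    first_fields = lines[0].split(",")
    is_csv = len(first_fields) == FINGERPRINT_LENGTH + 1 and "\t" not in lines[0]
    if is_csv:
        # header row then one drug per row
        for row, line in enumerate(lines[1:], start=2):
            fields = line.split(",")
            if len(fields) != FINGERPRINT_LENGTH + 1:
                raise FingerprintParseError(
                    f"row {row}: expected {FINGERPRINT_LENGTH + 1} CSV fields, "
                    f"found {len(fields)}"
                )
            drug_id = fields[0].strip()
            if set("".join(fields[1:])) - {"0", "1"}:
                raise FingerprintParseError(f"row {row}: non-binary value for {drug_id!r}")
            fp = SubstructureFingerprint(drug_id, np.array(fields[1:], dtype=np.int8))
            if drug_id in seen:
                raise FingerprintParseError(f"row {row}: duplicate drug id {drug_id!r}")
            seen.add(drug_id)
            fingerprints.append(fp)
    else:
        for row, line in enumerate(lines, start=1):
            fields = line.split("\t")
            if len(fields) != 2:
                raise FingerprintParseError(
                    f"row {row}: expected 'drug_id<TAB>bitstring', found "
                    f"{len(fields)} fields"
                )
            drug_id = fields[0].strip()
            if drug_id in seen:
                raise FingerprintParseError(f"row {row}: duplicate drug id {drug_id!r}")
            seen.add(drug_id)
            fingerprints.append(_parse_bitstring(drug_id, fields[1].strip(), row))
    return fingerprints


def write_fingerprint_table(fingerprints: Sequence[SubstructureFingerprint], path=None) -> str:
    """Serialize to the canonical TSV bitstring dialect."""
    text = "".join(f"{fp.drug_id}\t{fp.to_bitstring()}\n" for fp in fingerprints)
    if path is not None:
        Path(path).write_text(text)
    return text
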