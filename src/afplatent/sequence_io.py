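"""Reading, validating and writing protein sequences in FASTA.

Every downstream stage (CKSAAP encoding, model training) assumes sequences
over the 20 standard one-letter amino-acid codes.  This module owns that
contract: parsing is permissive (uppercasing, line wrapping), validation is
explicit and happens once, with either a hard failure (``strict``) or
replacement of non-standard residues by a mask symbol that no residue pair
can ever match (``mask``).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, lexicographic order. This ordering fixes the
#: CKSAAP column layout, so it must never change.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Symbol substituted for non-standard residues under the ``mask`` policy.
#: Chosen outside the amino-acid alphabet so no k-spaced pair matches it.
MASK_SYMBOL = "?"

#: Residue codes seen in public databases that are not one of the 20
#: standard amino acids (ambiguity codes, rare residues, gaps, stops).
NONSTANDARD_RESIDUES = frozenset("BJOUXZ*-")

_STANDARD_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus an amino-acid sequence.

    The record as parsed is *not* yet guaranteed to respect the 20-letter
    alphabet; run it through :func:`validate_record` first.
    """

    id: str
    sequence: str

    @property
    def length(self) -> int:
        """Number of residues L."""
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")


def read_fasta(path: str | Path) -> List[ProteinRecord]:
    """Parse a (possibly line-wrapped) multi-record FASTA file.

    Sequences are uppercased and stripped of whitespace but not
    alphabet-validated.  Records are returned in file order.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If the file is empty, or sequence data precedes the first header.
    """
    path = Path(path)
    with open(path) as handle:
        text = handle.read()

    first = next((ln for ln in text.splitlines() if ln.strip()), None)
    if first is None:
        raise ValueError(f"{path}: empty FASTA file")
    if not first.lstrip().startswith(">"):
        raise ValueError(
            f"{path}: sequence data before any '>' header (orphan line: {first[:40]!r})"
        )

    records: List[ProteinRecord] = []
    import io

    for title, seq in SimpleFastaParser(io.StringIO(text)):
        rec_id = title.split()[0] if title.split() else title
        records.append(ProteinRecord(id=rec_id, sequence="".join(seq.split()).upper()))

    if not records:
        raise ValueError(f"{path}: no FASTA records found")

    dupes = [i for i, n in Counter(r.id for r in records).items() if n > 1]
    if dupes:
        logger.warning("duplicate FASTA ids (allowed, keyed by position): %s", dupes)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with *width*-column wrapped sequence lines."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def validate_record(rec: ProteinRecord, policy: str = "strict") -> ProteinRecord:
    """Enforce the 20-letter alphabet on one record.

    policy="strict"
        Return the record unchanged if every residue is standard, otherwise
        raise :class:`ValueError` naming the record and the first offending
        1-based position.
    policy="mask"
        Replace every non-standard residue with :data:`MASK_SYMBOL`.  Masked
        positions still count toward sequence length (and hence toward the
        CKSAAP pair-count denominators) but match no residue pair.

    Idempotent under both policies.
    """
    if policy not in ("strict", "mask"):
        raise ValueError(f"unknown validation policy {policy!r}")
    seq = rec.sequence
    if policy == "strict":
        for pos, ch in enumerate(seq, start=1):
            if ch not in _STANDARD_SET:
                raise ValueError(
                    f"record {rec.id!r}: non-standard residue {ch!r} at position {pos}"
                )
        return rec
    masked = "".join(ch if ch in _STANDARD_SET else MASK_SYMBOL for ch in seq)
    if masked != seq:
        n = sum(1 for a, b in zip(seq, masked) if a != b)
        logger.info("record %r: masked %d non-standard residue(s)", rec.id, n)
        return ProteinRecord(id=rec.id, sequence=masked)
    return rec


def validate_records(
    records: Iterable[ProteinRecord], policy: str = "strict"
) -> List[ProteinRecord]:
    """Validate a list of records under one policy (see :func:`validate_record`)."""
    return [validate_record(r, policy) for r in records]
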