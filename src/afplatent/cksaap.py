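"""Composition of k-spaced amino acid pairs (CKSAAP) descriptor.

For each gap j = 0..k a sequence of length L contains N_j = L - (j + 1)
ordered residue pairs (s[i], s[i + j + 1]).  Block j of the descriptor is the
400-vector of pair frequencies count(a, b) / N_j over the lexicographically
ordered pairs AA, AC, AD, ..., YY; the full descriptor concatenates blocks
j = 0..k, giving length 400 * (k + 1) (3600 at the default k = 8).

Masked residues (see :mod:`afplatent.sequence_io`) match no pair but still
occupy positions, so N_j is unchanged — the denominator stays faithful to the
sequence length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .sequence_io import AMINO_ACIDS, ProteinRecord

logger = logging.getLogger(__name__)

N_PAIRS = 400  # 20 x 20 ordered residue pairs per gap block


@dataclass(frozen=True)
class CKSAAPConfig:
    """Encoding configuration: maximum gap ``k`` and residue ordering."""

    k: int = 8
    alphabet: Tuple[str, ...] = AMINO_ACIDS

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be non-negative, got {self.k}")
        if len(self.alphabet) != 20 or len(set(self.alphabet)) != 20:
            raise ValueError("alphabet must contain exactly 20 distinct symbols")


def feature_length(k: int) -> int:
    """Descriptor length 400 * (k + 1); 3600 for the default k = 8."""
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    return N_PAIRS * (k + 1)


def pair_labels(k: int, alphabet: Sequence[str] = AMINO_ACIDS) -> List[str]:
    """Column labels ``"A.gap0.A", "A.gap0.C", ...`` for the full descriptor."""
    return [
        f"{a}.gap{j}.{b}"
        for j in range(k + 1)
        for a in alphabet
        for b in alphabet
    ]


def _ranks(seq: str, alphabet: Sequence[str]) -> np.ndarray:
    """Residue -> alphabet rank; unknown symbols (mask) map to -1."""
    lut = np.full(128, -1, dtype=np.int64)
    for i, aa in enumerate(alphabet):
        lut[ord(aa)] = i
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return lut[codes]


def count_jspaced_pairs(
    seq: str, j: int, alphabet: Sequence[str] = AMINO_ACIDS
) -> Tuple[np.ndarray, int]:
    """Count ordered residue pairs separated by gap ``j``.

    Returns the 400 integer counts (lexicographic pair order for the given
    alphabet) and the window count N_j = L - (j + 1).  Windows containing a
    masked residue contribute to N_j but to no pair count.
    """
    L = len(seq)
    n_j = L - (j + 1)
    if n_j < 1:
        raise ValueError(f"sequence of length {L} too short for gap {j} (needs L >= {j + 2})")
    r = _ranks(seq, alphabet)
    a, b = r[: L - j - 1], r[j + 1 :]
    valid = (a >= 0) & (b >= 0)
    counts = np.bincount(20 * a[valid] + b[valid], minlength=N_PAIRS).astype(np.int64)
    return counts, n_j


def encode_sequence(
    rec: ProteinRecord, cfg: CKSAAPConfig = CKSAAPConfig(), pad_policy: str = "error"
) -> np.ndarray:
    """CKSAAP descriptor of one record: concatenated frequency blocks F_0..F_k.

    Each block sums to 1 (counts divided by N_j), so the full vector sums to
    k + 1.  Sequences shorter than k + 2 residues leave some N_j <= 0; by
    default that is an error, with ``pad_policy="zero"`` the unsatisfiable
    blocks are emitted as zeros (logged).
    """
    if pad_policy not in ("error", "zero"):
        raise ValueError(f"unknown pad_policy {pad_policy!r}")
    L = rec.length
    if L < cfg.k + 2 and pad_policy == "error":
        raise ValueError(
            f"record {rec.id!r}: length {L} < k + 2 = {cfg.k + 2}; "
            "use pad_policy='zero' to emit zero blocks for unsatisfiable gaps"
        )
    out = np.zeros(feature_length(cfg.k), dtype=np.float64)
    for j in range(cfg.k + 1):
        if L - (j + 1) < 1:
            logger.info("record %r: zero block for gap %d (L=%d)", rec.id, j, L)
            continue
        counts, n_j = count_jspaced_pairs(rec.sequence, j, cfg.alphabet)
        out[j * N_PAIRS : (j + 1) * N_PAIRS] = counts / n_j
    return out


def encode_dataset(
    records: Iterable[ProteinRecord],
    cfg: CKSAAPConfig = CKSAAPConfig(),
    on_error: str = "raise",
) -> Tuple[np.ndarray, List[str]]:
    """Encode records into a (n_records, 400*(k+1)) matrix plus row ids.

    Row order matches input order.  ``on_error="skip"`` drops (and logs)
    records that fail to encode instead of raising.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError(f"unknown on_error {on_error!r}")
    rows, ids = [], []
    for rec in records:
        try:
            rows.append(encode_sequence(rec, cfg))
        except ValueError as exc:
            if on_error == "raise":
                raise
            logger.warning("skipping record %r: %s", rec.id, exc)
            continue
        ids.append(rec.id)
    if rows:
        return np.vstack(rows), ids
    return np.empty((0, feature_length(cfg.k))), ids


def write_features(
    X: np.ndarray, ids: Sequence[str], path: str | Path, k: int
) -> None:
    """Write a feature matrix as TSV with pair-label header and id index."""
    pd.DataFrame(X, index=list(ids), columns=pair_labels(k)).to_csv(path, sep="\t")


def read_features(path: str | Path) -> Tuple[np.ndarray, List[str]]:
    """Read a feature matrix written by :func:`write_features`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=np.float64), [str(i) for i in df.index]
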