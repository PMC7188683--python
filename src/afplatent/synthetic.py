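"""Synthetic labeled protein sequences with planted k-spaced pair enrichment.

Real antifreeze-protein benchmarks cannot be bundled, so this module builds
datasets in which the positive class is distinguishable by construction:
negatives are i.i.d. residues from a background distribution; positives are
drawn from the same background and then have a controlled number of
(residue a, residue b, gap j) motif pairs written over random positions.
Planting overwrites rather than inserts, so the length distribution is
identical across classes and cannot act as a confounder.  The planted
columns of the CKSAAP descriptor then carry the class signal, letting the
whole encode -> train -> evaluate chain be exercised end to end.

Not a biological simulator: no real ice-binding motifs, no homology
structure, no compositional bias unless a background distribution is given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .sequence_io import AMINO_ACIDS, ProteinRecord

#: Default planted motif: a single ordered residue pair, so the whole
#: enrichment budget concentrates on one descriptor column (the cleanest
#: planted-signal condition).  The gap is kept small enough that the default
#: enrichment of 10 plantings fits the shortest default sequence
#: (enrichment x (gap + 2) <= L_min = 50).
DEFAULT_MOTIF_PAIRS: Tuple[Tuple[str, str, int], ...] = (("A", "C", 3),)

#: Approximate residue frequencies of naturally occurring proteins
#: (UniProt-scale averages), selectable instead of the uniform background.
NATURAL_FREQUENCIES = {
    "A": 0.0826, "C": 0.0136, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0472, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings for one synthetic two-class dataset.

    ``enrichment`` is the number of motif plantings per positive sequence
    (each planting picks one motif pair uniformly at random and overwrites
    two positions at its stated gap).
    """

    n_pos: int = 300
    n_neg: int = 300
    length_range: Tuple[int, int] = (50, 300)
    motif_pairs: Tuple[Tuple[str, str, int], ...] = DEFAULT_MOTIF_PAIRS
    enrichment: int = 10
    background: Optional[Sequence[float]] = None  # default uniform over 20
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be non-negative")
        if self.enrichment < 0:
            raise ValueError("enrichment must be non-negative")
        for a, b, j in self.motif_pairs:
            if a not in AMINO_ACIDS or b not in AMINO_ACIDS:
                raise ValueError(f"motif pair ({a},{b}) outside the 20-letter alphabet")
            if j < 0:
                raise ValueError("motif gap must be non-negative")
            if j > lo - 2:
                raise ValueError(
                    f"motif gap {j} cannot fit in the shortest sequence (L_min={lo})"
                )
        if self.motif_pairs and self.enrichment:
            max_gap = max(j for _, _, j in self.motif_pairs)
            if self.enrichment * (max_gap + 2) > lo:
                raise ValueError(
                    f"planting density impossible: enrichment {self.enrichment} x "
                    f"(max gap + 2) = {self.enrichment * (max_gap + 2)} > L_min {lo}"
                )
        if self.background is not None and len(self.background) != 20:
            raise ValueError("background must give 20 residue probabilities")


def generate_dataset(spec: SyntheticSpec) -> Tuple[List[ProteinRecord], np.ndarray]:
    """Generate shuffled records and binary labels (1 = positive class).

    Byte-identical for the same spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    probs = None
    if spec.background is not None:
        probs = np.asarray(spec.background, dtype=float)
        probs = probs / probs.sum()
    lo, hi = spec.length_range
    aa = np.array(list(AMINO_ACIDS))

    records: List[ProteinRecord] = []
    labels: List[int] = []
    for cls, count in ((1, spec.n_pos), (0, spec.n_neg)):
        for i in range(count):
            L = int(rng.integers(lo, hi + 1))
            seq = rng.choice(aa, size=L, p=probs)
            if cls == 1 and spec.enrichment and spec.motif_pairs:
                for _ in range(spec.enrichment):
                    a, b, j = spec.motif_pairs[rng.integers(len(spec.motif_pairs))]
                    pos = int(rng.integers(0, L - j - 1))
                    seq[pos] = a
                    seq[pos + j + 1] = b
            prefix = "pos" if cls == 1 else "neg"
            records.append(ProteinRecord(id=f"{prefix}{i:05d}", sequence="".join(seq)))
            labels.append(cls)

    order = rng.permutation(len(records))
    return [records[i] for i in order], np.asarray(labels)[order]


def parse_ratio(ratio: "str | int") -> int:
    """Accept ``"1:3"`` or the bare negative multiplier 3."""
    if isinstance(ratio, int):
        r = ratio
    else:
        parts = str(ratio).split(":")
        if len(parts) != 2 or parts[0].strip() != "1":
            raise ValueError(f"ratio must look like '1:r', got {ratio!r}")
        r = int(parts[1])
    if r < 1:
        raise ValueError(f"negative-class multiplier must be >= 1, got {r}")
    return r


def ratio_split(
    labels: np.ndarray,
    ratio: "str | int",
    n_pos_train: int,
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Index partition with a 1:r class ratio in the training set.

    The training set holds ``n_pos_train`` positives and ``r * n_pos_train``
    negatives sampled without replacement; every remaining sample forms the
    test set.  Returns (train_indices, test_indices), disjoint and jointly
    exhaustive.
    """
    labels = np.asarray(labels)
    r = parse_ratio(ratio)
    n_neg_train = r * n_pos_train
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if len(pos_idx) < n_pos_train:
        raise ValueError(
            f"need {n_pos_train} positives for training, have {len(pos_idx)}"
        )
    if len(neg_idx) < n_neg_train:
        raise ValueError(
            f"need {n_neg_train} negatives for training at ratio 1:{r}, "
            f"have {len(neg_idx)}"
        )
    rng = np.random.default_rng(seed)
    train_pos = rng.choice(pos_idx, size=n_pos_train, replace=False)
    train_neg = rng.choice(neg_idx, size=n_neg_train, replace=False)
    train = np.sort(np.concatenate([train_pos, train_neg]))
    mask = np.ones(len(labels), dtype=bool)
    mask[train] = False
    return train, np.flatnonzero(mask)


def write_labels(records: Sequence[ProteinRecord], labels: np.ndarray, path) -> None:
    """Two-column TSV: record id, label (1 = positive/AFP-like)."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for rec, lab in zip(records, labels):
            fh.write(f"{rec.id}\t{int(lab)}\n")


def read_labels(path) -> Tuple[List[str], np.ndarray]:
    """Read a label table written by :func:`write_labels`."""
    ids: List[str] = []
    labs: List[int] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty label file")
        for line in fh:
            if not line.strip():
                continue
            rec_id, lab = line.rstrip("\n").split("\t")
            ids.append(rec_id)
            labs.append(int(lab))
    return ids, np.asarray(labs)
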