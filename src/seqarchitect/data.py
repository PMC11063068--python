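"""Streaming of class-labelled genomic subsequences from FASTA collections.

Training and validation samples are drawn by picking random FASTA files per
class, choosing a fresh random start offset on every file visit, and
emitting disjoint consecutive windows of length L from that offset; every
training batch contains the same number of samples from each class, which
oversamples minority classes.  Test samples are deterministic: files in
listed order, windows from position 0, trailing fragments discarded.

Nucleotides are one-hot encoded over (A, C, G, T); ambiguous IUPAC codes
become all-zero columns so they contribute nothing to convolutions while
preserving sequence length.  Windows never span record boundaries.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml
from Bio import SeqIO

from .errors import FastaParseError, InvalidInputError, SequenceTooShortError

BASES = "ACGT"
_LUT = np.zeros((256, 4))
for _i, _b in enumerate(BASES):
    _LUT[ord(_b), _i] = 1.0
    _LUT[ord(_b.lower()), _i] = 1.0

_COMPLEMENT = str.maketrans("ACGTacgtRYSWKMBDHVNryswkmbdhvn",
                            "TGCAtgcaYRSWMKVHDBNyrswmkvhdbn")


@dataclass
class ClassDataset:
    """One class's FASTA files for one role (train/validation/test)."""

    class_name: str
    files: list
    role: str = "train"

    def __post_init__(self):
        if not self.files:
            raise InvalidInputError(f"class {self.class_name!r}: empty file list")
        for f in self.files:
            if not Path(f).exists():
                raise InvalidInputError(f"class {self.class_name!r}: missing file {f}")


@dataclass
class SequenceBatch:
    one_hot: np.ndarray  # (batch, L, 4)
    labels: np.ndarray  # (batch,) class indices
    per_class_counts: np.ndarray


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> list:
    """Parse a (possibly gzipped) FASTA file into (header, sequence) records."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected a '>' header, got {line.strip()[:40]!r}"
                )
            break
        else:
            raise FastaParseError(f"{path}: line 1: empty FASTA file")
    with _open_text(path) as fh:
        records = [(rec.description, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise FastaParseError(f"{path}: line 1: no records found")
    return records


def one_hot(sequence: str, L: int) -> np.ndarray:
    """Encode the first L bases as an (L, 4) block over (A, C, G, T)."""
    if len(sequence) < L:
        raise SequenceTooShortError(
            f"sequence of length {len(sequence)} is shorter than window L={L}"
        )
    codes = np.frombuffer(sequence[:L].encode("ascii"), dtype=np.uint8)
    return _LUT[codes]


def reverse_complement(seq):
    """Other-strand view of a sequence string or one-hot block.

    For one-hot arrays ((L, 4) or (B, L, 4)) positions are reversed and
    channels swapped A↔T, C↔G; this commutes with :func:`one_hot`.
    """
    if isinstance(seq, str):
        return seq.translate(_COMPLEMENT)[::-1]
    arr = np.asarray(seq)
    if arr.ndim == 2:
        return arr[::-1, ::-1]
    if arr.ndim == 3:
        return arr[:, ::-1, ::-1]
    raise InvalidInputError("expected a string or an (L,4)/(B,L,4) one-hot array")


class _ClassWindowStream:
    """Endless window stream for one class: random file, random offset, then
    consecutive disjoint windows until the record set is exhausted."""

    def __init__(self, dataset: ClassDataset, L: int, rng: np.random.Generator):
        self.dataset = dataset
        self.L = L
        self.rng = rng
        self._pending: list = []

    def _refill(self):
        while not self._pending:
            path = self.dataset.files[int(self.rng.integers(0, len(self.dataset.files)))]
            for _header, seq in read_fasta(path):
                if len(seq) < self.L:
                    continue
                offset = int(self.rng.integers(0, self.L))
                for start in range(offset, len(seq) - self.L + 1, self.L):
                    self._pending.append(seq[start : start + self.L])

    def take(self, n: int) -> list:
        out = []
        while len(out) < n:
            if not self._pending:
                self._refill()
            out.append(self._pending.pop(0))
        return out


class BatchSampler:
    """Reproducible class-balanced training batch stream."""

    def __init__(self, datasets: Sequence[ClassDataset], L: int, batch_size: int, rng=None):
        if batch_size % len(datasets) != 0:
            raise InvalidInputError(
                f"batch_size {batch_size} is not divisible by the class count {len(datasets)}"
            )
        self.datasets = list(datasets)
        self.L = L
        self.batch_size = batch_size
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.streams = [_ClassWindowStream(d, L, gen) for d in self.datasets]

    def next_batch(self) -> SequenceBatch:
        per_class = self.batch_size // len(self.datasets)
        blocks, labels = [], []
        for ci, stream in enumerate(self.streams):
            for seq in stream.take(per_class):
                blocks.append(one_hot(seq, self.L))
                labels.append(ci)
        counts = np.full(len(self.datasets), per_class)
        return SequenceBatch(
            one_hot=np.stack(blocks), labels=np.asarray(labels), per_class_counts=counts
        )

    def __iter__(self) -> Iterator[SequenceBatch]:
        while True:
            yield self.next_batch()


def sample_training_batch(
    datasets: Sequence[ClassDataset], L: int, batch_size: int, rng=None
) -> SequenceBatch:
    """Draw one class-balanced batch (fresh file/offset state)."""
    return BatchSampler(datasets, L, batch_size, rng).next_batch()


def iterate_test_samples(datasets: Sequence[ClassDataset], L: int):
    """Deterministic exhaustive stream of (class_index, one_hot_window).

    Files in listed order; windows start at position 0; the trailing
    fragment shorter than L of each record is discarded.
    """
    for ci, dataset in enumerate(datasets):
        for path in dataset.files:
            for _header, seq in read_fasta(path):
                for start in range(0, len(seq) - L + 1, L):
                    yield ci, one_hot(seq[start : start + L], L)


def class_balanced_accuracy(confusion) -> float:
    """Mean per-class recall of a (true × predicted) count matrix."""
    conf = np.asarray(confusion, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise InvalidInputError("confusion matrix must be square")
    row_sums = conf.sum(axis=1)
    if np.any(row_sums == 0):
        raise InvalidInputError("every true class needs at least one sample")
    return float(np.mean(np.diag(conf) / row_sums))


# ---------------------------------------------------------------------------
# Dataset manifests


def save_manifest(path, classes: dict) -> None:
    """Write a dataset manifest: class → role → file list.

    File paths are stored relative to the manifest's directory where
    possible, so the whole dataset directory can be moved as a unit.
    """
    base = Path(path).resolve().parent

    def _rel(f):
        p = Path(f).resolve()
        try:
            return str(p.relative_to(base))
        except ValueError:
            return str(p)

    doc = {
        cls: {role: [_rel(f) for f in files] for role, files in roles.items()}
        for cls, roles in classes.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_manifest(path) -> dict:
    """Read a manifest into role → list[ClassDataset] (classes sorted)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = Path(path).parent

    def _resolve(f):
        p = Path(f)
        if p.is_absolute() or p.exists():
            return str(p)
        return str(base / f)

    out: dict = {}
    for cls in sorted(doc):
        for role, files in doc[cls].items():
            out.setdefault(role, []).append(
                ClassDataset(class_name=cls, files=[_resolve(f) for f in files], role=role)
            )
    return out
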