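"""Synthetic multi-class genome collections with planted, class-discriminative motifs.

Each class is defined by a :class:`MotifSpec`: genomes are i.i.d. background
sequence (given base composition) into which the class's k-mer motifs are
written at Poisson-distributed positions at a chosen density.  Insertion
overwrites the background (genome length stays exact) and overlapping
instances resolve last-writer-wins.  These collections emulate the one
property the architecture search needs from real genome data — a planted,
learnable class signal at controllable strength — and none of its other
structure (no repeats, GC skew, phylogeny, or read errors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import ClassDataset, save_manifest
from .errors import InvalidInputError

BASES = "ACGT"

# Density chosen so that, at the default 20 insertions per kb, over 95% of
# 150-nt windows contain at least one full motif: the read-level task is
# learnable by construction.
DEFAULT_DENSITY = 20.0

# Disjoint 8-mer motif sets, two per class.
DEFAULT_CLASS_MOTIFS = {
    "alpha": ["ACGTACGG", "TTGACCAA"],
    "beta": ["GGCCTTAA", "CACAGTGT"],
    "gamma": ["TCGATCGA", "AATTGGCC"],
}


@dataclass(frozen=True)
class MotifSpec:
    """Planted-signal description of one synthetic class."""

    class_name: str
    motifs: tuple
    density: float = DEFAULT_DENSITY  # expected insertions per 1000 nt
    background: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.density < 0:
            raise InvalidInputError("density must be >= 0")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise InvalidInputError("background composition must sum to 1")
        for m in self.motifs:
            if not m or any(b not in BASES for b in m):
                raise InvalidInputError(f"motif {m!r} must be a non-empty A/C/G/T string")


def _write_fasta(path: Path, header: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{header}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def generate_genomes(
    specs,
    files_per_class: int,
    genome_length: int,
    rng=None,
    out_dir=".",
) -> dict:
    """Write per-class FASTA files; returns class name → list of paths.

    Deterministic under a fixed seed (byte-identical output).
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    longest = max((len(m) for spec in specs for m in spec.motifs), default=1)
    if genome_length < 10 * longest:
        raise InvalidInputError(
            f"genome_length {genome_length} must be at least 10x the longest motif ({longest})"
        )
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    out: dict = {}
    for spec in specs:
        cls_dir = out_dir / spec.class_name
        cls_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for fi in range(files_per_class):
            codes = gen.choice(base_arr, size=genome_length, p=np.asarray(spec.background))
            seq = bytearray(codes.tobytes())
            if spec.motifs and spec.density > 0:
                n_ins = int(gen.poisson(spec.density * genome_length / 1000.0))
                for _ in range(n_ins):
                    motif = spec.motifs[int(gen.integers(0, len(spec.motifs)))]
                    pos = int(gen.integers(0, genome_length - len(motif) + 1))
                    seq[pos : pos + len(motif)] = motif.encode()
            path = cls_dir / f"{spec.class_name}_{fi:03d}.fasta"
            _write_fasta(path, f"{spec.class_name}_{fi:03d} synthetic", seq.decode())
            paths.append(str(path))
        out[spec.class_name] = paths
    return out


def make_split(files, fractions=(0.7, 0.2, 0.1)) -> tuple:
    """File-level partition into (train, validation, test) lists.

    Counts are floor(fraction × n) with the remainder distributed to the
    parts with the largest fractional remainders (ties to the later part,
    so test data is never starved).  Parts with a zero fraction stay empty.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidInputError("fractions must sum to 1")
    n = len(files)
    parts = sum(1 for f in fractions if f > 0)
    if n < parts:
        raise InvalidInputError(f"{n} files cannot cover {parts} non-empty split parts")
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainders = [r - c for r, c in zip(raw, counts)]
    for _ in range(n - sum(counts)):
        i = max(range(len(fractions)), key=lambda j: (remainders[j], j))
        counts[i] += 1
        remainders[i] = -1.0
    # guarantee every non-empty part gets at least one file
    for i, f in enumerate(fractions):
        if f > 0 and counts[i] == 0:
            donor = max(range(len(counts)), key=lambda j: counts[j])
            counts[donor] -= 1
            counts[i] += 1
    splits, pos = [], 0
    for c in counts:
        splits.append(list(files[pos : pos + c]))
        pos += c
    return tuple(splits)


PROFILES = {
    # profile: (files_per_class, genome_length)
    "tiny": (6, 5_000),
    "small": (30, 50_000),
}


@dataclass
class FixtureBundle:
    """Generated collection plus its role → datasets mapping."""

    manifest_path: str
    datasets: dict  # role -> list[ClassDataset]
    class_names: list


def fixture_suite(profile: str = "tiny", out_dir=".", seed: int = 13) -> FixtureBundle:
    """Generate a ready-to-use 3-class planted-motif collection.

    tiny: 3 classes × 6 files × 5 kb (generates in seconds); small:
    3 classes × 30 files × 50 kb.  Files are split 70/20/10 per class and
    described by a manifest YAML next to the FASTA directories.
    """
    if profile not in PROFILES:
        raise InvalidInputError(f"unknown profile {profile!r}; choose from {list(PROFILES)}")
    files_per_class, genome_length = PROFILES[profile]
    rng = np.random.default_rng(seed)
    specs = [
        MotifSpec(class_name=name, motifs=tuple(motifs))
        for name, motifs in DEFAULT_CLASS_MOTIFS.items()
    ]
    by_class = generate_genomes(specs, files_per_class, genome_length, rng, out_dir)
    manifest: dict = {}
    datasets: dict = {}
    for spec in specs:
        train, val, test = make_split(by_class[spec.class_name])
        manifest[spec.class_name] = {"train": train, "validation": val, "test": test}
        for role, files in (("train", train), ("validation", val), ("test", test)):
            datasets.setdefault(role, []).append(
                ClassDataset(class_name=spec.class_name, files=files, role=role)
            )
    manifest_path = str(Path(out_dir) / "manifest.yaml")
    save_manifest(manifest_path, manifest)
    return FixtureBundle(
        manifest_path=manifest_path,
        datasets=datasets,
        class_names=[s.class_name for s in specs],
    )
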