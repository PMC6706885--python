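"""Core data model: circular genomes and stranded gene annotations.

All internal coordinates are 0-based half-open on the forward strand.
Origin-spanning features on a circular genome are stored with ``end >
genome.length`` so that interval arithmetic stays linear; they can be
normalized to two segments on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "PCG_GENES",
    "TRNA_GENES",
    "RRNA_GENES",
    "NONCODING_LABELS",
    "KNOWN_GENES",
    "Genome",
    "GeneAnnotation",
    "AnnotatedGenome",
    "revcomp",
]

PCG_GENES = (
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "cox1", "cox2", "cox3", "atp6", "atp8", "cob",
)
TRNA_GENES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)
RRNA_GENES = ("rrnL", "rrnS")
NONCODING_LABELS = ("CR", "CR2")
KNOWN_GENES = frozenset(PCG_GENES + TRNA_GENES + RRNA_GENES + NONCODING_LABELS)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """A (possibly circular) DNA molecule."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps modulo length when circular."""
        if end < start:
            raise ValueError(f"fetch: end {end} < start {start}")
        n = self.length
        if 0 <= start and end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError(
                f"fetch [{start}, {end}) outside linear genome of length {n}"
            )
        return "".join(self.sequence[i % n] for i in range(start, end))

    def rotated(self, offset: int) -> "Genome":
        """Genome with the origin moved to position ``offset``."""
        n = self.length
        offset %= n
        return Genome(self.id, self.sequence[offset:] + self.sequence[:offset], self.circular)


@dataclass(frozen=True, order=True)
class GeneAnnotation:
    """A named, stranded interval on the forward strand.

    ``end`` may exceed the genome length to represent a feature spanning
    the circular origin.
    """

    start: int
    end: int
    gene: str = field(compare=False)
    strand: str = field(default="+", compare=False)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene}: end must exceed start ({self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length

    def segments(self, genome_length: int) -> list[tuple[int, int]]:
        """Forward-strand segments, splitting at the origin when wrapping."""
        if not self.wraps(genome_length):
            return [(self.start, self.end)]
        return [(self.start, genome_length), (0, self.end - genome_length)]

    def rotated(self, offset: int, genome_length: int) -> "GeneAnnotation":
        start = (self.start - offset) % genome_length
        return replace(self, start=start, end=start + self.length)


class AnnotatedGenome:
    """A genome plus its ordered feature list."""

    def __init__(self, genome: Genome, features: list[GeneAnnotation]):
        seen: set[str] = set()
        for f in features:
            if f.start < 0 or f.start >= genome.length:
                raise ValueError(f"{f.gene}: start {f.start} outside [0, {genome.length})")
            if f.gene in seen and f.gene not in NONCODING_LABELS:
                raise ValueError(f"duplicate gene label {f.gene!r}")
            seen.add(f.gene)
        self.genome = genome
        self.features = sorted(features)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedGenome):
            return NotImplemented
        return (
            self.genome == other.genome
            and [(f.gene, f.strand, f.start, f.end) for f in self.features]
            == [(f.gene, f.strand, f.start, f.end) for f in other.features]
        )

    def __repr__(self) -> str:
        return f"AnnotatedGenome({self.genome.id!r}, {len(self.features)} features)"

    def get(self, gene: str) -> GeneAnnotation | None:
        for f in self.features:
            if f.gene == gene:
                return f
        return None

    def feature_sequence(self, feat: GeneAnnotation) -> str:
        """Gene-local (sense strand) sequence of a feature."""
        seq = self.genome.fetch(feat.start, feat.end)
        return revcomp(seq) if feat.strand == "-" else seq

    def select(self, genes) -> list[GeneAnnotation]:
        genes = set(genes)
        return [f for f in self.features if f.gene in genes]

    @property
    def pcgs(self) -> list[GeneAnnotation]:
        return self.select(PCG_GENES)

    @property
    def trnas(self) -> list[GeneAnnotation]:
        return self.select(TRNA_GENES)

    @property
    def rrnas(self) -> list[GeneAnnotation]:
        return self.select(RRNA_GENES)

    def rotated(self, offset: int) -> "AnnotatedGenome":
        n = self.genome.length
        return AnnotatedGenome(
            self.genome.rotated(offset),
            [f.rotated(offset, n) for f in self.features],
        )
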