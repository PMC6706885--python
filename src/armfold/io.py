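"""Read/write annotated mitogenomes (GenBank, FASTA, TSV feature tables).

GenBank I/O converts between 1-based inclusive coordinates at the file
boundary and the 0-based half-open convention used internally. Features
spanning the circular origin are stored with ``end > length``.
"""

from __future__ import annotations

import re
import warnings
from importlib import resources
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import (
    KNOWN_GENES,
    PCG_GENES,
    RRNA_GENES,
    TRNA_GENES,
    AnnotatedGenome,
    GeneAnnotation,
    Genome,
)

__all__ = [
    "normalize_gene_name",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "write_feature_table",
    "read_feature_table",
]


def _load_synonyms() -> tuple[dict, dict]:
    text = resources.files("armfold.data").joinpath("gene_synonyms.yaml").read_text()
    cfg = yaml.safe_load(text)
    return cfg["synonyms"], cfg["codon_qualified"]


_SYNONYMS, _CODON_QUALIFIED = _load_synonyms()
_QUALIFIER_RE = re.compile(r"\(([a-z]{3})\)")

_AA3 = {
    "ala": "a", "arg": "r", "asn": "n", "asp": "d", "cys": "c", "gln": "q",
    "glu": "e", "gly": "g", "his": "h", "ile": "i", "lys": "k", "met": "m",
    "phe": "f", "pro": "p", "thr": "t", "trp": "w", "tyr": "y", "val": "v",
    # Leu/Ser are ambiguous without a codon qualifier and stay three-letter
}


def normalize_gene_name(name: str) -> str:
    """Map a raw gene/product label to the controlled vocabulary.

    Unknown names are returned verbatim with a warning; they never abort
    a run.
    """
    key = name.strip().lower().replace(" ", "").replace("_", "").replace("-", "")
    key = key.removeprefix("trna").removeprefix("trn")
    m = re.fullmatch(r"([a-z]{3})(\([a-z]{3}\))?", key)
    if m and m.group(1) in _AA3:
        key = _AA3[m.group(1)] + (m.group(2) or "")
    elif m and m.group(1) in ("leu", "ser"):
        codon = (m.group(2) or "").strip("()")
        if codon:
            key = ("l" if m.group(1) == "leu" else "s") + f"({codon})"
    key = ("trn" + key) if len(key) <= 6 and re.fullmatch(r"[a-z](\d|\([a-z]{3}\))?", key) else key
    raw = name.strip().lower().replace(" ", "").replace("_", "")
    for table_key in (raw, key):
        if table_key in _CODON_QUALIFIED:
            return _CODON_QUALIFIED[table_key]
    key = _QUALIFIER_RE.sub("", key)
    raw = _QUALIFIER_RE.sub("", raw)
    for table_key in (raw, key):
        if table_key in _SYNONYMS:
            return _SYNONYMS[table_key]
    if name in KNOWN_GENES:
        return name
    warnings.warn(f"unknown gene name {name!r} retained verbatim", stacklevel=2)
    return name


def _feature_name(feat: SeqFeature) -> str | None:
    for qualifier in ("gene", "product", "note", "standard_name"):
        if qualifier in feat.qualifiers:
            return str(feat.qualifiers[qualifier][0])
    return None


_FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "misc_feature", "D-loop", "gene"}


def read_genbank(path) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`."""
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc
    circular = record.annotations.get("topology", "circular") == "circular"
    genome = Genome(record.id or record.name, str(record.seq), circular=circular)
    n = genome.length
    features: list[GeneAnnotation] = []
    seen: set[tuple] = set()
    for feat in record.features:
        if feat.type not in _FEATURE_TYPES or feat.type == "gene":
            continue
        name = _feature_name(feat)
        if name is None:
            continue
        gene = normalize_gene_name(name)
        loc = feat.location
        strand = "-" if loc.strand == -1 else "+"
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == n:
            # join() across the circular origin
            start, end = int(parts[1].start), n + int(parts[0].end)
        else:
            start, end = int(loc.start), int(loc.end)
        key = (gene, strand, start, end)
        if key in seen:
            continue
        seen.add(key)
        features.append(GeneAnnotation(start=start, end=end, gene=gene, strand=strand))
    return AnnotatedGenome(genome, features)


_GB_TYPES = dict(
    [(g, "CDS") for g in PCG_GENES]
    + [(g, "tRNA") for g in TRNA_GENES]
    + [(g, "rRNA") for g in RRNA_GENES]
)


def write_genbank(ag: AnnotatedGenome, path) -> None:
    """Write an AnnotatedGenome as a GenBank flat file."""
    record = SeqRecord(
        Seq(ag.genome.sequence),
        id=ag.genome.id,
        name=ag.genome.id[:16],
        description="annotated mitogenome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if ag.genome.circular else "linear",
        },
    )
    n = ag.genome.length
    for f in ag.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps(n):
            (s1, e1), (s2, e2) = f.segments(n)
            loc = CompoundLocation(
                [SimpleLocation(s1, e1, strand), SimpleLocation(s2, e2, strand)]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        ftype = _GB_TYPES.get(f.gene, "misc_feature")
        record.features.append(SeqFeature(loc, type=ftype, qualifiers={"gene": [f.gene]}))
    SeqIO.write([record], str(path), "genbank")


def read_fasta(path, circular: bool = True) -> Genome:
    record = SeqIO.read(str(path), "fasta")
    return Genome(record.id, str(record.seq), circular=circular)


def write_fasta(genome: Genome, path) -> None:
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")], str(path), "fasta")


def _coords_text(f: GeneAnnotation, n: int) -> str:
    """1-based inclusive coordinate text; two segments when origin-spanning."""
    if not f.wraps(n):
        return f"{f.start + 1}..{f.end}"
    (s1, e1), (s2, e2) = f.segments(n)
    return f"join({s1 + 1}..{e1},{s2 + 1}..{e2})"


def write_feature_table(ag: AnnotatedGenome, path) -> None:
    """Tab-separated feature table (gene, strand, coords, length)."""
    n = ag.genome.length
    lines = ["#gene\tstrand\tcoords\tlength"]
    for f in sorted(ag.features, key=lambda f: (f.start, f.gene)):
        lines.append(f"{f.gene}\t{f.strand}\t{_coords_text(f, n)}\t{f.length}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_table(path, genome: Genome) -> AnnotatedGenome:
    features = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        gene, strand, coords, _length = line.split("\t")
        if coords.startswith("join("):
            seg1, _seg2 = coords[5:-1].split(",")
            a, b = seg1.split("..")
            start = int(a) - 1
            end = start + int(_length)
        else:
            a, b = coords.split("..")
            start, end = int(a) - 1, int(b)
        features.append(GeneAnnotation(start=start, end=end, gene=gene, strand=strand))
    return AnnotatedGenome(genome, features)
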