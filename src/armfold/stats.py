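"""Compositional and codon-level descriptive statistics for mitogenomes.

A+T content and strand skews per partition, start/stop codon tallies
(including the single-"T" and "TA" truncated stops completed by
polyadenylation), overlap/spacer maps on the circular gene order, and
amino-acid frequencies / RSCU under the invertebrate mitochondrial code
(translation table 5).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Data import CodonTable

from .model import (
    PCG_GENES,
    RRNA_GENES,
    TRNA_GENES,
    AnnotatedGenome,
    GeneAnnotation,
    revcomp,
)

__all__ = [
    "SkewResult",
    "CodonTally",
    "OverlapMap",
    "at_content",
    "skews",
    "partitioned_composition",
    "tally_start_stop",
    "read_codon_table",
    "overlaps_and_spacers",
    "aa_frequencies_and_rscu",
]

MITO_TABLE = CodonTable.unambiguous_dna_by_id[5]


@dataclass(frozen=True)
class SkewResult:
    """(A-T)/(A+T) and (G-C)/(G+C); NaN marks an undefined skew (zero
    denominator), never 0 — a zero skew is meaningful."""

    at_skew: float
    gc_skew: float

    @property
    def at_defined(self) -> bool:
        return not math.isnan(self.at_skew)

    @property
    def gc_defined(self) -> bool:
        return not math.isnan(self.gc_skew)


def at_content(seq: str) -> float:
    """(#A+#T)/(#A+#C+#G+#T); N excluded; NaN when no unambiguous base."""
    c = Counter(seq.upper())
    denom = c["A"] + c["C"] + c["G"] + c["T"]
    if denom == 0:
        return float("nan")
    return (c["A"] + c["T"]) / denom


def skews(seq: str) -> SkewResult:
    c = Counter(seq.upper())
    at = (c["A"] - c["T"]) / (c["A"] + c["T"]) if c["A"] + c["T"] else float("nan")
    gc = (c["G"] - c["C"]) / (c["G"] + c["C"]) if c["G"] + c["C"] else float("nan")
    return SkewResult(at, gc)


def _codon_position_bases(seq: str, position: int) -> str:
    """Bases at codon position 1, 2 or 3 walking the reading frame."""
    return seq[position - 1 :: 3]


def _row(partition: str, seq: str) -> dict:
    sk = skews(seq)
    return {
        "partition": partition,
        "n_bases": len(seq),
        "at_content": at_content(seq),
        "at_skew": sk.at_skew,
        "gc_skew": sk.gc_skew,
    }


def partitioned_composition(ag: AnnotatedGenome) -> pd.DataFrame:
    """Composition table per gene, strand class, codon position and
    functional set.

    Codon positions use each PCG's own reading frame on its coding
    strand; a trailing partial codon (truncated stop) is ignored with a
    warning. Minus-strand partitions are measured on the reverse
    complement (the coding strand).
    """
    rows: list[dict] = []
    pcg_by_strand: dict[str, list[str]] = {"+": [], "-": []}
    for f in ag.pcgs:
        seq = ag.feature_sequence(f)
        if len(seq) % 3:
            warnings.warn(f"{f.gene}: length {len(seq)} not divisible by 3; "
                          "trailing partial codon ignored")
        rows.append(_row(f"gene:{f.gene}", seq))
        pcg_by_strand[f.strand].append(seq[: len(seq) - len(seq) % 3])
    for strand, seqs in pcg_by_strand.items():
        if not seqs:
            continue
        pooled = "".join(seqs)
        rows.append(_row(f"PCG:{strand}", pooled))
        for pos in (1, 2, 3):
            rows.append(
                _row(f"PCG:{strand}:pos{pos}", "".join(_codon_position_bases(s, pos) for s in seqs))
            )
    all_pcg = pcg_by_strand["+"] + pcg_by_strand["-"]
    if all_pcg:
        rows.append(_row("PCG:all", "".join(all_pcg)))
        for pos in (1, 2, 3):
            rows.append(
                _row(f"PCG:all:pos{pos}", "".join(_codon_position_bases(s, pos) for s in all_pcg))
            )
    for label, genes in (("tRNA", TRNA_GENES), ("rRNA", RRNA_GENES)):
        feats = ag.select(genes)
        if feats:
            rows.append(_row(label, "".join(ag.feature_sequence(f) for f in feats)))
    for f in ag.features:
        if f.gene in ("CR", "CR2"):
            rows.append(_row(f.gene, ag.feature_sequence(f)))
    return pd.DataFrame(rows)


@dataclass
class CodonTally:
    start_counts: Counter = field(default_factory=Counter)
    stop_counts: Counter = field(default_factory=Counter)

    @property
    def n_entries(self) -> int:
        return sum(self.start_counts.values())


def tally_start_stop(entries: list[tuple[str, str]]) -> CodonTally:
    """Exact counts of start codons and (possibly truncated) stops.

    Stops of 1 ("T") or 2 ("TA") nucleotides are the polyadenylation-
    completed truncations; anything of length 0 or more than 3 is
    rejected.
    """
    tally = CodonTally()
    for start, stop in entries:
        start, stop = start.upper(), stop.upper()
        if len(start) != 3:
            raise ValueError(f"start codon must be 3 nt, got {start!r}")
        if not 1 <= len(stop) <= 3:
            raise ValueError(f"stop codon must be 1-3 nt, got {stop!r}")
        tally.start_counts[start] += 1
        tally.stop_counts[stop] += 1
    return tally


def read_codon_table(path) -> list[tuple[str, str]]:
    """Read a codon TSV (gene, species, length, start_codon, stop_codon)."""
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["start_codon"], df["stop_codon"]))


@dataclass
class OverlapMap:
    """Signed gaps between circularly consecutive features.

    Negative = overlapping nucleotides, positive = non-coding spacer,
    zero = abutting."""

    entries: list[tuple[str, str, int]]

    def block_total_overlap(self, block: list[str]) -> int:
        """Total overlapping positions between consecutive members of a
        declared gene block (sum of negative gaps, reported >= 0)."""
        pairs = {(block[i], block[i + 1]) for i in range(len(block) - 1)}
        return -sum(g for a, b, g in self.entries if (a, b) in pairs and g < 0)

    @property
    def largest_spacer(self) -> tuple[str, str, int] | None:
        spacers = [e for e in self.entries if e[2] > 0]
        return max(spacers, key=lambda e: e[2]) if spacers else None


def overlaps_and_spacers(ag: AnnotatedGenome) -> OverlapMap:
    """Signed gap between consecutive features on the circular order."""
    feats = [f for f in ag.features]
    if len(feats) < 2:
        return OverlapMap([])
    n = ag.genome.length
    entries = []
    for i, f1 in enumerate(feats):
        f2 = feats[(i + 1) % len(feats)]
        start2 = f2.start + n if i == len(feats) - 1 else f2.start
        entries.append((f1.gene, f2.gene, start2 - f1.end))
    return OverlapMap(entries)


_SYNONYM_COUNTS = Counter(MITO_TABLE.forward_table.values())


def _translate_codon(codon: str) -> str:
    if codon in MITO_TABLE.stop_codons:
        return "*"
    return MITO_TABLE.forward_table.get(codon, "X")


def aa_frequencies_and_rscu(ag: AnnotatedGenome) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Amino-acid relative frequencies per strand class and RSCU table.

    RSCU(codon) = observed count x (number of synonymous codons) / total
    count for that amino acid. Internal stop codons are counted as the
    translation stop symbol with a warning.
    """
    codon_counts: Counter = Counter()
    aa_counts: dict[str, Counter] = {"+": Counter(), "-": Counter(), "all": Counter()}
    for f in ag.pcgs:
        seq = ag.feature_sequence(f)
        usable = len(seq) - len(seq) % 3
        for i in range(0, usable, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                continue
            aa = _translate_codon(codon)
            if aa == "*" and i + 3 < usable:
                warnings.warn(f"{f.gene}: internal stop codon {codon} at {i}")
            codon_counts[codon] += 1
            aa_counts[f.strand][aa] += 1
            aa_counts["all"][aa] += 1
    aa_rows = []
    for strand, counter in aa_counts.items():
        total = sum(c for aa, c in counter.items() if aa != "*") or 1
        for aa, count in sorted(counter.items()):
            if aa == "*":
                continue
            aa_rows.append(
                {"strand": strand, "aa": aa, "count": count, "frequency": count / total}
            )
    rscu_rows = []
    for aa in sorted(set(_SYNONYM_COUNTS)):
        synonyms = sorted(c for c, a in MITO_TABLE.forward_table.items() if a == aa)
        family_total = sum(codon_counts[c] for c in synonyms)
        for codon in synonyms:
            rscu = (
                codon_counts[codon] * len(synonyms) / family_total if family_total else float("nan")
            )
            rscu_rows.append(
                {"aa": aa, "codon": codon, "count": codon_counts[codon], "rscu": rscu}
            )
    return pd.DataFrame(aa_rows), pd.DataFrame(rscu_rows)


def stats_report(ag: AnnotatedGenome, out_path) -> None:
    """Write the full composition table plus overlap map as TSVs."""
    out = Path(out_path)
    partitioned_composition(ag).to_csv(out, sep="\t", index=False, float_format="%.6g")
    omap = overlaps_and_spacers(ag)
    pairs = pd.DataFrame(omap.entries, columns=["featureA", "featureB", "signed_gap"])
    pairs.to_csv(out.with_suffix(".overlaps.tsv"), sep="\t", index=False)
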