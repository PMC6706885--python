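"""Replication-origin scanning of non-coding regions.

Finds maximal DNA stem-loops (inverted repeats with bounded interior
mismatches and matching terminal pairs), homopolymer runs, and duplicated
motifs via seeded local self-alignment. G·T pairing in stems is off by
default: origin hairpins are described at the DNA level.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from Bio import Align

from .model import AnnotatedGenome

__all__ = [
    "StemLoop",
    "DuplicatedMotif",
    "NoncodingRegion",
    "find_stem_loops",
    "find_homopolymer_runs",
    "find_duplicated_motifs",
    "scan_noncoding",
]

_DNA_COMP = {"AT", "TA", "GC", "CG"}
_GU = {"GT", "TG"}


def _comp(a: str, b: str, allow_gu: bool) -> bool:
    duo = a + b
    return duo in _DNA_COMP or (allow_gu and duo in _GU)


@dataclass(frozen=True)
class StemLoop:
    """An inverted repeat: arm1 [start, start+stem), loop, arm2."""

    start: int
    stem: int
    loop: int
    mismatches: int
    run: tuple[str, int, str] | None = None  # (base, length, side "5'"/"3'")

    @property
    def end(self) -> int:
        return self.start + 2 * self.stem + self.loop

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def find_homopolymer_runs(seq: str, base: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of ``base`` of length >= min_len, as half-open spans."""
    if base not in "ACGT":
        raise ValueError(f"base must be one of A,C,G,T, got {base!r}")
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _flanking_run(seq: str, start: int, end: int, min_run: int) -> tuple[str, int, str] | None:
    best = None
    if start > 0:
        base = seq[start - 1]
        i = start - 1
        while i >= 0 and seq[i] == base:
            i -= 1
        length = start - 1 - i
        if length >= min_run:
            best = (base, length, "5'")
    if end < len(seq):
        base = seq[end]
        j = end
        while j < len(seq) and seq[j] == base:
            j += 1
        length = j - end
        if length >= min_run and (best is None or length > best[1]):
            best = (base, length, "3'")
    return best


def find_stem_loops(
    seq: str,
    min_stem: int = 6,
    max_loop: int = 20,
    max_mismatch: int = 1,
    min_loop: int = 3,
    allow_gu: bool = False,
    min_run: int = 8,
) -> list[StemLoop]:
    """All maximal inverted repeats meeting the thresholds.

    Terminal (outermost and innermost) stem pairs must be complementary;
    mismatches up to ``max_mismatch`` are interior. Maximality: the stem
    cannot be extended outward, nor inward into the loop, by another
    complementary pair. Sorted by stem length descending.
    """
    n = len(seq)
    out: list[StemLoop] = []
    min_total = 2 * min_stem + min_loop
    for i in range(n - min_total + 1):
        for e in range(i + min_total, n + 1):
            # outward-extendable candidates are never maximal
            if i > 0 and e < n and _comp(seq[i - 1], seq[e], allow_gu):
                continue
            if not _comp(seq[i], seq[e - 1], allow_gu):
                continue  # outermost pair must match
            span = e - i
            lmax_geom = (span - min_loop) // 2
            match: list[bool] = []
            mm = 0
            for k in range(lmax_geom + 1):
                ok = _comp(seq[i + k], seq[e - 1 - k], allow_gu)
                match.append(ok)
                if not ok:
                    mm += 1
                    if mm > max_mismatch:
                        break
            for L in range(min_stem, len(match) + 1):
                loop = span - 2 * L
                if not min_loop <= loop <= max_loop:
                    continue
                if sum(1 for f in match[:L] if not f) > max_mismatch:
                    continue
                if not match[L - 1]:
                    continue  # innermost pair must match
                inward_ok = loop - 2 >= min_loop and L < len(match) and match[L]
                if inward_ok:
                    continue  # extendable into the loop
                out.append(
                    StemLoop(
                        start=i,
                        stem=L,
                        loop=loop,
                        mismatches=sum(1 for f in match[:L] if not f),
                        run=_flanking_run(seq, i, e, min_run),
                    )
                )
    out.sort(key=lambda s: (-s.stem, s.start, s.loop))
    return out


@dataclass(frozen=True)
class DuplicatedMotif:
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    length: int  # alignment columns
    identity: float  # percent of alignment columns that match
    gaps: float  # percent of alignment columns that are gaps
    score: float = field(compare=False, default=0.0)


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _alignment_stats(aln) -> tuple[int, int, int]:
    """(columns, matches, gap_columns) of a pairwise alignment."""
    a_row, b_row = str(aln[0]), str(aln[1])
    cols = len(a_row)
    matches = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    gap_cols = sum(1 for x, y in zip(a_row, b_row) if x == "-" or y == "-")
    return cols, matches, gap_cols


def find_duplicated_motifs(
    seq: str,
    min_len: int = 50,
    min_identity: float = 85.0,
    seed_k: int = 11,
) -> list[DuplicatedMotif]:
    """Non-overlapping duplicated units found by seeded local self-alignment.

    Identity is matched columns over all alignment columns; gaps is gap
    columns over all alignment columns (both in percent). Candidate pairs
    come from shared ``seed_k``-mers grouped by diagonal, then refined by
    local alignment (match 1, mismatch -1, gap -2).
    """
    n = len(seq)
    if n < 2 * min_len:
        return []
    kmers: dict[str, list[int]] = defaultdict(list)
    for i in range(n - seed_k + 1):
        kmers[seq[i : i + seed_k]].append(i)
    diagonals: dict[int, list[int]] = defaultdict(list)
    for positions in kmers.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                d = positions[bi] - positions[ai]
                if d >= min_len:
                    diagonals[d].append(positions[ai])
    aligner = _local_aligner()
    margin = 25
    candidates: list[DuplicatedMotif] = []
    seen_regions: set[tuple[int, int, int, int]] = set()
    for d, starts in diagonals.items():
        a0 = max(0, min(starts) - margin)
        a1 = min(n, max(starts) + seed_k + margin)
        b0, b1 = a0 + d, min(n, a1 + d)
        a1 = min(a1, b0)  # keep the two regions non-overlapping
        if a1 - a0 < min_len or b1 - b0 < min_len:
            continue
        key = (a0, a1, b0, b1)
        if key in seen_regions:
            continue
        seen_regions.add(key)
        alignments = aligner.align(seq[a0:a1], seq[b0:b1])
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        cols, matches, gap_cols = _alignment_stats(aln)
        if cols < min_len:
            continue
        identity = 100.0 * matches / cols
        if identity < min_identity:
            continue
        (a_blocks, b_blocks) = aln.aligned
        span_a = (a0 + int(a_blocks[0][0]), a0 + int(a_blocks[-1][1]))
        span_b = (b0 + int(b_blocks[0][0]), b0 + int(b_blocks[-1][1]))
        candidates.append(
            DuplicatedMotif(
                span_a=span_a,
                span_b=span_b,
                length=cols,
                identity=identity,
                gaps=100.0 * gap_cols / cols,
                score=float(aln.score),
            )
        )
    candidates.sort(key=lambda m: (-m.score, m.span_a))
    accepted: list[DuplicatedMotif] = []

    def _overlaps(x: tuple[int, int], y: tuple[int, int]) -> bool:
        return x[0] < y[1] and y[0] < x[1]

    for cand in candidates:
        if any(
            _overlaps(cand.span_a, acc.span_a) or _overlaps(cand.span_b, acc.span_b)
            for acc in accepted
        ):
            continue
        accepted.append(cand)
    return accepted


@dataclass
class NoncodingRegion:
    label: str  # CR (largest) or CR2
    span: tuple[int, int]  # genomic, forward strand; end may wrap past length
    sequence: str
    stem_loops: list[StemLoop]
    runs: dict[str, list[tuple[int, int]]]
    motifs: list[DuplicatedMotif]


@dataclass
class NoncodingReport:
    regions: list[NoncodingRegion]
    shared_motifs: list[tuple[str, str, float]]  # (labelA, labelB, identity %)


def scan_noncoding(
    ag: AnnotatedGenome,
    min_region: int = 30,
    min_run: int = 8,
    min_shared_cols: int = 30,
    min_shared_identity: float = 60.0,
) -> NoncodingReport:
    """Scan all unannotated regions >= min_region nt of a genome.

    The largest region is labelled CR, the rest CR2; each is scanned for
    stem-loops, homopolymer runs and internal duplicated motifs, and
    motifs are cross-referenced between CR and the other regions by local
    alignment.
    """
    genome = ag.genome
    n = genome.length
    covered = [False] * n
    for f in ag.features:
        if f.gene in ("CR", "CR2"):
            continue  # pre-annotated control regions are what we look for
        for s, e in f.segments(n):
            for i in range(s, e):
                covered[i] = True
    # gaps on the circle
    gaps: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not covered[i]:
            j = i
            while j < n and not covered[j]:
                j += 1
            gaps.append((i, j))
            i = j
        else:
            i += 1
    if genome.circular and len(gaps) >= 2 and gaps[0][0] == 0 and gaps[-1][1] == n:
        first, last = gaps[0], gaps[-1]
        gaps = gaps[1:-1] + [(last[0], n + first[1])]
    gaps = [g for g in gaps if g[1] - g[0] >= min_region]
    if not gaps:
        return NoncodingReport([], [])
    gaps.sort(key=lambda g: (-(g[1] - g[0]), g[0]))
    regions = []
    for rank, (s, e) in enumerate(gaps):
        seq = genome.fetch(s, e)
        regions.append(
            NoncodingRegion(
                label="CR" if rank == 0 else "CR2",
                span=(s, e),
                sequence=seq,
                stem_loops=find_stem_loops(seq, min_run=min_run),
                runs={b: find_homopolymer_runs(seq, b, min_run) for b in "ACGT"},
                motifs=find_duplicated_motifs(seq),
            )
        )
    shared = []
    aligner = _local_aligner()
    cr = regions[0]
    for other in regions[1:]:
        alignments = aligner.align(cr.sequence, other.sequence)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        cols, matches, _ = _alignment_stats(aln)
        if cols >= min_shared_cols:
            identity = 100.0 * matches / cols
            if identity >= min_shared_identity:
                shared.append((cr.label, other.label, identity))
    return NoncodingReport(regions, shared)
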