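"""Per-genome tRNA annotation: route each identity to its expected
inter-gene window (from a reference gene order) and fold it there.

The expected strand from the gene order is searched first; if no
anticodon arm anchors there, the other strand is tried. Both per-class
results are retained for downstream consensus calling.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fold import (
    CandidateWindow,
    enumerate_foldings,
    extract_candidates,
    find_anticodon_arms,
    fold_sort_key,
)
from .gene_order import GeneOrder
from .grammar import FoldScore, ScoringWeights, TrnaClass, TrnaGrammar, TrnaStructure
from .model import PCG_GENES, RRNA_GENES, TRNA_GENES, AnnotatedGenome

__all__ = ["TrnaHit", "annotate_trnas", "stripped_view"]

_ANCHOR_GENES = set(PCG_GENES) | set(RRNA_GENES)


@dataclass
class TrnaHit:
    """Best fold of one tRNA identity in one genome."""

    identity: str
    genome_id: str
    window: CandidateWindow
    structure: TrnaStructure
    score: FoldScore
    per_class: dict[TrnaClass, tuple[TrnaStructure, FoldScore]]
    genomic_span: tuple[int, int]
    strand: str

    @property
    def sequence(self) -> str:
        return self.window.seq[self.structure.span[0] : self.structure.span[1]]


def stripped_view(ag: AnnotatedGenome) -> AnnotatedGenome:
    """The genome with only PCG/rRNA features (tRNA/CR discarded)."""
    return AnnotatedGenome(ag.genome, ag.select(_ANCHOR_GENES))


def _expected_flanks(order: GeneOrder, identity: str) -> tuple[str, str]:
    labels = [g for g, _ in order.genes]
    idx = labels.index(identity)
    n = len(labels)
    before = after = ""
    for d in range(1, n):
        g = labels[(idx - d) % n]
        if g in _ANCHOR_GENES:
            before = g
            break
    for d in range(1, n):
        g = labels[(idx + d) % n]
        if g in _ANCHOR_GENES:
            after = g
            break
    return before, after


def fold_candidate(
    seq: str,
    identity: str,
    grammar: TrnaGrammar | None = None,
    weights: ScoringWeights | None = None,
    anchor_wobble: int = 4,
) -> tuple[TrnaStructure, FoldScore, dict[TrnaClass, tuple[TrnaStructure, FoldScore]]] | None:
    """Overall best fold plus the per-class alternatives at its anchor.

    Alternative classes are same-molecule refoldings: they must share the
    winning anticodon-arm anchor (within ``anchor_wobble`` nt of register
    shift), so folds of unrelated loci elsewhere in the window never
    masquerade as an arm of this tRNA.
    """
    best: tuple[TrnaStructure, FoldScore] | None = None
    best_anchor: int | None = None
    per_anchor: dict[int, list[tuple[TrnaStructure, FoldScore]]] = {}
    for a in find_anticodon_arms(seq, identity, grammar):
        folds = enumerate_foldings(seq, a, grammar, weights)
        if not folds:
            continue
        per_anchor[a] = folds
        top = min(folds, key=fold_sort_key)
        if best is None or fold_sort_key(top) < fold_sort_key(best):
            best, best_anchor = top, a
    if best is None:
        return None
    per_class: dict[TrnaClass, tuple[TrnaStructure, FoldScore]] = {}
    for a, folds in per_anchor.items():
        if abs(a - best_anchor) > anchor_wobble:
            continue
        for st, sc in folds:
            cur = per_class.get(st.cls)
            if cur is None or fold_sort_key((st, sc)) < fold_sort_key(cur):
                per_class[st.cls] = (st, sc)
    return best[0].with_identity(identity), best[1], per_class


def _search_window(
    window: CandidateWindow,
    identity: str,
    grammar: TrnaGrammar | None,
    weights: ScoringWeights | None,
) -> tuple[TrnaStructure, FoldScore, dict] | None:
    return fold_candidate(window.seq, identity, grammar, weights)


def annotate_trnas(
    ag: AnnotatedGenome,
    order: GeneOrder,
    pad: int = 50,
    grammar: TrnaGrammar | None = None,
    weights: ScoringWeights | None = None,
    identities: tuple[str, ...] | None = None,
) -> dict[str, TrnaHit | None]:
    """Best fold per tRNA identity, searched in order-implied windows."""
    stripped = stripped_view(ag)
    windows = extract_candidates(stripped, pad)
    by_key = {(w.between, w.strand): w for w in windows}
    order_strand = {g: s for g, s in order.genes}
    n = ag.genome.length
    hits: dict[str, TrnaHit | None] = {}
    targets = identities or tuple(g for g, _ in order.genes if g in TRNA_GENES)
    for identity in targets:
        flanks = _expected_flanks(order, identity)
        expected = order_strand.get(identity, "+")
        hit = None
        for strand in (expected, "-" if expected == "+" else "+"):
            window = by_key.get((flanks, strand))
            if window is None:
                continue
            found = _search_window(window, identity, grammar, weights)
            if found is not None:
                st, sc, per_class = found
                hit = TrnaHit(
                    identity=identity,
                    genome_id=ag.genome.id,
                    window=window,
                    structure=st,
                    score=sc,
                    per_class=per_class,
                    genomic_span=window.to_genomic(st.span, n),
                    strand=strand,
                )
                break
        hits[identity] = hit
    return hits
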