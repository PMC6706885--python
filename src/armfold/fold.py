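"""Candidate extraction and grammar-driven folding of degenerate tRNAs.

The search is anchor-based: anticodon arms (a 5-pair stem enclosing a
7-nt loop whose central triplet is an allowed anticodon) are located
first, then for each of the four structural classes the grammar-consistent
layout maximizing the fold score is found around each anchor. No
covariance models and no thermodynamics: scoring is a weighted count of
canonical pairs, G·T wobble pairs and acceptor-stem mismatches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import yaml

from .grammar import (
    Arm,
    FoldScore,
    ScoringWeights,
    TrnaClass,
    TrnaGrammar,
    TrnaStructure,
    classify_pair,
)
from .model import PCG_GENES, RRNA_GENES, AnnotatedGenome, revcomp

__all__ = [
    "ANTICODONS",
    "CandidateWindow",
    "extract_candidates",
    "find_anticodon_arms",
    "enumerate_foldings",
    "best_fold",
    "fold_sort_key",
]


def _load_anticodons() -> dict[str, tuple[str, ...]]:
    text = resources.files("armfold.data").joinpath("anticodons.yaml").read_text()
    return {k: tuple(v) for k, v in yaml.safe_load(text)["anticodons"].items()}


ANTICODONS: dict[str, tuple[str, ...]] = _load_anticodons()


@dataclass(frozen=True)
class CandidateWindow:
    """A strand-oriented search window on a circular genome.

    ``start``/``end`` are forward-strand genomic coordinates (end may
    exceed the genome length when the window wraps the origin); ``seq``
    is already reverse-complemented for minus-strand windows.
    """

    genome_id: str
    strand: str
    start: int
    end: int
    seq: str
    between: tuple[str, str] = ("", "")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_genomic(self, local_span: tuple[int, int], genome_length: int) -> tuple[int, int]:
        """Map a window-local span to forward-strand genomic coordinates."""
        s, e = local_span
        if self.strand == "+":
            g = (self.start + s, self.start + e)
        else:
            g = (self.end - e, self.end - s)
        start = g[0] % genome_length
        return (start, start + (e - s))


def extract_candidates(ag: AnnotatedGenome, pad: int = 50) -> list[CandidateWindow]:
    """Windows between consecutive non-tRNA features, padded into them.

    Overlapping consecutive features collapse to a pad-only window around
    the junction. Every window is emitted on both strands.
    """
    genome = ag.genome
    n = genome.length
    anchors = sorted(ag.select(PCG_GENES + RRNA_GENES), key=lambda f: (f.start, f.gene))
    windows: list[CandidateWindow] = []

    def emit(w_start: int, w_end: int, between: tuple[str, str]) -> None:
        w_start_norm = w_start % n
        w_end_norm = w_start_norm + (w_end - w_start)
        seq = genome.fetch(w_start_norm, w_end_norm)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            windows.append(
                CandidateWindow(genome.id, strand, w_start_norm, w_end_norm, s, between)
            )

    if not anchors:
        warnings.warn("no non-tRNA features; emitting whole genome as one window")
        emit(0, n, ("", ""))
        return windows

    for idx, f1 in enumerate(anchors):
        f2 = anchors[(idx + 1) % len(anchors)]
        g0 = f1.end
        g1 = f2.start + n if idx == len(anchors) - 1 else f2.start
        if g1 >= g0:
            emit(g0 - pad, g1 + pad, (f1.gene, f2.gene))
        else:  # overlapping features: pad-only window at the junction
            emit(g1 - pad, g1 + pad, (f1.gene, f2.gene))
    return windows


def _ac_arm_ok(seq: str, a: int, g: TrnaGrammar) -> bool:
    """Valid anticodon stem at anchor ``a`` (stem5 start)."""
    L, loop = g.ac_stem_len, g.ac_loop_len
    arm = 2 * L + loop
    gu = mm = 0
    for k in range(L):
        kind = classify_pair(seq[a + k], seq[a + arm - 1 - k])
        if kind == "gu":
            gu += 1
        elif kind == "mismatch":
            mm += 1
        if gu > g.ac_stem_max_gu or mm > g.ac_stem_max_mismatch:
            return False
    return True


def find_anticodon_arms(
    window_seq: str,
    identity: str | None = None,
    grammar: TrnaGrammar | None = None,
    anticodons: tuple[str, ...] | None = None,
) -> list[int]:
    """All anchor positions of a valid anticodon arm in the window.

    ``identity`` selects the allowed anticodon set from the shipped
    config; pass ``anticodons`` directly to override, or neither to
    accept any triplet.
    """
    g = grammar or TrnaGrammar()
    if identity is not None:
        if identity not in ANTICODONS:
            raise KeyError(f"unknown tRNA identity {identity!r}")
        allowed: frozenset[str] | None = frozenset(ANTICODONS[identity])
    elif anticodons is not None:
        allowed = frozenset(anticodons)
    else:
        allowed = None
    arm = g.ac_arm_len
    off = g.ac_stem_len + g.anticodon_offset
    anchors = []
    for a in range(len(window_seq) - arm + 1):
        if allowed is not None and window_seq[a + off : a + off + 3] not in allowed:
            continue
        if _ac_arm_ok(window_seq, a, g):
            anchors.append(a)
    return anchors


def _ac_arm_score(seq: str, a: int, g: TrnaGrammar, w: ScoringWeights) -> FoldScore:
    L, arm = g.ac_stem_len, g.ac_arm_len
    kinds = [classify_pair(seq[a + k], seq[a + arm - 1 - k]) for k in range(L)]
    return FoldScore(kinds.count("canonical"), kinds.count("gu"), kinds.count("mismatch"), w)


def _hairpin_options(
    seq: str,
    anchor: int,
    side: str,
    stem_rng: tuple[int, int],
    loop_rng: tuple[int, int],
    pre_rng: tuple[int, int],
    post_rng: tuple[int, int],
    g: TrnaGrammar,
    w: ScoringWeights,
) -> dict[int, tuple[FoldScore, Arm]]:
    """Best mismatch-free hairpin per total extent on one side of the anchor.

    ``side`` is "left" (extent = pre + arm + post measured back from the
    anchor) or "right" (extent measured forward from the anticodon arm
    end). Returns extent -> (score, arm) keeping, per extent, the option
    with the best (score, canonical) key.
    """
    best: dict[int, tuple[FoldScore, Arm]] = {}
    ac_end = anchor + g.ac_arm_len
    n = len(seq)
    for stem in range(stem_rng[0], stem_rng[1] + 1):
        for loop in range(loop_rng[0], loop_rng[1] + 1):
            arm_len = 2 * stem + loop
            for pre in range(pre_rng[0], pre_rng[1] + 1):
                for post in range(post_rng[0], post_rng[1] + 1):
                    extent = pre + arm_len + post
                    if side == "left":
                        start = anchor - post - arm_len
                    else:
                        start = ac_end + pre
                    if start < 0 or start + arm_len > n:
                        continue
                    canon = gu = mm = 0
                    for k in range(stem):
                        kind = classify_pair(seq[start + k], seq[start + arm_len - 1 - k])
                        canon += kind == "canonical"
                        gu += kind == "gu"
                        mm += kind == "mismatch"
                        if mm > g.side_stem_max_mismatch:
                            break
                    if mm > g.side_stem_max_mismatch:
                        continue
                    score = FoldScore(canon, gu, mm, w)
                    arm = Arm(
                        stem5=(start, start + stem),
                        stem3=(start + stem + loop, start + arm_len),
                    )
                    cur = best.get(extent)
                    key = (score.score, -score.mismatches, score.canonical_pairs)
                    if cur is None or key > (
                        cur[0].score,
                        -cur[0].mismatches,
                        cur[0].canonical_pairs,
                    ):
                        best[extent] = (score, arm)
    return best


def _acceptor_eval(
    seq: str, a5: int, a3: int, g: TrnaGrammar, w: ScoringWeights
) -> tuple[FoldScore, Arm] | None:
    L = g.acceptor_len
    if a5 < 0 or a3 + L > len(seq):
        return None
    canon = gu = mm = 0
    for k in range(L):
        kind = classify_pair(seq[a5 + k], seq[a3 + L - 1 - k])
        canon += kind == "canonical"
        gu += kind == "gu"
        mm += kind == "mismatch"
    if mm > g.acceptor_max_mismatch:
        return None
    return FoldScore(canon, gu, mm, w), Arm(stem5=(a5, a5 + L), stem3=(a3, a3 + L))


def fold_sort_key(item: tuple[TrnaStructure, FoldScore]) -> tuple:
    """Deterministic ranking: higher score, fewer mismatches, more
    canonical pairs, shorter structure, 5'-most placement."""
    st, sc = item
    return (-sc.score, sc.mismatches, -sc.canonical_pairs, st.length, st.span[0])


def enumerate_foldings(
    window_seq: str,
    anchor: int,
    grammar: TrnaGrammar | None = None,
    weights: ScoringWeights | None = None,
) -> list[tuple[TrnaStructure, FoldScore]]:
    """Best grammar-consistent structure per class around one anchor.

    Classes whose grammar cannot be satisfied are omitted; the result is
    sorted best-first by :func:`fold_sort_key`.
    """
    g = grammar or TrnaGrammar()
    w = weights or ScoringWeights()
    seq = window_seq
    if not _ac_arm_ok(seq, anchor, g):
        return []
    ac_score = _ac_arm_score(seq, anchor, g, w)
    ac_end = anchor + g.ac_arm_len
    off = g.ac_stem_len + g.anticodon_offset
    anticodon = seq[anchor + off : anchor + off + 3]

    unit = (0, 0)
    d_options = _hairpin_options(seq, anchor, "left", g.d_stem, g.d_loop, g.conn_acc_d, g.conn_d_ac, g, w)
    t_options = _hairpin_options(seq, anchor, "right", g.t_stem, g.t_loop, g.var_loop, unit, g, w)
    plain = {
        "armless_l": {c: None for c in range(g.armless_conn[0], g.armless_conn[1] + 1)},
        "armless_r": {c: None for c in range(g.armless_conn[0], g.armless_conn[1] + 1)},
        "drepl": {c: None for c in range(g.d_replacement_loop[0], g.d_replacement_loop[1] + 1)},
        "tv": {c: None for c in range(g.tv_replacement_loop[0], g.tv_replacement_loop[1] + 1)},
    }

    class_sides = {
        TrnaClass.ARMLESS: (plain["armless_l"], plain["armless_r"]),
        TrnaClass.T_ARMLESS: (d_options, plain["tv"]),
        TrnaClass.D_ARMLESS: (plain["drepl"], t_options),
        TrnaClass.CLOVERLEAF: (d_options, t_options),
    }

    results: list[tuple[TrnaStructure, FoldScore]] = []
    for cls, (left_opts, right_opts) in class_sides.items():
        best: tuple | None = None
        for left, left_val in left_opts.items():
            a5 = anchor - left - g.acceptor_len
            for right, right_val in right_opts.items():
                a3 = ac_end + right
                acc = _acceptor_eval(seq, a5, a3, g, w)
                if acc is None:
                    continue
                acc_score, acc_arm = acc
                total = acc_score + ac_score
                d_arm = t_arm = None
                if isinstance(left_val, tuple):
                    total = total + left_val[0]
                    d_arm = left_val[1]
                if isinstance(right_val, tuple):
                    total = total + right_val[0]
                    t_arm = right_val[1]
                span = (a5, a3 + g.acceptor_len)
                length = span[1] - span[0]
                key = (-total.score, total.mismatches, -total.canonical_pairs, length, a5)
                if best is None or key < best[0]:
                    best = (key, cls, acc_arm, d_arm, t_arm, span, total)
        if best is not None:
            _, cls_, acc_arm, d_arm, t_arm, span, total = best
            shift = span[0]

            def _shift(arm: Arm | None) -> Arm | None:
                if arm is None:
                    return None
                return Arm(
                    stem5=(arm.stem5[0] - shift, arm.stem5[1] - shift),
                    stem3=(arm.stem3[0] - shift, arm.stem3[1] - shift),
                )

            structure = TrnaStructure(
                cls=cls_,
                length=span[1] - span[0],
                acceptor=_shift(acc_arm),
                ac_arm=_shift(Arm(stem5=(anchor, anchor + g.ac_stem_len),
                                  stem3=(ac_end - g.ac_stem_len, ac_end))),
                d_arm=_shift(d_arm),
                t_arm=_shift(t_arm),
                anticodon=anticodon,
                span=span,
            )
            results.append((structure, total))
    results.sort(key=fold_sort_key)
    return results


def best_fold(
    window_seq: str,
    identity: str | None = None,
    grammar: TrnaGrammar | None = None,
    weights: ScoringWeights | None = None,
    anticodons: tuple[str, ...] | None = None,
) -> tuple[TrnaStructure, FoldScore] | None:
    """Argmax of the fold score over all anchors and classes.

    Returns ``None`` when no anticodon arm can be anchored — never a
    fabricated structure.
    """
    anchors = find_anticodon_arms(window_seq, identity, grammar, anticodons)
    candidates: list[tuple[TrnaStructure, FoldScore]] = []
    for a in anchors:
        candidates.extend(enumerate_foldings(window_seq, a, grammar, weights))
    if not candidates:
        return None
    best = min(candidates, key=fold_sort_key)
    if identity is not None:
        best = (best[0].with_identity(identity), best[1])
    return best
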