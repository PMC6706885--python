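"""Cross-species consensus calling for orthologous tRNA candidates.

Per-species best structures are aligned (progressive pairwise global
alignment onto the longest candidate) and each side arm is tested for
conservation: an arm counts as conserved only when it is present in ALL
species, its spans map to overlapping alignment columns, and stem
lengths differ by at most one pair. The final structural class follows
from the two arm flags; a runner-up class scoring within tolerance in at
least half the species is reported as the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .grammar import TrnaClass, TrnaStructure
from .pipeline import TrnaHit

__all__ = [
    "OrthologSet",
    "Msa",
    "ConsensusCall",
    "align_orthologs",
    "assess_arm_conservation",
    "call_consensus",
]


@dataclass
class OrthologSet:
    identity: str
    candidates: dict[str, TrnaHit]  # species id -> hit

    def __post_init__(self) -> None:
        for sp, hit in self.candidates.items():
            if hit.identity != self.identity:
                raise ValueError(
                    f"conflicting identity {hit.identity!r} for species {sp} "
                    f"in ortholog set {self.identity!r}"
                )


@dataclass
class Msa:
    reference: str
    order: list[str]
    rows: dict[str, str]
    col_maps: dict[str, list[int]]  # sequence index -> alignment column

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def columns_of_span(self, species: str, span: tuple[int, int]) -> set[int]:
        cmap = self.col_maps[species]
        return {cmap[i] for i in range(span[0], span[1])}


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _pair_columns(aln) -> list[tuple[int | None, int | None]]:
    ref_idx, q_idx = aln.indices
    return [
        (int(r) if r >= 0 else None, int(q) if q >= 0 else None)
        for r, q in zip(ref_idx, q_idx)
    ]


def align_orthologs(seqs: dict[str, str]) -> Msa:
    """Deterministic star alignment to the longest sequence.

    Scoring: match 1, mismatch -1, gap open -2, gap extend -1. Reference
    = longest candidate, ties broken by species id order.
    """
    if not seqs:
        raise ValueError("empty ortholog set")
    order = sorted(seqs)
    ref_sp = min(order, key=lambda sp: (-len(seqs[sp]), sp))
    ref = seqs[ref_sp]
    others = [sp for sp in order if sp != ref_sp]
    if not others:
        return Msa(ref_sp, order, {ref_sp: ref}, {ref_sp: list(range(len(ref)))})
    aligner = _global_aligner()
    R = len(ref)
    # per species: insertions before each ref position, and ref->query map
    ins_before: dict[str, dict[int, list[int]]] = {}
    ref_to_q: dict[str, dict[int, int]] = {}
    for sp in others:
        aln = aligner.align(ref, seqs[sp])[0]
        ins: dict[int, list[int]] = {}
        r2q: dict[int, int] = {}
        pending: list[int] = []
        for r, q in _pair_columns(aln):
            if r is None:
                pending.append(q)
            else:
                if pending:
                    ins[r] = pending
                    pending = []
                if q is not None:
                    r2q[r] = q
        if pending:
            ins[R] = pending
        ins_before[sp] = ins
        ref_to_q[sp] = r2q
    gap_alloc = {
        r: max((len(ins_before[sp].get(r, ())) for sp in others), default=0)
        for r in range(R + 1)
    }
    rows: dict[str, list[str]] = {sp: [] for sp in order}
    col_maps: dict[str, list[int]] = {sp: [0] * len(seqs[sp]) for sp in order}
    col = 0
    for r in range(R + 1):
        for slot in range(gap_alloc[r]):
            for sp in others:
                ins = ins_before[sp].get(r, [])
                if slot < len(ins):
                    q = ins[slot]
                    rows[sp].append(seqs[sp][q])
                    col_maps[sp][q] = col
                else:
                    rows[sp].append("-")
            rows[ref_sp].append("-")
            col += 1
        if r < R:
            rows[ref_sp].append(ref[r])
            col_maps[ref_sp][r] = col
            for sp in others:
                q = ref_to_q[sp].get(r)
                if q is None:
                    rows[sp].append("-")
                else:
                    rows[sp].append(seqs[sp][q])
                    col_maps[sp][q] = col
            col += 1
    return Msa(ref_sp, order, {sp: "".join(rows[sp]) for sp in order}, col_maps)


def assess_arm_conservation(
    structures: dict[str, TrnaStructure],
    msa: Msa,
    stem_len_tol: int = 1,
    offsets: dict[str, int] | None = None,
) -> dict[str, str]:
    """Per-arm conservation flags over aligned per-species structures.

    Presence in less than all species immediately flags the arm as
    not_conserved (inconsistent presence/absence is itself the signal).
    ``offsets`` maps each species' structure-local coordinates into its
    aligned sequence (0 when the aligned sequences ARE the structures).
    """
    offsets = offsets or {}
    flags = {}
    for arm_name in ("D", "T"):
        arms = {
            sp: (st.d_arm if arm_name == "D" else st.t_arm)
            for sp, st in structures.items()
        }
        flags[arm_name] = _arm_flag(arms, msa, stem_len_tol, offsets)
    return flags


def _arm_flag(
    arms: dict[str, "object"],
    msa: Msa,
    stem_len_tol: int,
    offsets: dict[str, int],
) -> str:
    if not arms or any(arm is None for arm in arms.values()):
        return "not_conserved"
    col_sets = []
    for sp, arm in arms.items():
        off = offsets.get(sp, 0)
        col_sets.append(
            msa.columns_of_span(sp, (arm.span[0] + off, arm.span[1] + off))
        )
    common = set.intersection(*col_sets) if col_sets else set()
    lengths = [arm.stem_len for arm in arms.values()]
    if common and max(lengths) - min(lengths) <= stem_len_tol:
        return "conserved"
    return "not_conserved"


def _armed_candidates(hit: TrnaHit, arm_name: str):
    return [
        (st, sc)
        for cls, (st, sc) in hit.per_class.items()
        if (cls.has_d_arm if arm_name == "D" else cls.has_t_arm)
    ]


def _feasible_arm_structure(hit: TrnaHit, arm_name: str) -> TrnaStructure | None:
    """Best structure carrying the arm, or None when none is feasible."""
    from .fold import fold_sort_key

    candidates = _armed_candidates(hit, arm_name)
    if not candidates:
        return None
    return min(candidates, key=fold_sort_key)[0]


def _armed_score(hit: TrnaHit, arm_name: str) -> float:
    return max(sc.score for _, sc in _armed_candidates(hit, arm_name))


_CLASS_FROM_FLAGS = {
    ("conserved", "conserved"): TrnaClass.CLOVERLEAF,
    ("conserved", "not_conserved"): TrnaClass.T_ARMLESS,
    ("not_conserved", "conserved"): TrnaClass.D_ARMLESS,
    ("not_conserved", "not_conserved"): TrnaClass.ARMLESS,
}


@dataclass
class ConsensusCall:
    identity: str
    d_arm: str
    t_arm: str
    final_class: TrnaClass
    alternative: TrnaClass | None
    per_species: dict[str, TrnaHit]
    low_confidence: bool = False
    notes: list[str] = field(default_factory=list)


def call_consensus(
    os_: OrthologSet,
    score_tolerance: float = 1.0,
    stem_len_tol: int = 1,
) -> ConsensusCall:
    """Consensus structural class for one tRNA identity across species."""
    species = sorted(os_.candidates)
    notes: list[str] = []
    low_confidence = len(species) < 2
    if low_confidence:
        notes.append("fewer than 2 species with a candidate; low confidence")
    if not species:
        raise ValueError(f"no candidates for {os_.identity}")
    # align the union of all per-class candidate spans per species, so
    # arm spans of non-best (but credible) armed folds map to columns too
    regions: dict[str, tuple[int, int]] = {}
    seqs: dict[str, str] = {}
    for sp in species:
        hit = os_.candidates[sp]
        spans = [st.span for st, _ in hit.per_class.values()] + [hit.structure.span]
        r0 = min(s for s, _ in spans)
        r1 = max(e for _, e in spans)
        regions[sp] = (r0, r1)
        seqs[sp] = hit.window.seq[r0:r1]
    msa = align_orthologs(seqs)
    flags = {}
    for arm_name in ("D", "T"):
        # Species with no grammar-feasible armed fold at all are excluded
        # from this arm's assessment (they cannot testify); a species
        # whose armed fold is feasible but scores clearly below its best
        # fold testifies ABSENT. Conserved requires the arm credibly
        # present in every non-excluded species AND in a strict majority
        # of all candidate species.
        arms = {}
        offsets = {}
        absent_witness = False
        for sp in species:
            hit = os_.candidates[sp]
            st = _feasible_arm_structure(hit, arm_name)
            if st is None:
                continue  # excluded: armed structure missing entirely
            score = _armed_score(hit, arm_name)
            if score >= hit.score.score - score_tolerance:
                arms[sp] = st.d_arm if arm_name == "D" else st.t_arm
                offsets[sp] = st.span[0] - regions[sp][0]
            else:
                absent_witness = True
        if absent_witness or 2 * len(arms) <= len(species):
            flags[arm_name] = "not_conserved"
        else:
            flags[arm_name] = _arm_flag(arms, msa, stem_len_tol, offsets)
    final = _CLASS_FROM_FLAGS[(flags["D"], flags["T"])]

    # alternative: another class scoring within tolerance in >= half the species
    alt_support: dict[TrnaClass, int] = {}
    alt_scores: dict[TrnaClass, float] = {}
    for cls in TrnaClass:
        if cls is final:
            continue
        supporting = 0
        total_score = 0.0
        for sp in species:
            per_class = os_.candidates[sp].per_class
            if cls not in per_class:
                continue
            base = per_class.get(final)
            base_score = base[1].score if base else os_.candidates[sp].score.score
            if per_class[cls][1].score >= base_score - score_tolerance:
                supporting += 1
                total_score += per_class[cls][1].score
        if 2 * supporting >= len(species) and supporting > 0:
            alt_support[cls] = supporting
            alt_scores[cls] = total_score / supporting
    alternative = None
    if alt_support:
        alternative = max(
            alt_support, key=lambda c: (alt_support[c], alt_scores[c], c.value)
        )
        notes.append(
            f"alternative {alternative.value} within {score_tolerance} score "
            f"units in {alt_support[alternative]}/{len(species)} species"
        )
    if final in (TrnaClass.ARMLESS, TrnaClass.D_ARMLESS, TrnaClass.T_ARMLESS):
        reductions = []
        for sp in species:
            per_class = os_.candidates[sp].per_class
            chosen = per_class.get(final)
            if chosen is None:
                continue
            longer = max(
                (st.length for c, (st, _) in per_class.items() if c is not final),
                default=chosen[0].length,
            )
            if longer > chosen[0].length:
                reductions.append(longer - chosen[0].length)
        if reductions:
            notes.append(
                "arm-less call shortens candidate span by up to "
                f"{max(reductions)} nt (mean {sum(reductions)/len(reductions):.1f})"
            )
    return ConsensusCall(
        identity=os_.identity,
        d_arm=flags["D"],
        t_arm=flags["T"],
        final_class=final,
        alternative=alternative,
        per_species={sp: os_.candidates[sp] for sp in species},
        low_confidence=low_confidence,
        notes=notes,
    )
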