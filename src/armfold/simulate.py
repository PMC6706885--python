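"""Truth-annotated synthetic mitogenome clades.

Builds a circular ~14-kb ancestor following a reference gene order:
random-codon PCGs (invertebrate mitochondrial code, no internal stops,
truncated stops where the planned length demands), planted tRNAs of the
four structural classes (with optional acceptor-stem degradation and
literal sequence sharing for planned gene overlaps), a control region
with a planted stem-loop + poly-A run and a duplicated motif, and a short
second non-coding region sharing that motif. Species are derived by
per-site substitution in which planted paired positions mutate
compensatorily with a configurable fraction.

The ancestor is rejection-sampled until the annotation pipeline recovers
every planted tRNA class and span: the truth label is only meaningful if
the planted structure really is the optimal fold of its own sequence in
context.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .fold import ANTICODONS, best_fold
from .gene_order import GeneOrder, reference_order
from .grammar import Arm, TrnaClass, TrnaGrammar, TrnaStructure, classify_pair
from .model import (
    PCG_GENES,
    RRNA_GENES,
    TRNA_GENES,
    AnnotatedGenome,
    GeneAnnotation,
    Genome,
    revcomp,
)
from .pipeline import annotate_trnas, fold_candidate

__all__ = [
    "CladeConfig",
    "CladeTruth",
    "PlantedTrna",
    "PlantedCR",
    "build_trna_gene",
    "generate_clade",
    "DEFAULT_CLASS_PLAN",
    "DEFAULT_OVERLAP_PLAN",
    "BLOCK73_OVERLAP_PLAN",
]

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_CANONICAL = ("AT", "TA", "GC", "CG")

# class plan mirroring the dysderid pattern: most tRNAs lack the T arm,
# two lack the D arm, four lack both
DEFAULT_CLASS_PLAN: dict[str, TrnaClass] = {
    **{t: TrnaClass.T_ARMLESS for t in (
        "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
        "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnT", "trnV", "trnW",
    )},
    "trnQ": TrnaClass.D_ARMLESS,
    "trnS2": TrnaClass.D_ARMLESS,
    "trnA": TrnaClass.ARMLESS,
    "trnR": TrnaClass.ARMLESS,
    "trnS1": TrnaClass.ARMLESS,
    "trnY": TrnaClass.ARMLESS,
}

# default: modest overlaps inside the compacted six-tRNA block (the two
# largest mirror published dysderid junctions)
DEFAULT_OVERLAP_PLAN: dict[tuple[str, str], int] = {
    ("trnN", "trnA"): 4,
    ("trnA", "trnS1"): 10,
    ("trnS1", "trnR"): 6,
    ("trnR", "trnE"): 4,
    ("trnE", "trnF"): 4,
}

# aggressive plan realizing 73 overlapping positions across the block;
# plantable only with the arm margin disabled (overlap-accounting tests)
BLOCK73_OVERLAP_PLAN: dict[tuple[str, str], int] = {
    ("trnN", "trnA"): 15,
    ("trnA", "trnS1"): 15,
    ("trnS1", "trnR"): 15,
    ("trnR", "trnE"): 14,
    ("trnE", "trnF"): 14,
}

DEFAULT_PCG_LENGTHS = {
    "nad2": 927, "cox1": 1533, "cox2": 660, "atp8": 150, "atp6": 666,
    "cox3": 789, "nad3": 336, "nad5": 1650, "nad4": 1278, "nad4L": 263,
    "nad6": 434, "cob": 1128, "nad1": 903,
}
DEFAULT_RRNA_LENGTHS = {"rrnL": 1050, "rrnS": 690}
DEFAULT_SPACER_PLAN = {("cox1", "cox2"): 17}


@dataclass(frozen=True)
class CRPlan:
    length: int = 700
    stem: int = 8
    loop: int = 6
    polya: int = 12
    dup_len: int = 79
    dup_subs: int = 3
    cr2_length: int = 90


@dataclass(frozen=True)
class CladeConfig:
    n_species: int = 6
    seed: int = 1
    gene_order: str = "dysderoidea"
    divergence: float = 0.02  # per-site substitution probability per species
    compensatory_fraction: float = 0.8
    class_plan: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PLAN))
    acceptor_mismatches: dict = field(default_factory=dict)  # identity -> count
    overlap_plan: dict = field(default_factory=lambda: dict(DEFAULT_OVERLAP_PLAN))
    spacer_plan: dict = field(default_factory=lambda: dict(DEFAULT_SPACER_PLAN))
    default_spacer: int = 2
    pcg_lengths: dict = field(default_factory=lambda: dict(DEFAULT_PCG_LENGTHS))
    rrna_lengths: dict = field(default_factory=lambda: dict(DEFAULT_RRNA_LENGTHS))
    cr: CRPlan = CRPlan()
    at_richness: float = 0.71
    max_ancestor_tries: int = 60
    # planting margin: folds with arms the planted class lacks must score
    # at least this far below the planted fold (>= the consensus
    # credibility tolerance, so zero-divergence calls are exact). None
    # disables the check (needed for extreme overlap plans).
    arm_margin: float | None = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if not 0.0 <= self.compensatory_fraction <= 1.0:
            raise ValueError("compensatory_fraction must be in [0, 1]")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")


@dataclass
class PlantedTrna:
    identity: str
    cls: TrnaClass
    span: tuple[int, int]
    strand: str
    structure: TrnaStructure
    acceptor_mismatches: int


@dataclass
class PlantedCR:
    cr_span: tuple[int, int]
    cr2_span: tuple[int, int]
    hairpin_span: tuple[int, int]  # genomic, inside CR
    polya_span: tuple[int, int]
    dup_span_a: tuple[int, int]
    dup_span_b: tuple[int, int]


@dataclass
class CladeTruth:
    config: CladeConfig
    order: GeneOrder
    ancestor: AnnotatedGenome
    species: dict[str, AnnotatedGenome]
    trnas: dict[str, PlantedTrna]
    cr: PlantedCR
    pair_map: dict[int, int]  # genomic position -> partner (both directions)
    protected: set[int]


def _rand_base(rng: random.Random, at: float = 0.7) -> str:
    if rng.random() < at:
        return rng.choice("AT")
    return rng.choice("GC")


def _rand_seq(rng: random.Random, n: int, at: float = 0.7) -> str:
    return "".join(_rand_base(rng, at) for _ in range(n))


def _rand_pair(rng: random.Random) -> str:
    return rng.choices(_CANONICAL, weights=(0.3, 0.3, 0.2, 0.2))[0]


def _mismatch_base(partner: str, rng: random.Random) -> str:
    banned = {_COMP[partner]}
    if partner == "G":
        banned.add("T")  # would be a G-T wobble, not a mismatch
    elif partner == "T":
        banned.add("G")
    return rng.choice(sorted(set("ACGT") - banned))


def _layout(cls: TrnaClass, g: TrnaGrammar, rng: random.Random):
    """Sample element sizes and return (length, arms dict)."""
    acc = g.acceptor_len
    ac_arm = g.ac_arm_len
    ri = rng.randint

    def stem_len(rng_range: tuple[int, int]) -> int:
        # plant maximal stems: a single broken pair usually leaves an
        # in-grammar substem, so the arm stays detectable after mutation
        return rng_range[1]

    def loop_len(rng_range: tuple[int, int]) -> int:
        # keep planted loops short of the cap so an inner-pair break can
        # widen the loop and still satisfy the grammar
        return ri(rng_range[0], max(rng_range[0], rng_range[1] - 2))
    if cls is TrnaClass.ARMLESS:
        c5, c3 = ri(*g.armless_conn), ri(*g.armless_conn)
        left, right = c5, c3
        d_arm = t_arm = None
    elif cls is TrnaClass.T_ARMLESS:
        c1, ds, dl, c2 = ri(*g.conn_acc_d), stem_len(g.d_stem), loop_len(g.d_loop), ri(*g.conn_d_ac)
        d_start = acc + c1
        d_arm = Arm((d_start, d_start + ds), (d_start + ds + dl, d_start + 2 * ds + dl))
        left = c1 + 2 * ds + dl + c2
        right = ri(*g.tv_replacement_loop)
        t_arm = None
    elif cls is TrnaClass.D_ARMLESS:
        left = ri(*g.d_replacement_loop)
        vl, ts, tl = ri(*g.var_loop), stem_len(g.t_stem), loop_len(g.t_loop)
        t_start = acc + left + ac_arm + vl
        t_arm = Arm((t_start, t_start + ts), (t_start + ts + tl, t_start + 2 * ts + tl))
        right = vl + 2 * ts + tl
        d_arm = None
    else:
        c1, ds, dl, c2 = ri(*g.conn_acc_d), stem_len(g.d_stem), loop_len(g.d_loop), ri(*g.conn_d_ac)
        d_start = acc + c1
        d_arm = Arm((d_start, d_start + ds), (d_start + ds + dl, d_start + 2 * ds + dl))
        left = c1 + 2 * ds + dl + c2
        vl, ts, tl = ri(*g.var_loop), stem_len(g.t_stem), loop_len(g.t_loop)
        t_start = acc + left + ac_arm + vl
        t_arm = Arm((t_start, t_start + ts), (t_start + ts + tl, t_start + 2 * ts + tl))
        right = vl + 2 * ts + tl
    length = 2 * acc + ac_arm + left + right
    ac_start = acc + left
    arms = {
        "acceptor": Arm((0, acc), (length - acc, length)),
        "ac": Arm((ac_start, ac_start + g.ac_stem_len),
                  (ac_start + ac_arm - g.ac_stem_len, ac_start + ac_arm)),
        "d": d_arm,
        "t": t_arm,
    }
    return length, arms


def build_trna_gene(
    identity: str,
    cls: TrnaClass,
    rng: random.Random,
    grammar: TrnaGrammar | None = None,
    acceptor_mismatches: int = 0,
    fixed_prefix: str = "",
    fixed_suffix: str = "",
    max_tries: int = 60,
) -> tuple[str, TrnaStructure]:
    """Sample a tRNA gene sequence whose best fold is the planted class.

    ``fixed_prefix``/``fixed_suffix`` pin gene-local bases shared with an
    overlapping neighbour. Raises if no grammar-consistent sequence
    satisfying the constraints can be found.
    """
    g = grammar or TrnaGrammar()
    if cls not in TrnaClass:
        raise ValueError(f"unknown class {cls!r}")
    if acceptor_mismatches > g.acceptor_max_mismatch:
        raise ValueError("planned acceptor mismatches exceed grammar cap")
    anticodon_choices = ANTICODONS[identity]
    for _ in range(max_tries):
        length, arms = _layout(cls, g, rng)
        if len(fixed_prefix) + len(fixed_suffix) > length - 3:
            continue
        bases: list[str | None] = [None] * length
        fixed_idx: set[int] = set()
        for i, b in enumerate(fixed_prefix):
            bases[i] = b
            fixed_idx.add(i)
        for i, b in enumerate(fixed_suffix):
            pos = length - len(fixed_suffix) + i
            bases[pos] = b
            fixed_idx.add(pos)
        # anticodon must be compatible with the constrained bases
        ac_loop_start = arms["ac"].stem5[1]
        ac_pos = ac_loop_start + g.anticodon_offset
        anticodon = None
        for cand in anticodon_choices:
            if all(bases[ac_pos + k] in (None, cand[k]) for k in range(3)):
                anticodon = cand
                break
        if anticodon is None:
            continue
        for k in range(3):
            bases[ac_pos + k] = anticodon[k]
        pair_list: list[tuple[int, int]] = []
        for name in ("acceptor", "ac", "d", "t"):
            arm = arms[name]
            if arm is not None:
                pair_list.extend(arm.pairs)
        for i, j in pair_list:
            if bases[i] is not None and bases[j] is not None:
                continue
            if bases[i] is not None:
                bases[j] = _COMP[bases[i]]
            elif bases[j] is not None:
                bases[i] = _COMP[bases[j]]
            else:
                duo = _rand_pair(rng)
                bases[i], bases[j] = duo[0], duo[1]
        # degrade the acceptor stem where the 3' base is unconstrained
        free_acc = [
            (i, j) for i, j in arms["acceptor"].pairs
            if j not in fixed_idx and classify_pair(bases[i], bases[j]) != "mismatch"
        ]
        if len(free_acc) < acceptor_mismatches:
            continue
        for i, j in rng.sample(free_acc, acceptor_mismatches):
            bases[j] = _mismatch_base(bases[i], rng)
        for i in range(length):
            if bases[i] is None:
                bases[i] = _rand_base(rng)
        seq = "".join(bases)
        structure = TrnaStructure(
            cls=cls,
            length=length,
            acceptor=arms["acceptor"],
            ac_arm=arms["ac"],
            d_arm=arms["d"],
            t_arm=arms["t"],
            anticodon=anticodon,
            span=(0, length),
            identity=identity,
        )
        result = best_fold(seq, identity, g)
        if result is not None and result[0].cls is cls:
            return seq, structure
    raise RuntimeError(
        f"could not plant {identity} as {cls} under the given constraints"
    )


_STOPS = frozenset({"TAA", "TAG"})


def _rand_codon(rng: random.Random, at: float) -> str:
    while True:
        codon = _rand_seq(rng, 3, at)
        if codon not in _STOPS:
            return codon


def build_pcg(length: int, rng: random.Random, at: float = 0.71) -> str:
    """Random-codon PCG of the exact planned length.

    Length mod 3 of 1 or 2 yields a truncated stop ("T"/"TA"); otherwise
    a full TAA/TAG stop. No internal stop codons.
    """
    rem = length % 3
    n_full = length // 3
    start = rng.choice(("ATA", "ATA", "ATG"))  # ATA-biased like AT-rich genomes
    if rem == 0:
        body = [_rand_codon(rng, at) for _ in range(n_full - 2)]
        stop = rng.choice(("TAA", "TAG"))
        return start + "".join(body) + stop
    body = [_rand_codon(rng, at) for _ in range(n_full - 1)]
    return start + "".join(body) + ("T" if rem == 1 else "TA")


def _build_hairpin(stem: int, loop: int, rng: random.Random) -> tuple[str, list[tuple[int, int]]]:
    """GC-biased stem-loop sequence and its local pair list."""
    pairs5 = [rng.choices(_CANONICAL, weights=(0.2, 0.2, 0.3, 0.3))[0] for _ in range(stem)]
    arm5 = "".join(p[0] for p in pairs5)
    arm3 = "".join(p[1] for p in reversed(pairs5))
    loop_seq = _rand_seq(rng, loop)
    seq = arm5 + loop_seq + arm3
    pair_list = [(k, 2 * stem + loop - 1 - k) for k in range(stem)]
    return seq, pair_list


def _mutate_copy(seq: str, n_subs: int, rng: random.Random) -> str:
    out = list(seq)
    for pos in rng.sample(range(len(seq)), min(n_subs, len(seq))):
        out[pos] = rng.choice(sorted(set("ACGT") - {out[pos]}))
    return "".join(out)


def _build_cr(plan: CRPlan, rng: random.Random, at: float):
    """Control-region sequence with planted hairpin, poly-A and duplicate.

    Returns (seq, local truth dict, local pair list)."""
    hairpin, hp_pairs = _build_hairpin(plan.stem, plan.loop, rng)
    lead = _rand_seq(rng, 8, at)
    unit = lead + hairpin + "A" * plan.polya
    unit += _rand_seq(rng, plan.dup_len - len(unit), at)
    copy_b = _mutate_copy(unit, plan.dup_subs, rng)
    pre_len = max(10, (plan.length - 2 * plan.dup_len - 30))
    pre = _rand_seq(rng, pre_len // 2, at)
    mid = _rand_seq(rng, 30, at)
    seq = pre + unit + mid + copy_b
    seq += _rand_seq(rng, max(0, plan.length - len(seq)), at)
    a0 = len(pre)
    hp_start = a0 + len(lead)
    truth = {
        "hairpin": (hp_start, hp_start + len(hairpin)),
        "polya": (hp_start + len(hairpin), hp_start + len(hairpin) + plan.polya),
        "dup_a": (a0, a0 + plan.dup_len),
        "dup_b": (a0 + plan.dup_len + 30, a0 + 2 * plan.dup_len + 30),
    }
    pairs = [(hp_start + i, hp_start + j) for i, j in hp_pairs]
    return seq, truth, pairs, unit


def _build_cr2(plan: CRPlan, unit: str, rng: random.Random, at: float) -> str:
    core = _mutate_copy(unit[: min(len(unit), plan.cr2_length - 10)], 4, rng)
    seq = _rand_seq(rng, 5, at) + core
    return seq + _rand_seq(rng, max(0, plan.cr2_length - len(seq)), at)


def _placement(order: GeneOrder) -> list[tuple[str, str]]:
    items: list[tuple[str, str]] = []
    for g, s in order.genes:
        if g == "trnN":
            items.append(("CR2", "+"))
        if g == "trnM":
            items.append(("CR", "+"))
        items.append((g, s))
    return items


@dataclass
class _RegionResult:
    seq: str
    features: list  # (gene, strand, start, end) region-local
    plants: list  # (PlantedTrna with region-local span)
    pairs: list  # region-local pair positions
    protected: list  # region-local protected positions
    cr_offset: int | None = None
    cr2_offset: int | None = None


def _build_region(
    cfg: CladeConfig,
    items: list[tuple[str, str]],
    prev_gene: str,
    next_gene: str,
    prev_tail: str,
    next_head: str,
    cr_seq: str,
    cr2_seq: str,
    cr_pairs: list[tuple[int, int]],
    rng: random.Random,
    grammar: TrnaGrammar,
    max_tries: int = 100,
) -> _RegionResult:
    """Fill one inter-anchor region with tRNAs/CR, verified in context.

    The region is rejection-sampled until the annotation pipeline's
    window (region plus the 50-nt pads into both flanking anchors)
    recovers every planted tRNA class and span — the truth labels are
    only meaningful when the planted fold is optimal in context.
    """
    at = cfg.at_richness
    pad = len(prev_tail)
    parts: list[str] = []
    cur = 0
    res = _RegionResult("", [], [], [], [])
    plant_item: list[int] = []  # item index of each planted tRNA
    snaps: list[tuple] = []  # state before placing each item
    idx = 0
    rounds = 0
    max_rounds = 40 * max(1, len(items))

    def snapshot() -> tuple:
        return (
            len(parts), cur, len(res.features), len(res.plants),
            len(res.pairs), len(res.protected), res.cr_offset, res.cr2_offset,
        )

    def rollback(f: int) -> None:
        nonlocal cur, idx
        (n_parts, cur_, n_feat, n_plant, n_pairs, n_prot, cr_off, cr2_off) = snaps[f]
        del parts[n_parts:]
        del res.features[n_feat:]
        del res.plants[n_plant:]
        del plant_item[n_plant:]
        del res.pairs[n_pairs:]
        del res.protected[n_prot:]
        res.cr_offset, res.cr2_offset = cr_off, cr2_off
        cur = cur_
        del snaps[f:]
        idx = f

    def place(gene: str, strand: str, pg: str) -> bool:
        """Append one item; False when tRNA planting draws ran out."""
        nonlocal cur
        overlap = cfg.overlap_plan.get((pg, gene), 0)
        if overlap == 0:
            spacer = cfg.spacer_plan.get((pg, gene), cfg.default_spacer)
            if spacer:
                parts.append(_rand_seq(rng, spacer, at))
                cur += spacer
        joined = "".join(parts)
        if overlap > len(joined):
            raise ValueError(f"overlap before {gene} exceeds region prefix")
        shared = joined[len(joined) - overlap :] if overlap else ""
        start = cur - overlap
        if gene in TRNA_GENES:
            cls = cfg.class_plan.get(gene, TrnaClass.T_ARMLESS)
            mm = cfg.acceptor_mismatches.get(gene, 0)
            try:
                if strand == "+":
                    local, structure = build_trna_gene(
                        gene, cls, rng, grammar, mm, fixed_prefix=shared
                    )
                    genomic = local
                else:
                    local, structure = build_trna_gene(
                        gene, cls, rng, grammar, mm, fixed_suffix=revcomp(shared)
                    )
                    genomic = revcomp(local)
            except RuntimeError:
                return False
            L = len(local)
            end = start + L
            to_g = (lambda i, s=start: s + i) if strand == "+" else (
                lambda i, e=end: e - 1 - i
            )
            for i, j in structure.pairs:
                res.pairs.append((to_g(i), to_g(j)))
            ac_loop = structure.ac_arm.stem5[1]
            for k in range(3):
                res.protected.append(to_g(ac_loop + grammar.anticodon_offset + k))
            res.plants.append(PlantedTrna(gene, cls, (start, end), strand, structure, mm))
            plant_item.append(idx)
            res.features.append((gene, strand, start, end))
            parts.append(genomic[overlap:])
            cur = end
        elif gene in ("CR", "CR2"):
            if overlap:
                raise ValueError(f"overlap into {gene} unsupported")
            seq = cr_seq if gene == "CR" else cr2_seq
            if gene == "CR":
                res.cr_offset = cur
                for i, j in cr_pairs:
                    res.pairs.append((cur + i, cur + j))
            else:
                res.cr2_offset = cur
            res.features.append((gene, "+", cur, cur + len(seq)))
            parts.append(seq)
            cur += len(seq)
        else:
            raise ValueError(f"non-anchor gene {gene!r} unexpected in region")
        return True

    def verify(window: str) -> int | None:
        """Item index of the first unrecoverable plant, or None."""
        wlen = len(window)
        for k, plant in enumerate(res.plants):
            ws, we = plant.span[0] + pad, plant.span[1] + pad
            if plant.strand == "+":
                oriented, espan = window, (ws, we)
            else:
                oriented, espan = revcomp(window), (wlen - we, wlen - ws)
            found = fold_candidate(oriented, plant.identity, grammar)
            if found is None:
                return plant_item[k]
            st, sc, per_class = found
            if (
                st.cls is not plant.cls
                or abs(st.span[0] - espan[0]) > 2
                or abs(st.span[1] - espan[1]) > 2
            ):
                return plant_item[k]
            if cfg.arm_margin is not None:
                # no fold carrying an arm the planted class lacks may
                # come within the credibility margin of the best score
                for cls, (_, other_sc) in per_class.items():
                    if cls is plant.cls:
                        continue
                    extra_arm = (cls.has_d_arm and not plant.cls.has_d_arm) or (
                        cls.has_t_arm and not plant.cls.has_t_arm
                    )
                    if extra_arm and other_sc.score >= sc.score - cfg.arm_margin:
                        return plant_item[k]
        return None

    fail_counts = [0] * len(items)
    while True:
        fail_at: int | None = None
        while idx < len(items):
            snaps.append(snapshot())
            pg = items[idx - 1][0] if idx > 0 else prev_gene
            if not place(*items[idx], pg):
                fail_at = idx
                snaps.pop()
                break
            idx += 1
        if fail_at is None:
            trailing_len = cfg.spacer_plan.get(
                (items[-1][0], next_gene), cfg.default_spacer
            )
            trailing = _rand_seq(rng, trailing_len, at)
            region_seq = "".join(parts) + trailing
            fail_at = verify(prev_tail + region_seq + next_head)
            if fail_at is None:
                res.seq = region_seq
                return res
        rounds += 1
        if rounds > max_rounds:
            raise RuntimeError(
                f"region {prev_gene}->{next_gene} not plantable in {rounds} rounds"
            )
        # redraw from the first offending item, keeping earlier genes;
        # when one item keeps failing its upstream context is to blame,
        # so escalate the rollback one gene further back
        fail_counts[fail_at] += 1
        while fail_at > 0 and fail_counts[fail_at] > 6:
            fail_counts[fail_at] = 0
            fail_at -= 1
            fail_counts[fail_at] += 1
        rollback(fail_at)


def _assemble_ancestor(cfg: CladeConfig, order: GeneOrder, rng: random.Random):
    grammar = TrnaGrammar()
    at = cfg.at_richness
    # build both non-coding regions up front so CR2 shares the CR's
    # duplicated unit regardless of their order on the circle
    cr_seq, cr_truth_local, cr_pairs, cr_unit = _build_cr(cfg.cr, rng, at)
    cr2_seq = _build_cr2(cfg.cr, cr_unit, rng, at)

    placement = _placement(order)
    anchor_set = set(PCG_GENES) | set(RRNA_GENES)
    if placement[0][0] not in anchor_set:
        raise ValueError("gene order must start at an anchor (PCG/rRNA) gene")

    # phase 1: pre-generate every anchor gene's genomic sequence
    anchor_seqs: dict[str, str] = {}
    for gene, strand in placement:
        if gene in PCG_GENES:
            local = build_pcg(cfg.pcg_lengths[gene], rng, at)
            anchor_seqs[gene] = local if strand == "+" else revcomp(local)
        elif gene in RRNA_GENES:
            anchor_seqs[gene] = _rand_seq(rng, cfg.rrna_lengths[gene], at)

    # phase 2: walk the circle, filling inter-anchor regions with
    # context-verified plantings
    parts: list[str] = []
    cur = 0
    features: list[GeneAnnotation] = []
    trnas: dict[str, PlantedTrna] = {}
    pair_map: dict[int, int] = {}
    protected: set[int] = set()
    first_anchor = placement[0][0]
    pad = 50

    def flush_region(pending: list, prev_gene: str, next_gene: str) -> None:
        nonlocal cur
        prev_tail = anchor_seqs[prev_gene][-pad:]
        next_head = anchor_seqs[next_gene][:pad]
        res = _build_region(
            cfg, pending, prev_gene, next_gene, prev_tail, next_head,
            cr_seq, cr2_seq, cr_pairs, rng, grammar,
        )
        base = cur
        for gene, strand, s, e in res.features:
            features.append(GeneAnnotation(start=base + s, end=base + e, gene=gene, strand=strand))
        for plant in res.plants:
            trnas[plant.identity] = PlantedTrna(
                plant.identity, plant.cls,
                (base + plant.span[0], base + plant.span[1]),
                plant.strand, plant.structure, plant.acceptor_mismatches,
            )
        for i, j in res.pairs:
            gi, gj = base + i, base + j
            for pos, partner in ((gi, gj), (gj, gi)):
                old = pair_map.get(pos)
                if old is not None and old != partner:
                    # base shared by two overlapping stems: freeze the
                    # whole constraint cluster against mutation
                    protected.update((pos, partner, old))
                pair_map[pos] = partner
        protected.update(base + p for p in res.protected)
        parts.append(res.seq)
        cur += len(res.seq)

    pending: list[tuple[str, str]] = []
    prev_anchor = None
    for gene, strand in placement:
        if gene in anchor_set:
            if pending:
                flush_region(pending, prev_anchor, gene)
                pending = []
            elif prev_anchor is not None:
                spacer = cfg.spacer_plan.get((prev_anchor, gene), cfg.default_spacer)
                if spacer:
                    parts.append(_rand_seq(rng, spacer, at))
                    cur += spacer
            seq = anchor_seqs[gene]
            L = len(seq)
            if gene in PCG_GENES:  # protect start codon and stop text
                stop_len = 3 if L % 3 == 0 else L % 3
                if strand == "+":
                    protected.update(range(cur, cur + 3))
                    protected.update(range(cur + L - stop_len, cur + L))
                else:
                    protected.update(range(cur + L - 3, cur + L))
                    protected.update(range(cur, cur + stop_len))
            features.append(GeneAnnotation(start=cur, end=cur + L, gene=gene, strand=strand))
            parts.append(seq)
            cur += L
            prev_anchor = gene
        else:
            pending.append((gene, strand))
    if pending:
        flush_region(pending, prev_anchor, first_anchor)

    sequence = "".join(parts)
    cr_feat = next(f for f in features if f.gene == "CR")
    cr2_feat = next(f for f in features if f.gene == "CR2")
    cr_off = cr_feat.start
    planted_cr = PlantedCR(
        cr_span=(cr_feat.start, cr_feat.end),
        cr2_span=(cr2_feat.start, cr2_feat.end),
        hairpin_span=(cr_truth_local["hairpin"][0] + cr_off, cr_truth_local["hairpin"][1] + cr_off),
        polya_span=(cr_truth_local["polya"][0] + cr_off, cr_truth_local["polya"][1] + cr_off),
        dup_span_a=(cr_truth_local["dup_a"][0] + cr_off, cr_truth_local["dup_a"][1] + cr_off),
        dup_span_b=(cr_truth_local["dup_b"][0] + cr_off, cr_truth_local["dup_b"][1] + cr_off),
    )
    genome = Genome("sim_ancestor", sequence, circular=True)
    return AnnotatedGenome(genome, features), trnas, planted_cr, pair_map, protected


def _recovers_truth(ag: AnnotatedGenome, order: GeneOrder, trnas: dict[str, PlantedTrna],
                    end_tol: int = 2) -> bool:
    hits = annotate_trnas(ag, order)
    for identity, planted in trnas.items():
        hit = hits.get(identity)
        if hit is None or hit.structure.cls is not planted.cls:
            return False
        if hit.strand != planted.strand:
            return False
        (s, e), (ps, pe) = hit.genomic_span, planted.span
        if abs(s - ps) > end_tol or abs(e - pe) > end_tol:
            return False
    return True


def _mutate_species(
    ancestor: AnnotatedGenome,
    species_id: str,
    cfg: CladeConfig,
    pair_map: dict[int, int],
    protected: set[int],
    rng: random.Random,
) -> AnnotatedGenome:
    seq = list(ancestor.genome.sequence)
    n = len(seq)
    handled: set[int] = set()
    for pos in range(n):
        if pos in protected or pos in handled:
            continue
        if rng.random() >= cfg.divergence:
            continue
        partner = pair_map.get(pos)
        if partner is not None and pair_map.get(partner) != pos:
            # base shared by two overlapping stems: hold it invariant so
            # compensatory resampling cannot break the other gene's pair
            continue
        duo = seq[pos] + seq[partner] if partner is not None else ""
        if (
            partner is not None
            and partner not in protected
            and (duo in _CANONICAL or duo in ("GT", "TG"))
            and rng.random() < cfg.compensatory_fraction
        ):
            new = rng.choice([p for p in _CANONICAL if p != duo])
            seq[pos], seq[partner] = new[0], new[1]
            handled.add(partner)
        else:
            seq[pos] = rng.choice(sorted(set("ACGT") - {seq[pos]}))
    genome = Genome(species_id, "".join(seq), circular=True)
    return AnnotatedGenome(genome, list(ancestor.features))


def generate_clade(cfg: CladeConfig) -> CladeTruth:
    """Generate a clade of species diverged from one planted ancestor.

    Fully deterministic under a fixed config (including seed). Species
    share the ancestor's coordinates (substitutions only, no indels).
    """
    order = reference_order(cfg.gene_order) if isinstance(cfg.gene_order, str) else cfg.gene_order
    rng = random.Random(cfg.seed)
    last_error = None
    for attempt in range(cfg.max_ancestor_tries):
        try:
            ancestor, trnas, planted_cr, pair_map, protected = _assemble_ancestor(
                cfg, order, rng
            )
        except RuntimeError as exc:  # infeasible planting draw; resample
            last_error = exc
            continue
        if _recovers_truth(ancestor, order, trnas):
            break
    else:
        raise RuntimeError(
            f"no recoverable ancestor in {cfg.max_ancestor_tries} tries: {last_error}"
        )
    species = {}
    for k in range(cfg.n_species):
        sid = f"sp{k + 1}"
        species[sid] = _mutate_species(ancestor, sid, cfg, pair_map, protected, rng)
    return CladeTruth(
        config=cfg,
        order=order,
        ancestor=ancestor,
        species=species,
        trnas=trnas,
        cr=planted_cr,
        pair_map=pair_map,
        protected=protected,
    )
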