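"""Explicit secondary-structure grammar for degenerate mitochondrial tRNAs.

Four structural classes are modelled: the canonical cloverleaf, the two
single-arm-lacking forms (D-armless, T-armless) and the fully arm-less
form reduced to acceptor stem + anticodon arm. Pairing is evaluated at
the DNA level: A·T and G·C are canonical, G·T is the wobble pair, and
anything else is a mismatch. Mismatches are tolerated (and counted) only
in the acceptor stem unless explicitly relaxed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

__all__ = [
    "TrnaClass",
    "TrnaGrammar",
    "ScoringWeights",
    "FoldScore",
    "Arm",
    "TrnaStructure",
    "classify_pair",
    "validate_structure",
]

CANONICAL_PAIRS = frozenset({"AT", "TA", "GC", "CG"})
WOBBLE_PAIRS = frozenset({"GT", "TG"})


def classify_pair(a: str, b: str) -> str:
    """Classify a candidate base pair: 'canonical', 'gu' or 'mismatch'."""
    duo = a + b
    if duo in CANONICAL_PAIRS:
        return "canonical"
    if duo in WOBBLE_PAIRS:
        return "gu"
    return "mismatch"


class TrnaClass(enum.Enum):
    CLOVERLEAF = "CLOVERLEAF"
    D_ARMLESS = "D_ARMLESS"
    T_ARMLESS = "T_ARMLESS"
    ARMLESS = "ARMLESS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def has_d_arm(self) -> bool:
        return self in (TrnaClass.CLOVERLEAF, TrnaClass.T_ARMLESS)

    @property
    def has_t_arm(self) -> bool:
        return self in (TrnaClass.CLOVERLEAF, TrnaClass.D_ARMLESS)


@dataclass(frozen=True)
class TrnaGrammar:
    """Inclusive size ranges for every structural element.

    Replacement-loop ranges for the single-arm-lacking classes are not
    pinned by the source material; the defaults below span the canonical
    connector totals and are configurable.
    """

    acceptor_len: int = 7
    acceptor_max_mismatch: int = 4
    ac_stem_len: int = 5
    ac_stem_max_gu: int = 1
    ac_stem_max_mismatch: int = 0  # relax via flag only
    ac_loop_len: int = 7
    anticodon_offset: int = 2  # anticodon at loop positions 2-4 (0-based)
    d_stem: tuple[int, int] = (3, 4)
    d_loop: tuple[int, int] = (3, 9)
    t_stem: tuple[int, int] = (3, 5)
    t_loop: tuple[int, int] = (3, 9)
    # mismatches in side (D/T) stems are disallowed by default (they are
    # rare in practice); raising this relaxes the rule, scored per mismatch
    side_stem_max_mismatch: int = 0
    conn_acc_d: tuple[int, int] = (1, 3)  # canonical 2
    conn_d_ac: tuple[int, int] = (1, 2)  # canonical 1
    var_loop: tuple[int, int] = (2, 9)
    armless_conn: tuple[int, int] = (0, 4)
    d_replacement_loop: tuple[int, int] = (2, 12)
    tv_replacement_loop: tuple[int, int] = (2, 12)

    @property
    def ac_arm_len(self) -> int:
        return 2 * self.ac_stem_len + self.ac_loop_len

    def min_length(self, cls: TrnaClass) -> int:
        core = 2 * self.acceptor_len + self.ac_arm_len
        if cls is TrnaClass.ARMLESS:
            return core + 2 * self.armless_conn[0]
        d_block = self.conn_acc_d[0] + 2 * self.d_stem[0] + self.d_loop[0] + self.conn_d_ac[0]
        t_block = self.var_loop[0] + 2 * self.t_stem[0] + self.t_loop[0]
        if cls is TrnaClass.T_ARMLESS:
            return core + d_block + self.tv_replacement_loop[0]
        if cls is TrnaClass.D_ARMLESS:
            return core + self.d_replacement_loop[0] + t_block
        return core + d_block + t_block


@dataclass(frozen=True)
class ScoringWeights:
    canonical: float = 1.0
    gu: float = 0.5
    mismatch: float = -1.0


@dataclass(frozen=True)
class FoldScore:
    canonical_pairs: int
    gu_pairs: int
    mismatches: int
    weights: ScoringWeights = field(default=ScoringWeights(), compare=False)

    @property
    def score(self) -> float:
        w = self.weights
        return (
            w.canonical * self.canonical_pairs
            + w.gu * self.gu_pairs
            + w.mismatch * self.mismatches
        )

    def __add__(self, other: "FoldScore") -> "FoldScore":
        return FoldScore(
            self.canonical_pairs + other.canonical_pairs,
            self.gu_pairs + other.gu_pairs,
            self.mismatches + other.mismatches,
            self.weights,
        )


@dataclass(frozen=True)
class Arm:
    """A stem (possibly with enclosed loop) in structure-local coordinates.

    ``stem5``/``stem3`` are half-open spans of the two stem strands; the
    loop (if any) lies between them.
    """

    stem5: tuple[int, int]
    stem3: tuple[int, int]

    @property
    def stem_len(self) -> int:
        return self.stem5[1] - self.stem5[0]

    @property
    def loop_len(self) -> int:
        return self.stem3[0] - self.stem5[1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.stem5[0], self.stem3[1])

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [
            (self.stem5[0] + k, self.stem3[1] - 1 - k) for k in range(self.stem_len)
        ]


@dataclass(frozen=True)
class TrnaStructure:
    """A folded tRNA candidate in structure-local coordinates.

    ``span`` locates the structure inside the search window (strand
    orientation is carried by the window).
    """

    cls: TrnaClass
    length: int
    acceptor: Arm
    ac_arm: Arm
    d_arm: Arm | None
    t_arm: Arm | None
    anticodon: str
    span: tuple[int, int]
    identity: str | None = None

    @property
    def pairs(self) -> frozenset[tuple[int, int]]:
        out = list(self.acceptor.pairs) + list(self.ac_arm.pairs)
        for arm in (self.d_arm, self.t_arm):
            if arm is not None:
                out.extend(arm.pairs)
        return frozenset(out)

    @property
    def arms_present(self) -> dict[str, bool]:
        return {"D": self.d_arm is not None, "T": self.t_arm is not None}

    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)

    def with_identity(self, identity: str) -> "TrnaStructure":
        return replace(self, identity=identity)


def _check_range(name: str, value: int, rng: tuple[int, int], errors: list[str]) -> None:
    if not rng[0] <= value <= rng[1]:
        errors.append(f"{name} {value} outside [{rng[0]}, {rng[1]}]")


def validate_structure(
    structure: TrnaStructure, seq: str, grammar: TrnaGrammar | None = None
) -> list[str]:
    """Machine-check a structure against the grammar; returns violations."""
    g = grammar or TrnaGrammar()
    errors: list[str] = []
    s = structure

    if s.span[1] - s.span[0] != s.length:
        errors.append("span length disagrees with structure length")
    local = seq[s.span[0] : s.span[1]]

    # pair list: i < j, no index reuse, nested
    pairs = sorted(s.pairs)
    used: set[int] = set()
    for i, j in pairs:
        if not 0 <= i < j < s.length:
            errors.append(f"pair ({i},{j}) out of bounds")
        if i in used or j in used:
            errors.append(f"index reused in pair ({i},{j})")
        used.update((i, j))
    for i, j in pairs:
        for k, l in pairs:
            if i < k < j < l:
                errors.append(f"pseudoknot: ({i},{j}) crosses ({k},{l})")

    if s.acceptor.stem_len != g.acceptor_len:
        errors.append(f"acceptor stem {s.acceptor.stem_len} != {g.acceptor_len}")
    acc_mm = sum(
        1 for i, j in s.acceptor.pairs if classify_pair(local[i], local[j]) == "mismatch"
    )
    if acc_mm > g.acceptor_max_mismatch:
        errors.append(f"acceptor mismatches {acc_mm} > {g.acceptor_max_mismatch}")

    if s.ac_arm.stem_len != g.ac_stem_len:
        errors.append(f"anticodon stem {s.ac_arm.stem_len} != {g.ac_stem_len}")
    if s.ac_arm.loop_len != g.ac_loop_len:
        errors.append(f"anticodon loop {s.ac_arm.loop_len} != {g.ac_loop_len}")
    kinds = [classify_pair(local[i], local[j]) for i, j in s.ac_arm.pairs]
    if kinds.count("gu") > g.ac_stem_max_gu:
        errors.append("too many G-U pairs in anticodon stem")
    if kinds.count("mismatch") > g.ac_stem_max_mismatch:
        errors.append("mismatch in anticodon stem")
    loop_start = s.ac_arm.stem5[1]
    anticodon = local[loop_start + g.anticodon_offset : loop_start + g.anticodon_offset + 3]
    if anticodon != s.anticodon:
        errors.append(f"anticodon {s.anticodon} not at loop positions 2-4 ({anticodon})")

    if s.cls.has_d_arm != (s.d_arm is not None):
        errors.append(f"class {s.cls} vs D-arm presence mismatch")
    if s.cls.has_t_arm != (s.t_arm is not None):
        errors.append(f"class {s.cls} vs T-arm presence mismatch")

    if s.d_arm is not None:
        _check_range("D stem", s.d_arm.stem_len, g.d_stem, errors)
        _check_range("D loop", s.d_arm.loop_len, g.d_loop, errors)
        d_mm = sum(
            1 for i, j in s.d_arm.pairs if classify_pair(local[i], local[j]) == "mismatch"
        )
        if d_mm > g.side_stem_max_mismatch:
            errors.append(f"{d_mm} mismatches in D stem > {g.side_stem_max_mismatch}")
    if s.t_arm is not None:
        _check_range("T stem", s.t_arm.stem_len, g.t_stem, errors)
        _check_range("T loop", s.t_arm.loop_len, g.t_loop, errors)
        t_mm = sum(
            1 for i, j in s.t_arm.pairs if classify_pair(local[i], local[j]) == "mismatch"
        )
        if t_mm > g.side_stem_max_mismatch:
            errors.append(f"{t_mm} mismatches in T stem > {g.side_stem_max_mismatch}")

    # connector ranges
    acc5_end = s.acceptor.stem5[1]
    ac_start, ac_end = s.ac_arm.span
    acc3_start = s.acceptor.stem3[0]
    if s.cls is TrnaClass.ARMLESS:
        _check_range("5' connector", ac_start - acc5_end, g.armless_conn, errors)
        _check_range("3' connector", acc3_start - ac_end, g.armless_conn, errors)
    if s.d_arm is not None:
        _check_range("acceptor-D connector", s.d_arm.span[0] - acc5_end, g.conn_acc_d, errors)
        _check_range("D-anticodon connector", ac_start - s.d_arm.span[1], g.conn_d_ac, errors)
    elif s.cls is TrnaClass.D_ARMLESS:
        _check_range("D replacement loop", ac_start - acc5_end, g.d_replacement_loop, errors)
    if s.t_arm is not None:
        _check_range("variable loop", s.t_arm.span[0] - ac_end, g.var_loop, errors)
        if acc3_start != s.t_arm.span[1]:
            errors.append("T arm not adjacent to acceptor 3' strand")
    elif s.cls is TrnaClass.T_ARMLESS:
        _check_range("TV replacement loop", acc3_start - ac_end, g.tv_replacement_loop, errors)
    return errors
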