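"""Signed circular gene orders: strand counts and single-gene-event diffs.

Orders are equal up to rotation but NOT reflection — strand labels on a
mitogenome are meaningful. Diffs greedily decompose the difference into
single-gene transpositions and/or in-place inversions via the longest
common circular subsequence (signs respected).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "GeneOrder",
    "RearrangementDiff",
    "strand_counts",
    "diff_orders",
    "load_reference_orders",
    "reference_order",
]

SignedGene = tuple[str, str]  # (gene, '+'/'-')


@dataclass(frozen=True)
class GeneOrder:
    name: str
    genes: tuple[SignedGene, ...]

    def __post_init__(self) -> None:
        labels = [g for g, _ in self.genes]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{self.name}: duplicate gene labels")

    @classmethod
    def parse(cls, name: str, text: str) -> "GeneOrder":
        genes = []
        for token in text.split(","):
            token = token.strip()
            if token.startswith("-"):
                genes.append((token[1:], "-"))
            else:
                genes.append((token.lstrip("+"), "+"))
        return cls(name, tuple(genes))

    def __str__(self) -> str:
        return ",".join(("-" if s == "-" else "") + g for g, s in self.genes)

    def rotated(self, k: int) -> "GeneOrder":
        k %= len(self.genes)
        return GeneOrder(self.name, self.genes[k:] + self.genes[:k])

    def rotations(self):
        for k in range(len(self.genes)):
            yield self.rotated(k)

    def equal_up_to_rotation(self, other: "GeneOrder") -> bool:
        return any(r.genes == other.genes for r in self.rotations())

    def negated(self) -> "GeneOrder":
        return GeneOrder(self.name, tuple((g, "+" if s == "-" else "-") for g, s in self.genes))


def strand_counts(order: GeneOrder) -> tuple[int, int]:
    """(plus, minus) gene counts."""
    if not order.genes:
        raise ValueError("empty gene order")
    plus = sum(1 for _, s in order.genes if s == "+")
    return plus, len(order.genes) - plus


@dataclass(frozen=True)
class RearrangementDiff:
    moved: tuple[tuple[str, str], ...]  # (gene, event)
    unexplained: bool = False

    @property
    def is_empty(self) -> bool:
        return not self.moved and not self.unexplained


def _lcs_keep(a: list[SignedGene], b: list[SignedGene]) -> set[str]:
    """Gene labels in one longest common subsequence of two linear orders."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                dp[i][j] = dp[i + 1][j + 1] + 1
            else:
                dp[i][j] = max(dp[i + 1][j], dp[i][j + 1])
    keep: set[str] = set()
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            keep.add(a[i][0])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return keep


def _circular_lcs_keep(a: GeneOrder, b: GeneOrder) -> set[str]:
    """Best LCS over all relative rotations (both orders circular)."""
    best: set[str] = set()
    a_list = list(a.genes)
    for rot in b.rotations():
        keep = _lcs_keep(a_list, list(rot.genes))
        if len(keep) > len(best):
            best = keep
    return best


def _pred_in_keep(order: GeneOrder, gene: str, keep: set[str]) -> str | None:
    labels = [g for g, _ in order.genes]
    idx = labels.index(gene)
    n = len(labels)
    for d in range(1, n):
        cand = labels[(idx - d) % n]
        if cand in keep:
            return cand
    return None


def diff_orders(a: GeneOrder, b: GeneOrder, max_events: int = 5) -> RearrangementDiff:
    """Greedy single-gene event decomposition of b relative to a.

    Genes outside the longest common circular subsequence are events: a
    sign flip with unchanged circular position is an inversion, a position
    change with unchanged sign a transposition, both combined a
    transposition+inversion. More than ``max_events`` events sets
    ``unexplained``.
    """
    labels_a = {g for g, _ in a.genes}
    labels_b = {g for g, _ in b.genes}
    if labels_a != labels_b:
        raise ValueError("gene label sets differ")
    if a.equal_up_to_rotation(b):
        return RearrangementDiff(())
    keep = _circular_lcs_keep(a, b)
    signs_a = dict(a.genes)
    signs_b = dict(b.genes)
    moved = []
    for gene in sorted(labels_a - keep):
        flipped = signs_a[gene] != signs_b[gene]
        in_place = (
            _pred_in_keep(a, gene, keep) == _pred_in_keep(b, gene, keep)
        )
        if flipped and in_place:
            event = "inversion"
        elif flipped:
            event = "transposition+inversion"
        else:
            event = "transposition"
        moved.append((gene, event))
    return RearrangementDiff(tuple(moved), unexplained=len(moved) > max_events)


def load_reference_orders(path=None) -> dict[str, GeneOrder]:
    """Reference gene-order fixtures shipped with the package."""
    if path is None:
        text = resources.files("armfold.data").joinpath("gene_orders.txt").read_text()
    else:
        text = Path(path).read_text()
    orders = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, genes = line.partition(":")
        orders[name.strip()] = GeneOrder.parse(name.strip(), genes)
    return orders


def reference_order(name: str) -> GeneOrder:
    orders = load_reference_orders()
    if name not in orders:
        raise KeyError(f"unknown reference order {name!r}; have {sorted(orders)}")
    return orders[name]
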