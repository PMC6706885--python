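"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (exhaustive enumeration, regex,
textbook DP) kept separate from the package code paths they check.
"""

from __future__ import annotations

import re

COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
CANONICAL = {"AT", "TA", "GC", "CG"}
WOBBLE = {"GT", "TG"}


def pair_kind(a: str, b: str) -> str:
    duo = a + b
    if duo in CANONICAL:
        return "canonical"
    if duo in WOBBLE:
        return "gu"
    return "mismatch"


def _stem_counts(seq, positions):
    canon = gu = mm = 0
    for i, j in positions:
        kind = pair_kind(seq[i], seq[j])
        canon += kind == "canonical"
        gu += kind == "gu"
        mm += kind == "mismatch"
    return canon, gu, mm


def _score(canon, gu, mm):
    return canon + 0.5 * gu - mm


def _acc_pairs(a5, a3, L=7):
    return [(a5 + k, a3 + L - 1 - k) for k in range(L)]


def _hairpin_pairs(start, stem, loop):
    n = 2 * stem + loop
    return [(start + k, start + n - 1 - k) for k in range(stem)]


def brute_force_anchor_scores(seq: str, anchor: int) -> dict[str, float]:
    """Best score per structural class at one anticodon-arm anchor,
    by exhaustive enumeration of every grammar-consistent layout.

    Grammar constants are written out literally on purpose.
    """
    n = len(seq)
    # anticodon arm must itself be valid: 5 pairs, <=1 GU, 0 mismatches
    ac_pairs = [(anchor + k, anchor + 16 - k) for k in range(5)]
    if anchor < 0 or anchor + 17 > n:
        return {}
    canon, gu, mm = _stem_counts(seq, ac_pairs)
    if mm > 0 or gu > 1:
        return {}
    ac_score = _score(canon, gu, 0)
    ac_end = anchor + 17
    best: dict[str, float] = {}

    def acceptor(a5, a3):
        if a5 < 0 or a3 + 7 > n:
            return None
        c, g, m = _stem_counts(seq, _acc_pairs(a5, a3))
        if m > 4:
            return None
        return _score(c, g, m)

    def consider(cls, score):
        if cls not in best or score > best[cls]:
            best[cls] = score

    # ARMLESS: connectors 0-4 each side
    for c5 in range(0, 5):
        for c3 in range(0, 5):
            acc = acceptor(anchor - c5 - 7, ac_end + c3)
            if acc is not None:
                consider("ARMLESS", acc + ac_score)

    def d_arm_options():
        # (extent, arm score); mismatches beyond the default cap (0) skip
        for c1 in range(1, 4):
            for ds in range(3, 5):
                for dl in range(3, 10):
                    for c2 in range(1, 3):
                        start = anchor - c2 - (2 * ds + dl)
                        if start < 0:
                            continue
                        c, g, m = _stem_counts(seq, _hairpin_pairs(start, ds, dl))
                        if m > 0:
                            continue
                        yield c1 + 2 * ds + dl + c2, _score(c, g, m)

    def t_arm_options():
        for vl in range(2, 10):
            for ts in range(3, 6):
                for tl in range(3, 10):
                    start = ac_end + vl
                    if start + 2 * ts + tl > n:
                        continue
                    c, g, m = _stem_counts(seq, _hairpin_pairs(start, ts, tl))
                    if m > 0:
                        continue
                    yield vl + 2 * ts + tl, _score(c, g, m)

    d_opts = list(d_arm_options())
    t_opts = list(t_arm_options())

    for ext, d_score in d_opts:  # T_ARMLESS: D arm + TV loop 2-12
        for tv in range(2, 13):
            acc = acceptor(anchor - ext - 7, ac_end + tv)
            if acc is not None:
                consider("T_ARMLESS", acc + ac_score + d_score)
    for drepl in range(2, 13):  # D_ARMLESS: D replacement loop 2-12
        for ext, t_score in t_opts:
            acc = acceptor(anchor - drepl - 7, ac_end + ext)
            if acc is not None:
                consider("D_ARMLESS", acc + ac_score + t_score)
    for d_ext, d_score in d_opts:
        for t_ext, t_score in t_opts:
            acc = acceptor(anchor - d_ext - 7, ac_end + t_ext)
            if acc is not None:
                consider("CLOVERLEAF", acc + ac_score + d_score + t_score)
    return best


def brute_force_anchors(seq: str, anticodons=None) -> list[int]:
    """All valid anticodon-arm anchor positions, checked naively."""
    out = []
    for a in range(len(seq) - 16):
        if anticodons is not None and seq[a + 7 : a + 10] not in anticodons:
            continue
        pairs = [(a + k, a + 16 - k) for k in range(5)]
        canon, gu, mm = _stem_counts(seq, pairs)
        if mm == 0 and gu <= 1:
            out.append(a)
    return out


def brute_force_stem_loops(
    seq: str,
    min_stem: int = 6,
    max_loop: int = 20,
    max_mismatch: int = 1,
    min_loop: int = 3,
    allow_gu: bool = False,
) -> set[tuple[int, int, int]]:
    """All maximal inverted repeats as (start, stem, loop), O(n^3)."""
    n = len(seq)
    # precomputed complement of each base; a pair matches when
    # seq[x] == want[y] (plus the G/T cases when allow_gu)
    want = [COMP.get(c, "?") for c in seq]

    def comp(x, y):
        if seq[x] == want[y]:
            return True
        return allow_gu and seq[x] + seq[y] in WOBBLE

    found = set()
    for i in range(n):
        for loop in range(min_loop, max_loop + 1):
            for L in range(min_stem, (n - i - loop) // 2 + 1):
                e = i + 2 * L + loop
                if not comp(i, e - 1):
                    continue  # outermost pair must match
                mm = 0
                ok = True
                for k in range(1, L):
                    if not comp(i + k, e - 1 - k):
                        mm += 1
                        if mm > max_mismatch:
                            ok = False
                            break
                if not ok or not comp(i + L - 1, e - L):
                    continue  # mismatch budget / innermost pair
                outward = i > 0 and e < n and comp(i - 1, e)
                inward = loop - 2 >= min_loop and comp(i + L, e - 1 - L)
                if not outward and not inward:
                    found.add((i, L, loop))
    return found


def regex_homopolymer_runs(seq: str, base: str, min_len: int) -> list[tuple[int, int]]:
    return [
        (m.start(), m.end())
        for m in re.finditer(f"{base}{{{min_len},}}", seq)
    ]


def nw_affine(a: str, b: str, match=1, mismatch=-1, open_=-2, extend=-1):
    """Textbook affine-gap global alignment score (Gotoh)."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend, X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


def codon_position_bases(seq: str, position: int) -> str:
    """Bases at codon position 1/2/3 by explicit frame walk."""
    out = []
    for idx in range(0, len(seq) - len(seq) % 3, 3):
        out.append(seq[idx + position - 1])
    return "".join(out)
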