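"""Fixed-structure nearest-neighbor free-energy evaluation for RNA hairpins.

Evaluates the standard free energy (kcal/mol, 37 C) of a *given* secondary
structure — a pairing map over a sequence — rather than folding freely.
The model is the published Turner-style nearest-neighbor decomposition:
stacking terms for adjacent base pairs, length-dependent initiation
penalties for hairpin loops, bulges and internal loops (with an asymmetry
term), a terminal AU/GU helix-end penalty, and a simple affine multiloop
term.  Sequence-dependent loop terminal-mismatch bonuses are approximated
by their typical magnitudes, which keeps the evaluator a small pure
function; agreement with a full reference implementation is within the
couple-of-kcal range that matters for thresholding candidate hairpins.

An empty pairing map evaluates to exactly 0.0.
"""

from __future__ import annotations

import math

__all__ = ["StructureError", "evaluate", "pairs_from_dot_bracket",
           "normalize_hairpins"]

_RT37 = 0.6163  # kcal/mol at 37 C

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

# Watson-Crick nearest-neighbor stacks (Xia et al. 1998), kcal/mol at 37 C.
# Key: ((5' base of outer pair, its partner), (5' base of inner pair, its partner)).
_STACK_BASE: dict[tuple[tuple[str, str], tuple[str, str]], float] = {
    (("A", "U"), ("A", "U")): -0.93,
    (("A", "U"), ("U", "A")): -1.10,
    (("U", "A"), ("A", "U")): -1.33,
    (("C", "G"), ("U", "A")): -2.08,
    (("C", "G"), ("A", "U")): -2.11,
    (("G", "C"), ("U", "A")): -2.24,
    (("G", "C"), ("A", "U")): -2.35,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("G", "C")): -3.26,
    (("G", "C"), ("C", "G")): -3.42,
    # G.U wobble stacks (Mathews et al. 1999 / Turner 2004)
    (("A", "U"), ("G", "U")): -0.55,
    (("A", "U"), ("U", "G")): -1.36,
    (("C", "G"), ("G", "U")): -1.41,
    (("C", "G"), ("U", "G")): -2.11,
    (("G", "C"), ("G", "U")): -1.53,
    (("G", "C"), ("U", "G")): -2.51,
    (("G", "U"), ("G", "U")): -0.25,
    (("G", "U"), ("U", "G")): +1.29,
    (("U", "A"), ("G", "U")): -1.27,
    (("U", "A"), ("U", "G")): -1.00,
    (("U", "G"), ("G", "U")): +0.30,
}


def _full_stack_table() -> dict:
    """Complete the table by the strand-flip symmetry stack(p,q)=stack(q',p')."""
    table = dict(_STACK_BASE)
    for (p, q), v in list(_STACK_BASE.items()):
        flipped = ((q[1], q[0]), (p[1], p[0]))
        table.setdefault(flipped, v)
    return table


_STACK = _full_stack_table()

# Hairpin-loop initiation by size (Turner 2004); extrapolated beyond 9.
_HAIRPIN_INIT = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
# Bulge initiation by size; stacking continues across a single-nucleotide bulge.
_BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
# Internal-loop initiation by total size (n1+n2 >= 2).
_INTERNAL_INIT = {2: 1.5, 3: 2.2, 4: 1.1, 5: 2.0, 6: 1.9, 7: 2.1, 8: 2.3, 9: 2.4}
_INTERNAL_ASYM = 0.6       # per unpaired-count difference, capped
_INTERNAL_ASYM_MAX = 3.0
_INTERNAL_MISMATCH = -0.8  # generic terminal-mismatch bonus per side, loops of size >= 5
_HAIRPIN_MISMATCH_GC = -1.5  # first-mismatch bonus, hairpin closed by G-C/C-G
_HAIRPIN_MISMATCH = -0.8     # first-mismatch bonus, other closing pairs
_TERMINAL_AU = 0.45        # helix end closed by AU/UA/GU/UG
_ML_INIT = 3.4             # multiloop closing
_ML_BRANCH = 0.4


class StructureError(ValueError):
    """Raised for pairing maps that are not a valid nested structure."""


def _loop_extrapolate(init_table: dict[int, float], size: int) -> float:
    mx = max(init_table)
    if size <= mx:
        return init_table[size]
    return init_table[mx] + 1.75 * _RT37 * math.log(size / mx)


def pairs_from_dot_bracket(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at {i}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise StructureError(f"illegal character {c!r} at {i}")
    if stack:
        raise StructureError(f"unbalanced '(' at {stack[-1]}")
    return sorted(pairs)


def normalize_hairpins(pairs) -> list[tuple[int, int]]:
    """Unpair innermost pairs until every hairpin loop has >= 3 nucleotides.

    A closing pair enclosing fewer than three unpaired bases cannot form
    physically; motif grammars may nevertheless declare such pairs (e.g. a
    2-nt apical loop), so evaluation relaxes them.
    """
    plist = sorted((min(i, j), max(i, j)) for i, j in pairs)
    while True:
        enclosed = {p: 0 for p in plist}
        parent: dict[tuple[int, int], tuple[int, int] | None] = {}
        stack: list[tuple[int, int]] = []
        for p in plist:
            while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
                stack.pop()
            parent[p] = stack[-1] if stack else None
            if parent[p] is not None:
                enclosed[parent[p]] += 1
            stack.append(p)
        bad = [p for p in plist if enclosed[p] == 0 and p[1] - p[0] - 1 < 3]
        if not bad:
            return plist
        plist = [p for p in plist if p not in bad]


def _check_pairs(seq: str, pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    n = len(seq)
    seen: set[int] = set()
    norm = []
    for i, j in pairs:
        if i > j:
            i, j = j, i
        if not (0 <= i < j < n):
            raise StructureError(f"pair ({i},{j}) outside sequence of length {n}")
        if i in seen or j in seen:
            raise StructureError(f"position in pair ({i},{j}) paired twice")
        seen.update((i, j))
        if (seq[i], seq[j]) not in _CANONICAL:
            raise StructureError(
                f"non-canonical pair {seq[i]}{seq[j]} at ({i},{j})"
            )
        norm.append((i, j))
    norm.sort()
    for a, (i, j) in enumerate(norm):
        for i2, j2 in norm[a + 1 :]:
            if i2 > j:
                break
            if not (i < i2 < j2 < j):
                raise StructureError(
                    f"crossing pairs ({i},{j}) and ({i2},{j2}) (pseudoknot)"
                )
    return norm


def _pair_id(seq: str, i: int, j: int) -> tuple[str, str]:
    return (seq[i], seq[j])


def evaluate(seq: str, pairs, validate: bool = True) -> float:
    """Free energy (kcal/mol) of the fixed structure ``pairs`` on ``seq``.

    ``seq`` is RNA or DNA lettering (transliterated to RNA); ``pairs`` is an
    iterable of (i, j) index pairs or a dot-bracket string.  Raises
    :class:`StructureError` for out-of-range, duplicated, crossing or
    non-canonical pairs; internal callers that construct pairs from a
    pairing rule may skip that validation.
    """
    seq = seq.upper().replace("T", "U")
    if isinstance(pairs, str):
        pairs = pairs_from_dot_bracket(pairs)
    if validate:
        plist = _check_pairs(seq, list(pairs))
    else:
        plist = sorted(pairs)
    if not plist:
        return 0.0

    children_of: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in plist:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent = stack[-1] if stack else None
        children_of.setdefault(parent, []).append(p)
        children_of.setdefault(p, [])
        stack.append(p)

    total = 0.0
    for i, j in plist:
        kids = children_of[i, j]
        if not kids:
            size = j - i - 1
            if size < 3:
                raise StructureError(f"hairpin loop of size {size} at ({i},{j})")
            total += _loop_extrapolate(_HAIRPIN_INIT, size)
            if size > 3:
                closing = (seq[i], seq[j])
                total += (_HAIRPIN_MISMATCH_GC
                          if closing in (("G", "C"), ("C", "G"))
                          else _HAIRPIN_MISMATCH)
        elif len(kids) == 1:
            i2, j2 = kids[0]
            n1, n2 = i2 - i - 1, j - j2 - 1
            if n1 == 0 and n2 == 0:
                total += _STACK[_pair_id(seq, i, j), _pair_id(seq, i2, j2)]
            elif n1 == 0 or n2 == 0:  # bulge
                size = n1 + n2
                total += _loop_extrapolate(_BULGE_INIT, size)
                if size == 1:
                    total += _STACK[_pair_id(seq, i, j), _pair_id(seq, i2, j2)]
                else:
                    total += _end_penalty(seq, i, j) + _end_penalty(seq, i2, j2)
            else:  # internal loop
                size = n1 + n2
                total += _loop_extrapolate(_INTERNAL_INIT, size)
                total += min(_INTERNAL_ASYM * abs(n1 - n2), _INTERNAL_ASYM_MAX)
                if size >= 5:
                    total += 2 * _INTERNAL_MISMATCH
                total += _end_penalty(seq, i, j) + _end_penalty(seq, i2, j2)
        else:  # multiloop
            total += _ML_INIT + _ML_BRANCH * (len(kids) + 1)
            total += _end_penalty(seq, i, j)
            total += sum(_end_penalty(seq, a, b) for a, b in kids)

    # exterior helix ends
    for i, j in children_of[None]:
        total += _end_penalty(seq, i, j)
    return round(total, 2)


def _end_penalty(seq: str, i: int, j: int) -> float:
    """Terminal AU/GU penalty for a helix end closed by pair (i, j)."""
    pair = (seq[i], seq[j])
    return _TERMINAL_AU if pair in (("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")) else 0.0
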