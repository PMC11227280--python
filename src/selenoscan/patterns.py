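"""A PatScan-dialect structured-motif matcher for RNA.

The dialect covers what the three built-in SECIS search patterns need:

* pairing-rule declarations         ``r1={au,ua,gc,cg,gu,ug}``
* literals over IUPAC subset        ``NNGAN`` (A C G U T N R Y S W)
* named length-ranged segments      ``p1=7...15``
* anonymous length ranges           ``8...20``
* stem back-references              ``r1~p1[2,1,1]`` (mismatch/deletion/
  insertion budgets, PatScan order)
* literal alternation               ``(NGANN | NAANN)``

A back-reference ``rule~p[m,d,i]`` matches a substring *q* for which some
monotone alignment of *q* against the reverse of the bound segment *p* uses
at most ``d`` deletions (unaligned segment bases, shortening *q*), at most
``i`` insertions (unaligned *q* bases, lengthening it) and leaves at most
``m`` aligned positions whose (segment base, partner base) pair is not in
the rule.  ``N`` never satisfies a pairing rule.  Matching over segment
lengths and back-reference partner lengths is exhaustive, so every distinct
(start, full binding) combination is reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "PairingRule",
    "Literal",
    "Segment",
    "BackRef",
    "Alternation",
    "PatternSpec",
    "PatternMatch",
    "BackRefRealization",
    "PatternParseError",
    "parse_pattern",
    "match_all",
    "to_dot_bracket",
]

RULE_R1_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "N": "ACGUN",  # N in a pattern is a wildcard and also matches sequence N
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
}


class PatternParseError(ValueError):
    """Raised with a token position when pattern text cannot be parsed."""


@dataclass(frozen=True)
class PairingRule:
    name: str
    pairs: frozenset[tuple[str, str]]

    def allows(self, segment_base: str, partner_base: str) -> bool:
        return (segment_base, partner_base) in self.pairs


@dataclass(frozen=True)
class Literal:
    text: str  # over the IUPAC subset, RNA alphabet

    @property
    def min_len(self) -> int:
        return len(self.text)

    @property
    def max_len(self) -> int:
        return len(self.text)


@dataclass(frozen=True)
class Segment:
    name: str | None
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.min_len <= self.max_len):
            raise PatternParseError(
                f"segment {self.name or '<anon>'}: bad range "
                f"{self.min_len}...{self.max_len}"
            )


@dataclass(frozen=True)
class BackRef:
    rule: PairingRule
    segment_name: str
    budgets: tuple[int, int, int]  # (mismatches, deletions, insertions)

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.budgets):
            raise PatternParseError(f"negative budget in {self.budgets}")


@dataclass(frozen=True)
class Alternation:
    branches: tuple[tuple, ...]  # tuple of element tuples


@dataclass(frozen=True)
class PatternSpec:
    elements: tuple
    rules: dict[str, PairingRule] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        declared: set[str] = set()
        for el in self.elements:
            if isinstance(el, Segment) and el.name:
                declared.add(el.name)
            elif isinstance(el, BackRef) and el.segment_name not in declared:
                raise PatternParseError(
                    f"back-reference to undeclared segment {el.segment_name!r}"
                )

    def min_span(self) -> int:
        return sum(_min_span(el) for el in self.elements)

    def max_span(self) -> int:
        return sum(_max_span(el, self) for el in self.elements)


def _min_span(el) -> int:
    if isinstance(el, (Literal, Segment)):
        return el.min_len
    if isinstance(el, BackRef):
        return 0  # resolved against the bound segment at match time
    if isinstance(el, Alternation):
        return min(sum(_min_span(e) for e in br) for br in el.branches)
    raise TypeError(el)


def _max_span(el, spec: PatternSpec) -> int:
    if isinstance(el, (Literal, Segment)):
        return el.max_len
    if isinstance(el, BackRef):
        seg = next(
            e for e in spec.elements
            if isinstance(e, Segment) and e.name == el.segment_name
        )
        return seg.max_len + el.budgets[2]
    if isinstance(el, Alternation):
        return max(sum(_max_span(e, spec) for e in br) for br in el.branches)
    raise TypeError(el)


# ---------------------------------------------------------------------------
# Parsing

_RULE_RE = re.compile(r"^([A-Za-z]\w*)=\{([a-zA-Z,]+)\}$")
_SEG_RE = re.compile(r"^([A-Za-z]\w*)=(\d+)\.\.\.(\d+)$")
_ANON_RE = re.compile(r"^(\d+)\.\.\.(\d+)$")
_BREF_RE = re.compile(r"^([A-Za-z]\w*)~([A-Za-z]\w*)\[(\d+),(\d+),(\d+)\]$")
_LIT_RE = re.compile(r"^[ACGUTNRYSWacgutnrysw]+$")


def _tokenize(text: str) -> list[str]:
    text = text.replace("(", " ( ").replace(")", " ) ").replace("|", " | ")
    return text.split()


def parse_pattern(text: str) -> PatternSpec:
    """Parse pattern text in the dialect into a :class:`PatternSpec`."""
    tokens = _tokenize(text)
    rules: dict[str, PairingRule] = {}
    declared_segments: set[str] = set()
    elements: list = []
    i = 0

    def parse_simple(tok: str, pos: int):
        m = _SEG_RE.match(tok)
        if m:
            name, lo, hi = m.group(1), int(m.group(2)), int(m.group(3))
            if int(lo) > int(hi):
                raise PatternParseError(f"token {pos}: range {lo}...{hi} inverted")
            declared_segments.add(name)
            return Segment(name, lo, hi)
        m = _ANON_RE.match(tok)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if lo > hi:
                raise PatternParseError(f"token {pos}: range {lo}...{hi} inverted")
            return Segment(None, lo, hi)
        m = _BREF_RE.match(tok)
        if m:
            rname, sname = m.group(1), m.group(2)
            if rname not in rules:
                raise PatternParseError(f"token {pos}: undeclared rule {rname!r}")
            if sname not in declared_segments:
                raise PatternParseError(
                    f"token {pos}: back-reference to undeclared segment {sname!r}"
                )
            budgets = (int(m.group(3)), int(m.group(4)), int(m.group(5)))
            return BackRef(rules[rname], sname, budgets)
        if _LIT_RE.match(tok):
            return Literal(tok.upper().replace("T", "U"))
        raise PatternParseError(f"token {pos}: cannot parse {tok!r}")

    while i < len(tokens):
        tok = tokens[i]
        m = _RULE_RE.match(tok)
        if m:
            name = m.group(1)
            pairs = set()
            for pair in m.group(2).split(","):
                pair = pair.strip().upper().replace("T", "U")
                if len(pair) != 2 or any(c not in "ACGU" for c in pair):
                    raise PatternParseError(f"token {i}: bad pair {pair!r}")
                pairs.add((pair[0], pair[1]))
            rules[name] = PairingRule(name, frozenset(pairs))
            i += 1
            continue
        if tok == "(":
            depth_end = None
            j = i + 1
            branch: list = []
            branches: list[tuple] = []
            while j < len(tokens):
                if tokens[j] == ")":
                    depth_end = j
                    break
                if tokens[j] == "|":
                    branches.append(tuple(branch))
                    branch = []
                elif tokens[j] == "(":
                    raise PatternParseError(f"token {j}: nested groups unsupported")
                else:
                    branch.append(parse_simple(tokens[j], j))
                j += 1
            if depth_end is None:
                raise PatternParseError(f"token {i}: unclosed '('")
            branches.append(tuple(branch))
            if any(not br for br in branches):
                raise PatternParseError(f"token {i}: empty alternation branch")
            elements.append(Alternation(tuple(branches)))
            i = depth_end + 1
            continue
        if tok in (")", "|"):
            raise PatternParseError(f"token {i}: unexpected {tok!r}")
        elements.append(parse_simple(tok, i))
        i += 1

    if not elements:
        raise PatternParseError("empty pattern")
    return PatternSpec(tuple(elements), rules)


# ---------------------------------------------------------------------------
# Matching

@dataclass(frozen=True)
class BackRefRealization:
    """The chosen alignment of a back-reference partner to its segment.

    ``pairs`` holds (segment position, partner position) index pairs on the
    searched string for aligned columns that satisfy the pairing rule;
    ``mismatch_positions`` are aligned columns that do not.
    """

    segment_name: str
    segment_interval: tuple[int, int]
    interval: tuple[int, int]
    pairs: tuple[tuple[int, int], ...]
    mismatch_positions: tuple[tuple[int, int], ...]
    mismatches: int
    deletions: int
    insertions: int


@dataclass(frozen=True)
class PatternMatch:
    start: int
    end: int
    bindings: dict[str, tuple[int, int]] = field(compare=False)
    element_intervals: tuple[tuple[int, int], ...] = ()
    backrefs: tuple[BackRefRealization, ...] = ()
    branch_choices: tuple[int, ...] = ()

    @property
    def key(self) -> tuple:
        return (self.start, self.element_intervals, self.branch_choices)


def _literal_matches(lit: str, seq: str, pos: int) -> bool:
    if pos + len(lit) > len(seq):
        return False
    for k, pc in enumerate(lit):
        if seq[pos + k] not in _IUPAC[pc]:
            return False
    return True


_MIS_TABLES: dict[int, tuple] = {}


def _mis_table(rule: PairingRule):
    """128x128 mismatch lookup (1 = pair not allowed) for byte-indexed bases."""
    tab = _MIS_TABLES.get(id(rule))
    if tab is None:
        rows = [bytes([1]) * 128 for _ in range(128)]
        rows = [bytearray(r) for r in rows]
        for x, y in rule.pairs:
            rows[ord(x)][ord(y)] = 0
        tab = tuple(bytes(r) for r in rows)
        _MIS_TABLES[id(rule)] = (tab,)
        return tab
    return tab[0]


def _align_backref(p: str, q: str, rule: PairingRule,
                   budgets: tuple[int, int, int]):
    """Best monotone alignment of partner q against reversed segment p.

    Returns ``None`` if no alignment fits the budgets, else
    ``(mm, dd, ii, columns)`` where ``columns`` is a tuple of
    (segment offset, partner offset) aligned pairs.  The reported alignment
    is a deterministic representative: the ungapped register when feasible,
    otherwise the minimum-mismatch single-deletion/insertion register.
    """
    m_max, d_max, i_max = budgets
    L, n = len(p), len(q)
    if not (L - d_max <= n <= L + i_max):
        return None
    if d_max <= 1 and i_max <= 1:
        sb = (p + q).encode()
        return _align_small(sb, 0, L, L, n, _mis_table(rule), m_max,
                            d_max, i_max)
    return _align_dp(p, q, rule, budgets)


def _align_small(sb, a: int, L: int, b: int, n: int, mis,
                 m_max: int, d_max: int, i_max: int):
    """Closed-form register alignment for deletion/insertion budgets <= 1.

    ``sb`` is the byte-encoded sequence; the segment occupies [a, a+L) and
    the partner [b, b+n).  Columns pair segment offset L-1-k with partner
    offset k (innermost first).
    """
    if L == 0 or n == 0:
        return (0, L if n == 0 else 0, n if L == 0 else 0, ())
    delta = L - n
    e = a + L - 1  # byte index of rp[0]
    if delta == 0:
        mm0 = 0
        for k in range(n):
            mm0 += mis[sb[e - k]][sb[b + k]]
            if mm0 > m_max:
                break
        if mm0 <= m_max:
            cols = tuple((L - 1 - k, k) for k in range(n))
            return (mm0, 0, 0, cols)
        if d_max == 0 or i_max == 0 or n < 2:
            return None
        # one deletion (rp[t]) plus one insertion (q[u]); registers cancel
        # outside the [t, u) / [u, t] window.  total = A(t)+B(u)+const with
        # prefix scans, minimised in one fused pass for both orders.
        p0 = 0          # prefix of reg0 up to k
        smv = 0         # prefix of reg-minus (rp[k+1] vs q[k])
        spv = 0         # prefix of reg-plus (rp[k] vs q[k+1])
        bt = bu = 0
        bta = bua = 0   # best A-values and arg for each order
        best_di = None  # (mm_without_const, t, u)
        best_id = None
        for k in range(n):
            r0 = mis[sb[e - k]][sb[b + k]]
            if k < n - 1:
                rm = mis[sb[e - k - 1]][sb[b + k]]
                rp_ = mis[sb[e - k]][sb[b + k + 1]]
            else:
                rm = rp_ = 0
            # A_di(t) = P0(t) - Sm(t) at t == k
            v = p0 - smv
            if k == 0 or v < bta:
                bta, bt = v, k
            tot = bta + smv + (-(p0 + r0))  # + P0n added later
            if best_di is None or tot < best_di[0]:
                best_di = (tot, bt, k)
            v = p0 - spv
            if k == 0 or v < bua:
                bua, bu = v, k
            tot = bua + spv + (-(p0 + r0))
            if best_id is None or tot < best_id[0]:
                best_id = (tot, bu, k)
            p0 += r0
            smv += rm
            spv += rp_
        p0n = p0
        di = (best_di[0] + p0n, best_di[1], best_di[2])
        idc = (best_id[0] + p0n, best_id[1], best_id[2])
        if di[0] <= idc[0]:
            mm, plan = di[0], ("di", di[1], di[2])
        else:
            mm, plan = idc[0], ("id", idc[1], idc[2])
        if mm > m_max:
            return None
        return (mm, 1, 1, _cols_small(plan, L, n))
    if delta == 1:
        if d_max == 0:
            return None
        # single deletion of rp[t]
        p0 = 0
        smv = 0
        best = None
        suf = [0] * (n + 1)
        for k in range(n - 1, -1, -1):
            suf[k] = suf[k + 1] + mis[sb[e - k - 1]][sb[b + k]]
        for t in range(n + 1):
            tot = p0 + suf[t] if t < n + 1 else p0
            if best is None or tot < best[0]:
                best = (tot, t)
            if t < n:
                p0 += mis[sb[e - t]][sb[b + t]]
        if best[0] > m_max:
            return None
        return (best[0], 1, 0, _cols_small(("d", best[1]), L, n))
    # delta == -1: single insertion at q[u]
    if i_max == 0:
        return None
    p0 = 0
    best = None
    suf = [0] * (L + 1)
    for k in range(L - 1, -1, -1):
        suf[k] = suf[k + 1] + mis[sb[e - k]][sb[b + k + 1]]
    for u in range(L + 1):
        tot = p0 + suf[u] if u < L + 1 else p0
        if best is None or tot < best[0]:
            best = (tot, u)
        if u < L:
            p0 += mis[sb[e - u]][sb[b + u]]
    if best[0] > m_max:
        return None
    return (best[0], 0, 1, _cols_small(("i", best[1]), L, n))


def _cols_small(plan, L, n):
    """Aligned (segment offset, partner offset) columns for a register plan."""
    kind = plan[0]
    if kind == "d":  # rp[t] deleted
        t = plan[1]
        cols = [(k, k) for k in range(t)] + [(k + 1, k) for k in range(t, n)]
    elif kind == "i":  # q[u] inserted
        u = plan[1]
        cols = [(k, k) for k in range(u)] + [(k, k + 1) for k in range(u, L)]
    elif kind == "di":  # rp[t] deleted then q[u] inserted, t <= u
        t, u = plan[1], plan[2]
        cols = ([(k, k) for k in range(t)]
                + [(j + 1, j) for j in range(t, u)]
                + [(j, j) for j in range(u + 1, n)])
    else:  # "id": q[u] inserted then rp[t] deleted, u <= t
        u, t = plan[1], plan[2]
        cols = ([(k, k) for k in range(u)]
                + [(j - 1, j) for j in range(u + 1, t + 1)]
                + [(j, j) for j in range(t + 1, n)])
    return tuple(sorted((L - 1 - k, j) for k, j in cols))


def _align_dp(p: str, q: str, rule: PairingRule, budgets):
    """Generic small DP over (deletions, insertions) states; any budgets."""
    m_max, d_max, i_max = budgets
    rp = p[::-1]
    n, nq = len(rp), len(q)
    prev: list[dict] = [dict() for _ in range(nq + 1)]
    prev[0][(0, 0)] = 0
    for jj in range(1, min(nq, i_max) + 1):
        prev[jj][(0, jj)] = 0
    for row in range(1, n + 1):
        cur: list[dict] = [dict() for _ in range(nq + 1)]
        pc = rp[row - 1]
        alive = False
        for jj in range(nq + 1):
            cell = cur[jj]
            for (dd, ins), mm in prev[jj].items():
                if dd + 1 <= d_max and cell.get((dd + 1, ins), 99) > mm:
                    cell[(dd + 1, ins)] = mm
            if jj >= 1:
                for (dd, ins), mm in cur[jj - 1].items():
                    if ins + 1 <= i_max and cell.get((dd, ins + 1), 99) > mm:
                        cell[(dd, ins + 1)] = mm
                cost = 0 if rule.allows(pc, q[jj - 1]) else 1
                for (dd, ins), mm in prev[jj - 1].items():
                    if mm + cost <= m_max and cell.get((dd, ins), 99) > mm + cost:
                        cell[(dd, ins)] = mm + cost
            if cell:
                alive = True
        if not alive:
            return None
        prev = cur
    best = None
    for (dd, ins), mm in prev[nq].items():
        cand = (mm + dd + ins, mm, dd)
        if best is None or cand < best[0]:
            best = (cand, mm, dd, ins)
    if best is None:
        return None
    _, mm, dd, ins = best
    cols = _dp_traceback(rp, q, rule, mm, dd, ins)
    return mm, dd, ins, _cols_to_segment(cols, n)


def _dp_traceback(rp, q, rule, mm_t, dd_t, ii_t):
    """Recover one alignment achieving exactly (mm_t, dd_t, ii_t)."""
    sol = []

    def rec(i, j, mm, dd, ii, cols):
        if i == len(rp) and j == len(q):
            if (mm, dd, ii) == (mm_t, dd_t, ii_t):
                sol.append(tuple(cols))
                return True
            return False
        if mm > mm_t or dd > dd_t or ii > ii_t:
            return False
        if i < len(rp) and j < len(q):
            cost = 0 if rule.allows(rp[i], q[j]) else 1
            if rec(i + 1, j + 1, mm + cost, dd, ii, cols + [(i, j)]):
                return True
        if i < len(rp) and rec(i + 1, j, mm, dd + 1, ii, cols):
            return True
        if j < len(q) and rec(i, j + 1, mm, dd, ii + 1, cols):
            return True
        return False

    rec(0, 0, 0, 0, 0, [])
    return sol[0]


def _min_span_el(el) -> int:
    if isinstance(el, Literal):
        return len(el.text)
    if isinstance(el, Segment):
        return el.min_len
    if isinstance(el, BackRef):
        return 0  # refined against the declared segment in _suffix_mins
    if isinstance(el, Alternation):
        return min(sum(_min_span_el(e) for e in br) for br in el.branches)
    raise TypeError(el)


def _suffix_mins(elems) -> list[int]:
    seg_min: dict[str, int] = {}

    def collect(seq_):
        for e in seq_:
            if isinstance(e, Segment) and e.name:
                seg_min[e.name] = e.min_len
            elif isinstance(e, Alternation):
                for br in e.branches:
                    collect(br)

    collect(elems)
    out = [0] * (len(elems) + 1)
    for idx in range(len(elems) - 1, -1, -1):
        el = elems[idx]
        if isinstance(el, BackRef):
            span = max(0, seg_min.get(el.segment_name, 0) - el.budgets[1])
        else:
            span = _min_span_el(el)
        out[idx] = out[idx + 1] + span
    return out


def _needed_names(elems) -> list[tuple[str, ...]]:
    """needed[idx]: outer segment bindings the suffix elems[idx:] depends on."""
    out: list[tuple[str, ...]] = [()] * (len(elems) + 1)
    need: set[str] = set()
    for idx in range(len(elems) - 1, -1, -1):
        el = elems[idx]
        if isinstance(el, BackRef):
            need.add(el.segment_name)
        elif isinstance(el, Segment) and el.name:
            need.discard(el.name)
        elif isinstance(el, Alternation):
            for br in el.branches:
                for e in br:
                    if isinstance(e, BackRef):
                        need.add(e.segment_name)
            for br in el.branches:
                for e in br:
                    if isinstance(e, Segment) and e.name:
                        need.discard(e.name)
        out[idx] = tuple(sorted(need))
    return out


def match_all(spec: PatternSpec, seq: str) -> list[PatternMatch]:
    """All distinct anchored matches of ``spec`` anywhere in ``seq``.

    ``seq`` may be DNA or RNA; it is transliterated to RNA internally.
    Matches are reported in left-to-right start order (ties broken by the
    full element-interval tuple), one per distinct (start, binding).
    Suffix completions are memoized on (element index, position, the
    bindings the suffix references), collapsing shared tails.
    """
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters {sorted(bad)}")
    n = len(seq)
    elems = spec.elements
    suffix_min = _suffix_mins(elems)
    needed = _needed_names(elems)
    n_el = len(elems)
    # memoize only where a bound named segment is no longer referenced by
    # the suffix: elsewhere every (position, bindings) key is unique and the
    # cache would be pure overhead
    declared: set[str] = set()
    memo_flag = [False] * (n_el + 1)
    for _i, _el in enumerate(elems):
        memo_flag[_i] = bool(declared - set(needed[_i]))
        if isinstance(_el, Segment) and _el.name:
            declared.add(_el.name)
    memo_flag[n_el] = False
    lit_sets = {
        idx: [_IUPAC[c] for c in el.text]
        for idx, el in enumerate(elems) if isinstance(el, Literal)
    }
    kinds = [0 if isinstance(el, Literal) else
             1 if isinstance(el, Segment) else
             2 if isinstance(el, BackRef) else 3 for el in elems]
    mis_of = {idx: _mis_table(el.rule) for idx, el in enumerate(elems)
              if isinstance(el, BackRef)}
    sbytes = seq.encode()
    env: dict[str, tuple[int, int]] = {}
    memo: dict[tuple, list] = {}
    align_cache: dict[int, object] = {}
    stride = n + 2

    def realize(el, mis, seg_iv, pos, qlen):
        key = (((id(el) * stride + seg_iv[0]) * stride + seg_iv[1]) * stride
               + pos) * stride + qlen
        hit = align_cache.get(key, False)
        if hit is not False:
            return hit
        budgets = el.budgets
        plen = seg_iv[1] - seg_iv[0]
        if budgets[1] <= 1 and budgets[2] <= 1:
            res = _align_small(sbytes, seg_iv[0], plen, pos, qlen, mis,
                               budgets[0], budgets[1], budgets[2])
        else:
            res = _align_dp(seq[seg_iv[0]:seg_iv[1]], seq[pos:pos + qlen],
                            el.rule, budgets)
        if res is not None:
            mm, dd, ii, cols = res
            pairs, mis_cols = [], []
            allows = el.rule.pairs
            for soff, poff in cols:
                si, qi = seg_iv[0] + soff, pos + poff
                if (seq[si], seq[qi]) in allows:
                    pairs.append((si, qi))
                else:
                    mis_cols.append((si, qi))
            res = BackRefRealization(
                el.segment_name, seg_iv, (pos, pos + qlen),
                tuple(pairs), tuple(mis_cols), mm, dd, ii,
            )
        align_cache[key] = res
        return res

    def match_branch(branch, j, pos, min_after):
        """Completions of branch[j:] at pos; entries (ivs, brs, bids, end)."""
        if j == len(branch):
            return [((), (), (), pos)]
        el = branch[j]
        rest_min = sum(_min_span_el(e) for e in branch[j + 1:]) + min_after
        out = []
        if isinstance(el, Literal):
            endp = pos + len(el.text)
            if endp + rest_min <= n:
                for k, c in enumerate(el.text):
                    if seq[pos + k] not in _IUPAC[c]:
                        break
                else:
                    iv = (pos, endp)
                    out = [((iv,) + ivs, brs, bids, e)
                           for ivs, brs, bids, e in match_branch(
                               branch, j + 1, endp, min_after)]
        elif isinstance(el, Segment):
            hi = min(el.max_len, n - pos - rest_min)
            for L in range(el.min_len, hi + 1):
                iv = (pos, pos + L)
                if el.name:
                    env[el.name] = iv
                for ivs, brs, bids, e in match_branch(branch, j + 1,
                                                      pos + L, min_after):
                    out.append(((iv,) + ivs, brs, bids, e))
            if el.name and el.name in env:
                del env[el.name]
        elif isinstance(el, BackRef):
            seg_iv = env[el.segment_name]
            plen = seg_iv[1] - seg_iv[0]
            lo = max(0, plen - el.budgets[1])
            hi = min(plen + el.budgets[2], n - pos - rest_min)
            mis = _mis_table(el.rule)
            for qlen in range(lo, hi + 1):
                real = realize(el, mis, seg_iv, pos, qlen)
                if real is None:
                    continue
                iv = (pos, pos + qlen)
                for ivs, brs, bids, e in match_branch(branch, j + 1,
                                                      pos + qlen, min_after):
                    out.append(((iv,) + ivs, (real,) + brs, bids, e))
        else:  # pragma: no cover - parser rejects nested alternations
            raise TypeError(el)
        return out

    memo_get = memo.get

    def completions(idx: int, pos: int) -> list:
        """Entries (interval tuple, backref tuple, branch ids, end)."""
        if idx == n_el:
            return ((), (), (), pos),
        if memo_flag[idx]:
            nd = needed[idx]
            key = (idx, pos) + tuple(env[nm] for nm in nd) if nd else (idx, pos)
            got = memo_get(key)
            if got is not None:
                return got
        else:
            key = None
        out: list = []
        kind = kinds[idx]
        el = elems[idx]
        if kind == 0:
            sets = lit_sets[idx]
            endp = pos + len(sets)
            if endp + suffix_min[idx + 1] <= n:
                for k, allowed in enumerate(sets):
                    if seq[pos + k] not in allowed:
                        break
                else:
                    iv = (pos, endp)
                    out = [((iv,) + ivs, brs, bids, e)
                           for ivs, brs, bids, e in completions(idx + 1, endp)]
        elif kind == 1:
            hi = min(el.max_len, n - pos - suffix_min[idx + 1])
            name = el.name
            ap = out.append
            for L in range(el.min_len, hi + 1):
                iv = (pos, pos + L)
                if name:
                    env[name] = iv
                for ivs, brs, bids, e in completions(idx + 1, pos + L):
                    ap(((iv,) + ivs, brs, bids, e))
            if name and name in env:
                del env[name]
        elif kind == 2:
            seg_iv = env[el.segment_name]
            plen = seg_iv[1] - seg_iv[0]
            lo = max(0, plen - el.budgets[1])
            hi = min(plen + el.budgets[2], n - pos - suffix_min[idx + 1])
            mis = mis_of[idx]
            ap = out.append
            for qlen in range(lo, hi + 1):
                real = realize(el, mis, seg_iv, pos, qlen)
                if real is None:
                    continue
                iv = (pos, pos + qlen)
                for ivs, brs, bids, e in completions(idx + 1, pos + qlen):
                    ap(((iv,) + ivs, (real,) + brs, bids, e))
        else:  # Alternation
            for bi, branch in enumerate(el.branches):
                for bivs, bbrs, _b, endp in match_branch(
                    branch, 0, pos, suffix_min[idx + 1]
                ):
                    for ivs, brs, bids, e in completions(idx + 1, endp):
                        out.append((bivs + ivs, bbrs + brs, (bi,) + bids, e))
        if key is not None:
            memo[key] = out
        return out

    results: dict[tuple, PatternMatch] = {}
    for start in range(0, n - suffix_min[0] + 1):
        for ivs, brs, bids, endp in completions(0, start):
            bindings = _bindings_from_intervals(elems, ivs, bids)
            m = PatternMatch(
                start=start, end=endp, bindings=bindings,
                element_intervals=ivs, backrefs=brs, branch_choices=bids,
            )
            results.setdefault(m.key, m)
    return sorted(results.values(),
                  key=lambda m: (m.start, m.end, m.element_intervals,
                                 m.branch_choices))


def _bindings_from_intervals(elems, ivs, bids) -> dict[str, tuple[int, int]]:
    """Recover named-segment bindings from the flat interval tuple."""
    bindings: dict[str, tuple[int, int]] = {}
    k = 0
    bi_iter = iter(bids)
    for el in elems:
        if isinstance(el, Alternation):
            branch = el.branches[next(bi_iter)]
            for e in branch:
                if isinstance(e, Segment) and e.name:
                    bindings[e.name] = ivs[k]
                k += 1
        else:
            if isinstance(el, Segment) and el.name:
                bindings[el.name] = ivs[k]
            k += 1
    return bindings


def to_dot_bracket(match: PatternMatch, length: int | None = None) -> str:
    """Dot-bracket over the match span; budget-consumed positions stay dots."""
    span_start, span_end = match.start, match.end
    if length is None:
        length = span_end - span_start
    chars = ["."] * length
    for br in match.backrefs:
        for i, j in br.pairs:
            a, b = sorted((i, j))
            chars[a - span_start] = "("
            chars[b - span_start] = ")"
    return "".join(chars)
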