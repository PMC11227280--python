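"""Independent brute-force oracles for the pattern engine and finder.

Written independently of the package internals: a plain recursive
enumerator that tries every start, every segment-length combination, every
alternation branch and every back-reference partner length, with an
exhaustive recursive search over gapped stem alignments.  Deliberately slow
and simple — it is the ground truth the fast matcher is compared against.
"""

from __future__ import annotations

from selenoscan.patterns import Alternation, BackRef, Literal, Segment

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "N": "ACGUN", "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
}


def can_align(rp: str, q: str, pairs, m: int, d: int, i: int) -> bool:
    """Does any monotone alignment of q vs rp fit the budgets?"""
    if not rp and not q:
        return True
    if rp and q:
        cost = 0 if (rp[0], q[0]) in pairs else 1
        if cost <= m and can_align(rp[1:], q[1:], pairs, m - cost, d, i):
            return True
    if rp and d > 0 and can_align(rp[1:], q, pairs, m, d - 1, i):
        return True
    if q and i > 0 and can_align(rp, q[1:], pairs, m, d, i - 1):
        return True
    return False


def _flatten(elements):
    """Expand alternations into (branch ids, flat element list) variants."""
    variants = [((), [])]
    for el in elements:
        if isinstance(el, Alternation):
            variants = [
                (bids + (bi,), items + [("el", e) for e in br])
                for bids, items in variants
                for bi, br in enumerate(el.branches)
            ]
        else:
            variants = [(bids, items + [("el", el)]) for bids, items in variants]
    return [(bids, [e for _tag, e in items]) for bids, items in variants]


def oracle_matches(spec, seq: str) -> set[tuple]:
    """All (start, element interval tuple, branch ids) satisfying the spec."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    found: set[tuple] = set()
    for bids, elems in _flatten(spec.elements):
        for start in range(n + 1):
            _search(elems, 0, start, {}, [], seq, n, start, bids, found)
    return found


def _search(elems, idx, pos, env, ivs, seq, n, start, bids, found):
    if idx == len(elems):
        found.add((start, tuple(ivs), bids))
        return
    el = elems[idx]
    if isinstance(el, Literal):
        end = pos + len(el.text)
        if end <= n and all(seq[pos + k] in IUPAC[c]
                            for k, c in enumerate(el.text)):
            _search(elems, idx + 1, end, env, ivs + [(pos, end)],
                    seq, n, start, bids, found)
    elif isinstance(el, Segment):
        for L in range(el.min_len, el.max_len + 1):
            if pos + L > n:
                break
            env2 = dict(env)
            if el.name:
                env2[el.name] = (pos, pos + L)
            _search(elems, idx + 1, pos + L, env2, ivs + [(pos, pos + L)],
                    seq, n, start, bids, found)
    elif isinstance(el, BackRef):
        a, b = env[el.segment_name]
        p = seq[a:b]
        m, d, i = el.budgets
        for qlen in range(max(0, len(p) - d), len(p) + i + 1):
            if pos + qlen > n:
                break
            q = seq[pos:pos + qlen]
            if can_align(p[::-1], q, el.rule.pairs, m, d, i):
                _search(elems, idx + 1, pos + qlen, env,
                        ivs + [(pos, pos + qlen)], seq, n, start, bids, found)
    else:  # pragma: no cover
        raise TypeError(el)


def brute_force_operon_pairs(annotations, labels=("hdrA", "frhD"),
                             max_gap_nt=60):
    """All-pairs re-implementation of adjacent same-strand label pairs."""
    want = {labels[0].lower(), labels[1].lower()}
    out = []
    for a in annotations:
        for b in annotations:
            if a is b or a.contig_id != b.contig_id or a.strand != b.strand:
                continue
            if a.start >= b.start:
                continue
            la, lb = (a.product_label or "").lower(), (b.product_label or "").lower()
            if {la, lb} != want:
                continue
            between = any(
                c is not a and c is not b
                and c.contig_id == a.contig_id and c.strand == a.strand
                and a.start < c.start < b.start
                for c in annotations
            )
            if between:
                continue
            gap = b.start - a.end
            if gap <= max_gap_nt:
                out.append((a, b, gap))
    return out


def ss_triplet_brute(seq: str, pairs, offset: int = 0) -> bool:
    """Any three successive stem pairs whose bases are all C or G."""
    plist = sorted(pairs)
    for k in range(len(plist) - 2):
        if all(seq[i - offset] in "CG" and seq[j - offset] in "CG"
               for i, j in plist[k:k + 3]):
            return True
    return False
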