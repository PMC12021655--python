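"""Independent brute-force reference for the METEOR-style scorer.

Unlike the package implementation (stage-wise leftmost-greedy
alignment), this oracle enumerates *every* maximal matching at each
stage, takes the alignments with the maximum number of matches, and
among those minimizes the chunk count before applying the scoring
formula. On sentence pairs where the greedy alignment attains the
chunk-optimal solution the two must agree exactly.
"""

from dualinf._text import light_stem, tokenize
from dualinf.meteor import SYNONYM_PAIRS


def _match_fns():
    return [
        lambda c, r: c == r,
        lambda c, r: light_stem(c) == light_stem(r),
        lambda c, r: frozenset((c, r)) in SYNONYM_PAIRS,
    ]


def _maximal_matchings(cand_idx, ref_idx, cand, ref, match):
    """All maximal matchings (as frozensets of (ci, rj) pairs) between
    the given free candidate/reference positions under ``match``."""
    results: set[frozenset] = set()

    def rec(ci_list, free_refs, acc):
        if not ci_list:
            results.add(frozenset(acc))
            return
        ci, rest = ci_list[0], ci_list[1:]
        options = [rj for rj in free_refs if match(cand[ci], ref[rj])]
        if not options:
            rec(rest, free_refs, acc)
            return
        for rj in options:
            rec(rest, [r for r in free_refs if r != rj], acc + [(ci, rj)])
        # also consider leaving ci unmatched; smaller matchings are
        # discarded by the max-size filter below
        rec(rest, free_refs, acc)

    rec(list(cand_idx), list(ref_idx), [])
    if not results:
        return [frozenset()]
    best = max(len(m) for m in results)
    return [m for m in results if len(m) == best]


def _count_chunks(pairs):
    pairs = sorted(pairs)
    if not pairs:
        return 0
    chunks = 1
    for (c0, r0), (c1, r1) in zip(pairs, pairs[1:]):
        if c1 != c0 + 1 or r1 != r0 + 1:
            chunks += 1
    return chunks


def reference_meteor(candidate: str, reference: str) -> float:
    cand = tokenize(candidate)
    ref = tokenize(reference)
    if not cand or not ref:
        return 0.0
    # enumerate alignments stage by stage: each stage's matchings are
    # computed on the positions left free by the chosen earlier matchings
    partials: list[frozenset] = [frozenset()]
    for match in _match_fns():
        next_partials = []
        for partial in partials:
            used_c = {c for c, _ in partial}
            used_r = {r for _, r in partial}
            free_c = [i for i in range(len(cand)) if i not in used_c]
            free_r = [j for j in range(len(ref)) if j not in used_r]
            for m in _maximal_matchings(free_c, free_r, cand, ref, match):
                next_partials.append(partial | m)
        # dedupe
        partials = list(set(next_partials))
    alignments = partials
    best_m = max(len(a) for a in alignments)
    candidates = [a for a in alignments if len(a) == best_m]
    if best_m == 0:
        return 0.0
    chunks = min(_count_chunks(a) for a in candidates)
    precision = best_m / len(cand)
    recall = best_m / len(ref)
    f_mean = 10 * precision * recall / (recall + 9 * precision)
    penalty = 0.0 if chunks == 1 else 0.5 * (chunks / best_m) ** 3
    return f_mean * (1.0 - penalty)
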