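"""In-core METEOR-style sentence similarity.

Unigram alignment in three stages — exact surface match, stem match,
synonym match — followed by the harmonic mean of unigram precision and
recall weighted 9:1 toward recall, discounted by a fragmentation
penalty based on the number of contiguous match chunks:

    P = m / |candidate|,  R = m / |reference|
    F = 10 P R / (R + 9 P)
    penalty = 0 if chunks == 1 else 0.5 * (chunks / m) ** 3
    score = F * (1 - penalty)

Identical sentences score exactly 1.0 (a single perfectly ordered chunk
carries no penalty) and sentences with disjoint vocabulary score 0.0.
Within a stage, duplicate tokens are assigned left-to-right (leftmost
candidate occurrence to leftmost unmatched reference occurrence), a
deterministic tie-break.

The stemmer is the package's light suffix stripper and the synonym
stage uses a small embedded table of common clinical/general pairs —
deliberately modest, auditable machinery rather than a WordNet
dependency.
"""

from __future__ import annotations

from ._text import light_stem, tokenize

#: Unordered synonym pairs recognized by the synonym stage (lowercase).
SYNONYM_PAIRS: frozenset[frozenset[str]] = frozenset(
    frozenset(p)
    for p in [
        ("doctor", "physician"),
        ("heart", "cardiac"),
        ("lung", "pulmonary"),
        ("kidney", "renal"),
        ("liver", "hepatic"),
        ("stomach", "gastric"),
        ("brain", "cerebral"),
        ("skin", "cutaneous"),
        ("belly", "abdomen"),
        ("abdominal", "abdomen"),
        ("fever", "pyrexia"),
        ("febrile", "fever"),
        ("vomiting", "emesis"),
        ("itching", "pruritus"),
        ("sweating", "diaphoresis"),
        ("dizziness", "vertigo"),
        ("bruise", "contusion"),
        ("rash", "exanthem"),
        ("breathlessness", "dyspnea"),
        ("tiredness", "fatigue"),
        ("swelling", "edema"),
        ("clot", "thrombus"),
        ("pain", "ache"),
        ("sudden", "abrupt"),
        ("severe", "intense"),
        ("absent", "missing"),
        ("enlarged", "swollen"),
        ("high", "elevated"),
        ("low", "decreased"),
    ]
)


def _synonyms(a: str, b: str) -> bool:
    return frozenset((a, b)) in SYNONYM_PAIRS


def align(candidate_tokens: list[str], reference_tokens: list[str]) -> list[tuple[int, int]]:
    """Three-stage unigram alignment; returns (candidate, reference)
    index pairs sorted by candidate position."""
    cand_free = [True] * len(candidate_tokens)
    ref_free = [True] * len(reference_tokens)
    pairs: list[tuple[int, int]] = []

    def stage(match) -> None:
        for i, ct in enumerate(candidate_tokens):
            if not cand_free[i]:
                continue
            for j, rt in enumerate(reference_tokens):
                if ref_free[j] and match(ct, rt):
                    pairs.append((i, j))
                    cand_free[i] = False
                    ref_free[j] = False
                    break

    stage(lambda c, r: c == r)
    stage(lambda c, r: light_stem(c) == light_stem(r))
    stage(_synonyms)
    return sorted(pairs)


def count_chunks(pairs: list[tuple[int, int]]) -> int:
    """Number of maximal runs of adjacent, order-preserving matches."""
    if not pairs:
        return 0
    chunks = 1
    for (c0, r0), (c1, r1) in zip(pairs, pairs[1:]):
        if c1 != c0 + 1 or r1 != r0 + 1:
            chunks += 1
    return chunks


def meteor_score(candidate: str, reference: str) -> float:
    """METEOR-style score of ``candidate`` against ``reference`` in [0, 1]."""
    cand = tokenize(candidate)
    ref = tokenize(reference)
    if not cand or not ref:
        return 0.0
    pairs = align(cand, ref)
    m = len(pairs)
    if m == 0:
        return 0.0
    precision = m / len(cand)
    recall = m / len(ref)
    f_mean = 10 * precision * recall / (recall + 9 * precision)
    chunks = count_chunks(pairs)
    penalty = 0.0 if chunks == 1 else 0.5 * (chunks / m) ** 3
    return f_mean * (1.0 - penalty)
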