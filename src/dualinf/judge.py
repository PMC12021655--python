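"""Consistency judges.

A judge decides whether a claim (one evidence sentence) is consistent
with any of a set of reference statements. The in-core judge is purely
lexical — content-token Jaccard overlap after stopword filtering and
light stemming — so the whole pipeline is deterministic and testable
offline. A chat-model judge can be plugged in through the same
interface (see :class:`BackendJudge`).
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

from ._text import content_tokens, jaccard


@dataclass(frozen=True)
class LexicalJudge:
    """Deterministic lexical entailment: consistent iff the claim's
    content-token Jaccard overlap with any reference is >= ``threshold``.

    The default threshold of 0.5 accepts paraphrases that preserve the
    medical content words ("sudden onset chest pain" vs "chest pain of
    sudden onset") while rejecting statements about different findings.
    """

    threshold: float = 0.5

    def consistent(self, claim: str, references: Iterable[str]) -> bool:
        return self.score(claim, references) >= self.threshold

    def score(self, claim: str, references: Iterable[str]) -> float:
        """Best overlap against any reference, in [0, 1]."""
        ct = content_tokens(claim)
        best = 0.0
        for ref in references:
            best = max(best, jaccard(ct, content_tokens(ref)))
            if best == 1.0:
                break
        return best


class BackendJudge:
    """Consistency judging delegated to a text backend via the judge
    template. Intended for chat-model judges; not used by the offline
    test suite."""

    def __init__(self, backend, temperature: float = 0.0, seed: int = 0):
        self.backend = backend
        self.temperature = temperature
        self.seed = seed

    def consistent(self, claim: str, references: Iterable[str]) -> bool:
        from .prompts import render_prompt

        refs = list(references)
        if not refs:
            return False
        prompt = render_prompt(
            "judge", claim=claim, references="\n".join(f"- {r}" for r in refs)
        )
        reply = self.backend.complete(prompt, temperature=self.temperature, seed=self.seed)
        return "INCONSISTENT" not in reply.upper() and "CONSISTENT" in reply.upper()
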