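"""The structured output grammar all prompting strategies parse into.

Backends are asked to answer in a fixed plain-text shape::

    1. Pneumothorax
    - sudden chest pain
    - absent breath sounds
    2. Rib fracture
    - point tenderness over the fifth rib

Numbered lines open a diagnosis block; dash-prefixed lines attach
explanations to the open block. Anything before the first numbered line
(step-by-step reasoning, preamble chatter) is ignored. Duplicate
diagnoses (after normalization) are merged with an order-preserving
union of their explanations.
"""

from __future__ import annotations

import re

from ._text import normalize_diagnosis, normalize_text
from .errors import MalformedOutputError
from .types import DDxItem, DDxPrediction, ExplanationItem, RecalledProfile

_DX_LINE_RE = re.compile(r"^\s*(\d+)[.)]\s*(.+?)\s*$")
_EXPL_LINE_RE = re.compile(r"^\s*[-*]\s*(.+?)\s*$")


def _parse_blocks(raw: str) -> list[tuple[str, list[str]]]:
    """Parse raw text into (diagnosis, explanation lines) blocks, merging
    duplicate diagnoses by explanation union."""
    if not raw or not raw.strip():
        raise MalformedOutputError("empty backend response", raw=raw)
    order: list[str] = []
    blocks: dict[str, tuple[str, list[str]]] = {}
    current: str | None = None
    for line in raw.splitlines():
        m = _DX_LINE_RE.match(line)
        if m:
            name = m.group(2).strip().rstrip(".")
            if not normalize_text(name):
                continue
            key = normalize_diagnosis(name)
            if key not in blocks:
                blocks[key] = (name, [])
                order.append(key)
            current = key
            continue
        m = _EXPL_LINE_RE.match(line)
        if m and current is not None:
            text = m.group(1)
            _, expls = blocks[current]
            if normalize_text(text) not in {normalize_text(e) for e in expls}:
                expls.append(text)
    if not order:
        raise MalformedOutputError(
            "no numbered diagnosis lines found in backend response", raw=raw
        )
    return [blocks[k] for k in order]


def parse_structured_output(
    raw: str, *, strategy: str = "unknown", note_id: str = "", iteration: int = 1
) -> DDxPrediction:
    """Parse backend text into a :class:`DDxPrediction`.

    All explanations enter with provenance="forward", status="kept".
    Raises :class:`MalformedOutputError` (carrying the raw text) when no
    diagnosis block can be found; the caller may retry once.
    """
    blocks = _parse_blocks(raw)
    items = [
        DDxItem(diagnosis=name, explanations=[ExplanationItem(text=t) for t in expls])
        for name, expls in blocks
    ]
    return DDxPrediction(items=items, strategy=strategy, note_id=note_id, iteration=iteration)


def parse_recall(raw: str, diagnoses: list[str]) -> RecalledProfile:
    """Parse backward-inference text into a :class:`RecalledProfile`.

    Every requested diagnosis gets an entry; diagnoses the backend said
    nothing about (or answered with no dash lines) map to empty lists.
    """
    profile = {normalize_diagnosis(d): [] for d in diagnoses}
    try:
        blocks = _parse_blocks(raw)
    except MalformedOutputError:
        return RecalledProfile(per_diagnosis=profile)
    for name, findings in blocks:
        key = normalize_diagnosis(name)
        if key in profile:
            profile[key] = list(findings)
    return RecalledProfile(per_diagnosis=profile)


def render_prediction(prediction: DDxPrediction, *, kept_only: bool = False) -> str:
    """Serialize a prediction back into the output grammar.

    Round-trip: ``parse_structured_output(render_prediction(p))``
    reproduces diagnosis names and explanation texts (statuses and
    provenance reset to their parse defaults).
    """
    lines: list[str] = []
    for i, item in enumerate(prediction.items, start=1):
        lines.append(f"{i}. {item.diagnosis}")
        for e in item.explanations:
            if kept_only and e.status != "kept":
                continue
            lines.append(f"- {e.text}")
    return "\n".join(lines)


def render_blocks(blocks: list[tuple[str, list[str]]]) -> str:
    """Render (name, lines) blocks in the output grammar (mock backends)."""
    lines: list[str] = []
    for i, (name, expls) in enumerate(blocks, start=1):
        lines.append(f"{i}. {name}")
        lines.extend(f"- {e}" for e in expls)
    return "\n".join(lines)
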