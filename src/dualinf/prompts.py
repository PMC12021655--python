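"""Prompt templates and deterministic rendering.

Templates live as plain-text files under ``dualinf/templates`` with
``$name`` placeholders (``string.Template`` syntax). Machine-readable
section markers (``[NOTE]…[/NOTE]``, ``[FEEDBACK]…[/FEEDBACK]``,
``[DIAGNOSES]…[/DIAGNOSES]``, ``[DISPUTED]…[/DISPUTED]``) delimit the
structured parts of every prompt so that any backend — including the
deterministic simulated clinician — can recover them without natural-
language understanding.

Feedback to the forward module is phrased neutrally ("previously
low-confidence … reconsider on its merits"), never as an instruction to
remove a diagnosis, so that correct diagnoses are not suppressed by
false-negative feedback.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources
from string import Template

from .errors import TemplateError

TEMPLATE_IDS = (
    "forward",
    "backward",
    "cot",
    "diagnosis_cot",
    "self_contrast_a",
    "self_contrast_b",
    "self_contrast_c",
    "self_contrast_arbitrate",
    "judge",
)


@lru_cache(maxsize=None)
def _load(template_id: str) -> Template:
    if template_id not in TEMPLATE_IDS:
        raise TemplateError(f"unknown template {template_id!r}")
    text = (
        resources.files("dualinf").joinpath("templates", f"{template_id}.txt").read_text("utf-8")
    )
    return Template(text)


def render_prompt(template_id: str, **context: str) -> str:
    """Render a template with all placeholders bound; deterministic.

    Raises :class:`TemplateError` for an unknown template or an unbound
    placeholder.
    """
    template = _load(template_id)
    try:
        return template.substitute(**context)
    except KeyError as exc:
        raise TemplateError(
            f"template {template_id!r}: unbound placeholder {exc.args[0]!r}"
        ) from None


def format_feedback(names: list[str]) -> str:
    """Neutral feedback block listing previously low-confidence diagnoses."""
    if not names:
        return "(none)"
    lines = [
        "The following diagnoses were previously low-confidence. Reconsider each "
        "one on its clinical merits with fresh supporting evidence from the note; "
        "retain it if the findings justify it:"
    ]
    lines.extend(f"- {n}" for n in names)
    return "\n".join(lines)


def format_diagnoses(names: list[str]) -> str:
    return "\n".join(f"{i}. {n}" for i, n in enumerate(names, start=1))


_SECTION_RES: dict[str, re.Pattern[str]] = {}


def extract_section(prompt: str, section: str) -> str | None:
    """Pull the text between ``[SECTION]`` and ``[/SECTION]`` markers."""
    pat = _SECTION_RES.get(section)
    if pat is None:
        pat = re.compile(
            re.escape(f"[{section}]") + r"\n?(.*?)\n?" + re.escape(f"[/{section}]"),
            re.DOTALL,
        )
        _SECTION_RES[section] = pat
    m = pat.search(prompt)
    return m.group(1).strip() if m else None


def extract_feedback_names(prompt: str) -> list[str]:
    """Diagnosis names listed in the [FEEDBACK] block, if any."""
    block = extract_section(prompt, "FEEDBACK")
    if not block or block.strip() == "(none)":
        return []
    return [
        line[2:].strip()
        for line in block.splitlines()
        if line.startswith("- ") and line[2:].strip()
    ]


def extract_listed_names(prompt: str, section: str) -> list[str]:
    """Numbered diagnosis names inside a section ([DIAGNOSES]/[DISPUTED])."""
    block = extract_section(prompt, section)
    if not block:
        return []
    names = []
    for line in block.splitlines():
        m = re.match(r"^\s*\d+[.)]\s*(.+?)\s*$", line)
        if m:
            names.append(m.group(1))
        elif line.startswith("- ") and line[2:].strip():
            names.append(line[2:].strip())
    return names
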