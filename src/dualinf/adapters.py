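"""Real chat-API adapters.

These satisfy the same :class:`~dualinf.backend.TextBackend` contract as
the mock and are selected via ``backend.name = "openai-chat"``. They are
network-facing and therefore opt-in: nothing in the offline pipeline or
the test suite touches them. Credentials are taken from the environment
(``OPENAI_API_KEY``), never from configuration files. Every request and
response is hashed into ``audit_log`` so runs can be audited without
storing raw clinical text.
"""

from __future__ import annotations

import hashlib
import os

from .errors import ConfigurationError


def _sha(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


class OpenAIChatBackend:
    """Adapter for OpenAI-compatible chat-completion APIs.

    ``model`` defaults to a GPT-4-class endpoint; any OpenAI-compatible
    ``base_url`` (e.g. a locally served open-weights model) works. The
    ``seed`` parameter is forwarded on a best-effort basis: hosted chat
    models are not strictly deterministic even at low temperature.
    """

    name = "openai-chat"
    supports_seed = True
    is_deterministic = False

    def __init__(self, model: str = "gpt-4-turbo-preview", base_url: str | None = None):
        try:
            from openai import OpenAI  # lazy: optional dependency
        except ImportError as exc:  # pragma: no cover - exercised only with the extra installed
            raise ConfigurationError(
                "the openai-chat backend requires the 'openai' package"
            ) from exc
        api_key = os.environ.get("OPENAI_API_KEY")
        if not api_key:
            raise ConfigurationError(
                "set OPENAI_API_KEY in the environment to use the openai-chat backend"
            )
        self._client = OpenAI(api_key=api_key, base_url=base_url)
        self.model = model
        self.audit_log: list[dict[str, str]] = []

    def complete(self, prompt: str, *, temperature: float = 0.1, seed: int = 0) -> str:  # pragma: no cover
        response = self._client.chat.completions.create(
            model=self.model,
            messages=[{"role": "user", "content": prompt}],
            temperature=temperature,
            seed=seed,
        )
        text = response.choices[0].message.content or ""
        self.audit_log.append(
            {"model": self.model, "prompt_sha256": _sha(prompt), "response_sha256": _sha(text)}
        )
        return text


def make_backend(name: str, **kwargs):
    """Backend factory keyed by ``backend.name`` (mock | openai-chat)."""
    if name == "mock":
        from .backend import MockClinicianBackend

        return MockClinicianBackend(**kwargs)
    if name == "openai-chat":
        return OpenAIChatBackend(**kwargs)
    raise ConfigurationError(f"unknown backend {name!r}")
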