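"""Semantic adjudication of candidate pairs under an explicit acceptance prompt.

Each candidate pair is rendered into a fixed prompt that asks whether two
short descriptions refer to the same disease or medical condition, with a
directional subsumption rule: the candidate (second description) is accepted
only when it is equivalent to or broader than the input (first description).
A narrower candidate is rejected.  Responses must start with Y or N followed
by a short justification.

The adjudication backend is pluggable.  :class:`MockAdjudicator` is a
deterministic stand-in used by tests — it accepts exactly the pairs whose
normalized texts are equal or that appear in a user-supplied accept-table;
it makes no attempt to imitate model judgment.  :class:`RemoteChatAdjudicator`
adapts an OpenAI-style chat-completions endpoint and is not used in tests.
"""

from __future__ import annotations

import json
import logging
import os
import re
import urllib.request
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Iterable, Optional

from .candidates import CandidatePair

logger = logging.getLogger(__name__)

__all__ = [
    "PROMPT_TEMPLATES",
    "AdjudicationPrompt",
    "AdjudicationResult",
    "AdjudicatorBackend",
    "MockAdjudicator",
    "RemoteChatAdjudicator",
    "UnparseableResponseError",
    "build_prompt",
    "parse_decision",
    "adjudicate",
]

STRICT_CRITERIA = (
    "Given two short descriptions, decide whether they refer to the same "
    "disease or medical condition. If the second description is more narrow "
    'or specific, choose "No" as an answer. If the second description is '
    'broader or more generic, choose "Yes" as an answer. Start your answer '
    'from "Y" for "yes" or "N" for "no" and provide a concise justification, '
    "no more than 30 words, why you came to this conclusion."
)

RELAXED_CRITERIA = (
    "Given two short descriptions, decide whether they refer to the same "
    "disease or medical condition, or to a related but more general or more "
    'specific condition. If so, choose "Yes" as an answer; otherwise choose '
    '"No". Start your answer from "Y" for "yes" or "N" for "no" and provide '
    "a concise justification, no more than 30 words, why you came to this "
    "conclusion."
)

# versioned prompt templates; "strict" is the default acceptance protocol
PROMPT_TEMPLATES: dict[str, str] = {
    "strict": STRICT_CRITERIA,
    "relaxed": RELAXED_CRITERIA,
}


class UnparseableResponseError(ValueError):
    """Raised when a response does not start with a recognizable Y/N verdict."""


@dataclass(frozen=True)
class AdjudicationPrompt:
    """A rendered prompt: criteria block plus the two descriptions in order."""

    text: str
    first_description: str
    second_description: str


@dataclass(frozen=True)
class AdjudicationResult:
    pair: CandidatePair
    decision: str  # "accept" | "reject"
    justification: str
    raw_response: str
    backend_name: str
    error: bool = False  # True when rejected after unparseable responses


class AdjudicatorBackend(ABC):
    """Contract: map a rendered prompt to a raw response string."""

    name: str
    max_retries: int = 1

    @abstractmethod
    def respond(self, prompt: AdjudicationPrompt) -> str: ...


_NORM_RE = re.compile(r"[^a-z0-9 ]+")


def _normalize_text(s: str) -> str:
    return _NORM_RE.sub("", " ".join(s.lower().split()))


class MockAdjudicator(AdjudicatorBackend):
    """Deterministic offline adjudicator for tests and fixtures.

    Accepts a pair iff the normalized (case- and punctuation-insensitive)
    source text equals the normalized target label, or the (source, target)
    pair appears in the configured accept-table.  Always emits a well-formed
    "Y — ..." / "N — ..." response.
    """

    def __init__(self, accept_table: Optional[Iterable[tuple[str, str]]] = None):
        self.name = "mock"
        self.accept_table = {
            (_normalize_text(a), _normalize_text(b)) for a, b in (accept_table or [])
        }

    def respond(self, prompt: AdjudicationPrompt) -> str:
        a = _normalize_text(prompt.first_description)
        b = _normalize_text(prompt.second_description)
        if a == b:
            return "Y — the two descriptions are textually equivalent."
        if (a, b) in self.accept_table:
            return "Y — pair listed as an accepted mapping."
        return "N — descriptions are not equivalent under the configured table."


class RemoteChatAdjudicator(AdjudicatorBackend):
    """Adapter for an OpenAI-style chat-completions endpoint (e.g. GPT-4o).

    Credentials come from the environment (``ONTOMAP_CHAT_API_KEY``); request
    and response bodies are appended to a JSONL audit log when configured.
    Not exercised by the test suite.
    """

    def __init__(
        self,
        endpoint: str = "https://api.openai.com/v1/chat/completions",
        model: str = "gpt-4o",
        api_key_env: str = "ONTOMAP_CHAT_API_KEY",
        timeout: float = 60.0,
        max_retries: int = 1,
        audit_log: Optional[str] = None,
    ):
        self.name = f"remote:{model}"
        self.endpoint = endpoint
        self.model = model
        self.api_key_env = api_key_env
        self.timeout = timeout
        self.max_retries = max_retries
        self.audit_log = audit_log

    def respond(self, prompt: AdjudicationPrompt) -> str:  # pragma: no cover - network
        key = os.environ.get(self.api_key_env)
        if not key:
            raise RuntimeError(f"set {self.api_key_env} to use the remote chat backend")
        body = json.dumps(
            {"model": self.model, "messages": [{"role": "user", "content": prompt.text}]}
        ).encode()
        req = urllib.request.Request(
            self.endpoint,
            data=body,
            headers={"Content-Type": "application/json", "Authorization": f"Bearer {key}"},
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            payload = json.loads(resp.read())
        answer = payload["choices"][0]["message"]["content"]
        if self.audit_log:
            with open(self.audit_log, "a") as fh:
                fh.write(json.dumps({"prompt": prompt.text, "response": answer}) + "\n")
        return answer


def build_prompt(pair: CandidatePair, template: str = "strict") -> AdjudicationPrompt:
    """Render the acceptance prompt for one candidate pair.

    The input record text is always the first description and the candidate
    concept label the second: the acceptance criteria are directional (the
    candidate must be equivalent or broader).  Byte-stable for equal inputs.
    """
    if not pair.source_text.strip():
        raise ValueError("pair has an empty source description")
    if not pair.target_label.strip():
        raise ValueError("pair has an empty target description")
    criteria = PROMPT_TEMPLATES[template]
    text = (
        f"{criteria}\n\n"
        f"Description 1: {pair.source_text}\n"
        f"Description 2: {pair.target_label}\n"
    )
    return AdjudicationPrompt(
        text=text,
        first_description=pair.source_text,
        second_description=pair.target_label,
    )


_DECORATION = " \t\r\n\"'`*_#>-–—“”‘’"


def parse_decision(raw: str) -> str:
    """Map a raw response to accept/reject by its leading verdict letter.

    Strips whitespace, quotes and markdown decoration, then reads the first
    alphabetic character: Y/y → accept, N/n → reject; anything else raises
    :class:`UnparseableResponseError`.
    """
    if not raw or not raw.strip():
        raise UnparseableResponseError("empty response")
    stripped = raw.lstrip(_DECORATION)
    first = stripped[0] if stripped and stripped[0].isalpha() else ""
    if first in ("Y", "y"):
        return "accept"
    if first in ("N", "n"):
        return "reject"
    raise UnparseableResponseError(f"response does not start with Y or N: {raw[:80]!r}")


def _justification(raw: str) -> str:
    stripped = raw.lstrip(_DECORATION)
    # drop the verdict token ("Y", "Yes", "No", ...) and any separator
    m = re.match(r"[A-Za-z]+", stripped)
    rest = stripped[m.end() :] if m else stripped
    return rest.lstrip(" \t.,:;—–-\"'").strip()


def adjudicate(
    pairs: Iterable[CandidatePair],
    backend: AdjudicatorBackend,
    template: str = "strict",
) -> list[AdjudicationResult]:
    """Adjudicate every pair in order, one result per pair.

    An unparseable response is retried per the backend's policy; after
    exhaustion the pair is conservatively marked rejected-with-error (a
    mapping is never accepted by default).  Raw responses are retained for
    audit.
    """
    results: list[AdjudicationResult] = []
    for pair in pairs:
        prompt = build_prompt(pair, template=template)
        decision = None
        raw = ""
        for _ in range(backend.max_retries + 1):
            raw = backend.respond(prompt)
            try:
                decision = parse_decision(raw)
                break
            except UnparseableResponseError:
                logger.warning("unparseable response for pair %s: %r", pair.key, raw[:80])
        if decision is None:
            results.append(
                AdjudicationResult(
                    pair=pair,
                    decision="reject",
                    justification="unparseable response after retries",
                    raw_response=raw,
                    backend_name=backend.name,
                    error=True,
                )
            )
            continue
        justification = _justification(raw)
        if len(justification.split()) > 30:
            logger.warning("justification exceeds 30 words for pair %s", pair.key)
        results.append(
            AdjudicationResult(
                pair=pair,
                decision=decision,
                justification=justification,
                raw_response=raw,
                backend_name=backend.name,
            )
        )
    return results
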