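"""Agreement and acceptance statistics for two-adjudicator evaluations.

The central object is a 2×2 contingency of accept/reject decisions by two
adjudicators (typically an automated adjudicator and a human expert) over a
shared set of candidate pairs.  Percent agreement is the share of pairs on
which both give the same decision; Cohen's kappa is reported as supplementary
chance-corrected output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, TypeVar

from .adjudicate import AdjudicationResult
from .candidates import CandidatePair

T = TypeVar("T")

__all__ = [
    "LabeledPair",
    "AgreementReport",
    "AcceptanceSummary",
    "agreement_report",
    "acceptance_summary",
    "sample_for_review",
]

_DECISIONS = ("accept", "reject")


@dataclass(frozen=True)
class LabeledPair:
    """One pair with decisions from two adjudicators (e.g. LLM and expert)."""

    pair: Optional[CandidatePair]
    decision_a: str
    decision_b: str

    def __post_init__(self):
        for d in (self.decision_a, self.decision_b):
            if d not in _DECISIONS:
                raise ValueError(f"decision must be one of {_DECISIONS}, got {d!r}")


@dataclass(frozen=True)
class AgreementReport:
    """2×2 decision contingency with percent agreement and Cohen's kappa."""

    n_total: int
    n_both_accept: int
    n_both_reject: int
    n_a_only: int  # a accepts, b rejects
    n_b_only: int  # b accepts, a rejects

    @property
    def percent_agreement(self) -> float:
        return (self.n_both_accept + self.n_both_reject) / self.n_total * 100.0

    @property
    def percent_agreement_1dp(self) -> float:
        return round(self.percent_agreement, 1)

    @property
    def percent_agreement_int(self) -> int:
        return round(self.percent_agreement)

    @property
    def cohen_kappa(self) -> float:
        """Chance-corrected agreement (supplementary output)."""
        n = self.n_total
        po = (self.n_both_accept + self.n_both_reject) / n
        pa_a = (self.n_both_accept + self.n_a_only) / n
        pa_b = (self.n_both_accept + self.n_b_only) / n
        pe = pa_a * pa_b + (1 - pa_a) * (1 - pa_b)
        if pe == 1.0:
            return 1.0 if po == 1.0 else 0.0
        return (po - pe) / (1 - pe)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_both_accept": self.n_both_accept,
            "n_both_reject": self.n_both_reject,
            "n_a_only": self.n_a_only,
            "n_b_only": self.n_b_only,
            "percent_agreement": self.percent_agreement,
            "percent_agreement_1dp": self.percent_agreement_1dp,
            "percent_agreement_int": self.percent_agreement_int,
            "cohen_kappa": self.cohen_kappa,
        }

    def to_text(self) -> str:
        """Human-readable contingency table."""
        lines = [
            f"{'':>12} {'b: accept':>10} {'b: reject':>10}",
            f"{'a: accept':>12} {self.n_both_accept:>10} {self.n_a_only:>10}",
            f"{'a: reject':>12} {self.n_b_only:>10} {self.n_both_reject:>10}",
            f"agreement: {self.percent_agreement_1dp}% "
            f"({self.n_both_accept + self.n_both_reject}/{self.n_total}), "
            f"kappa: {self.cohen_kappa:.3f}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class AcceptanceSummary:
    """Accepted share of adjudicated pairs; errored rejections tallied apart."""

    n_pairs: int
    n_accepted: int
    n_rejected_with_error: int = 0

    @property
    def ratio(self) -> float:
        return self.n_accepted / self.n_pairs

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_accepted": self.n_accepted,
            "n_rejected_with_error": self.n_rejected_with_error,
            "ratio": self.ratio,
        }


def agreement_report(labeled: Iterable[LabeledPair]) -> AgreementReport:
    """Count the 2×2 decision contingency over a shared pair set.

    Percent agreement is (both-accept + both-reject) / total × 100, stored at
    full precision; one-decimal and nearest-integer renderings are exposed as
    properties.  Raises on empty input.
    """
    cells = {"aa": 0, "rr": 0, "ar": 0, "ra": 0}
    n = 0
    for lp in labeled:
        n += 1
        key = ("a" if lp.decision_a == "accept" else "r") + (
            "a" if lp.decision_b == "accept" else "r"
        )
        cells[key] += 1
    if n == 0:
        raise ValueError("cannot compute agreement over an empty pair set")
    return AgreementReport(
        n_total=n,
        n_both_accept=cells["aa"],
        n_both_reject=cells["rr"],
        n_a_only=cells["ar"],
        n_b_only=cells["ra"],
    )


def acceptance_summary(results: Iterable[AdjudicationResult]) -> AcceptanceSummary:
    """Share of accepted pairs; rejected-with-error counts as rejected."""
    n = n_acc = n_err = 0
    for r in results:
        n += 1
        if r.decision == "accept":
            n_acc += 1
        elif r.error:
            n_err += 1
    if n == 0:
        raise ValueError("cannot summarize an empty result set")
    return AcceptanceSummary(n_pairs=n, n_accepted=n_acc, n_rejected_with_error=n_err)


def sample_for_review(items: Sequence[T], n: int, seed: int) -> list[T]:
    """Uniform sample of min(n, total) items without replacement.

    Reproducible from the seed; the sampled subset is returned in the items'
    original order so repeated runs produce byte-identical review files.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = len(items)
    if n >= total:
        return list(items)
    rng = random.Random(seed)
    idx = sorted(rng.sample(range(total), n))
    return [items[i] for i in idx]
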