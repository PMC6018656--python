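"""Subject-retirement logic of the citizen-science platform.

Each image ("subject") is shown to volunteers until it is retired.  An
image said by anyone to contain animals is seen by ten volunteers by
default; if instead the first four volunteers all answer that no animals
are present or that they can't tell, the image is retired early as blank.
A single yes before the blank window completes cancels blank retirement
permanently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

DEFAULT_VIEWS = 10
BLANK_WINDOW = 4

#: Answers counting toward the blank window ("no animals, or unsure").
_BLANK_ANSWERS = frozenset({"no", "cant_tell"})


@dataclass(frozen=True)
class RetirementResult:
    """Outcome of the retirement rule for one subject's answer stream."""

    retired_after: int | None
    reason: str  # "blank_consensus", "view_limit" or "active"

    @property
    def retired(self) -> bool:
        return self.retired_after is not None


def simulate_retirement(
    answers: Iterable[str],
    default_views: int = DEFAULT_VIEWS,
    blank_window: int = BLANK_WINDOW,
) -> RetirementResult:
    """Apply the retirement rule to an ordered stream of answers.

    Parameters
    ----------
    answers : iterable of {"yes", "no", "cant_tell"}
        The subject's classification stream, in order of arrival.
    default_views : int
        Views after which a subject retires regardless of content.
    blank_window : int
        Length of the initial all-blank run that retires a subject early.

    Returns
    -------
    RetirementResult
        ``retired_after`` is the number of classifications consumed, or
        ``None`` (reason "active") if the stream ended before retirement.
    """
    answers = list(answers)
    bad = set(answers) - _BLANK_ANSWERS - {"yes"}
    if bad:
        raise ValueError(f"unknown answer(s): {sorted(bad)}")
    head = answers[:blank_window]
    if len(head) == blank_window and all(a in _BLANK_ANSWERS for a in head):
        return RetirementResult(retired_after=blank_window, reason="blank_consensus")
    if len(answers) >= default_views:
        return RetirementResult(retired_after=default_views, reason="view_limit")
    return RetirementResult(retired_after=None, reason="active")


def views_required(
    answers: Sequence[str],
    default_views: int = DEFAULT_VIEWS,
    blank_window: int = BLANK_WINDOW,
) -> int:
    """Number of views a subject would receive given a hypothetical stream.

    Convenience for the volunteer simulator: assumes the stream is long
    enough to reach retirement, truncating at ``default_views``.
    """
    head = list(answers[:blank_window])
    if len(head) == blank_window and all(a in _BLANK_ANSWERS for a in head):
        return blank_window
    return default_views
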