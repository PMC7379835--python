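"""Shared plumbing for the implicit shortest-path searches."""

from __future__ import annotations

from dataclasses import dataclass


class AlignmentNotFound(Exception):
    """No connecting path exists (within the configured limits)."""


class SearchLimitExceeded(AlignmentNotFound):
    """The state budget or cost cap was exhausted before a path was found."""


@dataclass
class SearchLimits:
    """Resource bounds for one shortest-path subtask.

    ``max_states`` caps the number of settled product-graph states;
    ``cost_cap`` abandons the search once the frontier cost exceeds it.
    Both failures raise :class:`SearchLimitExceeded`, which callers treat as
    "keep the partial alignment and move on".
    """

    max_states: int = 5_000_000
    cost_cap: float | None = None
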