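"""Homology-hit screening and iterative bait expansion.

Hits are kept when they clear all three retrieval thresholds at once:
E-value strictly below ``e_max``, percent identity at least ``id_min``,
and query (bait) coverage — aligned span over bait length — at least
``cov_min``.  Iterative search grows the bait set with kept subjects until
a fixed point or a round cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional

from .model import HomologyHit, RcdError, SearchError


@dataclass(frozen=True)
class ScreenParams:
    """Retrieval thresholds: E-value < e_max, identity >= id_min (percent),
    query coverage >= cov_min (fraction), and an iteration cap."""

    e_max: float = 1e-5
    id_min: float = 30.0
    cov_min: float = 0.80
    max_rounds: int = 3

    def __post_init__(self):
        if not (0 < self.cov_min <= 1):
            raise ValueError("cov_min must be in (0, 1]")
        if not (0 <= self.id_min <= 100):
            raise ValueError("id_min must be in [0, 100]")
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


def query_coverage(hit: HomologyHit, query_length: int) -> float:
    """Aligned fraction of the query: (q_end - q_start + 1) / length."""
    return (hit.q_end - hit.q_start + 1) / query_length


def filter_hits(
    hits: Iterable[HomologyHit],
    query_lengths: Mapping[str, int],
    params: ScreenParams = ScreenParams(),
) -> list[HomologyHit]:
    """Keep hits clearing all thresholds; input order is preserved.

    Raises :class:`RcdError` naming the query when its length is unknown.
    Identity and coverage thresholds are inclusive; E-value is strict.
    """
    kept: list[HomologyHit] = []
    for h in hits:
        if h.query_id not in query_lengths:
            raise RcdError(f"no query length for {h.query_id!r}")
        if (
            h.e_value < params.e_max
            and h.pct_identity >= params.id_min
            and query_coverage(h, query_lengths[h.query_id]) >= params.cov_min
        ):
            kept.append(h)
    return kept


def expand_baits(
    kept_hits: Iterable[HomologyHit], current_baits: Iterable[str]
) -> frozenset[str]:
    """Union of the current bait set with the subjects of kept hits."""
    return frozenset(current_baits) | {h.subject_id for h in kept_hits}


@dataclass(frozen=True)
class RoundLog:
    round: int
    n_hits: int
    n_kept: int
    n_new_baits: int


def iterate_search(
    search_fn: Callable[[frozenset[str]], Iterable[HomologyHit]],
    seed_baits: Iterable[str],
    params: ScreenParams = ScreenParams(),
    query_lengths: Optional[Mapping[str, int]] = None,
) -> tuple[frozenset[str], list[RoundLog]]:
    """Iterate ``search_fn`` (an injected search backend or test stub) from
    the seed baits until no round adds a bait or ``max_rounds`` is reached.

    When ``query_lengths`` is given, every round's hits are screened with
    :func:`filter_hits` first.  Bait sets grow monotonically; failures of
    the backend are re-raised with round context.
    """
    baits = frozenset(seed_baits)
    log: list[RoundLog] = []
    for rnd in range(1, params.max_rounds + 1):
        try:
            hits = list(search_fn(baits))
        except Exception as exc:
            raise SearchError(f"search backend failed in round {rnd}: {exc}") from exc
        kept = (
            filter_hits(hits, query_lengths, params)
            if query_lengths is not None
            else hits
        )
        grown = expand_baits(kept, baits)
        log.append(RoundLog(rnd, len(hits), len(kept), len(grown) - len(baits)))
        if grown == baits:
            break
        baits = grown
    return baits, log
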