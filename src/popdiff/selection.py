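"""Variant selection: the two-criterion coverage/impact filter and summaries.

A variant is retained when its supporting read depth is at least
``min_depth`` (inclusive — a "minimum of 10 reads" keeps a depth-10 call)
and its predicted impact class belongs to an allowed set.  Impact labels
are consumed as input annotations; they are never re-derived here.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable

from .types import IMPACTS, VariantRecord

#: The study's default filter: keep everything except low-impact variants.
DEFAULT_MIN_DEPTH = 10
DEFAULT_IMPACTS = frozenset({"modifier", "moderate", "high"})


def select_variants(
    records: Iterable[VariantRecord],
    min_depth: int = DEFAULT_MIN_DEPTH,
    allowed_impacts: Iterable[str] = DEFAULT_IMPACTS,
) -> list[VariantRecord]:
    """Return records with ``depth >= min_depth`` and an allowed impact, order preserved."""
    if min_depth < 0:
        raise ValueError("min_depth must be non-negative")
    allowed = frozenset(allowed_impacts)
    if not allowed or not allowed <= set(IMPACTS):
        raise ValueError(f"allowed_impacts must be a non-empty subset of {IMPACTS}")
    return [r for r in records if r.depth >= min_depth and r.impact in allowed]


def summarize_by_impact(records: Iterable[VariantRecord]) -> dict[str, int]:
    """Count records per impact class (classes absent from the input are omitted)."""
    return dict(Counter(r.impact for r in records))


def summarize_by_gene(records: Iterable[VariantRecord]) -> dict[str, int]:
    """Count records per gene symbol."""
    return dict(Counter(r.gene for r in records))
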