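"""Foreign-transcript identification.

Assembled transcripts are searched against two reference sets: an ingroup
nucleotide database (sequences from the host's own superfamily, e.g.
Coccoidea) and a broad nucleotide database.  A transcript is called
*foreign* — cross-sample or environmental carry-over rather than host
sequence — when it is simultaneously a poor match to the ingroup
(best percent identity < ``low``, default 90, strict) and a near-perfect
match to something in the broad database (best percent identity >=
``high``, default 98, inclusive).  Everything else is retained.

A transcript with no ingroup hit has ingroup identity 0 (maximally
compatible with being foreign); a transcript with no broad-database hit has
broad identity 0 and therefore cannot satisfy the >= ``high`` arm, so it is
retained — calling a sequence foreign requires positive evidence of a
strong match elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .model import HitTable

__all__ = ["ForeignCallRecord", "classify_foreign"]


@dataclass(frozen=True)
class ForeignCallRecord:
    transcript_id: str
    ingroup_identity: float
    broad_identity: float
    verdict: str  # "foreign" | "retained"


def classify_foreign(
    transcripts: Iterable[str],
    ingroup_hits: HitTable,
    broad_hits: HitTable,
    low: float = 90.0,
    high: float = 98.0,
) -> list[ForeignCallRecord]:
    """Classify every transcript as foreign or retained.

    Parameters
    ----------
    transcripts
        Ids of all assembled transcripts (the partition: each receives
        exactly one verdict).
    ingroup_hits, broad_hits
        Hit tables keyed by transcript id against the ingroup and broad
        reference sets.  Per-transcript best identity is the maximum
        identity over that transcript's hits; no hit means identity 0.
    low, high
        Identity thresholds, in (0, 100].  Foreign requires
        ``ingroup < low`` (strict) and ``broad >= high`` (inclusive).
    """
    for name, thr in (("low", low), ("high", high)):
        if not 0.0 < thr <= 100.0:
            raise ValueError(f"threshold {name} must be in (0, 100], got {thr}")
    calls = []
    for tid in transcripts:
        ing = ingroup_hits.best_identity(tid)
        broad = broad_hits.best_identity(tid)
        verdict = "foreign" if (ing < low and broad >= high) else "retained"
        calls.append(ForeignCallRecord(tid, ing, broad, verdict))
    return calls
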