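"""Final biological boost and ranking assembly.

The voting score of each gene is multiplied by (1 + normalized average
differential expression): genes whose mean expression differs most between
control and case samples gain up to a factor of 2, adding expression
evidence on top of the purely network-derived vote.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

from .types import RankedEntry, RankedGeneList

logger = logging.getLogger(__name__)

__all__ = ["final_score"]


def final_score(
    voting: Mapping[str, float],
    normalized_ade: Mapping[str, float],
    exclude: Iterable[str] = (),
) -> RankedGeneList:
    """Assemble the output ranking: final = voting * (1 + normalized ADE).

    Genes missing an ADE value get boost factor 1 (with a warning); the
    list is sorted by final score descending, ties broken by ascending
    gene identifier. ``exclude`` removes genes (typically the seeds, for
    benchmarking) before ranks are assigned.
    """
    exclude = set(exclude)
    rows = []
    n_missing = 0
    for g, v in voting.items():
        if g in exclude:
            continue
        if g in normalized_ade:
            a = float(normalized_ade[g])
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"normalized ADE for {g} is {a}, outside [0, 1]")
        else:
            a = 0.0
            n_missing += 1
        rows.append((g, float(v), a, float(v) * (1.0 + a)))
    if n_missing:
        logger.warning("%d voted gene(s) without an ADE value: boost factor 1", n_missing)
    rows.sort(key=lambda r: (-r[3], r[0]))
    entries = [
        RankedEntry(gene=g, voting_score=v, normalized_ade=a, final_score=f, rank=i)
        for i, (g, v, a, f) in enumerate(rows, start=1)
    ]
    return RankedGeneList(entries)
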