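"""Placement of novel contigs on reference chromosomes from mate pairs.

Reads mapping within the terminal windows (default 300 bp) of a contig whose
mates map to a different sequence carry the linking evidence.  An end is
placed when at least ``min_support`` such reads agree: >=80% of mates on one
chromosome, their leftmost coordinates spanning <=1,000 bp; the placement
coordinate is the median of those coordinates.  When both ends place on the
same chromosome the lower coordinate wins; conflicting ends cancel the
placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

logger = logging.getLogger("panpav")

__all__ = ["EndLink", "Placement", "collect_end_links", "evaluate_end",
           "place_contig", "place_all_contigs"]


@dataclass(frozen=True)
class EndLink:
    contig_id: str
    end: str  # left | right
    read_id: str
    read_pos: int
    mate_seq_id: str
    mate_pos: int


@dataclass(frozen=True)
class Placement:
    contig_id: str
    target_seq_id: str
    coordinate: int
    supporting_reads: int
    ends_used: str  # left | right | both
    left_support: int = 0
    right_support: int = 0


def collect_end_links(records, contig_id: str, contig_len: int,
                      window: int = 300, min_mapq: int = 10
                      ) -> dict[str, list[EndLink]]:
    """Collect linking reads for both ends of one contig.

    A read qualifies when it maps to the contig with MAPQ >= ``min_mapq``,
    is not a proper pair, is mapped, its mate is mapped, it is not a
    duplicate, and its mate maps to a different sequence.  The read's
    leftmost position assigns it to the first-``window`` (left) and/or
    last-``window`` (right) end; on short contigs one read can qualify for
    both ends and is counted once per end.
    """
    links: dict[str, list[EndLink]] = {"left": [], "right": []}
    if contig_len <= 200:
        logger.info("contig %s length %d <= 200 bp; skipped",
                    contig_id, contig_len)
        return links
    right_start = contig_len - window + 1
    for r in records:
        if r.seq_id != contig_id:
            continue
        if (r.mapq < min_mapq or r.is_proper_pair or r.is_unmapped
                or "mate_unmapped" in r.flags or r.is_duplicate):
            continue
        if r.mate_seq_id in (contig_id, "*", "="):
            continue
        if r.pos <= window:
            links["left"].append(EndLink(contig_id, "left", r.read_id,
                                         r.pos, r.mate_seq_id, r.mate_pos))
        if r.pos >= right_start:
            links["right"].append(EndLink(contig_id, "right", r.read_id,
                                          r.pos, r.mate_seq_id, r.mate_pos))
    return links


def _lower_median(values: list[int]) -> int:
    """Median keeping coordinates integral: lower of two middles when even."""
    v = sorted(values)
    return v[(len(v) - 1) // 2]


def evaluate_end(links: Iterable[EndLink], min_support: int = 10,
                 majority: float = 0.8, max_span: int = 1000
                 ) -> tuple[str, int, int] | None:
    """Evaluate one end's links; returns (target, coordinate, n_support).

    Requires >= ``min_support`` inspected reads, >= ``majority`` (inclusive)
    of mates on a single target, and the majority-target mate coordinates
    spanning <= ``max_span``.  The coordinate is the median of the
    majority-target mate positions.
    """
    links = list(links)
    if len(links) < min_support:
        return None
    by_target: dict[str, list[int]] = {}
    for l in links:
        by_target.setdefault(l.mate_seq_id, []).append(l.mate_pos)
    target, positions = max(by_target.items(), key=lambda kv: len(kv[1]))
    if len(positions) / len(links) < majority:
        return None
    if max(positions) - min(positions) > max_span:
        return None
    return target, _lower_median(positions), len(positions)


def place_contig(left_candidate: tuple[str, int, int] | None,
                 right_candidate: tuple[str, int, int] | None,
                 contig_id: str = "") -> Placement | None:
    """Combine the two end candidates into a placement, or none on conflict."""
    if left_candidate is None and right_candidate is None:
        return None
    if left_candidate is not None and right_candidate is not None:
        lt, lc, ln = left_candidate
        rt, rc, rn = right_candidate
        if lt != rt:
            logger.info("contig %s: conflicting ends (%s vs %s); not placed",
                        contig_id, lt, rt)
            return None
        return Placement(contig_id, lt, min(lc, rc), ln + rn, "both", ln, rn)
    if left_candidate is not None:
        t, c, n = left_candidate
        return Placement(contig_id, t, c, n, "left", left_support=n)
    t, c, n = right_candidate
    return Placement(contig_id, t, c, n, "right", right_support=n)


def place_all_contigs(records, contig_lengths: Mapping[str, int],
                      window: int = 300, min_mapq: int = 10,
                      min_support: int = 10) -> list[Placement]:
    """Place every contig >200 bp using one pass over the records."""
    records = list(records)
    by_contig: dict[str, list] = {}
    for r in records:
        by_contig.setdefault(r.seq_id, []).append(r)
    out = []
    for cid, length in contig_lengths.items():
        links = collect_end_links(by_contig.get(cid, []), cid, length,
                                  window, min_mapq)
        left = evaluate_end(links["left"], min_support)
        right = evaluate_end(links["right"], min_support)
        p = place_contig(left, right, cid)
        if p is not None:
            out.append(p)
    return out
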