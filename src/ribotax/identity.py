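"""Pairwise global-alignment identity and greedy centroid clustering.

One identity metric and one clustering routine serve both database
dereplication (99% identity) and OTU generation (97% identity), so the
two can never drift apart.

Identity is computed from a Needleman-Wunsch global alignment with match
+1, mismatch -1 and linear gap -2, as matches divided by alignment
columns after trimming terminal gap columns.  Alignment is delegated to
Biopython's PairwiseAligner.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from Bio import Align

MATCH = 1
MISMATCH = -1
GAP = -2

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=MATCH,
    mismatch_score=MISMATCH,
    open_gap_score=GAP,
    extend_gap_score=GAP,
)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the optimal global alignment.

    Terminal gap columns (overhangs) are trimmed before counting, so a
    short fragment aligned inside a full-length sequence is scored only
    over the region it covers.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    aln = _aligner.align(a.upper(), b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    start, end = 0, len(ga)
    while start < end and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    if end == start:
        return 0.0
    matches = sum(1 for x, y in zip(ga[start:end], gb[start:end]) if x == y and x != "-")
    return matches / (end - start)


def greedy_cluster(
    items: Sequence[tuple[str, str]], threshold: float
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Greedy centroid clustering at an identity threshold.

    Sequences are processed longest-first (ties broken lexicographically
    by id, favouring full-length representatives and determinism).  Each
    sequence joins the first existing representative — in founding order —
    with identity >= *threshold*, otherwise it founds a new cluster.

    Returns the representatives (in founding order) and a membership map
    id -> representative id.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(items, key=lambda t: (-len(t[1]), t[0]))
    reps: list[tuple[str, str]] = []
    membership: dict[str, str] = {}
    for sid, seq in order:
        for rid, rseq in reps:
            if pairwise_identity(seq, rseq) >= threshold:
                membership[sid] = rid
                break
        else:
            reps.append((sid, seq))
            membership[sid] = sid
    return reps, membership


def cluster_sizes(membership: dict[str, str]) -> dict[str, int]:
    """Number of members (including the representative) per cluster."""
    sizes: dict[str, int] = {}
    for rid in membership.values():
        sizes[rid] = sizes.get(rid, 0) + 1
    return sizes
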