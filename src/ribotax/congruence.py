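"""Multi-training-set classification and congruence analytics.

Classifies one query set against several alternative training sets and
computes the statistics used to compare them: rank-wise congruence
(all sets agree / all sets mutually differ / partial), pairwise agreement
counts, unclassified tallies, mean bootstrap confidence per family, plus
exact dereplication and 97%-identity OTU tallies per family.

Taxon identity for the congruence and agreement statistics is the full
ancestral path down to the rank under comparison (a label means nothing
apart from its lineage: the same genus name reached through different
higher ranks is a different classification).  This makes congruence
non-increasing with taxonomic depth by construction.  The "unclassified"
sentinel collapses to a single distinct label regardless of lineage: two
sets both reporting it agree as labels (relevant to the mutually-different
count), but it never counts as agreement for the congruent or
pairwise-agreement statistics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import nbc
from .identity import greedy_cluster
from .nbc import Classification
from .taxonomy import N_RANKS, RANKS, UNCLASSIFIED, rank_index
from .trainset import TrainingSet

DEFAULT_OTU_IDENTITY = 0.97


@dataclass
class ClassificationTable:
    """Complete query x training-set grid of thresholded classifications."""

    queries: list[str]
    sets: list[str]
    cells: dict[tuple[str, str], Classification]
    cutoff: float

    def get(self, query: str, set_name: str) -> Classification:
        return self.cells[(query, set_name)]

    def validate(self) -> "ClassificationTable":
        for q in self.queries:
            for s in self.sets:
                if (q, s) not in self.cells:
                    raise ValueError(f"missing cell ({q!r}, {s!r})")
        return self

    @property
    def n_queries(self) -> int:
        return len(self.queries)


def set_seed(master_seed: int, set_name: str) -> int:
    """Deterministic per-training-set seed derived from the master seed."""
    return (master_seed * 1_000_003 + zlib.crc32(set_name.encode())) % (2**31)


def classify_all(
    queries: Sequence[tuple[str, str]],
    training_sets: Sequence[TrainingSet],
    cutoff: float = nbc.DEFAULT_CUTOFF,
    seed: int = 0,
    trials: int = nbc.DEFAULT_TRIALS,
    word_size: int = nbc.DEFAULT_WORD_SIZE,
) -> ClassificationTable:
    """Bootstrap-classify every query against every training set.

    Per-read bootstrap seeds are drawn from a per-set stream derived from
    the master seed and the set name, so the table is reproducible and
    adding a set does not disturb the others.
    """
    if not queries:
        raise ValueError("no queries")
    if not training_sets:
        raise ValueError("no training sets")
    names = [ts.name for ts in training_sets]
    if len(set(names)) != len(names):
        raise ValueError("training-set names must be unique")
    cells: dict[tuple[str, str], Classification] = {}
    for ts in training_sets:
        model = nbc.train(ts, word_size)
        read_seeds = np.random.default_rng(set_seed(seed, ts.name)).integers(
            0, 2**31, size=len(queries)
        )
        for (qid, seq), rseed in zip(queries, read_seeds):
            cells[(qid, ts.name)] = nbc.classify_with_confidence(
                model, seq, trials=trials, cutoff_pct=cutoff, seed=int(rseed), query_id=qid
            )
    return ClassificationTable([q for q, _ in queries], names, cells, cutoff).validate()


def _taxon_at(cell: Classification, r: int):
    """Comparison label at rank *r*: the ancestral path, or the sentinel."""
    if cell.per_rank[r][0] == UNCLASSIFIED:
        return UNCLASSIFIED
    return tuple(lab for lab, _ in cell.per_rank[: r + 1])


def rank_congruence(table: ClassificationTable, rank: int | str) -> tuple[int, int, int]:
    """(n_congruent, n_all_mutually_different, n_partial) at *rank*.

    Congruent: every set reports the same non-"unclassified" taxon (full
    path down to the rank).  Mutually different: all pairwise taxa differ
    ("unclassified" counts as a distinct label value).  Partial:
    everything else.  The three categories partition the query set.
    """
    r = rank_index(rank)
    if len(table.sets) < 2:
        raise ValueError("congruence needs at least 2 training sets")
    n_con = n_dif = n_par = 0
    for q in table.queries:
        labels = [_taxon_at(table.get(q, s), r) for s in table.sets]
        uniq = set(labels)
        if len(uniq) == 1 and labels[0] != UNCLASSIFIED:
            n_con += 1
        elif len(uniq) == len(labels):
            n_dif += 1
        else:
            n_par += 1
    return n_con, n_dif, n_par


def congruence_frame(table: ClassificationTable) -> pd.DataFrame:
    """Rank-by-rank congruence counts as a tidy DataFrame."""
    rows = []
    for r, rank in enumerate(RANKS):
        n_con, n_dif, n_par = rank_congruence(table, r)
        rows.append({"rank": rank, "n_congruent": n_con,
                     "n_mutually_different": n_dif, "n_partial": n_par,
                     "n_queries": table.n_queries})
    return pd.DataFrame(rows)


def pairwise_agreement(table: ClassificationTable, rank: int | str) -> pd.DataFrame:
    """Symmetric set-by-set matrix of identical non-unclassified labels."""
    r = rank_index(rank)
    if len(table.sets) < 2:
        raise ValueError("pairwise agreement needs at least 2 training sets")
    n = len(table.sets)
    mat = np.zeros((n, n), dtype=int)
    np.fill_diagonal(mat, table.n_queries)
    for i in range(n):
        for j in range(i + 1, n):
            count = 0
            for q in table.queries:
                a = _taxon_at(table.get(q, table.sets[i]), r)
                b = _taxon_at(table.get(q, table.sets[j]), r)
                if a == b and a != UNCLASSIFIED:
                    count += 1
            mat[i, j] = mat[j, i] = count
    return pd.DataFrame(mat, index=table.sets, columns=table.sets)


def unclassified_counts(table: ClassificationTable) -> tuple[dict[str, int], pd.DataFrame]:
    """Overall (Domain-level) and per-rank unclassified counts per set.

    A query is unclassified *overall* for a set when even its Domain rank
    is "unclassified" after thresholding; the per-rank frame counts the
    sentinel at every rank.
    """
    overall = {s: 0 for s in table.sets}
    per_rank = pd.DataFrame(0, index=list(RANKS), columns=table.sets)
    for s in table.sets:
        for q in table.queries:
            cell = table.get(q, s)
            if cell.is_unclassified:
                overall[s] += 1
            for r, rank in enumerate(RANKS):
                if cell.label(r) == UNCLASSIFIED:
                    per_rank.loc[rank, s] += 1
    return overall, per_rank


def mean_bootstrap_by_family(table: ClassificationTable) -> pd.DataFrame:
    """Mean family-rank bootstrap confidence per (set, family label).

    Groups each set's queries by the family label that set assigned
    (queries unclassified at Family are excluded) and averages the
    family-rank confidence.  Long format: set, family, mean_bootstrap, n.
    """
    fam = rank_index("Family")
    rows = []
    for s in table.sets:
        groups: dict[str, list[float]] = {}
        for q in table.queries:
            cell = table.get(q, s)
            label = cell.label(fam)
            if label == UNCLASSIFIED:
                continue
            groups.setdefault(label, []).append(cell.confidence(fam))
        for label in sorted(groups):
            confs = groups[label]
            rows.append({"set": s, "family": label,
                         "mean_bootstrap": float(np.mean(confs)), "n": len(confs)})
    return pd.DataFrame(rows, columns=["set", "family", "mean_bootstrap", "n"])


def dereplicate_exact(
    reads: Sequence[tuple[str, str]]
) -> tuple[list[tuple[str, str]], dict[str, int], dict[str, str]]:
    """Collapse exactly identical reads (after uppercase/gap-strip).

    Returns unique sequences (representative id = first-seen read id, in
    first-seen order), per-representative abundances, and the read ->
    representative membership map.
    """
    uniques: list[tuple[str, str]] = []
    by_seq: dict[str, str] = {}
    abundance: dict[str, int] = {}
    membership: dict[str, str] = {}
    for rid, seq in reads:
        norm = seq.upper().replace("-", "").replace(".", "")
        rep = by_seq.get(norm)
        if rep is None:
            by_seq[norm] = rid
            uniques.append((rid, norm))
            abundance[rid] = 1
            membership[rid] = rid
        else:
            abundance[rep] += 1
            membership[rid] = rep
    return uniques, abundance, membership


def otu_cluster(
    unique_seqs: Sequence[tuple[str, str]], threshold: float = DEFAULT_OTU_IDENTITY
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Greedy centroid OTU clustering (shared with database dereplication)."""
    return greedy_cluster(unique_seqs, threshold)


def otu_by_family(
    partition: tuple[list[tuple[str, str]], dict[str, str]],
    table: ClassificationTable,
    set_name: str,
) -> pd.DataFrame:
    """Per-family unique-sequence and OTU tallies for one training set.

    Each unique sequence takes the family label *set_name* assigned to it;
    an OTU is attributed to the family of its representative sequence.
    """
    if set_name not in table.sets:
        raise ValueError(f"unknown training set {set_name!r}")
    reps, membership = partition
    fam = rank_index("Family")
    fam_of = {q: table.get(q, set_name).label(fam) for q in table.queries}
    n_unique: dict[str, int] = {}
    for q in membership:
        n_unique[fam_of[q]] = n_unique.get(fam_of[q], 0) + 1
    n_otus: dict[str, int] = {}
    for rid, _ in reps:
        n_otus[fam_of[rid]] = n_otus.get(fam_of[rid], 0) + 1
    rows = [
        {"family": f, "n_unique": n_unique.get(f, 0), "n_otus": n_otus.get(f, 0)}
        for f in sorted(set(n_unique) | set(n_otus))
    ]
    return pd.DataFrame(rows, columns=["family", "n_unique", "n_otus"])
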