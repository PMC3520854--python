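"""Word-based naive Bayesian taxonomic classifier with bootstrap confidence.

The model follows the classical rRNA word-presence formulation: every
reference sequence is reduced to the set of overlapping nucleotide words
(8-mers by default) it contains, and a query is assigned to the genus
maximizing the joint probability of its distinct words.  With ``N`` total
training sequences, ``n(w)`` of them containing word ``w``, and ``m(w)`` of
the ``M`` sequences of genus ``G`` containing ``w``:

    prior(w)  = (n(w) + 0.5) / (N + 1)
    P(w | G)  = (m(w) + prior(w)) / (M + 1)
    score(G)  = sum over the query's distinct words of log P(w | G)

The pseudo-counts keep every conditional probability strictly positive, so
no genus score is ever ``-inf``.  Confidence is estimated by bootstrap:
each trial re-classifies a random subsample (one eighth of the query's
distinct words, drawn with replacement) and the confidence of a taxon is
the percentage of trials whose winning genus's lineage passes through it.
Lineage membership is counted on full ancestral paths, which makes
confidence non-decreasing from Genus up to Domain by construction.

All tie-breaks are lexicographic on the genus identifier, and every random
draw flows from an explicit seed, so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .taxonomy import N_RANKS, UNCLASSIFIED, TaxonomyPath, rank_index

if TYPE_CHECKING:  # pragma: no cover
    from .trainset import ReferenceSeq, TrainingSet

DEFAULT_WORD_SIZE = 8
DEFAULT_TRIALS = 100
DEFAULT_CUTOFF = 60.0

#: Fraction of a query's distinct words drawn (with replacement) per
#: bootstrap trial: subsample size = max(1, V // BOOTSTRAP_DIVISOR).
BOOTSTRAP_DIVISOR = 8

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def word_codes(sequence: str, word_size: int) -> np.ndarray:
    """Integer codes (base-4) of every valid word window, in order.

    Windows overlapping any non-ACGT character are skipped.  Sequences
    shorter than ``word_size`` yield an empty array.
    """
    if word_size < 1:
        raise ValueError("word_size must be >= 1")
    seq = sequence.upper()
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size < word_size:
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(arr, word_size)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(word_size - 1, -1, -1, dtype=np.int64)
    codes = windows.astype(np.int64) @ powers
    return codes[valid]


def extract_words(sequence: str, word_size: int = DEFAULT_WORD_SIZE) -> list[str]:
    """Every overlapping word of ``word_size``, ambiguity windows skipped.

    Duplicates are retained and order is preserved; use
    :func:`distinct_words` for the deduplicated view.
    """
    if word_size < 1:
        raise ValueError("word_size must be >= 1")
    seq = sequence.upper()
    out = []
    for i in range(len(seq) - word_size + 1):
        window = seq[i : i + word_size]
        if all(c in "ACGT" for c in window):
            out.append(window)
    return out


def distinct_words(sequence: str, word_size: int = DEFAULT_WORD_SIZE) -> list[str]:
    """Distinct valid words in order of first occurrence."""
    return list(dict.fromkeys(extract_words(sequence, word_size)))


def code_to_word(code: int, word_size: int) -> str:
    letters = []
    for _ in range(word_size):
        letters.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(letters))


@dataclass(frozen=True)
class Classification:
    """Per-rank taxon and bootstrap confidence for one query.

    ``per_rank`` holds six ``(label, confidence)`` pairs, Domain first.
    After :func:`apply_threshold`, labels below the first sub-threshold
    rank are the sentinel ``"unclassified"`` (confidences are retained).
    """

    query_id: str
    winning_genus: str
    per_rank: tuple[tuple[str, float], ...]
    threshold_applied: float | None = None

    def label(self, rank: int | str) -> str:
        return self.per_rank[rank_index(rank)][0]

    def confidence(self, rank: int | str) -> float:
        return self.per_rank[rank_index(rank)][1]

    @property
    def is_unclassified(self) -> bool:
        """True when even the Domain rank fell below the cutoff."""
        return self.per_rank[0][0] == UNCLASSIFIED


class NBCModel:
    """Trained word-probability model over a fixed set of genera.

    Genera are identified by their display label at the Genus rank and are
    stored sorted, so ``argmax`` over the score vector realizes the
    lexicographic tie-break for free.
    """

    def __init__(
        self,
        word_size: int,
        genera: list[str],
        genus_lineage: dict[str, TaxonomyPath],
        genus_counts: np.ndarray,
        doc_counts: np.ndarray,
        cond_counts: np.ndarray,
        n_train_seqs: int,
    ) -> None:
        if list(genera) != sorted(genera):
            raise ValueError("genera must be sorted")
        self.word_size = int(word_size)
        self.genera = list(genera)
        self.genus_lineage = dict(genus_lineage)
        self.genus_counts = np.asarray(genus_counts, dtype=np.int64)
        self.doc_counts = np.asarray(doc_counts, dtype=np.int64)
        self.cond_counts = np.asarray(cond_counts, dtype=np.int64)
        self.n_train_seqs = int(n_train_seqs)
        prior = (self.doc_counts + 0.5) / (self.n_train_seqs + 1.0)
        self._prior = prior
        self.log_cond = np.log(
            (self.cond_counts + prior[None, :]) / (self.genus_counts[:, None] + 1.0)
        )
        # rank_groups[r, g]: integer id of genus g's ancestral path prefix
        # down to rank r; equal ids <=> identical lineage prefix.
        groups = np.empty((N_RANKS, len(genera)), dtype=np.int64)
        for r in range(N_RANKS):
            seen: dict[tuple[str, ...], int] = {}
            for g, genus in enumerate(genera):
                pref = self.genus_lineage[genus].prefix(r)
                groups[r, g] = seen.setdefault(pref, len(seen))
        self.rank_groups = groups

    def word_prior(self, word: str | int) -> float:
        """prior(w) = (n(w) + 0.5) / (N + 1); strictly inside (0, 1)."""
        return float(self._prior[self._code(word)])

    def cond_prob(self, genus: str, word: str | int) -> float:
        """P(w | G); strictly positive thanks to the pseudo-counts."""
        g = self.genera.index(genus)
        return float(np.exp(self.log_cond[g, self._code(word)]))

    def _code(self, word: str | int) -> int:
        if isinstance(word, str):
            codes = word_codes(word, self.word_size)
            if codes.size != 1:
                raise ValueError(f"not a single valid word of size {self.word_size}: {word!r}")
            return int(codes[0])
        return int(word)


def train(refs: "TrainingSet | Iterable[ReferenceSeq]", word_size: int = DEFAULT_WORD_SIZE) -> NBCModel:
    """Train an :class:`NBCModel` from labelled reference sequences.

    Counts, for every word, the number of training sequences containing it
    (word presence, not multiplicity) overall and per genus, then applies
    the pseudo-count formulas documented in the module docstring.
    """
    ref_list = list(getattr(refs, "refs", refs))
    if not ref_list:
        raise ValueError("empty training set")
    lineages: dict[str, TaxonomyPath] = {}
    for ref in ref_list:
        if ref.taxonomy is None:
            raise ValueError(f"reference {ref.id!r} has no taxonomy")
        genus = ref.taxonomy.display(N_RANKS - 1)
        prev = lineages.setdefault(genus, ref.taxonomy)
        if prev.display_labels != ref.taxonomy.display_labels:
            raise ValueError(f"genus {genus!r} appears with two different lineages")
    genera = sorted(lineages)
    gidx = {g: i for i, g in enumerate(genera)}
    n_words = 4**word_size
    doc = np.zeros(n_words, dtype=np.int64)
    cond = np.zeros((len(genera), n_words), dtype=np.int64)
    counts = np.zeros(len(genera), dtype=np.int64)
    for ref in ref_list:
        codes = np.unique(word_codes(ref.sequence, word_size))
        g = gidx[ref.taxonomy.display(N_RANKS - 1)]
        doc[codes] += 1
        cond[g, codes] += 1
        counts[g] += 1
    return NBCModel(word_size, genera, lineages, counts, doc, cond, len(ref_list))


def classify(model: NBCModel, read: str) -> tuple[str, dict[str, float]]:
    """Maximum-joint-probability genus for *read*.

    Returns the winning genus (ties broken toward the lexicographically
    smallest identifier) and the per-genus log-joint scores.
    """
    codes = np.unique(word_codes(read, model.word_size))
    if codes.size == 0:
        raise ValueError("no classifiable words")
    scores = model.log_cond[:, codes].sum(axis=1)
    win = int(np.argmax(scores))  # first max = lexicographically smallest
    return model.genera[win], {g: float(s) for g, s in zip(model.genera, scores)}


def bootstrap_confidence(
    model: NBCModel,
    read: str,
    trials: int = DEFAULT_TRIALS,
    seed: int | None = None,
    query_id: str = "",
) -> Classification:
    """Bootstrap classification of *read* with per-rank confidence.

    Each trial draws ``max(1, V // 8)`` of the read's ``V`` distinct words
    uniformly with replacement, classifies on that subset, and records the
    winning genus.  Confidence at a rank is 100 x the fraction of trials
    whose winner shares the reported genus's ancestral path down to that
    rank, so ancestors always score at least as high as descendants.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    codes = np.unique(word_codes(read, model.word_size))
    if codes.size == 0:
        raise ValueError("no classifiable words")
    v = codes.size
    subset = max(1, v // BOOTSTRAP_DIVISOR)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v, size=(trials, subset))
    trial_scores = model.log_cond[:, codes[idx]].sum(axis=2)  # (G, trials)
    winners = np.argmax(trial_scores, axis=0)
    wins = np.bincount(winners, minlength=len(model.genera))
    win_g = int(np.argmax(wins))
    lineage = model.genus_lineage[model.genera[win_g]]
    per_rank = []
    for r in range(N_RANKS):
        grp = model.rank_groups[r]
        conf = 100.0 * float(np.mean(grp[winners] == grp[win_g]))
        per_rank.append((lineage.display(r), conf))
    return Classification(query_id, model.genera[win_g], tuple(per_rank))


def apply_threshold(c: Classification, cutoff_pct: float = DEFAULT_CUTOFF) -> Classification:
    """Truncate *c* at the reporting threshold.

    Scanning Domain to Genus, the first rank with confidence strictly
    below ``cutoff_pct`` and every deeper rank are relabelled
    ``"unclassified"`` (confidence >= cutoff passes).  Truncation is
    prefix-monotone: once a rank fails, all deeper ranks fail.
    """
    if not 0.0 <= cutoff_pct <= 100.0:
        raise ValueError("cutoff must be in [0, 100]")
    per_rank = []
    failed = False
    for label, conf in c.per_rank:
        failed = failed or conf < cutoff_pct
        per_rank.append((UNCLASSIFIED if failed else label, conf))
    return Classification(c.query_id, c.winning_genus, tuple(per_rank), cutoff_pct)


def classify_with_confidence(
    model: NBCModel,
    read: str,
    trials: int = DEFAULT_TRIALS,
    cutoff_pct: float = DEFAULT_CUTOFF,
    seed: int | None = None,
    query_id: str = "",
) -> Classification:
    """Bootstrap classification followed by threshold truncation."""
    return apply_threshold(
        bootstrap_confidence(model, read, trials=trials, seed=seed, query_id=query_id),
        cutoff_pct,
    )
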