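"""Construction of an environment-specific custom training database.

Pipeline for turning candidate full-length rRNA clone-library sequences
into a classifier training set for an under-characterized habitat:

1. keep near-full-length candidates (>= 1250 bp by default);
2. dereplicate at 99% identity to cluster representatives;
3. find each representative's best cultured hit by global-alignment
   identity;
4. assign taxonomy: a hit above 95% identity lends its genus-level
   lineage; otherwise the representative is placed at the class supplied
   by the user's phylogenetic framework and marked *incertae sedis* below
   it, preserving any environment-specific clade name (e.g. "firm-4") at
   the Family rank.

Clade membership is an input (the ``clade_map``), not computed: it comes
from a phylogenetic analysis and taxonomic judgement outside this
package's scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .identity import greedy_cluster, pairwise_identity
from .taxonomy import TaxonomyPath
from .trainset import ReferenceSeq, TrainingSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 1250
DEFAULT_DEREP_IDENTITY = 0.99

#: Strict lower bound on identity for adopting the cultured hit's genus.
GENUS_IDENTITY = 0.95

BASIS_GENUS = "genus_by_identity"
BASIS_CLASS = "class_incertae_sedis"


@dataclass(frozen=True)
class CladeInfo:
    """User-supplied placement for a candidate without a close cultured hit."""

    clade_class: str
    clade_name: str | None = None
    genus_name: str | None = None


@dataclass(frozen=True)
class CladeAssignment:
    """Provenance of one representative's taxonomy assignment."""

    novel_id: str
    hit_id: str | None
    identity: float
    clade_class: str | None
    assigned: TaxonomyPath
    basis: str


def length_filter(
    seqs: Sequence[tuple[str, str]], min_len: int = DEFAULT_MIN_LENGTH
) -> list[tuple[str, str]]:
    """Keep sequences whose ungapped length is at least *min_len* (inclusive)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [(sid, seq) for sid, seq in seqs if len(seq.replace("-", "").replace(".", "")) >= min_len]
    logger.info("length filter >=%d bp: kept %d of %d", min_len, len(kept), len(seqs))
    return kept


def dereplicate(
    seqs: Sequence[tuple[str, str]], identity_threshold: float = DEFAULT_DEREP_IDENTITY
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Greedy centroid dereplication; see :func:`ribotax.identity.greedy_cluster`."""
    reps, membership = greedy_cluster(seqs, identity_threshold)
    logger.info("dereplication at %.0f%%: %d -> %d representatives",
                100 * identity_threshold, len(seqs), len(reps))
    return reps, membership


def best_cultured_hit(novel: str, cultured: TrainingSet) -> tuple[str, float]:
    """Cultured reference maximizing identity to *novel* (ties lexicographic)."""
    if not cultured.refs:
        raise ValueError("empty cultured reference set")
    best_id, best_ident = None, -1.0
    for ref in sorted(cultured.refs, key=lambda r: r.id):
        ident = pairwise_identity(novel, ref.sequence)
        if ident > best_ident:
            best_id, best_ident = ref.id, ident
    return best_id, best_ident


def assign_taxonomy(
    novel_id: str,
    hit: ReferenceSeq,
    identity: float,
    clade_class: str | None = None,
    clade_name: str | None = None,
    genus_name: str | None = None,
) -> CladeAssignment:
    """Apply the genus / class-incertae-sedis placement rule.

    Identity strictly above 95% adopts the cultured hit's full lineage
    (the novel sequence is placed in the hit's genus).  At or below 95%
    the sequence is placed in the hit's domain and phylum with
    *clade_class* at Class, and the ranks below Class are incertae-sedis:
    a supplied *clade_name* occupies Family, a retained *genus_name*
    occupies Genus, and remaining ranks take placeholders named after the
    deepest assigned label.
    """
    if hit.taxonomy is None:
        raise ValueError(f"cultured hit {hit.id!r} has no taxonomy")
    if identity > GENUS_IDENTITY:
        return CladeAssignment(novel_id, hit.id, identity, None, hit.taxonomy, BASIS_GENUS)
    if clade_class is None:
        raise ValueError(f"unplaced sequence {novel_id!r}: identity {identity:.3f} "
                         f"<= {GENUS_IDENTITY} and no clade_class supplied")
    domain, phylum = hit.taxonomy.labels[0], hit.taxonomy.labels[1]
    order = clade_class
    family = clade_name if clade_name is not None else clade_class
    genus = genus_name if genus_name is not None else family
    path = TaxonomyPath(
        (domain, phylum, clade_class, order, family, genus),
        (False, False, False, True, True, True),
    )
    return CladeAssignment(novel_id, hit.id, identity, clade_class, path, BASIS_CLASS)


def read_clade_map(path: str | Path) -> dict[str, CladeInfo]:
    """Parse ``id<TAB>class_label[<TAB>clade_name[<TAB>genus_name]]`` lines."""
    mapping: dict[str, CladeInfo] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: expected id<TAB>class_label")
            mapping[fields[0]] = CladeInfo(
                fields[1],
                fields[2] if len(fields) > 2 and fields[2] else None,
                fields[3] if len(fields) > 3 and fields[3] else None,
            )
    return mapping


def build_custom_db(
    candidates: Sequence[tuple[str, str]],
    cultured: TrainingSet,
    clade_map: Mapping[str, CladeInfo] | None = None,
    min_len: int = DEFAULT_MIN_LENGTH,
    derep_threshold: float = DEFAULT_DEREP_IDENTITY,
    name: str = "custom",
) -> tuple[TrainingSet, list[CladeAssignment]]:
    """Run the full custom-database pipeline.

    Returns the resulting training set (cluster representatives with their
    assigned taxonomies) and the per-representative provenance records.
    Candidates that neither hit a cultured sequence above 95% identity nor
    appear in *clade_map* are collected and reported in one error.
    """
    clade_map = dict(clade_map or {})
    kept = length_filter(candidates, min_len)
    reps, membership = dereplicate(kept, derep_threshold)
    cultured_by_id = {r.id: r for r in cultured.refs}
    assignments: list[CladeAssignment] = []
    unresolved: list[str] = []
    refs: list[ReferenceSeq] = []
    for rep_id, seq in reps:
        hit_id, ident = best_cultured_hit(seq, cultured)
        hit = cultured_by_id[hit_id]
        if ident > GENUS_IDENTITY:
            assignment = assign_taxonomy(rep_id, hit, ident)
        elif rep_id in clade_map:
            info = clade_map[rep_id]
            assignment = assign_taxonomy(
                rep_id, hit, ident, info.clade_class, info.clade_name, info.genus_name
            )
        else:
            unresolved.append(rep_id)
            continue
        assignments.append(assignment)
        refs.append(ReferenceSeq(rep_id, seq, assignment.assigned))
    if unresolved:
        raise ValueError(
            "unplaced sequences (no >95% cultured hit and no clade_map entry): "
            + ", ".join(sorted(unresolved))
        )
    ts = TrainingSet(name, refs).validate()
    return ts, assignments
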