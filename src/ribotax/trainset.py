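"""Training-set container and FASTA / mothur-dialect taxonomy I/O.

A training set is the pair of files a naive Bayesian rRNA classifier is
trained from: an unaligned FASTA of reference sequences and a
tab-separated taxonomy file mapping each sequence id to a
semicolon-delimited lineage ("id<TAB>Domain;...;Genus;").  This module
reads and writes that dialect, validates the container invariants, merges
(augments) a base set with a custom database, and (de)serializes trained
models as flat text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from .nbc import NBCModel
from .taxonomy import N_RANKS, TaxonomyPath

_GAP_TABLE = str.maketrans("", "", "-.")


@dataclass
class ReferenceSeq:
    """One labelled reference sequence."""

    id: str
    sequence: str
    taxonomy: TaxonomyPath | None = None

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for id {self.id!r}")


@dataclass
class TrainingSet:
    """Named, ordered collection of reference sequences."""

    name: str
    refs: list[ReferenceSeq] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.refs)

    def ids(self) -> list[str]:
        return [r.id for r in self.refs]

    def validate(self) -> "TrainingSet":
        """Check container invariants; returns self for chaining.

        Raises on: empty set, duplicate ids, missing or non-6-rank
        taxonomies, and a taxon label appearing under two different
        parent lineages (which would corrupt congruence attribution).
        """
        if not self.refs:
            raise ValueError("empty training set")
        seen: set[str] = set()
        for ref in self.refs:
            if ref.id in seen:
                raise ValueError(f"duplicate sequence id {ref.id!r}")
            seen.add(ref.id)
            if ref.taxonomy is None:
                raise ValueError(f"reference {ref.id!r} has no taxonomy")
        for r in range(1, N_RANKS):
            parents: dict[str, tuple[str, ...]] = {}
            for ref in self.refs:
                tax = ref.taxonomy
                label = tax.display(r)
                parent = tax.prefix(r - 1)
                prev = parents.setdefault(label, parent)
                if prev != parent:
                    raise ValueError(
                        f"label {label!r} at rank {r} appears under two parents: "
                        f"{prev} and {parent}"
                    )
        return self

    def taxonomy_map(self) -> dict[str, TaxonomyPath]:
        return {r.id: r.taxonomy for r in self.refs}


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA into ``(id, sequence)`` pairs in file order.

    The id is the header token up to the first whitespace; sequences are
    uppercased and alignment gaps ('-', '.') are stripped.  Duplicate ids
    and empty records are errors.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if not record.id:
            raise ValueError(f"{path}: record without id")
        if record.id in seen:
            raise ValueError(f"{path}: duplicate id {record.id!r}")
        seen.add(record.id)
        seq = str(record.seq).upper().translate(_GAP_TABLE)
        if not seq:
            raise ValueError(f"{path}: empty record {record.id!r}")
        pairs.append((record.id, seq))
    return pairs


def write_fasta(refs: Iterable[ReferenceSeq] | Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write sequences as wrapped FASTA (deterministic layout)."""
    with open(path, "w") as fh:
        for item in refs:
            sid, seq = (item.id, item.sequence) if isinstance(item, ReferenceSeq) else item
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyPath]:
    """Parse a mothur-dialect taxonomy file.

    Each non-blank line is ``id<TAB>Rank1;Rank2;...;`` (trailing semicolon
    optional).  Lineages shorter than six ranks are padded downward with
    incertae-sedis placeholders named after the deepest named label; more
    than six ranks is an error.
    """
    mapping: dict[str, TaxonomyPath] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "\t" not in line:
                raise ValueError(f"{path}:{lineno}: missing tab separator")
            sid, lineage = line.split("\t", 1)
            sid = sid.strip()
            if not sid:
                raise ValueError(f"{path}:{lineno}: missing sequence id")
            if sid in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate id {sid!r}")
            try:
                mapping[sid] = TaxonomyPath.from_lineage(lineage)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return mapping


def write_taxonomy(mapping: Mapping[str, TaxonomyPath], path: str | Path) -> None:
    """Write ``id<TAB>lineage;`` lines; flagged ranks get the suffix."""
    with open(path, "w") as fh:
        for sid, tax in mapping.items():
            fh.write(f"{sid}\t{tax.to_lineage()}\n")


def load_training_set(fasta_path: str | Path, tax_path: str | Path, name: str | None = None) -> TrainingSet:
    """Read the FASTA + taxonomy pair into a validated TrainingSet."""
    pairs = read_fasta(fasta_path)
    taxa = read_taxonomy(tax_path)
    refs = []
    for sid, seq in pairs:
        if sid not in taxa:
            raise ValueError(f"sequence {sid!r} has no taxonomy entry in {tax_path}")
        refs.append(ReferenceSeq(sid, seq, taxa[sid]))
    return TrainingSet(name or Path(fasta_path).stem, refs).validate()


def save_training_set(ts: TrainingSet, fasta_path: str | Path, tax_path: str | Path) -> None:
    write_fasta(ts.refs, fasta_path)
    write_taxonomy(ts.taxonomy_map(), tax_path)


def augment(base: TrainingSet, custom: TrainingSet, name: str) -> TrainingSet:
    """Union of *base* and *custom* references (base first).

    Emulates extending a public training set with an environment-specific
    database.  Shared sequence ids are a hard error (silent override would
    corrupt congruence attribution); augmenting with an empty custom set
    returns an equal copy of *base*.
    """
    collisions = sorted(set(base.ids()) & set(custom.ids()))
    if collisions:
        raise ValueError(f"id collision between training sets: {', '.join(collisions)}")
    merged = TrainingSet(name, list(base.refs) + list(custom.refs))
    if merged.refs:
        merged.validate()
    return merged


# --- flat-text model serialization -------------------------------------------

_MODEL_MAGIC = "#ribotax-model\tv1"


def save_model(model: NBCModel, path: str | Path) -> None:
    """Serialize a trained model as inspectable flat text.

    Layout: header lines, then one ``G`` line per genus (label, number of
    training sequences, lineage), one ``W`` line per word present in the
    training set (code, document count) and one ``C`` line per non-zero
    (genus, word) presence count.
    """
    with open(path, "w") as fh:
        fh.write(_MODEL_MAGIC + "\n")
        fh.write(f"#word_size\t{model.word_size}\n")
        fh.write(f"#n_train_seqs\t{model.n_train_seqs}\n")
        for genus in model.genera:
            g = model.genera.index(genus)
            fh.write(f"G\t{genus}\t{model.genus_counts[g]}\t{model.genus_lineage[genus].to_lineage()}\n")
        for code in np.nonzero(model.doc_counts)[0]:
            fh.write(f"W\t{code}\t{model.doc_counts[code]}\n")
        gs, ws = np.nonzero(model.cond_counts)
        for g, w in zip(gs, ws):
            fh.write(f"C\t{g}\t{w}\t{model.cond_counts[g, w]}\n")


def load_model(path: str | Path) -> NBCModel:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _MODEL_MAGIC:
        raise ValueError(f"{path}: not a ribotax model file")
    word_size = n_train = None
    genera: list[str] = []
    lineages: dict[str, TaxonomyPath] = {}
    counts: list[int] = []
    w_rows: list[tuple[int, int]] = []
    c_rows: list[tuple[int, int, int]] = []
    for line in lines[1:]:
        if not line:
            continue
        fields = line.split("\t")
        if fields[0] == "#word_size":
            word_size = int(fields[1])
        elif fields[0] == "#n_train_seqs":
            n_train = int(fields[1])
        elif fields[0] == "G":
            genera.append(fields[1])
            counts.append(int(fields[2]))
            lineages[fields[1]] = TaxonomyPath.from_lineage(fields[3])
        elif fields[0] == "W":
            w_rows.append((int(fields[1]), int(fields[2])))
        elif fields[0] == "C":
            c_rows.append((int(fields[1]), int(fields[2]), int(fields[3])))
        else:
            raise ValueError(f"{path}: unrecognized model line {line!r}")
    if word_size is None or n_train is None or not genera:
        raise ValueError(f"{path}: incomplete model file")
    n_words = 4**word_size
    doc = np.zeros(n_words, dtype=np.int64)
    for code, n in w_rows:
        doc[code] = n
    cond = np.zeros((len(genera), n_words), dtype=np.int64)
    for g, w, m in c_rows:
        cond[g, w] = m
    return NBCModel(word_size, genera, lineages, np.array(counts), doc, cond, n_train)
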