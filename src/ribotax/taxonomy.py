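"""Six-rank bacterial lineages with *incertae sedis* marking.

Classification output and training labels both use an ordered lineage over
the six ranks predominantly used for 16S rRNA taxonomy: Domain, Phylum,
Class, Order, Family, Genus.  A rank can be flagged *incertae sedis*: the
position is deliberately left taxonomically unsettled below a confidently
assigned rank (e.g. a clade known only from environmental sequences).

In memory a flagged label never carries the ``_incertae_sedis`` suffix; the
flag is a separate boolean.  Serialization (``to_lineage``) appends the
suffix, and parsing (``from_lineage``) strips it back to a flag, so lineage
strings round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The six ranks, shallowest first.
RANKS: tuple[str, ...] = ("Domain", "Phylum", "Class", "Order", "Family", "Genus")
N_RANKS = len(RANKS)

INCERTAE_SUFFIX = "_incertae_sedis"

#: Sentinel label reported for ranks whose bootstrap confidence falls below
#: the reporting threshold.
UNCLASSIFIED = "unclassified"

_RANK_INDEX = {name: i for i, name in enumerate(RANKS)}
_RANK_INDEX.update({name.lower(): i for i, name in enumerate(RANKS)})


def rank_index(rank: int | str) -> int:
    """Resolve a rank given as index (0..5) or name ('Family')."""
    if isinstance(rank, str):
        try:
            return _RANK_INDEX[rank if rank in _RANK_INDEX else rank.lower()]
        except KeyError:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}") from None
    r = int(rank)
    if not 0 <= r < N_RANKS:
        raise ValueError(f"rank index {r} outside 0..{N_RANKS - 1}")
    return r


@dataclass(frozen=True)
class TaxonomyPath:
    """An ordered six-rank lineage (Domain..Genus).

    Parameters
    ----------
    labels
        Exactly six non-empty labels, shallowest first.  Labels may not
        contain semicolons or tabs (reserved by the lineage serialization).
    incertae
        Per-rank *incertae sedis* flags; defaults to all ``False``.
    """

    labels: tuple[str, ...]
    incertae: tuple[bool, ...] = field(default=(False,) * N_RANKS)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        incertae = tuple(bool(f) for f in self.incertae)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "incertae", incertae)
        if len(labels) != N_RANKS:
            raise ValueError(f"lineage needs exactly {N_RANKS} ranks, got {len(labels)}")
        if len(incertae) != N_RANKS:
            raise ValueError("incertae flags must align with the six labels")
        for lab in labels:
            if not lab:
                raise ValueError("empty rank label")
            if ";" in lab or "\t" in lab:
                raise ValueError(f"label {lab!r} contains a reserved character")

    def display(self, rank: int | str) -> str:
        """Label at *rank*, with the incertae-sedis suffix when flagged."""
        r = rank_index(rank)
        lab = self.labels[r]
        return lab + INCERTAE_SUFFIX if self.incertae[r] else lab

    @property
    def display_labels(self) -> tuple[str, ...]:
        return tuple(self.display(r) for r in range(N_RANKS))

    def prefix(self, rank: int | str) -> tuple[str, ...]:
        """Display labels from Domain down to *rank* inclusive."""
        return self.display_labels[: rank_index(rank) + 1]

    def to_lineage(self) -> str:
        """Semicolon-delimited lineage string with trailing semicolon."""
        return ";".join(self.display_labels) + ";"

    @classmethod
    def from_lineage(cls, text: str, pad: bool = True) -> "TaxonomyPath":
        """Parse a semicolon-delimited lineage.

        A trailing semicolon is optional.  Labels ending in
        ``_incertae_sedis`` have the suffix stripped and the flag set.
        With ``pad=True`` (default) lineages shorter than six ranks are
        extended downward with placeholders named after the deepest named
        label and flagged incertae sedis; more than six ranks is an error.
        """
        tokens = [t.strip() for t in text.split(";")]
        if tokens and tokens[-1] == "":
            tokens.pop()
        if not tokens:
            raise ValueError("empty lineage")
        if len(tokens) > N_RANKS:
            raise ValueError(f"lineage has {len(tokens)} ranks; at most {N_RANKS} supported")
        labels: list[str] = []
        flags: list[bool] = []
        for tok in tokens:
            if not tok:
                raise ValueError(f"empty rank label in lineage {text!r}")
            if tok.endswith(INCERTAE_SUFFIX):
                base = tok[: -len(INCERTAE_SUFFIX)]
                if not base:
                    raise ValueError(f"bare incertae-sedis label in {text!r}")
                labels.append(base)
                flags.append(True)
            else:
                labels.append(tok)
                flags.append(False)
        if len(labels) < N_RANKS:
            if not pad:
                raise ValueError(f"lineage has {len(labels)} ranks; expected {N_RANKS}")
            deepest = labels[-1]
            while len(labels) < N_RANKS:
                labels.append(deepest)
                flags.append(True)
        return cls(tuple(labels), tuple(flags))
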