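"""Seeded synthetic data: taxonomies, references, amplicon reads, holdouts.

Emulates the statistical structure of a 16S rRNA amplicon study of an
under-characterized habitat: a six-rank reference taxonomy, per-genus
reference sequence families with controlled divergence, short
error-bearing reads excised from a hypervariable-region-like subwindow,
and "novel clade" holdout designs in which query lineages are absent from
the public-style base training sets but present in a custom database.

Evolution is substitution-only (no indels): a root sequence is mutated
down the hierarchy at per-rank substitution fractions, which keeps
pairwise identities and window excision well-defined.  Every output is a
deterministic function of the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .taxonomy import N_RANKS, TaxonomyPath
from .trainset import ReferenceSeq, TrainingSet

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

# Sub-stream tags so references, reads and holdout bookkeeping draw from
# independent deterministic streams of the one scenario seed.
_STREAM_REFS = 11
_STREAM_READS = 13
_STREAM_HOLDOUT = 17


@dataclass(frozen=True)
class Divergence:
    """Per-rank substitution fractions applied while descending the tree."""

    within_genus: float = 0.02
    between_genera: float = 0.08
    between_families: float = 0.15
    between_phyla: float = 0.25

    def validate(self) -> None:
        seq = (self.within_genus, self.between_genera, self.between_families, self.between_phyla)
        if any(not 0.0 <= d <= 1.0 for d in seq):
            raise ValueError("divergences must be fractions in [0, 1]")
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError("divergences must strictly increase with rank distance")


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Defaults emulate a V1/V2-style amplicon study: 16 genera in 4 phyla,
    5 references of 1300 bp per genus, 500 reads of 250 bp excised from
    positions 20-340 with 0.5% per-base substitution error.
    """

    seed: int = 1
    n_phyla: int = 4
    families_per_phylum: int = 2
    genera_per_family: int = 2
    refs_per_genus: int = 5
    ref_length: int = 1300
    divergence: Divergence = field(default_factory=Divergence)
    read_window: tuple[int, int] = (20, 340)
    read_length: int = 250
    read_error_rate: float = 0.005
    n_reads: int = 500
    holdout_genera: list[str] | None = None
    holdout_enrichment: float = 0.5

    def validate(self) -> None:
        for name in ("n_phyla", "families_per_phylum", "genera_per_family",
                     "refs_per_genus", "ref_length", "read_length", "n_reads"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.divergence.validate()
        start, end = self.read_window
        if not 0 <= start < end <= self.ref_length:
            raise ValueError("read_window must fit inside ref_length")
        if not 0.0 <= self.read_error_rate <= 0.25:
            raise ValueError("read_error_rate must be in [0, 0.25]")
        if not 0.0 <= self.holdout_enrichment <= 1.0:
            raise ValueError("holdout_enrichment must be in [0, 1]")

    def to_flat(self) -> dict[str, str]:
        """Flat key-value view for config echo files."""
        d = {
            "seed": self.seed, "n_phyla": self.n_phyla,
            "families_per_phylum": self.families_per_phylum,
            "genera_per_family": self.genera_per_family,
            "refs_per_genus": self.refs_per_genus, "ref_length": self.ref_length,
            "divergence.within_genus": self.divergence.within_genus,
            "divergence.between_genera": self.divergence.between_genera,
            "divergence.between_families": self.divergence.between_families,
            "divergence.between_phyla": self.divergence.between_phyla,
            "read_window": f"{self.read_window[0]}-{self.read_window[1]}",
            "read_length": self.read_length,
            "read_error_rate": self.read_error_rate, "n_reads": self.n_reads,
            "holdout_genera": ",".join(self.holdout_genera or []),
            "holdout_enrichment": self.holdout_enrichment,
        }
        return {k: str(v) for k, v in d.items()}


def generate_taxonomy(config: ScenarioConfig) -> list[TaxonomyPath]:
    """Systematically labelled 6-rank hierarchy; one path per genus.

    Domain is fixed "Bacteria"; Class is 1:1 with phylum and Order 1:1
    with family, so the only branching ranks are Phylum, Family, Genus.
    """
    config.validate()
    paths = []
    for p in range(1, config.n_phyla + 1):
        for f in range(1, config.families_per_phylum + 1):
            for g in range(1, config.genera_per_family + 1):
                paths.append(TaxonomyPath((
                    "Bacteria", f"P{p}", f"P{p}_C", f"P{p}_F{f}_O",
                    f"P{p}_F{f}", f"P{p}_F{f}_G{g}",
                )))
    return paths


def _mutate(seq: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute ~Binomial(L, fraction) uniformly chosen positions."""
    out = seq.copy()
    k = rng.binomial(len(seq), fraction)
    if k == 0:
        return out
    pos = rng.choice(len(seq), size=k, replace=False)
    # new base uniform over the three alternatives (transitions and
    # transversions equiprobable)
    out[pos] = (out[pos] + rng.integers(1, 4, size=k)) % 4
    return out


def _to_str(arr: np.ndarray) -> str:
    return _ALPHABET[arr].tobytes().decode("ascii")


def generate_references(config: ScenarioConfig) -> tuple[TrainingSet, dict[str, TaxonomyPath]]:
    """References for every genus, plus the truth map ref_id -> lineage.

    A uniform-random root sequence is mutated down the hierarchy at the
    per-rank divergence fractions; each genus's references then mutate
    the genus ancestor at the within-genus fraction.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_REFS]))
    d = config.divergence
    root = rng.integers(0, 4, size=config.ref_length, dtype=np.int8)
    paths = generate_taxonomy(config)
    refs: list[ReferenceSeq] = []
    truth: dict[str, TaxonomyPath] = {}
    i = 0
    for p in range(config.n_phyla):
        phy = _mutate(root, d.between_phyla, rng)
        for f in range(config.families_per_phylum):
            fam = _mutate(phy, d.between_families, rng)
            for g in range(config.genera_per_family):
                gen = _mutate(fam, d.between_genera, rng)
                path = paths[i]
                i += 1
                genus = path.labels[-1]
                for r in range(1, config.refs_per_genus + 1):
                    rid = f"{genus}_R{r}"
                    seq = _to_str(_mutate(gen, d.within_genus, rng))
                    refs.append(ReferenceSeq(rid, seq, path))
                    truth[rid] = path
    return TrainingSet("reference", refs).validate(), truth


def _draw_reads(
    config: ScenarioConfig,
    refs: TrainingSet,
    rng: np.random.Generator,
    holdout: Sequence[str] = (),
    enrichment: float = 0.0,
) -> tuple[list[tuple[str, str]], dict[str, TaxonomyPath]]:
    by_genus: dict[str, list[ReferenceSeq]] = {}
    for ref in refs.refs:
        by_genus.setdefault(ref.taxonomy.labels[-1], []).append(ref)
    start, end = config.read_window
    if end > min(len(r.sequence) for r in refs.refs):
        raise ValueError("read_window outside reference bounds")
    holdout_set = [g for g in sorted(by_genus) if g in set(holdout)]
    other = [g for g in sorted(by_genus) if g not in set(holdout)]
    reads: list[tuple[str, str]] = []
    truth: dict[str, TaxonomyPath] = {}
    for i in range(config.n_reads):
        if holdout_set and rng.random() < enrichment:
            genus = holdout_set[rng.integers(len(holdout_set))]
        else:
            pool = other or holdout_set
            genus = pool[rng.integers(len(pool))]
        source = by_genus[genus][rng.integers(len(by_genus[genus]))]
        window = source.sequence[start:end][: config.read_length]
        arr = np.frombuffer(window.encode("ascii"), dtype=np.uint8)
        codes = np.zeros(len(arr), dtype=np.int8)
        for b, c in zip(b"ACGT", range(4)):
            codes[arr == b] = c
        errs = rng.random(len(codes)) < config.read_error_rate
        if errs.any():
            codes[errs] = (codes[errs] + rng.integers(1, 4, size=int(errs.sum()))) % 4
        rid = f"read{i:05d}"
        reads.append((rid, _to_str(codes)))
        truth[rid] = source.taxonomy
    return reads, truth


def generate_reads(
    config: ScenarioConfig, refs: TrainingSet
) -> tuple[list[tuple[str, str]], dict[str, TaxonomyPath]]:
    """Forward-oriented reads drawn uniformly over genera, then references.

    Each read excises the configured window from its source reference,
    truncates to ``read_length`` and applies independent per-base
    substitution errors at ``read_error_rate``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_READS]))
    return _draw_reads(config, refs, rng)


# --- holdout ("novel clade") scenario ----------------------------------------

_BASE_TAGS = ("dbA", "dbB", "dbC")


@dataclass
class HoldoutScenario:
    """Three jackknifed base sets, a custom set, reads and ground truth."""

    config: ScenarioConfig
    base_sets: list[TrainingSet]
    custom_set: TrainingSet
    reads: list[tuple[str, str]]
    read_truth: dict[str, TaxonomyPath]
    ref_truth: dict[str, TaxonomyPath]
    holdout_genera: list[str]
    dialect_maps: dict[str, dict[str, str]]


def apply_dialect(tax: TaxonomyPath, mapping: dict[str, str]) -> TaxonomyPath:
    """Rename labels above genus through a dialect map (invertible)."""
    labels = list(tax.labels)
    for r in range(1, N_RANKS - 1):  # Phylum..Family; Domain and Genus kept
        labels[r] = mapping.get(labels[r], labels[r])
    return TaxonomyPath(tuple(labels), tax.incertae)


def invert_dialect(mapping: dict[str, str]) -> dict[str, str]:
    return {v: k for k, v in mapping.items()}


def make_holdout_scenario(config: ScenarioConfig) -> HoldoutScenario:
    """Build the novel-clade experiment the congruence evaluation runs on.

    Holdout genera (by default all genera of one seeded-chosen phylum, so
    the held-out lineages have no close relatives left) are removed from
    the three base sets and form the custom set with correct taxonomy.
    Each base set additionally drops a distinct third of every remaining
    genus's references (jackknife) and renames all labels above genus
    through its own recorded dialect map, emulating the disagreeing
    taxonomic frameworks of independently curated public databases.
    Reads are drawn with ``holdout_enrichment`` probability from holdout
    genera.
    """
    config.validate()
    refs, ref_truth = generate_references(config)
    genera = sorted({r.taxonomy.labels[-1] for r in refs.refs})
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_HOLDOUT]))
    if config.holdout_genera:
        unknown = sorted(set(config.holdout_genera) - set(genera))
        if unknown:
            raise ValueError(f"unknown holdout genera: {', '.join(unknown)}")
        holdout = sorted(config.holdout_genera)
    else:
        phylum = f"P{rng.integers(1, config.n_phyla + 1)}"
        holdout = [g for g in genera if g.startswith(phylum + "_")]
    if not holdout:
        raise ValueError("holdout_genera is empty")

    custom_refs = [r for r in refs.refs if r.taxonomy.labels[-1] in set(holdout)]
    base_refs = [r for r in refs.refs if r.taxonomy.labels[-1] not in set(holdout)]
    custom_set = TrainingSet("custom", custom_refs).validate()

    # per-genus round-robin jackknife groups; base set k drops group k
    drop_group: dict[str, int] = {}
    by_genus: dict[str, list[ReferenceSeq]] = {}
    for r in base_refs:
        by_genus.setdefault(r.taxonomy.labels[-1], []).append(r)
    for gi, genus in enumerate(sorted(by_genus)):
        members = by_genus[genus]
        perm = rng.permutation(len(members))
        # rotate the uneven remainder across genera so set sizes balance
        for slot, idx in enumerate(perm):
            drop_group[members[idx].id] = (slot + gi) % 3

    above_genus = sorted({lab for r in base_refs for lab in r.taxonomy.labels[1:-1]})
    base_sets: list[TrainingSet] = []
    dialect_maps: dict[str, dict[str, str]] = {}
    for k, tag in enumerate(_BASE_TAGS):
        mapping = {lab: f"{lab}@{tag}" for lab in above_genus}
        members = [
            ReferenceSeq(r.id, r.sequence, apply_dialect(r.taxonomy, mapping))
            for r in base_refs
            if drop_group[r.id] != k
        ]
        name = f"base{tag[-1]}"
        base_sets.append(TrainingSet(name, members).validate())
        dialect_maps[name] = mapping

    read_rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_READS]))
    reads, read_truth = _draw_reads(config, refs, read_rng, holdout, config.holdout_enrichment)
    return HoldoutScenario(
        replace(config, holdout_genera=list(holdout)),
        base_sets, custom_set, reads, read_truth, ref_truth, list(holdout), dialect_maps,
    )
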