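import pytest

from ribotax import ReferenceSeq, TaxonomyPath, TrainingSet
from ribotax.nbc import Classification
from ribotax.taxonomy import RANKS


def lineage(genus, family=None, order=None, klass=None, phylum=None, domain="Bacteria",
            incertae=None):
    """Build a 6-rank path with per-genus defaults that keep parents unique."""
    family = family if family is not None else f"{genus}_fam"
    order = order if order is not None else f"{family}_ord"
    klass = klass if klass is not None else f"{family}_cls"
    phylum = phylum if phylum is not None else f"{klass}_phy"
    labels = (domain, phylum, klass, order, family, genus)
    return TaxonomyPath(labels, incertae or (False,) * 6)


def make_ts(name, entries):
    """entries: iterable of (id, sequence, TaxonomyPath)."""
    return TrainingSet(name, [ReferenceSeq(i, s, t) for i, s, t in entries]).validate()


def make_classification(qid, labels, confs, genus=None, threshold=None):
    assert len(labels) == 6 and len(confs) == 6
    return Classification(qid, genus or labels[-1],
                          tuple(zip(labels, (float(c) for c in confs))), threshold)
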