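"""Independent brute-force oracles used by the test suite.

Everything here is implemented from first principles (pure python, no
numpy, no code shared with the package's computation paths) so that
agreement between package and oracle is informative.
"""

import math
import random

DNA = "ACGT"


# --- word extraction ---------------------------------------------------------

def words_bruteforce(seq, w):
    """Enumerate every i..i+w-1 substring, skipping ambiguity windows."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - w + 1):
        win = seq[i : i + w]
        if all(c in DNA for c in win):
            out.append(win)
    return out


# --- naive Bayes scoring -----------------------------------------------------

def nbc_word_tables(refs, word_size):
    """refs: list of (genus, sequence). Returns (N, doc_counts, genus word-sets)."""
    genus_sets = {}
    for genus, seq in refs:
        genus_sets.setdefault(genus, []).append(set(words_bruteforce(seq, word_size)))
    doc = {}
    for sets in genus_sets.values():
        for s in sets:
            for w in s:
                doc[w] = doc.get(w, 0) + 1
    return len(refs), doc, genus_sets


def nbc_scores(refs, word_size, read):
    """Log-joint score per genus by direct enumeration and log-summing."""
    n_total, doc, genus_sets = nbc_word_tables(refs, word_size)
    qwords = sorted(set(words_bruteforce(read, word_size)))
    scores = {}
    for genus, sets in genus_sets.items():
        m_genus = len(sets)
        total = 0.0
        for w in qwords:
            prior = (doc.get(w, 0) + 0.5) / (n_total + 1)
            m = sum(1 for s in sets if w in s)
            total += math.log((m + prior) / (m_genus + 1))
        scores[genus] = total
    return scores


def nbc_argmax(scores):
    """Max score, ties to the lexicographically smallest genus."""
    best = max(scores.values())
    return min(g for g, s in scores.items() if s == best)


def bootstrap_mc(refs, lineages, word_size, read, trials, rng):
    """Monte-Carlo re-simulation of the bootstrap confidence scheme.

    refs: list of (genus, sequence); lineages: genus -> 6-tuple of display
    labels.  Returns (winner genus, per-rank confidence list).
    """
    n_total, doc, genus_sets = nbc_word_tables(refs, word_size)
    qwords = sorted(set(words_bruteforce(read, word_size)))
    logp = {}
    for genus, sets in genus_sets.items():
        m_genus = len(sets)
        for w in qwords:
            prior = (doc.get(w, 0) + 0.5) / (n_total + 1)
            m = sum(1 for s in sets if w in s)
            logp[(genus, w)] = math.log((m + prior) / (m_genus + 1))
    genera = sorted(genus_sets)
    subset = max(1, len(qwords) // 8)
    wins = {g: 0 for g in genera}
    winners = []
    for _ in range(trials):
        sample = [qwords[rng.randrange(len(qwords))] for _ in range(subset)]
        scores = {g: sum(logp[(g, w)] for w in sample) for g in genera}
        win = nbc_argmax(scores)
        wins[win] += 1
        winners.append(win)
    best = max(wins.values())
    overall = min(g for g, n in wins.items() if n == best)
    confs = []
    for r in range(6):
        hits = sum(1 for g in winners if lineages[g][: r + 1] == lineages[overall][: r + 1])
        confs.append(100.0 * hits / trials)
    return overall, confs


# --- random classifier instances --------------------------------------------


def random_instance(rng):
    """Small random training set + read (<=6 genera, <=5 seqs, short read)."""
    n_genera = rng.randint(2, 6)
    refs = []
    for g in range(n_genera):
        genus = f"G{chr(ord('a') + g)}"
        for s in range(rng.randint(1, 5)):
            seq = "".join(rng.choice(DNA) for _ in range(rng.randint(40, 80)))
            refs.append((genus, seq))
    read = "".join(rng.choice(DNA) for _ in range(rng.randint(30, 60)))
    return refs, read


# --- alignment and clustering ------------------------------------------------


def nw_identity(a, b, match=1, mismatch=-1, gap=-2):
    """Needleman-Wunsch with traceback; identity over non-terminal-gap columns."""
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            score[i][j] = max(diag, score[i - 1][j] + gap, score[i][j - 1] + gap)
    ga, gb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            ga.append(a[i - 1]); gb.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i][j] == score[i - 1][j] + gap:
            ga.append(a[i - 1]); gb.append("-"); i -= 1
        else:
            ga.append("-"); gb.append(b[j - 1]); j -= 1
    ga, gb = "".join(reversed(ga)), "".join(reversed(gb))
    start, end = 0, len(ga)
    while start < end and ("-" in (ga[start], gb[start])):
        start += 1
    while end > start and ("-" in (ga[end - 1], gb[end - 1])):
        end -= 1
    if end == start:
        return 0.0
    matches = sum(1 for x, y in zip(ga[start:end], gb[start:end]) if x == y != "-")
    return matches / (end - start)


def components_partition(items, threshold, identity_fn):
    """All-pairs identity + connected components (union-find) partition.

    Returns frozensets of member ids.
    """
    ids = [i for i, _ in items]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (ida, seqa) in enumerate(items):
        for idb, seqb in items[i + 1 :]:
            if identity_fn(seqa, seqb) >= threshold:
                parent[find(ida)] = find(idb)
    groups = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def mutate_seq(seq, fraction, rng):
    """Substitute round(fraction * len) distinct positions."""
    seq = list(seq)
    k = round(fraction * len(seq))
    for pos in rng.sample(range(len(seq)), k):
        seq[pos] = rng.choice([c for c in DNA if c != seq[pos]])
    return "".join(seq)


def random_dna(length, rng):
    return "".join(rng.choice(DNA) for _ in range(length))
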