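import numpy as np
import pytest

from episcan import (GenomeLayout, SampleClassification, StateTrack,
                     StateVocabulary, WindowProfile)
from episcan.windowing import Window

TOY_VOCAB = StateVocabulary("toy", ("Tx", "Enh", "Het", "Quies"))


@pytest.fixture
def toy_vocab() -> StateVocabulary:
    return TOY_VOCAB


@pytest.fixture
def layout() -> GenomeLayout:
    return GenomeLayout({"chr1": 20_000, "chr2": 12_000})


def make_profile(states, groups=None, window=None) -> WindowProfile:
    """Profile over samples s0..sN-1; groups defaults alternating A/B."""
    samples = tuple(f"s{i}" for i in range(len(states)))
    return WindowProfile(window or Window("chr1", 0, 5000), samples,
                         tuple(states))


def make_classification(groups) -> SampleClassification:
    return SampleClassification({f"s{i}": g for i, g in enumerate(groups)})


def grid_track(sample_id, vocab, states_per_chrom, segment=200) -> StateTrack:
    """Track from per-chromosome state-label lists on a uniform segment grid."""
    data = {}
    for chrom, labels in states_per_chrom.items():
        codes = np.array([vocab.index(s) for s in labels], dtype=np.int16)
        starts = np.arange(len(labels), dtype=np.int64) * segment
        data[chrom] = (starts, starts + segment, codes)
    return StateTrack.from_arrays(sample_id, vocab, data)


# ---------------------------------------------------------------------------
# independent oracles (definition-level reimplementations used only in tests)
# ---------------------------------------------------------------------------

def mi_bruteforce(states, groups) -> float:
    """Direct double sum over the joint count table, undefined excluded."""
    import math
    pairs = [(g, s) for g, s in zip(groups, states) if s != "undefined"]
    if len(pairs) < 2:
        return 0.0
    n = len(pairs)
    joint: dict = {}
    pg: dict = {}
    ps: dict = {}
    for g, s in pairs:
        joint[(g, s)] = joint.get((g, s), 0) + 1
        pg[g] = pg.get(g, 0) + 1
        ps[s] = ps.get(s, 0) + 1
    mi = 0.0
    for (g, s), c in joint.items():
        p_gs = c / n
        mi += p_gs * math.log2(p_gs / ((pg[g] / n) * (ps[s] / n)))
    return max(mi, 0.0)


def exact_permutation_p(states, groups) -> float:
    """Exact null: fraction of all n! arrangements with MI >= observed."""
    from itertools import permutations
    obs = mi_bruteforce(states, groups)
    hits = total = 0
    for perm in permutations(states):
        total += 1
        if mi_bruteforce(perm, groups) >= obs - 1e-12:
            hits += 1
    return hits / total


def bh_bruteforce(pvalues):
    """Quadratic-time Benjamini–Hochberg step-up."""
    p = list(map(float, pvalues))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    for rank_pos, i in enumerate(order):
        # min over all j with rank >= this one
        vals = [p[order[jpos]] * n / (jpos + 1)
                for jpos in range(rank_pos, n)]
        adj[i] = min(1.0, min(vals))
    return adj


def hypergeom_tail_bruteforce(k, N, n, K) -> float:
    """P(X >= k) for X ~ Hypergeom(N, n, K) by direct summation."""
    from math import comb
    upper = min(n, K)
    total = comb(N, K)
    return sum(comb(n, x) * comb(N - n, K - x) for x in range(k, upper + 1)) / total
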