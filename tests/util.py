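"""Shared fixture builders and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

from ddri.clustering import CodeCorpus
from ddri.io import Stratum, TestResult


def make_stratum(
    values,
    codes_list=None,
    sex: str = "female",
    age_lo: int = 20,
    age_hi: int = 29,
) -> Stratum:
    """Build a stratum directly from values and (optional) per-result code lists."""
    values = list(values)
    codes_list = codes_list or [()] * len(values)
    s = Stratum(sex=sex, age_lo=age_lo, age_hi=age_hi)
    for i, (v, codes) in enumerate(zip(values, codes_list)):
        s.results.append(
            TestResult(value=float(v), age=age_lo, sex=sex, case_id=f"c{i}",
                       codes=tuple(codes))
        )
    return s


def planted_corpus(seed: int, n_sent: int = 1000, block_size: int = 10) -> CodeCorpus:
    """Two-block co-occurrence corpus: codes only ever co-coded within a block."""
    rng = np.random.default_rng(seed)
    blocks = [
        [f"A{i:02d}" for i in range(block_size)],
        [f"B{i:02d}" for i in range(block_size)],
    ]
    sents = []
    for i in range(n_sent):
        b = blocks[i % 2]
        k = int(rng.integers(2, 6))
        sents.append(tuple(rng.choice(b, size=min(k, len(b)), replace=False)))
    return CodeCorpus(
        sentences=sents, vocabulary=Counter(c for s in sents for c in s)
    )


def brute_force_mwu_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration, computed from
    pairwise comparisons (independent of any ranking implementation)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    center = n1 * len(y) / 2.0
    d_obs = abs(u_stat(x, y) - center)
    hits = total = 0
    indices = set(range(len(pooled)))
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in indices - set(idx)]
        total += 1
        if abs(u_stat(xs, ys) - center) >= d_obs - 1e-9:
            hits += 1
    return hits / total


def benjamini_hochberg(p) -> np.ndarray:
    """Hand-computed BH adjusted p-values (step-up), independent oracle."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out
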