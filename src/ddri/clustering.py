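"""ICD-10 code clustering from co-occurrence on test results.

Codes that are coded together on the same laboratory result tend to describe
related conditions (comorbidity).  Each result's code list is treated as a
short sentence; a word2vec-style skip-gram model with negative sampling
(implemented here with vectorized numpy mini-batch SGD, deterministic under a
seed) embeds the codes, pairwise cosine similarity is converted to a distance
(1 - similarity by default), and agglomerative (bottom-up) hierarchical
clustering - or k-means on the embedding vectors - partitions the codes into
k clusters (default 800, capped at vocabulary size).  Cluster-level testing
and removal then mirrors the per-code Differential Distribution, with the
benefit that rare related codes pool into groups large enough to test.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .differential import (
    DiagnosisTable,
    DifferentialDistribution,
    _build_table_from_groups,
)
from .io import ConfigurationError, Stratum

logger = logging.getLogger("ddri")


@dataclass
class CodeCorpus:
    """Sentences of co-coded ICD-10 codes, one per coded test result."""

    sentences: list[tuple[str, ...]]
    vocabulary: Counter

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sentences)


@dataclass
class CodeEmbedding:
    """Trained code vectors plus the training configuration that produced them."""

    vectors: dict[str, np.ndarray]
    d: int
    training_params: dict = field(default_factory=dict)

    @property
    def codes(self) -> list[str]:
        return sorted(self.vectors)


@dataclass
class CodeClustering:
    """Cosine similarity/distance matrices and the code -> cluster assignment."""

    codes: list[str]
    similarity: np.ndarray
    distance: np.ndarray
    assignments: dict[str, int]
    k: int
    method: str
    linkage: str | None = None

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for c, cid in self.assignments.items():
            out.setdefault(cid, []).append(c)
        return {cid: sorted(cs) for cid, cs in out.items()}

    def to_frame(self) -> pd.DataFrame:
        sizes = Counter(self.assignments.values())
        return pd.DataFrame(
            [
                {"code": c, "cluster_id": cid, "cluster_size": sizes[cid]}
                for c, cid in sorted(self.assignments.items())
            ]
        )


def build_code_corpus(stratum: Stratum) -> CodeCorpus:
    """One sentence per coded result; uncoded results contribute nothing."""
    sentences = [r.codes for r in stratum.results if r.codes]
    vocab = Counter(c for s in sentences for c in s)
    return CodeCorpus(sentences=sentences, vocabulary=vocab)


# ---------------------------------------------------------------------------
# skip-gram with negative sampling


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embeddings(
    corpus: CodeCorpus,
    d: int = 100,
    window: int = 5,
    epochs: int = 20,
    min_count: int = 6,
    seed: int = 0,
    negative: int = 5,
    lr: float = 2.0,
    lr_min: float = 1e-3,
    batch_size: int = 1024,
) -> CodeEmbedding:
    """Train skip-gram code embeddings with negative sampling.

    Deterministic for a fixed seed (single-threaded mini-batch gradient
    descent with batch-averaged gradients, hence the large base learning
    rate).  Codes seen fewer than ``min_count`` times receive no vector.
    ``window`` >= 4 means every code pair within a 5-code sentence
    co-occurs.  Negative targets are drawn from the unigram distribution
    raised to 3/4.
    """
    counts = {c: n for c, n in corpus.vocabulary.items() if n >= min_count}
    vocab = sorted(counts)
    index = {c: i for i, c in enumerate(vocab)}
    V = len(vocab)

    # (center, context) pairs within the window, sentence order preserved
    centers, contexts = [], []
    for sent in corpus.sentences:
        ids = [index[c] for c in sent if c in index]
        for i, ci in enumerate(ids):
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if j != i:
                    centers.append(ci)
                    contexts.append(ids[j])
    if V < 2 or not centers:
        raise ValueError(
            "corpus has no co-occurrence signal (fewer than two codes per "
            "sentence after frequency filtering); skip clustering for this stratum"
        )
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)

    rng = np.random.default_rng(seed)
    w_in = (rng.random((V, d)) - 0.5) / d
    w_out = np.zeros((V, d))

    freq = np.array([counts[c] for c in vocab], float) ** 0.75
    noise = freq / freq.sum()

    n_pairs = centers.size
    total_batches = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            sel = order[start : start + batch_size]
            c, o = centers[sel], contexts[sel]
            neg = rng.choice(V, size=(sel.size, negative), p=noise)
            # batch-averaged gradient: stable even when a small vocabulary
            # makes the same rows recur many times within one batch
            eta = max(lr_min, lr * (1.0 - step / total_batches)) / sel.size
            step += 1

            h = w_in[c]                                   # (B, d)
            # positive pair: label 1
            g_pos = _sigmoid(np.einsum("bd,bd->b", h, w_out[o])) - 1.0
            # negative samples: label 0
            g_neg = _sigmoid(np.einsum("bkd,bd->bk", w_out[neg], h))

            grad_h = g_pos[:, None] * w_out[o] + np.einsum(
                "bk,bkd->bd", g_neg, w_out[neg]
            )
            np.add.at(w_out, o, -eta * g_pos[:, None] * h)
            np.add.at(
                w_out,
                neg.ravel(),
                (-eta * g_neg[:, :, None] * h[:, None, :]).reshape(-1, d),
            )
            np.add.at(w_in, c, -eta * grad_h)

    vectors = {c: w_in[index[c]].copy() for c in vocab}
    return CodeEmbedding(
        vectors=vectors,
        d=d,
        training_params={
            "algorithm": "skip-gram",
            "window": window,
            "epochs": epochs,
            "min_count": min_count,
            "negative": negative,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# similarity and clustering


def similarity_matrix(embedding: CodeEmbedding) -> tuple[list[str], np.ndarray]:
    """Pairwise cosine similarity of all embedded codes.

    Zero-norm vectors are dropped with a warning (cosine undefined).
    """
    codes = embedding.codes
    mat = np.array([embedding.vectors[c] for c in codes])
    norms = np.linalg.norm(mat, axis=1)
    ok = norms > 0
    dropped = [c for c, keep in zip(codes, ok) if not keep]
    if dropped:
        logger.warning("dropping zero-norm embedding vectors: %s", dropped)
    codes = [c for c, keep in zip(codes, ok) if keep]
    mat = mat[ok]
    unit = mat / np.linalg.norm(mat, axis=1, keepdims=True)
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return codes, sim


def similarity_to_distance(similarity: np.ndarray, mode: str = "complement") -> np.ndarray:
    """Turn cosine similarity into a distance: 1 - s (default) or arccos(s)/pi."""
    if mode == "complement":
        dist = np.clip(1.0 - similarity, 0.0, None)
    elif mode == "angular":
        dist = np.arccos(np.clip(similarity, -1.0, 1.0)) / np.pi
    else:
        raise ConfigurationError(f"unknown distance_mode {mode!r}")
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return dist


def cluster_codes(
    codes: list[str],
    similarity: np.ndarray,
    k: int = 800,
    method: str = "hierarchical",
    linkage: str = "average",
    seed: int = 0,
    distance_mode: str = "complement",
    vectors: np.ndarray | None = None,
) -> CodeClustering:
    """Partition embedded codes into (at most) k clusters.

    ``hierarchical`` runs bottom-up agglomeration on the cosine distance
    matrix and cuts the tree at ``min(k, N)`` clusters; ``kmeans`` runs on
    the embedding vectors (required) with a fixed seed.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    n = len(codes)
    if similarity.shape != (n, n):
        raise ConfigurationError("similarity matrix shape does not match code list")
    dist = similarity_to_distance(similarity, distance_mode)
    k_eff = min(k, n)
    if method == "hierarchical":
        if n == 1:
            labels = np.array([1])
        else:
            z = scipy_linkage(squareform(dist, checks=False), method=linkage)
            labels = fcluster(z, t=k_eff, criterion="maxclust")
    elif method == "kmeans":
        if vectors is None:
            raise ConfigurationError("kmeans clustering requires embedding vectors")
        labels = KMeans(n_clusters=k_eff, random_state=seed, n_init=10).fit_predict(
            np.asarray(vectors)
        )
        labels = labels + 1
    else:
        raise ConfigurationError(f"unknown clustering method {method!r}")
    return CodeClustering(
        codes=list(codes),
        similarity=similarity,
        distance=dist,
        assignments={c: int(l) for c, l in zip(codes, labels)},
        k=k_eff,
        method=method,
        linkage=linkage if method == "hierarchical" else None,
    )


def cluster_stratum_codes(
    stratum: Stratum,
    k: int = 800,
    method: str = "hierarchical",
    linkage: str = "average",
    seed: int = 0,
    distance_mode: str = "complement",
    embedding_params: dict | None = None,
) -> tuple[CodeEmbedding, CodeClustering]:
    """Convenience: corpus -> embeddings -> similarity -> clustering for one stratum."""
    corpus = build_code_corpus(stratum)
    embedding = train_embeddings(corpus, seed=seed, **(embedding_params or {}))
    codes, sim = similarity_matrix(embedding)
    vectors = np.array([embedding.vectors[c] for c in codes])
    clustering = cluster_codes(
        codes, sim, k=k, method=method, linkage=linkage, seed=seed,
        distance_mode=distance_mode, vectors=vectors,
    )
    return embedding, clustering


def cluster_table_and_dd(
    stratum: Stratum,
    clustering: CodeClustering,
    min_n: int = 6,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    seed: int = 0,
    compare_to_complement: bool = False,
    threshold_on: str = "q",
) -> tuple[DiagnosisTable, DifferentialDistribution]:
    """Cluster-level significance table and the resulting "DD with Clustering".

    A result belongs to a cluster's value group if any of its codes is a
    member (each result counted once per cluster); stratum codes without an
    embedding form singleton pseudo-clusters so rare codes keep per-code
    behavior.  Testing, q-values and removal mirror the per-code pipeline.
    """
    code_to_cluster: dict[str, str] = {
        c: f"C{cid:04d}" for c, cid in clustering.assignments.items()
    }
    members: dict[str, set[str]] = {}
    for c, label in code_to_cluster.items():
        members.setdefault(label, set()).add(c)
    stratum_codes = {c for r in stratum.results for c in r.codes}
    for c in sorted(stratum_codes - set(code_to_cluster)):
        label = f"S_{c}"
        code_to_cluster[c] = label
        members[label] = {c}

    groups: dict[str, list[float]] = {}
    for r in stratum.results:
        for label in {code_to_cluster[c] for c in r.codes}:
            groups.setdefault(label, []).append(r.value)
    groups_arr = {l: np.asarray(v, float) for l, v in groups.items()}
    members_t = {l: tuple(sorted(ms)) for l, ms in members.items()}

    table = _build_table_from_groups(
        stratum, groups_arr, members_t, min_n, alpha, normality_alpha, seed,
        compare_to_complement, threshold_on,
    )

    sig_codes = table.significant_codes
    kept_vals, removed = [], []
    for r in stratum.results:
        if any(c in sig_codes for c in r.codes):
            removed.append(r)
        else:
            kept_vals.append(r.value)
    dd = DifferentialDistribution(
        stratum=stratum,
        removed_codes=sig_codes,
        dd_values=np.asarray(kept_vals, float),
        removed_results=removed,
    )
    return table, dd
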