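"""Latent semantic scoring of gene-literature association.

A gene-linked corpus (JSON lines: doc_id, text, genes) is tokenized,
TF-IDF weighted (log-scaled TF, smoothed IDF) and factorized with a
truncated SVD.  Each gene is represented by the centroid of its linked
documents in latent space; association with an interrogation term is the
cosine between that centroid and the projected term query, clipped to
[0, 1].  Cosines >= 0.1 count as at least an implicit association and are
the only ones contributing to dataset-level totals.
"""

from __future__ import annotations

import json
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

IMPLICIT_THRESHOLD = 0.1
_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _load_stopwords() -> frozenset:
    text = resources.files("ftdconv.data").joinpath("stopwords.txt").read_text()
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


STOPWORDS = _load_stopwords()


def tokenize(text: str, stopwords: frozenset = STOPWORDS) -> List[str]:
    """Lower-cased alphanumeric word tokens with stop words removed."""
    return [t for t in _TOKEN_RE.findall(text.lower()) if t not in stopwords]


def read_corpus_jsonl(path) -> List[dict]:
    docs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                docs.append(json.loads(line))
    return docs


def write_corpus_jsonl(docs: Iterable[dict], path) -> None:
    with open(path, "w") as fh:
        for doc in docs:
            fh.write(json.dumps(doc, sort_keys=True) + "\n")


@dataclass(frozen=True)
class SemanticScore:
    gene: str
    term: str
    cosine: float
    implicit: bool


@dataclass(frozen=True)
class DatasetSemanticScore:
    dataset_id: str
    term: str
    total_score: float
    size_adjusted_score: float


@dataclass
class LsiModel:
    """Truncated-SVD factorization of a TF-IDF term-document matrix."""

    vocabulary: List[str]
    idf: np.ndarray                 # (n_terms,)
    term_vectors: np.ndarray        # U_k, (n_terms, k)
    singular_values: np.ndarray     # (k,), non-increasing
    doc_latent: np.ndarray          # (k, n_docs) = diag(s) @ Vt
    doc_ids: List[str]
    gene_centroids: Dict[str, np.ndarray]
    _vocab_index: Dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def latent_dim(self) -> int:
        return len(self.singular_values)

    def query_vector(self, term: str) -> np.ndarray:
        """Project a free-text interrogation term into latent space."""
        counts = Counter(tokenize(term))
        q = np.zeros(len(self.vocabulary))
        for tok, c in counts.items():
            i = self._vocab_index.get(tok)
            if i is not None:
                q[i] = (1.0 + np.log(c)) * self.idf[i]
        if not q.any():
            warnings.warn(f"term {term!r} fully out of vocabulary; score 0")
        return self.term_vectors.T @ q


def build_model(
    docs: Sequence[Mapping],
    latent_dim: Optional[int] = 100,
) -> LsiModel:
    """Fit the LSI model on a gene-linked corpus.

    TF is log-scaled (1 + ln count), IDF is smoothed
    (ln((1 + n_docs)/(1 + df)) + 1); the factorization keeps
    min(latent_dim, matrix rank) components (clipped with a warning).
    Gene centroids average the latent vectors of the gene's linked
    documents.  IDF is recomputed from the supplied corpus; adding or
    removing any document, gene-linked or not, may shift every score.
    """
    if not docs:
        raise ValueError("corpus is empty")
    tokenized = [tokenize(d["text"]) for d in docs]
    vocab = sorted({t for toks in tokenized for t in toks})
    if not vocab:
        raise ValueError("corpus has no in-vocabulary tokens")
    vocab_index = {t: i for i, t in enumerate(vocab)}
    n_docs = len(docs)

    tf = np.zeros((len(vocab), n_docs))
    for j, toks in enumerate(tokenized):
        for tok, c in Counter(toks).items():
            tf[vocab_index[tok], j] = 1.0 + np.log(c)
    df = (tf > 0).sum(axis=1)
    idf = np.log((1.0 + n_docs) / (1.0 + df)) + 1.0
    X = tf * idf[:, None]

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    rank = int((s > tol).sum())
    k = rank if latent_dim is None else min(latent_dim, rank)
    if latent_dim is not None and latent_dim > rank:
        warnings.warn(f"latent_dim {latent_dim} exceeds rank {rank}; clipped")
    k = max(k, 1)
    U_k, s_k, Vt_k = U[:, :k], s[:k], Vt[:k]
    doc_latent = s_k[:, None] * Vt_k

    gene_docs: Dict[str, List[int]] = {}
    for j, d in enumerate(docs):
        for g in d.get("genes", []):
            gene_docs.setdefault(str(g).upper(), []).append(j)
    centroids = {g: doc_latent[:, js].mean(axis=1) for g, js in gene_docs.items()}

    return LsiModel(
        vocabulary=vocab,
        idf=idf,
        term_vectors=U_k,
        singular_values=s_k,
        doc_latent=doc_latent,
        doc_ids=[str(d.get("doc_id", j)) for j, d in enumerate(docs)],
        gene_centroids=centroids,
        _vocab_index=vocab_index,
    )


def gene_term_cosine(model: LsiModel, gene: str, term: str) -> SemanticScore:
    """Cosine in [0, 1] between a gene centroid and an interrogation term."""
    gene = gene.upper()
    if gene not in model.gene_centroids:
        raise KeyError(f"gene {gene!r} has no linked documents")
    g = model.gene_centroids[gene]
    q = model.query_vector(term)
    ng, nq = np.linalg.norm(g), np.linalg.norm(q)
    cos = 0.0 if ng == 0 or nq == 0 else float(g @ q / (ng * nq))
    cos = min(max(cos, 0.0), 1.0)
    return SemanticScore(gene=gene, term=term, cosine=cos, implicit=cos >= IMPLICIT_THRESHOLD)


def dataset_score(
    model: LsiModel,
    genes: Sequence[str],
    terms: Sequence[str],
    dataset_id: str = "dataset",
    threshold: float = IMPLICIT_THRESHOLD,
) -> Tuple[List[DatasetSemanticScore], float]:
    """Size-adjusted semantic totals for a gene set over interrogation terms.

    Per term, total_score sums cosines >= threshold over the genes;
    size_adjusted_score divides by the gene-set size.  The combined score
    sums size-adjusted scores over the terms.
    """
    if not genes:
        raise ValueError("gene list is empty")
    per_term = []
    combined = 0.0
    for term in terms:
        total = 0.0
        for gene in genes:
            if str(gene).upper() not in model.gene_centroids:
                continue
            s = gene_term_cosine(model, gene, term)
            if s.cosine >= threshold:
                total += s.cosine
        adj = total / len(genes)
        per_term.append(
            DatasetSemanticScore(
                dataset_id=dataset_id, term=term, total_score=total, size_adjusted_score=adj
            )
        )
        combined += adj
    return per_term, combined


def word_frequencies(
    texts: Iterable[str],
    top_k: Optional[int] = None,
    stopwords: frozenset = STOPWORDS,
) -> List[Tuple[str, int]]:
    """Descending (word, count) pairs after stop-word removal.

    Ties are broken alphabetically; ``top_k`` truncates the ranking.
    """
    counts = Counter()
    for text in texts:
        counts.update(tokenize(text, stopwords=stopwords))
    ranked = sorted(counts.items(), key=lambda wc: (-wc[1], wc[0]))
    return ranked[:top_k] if top_k is not None else ranked
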