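import numpy as np
import pytest

from ftdconv.lsi import (
    build_model,
    dataset_score,
    gene_term_cosine,
    tokenize,
    word_frequencies,
    write_corpus_jsonl,
    read_corpus_jsonl,
)
from ftdconv.synthetic import CorpusSimConfig, simulate_corpus


def doc(doc_id, text, genes=()):
    return {"doc_id": doc_id, "text": text, "genes": list(genes)}


class TestTokenize:
    def test_lowercase_alnum_stopwords(self):
        toks = tokenize("The Cytoskeleton, and SYNAPSE-2 formation!")
        assert toks == ["cytoskeleton", "synapse", "2", "formation"]

    def test_empty(self):
        assert tokenize("") == []


class TestWordFrequencies:
    def test_counting_example(self):
        out = word_frequencies(["cytoskeleton cytoskeleton synapse"])
        assert out == [("cytoskeleton", 2), ("synapse", 1)]

    def test_empty_input(self):
        assert word_frequencies([]) == []

    def test_tie_break_alphabetical_and_topk(self):
        out = word_frequencies(["beta alpha beta alpha gamma"], top_k=2)
        assert out == [("alpha", 2), ("beta", 2)]

    def test_counts_conserve_tokens(self):
        texts = ["cytoskeleton synapse dendrites", "synapse tau tangles"]
        out = word_frequencies(texts)
        total = sum(len(tokenize(t)) for t in texts)
        assert sum(c for _, c in out) == total


class TestBuildModel:
    def test_identical_documents_rank_one(self):
        docs = [doc(f"d{i}", "cytoskeleton synapse", ["G1"]) for i in range(4)]
        model = build_model(docs, latent_dim=None)
        assert model.latent_dim == 1
        # all document representations collinear
        vecs = model.doc_latent / np.linalg.norm(model.doc_latent, axis=0)
        assert np.allclose(np.abs(vecs.T @ vecs), 1.0)

    def test_latent_dim_clipped_with_warning(self):
        docs = [doc("d1", "alpha beta", ["G1"]), doc("d2", "alpha gamma", ["G2"])]
        with pytest.warns(UserWarning, match="clipped"):
            model = build_model(docs, latent_dim=50)
        assert model.latent_dim <= 2

    def test_singular_values_sorted_nonnegative(self):
        rng = np.random.default_rng(0)
        docs = [
            doc(f"d{i}", " ".join(rng.choice(list("abcdefgh"), size=6)), ["G1"])
            for i in range(8)
        ]
        model = build_model(docs, latent_dim=None)
        s = model.singular_values
        assert (s >= 0).all() and (np.diff(s) <= 1e-12).all()

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_model([])

    @pytest.mark.parametrize("seed", range(6))
    def test_full_rank_cosine_equals_tfidf_cosine(self, seed):
        # brute-force oracle: with n_docs >= n_terms and full-rank TF-IDF,
        # latent cosines must equal raw TF-IDF cosines
        rng = np.random.default_rng(seed)
        vocab = ["alpha", "beta", "gamma", "delta", "epsilon"]
        docs = []
        for i in range(10):
            words = [w for w in vocab for _ in range(int(rng.integers(0, 4)))]
            if not words:
                words = ["alpha"]
            rng.shuffle(words)
            docs.append(doc(f"d{i}", " ".join(words), ["G1"] if i % 2 == 0 else ["G2"]))
        model = build_model(docs, latent_dim=None)
        if model.latent_dim < len(model.vocabulary):
            pytest.skip("degenerate rank for this seed")

        # independent dense TF-IDF reconstruction
        from collections import Counter

        tf = np.zeros((len(model.vocabulary), len(docs)))
        index = {t: i for i, t in enumerate(model.vocabulary)}
        for j, d in enumerate(docs):
            for tok, c in Counter(tokenize(d["text"])).items():
                tf[index[tok], j] = 1.0 + np.log(c)
        dfreq = (tf > 0).sum(axis=1)
        X = tf * (np.log((1 + len(docs)) / (1 + dfreq)) + 1.0)[:, None]

        for gene in ("G1", "G2"):
            cols = [j for j, d in enumerate(docs) if gene in d["genes"]]
            centroid = X[:, cols].mean(axis=1)
            for term in vocab:
                q = np.zeros(len(model.vocabulary))
                q[index[term]] = (1.0 + np.log(1)) * (
                    np.log((1 + len(docs)) / (1 + dfreq[index[term]])) + 1.0
                )
                raw = centroid @ q / (np.linalg.norm(centroid) * np.linalg.norm(q))
                raw = min(max(raw, 0.0), 1.0)
                got = gene_term_cosine(model, gene, term).cosine
                assert got == pytest.approx(raw, abs=1e-9)


class TestGeneTermCosine:
    def test_identical_vectors_give_one(self):
        docs = [
            doc("d1", "cytoskeleton", ["G1"]),
            doc("d2", "synapse", ["G2"]),
            doc("d3", "tau", ["G3"]),
        ]
        model = build_model(docs, latent_dim=None)
        s = gene_term_cosine(model, "G1", "cytoskeleton")
        assert s.cosine == pytest.approx(1.0)
        assert s.implicit

    def test_orthogonal_term_gives_zero(self):
        docs = [
            doc("d1", "cytoskeleton actin", ["G1"]),
            doc("d2", "synapse vesicle", ["G2"]),
        ]
        model = build_model(docs, latent_dim=None)
        s = gene_term_cosine(model, "G1", "synapse vesicle")
        assert s.cosine == pytest.approx(0.0, abs=1e-9)
        assert not s.implicit

    def test_oov_term_warns_scores_zero(self):
        docs = [doc("d1", "cytoskeleton", ["G1"]), doc("d2", "synapse", ["G2"])]
        model = build_model(docs, latent_dim=None)
        with pytest.warns(UserWarning, match="out of vocabulary"):
            s = gene_term_cosine(model, "G1", "zzzzz")
        assert s.cosine == 0.0

    def test_unlinked_gene_rejected(self):
        docs = [doc("d1", "cytoskeleton", ["G1"])]
        model = build_model(docs, latent_dim=None)
        with pytest.raises(KeyError):
            gene_term_cosine(model, "G9", "cytoskeleton")

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_pair_detected(self, seed):
        cfg = CorpusSimConfig(
            n_documents=120,
            vocabulary=tuple(f"term{i}" for i in range(20)),
            planted_links=(("GENEA", "term0", 0.8),),
            background_rate=0.05,
            seed=seed,
        )
        docs, _ = simulate_corpus(cfg)
        model = build_model(docs, latent_dim=None)
        planted = gene_term_cosine(model, "GENEA", "term0").cosine
        random_term = gene_term_cosine(model, "GENEA", "term7").cosine
        assert planted >= 0.1
        assert planted > random_term


class TestDatasetScore:
    def _model(self):
        docs = [
            doc("d1", "dementia neurodegeneration", ["G1"]),
            doc("d2", "dementia aging", ["G2"]),
            doc("d3", "crystallography", ["G3"]),
        ]
        return build_model(docs, latent_dim=None)

    def test_below_threshold_contributes_zero(self):
        model = self._model()
        per_term, combined = dataset_score(model, ["G3"], ["dementia"])
        assert per_term[0].total_score == 0.0
        assert combined == 0.0

    def test_duplication_leaves_size_adjusted_unchanged(self):
        model = self._model()
        genes = ["G1", "G2"]
        _, combined = dataset_score(model, genes, ["dementia"])
        _, combined_dup = dataset_score(model, genes * 2, ["dementia"])
        assert combined_dup == pytest.approx(combined)

    def test_permutation_invariance(self):
        model = self._model()
        _, c1 = dataset_score(model, ["G1", "G2"], ["dementia", "aging"])
        _, c2 = dataset_score(model, ["G2", "G1"], ["aging", "dementia"])
        assert c1 == pytest.approx(c2)

    def test_empty_genes_rejected(self):
        with pytest.raises(ValueError):
            dataset_score(self._model(), [], ["dementia"])

    def test_size_adjusted_bounded_by_max_cosine(self):
        model = self._model()
        per_term, _ = dataset_score(model, ["G1", "G2", "G3"], ["dementia"])
        assert per_term[0].size_adjusted_score <= 1.0 + 1e-12

    def test_linked_dataset_outscores_unlinked(self):
        # mirrors the designed contrast: one dataset's genes link to the
        # interrogation terms, the other's do not
        wins = 0
        for seed in range(15):
            cfg = CorpusSimConfig(
                n_documents=90,
                vocabulary=tuple(["dementia", "aging"] + [f"t{i}" for i in range(15)]),
                planted_links=(("GA1", "dementia", 0.7), ("GA2", "aging", 0.7)),
                background_rate=0.05,
                n_background_genes=2,
                seed=seed,
            )
            docs, _ = simulate_corpus(cfg)
            model = build_model(docs, latent_dim=None)
            _, score_a = dataset_score(model, ["GA1", "GA2"], ["dementia", "aging"])
            _, score_b = dataset_score(model, ["BG01", "BG02"], ["dementia", "aging"])
            wins += score_a > score_b
        assert wins >= 14


def test_corpus_jsonl_roundtrip(tmp_path):
    docs = [doc("d1", "alpha beta", ["G1"]), doc("d2", "gamma", [])]
    path = tmp_path / "c.jsonl"
    write_corpus_jsonl(docs, path)
    assert read_corpus_jsonl(path) == docs
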