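"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Model: K topics; document d draws theta_d ~ Dirichlet(alpha), each token
draws a topic z ~ theta_d and a word w ~ phi_z with phi_k ~ Dirichlet(eta).
The sampler integrates theta and phi out and resamples each token's topic
from the collapsed conditional

    p(z_i = k | z_-i, w) ∝ (n_dk + alpha) * (n_kw + eta) / (n_k + V * eta)

where the counts exclude token i. Point estimates of phi and theta are
posterior means averaged over post-burn-in sweeps.

Two sweep implementations share one random stream (a pre-drawn uniform per
token per sweep): a numba-compiled kernel used by default and a pure-Python
replica that can also record every conditional distribution, which the test
suite checks token-by-token against brute-force evaluation of the collapsed
conditional. Both produce bit-identical trajectories for a given seed.

Defaults follow common practice where nothing else is specified:
alpha = 50/K, eta = 0.01, 2000 sweeps with 500 burn-in.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


DEFAULT_STOPWORDS = frozenset(
    "a an and are as at be by for from has he in is it its of on or that".split()
    + "the to was were will with this their they she his her not no".split()
)


@dataclass
class Corpus:
    """Bag-of-words corpus: ordered vocabulary + sparse doc-term counts."""

    doc_ids: list[str]
    vocabulary: list[str]
    counts: sparse.csr_matrix = field(repr=False)
    excluded_doc_ids: list[str] = field(default_factory=list)

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_terms(self) -> int:
        return self.counts.shape[1]

    @property
    def n_tokens(self) -> int:
        return int(self.counts.sum())

    def term_marginal(self) -> np.ndarray:
        """Empirical corpus-wide term probability p_w."""
        totals = np.asarray(self.counts.sum(axis=0)).ravel().astype(float)
        return totals / totals.sum()


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str, stopwords=DEFAULT_STOPWORDS,
             min_token_len: int = 2) -> list[str]:
    return [t for t in _TOKEN_RE.findall(str(text).lower())
            if len(t) >= min_token_len and t not in stopwords]


def build_corpus(texts, doc_ids=None, stopwords=DEFAULT_STOPWORDS,
                 min_token_len: int = 2) -> Corpus:
    """Tokenize raw strings into a Corpus.

    Lowercases, strips punctuation, drops tokens shorter than
    ``min_token_len`` and stopwords; vocabulary is ordered by first
    appearance. Documents left empty after preprocessing are excluded and
    logged, never silently kept.
    """
    texts = list(texts)
    if doc_ids is None:
        doc_ids = [f"doc{i:05d}" for i in range(len(texts))]
    vocab_index: dict[str, int] = {}
    rows, cols, vals = [], [], []
    kept_ids, excluded = [], []
    for did, text in zip(doc_ids, texts):
        toks = tokenize(text, stopwords, min_token_len)
        if not toks:
            excluded.append(did)
            logger.info("document %s empty after preprocessing; excluded", did)
            continue
        counts: dict[int, int] = {}
        for t in toks:
            j = vocab_index.setdefault(t, len(vocab_index))
            counts[j] = counts.get(j, 0) + 1
        r = len(kept_ids)
        kept_ids.append(did)
        for j, c in counts.items():
            rows.append(r); cols.append(j); vals.append(c)
    if not kept_ids:
        raise ValueError("no document survived preprocessing")
    mat = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(kept_ids), len(vocab_index)),
        dtype=np.int64)
    vocabulary = [None] * len(vocab_index)
    for term, j in vocab_index.items():
        vocabulary[j] = term
    return Corpus(kept_ids, vocabulary, mat, excluded)


@dataclass
class TopicModelFit:
    k: int
    alpha: float
    eta: float
    phi: np.ndarray = field(repr=False)    # (K, V)
    theta: np.ndarray = field(repr=False)  # (D, K)
    n_iterations: int
    n_burnin: int
    seed: int
    doc_ids: list[str] = field(repr=False)
    vocabulary: list[str] = field(repr=False)
    term_marginal: np.ndarray = field(repr=False, default=None)
    conditional_log: list = field(repr=False, default=None)
    assignment_log: list = field(repr=False, default=None)


@njit(cache=False)
def _sweep_numba(doc_of, word_of, z, ndk, nkw, nk, alpha, eta, uniforms):
    n_tokens = z.shape[0]
    k = nk.shape[0]
    v = nkw.shape[1]
    for i in range(n_tokens):
        d = doc_of[i]
        w = word_of[i]
        old = z[i]
        ndk[d, old] -= 1
        nkw[old, w] -= 1
        nk[old] -= 1
        total = 0.0
        for t in range(k):
            total += (ndk[d, t] + alpha) * (nkw[t, w] + eta) / (nk[t] + v * eta)
        r = uniforms[i] * total
        acc = 0.0
        new = k - 1
        for t in range(k):
            acc += (ndk[d, t] + alpha) * (nkw[t, w] + eta) / (nk[t] + v * eta)
            if acc > r:
                new = t
                break
        z[i] = new
        ndk[d, new] += 1
        nkw[new, w] += 1
        nk[new] += 1


def _sweep_python(doc_of, word_of, z, ndk, nkw, nk, alpha, eta, uniforms,
                  record=None):
    k = nk.shape[0]
    v = nkw.shape[1]
    for i in range(z.shape[0]):
        d, w, old = doc_of[i], word_of[i], z[i]
        ndk[d, old] -= 1
        nkw[old, w] -= 1
        nk[old] -= 1
        p = np.empty(k)
        total = 0.0
        for t in range(k):
            p[t] = (ndk[d, t] + alpha) * (nkw[t, w] + eta) / (nk[t] + v * eta)
            total += p[t]
        if record is not None:
            record.append((i, p / total))
        r = uniforms[i] * total
        acc = 0.0
        new = k - 1
        for t in range(k):
            acc += p[t]
            if acc > r:
                new = t
                break
        z[i] = new
        ndk[d, new] += 1
        nkw[new, w] += 1
        nk[new] += 1


def _expand_tokens(corpus: Corpus) -> tuple[np.ndarray, np.ndarray]:
    coo = corpus.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    doc_of = np.repeat(coo.row[order], coo.data[order]).astype(np.int64)
    word_of = np.repeat(coo.col[order], coo.data[order]).astype(np.int64)
    return doc_of, word_of


def fit_lda(corpus: Corpus, k: int, alpha: float | None = None,
            eta: float = 0.01, n_iterations: int = 2000,
            n_burnin: int = 500, seed: int = 0,
            record_conditionals: bool = False) -> TopicModelFit:
    """Fit LDA by collapsed Gibbs sampling; reproducible from seed.

    When ``record_conditionals`` is set the (slow) instrumented sweep is
    used and every token's conditional distribution and the post-sweep
    assignment vector are kept on the returned fit, for oracle checking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if corpus.n_docs == 0:
        raise ValueError("corpus is empty")
    if k > corpus.n_terms:
        raise ValueError(f"k={k} exceeds the {corpus.n_terms} distinct terms")
    if n_burnin >= n_iterations:
        raise ValueError("n_burnin must be < n_iterations")
    if alpha is None:
        alpha = 50.0 / k

    doc_of, word_of = _expand_tokens(corpus)
    n_tokens = doc_of.shape[0]
    d_count, v = corpus.n_docs, corpus.n_terms

    rng = np.random.default_rng(seed)
    z = rng.integers(0, k, n_tokens).astype(np.int64)
    ndk = np.zeros((d_count, k), dtype=np.int64)
    nkw = np.zeros((k, v), dtype=np.int64)
    nk = np.zeros(k, dtype=np.int64)
    np.add.at(ndk, (doc_of, z), 1)
    np.add.at(nkw, (z, word_of), 1)
    np.add.at(nk, z, 1)

    nd = ndk.sum(axis=1, keepdims=True).astype(float)
    phi_acc = np.zeros((k, v))
    theta_acc = np.zeros((d_count, k))
    n_samples = 0
    cond_log: list | None = [] if record_conditionals else None
    assign_log: list | None = [] if record_conditionals else None

    use_numba = _HAVE_NUMBA and not record_conditionals
    for it in range(n_iterations):
        uniforms = rng.random(n_tokens)
        if use_numba:
            _sweep_numba(doc_of, word_of, z, ndk, nkw, nk,
                         float(alpha), float(eta), uniforms)
        else:
            rec: list | None = [] if record_conditionals else None
            _sweep_python(doc_of, word_of, z, ndk, nkw, nk,
                          float(alpha), float(eta), uniforms, record=rec)
            if record_conditionals:
                cond_log.append(rec)
                assign_log.append(z.copy())
        if it >= n_burnin:
            phi_acc += (nkw + eta) / (nk[:, None] + v * eta)
            theta_acc += (ndk + alpha) / (nd + k * alpha)
            n_samples += 1

    assert int(nk.sum()) == n_tokens, "token count not conserved"
    return TopicModelFit(
        k=k, alpha=float(alpha), eta=float(eta),
        phi=phi_acc / n_samples, theta=theta_acc / n_samples,
        n_iterations=n_iterations, n_burnin=n_burnin, seed=seed,
        doc_ids=list(corpus.doc_ids), vocabulary=list(corpus.vocabulary),
        term_marginal=corpus.term_marginal(),
        conditional_log=cond_log, assignment_log=assign_log,
    )


def infer_theta_for_documents(fit: TopicModelFit, corpus: Corpus,
                              n_iterations: int = 200, n_burnin: int = 50,
                              seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Fold-in inference of document-topic proportions under a fixed phi.

    Tokens are resampled from p(z=k) ∝ phi_kw * (n_dk + alpha); theta is
    the post-burn-in mean. Out-of-vocabulary terms are dropped; documents
    with no in-vocabulary token get the uniform distribution and a flag.

    Returns (theta, uniform_flags) aligned with corpus.doc_ids.
    """
    term_to_col = {t: j for j, t in enumerate(fit.vocabulary)}
    proj = np.full(corpus.n_terms, -1, dtype=np.int64)
    for j, term in enumerate(corpus.vocabulary):
        proj[j] = term_to_col.get(term, -1)

    rng = np.random.default_rng(seed)
    k = fit.k
    theta = np.empty((corpus.n_docs, k))
    flags = np.zeros(corpus.n_docs, dtype=bool)
    csr = corpus.counts
    for d in range(corpus.n_docs):
        cols = csr.indices[csr.indptr[d]:csr.indptr[d + 1]]
        reps = csr.data[csr.indptr[d]:csr.indptr[d + 1]]
        words = np.repeat(proj[cols], reps)
        words = words[words >= 0]
        if words.size == 0:
            theta[d] = 1.0 / k
            flags[d] = True
            continue
        z = rng.integers(0, k, words.size)
        ndk = np.bincount(z, minlength=k).astype(float)
        acc = np.zeros(k)
        n_samp = 0
        phi_w = fit.phi[:, words]  # (K, n_tokens)
        for it in range(n_iterations):
            u = rng.random(words.size)
            for i in range(words.size):
                ndk[z[i]] -= 1
                p = phi_w[:, i] * (ndk + fit.alpha)
                cum = np.cumsum(p)
                z[i] = int(np.searchsorted(cum, u[i] * cum[-1], side="right"))
                ndk[z[i]] += 1
            if it >= n_burnin:
                acc += (ndk + fit.alpha) / (words.size + k * fit.alpha)
                n_samp += 1
        theta[d] = acc / n_samp
    return theta, flags


def rank_terms_by_relevance(fit: TopicModelFit, topic_index: int,
                            lambda_weight: float = 0.6,
                            top_n: int | None = 30):
    """Rank a topic's terms by relevance.

    relevance(w, t) = lambda * log phi_tw + (1 - lambda) * log(phi_tw / p_w)
    with p_w the corpus marginal term probability; lambda = 1 ranks by
    within-topic probability, lambda = 0 by lift.
    """
    if not 0.0 <= lambda_weight <= 1.0:
        raise ValueError("lambda_weight must lie in [0, 1]")
    phi_t = fit.phi[topic_index]
    p_w = fit.term_marginal
    log_phi = np.log(phi_t)
    scores = lambda_weight * log_phi + (1 - lambda_weight) * (log_phi - np.log(p_w))
    order = np.argsort(-scores, kind="stable")
    if top_n is not None:
        order = order[:top_n]
    return [(fit.vocabulary[j], float(scores[j])) for j in order]


def save_corpus(corpus: Corpus, out_dir) -> None:
    """Write a corpus as a term-index JSON plus Matrix Market counts."""
    import json
    from pathlib import Path

    from scipy.io import mmwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"doc_ids": corpus.doc_ids,
            "term_index": {t: j for j, t in enumerate(corpus.vocabulary)},
            "excluded_doc_ids": corpus.excluded_doc_ids}
    (out / "corpus.json").write_text(json.dumps(meta, sort_keys=True),
                                     encoding="utf-8")
    mmwrite(out / "counts.mtx", corpus.counts)


def load_corpus(in_dir) -> Corpus:
    import json
    from pathlib import Path

    from scipy.io import mmread

    src = Path(in_dir)
    meta = json.loads((src / "corpus.json").read_text(encoding="utf-8"))
    vocab = [None] * len(meta["term_index"])
    for term, j in meta["term_index"].items():
        vocab[j] = term
    counts = sparse.csr_matrix(mmread(src / "counts.mtx"), dtype=np.int64)
    return Corpus(meta["doc_ids"], vocab, counts, meta["excluded_doc_ids"])


def save_fit(fit: TopicModelFit, out_dir) -> None:
    """Serialize a fit as JSON metadata plus dense CSV arrays."""
    import json
    from pathlib import Path

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"k": fit.k, "alpha": fit.alpha, "eta": fit.eta,
            "n_iterations": fit.n_iterations, "n_burnin": fit.n_burnin,
            "seed": fit.seed, "doc_ids": fit.doc_ids,
            "vocabulary": fit.vocabulary,
            "term_marginal": fit.term_marginal.tolist()}
    (out / "fit.json").write_text(json.dumps(meta, sort_keys=True),
                                  encoding="utf-8")
    pd.DataFrame(fit.phi).to_csv(out / "phi.csv", index=False,
                                 float_format="%.17g")
    pd.DataFrame(fit.theta).to_csv(out / "theta.csv", index=False,
                                   float_format="%.17g")


def load_fit(in_dir) -> TopicModelFit:
    import json
    from pathlib import Path

    import pandas as pd

    src = Path(in_dir)
    meta = json.loads((src / "fit.json").read_text(encoding="utf-8"))
    return TopicModelFit(
        k=meta["k"], alpha=meta["alpha"], eta=meta["eta"],
        phi=pd.read_csv(src / "phi.csv",
                        float_precision="round_trip").to_numpy(),
        theta=pd.read_csv(src / "theta.csv",
                          float_precision="round_trip").to_numpy(),
        n_iterations=meta["n_iterations"], n_burnin=meta["n_burnin"],
        seed=meta["seed"], doc_ids=meta["doc_ids"],
        vocabulary=meta["vocabulary"],
        term_marginal=np.asarray(meta["term_marginal"]))


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def match_topics(phi_est: np.ndarray, phi_ref: np.ndarray):
    """Optimal topic alignment by minimum total-variation assignment.

    Returns (mapping, tv) where mapping[j] is the estimated topic assigned
    to reference topic j and tv[j] the corresponding TV distance. Handles
    phi_est with at least as many rows as phi_ref.
    """
    from scipy.optimize import linear_sum_assignment

    cost = np.array([[total_variation(pe, pr) for pe in phi_est]
                     for pr in phi_ref])
    rows, cols = linear_sum_assignment(cost)
    mapping = {int(r): int(c) for r, c in zip(rows, cols)}
    tv = np.array([cost[r, mapping[r]] for r in range(phi_ref.shape[0])])
    return mapping, tv
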