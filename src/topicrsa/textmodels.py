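"""Sentence-representation models and their evaluation.

Four sentence representations are supported:

* **averaged embeddings** — the unweighted mean of the word vectors of a
  sentence's constituent words (bag-of-words, word-level meaning);
* **CNN final layer** — the last dense layer (pre-softmax) of a convolutional
  topic classifier trained on the labelled corpus (topic-level meaning);
* **tf-idf** — the mean over words of topic-level tf-idf vectors, a
  category-informed word-level control;
* **MLP** — hidden-layer features of a multilayer perceptron trained on the
  averaged embeddings, a topic-informed but order-blind control.

Representations are evaluated with nearest-centroid top-k classification
(centroid = mean training vector per topic, scored by Pearson correlation),
and the module also implements the frequency/length/cluster-silhouette
stimulus-selection pipeline.

The CNN is a compact numpy implementation: trainable embedding layer, two
convolution + max-pool blocks over token trigrams, two dense layers and a
softmax head, trained with Adam on cross-entropy.  It is deliberately small —
the tested contract is single-threaded, seed-deterministic training at desk
scale, not GPU throughput.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier

from .geometry import build_rdm, cut_clusters, silhouette_scores, ward_dendrogram
from .synthetic import EmbeddingTable, TopicCorpus

logger = logging.getLogger("topicrsa")

__all__ = [
    "SentenceFeatures",
    "CNNConfig",
    "MLPConfig",
    "ClassifierReport",
    "tokenize",
    "average_embedding_features",
    "fit_tfidf",
    "tfidf_features",
    "train_cnn",
    "train_mlp",
    "extract_layer_features",
    "nearest_centroid_topk",
    "chance_topk",
    "select_stimuli",
    "write_features",
    "read_features",
]


# ---------------------------------------------------------------------------
# containers & configs
# ---------------------------------------------------------------------------

@dataclass
class SentenceFeatures:
    """n_sentences × d representation matrix tagged with its model name."""

    matrix: np.ndarray
    model_name: str = ""
    sentence_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite feature values")
        if not self.sentence_ids:
            self.sentence_ids = list(range(self.matrix.shape[0]))
        if len(self.sentence_ids) != self.matrix.shape[0]:
            raise ValueError("sentence_ids length mismatch")

    @property
    def n_sentences(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CNNConfig:
    """Topic-CNN hyperparameters.

    Defaults follow the tuned full-scale configuration (128 trigram filters,
    pool width 3, ELU, dropout 0.2, Adam, batch 512, 3 epochs, 38-token
    padding); tests shrink the widths and raise epochs for tiny corpora.
    """

    embed_dim: int = 300
    n_filters: int = 128
    kernel_width: int = 3
    pool_width: int = 3
    dense_sizes: tuple[int, int] = (128, 64)
    dropout_rate: float = 0.2
    activation: str = "elu"
    batch_size: int = 512
    epochs: int = 3
    learning_rate: float = 1e-3
    pad_length: int = 38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_width < 1:
            raise ValueError("kernel_width must be >= 1")
        if len(self.dense_sizes) != 2:
            raise ValueError("dense_sizes must hold exactly two layer widths")
        if self.activation != "elu":
            raise ValueError("only ELU activation is implemented")


@dataclass
class MLPConfig:
    """Control-MLP hyperparameters (scikit-learn backend); defaults are the
    tuned full-scale values: layers 300/512/128, tanh, alpha 0.1, batch 256."""

    hidden_sizes: tuple[int, ...] = (300, 512, 128)
    activation: str = "tanh"
    l2_penalty: float = 0.1
    batch_size: int = 256
    learning_rate_init: float = 0.001
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) < 1:
            raise ValueError("need at least one hidden layer")


@dataclass
class ClassifierReport:
    """Top-k accuracies (percent) of a nearest-centroid evaluation."""

    top_k_accuracy: dict[int, float]
    n_test: int
    n_categories: int

    def __post_init__(self) -> None:
        ks = sorted(self.top_k_accuracy)
        accs = [self.top_k_accuracy[k] for k in ks]
        if any(a < 0 or a > 100 for a in accs):
            raise ValueError("accuracies must be in [0, 100]")
        if any(b < a - 1e-9 for a, b in zip(accs, accs[1:])):
            raise ValueError("top-k accuracy must be non-decreasing in k")


# ---------------------------------------------------------------------------
# tokenization & bag-of-words representations
# ---------------------------------------------------------------------------

_DIGIT_RE = re.compile(r"\d")
_PUNCT_RE = re.compile(r"[^\w\s#]", re.UNICODE)


def tokenize(raw_sentence: str) -> list[str]:
    """Lowercase, strip punctuation, mask each digit with '#', split.

    ``"Nel 1945, riaprì."`` -> ``["nel", "####", "riaprì"]``.
    """
    s = raw_sentence.lower()
    s = _DIGIT_RE.sub("#", s)
    s = _PUNCT_RE.sub("", s)
    toks = s.split()
    if not toks:
        raise ValueError(f"sentence tokenized to nothing: {raw_sentence!r}")
    return toks


def average_embedding_features(
    corpus: TopicCorpus, table: EmbeddingTable
) -> SentenceFeatures:
    """Mean word vector per sentence (each occurrence counted; stopwords
    included; out-of-vocabulary tokens skipped)."""
    rows = np.empty((len(corpus), table.dim))
    for i, toks in enumerate(corpus.sentences):
        vecs = [table[w] for w in toks if w in table]
        if not vecs:
            raise ValueError(
                f"sentence {i} has no in-vocabulary token: {' '.join(toks)!r}"
            )
        rows[i] = np.mean(vecs, axis=0)
    return SentenceFeatures(rows, "average_embeddings")


def fit_tfidf(corpus: TopicCorpus) -> dict[str, np.ndarray]:
    """Topic-level tf-idf vectors of length n_topics for every word.

    tf(w, c) = count of w in topic c's concatenated text / topic c's total
    tokens; idf(w) = ln(n_topics / number of topics containing w).
    """
    C = corpus.n_topics
    counts = [dict() for _ in range(C)]
    totals = np.zeros(C)
    for toks, lab in zip(corpus.sentences, corpus.labels):
        d = counts[lab]
        for w in toks:
            d[w] = d.get(w, 0) + 1
        totals[lab] += len(toks)
    if np.any(totals == 0):
        raise ValueError("every topic needs at least one sentence")
    df = {}
    for c in range(C):
        for w in counts[c]:
            df[w] = df.get(w, 0) + 1
    table = {}
    for w in df:
        idf = np.log(C / df[w])
        vec = np.zeros(C)
        for c in range(C):
            n = counts[c].get(w, 0)
            if n:
                vec[c] = (n / totals[c]) * idf
        table[w] = vec
    for w in corpus.vocab:
        table.setdefault(w, np.zeros(C))
    return table


def tfidf_features(
    corpus: TopicCorpus, tfidf_table: dict[str, np.ndarray]
) -> SentenceFeatures:
    """Mean tf-idf vector over a sentence's constituent words."""
    dim = len(next(iter(tfidf_table.values())))
    rows = np.empty((len(corpus), dim))
    for i, toks in enumerate(corpus.sentences):
        vecs = [tfidf_table[w] for w in toks if w in tfidf_table]
        if not vecs:
            raise ValueError(f"sentence {i} has no word in the tf-idf table")
        rows[i] = np.mean(vecs, axis=0)
    return SentenceFeatures(rows, "tfidf")


# ---------------------------------------------------------------------------
# the topic CNN (numpy)
# ---------------------------------------------------------------------------

def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0)))


def _elu_grad(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y = elu(x); derivative is 1 for x > 0 and y + 1 otherwise
    return np.where(x > 0, 1.0, y + 1.0)


def _windows(X: np.ndarray, k: int) -> np.ndarray:
    """(N, L, C) -> (N, L - k + 1, k * C) sliding token windows."""
    v = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (N, L', C, k)
    v = np.swapaxes(v, 2, 3)  # (N, L', k, C)
    N, Lp, _, C = v.shape
    return np.ascontiguousarray(v).reshape(N, Lp, k * C)


def _scatter_windows(dwin: np.ndarray, L: int, k: int, C: int) -> np.ndarray:
    """Adjoint of :func:`_windows`: accumulate window grads back to tokens."""
    N, Lp, _ = dwin.shape
    d = dwin.reshape(N, Lp, k, C)
    out = np.zeros((N, L, C))
    for j in range(k):
        out[:, j : j + Lp, :] += d[:, :, j, :]
    return out


def _pool_max(X: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Non-overlapping max-pool of width p along axis 1 (ceil semantics: a
    short final window is kept).  Returns pooled values, argmax positions and
    the padded length used."""
    N, L, C = X.shape
    P = -(-L // p)
    pad = P * p - L
    if pad:
        X = np.concatenate([X, np.full((N, pad, C), -np.inf)], axis=1)
    Xr = X.reshape(N, P, p, C)
    arg = Xr.argmax(axis=2)
    pooled = np.take_along_axis(Xr, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return pooled, arg, P * p


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1**self.t)
            vh = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + eps)


class TrainedCNN:
    """Topic classifier: embedding -> 2 × (conv, max-pool) -> 2 dense -> softmax.

    Exposes ``predict_proba`` and per-layer feature extraction; the second
    dense layer (``"dense2"``, pre-softmax) is the topic-level sentence
    representation used throughout the study.
    """

    LAYERS = ("embedding", "conv1", "pool1", "conv2", "pool2", "dense1", "dense2", "softmax")

    def __init__(self, config: CNNConfig, word_index: dict[str, int], n_classes: int):
        self.config = config
        self.word_index = word_index  # word -> id, 0 reserved for padding
        self.n_classes = n_classes
        self.params: dict[str, np.ndarray] = {}

    # -- shapes -----------------------------------------------------------
    def _seq_lengths(self) -> tuple[int, int, int, int]:
        c = self.config
        L1 = c.pad_length - c.kernel_width + 1
        P1 = -(-L1 // c.pool_width)
        L2 = P1 - c.kernel_width + 1
        P2 = -(-L2 // c.pool_width)
        if L1 < 1 or L2 < 1:
            raise ValueError(
                f"pad_length={c.pad_length} too short for kernel_width="
                f"{c.kernel_width} with pool_width={c.pool_width}"
            )
        return L1, P1, L2, P2

    def _init_params(self, table: EmbeddingTable | None, rng: np.random.Generator):
        c = self.config
        V = len(self.word_index)
        E = np.zeros((V + 1, c.embed_dim))
        if table is not None:
            scale = 1.0 / np.sqrt(c.embed_dim)
            for w, i in self.word_index.items():
                E[i] = table[w] * scale if w in table else rng.standard_normal(c.embed_dim) * 0.01
        else:
            E[1:] = rng.standard_normal((V, c.embed_dim)) * 0.05

        def glorot(fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out))

        _, _, _, P2 = self._seq_lengths()
        k, F, D = c.kernel_width, c.n_filters, c.embed_dim
        H1, H2 = c.dense_sizes
        self.params = {
            "E": E,
            "W1": glorot(k * D, F), "b1": np.zeros(F),
            "W2": glorot(k * F, F), "b2": np.zeros(F),
            "Wd1": glorot(P2 * F, H1), "bd1": np.zeros(H1),
            "Wd2": glorot(H1, H2), "bd2": np.zeros(H2),
            "Ws": glorot(H2, self.n_classes), "bs": np.zeros(self.n_classes),
        }

    # -- encoding ---------------------------------------------------------
    def encode(self, sentences: list[list[str]]) -> np.ndarray:
        c = self.config
        ids = np.zeros((len(sentences), c.pad_length), dtype=np.int64)
        for i, toks in enumerate(sentences):
            if len(toks) > c.pad_length:
                raise ValueError(
                    f"sentence {i} has {len(toks)} tokens > pad_length={c.pad_length}"
                )
            for j, w in enumerate(toks):
                ids[i, j] = self.word_index.get(w, 0)
        return ids

    # -- forward ----------------------------------------------------------
    def _forward(self, ids: np.ndarray, rng=None):
        c = self.config
        p = self.params
        cache: dict[str, np.ndarray] = {"ids": ids}
        X = p["E"][ids]
        cache["embedding"] = X
        win1 = _windows(X, c.kernel_width)
        A1 = win1 @ p["W1"] + p["b1"]
        Z1 = _elu(A1)
        pool1, arg1, pad1 = _pool_max(Z1, c.pool_width)
        win2 = _windows(pool1, c.kernel_width)
        A2 = win2 @ p["W2"] + p["b2"]
        Z2 = _elu(A2)
        pool2, arg2, pad2 = _pool_max(Z2, c.pool_width)
        flat = pool2.reshape(len(ids), -1)
        Ad1 = flat @ p["Wd1"] + p["bd1"]
        Zd1 = _elu(Ad1)
        if rng is not None and c.dropout_rate > 0:
            mask = (rng.random(Zd1.shape) >= c.dropout_rate) / (1 - c.dropout_rate)
            Zd1 = Zd1 * mask
            cache["drop_mask"] = mask
        Ad2 = Zd1 @ p["Wd2"] + p["bd2"]
        Zd2 = _elu(Ad2)
        logits = Zd2 @ p["Ws"] + p["bs"]
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        cache.update(
            win1=win1, A1=A1, Z1=Z1, arg1=arg1, pad1=pad1, pool1=pool1,
            win2=win2, A2=A2, Z2=Z2, arg2=arg2, pad2=pad2, pool2=pool2,
            flat=flat, Ad1=Ad1, Zd1=Zd1, Ad2=Ad2, Zd2=Zd2, probs=probs,
        )
        return probs, cache

    def _backward(self, cache, y_onehot) -> dict[str, np.ndarray]:
        c = self.config
        p = self.params
        N = len(y_onehot)
        g: dict[str, np.ndarray] = {}
        dlogits = (cache["probs"] - y_onehot) / N
        g["Ws"] = cache["Zd2"].T @ dlogits
        g["bs"] = dlogits.sum(0)
        dZd2 = dlogits @ p["Ws"].T
        dAd2 = dZd2 * _elu_grad(cache["Ad2"], cache["Zd2"])
        g["Wd2"] = cache["Zd1"].T @ dAd2
        g["bd2"] = dAd2.sum(0)
        dZd1 = dAd2 @ p["Wd2"].T
        if "drop_mask" in cache:
            dZd1 = dZd1 * cache["drop_mask"]
        dAd1 = dZd1 * _elu_grad(cache["Ad1"], _elu(cache["Ad1"]))
        g["Wd1"] = cache["flat"].T @ dAd1
        g["bd1"] = dAd1.sum(0)
        dflat = dAd1 @ p["Wd1"].T
        dpool2 = dflat.reshape(cache["pool2"].shape)

        # un-pool 2
        F = c.n_filters
        dZ2p = np.zeros((N, cache["pad2"], F))
        P2 = dpool2.shape[1]
        n_idx = np.arange(N)[:, None, None]
        p_idx = np.arange(P2)[None, :, None]
        f_idx = np.arange(F)[None, None, :]
        flatpos = p_idx * c.pool_width + cache["arg2"]
        dZ2p[n_idx, flatpos, f_idx] += dpool2
        dZ2 = dZ2p[:, : cache["Z2"].shape[1], :]
        dA2 = dZ2 * _elu_grad(cache["A2"], cache["Z2"])
        g["W2"] = np.einsum("nlk,nlf->kf", cache["win2"], dA2)
        g["b2"] = dA2.sum((0, 1))
        dwin2 = dA2 @ p["W2"].T
        dpool1 = _scatter_windows(dwin2, cache["pool1"].shape[1], c.kernel_width, F)

        # un-pool 1
        dZ1p = np.zeros((N, cache["pad1"], F))
        P1 = dpool1.shape[1]
        p_idx = np.arange(P1)[None, :, None]
        flatpos = p_idx * c.pool_width + cache["arg1"]
        dZ1p[n_idx, flatpos, f_idx] += dpool1
        dZ1 = dZ1p[:, : cache["Z1"].shape[1], :]
        dA1 = dZ1 * _elu_grad(cache["A1"], cache["Z1"])
        g["W1"] = np.einsum("nlk,nlf->kf", cache["win1"], dA1)
        g["b1"] = dA1.sum((0, 1))
        dwin1 = dA1 @ p["W1"].T
        dX = _scatter_windows(dwin1, c.pad_length, c.kernel_width, c.embed_dim)

        dE = np.zeros_like(p["E"])
        np.add.at(dE, cache["ids"], dX)
        dE[0] = 0.0  # padding row stays frozen
        g["E"] = dE
        return g

    # -- public API -------------------------------------------------------
    def fit(self, sentences, labels, table: EmbeddingTable | None):
        c = self.config
        rng = np.random.default_rng(c.seed)
        self._init_params(table, rng)
        ids = self.encode(sentences)
        y = np.asarray(labels)
        onehot = np.eye(self.n_classes)[y]
        opt = _Adam(self.params, c.learning_rate)
        n = len(ids)
        for epoch in range(c.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, c.batch_size):
                b = order[start : start + c.batch_size]
                probs, cache = self._forward(ids[b], rng=rng)
                losses.append(-np.mean(np.log(probs[np.arange(len(b)), y[b]] + 1e-12)))
                grads = self._backward(cache, onehot[b])
                opt.step(self.params, grads)
            logger.debug("cnn epoch %d loss %.4f", epoch, float(np.mean(losses)))
        return self

    def predict_proba(self, sentences, batch_size: int = 512) -> np.ndarray:
        ids = self.encode(sentences)
        out = []
        for start in range(0, len(ids), batch_size):
            probs, _ = self._forward(ids[start : start + batch_size])
            out.append(probs)
        return np.vstack(out)

    def layer_features(self, sentences, layer: str = "dense2", batch_size: int = 512) -> np.ndarray:
        if layer not in self.LAYERS:
            raise ValueError(f"unknown layer {layer!r}; available: {list(self.LAYERS)}")
        key = {"softmax": "probs", "embedding": "embedding"}.get(layer, layer)
        key = {"dense1": "Zd1", "dense2": "Zd2", "conv1": "Z1", "conv2": "Z2"}.get(layer, key)
        ids = self.encode(sentences)
        out = []
        for start in range(0, len(ids), batch_size):
            _, cache = self._forward(ids[start : start + batch_size])
            val = cache[key]
            out.append(val.reshape(len(val), -1))
        return np.vstack(out)


def train_cnn(
    corpus: TopicCorpus,
    table: EmbeddingTable,
    config: CNNConfig,
    split: tuple[np.ndarray, np.ndarray],
) -> TrainedCNN:
    """Train the topic CNN on a train/test index partition of the corpus.

    The embedding layer is initialised from ``table`` and remains trainable.
    Raises if the test split contains a label absent from the training split,
    or if any sentence exceeds ``pad_length``.
    """
    train_idx, test_idx = (np.asarray(s, dtype=int) for s in split)
    labels = corpus.labels
    train_labels = set(labels[train_idx].tolist())
    missing = set(labels[test_idx].tolist()) - train_labels
    if missing:
        raise ValueError(f"test split contains unseen labels: {sorted(missing)}")
    max_len = max(len(s) for s in corpus.sentences)
    if config.pad_length < max_len:
        raise ValueError(
            f"pad_length={config.pad_length} < longest sentence ({max_len})"
        )
    word_index = {w: i + 1 for i, w in enumerate(corpus.vocab)}
    model = TrainedCNN(config, word_index, corpus.n_topics)
    sents = [corpus.sentences[i] for i in train_idx]
    model.fit(sents, labels[train_idx], table)
    return model


class TrainedMLP:
    """Bag-of-words control classifier over averaged-embedding inputs.

    Thin wrapper around scikit-learn's ``MLPClassifier``; hidden-layer
    activations are recomputed with an explicit tanh forward pass so the last
    hidden layer can serve as a sentence representation.
    """

    def __init__(self, config: MLPConfig, clf: MLPClassifier):
        self.config = config
        self.clf = clf
        n_hidden = len(config.hidden_sizes)
        self.LAYERS = tuple(f"hidden{i+1}" for i in range(n_hidden)) + ("softmax",)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(np.asarray(features, dtype=float))

    def layer_features(self, features: np.ndarray, layer: str | None = None) -> np.ndarray:
        layer = layer or self.LAYERS[-2]
        if layer not in self.LAYERS:
            raise ValueError(f"unknown layer {layer!r}; available: {list(self.LAYERS)}")
        X = np.asarray(features, dtype=float)
        if layer == "softmax":
            return self.predict_proba(X)
        depth = int(layer.replace("hidden", ""))
        for i in range(depth):
            X = np.tanh(X @ self.clf.coefs_[i] + self.clf.intercepts_[i])
        return X


def train_mlp(
    features: SentenceFeatures,
    labels: np.ndarray,
    config: MLPConfig,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedMLP:
    """Train the MLP control model on averaged-embedding sentence features."""
    labels = np.asarray(labels)
    X = features.matrix
    if split is not None:
        train_idx, test_idx = (np.asarray(s, dtype=int) for s in split)
        missing = set(labels[test_idx].tolist()) - set(labels[train_idx].tolist())
        if missing:
            raise ValueError(f"test split contains unseen labels: {sorted(missing)}")
        X, labels = X[train_idx], labels[train_idx]
    clf = MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden_sizes),
        activation=config.activation,
        alpha=config.l2_penalty,
        batch_size=min(config.batch_size, len(X)),
        learning_rate_init=config.learning_rate_init,
        solver="adam",
        max_iter=config.max_iter,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        clf.fit(X, labels)
    return TrainedMLP(config, clf)


def extract_layer_features(model, inputs, layer: str | None = None) -> SentenceFeatures:
    """Activations of a named layer as SentenceFeatures.

    For the CNN the default layer is ``dense2`` (the pre-softmax "final
    layer"); for the MLP it is the last hidden layer.
    """
    if isinstance(model, TrainedCNN):
        layer = layer or "dense2"
        mat = model.layer_features(inputs, layer)
        name = f"cnn_{layer}" if layer != "dense2" else "cnn_final_layer"
    else:
        mat = model.layer_features(inputs, layer)
        name = "mlp_final_layer"
    return SentenceFeatures(mat, name)


# ---------------------------------------------------------------------------
# nearest-centroid evaluation
# ---------------------------------------------------------------------------

def _pearson_to_centroids(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    cc = centroids - centroids.mean(axis=1, keepdims=True)
    num = cc @ xc
    den = np.sqrt((cc**2).sum(axis=1) * (xc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def nearest_centroid_topk(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    test_labels: np.ndarray,
    ks: list[int],
) -> ClassifierReport:
    """Nearest-centroid classification by Pearson correlation.

    Centroid = mean training vector per category; a test item is top-k
    correct when its true label is among the k most correlated centroids
    (ties broken toward the lowest category index).  Constant test vectors
    are counted as errors with a warning.
    """
    Xtr = np.asarray(getattr(train_features, "matrix", train_features), dtype=float)
    Xte = np.asarray(getattr(test_features, "matrix", test_features), dtype=float)
    ytr, yte = np.asarray(train_labels), np.asarray(test_labels)
    cats = np.unique(ytr)
    if not set(np.unique(yte)).issubset(set(cats.tolist())):
        raise ValueError("test labels contain categories absent from training")
    cat_to_rank = {c: i for i, c in enumerate(cats)}
    centroids = np.stack([Xtr[ytr == c].mean(axis=0) for c in cats])
    ks = sorted(set(int(k) for k in ks))
    if ks[-1] > len(cats):
        raise ValueError("k exceeds number of categories")
    hits = {k: 0 for k in ks}
    for x, y in zip(Xte, yte):
        if np.std(x) == 0:
            warnings.warn("constant test vector scored as incorrect")
            continue
        scores = _pearson_to_centroids(x, centroids)
        order = np.argsort(-scores, kind="stable")  # ties -> lowest index first
        rank = int(np.flatnonzero(order == cat_to_rank[y])[0])
        for k in ks:
            if rank < k:
                hits[k] += 1
    n = len(Xte)
    return ClassifierReport({k: 100.0 * hits[k] / n for k in ks}, n, len(cats))


def chance_topk(n_categories: int, k: int) -> float:
    """Chance-level top-k accuracy in percent: 100 k / n_categories."""
    if k < 1 or k > n_categories:
        raise ValueError("require 1 <= k <= n_categories")
    return 100.0 * k / n_categories


def display_round(x: float, decimals: int = 1) -> float:
    """Half-up decimal rounding for displayed accuracies/alphas (so 6.25%
    prints as 6.3, not banker's 6.2); the exact value is always retained by
    the computing functions."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# stimulus selection
# ---------------------------------------------------------------------------

def select_stimuli(
    candidates: TopicCorpus,
    freq_dict: dict[str, float],
    length_range: tuple[int, int],
    percentile_band: tuple[float, float],
    n_clusters: int,
    per_cluster: int,
    features: SentenceFeatures,
) -> np.ndarray:
    """Frequency / length / cluster-silhouette stimulus selection.

    (1) drop sentences whose mean log10 lexical frequency falls outside the
    given percentile band of the candidate pool; (2) keep sentences with
    lengths inside ``length_range``; (3) Ward-cluster survivors' features into
    ``n_clusters``; (4) keep the ``per_cluster`` highest-silhouette sentences
    of each cluster (all of them if the cluster is smaller).  Returns selected
    sentence indices into ``candidates``.
    """
    if features.n_sentences != len(candidates):
        raise ValueError("features do not align with candidates")
    mean_logf = np.array(
        [
            np.mean([np.log10(freq_dict[w]) for w in toks if freq_dict.get(w, 0) > 0])
            for toks in candidates.sentences
        ]
    )
    lo, hi = np.percentile(mean_logf, percentile_band)
    keep = (mean_logf >= lo) & (mean_logf <= hi)
    if not keep.any():
        raise ValueError("frequency-percentile filter removed every candidate")
    lengths = np.array([len(s) for s in candidates.sentences])
    keep &= (lengths >= length_range[0]) & (lengths <= length_range[1])
    if not keep.any():
        raise ValueError("length filter removed every candidate")
    surv = np.flatnonzero(keep)
    X = features.matrix[surv]
    if n_clusters > len(surv):
        raise ValueError("more clusters requested than surviving sentences")
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters for silhouette scoring")
    labels = cut_clusters(ward_dendrogram(X), n_clusters)
    sil = silhouette_scores(X, labels)
    chosen = []
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        order = members[np.argsort(-sil[members], kind="stable")]
        chosen.extend(surv[order[:per_cluster]].tolist())
    return np.array(sorted(chosen))


# ---------------------------------------------------------------------------
# feature I/O
# ---------------------------------------------------------------------------

def write_features(features: SentenceFeatures, path) -> None:
    """Tab-separated matrix with a header row of sentence ids."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(str(i) for i in features.sentence_ids) + "\n")
        for col in features.matrix.T:
            fh.write("\t".join(f"{x:.10g}" for x in col) + "\n")


def read_features(path, model_name: str = "") -> SentenceFeatures:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    ids = lines[0].split("\t")
    mat = np.array([[float(x) for x in ln.split("\t")] for ln in lines[1:]]).T
    return SentenceFeatures(mat, model_name, ids)
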