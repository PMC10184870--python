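"""Synthetic corpora, word embeddings and volumetric brain patterns.

Every downstream stage of the pipeline (sentence representations, RDMs,
searchlight / ROI RSA, group statistics) is exercised against data produced
here, with known planted structure:

* :func:`make_topic_corpus` — a topic-labelled sentence corpus with
  hierarchical supra-category structure (topics inside a supra-category share
  part of their content-word distribution).
* :func:`make_embedding_table` — word vectors clustered by topic and
  supra-category at a controllable strength.
* :func:`make_brain_dataset` — per-subject sentence × voxel response patterns
  in which a chosen model RDM is planted inside designated ROIs at a
  controllable signal-to-noise ratio.

The brain generator works at the "per-sentence response amplitude" level; it
does not simulate hemodynamics, trial time series or GLM estimation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

logger = logging.getLogger("topicrsa")

__all__ = [
    "CorpusConfig",
    "TopicCorpus",
    "EmbeddingTable",
    "BrainGeometry",
    "BrainDataset",
    "make_topic_corpus",
    "make_cooccurrence_corpus",
    "make_embedding_table",
    "make_ball_geometry",
    "psd_project",
    "make_brain_dataset",
    "make_frequency_dictionary",
    "write_corpus",
    "read_corpus",
    "write_embedding_table",
    "read_embedding_table",
    "save_geometry_nifti",
    "save_patterns_nifti",
]


# ---------------------------------------------------------------------------
# configuration & containers
# ---------------------------------------------------------------------------

@dataclass
class CorpusConfig:
    """Parameters of the synthetic topic-labelled corpus.

    Defaults mirror the study conditions: 64 topics, sentence lengths between
    6 and 38 words, with the per-topic sentence count scaled to desk size.
    ``supra_mixture`` is the probability that a content token is drawn from
    the supra-category's shared pool instead of the topic's own pool, which is
    what makes the supra-structure recoverable by clustering.
    """

    n_topics: int = 64
    n_supra: int = 8
    vocab_size: int = 2000
    sentences_per_topic: int = 100
    length_range: tuple[int, int] = (6, 38)
    stopword_fraction: float = 0.4
    topic_concentration: float = 5.0
    supra_mixture: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_supra > self.n_topics:
            raise ValueError("n_supra must not exceed n_topics")
        if self.length_range[0] < 1 or self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid length_range")
        if not 0 <= self.stopword_fraction < 1:
            raise ValueError("stopword_fraction must be in [0, 1)")
        if self.topic_concentration <= 0:
            raise ValueError("topic_concentration must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["length_range"] = list(self.length_range)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CorpusConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["length_range"] = tuple(d["length_range"])
        return cls(**d)


@dataclass
class TopicCorpus:
    """Tokenised, topic-labelled sentences with optional supra-category map."""

    sentences: list[list[str]]
    labels: np.ndarray
    topic_names: list[str]
    supra_of_topic: np.ndarray
    vocab: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.supra_of_topic = np.asarray(self.supra_of_topic, dtype=int)
        if len(self.sentences) != len(self.labels):
            raise ValueError("sentences and labels differ in length")
        if self.labels.size and self.labels.max() >= len(self.topic_names):
            raise ValueError("label out of range")

    @property
    def n_topics(self) -> int:
        return len(self.topic_names)

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass
class EmbeddingTable:
    """Fixed-dimension word vectors covering a corpus vocabulary."""

    vocab: list[str]
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent vector dimensions: {dims}")
        for w, v in self.vectors.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite vector for {w!r}")

    @property
    def dim(self) -> int:
        return next(iter(self.vectors.values())).shape[0]

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word]


@dataclass
class BrainGeometry:
    """A 3-D voxel grid with a brain mask and named ROI masks."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    brain_mask: np.ndarray
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if np.isscalar(self.voxel_size_mm):
            self.voxel_size_mm = (float(self.voxel_size_mm),) * 3
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.shape:
            raise ValueError("brain_mask shape mismatch")
        for name, m in self.roi_masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.shape:
                raise ValueError(f"ROI {name!r} shape mismatch")
            if np.any(m & ~self.brain_mask):
                raise ValueError(f"ROI {name!r} extends outside the brain mask")
            self.roi_masks[name] = m

    @property
    def n_voxels(self) -> int:
        return int(self.brain_mask.sum())

    def voxel_coords(self) -> np.ndarray:
        """(n_voxels, 3) integer grid coordinates, C order — the canonical
        voxel ordering used by all pattern matrices."""
        return np.argwhere(self.brain_mask)

    def flat_index_volume(self) -> np.ndarray:
        """3-D int volume mapping grid position -> column index, -1 outside."""
        vol = np.full(self.shape, -1, dtype=np.int64)
        vol[self.brain_mask] = np.arange(self.n_voxels)
        return vol

    def roi_columns(self, name: str) -> np.ndarray:
        """Column indices (into the pattern matrix) of an ROI's voxels."""
        return self.flat_index_volume()[self.roi_masks[name]]

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff


@dataclass
class BrainDataset:
    """Per-subject sentence × voxel patterns plus generation provenance."""

    patterns: np.ndarray  # (n_subjects, n_sentences, n_voxels)
    geometry: BrainGeometry
    provenance: dict

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 3:
            raise ValueError("patterns must be (subjects, sentences, voxels)")
        if self.patterns.shape[2] != self.geometry.n_voxels:
            raise ValueError("voxel count mismatch with geometry")
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("non-finite values in patterns")

    @property
    def n_subjects(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_sentences(self) -> int:
        return self.patterns.shape[1]


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

_ALPHA = "abcdefghijklmnopqrstuvwxyz"


def _letters(i: int) -> str:
    """Encode a non-negative integer as a lowercase base-26 string (digit-free
    so tokens pass untouched through the digit-masking tokenizer)."""
    s = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        s = _ALPHA[r] + s
    return s


def make_topic_corpus(config: CorpusConfig) -> TopicCorpus:
    """Generate a topic-labelled corpus with planted hierarchical structure.

    Each topic owns a disjoint pool of content words; topics within a
    supra-category additionally share a supra pool (drawn with probability
    ``supra_mixture`` for content tokens), and all topics share a stopword
    pool.  Word probabilities within a pool are Dirichlet with parameter
    ``1 / topic_concentration``, so larger concentration gives more peaked,
    more separable topics.  Deterministic for a fixed seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_stop = max(10, cfg.vocab_size // 10)
    n_content = cfg.vocab_size - n_stop
    supra_pool_total = n_content // 4
    per_supra = supra_pool_total // cfg.n_supra
    per_topic = (n_content - per_supra * cfg.n_supra) // cfg.n_topics
    if per_topic < 3 or per_supra < 1:
        raise ValueError(
            f"vocab_size={cfg.vocab_size} too small to give each of "
            f"{cfg.n_topics} topics a distinct content-word pool"
        )

    stopwords = [f"sw{_letters(i)}" for i in range(n_stop)]
    supra_pools = [
        [f"s{_letters(s)}w{_letters(i)}" for i in range(per_supra)]
        for s in range(cfg.n_supra)
    ]
    topic_pools = [
        [f"t{_letters(t)}w{_letters(i)}" for i in range(per_topic)]
        for t in range(cfg.n_topics)
    ]
    vocab = stopwords + [w for p in supra_pools for w in p] + [
        w for p in topic_pools for w in p
    ]

    supra_of_topic = np.array(
        [t * cfg.n_supra // cfg.n_topics for t in range(cfg.n_topics)]
    )

    alpha = 1.0 / cfg.topic_concentration
    stop_w = rng.dirichlet(np.full(n_stop, alpha))
    supra_w = [rng.dirichlet(np.full(per_supra, alpha)) for _ in range(cfg.n_supra)]
    topic_w = [rng.dirichlet(np.full(per_topic, alpha)) for _ in range(cfg.n_topics)]

    lo, hi = cfg.length_range
    sentences: list[list[str]] = []
    labels: list[int] = []
    for t in range(cfg.n_topics):
        s_idx = supra_of_topic[t]
        for _ in range(cfg.sentences_per_topic):
            length = int(rng.integers(lo, hi + 1))
            u = rng.random(length)
            toks = []
            for ui in u:
                if ui < cfg.stopword_fraction:
                    toks.append(stopwords[rng.choice(n_stop, p=stop_w)])
                elif ui < cfg.stopword_fraction + (1 - cfg.stopword_fraction) * cfg.supra_mixture:
                    toks.append(supra_pools[s_idx][rng.choice(per_supra, p=supra_w[s_idx])])
                else:
                    toks.append(topic_pools[t][rng.choice(per_topic, p=topic_w[t])])
            sentences.append(toks)
            labels.append(t)

    topic_names = [f"topic_{_letters(t)}" for t in range(cfg.n_topics)]
    return TopicCorpus(sentences, np.array(labels), topic_names, supra_of_topic, vocab)


def make_cooccurrence_corpus(
    words_per_group: int = 12,
    sentences_per_topic: int = 1000,
    length_range: tuple[int, int] = (8, 14),
    stopword_fraction: float = 0.2,
    n_stopwords: int = 8,
    seed: int = 0,
) -> TopicCorpus:
    """Two-topic corpus where topics differ only in word *co-occurrence*.

    Four word groups A0, A1, B0, B1.  Topic 0 sentences mix (A0 with B0) or
    (A1 with B1); topic 1 sentences mix (A0 with B1) or (A1 with B0).  The
    unigram distribution of the two topics is identical (uniform over all four
    groups), so bag-of-words sentence representations carry no topic signal in
    expectation while a model sensitive to which words appear *together* can
    separate the topics.
    """
    rng = np.random.default_rng(seed)
    groups = {
        name: [f"{name}{_letters(i)}" for i in range(words_per_group)]
        for name in ("qa", "qb", "ra", "rb")  # A0, A1, B0, B1
    }
    stopwords = [f"sw{_letters(i)}" for i in range(n_stopwords)]
    variants = {
        0: [("qa", "ra"), ("qb", "rb")],
        1: [("qa", "rb"), ("qb", "ra")],
    }
    lo, hi = length_range
    sentences, labels = [], []
    for topic in (0, 1):
        for _ in range(sentences_per_topic):
            g1, g2 = variants[topic][int(rng.integers(2))]
            length = int(rng.integers(lo, hi + 1))
            toks = []
            for _ in range(length):
                u = rng.random()
                if u < stopword_fraction:
                    toks.append(stopwords[int(rng.integers(n_stopwords))])
                elif u < stopword_fraction + (1 - stopword_fraction) / 2:
                    toks.append(groups[g1][int(rng.integers(words_per_group))])
                else:
                    toks.append(groups[g2][int(rng.integers(words_per_group))])
            rng.shuffle(toks)
            sentences.append(toks)
            labels.append(topic)
    vocab = stopwords + [w for g in groups.values() for w in g]
    return TopicCorpus(
        sentences, np.array(labels), ["topic_a", "topic_b"], np.zeros(2, int), vocab
    )


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def make_embedding_table(
    corpus: TopicCorpus, dim: int, cluster_strength: float, seed: int
) -> EmbeddingTable:
    """Generate topic-clustered word vectors for a corpus vocabulary.

    Each word is assigned to the topic (and its supra-category) that accounts
    for the majority of its occurrences; its vector is then
    ``cluster_strength * (supra_centroid + topic_centroid) + noise`` with unit
    isotropic Gaussian noise.  Words spread across topics (stopwords) get
    noise around the global mean only.  ``cluster_strength = 0`` therefore
    plants no structure at all.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)
    n_topics = corpus.n_topics
    n_supra = int(corpus.supra_of_topic.max()) + 1 if n_topics else 1

    # occurrence counts per (word, topic) to assign words to clusters
    per_topic: dict[str, Counter] = {}
    for toks, lab in zip(corpus.sentences, corpus.labels):
        for w in toks:
            per_topic.setdefault(w, Counter())[lab] += 1

    supra_centroids = rng.standard_normal((n_supra, dim))
    topic_centroids = rng.standard_normal((n_topics, dim))

    vectors: dict[str, np.ndarray] = {}
    for w in corpus.vocab:
        noise = rng.standard_normal(dim)
        counts = per_topic.get(w)
        mean = np.zeros(dim)
        if counts is not None:
            total = sum(counts.values())
            top_t, top_n = counts.most_common(1)[0]
            supra_counts = Counter()
            for t, n in counts.items():
                supra_counts[int(corpus.supra_of_topic[t])] += n
            top_s, top_sn = supra_counts.most_common(1)[0]
            if top_n / total >= 0.5:
                mean = supra_centroids[corpus.supra_of_topic[top_t]] + topic_centroids[top_t]
            elif top_sn / total >= 0.5:
                mean = supra_centroids[top_s]
        vectors[w] = cluster_strength * mean + noise
    return EmbeddingTable(list(corpus.vocab), vectors)


# ---------------------------------------------------------------------------
# brain geometry & pattern planting
# ---------------------------------------------------------------------------

def make_ball_geometry(
    shape: tuple[int, int, int] = (24, 24, 24),
    voxel_size_mm: float | tuple[float, float, float] = 2.0,
    rois: dict[str, tuple[tuple[float, float, float], float]] | None = None,
) -> BrainGeometry:
    """Spherical brain mask inscribed in ``shape`` with spherical ROIs.

    ``rois`` maps name -> (center voxel coordinates, radius in voxels).  The
    default 24³ grid at 2 mm isotropic matches the acquisition voxel size at a
    desk-scale field of view.
    """
    shape = tuple(int(s) for s in shape)
    idx = np.indices(shape, dtype=float)
    center = (np.asarray(shape, float) - 1) / 2
    r = min(shape) / 2 - 0.5
    dist2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    brain = dist2 <= r**2
    roi_masks = {}
    for name, (c, rad) in (rois or {}).items():
        d2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
        roi_masks[name] = (d2 <= rad**2) & brain
    return BrainGeometry(shape, voxel_size_mm, brain, roi_masks)


def psd_project(S: np.ndarray) -> np.ndarray:
    """Nearest positive-semidefinite repair of a similarity matrix.

    Eigenvalues are clipped at zero and the diagonal rescaled back to 1, so an
    already-PSD unit-diagonal matrix passes through unchanged (up to numerical
    tolerance).
    """
    S = np.asarray(S, dtype=float)
    S = (S + S.T) / 2
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 0, None)
    S2 = (V * w) @ V.T
    d = np.clip(np.diag(S2), 1e-12, None)
    S2 = S2 / np.sqrt(np.outer(d, d))
    return (S2 + S2.T) / 2


def _similarity_factor(S: np.ndarray) -> np.ndarray:
    """L with L @ L.T = S for PSD S (eigen square root)."""
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 0, None)
    return V * np.sqrt(w)


def make_brain_dataset(
    model_rdm_per_roi: dict[str, np.ndarray],
    geometry: BrainGeometry,
    n_subjects: int,
    snr: dict[str, float],
    noise_sd: float = 1.0,
    seed: int = 0,
    model_names: dict[str, str] | None = None,
) -> BrainDataset:
    """Generate subject pattern matrices with model RDMs planted in ROIs.

    For each signal ROI the similarity matrix ``S = 1 - RDM`` (unit diagonal)
    is projected to the nearest PSD matrix and factored as ``L @ L.T = S``;
    the ROI's pattern block is then ``snr * (L @ Z) + noise_sd * E`` with
    ``Z, E`` independent standard normal, so each voxel's response profile has
    covariance ``snr² S + noise_sd² I`` across sentences and the expected
    pattern RSM approaches ``S`` as ``snr / noise_sd`` grows.  Voxels outside
    every signal ROI receive pure noise.  Subject ``s`` uses sub-seed
    ``seed + s``.
    """
    rdms = {k: np.asarray(v, dtype=float) for k, v in model_rdm_per_roi.items()}
    ns = {a.shape[0] for a in rdms.values()}
    if len(ns) != 1:
        raise ValueError("all model RDMs must have the same number of items")
    n_sent = ns.pop()
    for name, a in rdms.items():
        if a.shape != (n_sent, n_sent):
            raise ValueError(f"RDM for {name!r} is not square")
        if a.min() < -1e-10 or a.max() > 2 + 1e-10:
            raise ValueError(f"RDM for {name!r} has entries outside [0, 2]")
        if name not in geometry.roi_masks:
            raise ValueError(f"unknown ROI {name!r}")
        if geometry.roi_masks[name].sum() == 0:
            raise ValueError(f"ROI {name!r} is empty")

    factors = {}
    for name, a in rdms.items():
        S = 1.0 - a
        np.fill_diagonal(S, 1.0)
        factors[name] = _similarity_factor(psd_project(S))

    n_vox = geometry.n_voxels
    roi_cols = {name: geometry.roi_columns(name) for name in rdms}
    patterns = np.empty((n_subjects, n_sent, n_vox))
    for s in range(n_subjects):
        rng = np.random.default_rng(seed + s)
        X = noise_sd * rng.standard_normal((n_sent, n_vox))
        for name in sorted(rdms):
            cols = roi_cols[name]
            Z = rng.standard_normal((n_sent, cols.size))
            E = rng.standard_normal((n_sent, cols.size))
            X[:, cols] = snr.get(name, 0.0) * (factors[name] @ Z) + noise_sd * E
        patterns[s] = X

    prov = {
        "planted_model_per_roi": dict(model_names or {k: k for k in rdms}),
        "snr_per_roi": {k: float(v) for k, v in snr.items()},
        "noise_sd": float(noise_sd),
        "seed": int(seed),
    }
    return BrainDataset(patterns, geometry, prov)


# ---------------------------------------------------------------------------
# frequency dictionary
# ---------------------------------------------------------------------------

def make_frequency_dictionary(corpus: TopicCorpus) -> dict[str, float]:
    """Relative token frequencies over the whole corpus (sum to 1); every
    vocabulary token is present, with zero-count tokens getting 0."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    counts = Counter(w for toks in corpus.sentences for w in toks)
    total = sum(counts.values())
    return {w: counts.get(w, 0) / total for w in corpus.vocab}


# ---------------------------------------------------------------------------
# external formats
# ---------------------------------------------------------------------------

def write_corpus(corpus: TopicCorpus, sentences_path: str | Path, labels_path: str | Path) -> None:
    """One sentence per line (space-joined tokens) + TSV label table."""
    Path(sentences_path).write_text(
        "\n".join(" ".join(toks) for toks in corpus.sentences) + "\n", encoding="utf-8"
    )
    lines = ["sentence_id\ttopic_index\ttopic_name\tsupra_index"]
    for i, lab in enumerate(corpus.labels):
        lines.append(
            f"{i}\t{lab}\t{corpus.topic_names[lab]}\t{corpus.supra_of_topic[lab]}"
        )
    Path(labels_path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_corpus(sentences_path: str | Path, labels_path: str | Path) -> TopicCorpus:
    sentences = [
        line.split()
        for line in Path(sentences_path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    rows = Path(labels_path).read_text(encoding="utf-8").splitlines()[1:]
    labels, names, supra = [], {}, {}
    for row in rows:
        if not row.strip():
            continue
        _, t, name, s = row.split("\t")
        labels.append(int(t))
        names[int(t)] = name
        supra[int(t)] = int(s)
    n_topics = max(names) + 1
    topic_names = [names.get(t, f"topic_{t}") for t in range(n_topics)]
    supra_of_topic = np.array([supra.get(t, 0) for t in range(n_topics)])
    vocab = sorted({w for toks in sentences for w in toks})
    return TopicCorpus(sentences, np.array(labels), topic_names, supra_of_topic, vocab)


def write_embedding_table(table: EmbeddingTable, path: str | Path) -> None:
    """word2vec-style text: word followed by d floats per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for w in table.vocab:
            vec = " ".join(f"{x:.8g}" for x in table.vectors[w])
            fh.write(f"{w} {vec}\n")


def read_embedding_table(path: str | Path) -> EmbeddingTable:
    vocab, vectors = [], {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split()
        vocab.append(parts[0])
        vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    return EmbeddingTable(vocab, vectors)


def save_geometry_nifti(geometry: BrainGeometry, out_dir: str | Path) -> None:
    """Write brain mask and each ROI mask as uint8 NIfTI volumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = geometry.affine()
    nib.save(
        nib.Nifti1Image(geometry.brain_mask.astype(np.uint8), aff),
        out / "brain_mask.nii",
    )
    for name, m in geometry.roi_masks.items():
        nib.save(nib.Nifti1Image(m.astype(np.uint8), aff), out / f"roi_{name}.nii")


def save_patterns_nifti(dataset: BrainDataset, out_dir: str | Path) -> None:
    """One 4-D NIfTI per subject, sentence-major on the 4th axis."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geo = dataset.geometry
    aff = geo.affine()
    for s in range(dataset.n_subjects):
        vol = np.zeros(geo.shape + (dataset.n_sentences,), dtype=np.float32)
        vol[geo.brain_mask, :] = dataset.patterns[s].T
        nib.save(nib.Nifti1Image(vol, aff), out / f"subject_{s:02d}.nii")
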