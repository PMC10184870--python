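"""End-to-end experiment orchestration from a single YAML config.

The pipeline composes the package's stages in the order the method runs:

1. **simulate** — generate the topic corpus and the word-embedding table;
2. **represent** — train the requested sentence-representation models,
   select stimulus sentences, compute one model RDM per representation and
   their pairwise correlations;
3. **rsa** — generate (or load) subject-level brain patterns with model RDMs
   planted in ROIs, then run ROI and/or searchlight RSA per subject/model;
4. **stats** — paired one-tailed model contrasts per ROI with
   Bonferroni-adjusted alpha and Cohen's d, and (in searchlight mode) the
   voxelwise contrast with sign-flip permutation cluster correction.

Every artifact is written under the output directory and is a deterministic
function of the config and its seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import brainrsa, groupstats, synthetic, textmodels
from .geometry import RDM, build_rdm, compare_rdms, write_rdm, read_rdm

logger = logging.getLogger("topicrsa")

MODEL_NAMES = ("average_embeddings", "cnn_final_layer", "tfidf", "mlp")

__all__ = ["ExperimentConfig", "run_experiment", "stage_simulate",
           "stage_represent", "stage_rsa", "stage_stats"]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    corpus: dict = field(default_factory=dict)
    embedding: dict = field(default_factory=lambda: {"dim": 50, "cluster_strength": 1.0})
    models: list[str] = field(default_factory=lambda: ["cnn_final_layer", "average_embeddings"])
    cnn: dict = field(default_factory=dict)
    mlp: dict = field(default_factory=dict)
    stimuli: dict = field(default_factory=dict)   # select_stimuli kwargs or {}
    brain: dict = field(default_factory=dict)     # synthetic generation or file paths
    rsa: dict = field(default_factory=dict)       # RsaConfig fields + mode
    stats: dict = field(default_factory=lambda: {"alpha": 0.05})
    train_fraction: float = 0.8
    seed: int = 0
    out_dir: str = "topicrsa_out"

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if len(self.models) < 2 and self.stats.get("contrast", True):
            raise ValueError("need >= 2 models for a contrast")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: ExperimentConfig, out: Path) -> dict:
    """Corpus + embedding table; written as plain-text artifacts."""
    out.mkdir(parents=True, exist_ok=True)
    ccfg = synthetic.CorpusConfig(**{"seed": cfg.seed, **cfg.corpus})
    corpus = synthetic.make_topic_corpus(ccfg)
    emb = synthetic.make_embedding_table(
        corpus,
        dim=int(cfg.embedding.get("dim", 50)),
        cluster_strength=float(cfg.embedding.get("cluster_strength", 1.0)),
        seed=int(cfg.embedding.get("seed", cfg.seed + 1)),
    )
    synthetic.write_corpus(corpus, out / "corpus.txt", out / "labels.tsv")
    synthetic.write_embedding_table(emb, out / "embeddings.txt")
    ccfg.to_yaml(out / "corpus_config.yaml")
    logger.info("simulate: %d sentences, vocab %d", len(corpus), len(corpus.vocab))
    return {"corpus": corpus, "embeddings": emb}


def _train_test_split(n: int, labels: np.ndarray, fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    train, test = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        k = max(1, int(round(fraction * idx.size)))
        train.extend(idx[:k].tolist())
        test.extend(idx[k:].tolist())
    return np.array(sorted(train)), np.array(sorted(test))


def stage_represent(cfg: ExperimentConfig, out: Path, corpus, embeddings) -> dict:
    """Model features over stimulus sentences, model RDMs, RDM correlations."""
    labels = corpus.labels
    train_idx, test_idx = _train_test_split(
        len(corpus), labels, cfg.train_fraction, cfg.seed + 2
    )

    # candidate stimuli = held-out sentences; optionally filtered/clustered
    stim_idx = test_idx
    trained = {}
    feats_full = {}

    if "average_embeddings" in cfg.models or "mlp" in cfg.models:
        feats_full["average_embeddings"] = textmodels.average_embedding_features(
            corpus, embeddings
        )
    if "cnn_final_layer" in cfg.models:
        ccfg = textmodels.CNNConfig(
            **{"seed": cfg.seed + 3, "embed_dim": embeddings.dim,
               "pad_length": max(len(s) for s in corpus.sentences), **cfg.cnn}
        )
        cnn = textmodels.train_cnn(corpus, embeddings, ccfg, (train_idx, test_idx))
        trained["cnn"] = cnn
        feats_full["cnn_final_layer"] = textmodels.extract_layer_features(
            cnn, corpus.sentences
        )
    if "tfidf" in cfg.models:
        sub = synthetic.TopicCorpus(
            [corpus.sentences[i] for i in train_idx], labels[train_idx],
            corpus.topic_names, corpus.supra_of_topic, corpus.vocab,
        )
        table = textmodels.fit_tfidf(sub)
        feats_full["tfidf"] = textmodels.tfidf_features(corpus, table)
    if "mlp" in cfg.models:
        mcfg = textmodels.MLPConfig(**{"seed": cfg.seed + 4, **cfg.mlp})
        mlp = textmodels.train_mlp(
            feats_full["average_embeddings"], labels, mcfg, (train_idx, test_idx)
        )
        trained["mlp"] = mlp
        feats_full["mlp"] = textmodels.extract_layer_features(
            mlp, feats_full["average_embeddings"].matrix
        )

    if cfg.stimuli:
        sel_model = cfg.stimuli.get("cluster_on", cfg.models[0])
        cand = synthetic.TopicCorpus(
            [corpus.sentences[i] for i in stim_idx], labels[stim_idx],
            corpus.topic_names, corpus.supra_of_topic, corpus.vocab,
        )
        freq = synthetic.make_frequency_dictionary(corpus)
        sub_feats = textmodels.SentenceFeatures(
            feats_full[sel_model].matrix[stim_idx], sel_model
        )
        chosen = textmodels.select_stimuli(
            cand, freq,
            tuple(cfg.stimuli.get("length_range", (1, 10**6))),
            tuple(cfg.stimuli.get("percentile_band", (5, 95))),
            int(cfg.stimuli["n_clusters"]),
            int(cfg.stimuli["per_cluster"]),
            sub_feats,
        )
        stim_idx = stim_idx[chosen]

    np.savetxt(out / "stimulus_ids.tsv", stim_idx, fmt="%d")
    rdms = {}
    for name in cfg.models:
        sf = textmodels.SentenceFeatures(
            feats_full[name].matrix[stim_idx], name, stim_idx.tolist()
        )
        textmodels.write_features(sf, out / f"features_{name}.tsv")
        rdms[name] = build_rdm(sf)
        write_rdm(rdms[name], out / f"rdm_{name}.tsv")

    # descriptive inter-model RDM correlations
    lines = ["model_a\tmodel_b\tr"]
    for i, a in enumerate(cfg.models):
        for b in cfg.models[i + 1:]:
            r = compare_rdms(rdms[a], rdms[b])
            lines.append(f"{a}\t{b}\t{r:.6f}")
            logger.info("RDM correlation %s vs %s: r=%.3f", a, b, r)
    (out / "model_rdm_correlations.tsv").write_text("\n".join(lines) + "\n")
    return {"rdms": rdms, "stim_idx": stim_idx, "trained": trained,
            "split": (train_idx, test_idx)}


def stage_rsa(cfg: ExperimentConfig, out: Path, rdms: dict[str, RDM]) -> dict:
    """Brain data (synthetic planting or NIfTI loading) + per-subject RSA."""
    b = cfg.brain
    rcfg = brainrsa.RsaConfig(
        **{k: v for k, v in cfg.rsa.items() if k in
           ("radius_mm", "smooth_fwhm_mm", "min_sphere_voxels", "demean")}
    )
    mode = cfg.rsa.get("mode", "roi")

    if "patterns_files" in b:
        import nibabel as nib
        mask = np.asarray(nib.load(b["brain_mask"]).dataobj) > 0
        img = nib.load(b["brain_mask"])
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        roi_masks = {
            name: np.asarray(nib.load(p).dataobj) > 0
            for name, p in b.get("roi_masks", {}).items()
        }
        geometry = synthetic.BrainGeometry(mask.shape, vox, mask, roi_masks)
        pats = []
        for f in b["patterns_files"]:
            vol = np.asarray(nib.load(f).dataobj, dtype=float)
            pats.append(vol[mask, :].T)
        dataset = synthetic.BrainDataset(
            np.stack(pats), geometry, {"source": "files"}
        )
    else:
        geometry = synthetic.make_ball_geometry(
            tuple(b.get("shape", (24, 24, 24))),
            b.get("voxel_size_mm", 2.0),
            {name: (tuple(spec["center"]), float(spec["radius"]))
             for name, spec in b.get("rois", {}).items()},
        )
        planted = b.get("planted", {})
        dataset = synthetic.make_brain_dataset(
            {roi: rdms[model].matrix for roi, model in planted.items()},
            geometry,
            int(b.get("n_subjects", 24)),
            {roi: float(v) for roi, v in b.get("snr", {}).items()},
            float(b.get("noise_sd", 1.0)),
            int(b.get("seed", cfg.seed + 10)),
            model_names=planted,
        )
        synthetic.save_geometry_nifti(geometry, out / "masks")

    results = {"geometry": geometry, "dataset": dataset}
    if mode in ("roi", "both"):
        rows = ["subject\troi\tmodel\tr"]
        roi_r = {}
        for roi in sorted(geometry.roi_masks):
            cols = geometry.roi_columns(roi)
            for model, rdm in rdms.items():
                rs = [
                    brainrsa.roi_rsa(dataset.patterns[s], cols, rdm, rcfg)
                    for s in range(dataset.n_subjects)
                ]
                roi_r[(roi, model)] = np.array(rs)
                rows += [f"{s}\t{roi}\t{model}\t{r:.6f}" for s, r in enumerate(rs)]
        (out / "roi_rsa.tsv").write_text("\n".join(rows) + "\n")
        results["roi_r"] = roi_r
    if mode in ("searchlight", "both"):
        maps = {}
        mdir = out / "zmaps"
        mdir.mkdir(parents=True, exist_ok=True)
        for model, rdm in rdms.items():
            maps[model] = []
            for s in range(dataset.n_subjects):
                smap = brainrsa.searchlight_rsa(
                    dataset.patterns[s], geometry, rdm, rcfg,
                    model_name=model, subject_id=f"{s:02d}",
                )
                brainrsa.save_map_nifti(smap, mdir / f"{model}_sub{s:02d}.nii")
                maps[model].append(smap)
        results["maps"] = maps
    return results


def stage_stats(cfg: ExperimentConfig, out: Path, rsa_out: dict) -> dict:
    """Group contrasts: ROI paired t-tests and/or voxelwise cluster stats."""
    alpha = float(cfg.stats.get("alpha", 0.05))
    models = cfg.models
    pairs = [(a, b) for i, a in enumerate(models) for b in models[i + 1:]]
    summary = {}

    if "roi_r" in rsa_out:
        roi_r = rsa_out["roi_r"]
        rois = sorted({k[0] for k in roi_r})
        m_tests = len(rois)
        adj = groupstats.bonferroni_alpha(alpha, m_tests)
        rows = ["roi\tmodel_a\tmodel_b\tt\tdf\tp_uncorrected\talpha_adjusted"
                "\tsignificant_corrected\tsignificant_uncorrected\tcohens_d"]
        contrasts = {}
        for a, b in pairs:
            for roi in rois:
                res = groupstats.paired_ttest_onetailed(
                    roi_r[(roi, a)], roi_r[(roi, b)], "greater"
                )
                d = groupstats.cohens_d_paired(roi_r[(roi, a)], roi_r[(roi, b)])
                rows.append(
                    f"{roi}\t{a}\t{b}\t{res.t:.6f}\t{res.df}\t{res.p:.6g}\t"
                    f"{adj:.6g}\t{res.p < adj}\t{res.p < alpha}\t{d:.6f}"
                )
                contrasts[(roi, a, b)] = res
        (out / "roi_contrasts.tsv").write_text("\n".join(rows) + "\n")
        summary["roi_contrasts"] = contrasts
        summary["alpha_adjusted"] = adj

    if "maps" in rsa_out and len(pairs) >= 1:
        a, b = pairs[0]
        maps_a, maps_b = rsa_out["maps"][a], rsa_out["maps"][b]
        t_map, p_map = groupstats.voxelwise_paired_contrast(maps_a, maps_b)
        geometry = rsa_out["geometry"]
        brainrsa.save_map_nifti(
            brainrsa.SearchlightMap(t_map, geometry, f"{a}-minus-{b}"),
            out / "contrast_tmap.nii",
        )
        diffs = np.stack(
            [ma.data - mb.data for ma, mb in zip(maps_a, maps_b)]
        )
        table = groupstats.cluster_correct_permutation(
            diffs,
            float(cfg.stats.get("cluster_forming_p", 0.001)),
            int(cfg.stats.get("n_permutations", 1000)),
            seed=cfg.seed + 20,
        )
        table.to_tsv(out / "clusters.tsv")
        summary["cluster_table"] = table
        summary["t_map"] = t_map
    return summary


def run_experiment(config: ExperimentConfig) -> dict:
    """Run all stages; returns a dict of in-memory results and writes every
    artifact (tables, maps, logs) under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.dump(out / "experiment_config.yaml")
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    try:
        logger.info("seeds: master=%d", config.seed)
        sim = stage_simulate(config, out)
        rep = stage_represent(config, out, sim["corpus"], sim["embeddings"])
        rsa_out = stage_rsa(config, out, rep["rdms"])
        stats_out = stage_stats(config, out, rsa_out)
    finally:
        logger.removeHandler(fh)
        fh.close()
    report = {"out_dir": str(out), **sim, **rep, **rsa_out, **stats_out}
    (out / "summary.json").write_text(
        json.dumps(
            {
                "n_sentences_stimuli": int(len(rep["stim_idx"])),
                "models": config.models,
                "n_subjects": int(rsa_out["dataset"].n_subjects),
                "alpha_adjusted": float(stats_out.get("alpha_adjusted", float("nan"))),
            },
            indent=2,
        )
    )
    return report
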