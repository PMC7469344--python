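"""End-to-end orchestration: similarities -> features -> encoder -> booster.

Two leakage regimes are supported. In ``strict`` mode every similarity
matrix and interaction profile is rebuilt from the training-fold
associations only, the autoencoder is refit per fold, and each pair's own
interaction cell is masked out of its features. In ``paper_faithful`` mode
everything is precomputed once from the full known association matrix (the
single-precomputation workflow common in this literature); scores from that
mode are optimistically biased and are labeled as such in reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from lncboost.autoencoder import AeTrainConfig, encode, train_autoencoder
from lncboost.config import RunConfig
from lncboost.data_io import (
    HierarchyRecordSet,
    InteractionMatrix,
    SimilarityMatrix,
    write_matrix,
)
from lncboost.feature_builder import (
    FeatureMatrix,
    LabeledPairSet,
    assemble_pair_features,
    balanced_pair_set,
    get_layout,
)
from lncboost.gradient_boosting import predict_score, train_gbm
from lncboost.profile_sim import disease_sets, gip_similarity, lncfs_matrix
from lncboost.semantic_sim import semantic_similarity_matrices
from lncboost.synthetic import SyntheticBundle, SyntheticSpec, generate_bundle

logger = logging.getLogger(__name__)


@dataclass
class AssociationDataset:
    """Known associations, the disease hierarchy, and the labeled pair sample."""

    interaction: InteractionMatrix
    hierarchy: HierarchyRecordSet
    pairs: LabeledPairSet
    _semantic_cache: dict = field(default_factory=dict, repr=False)

    def semantic(self, config: RunConfig) -> tuple[SimilarityMatrix, SimilarityMatrix]:
        """Both disease semantic similarity matrices (split-independent; cached)."""
        sc = config.semantic
        key = (sc.delta, sc.disss2_sign, sc.log_base, sc.include_target_term)
        if key not in self._semantic_cache:
            self._semantic_cache[key] = semantic_similarity_matrices(
                self.hierarchy, self.interaction.index, sc
            )
        return self._semantic_cache[key]

    def permuted_labels(self, seed: int) -> "AssociationDataset":
        """Same pairs and features, labels randomly permuted (null benchmark)."""
        rng = np.random.default_rng(seed)
        labels = self.pairs.labels[rng.permutation(len(self.pairs))]
        return AssociationDataset(
            interaction=self.interaction,
            hierarchy=self.hierarchy,
            pairs=LabeledPairSet(pairs=list(self.pairs.pairs), labels=labels),
            _semantic_cache=self._semantic_cache,
        )


def dataset_from_bundle(
    bundle: SyntheticBundle, negative_seed: int = 0, n_negatives: int | None = None
) -> AssociationDataset:
    """Balanced labeled pair sample (all positives + sampled negatives)."""
    return AssociationDataset(
        interaction=bundle.interaction,
        hierarchy=bundle.hierarchy,
        pairs=balanced_pair_set(bundle.interaction, seed=negative_seed, n_negatives=n_negatives),
    )


class PairPipeline:
    """Fit the full similarity -> feature -> encoder -> booster stack on one split."""

    def __init__(self, dataset: AssociationDataset, config: RunConfig):
        self.dataset = dataset
        self.config = config
        self.layout = get_layout(config.features.layout)
        self.matrices_: dict[str, SimilarityMatrix] = {}
        self.train_matrix_: InteractionMatrix | None = None
        self.encoder_ = None
        self.booster_ = None

    # -- similarity construction -------------------------------------------------
    def _training_matrix(self, train_pairs: LabeledPairSet) -> InteractionMatrix:
        if self.config.mode == "paper_faithful":
            return self.dataset.interaction
        values = np.zeros_like(self.dataset.interaction.values)
        for (i, j), lab in zip(train_pairs.pairs, train_pairs.labels):
            if lab == 1:
                values[i, j] = 1
        return InteractionMatrix(values=values, index=self.dataset.interaction.index)

    def _build_matrices(self, train_matrix: InteractionMatrix) -> None:
        from lncboost.feature_builder import fuse_similarity

        cfg = self.config
        disss1, disss2 = self.dataset.semantic(cfg)
        disgs = gip_similarity(train_matrix, "diseases", cfg.gip)
        lncgs = gip_similarity(train_matrix, "lncrnas", cfg.gip)
        sets = disease_sets(train_matrix)
        lncrnas = train_matrix.index.lncrnas
        lncfs1 = lncfs_matrix(sets, disss1, lncrnas, kind="LNCFS1")
        lncfs2 = lncfs_matrix(sets, disss2, lncrnas, kind="LNCFS2")
        # within-pipeline LNCFS/DISSS features use the averaged semantic scores
        disss = SimilarityMatrix(
            values=(disss1.values + disss2.values) / 2.0, labels=disss1.labels, kind="DISSS"
        )
        lncfs = SimilarityMatrix(
            values=(lncfs1.values + lncfs2.values) / 2.0, labels=lncfs1.labels, kind="LNCFS"
        )
        diss = fuse_similarity(disss1, disss2, disgs, kind="DISS")
        lncs = fuse_similarity(lncfs1, lncfs2, lncgs, kind="LNCS")
        self.matrices_ = {
            "DISSS1": disss1, "DISSS2": disss2, "DISSS": disss,
            "LNCFS1": lncfs1, "LNCFS2": lncfs2, "LNCFS": lncfs,
            "DISGS": disgs, "LNCGS": lncgs, "DISS": diss, "LNCS": lncs,
        }

    def _features(self, pairs: LabeledPairSet) -> FeatureMatrix:
        m = self.matrices_
        return assemble_pair_features(
            pairs,
            self.layout,
            self.train_matrix_,
            disss=m["DISSS"],
            disgs=m["DISGS"],
            diss=m["DISS"],
            lncfs=m["LNCFS"],
            lncgs=m["LNCGS"],
            lncs=m["LNCS"],
            mask_target=self.config.mask_target,
            interaction_blocks=self.config.features.interaction_blocks,
        )

    # -- training / scoring ------------------------------------------------------
    def fit(self, train_pairs: LabeledPairSet) -> "PairPipeline":
        self.train_matrix_ = self._training_matrix(train_pairs)
        self._build_matrices(self.train_matrix_)
        feats = self._features(train_pairs)
        ae_cfg = self.config.autoencoder
        latent = min(ae_cfg.latent_dim, feats.dim)
        if latent != ae_cfg.latent_dim:
            logger.info("latent_dim clamped to feature dim %d", latent)
        ae_cfg = AeTrainConfig(
            epochs=ae_cfg.epochs, batch_size=ae_cfg.batch_size, latent_dim=latent,
            seed=ae_cfg.seed, step_size=ae_cfg.step_size,
        )
        self.encoder_ = train_autoencoder(feats.rows, ae_cfg)
        Z = encode(self.encoder_, feats.rows)
        self.booster_ = train_gbm(Z, feats.labels, self.config.gbm)
        return self

    def score(self, pairs: LabeledPairSet) -> np.ndarray:
        if self.booster_ is None:
            raise RuntimeError("pipeline not fitted")
        feats = self._features(pairs)
        return predict_score(self.booster_, encode(self.encoder_, feats.rows))


# -- full-run orchestration ------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(
    config: RunConfig,
    outdir: str | Path,
    spec: SyntheticSpec | None = None,
    dataset: AssociationDataset | None = None,
) -> dict:
    """Run simulate -> similarities -> featurize -> reduce -> train -> evaluate,
    writing stage artifacts and a manifest with checksums into ``outdir``.

    Re-running with the same config and inputs reproduces every artifact
    bit-identically (all randomness is seeded).
    """
    from lncboost.evaluation import kfold_eval

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        artifacts[name] = _sha256(path)

    if dataset is None:
        spec = spec or SyntheticSpec()
        bundle = generate_bundle(spec)
        dataset = dataset_from_bundle(bundle, negative_seed=config.sampling.seed,
                                      n_negatives=config.sampling.n_negatives)
        emit("hierarchy.tsv", lambda p: p.write_text(
            "".join(f"{d}\t{c}\n" for d in bundle.hierarchy.records
                    for c in sorted(bundle.hierarchy.records[d]))))
    emit("interaction.tsv", lambda p: write_matrix(dataset.interaction, p))

    pipe = PairPipeline(dataset, config)
    train_matrix = (dataset.interaction if config.mode == "paper_faithful"
                    else pipe._training_matrix(dataset.pairs))
    pipe.train_matrix_ = train_matrix
    pipe._build_matrices(train_matrix)
    for kind in ("DISSS1", "DISSS2", "DISGS", "LNCGS", "LNCFS1", "LNCFS2", "DISS", "LNCS"):
        emit(f"{kind}.tsv", lambda p, k=kind: write_matrix(pipe.matrices_[k], p))

    feats = pipe._features(dataset.pairs)
    emit("features.tsv", lambda p: write_matrix(
        __import__("pandas").DataFrame(feats.rows), p))

    ae_cfg = config.autoencoder
    latent = min(ae_cfg.latent_dim, feats.dim)
    encoder = train_autoencoder(feats.rows, AeTrainConfig(
        epochs=ae_cfg.epochs, batch_size=ae_cfg.batch_size, latent_dim=latent,
        seed=ae_cfg.seed, step_size=ae_cfg.step_size))
    emit("encoder.json", encoder.save)
    Z = encode(encoder, feats.rows)
    booster = train_gbm(Z, feats.labels, config.gbm)
    emit("booster.json", booster.save)

    cv = kfold_eval(dataset, config, k=config.evaluation.k_folds, seed=config.seed)
    report = {"mode": config.mode, "protocol": "kfold",
              "mean": cv.means, "folds": [r.to_dict() for r in cv.fold_reports]}
    emit("report.json", lambda p: p.write_text(json.dumps(report, indent=2)))

    emit("config.yaml", config.to_yaml)
    manifest = {"config": config.to_dict(), "artifacts": artifacts,
                "final_mean_auc": cv.means["auc"]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_ablation(
    config: RunConfig,
    layouts: list[str],
    dataset: AssociationDataset,
    k: int | None = None,
) -> list[dict]:
    """Evaluate each feature layout with shared CV splits; one row per layout."""
    from lncboost.evaluation import kfold_eval
    import dataclasses

    if not layouts:
        raise ValueError("empty layout list")
    rows = []
    for name in layouts:
        cfg = dataclasses.replace(config, features=dataclasses.replace(
            config.features, layout=name))
        cv = kfold_eval(dataset, cfg, k=k or config.evaluation.k_folds, seed=config.seed)
        row = {"layout": name, "blocks": "+".join(get_layout(name).blocks), **cv.means}
        logger.info("ablation %s: auc=%.4f", name, row["auc"])
        rows.append(row)
    return rows
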