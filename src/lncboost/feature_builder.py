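"""Similarity fusion, negative sampling, and per-pair feature assembly.

A pair (disease i, lncRNA j) is represented by concatenating, in fixed
order, a disease-side similarity row (length N_d), a lncRNA-side similarity
row (length N_l), and optionally the pair's two interaction profiles
(disease i over lncRNAs, length N_l; lncRNA j over diseases, length N_d).
Which blocks enter is controlled by a named layout; the 15 presets span the
full (FHN), four-block (THN), three-block (TriHN) and two-block (DHN)
heterogeneous networks of the ablation study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from lncboost.data_io import InteractionMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

BLOCKS = ("DISSS", "LNCFS", "LNCGS", "DISGS", "LNCDIS")


@dataclass(frozen=True)
class FeatureLayout:
    """A named, ordered subset of the five feature blocks."""

    name: str
    blocks: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("layout needs at least one block")
        unknown = set(self.blocks) - set(BLOCKS)
        if unknown:
            raise ValueError(f"unknown blocks: {sorted(unknown)}")


# Repository mapping of the 15 heterogeneous-network presets. FHN is all five
# blocks; THN drops one similarity/interaction source from FHN; TriHN pairs
# the interaction profiles with two similarity sources (or keeps the three
# lncRNA/disease-side similarities); DHN pairs one disease-side with one
# lncRNA-side similarity.
LAYOUT_PRESETS: dict[str, tuple[str, ...]] = {
    "FHN": ("DISSS", "LNCFS", "LNCGS", "DISGS", "LNCDIS"),
    "THN1": ("DISSS", "LNCFS", "LNCGS", "DISGS"),
    "THN2": ("DISSS", "LNCFS", "LNCGS", "LNCDIS"),
    "THN3": ("DISSS", "LNCFS", "DISGS", "LNCDIS"),
    "THN4": ("DISSS", "LNCGS", "DISGS", "LNCDIS"),
    "TriHN1": ("DISSS", "LNCFS", "LNCDIS"),
    "TriHN2": ("LNCGS", "DISGS", "LNCDIS"),
    "TriHN3": ("DISSS", "LNCGS", "LNCDIS"),
    "TriHN4": ("LNCFS", "DISGS", "LNCDIS"),
    "TriHN5": ("DISSS", "LNCFS", "LNCGS"),
    "TriHN6": ("DISSS", "LNCFS", "DISGS"),
    "DHN1": ("DISSS", "LNCFS"),
    "DHN2": ("LNCGS", "DISGS"),
    "DHN3": ("DISSS", "LNCGS"),
    "DHN4": ("LNCFS", "DISGS"),
}


def layout_presets() -> list[FeatureLayout]:
    """The 15 named heterogeneous-network layouts (logged with block lists)."""
    presets = [FeatureLayout(name=n, blocks=b) for n, b in LAYOUT_PRESETS.items()]
    for p in presets:
        logger.info("layout preset %s: %s", p.name, "+".join(p.blocks))
    return presets


def get_layout(name: str) -> FeatureLayout:
    """Look up a preset by name, or parse 'A+B+...' as a custom layout."""
    if name in LAYOUT_PRESETS:
        return FeatureLayout(name=name, blocks=LAYOUT_PRESETS[name])
    blocks = tuple(b.strip() for b in name.split("+") if b.strip())
    return FeatureLayout(name="custom", blocks=blocks)


@dataclass
class LabeledPairSet:
    """(disease index, lncRNA index) pairs with binary labels."""

    pairs: list[tuple[int, int]]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs/labels length mismatch")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("repeated pair in LabeledPairSet")

    def __len__(self) -> int:
        return len(self.pairs)

    def subset(self, idx: np.ndarray) -> "LabeledPairSet":
        return LabeledPairSet(
            pairs=[self.pairs[i] for i in idx], labels=self.labels[np.asarray(idx)]
        )


@dataclass
class FeatureMatrix:
    """Per-pair feature rows plus labels under a named layout."""

    rows: np.ndarray
    labels: np.ndarray
    layout: FeatureLayout
    pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.rows.shape[1]


def fuse_similarity(
    s1: SimilarityMatrix,
    s2: SimilarityMatrix,
    gip: SimilarityMatrix,
    kind: str = "DISS",
    presence: str = "pair",
) -> SimilarityMatrix:
    """Average the two semantic/functional scores where semantic information
    exists, else fall back to the interaction-profile kernel.

    ``presence`` controls what "semantic information present" means:

    * ``'pair'`` (default): both entities carry semantic information (their
      self-similarity is positive, i.e. a non-empty DAG / disease set). A
      genuine semantic similarity of 0 between two mapped entities is kept —
      disjoint ancestor sets are informative, not missing data. Only rows of
      unmapped entities inherit the kernel.
    * ``'entry'``: entrywise max(s1, s2) > 0, the literal value-based test;
      true semantic zeros are then replaced by the kernel value too.
    """
    if s1.values.shape != s2.values.shape or s1.values.shape != gip.values.shape:
        raise ValueError("shape mismatch between similarity matrices")
    semantic = (s1.values + s2.values) / 2.0
    if presence == "pair":
        mapped = (np.diag(s1.values) > 0) | (np.diag(s2.values) > 0)
        present = mapped[:, None] & mapped[None, :]
    elif presence == "entry":
        present = np.maximum(s1.values, s2.values) > 0
    else:
        raise ValueError("presence must be 'pair' or 'entry'")
    values = np.where(present, semantic, gip.values)
    return SimilarityMatrix(values=values, labels=list(s1.labels), kind=kind)


def positive_pairs(matrix: InteractionMatrix) -> list[tuple[int, int]]:
    """All (disease, lncRNA) index pairs with a known association."""
    rows, cols = np.nonzero(matrix.values)
    return list(zip(rows.tolist(), cols.tolist()))


def sample_negative_pairs(
    matrix: InteractionMatrix,
    n: int,
    seed: int = 0,
    exclude: set[tuple[int, int]] | None = None,
) -> LabeledPairSet:
    """Uniform draw of ``n`` zero-entry cells without replacement (seeded).

    ``exclude`` removes additional candidate cells (e.g. a query disease's
    whole row during ranking).
    """
    zero_rows, zero_cols = np.nonzero(matrix.values == 0)
    cells = list(zip(zero_rows.tolist(), zero_cols.tolist()))
    if exclude:
        cells = [c for c in cells if c not in exclude]
    if n > len(cells):
        raise ValueError(f"requested {n} negatives but only {len(cells)} zero cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(cells), size=n, replace=False)
    pairs = [cells[i] for i in sorted(chosen.tolist())]
    return LabeledPairSet(pairs=pairs, labels=np.zeros(n, dtype=np.int8))


def balanced_pair_set(
    matrix: InteractionMatrix, seed: int = 0, n_negatives: int | None = None
) -> LabeledPairSet:
    """All positives plus ``n_negatives`` sampled negatives (1:1 by default)."""
    pos = positive_pairs(matrix)
    n_neg = len(pos) if n_negatives is None else n_negatives
    neg = sample_negative_pairs(matrix, n_neg, seed=seed)
    return LabeledPairSet(
        pairs=pos + neg.pairs,
        labels=np.concatenate([np.ones(len(pos), dtype=np.int8), neg.labels]),
    )


def feature_dim(layout: FeatureLayout, n_diseases: int, n_lncrnas: int,
                interaction_blocks: str = "both") -> int:
    """Feature-vector length implied by a layout on given matrix shapes."""
    dim = 0
    if "DISSS" in layout.blocks or "DISGS" in layout.blocks:
        dim += n_diseases
    if "LNCFS" in layout.blocks or "LNCGS" in layout.blocks:
        dim += n_lncrnas
    if "LNCDIS" in layout.blocks:
        if interaction_blocks in ("both", "disease_row"):
            dim += n_lncrnas
        if interaction_blocks in ("both", "lncrna_col"):
            dim += n_diseases
    return dim


def assemble_pair_features(
    pairs: LabeledPairSet,
    layout: FeatureLayout,
    interaction: InteractionMatrix,
    disss: SimilarityMatrix | None = None,
    disgs: SimilarityMatrix | None = None,
    diss: SimilarityMatrix | None = None,
    lncfs: SimilarityMatrix | None = None,
    lncgs: SimilarityMatrix | None = None,
    lncs: SimilarityMatrix | None = None,
    mask_target: bool = True,
    interaction_blocks: str = "both",
) -> FeatureMatrix:
    """Concatenate the layout's blocks into one feature row per pair.

    Block order is fixed: [disease similarity row, lncRNA similarity row,
    disease interaction profile, lncRNA interaction profile]. When both the
    semantic and kernel matrix of one side are in the layout the fused matrix
    (``diss``/``lncs``) is used; with a single one, that matrix directly.
    ``mask_target`` zeroes the pair's own cell inside the interaction blocks
    so no row encodes its own label.
    """
    want_d_sem, want_d_gip = "DISSS" in layout.blocks, "DISGS" in layout.blocks
    want_l_sem, want_l_gip = "LNCFS" in layout.blocks, "LNCGS" in layout.blocks

    def pick(sem_wanted, gip_wanted, fused, sem, gip, side):
        if sem_wanted and gip_wanted:
            if fused is None:
                raise ValueError(f"layout needs the fused {side} similarity matrix")
            return fused
        if sem_wanted:
            if sem is None:
                raise ValueError(f"layout needs the semantic/functional {side} matrix")
            return sem
        if gip_wanted:
            if gip is None:
                raise ValueError(f"layout needs the {side} interaction-profile kernel")
            return gip
        return None

    d_mat = pick(want_d_sem, want_d_gip, diss, disss, disgs, "disease")
    l_mat = pick(want_l_sem, want_l_gip, lncs, lncfs, lncgs, "lncRNA")

    inter = interaction.values.astype(float)
    blocks_per_pair = []
    for (i, j), _ in zip(pairs.pairs, pairs.labels):
        parts = []
        if d_mat is not None:
            parts.append(d_mat.values[i])
        if l_mat is not None:
            parts.append(l_mat.values[j])
        if "LNCDIS" in layout.blocks:
            if interaction_blocks in ("both", "disease_row"):
                row = inter[i].copy()
                if mask_target:
                    row[j] = 0.0
                parts.append(row)
            if interaction_blocks in ("both", "lncrna_col"):
                col = inter[:, j].copy()
                if mask_target:
                    col[i] = 0.0
                parts.append(col)
        blocks_per_pair.append(np.concatenate(parts))
    rows = np.vstack(blocks_per_pair) if blocks_per_pair else np.zeros(
        (0, feature_dim(layout, interaction.index.n_diseases,
                        interaction.index.n_lncrnas, interaction_blocks))
    )
    if not np.isfinite(rows).all():
        raise ValueError("non-finite feature values")
    return FeatureMatrix(rows=rows, labels=pairs.labels.copy(), layout=layout,
                         pairs=list(pairs.pairs))
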