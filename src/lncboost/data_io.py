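"""Reading/writing association pair lists, hierarchy records and labeled matrices.

All interchange is plain TSV: a pair list is ``lncRNA<TAB>disease``, a
hierarchy file is ``disease<TAB>tree-code`` (dot-delimited tree numbers in the
style of MeSH tree codes), and matrices are written with a header row of
column labels and a first column of row labels, reals at 12 significant
digits.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: printed precision of reals in the TSV interchange format
FLOAT_FORMAT = "%.12g"

_TREE_CODE_RE = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+)*$")


def normalize_identifier(name: str) -> str:
    """Whitespace-normalized, case-folded form used to match disease names."""
    return " ".join(name.split()).casefold()


@dataclass
class AssociationPairList:
    """Ordered, de-duplicated (lncRNA, disease) identifier pairs."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate (lncRNA, disease) pairs")
        for lnc, dis in self.pairs:
            if not lnc or not dis:
                raise ValueError("empty identifier in pair list")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class EntityIndex:
    """Stable positional indexing of the disease and lncRNA identifier sets."""

    diseases: list[str]
    lncrnas: list[str]

    def __post_init__(self) -> None:
        if not self.diseases or not self.lncrnas:
            raise ValueError("EntityIndex requires at least one disease and one lncRNA")
        self._disease_pos = {d: i for i, d in enumerate(self.diseases)}
        self._lncrna_pos = {l: j for j, l in enumerate(self.lncrnas)}
        if len(self._disease_pos) != len(self.diseases) or len(self._lncrna_pos) != len(self.lncrnas):
            raise ValueError("duplicate identifiers in EntityIndex")

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrnas)

    def disease_position(self, disease: str) -> int:
        return self._disease_pos[disease]

    def lncrna_position(self, lncrna: str) -> int:
        return self._lncrna_pos[lncrna]


@dataclass
class InteractionMatrix:
    """Binary disease x lncRNA adjacency (rows: diseases, columns: lncRNAs)."""

    values: np.ndarray
    index: EntityIndex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.index.n_diseases, self.index.n_lncrnas):
            raise ValueError("interaction matrix shape does not match index")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("interaction matrix entries must be 0/1")
        self.values = self.values.astype(np.int8)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.index.diseases, columns=self.index.lncrnas)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over diseases or lncRNAs, entries in [0, 1]."""

    values: np.ndarray
    labels: list[str]
    kind: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class HierarchyRecordSet:
    """Disease -> set of dot-delimited tree codes, plus code -> term names.

    ``term_names`` maps a full tree code to the disease identifier that owns
    it; prefix codes without an owner are referred to by the code string
    itself when DAGs are built.
    """

    records: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_norm = {normalize_identifier(d): d for d in self.records}

    def codes_for(self, disease: str) -> set[str]:
        """Tree codes for a disease, matched case-insensitively; empty set if unmapped."""
        key = self._by_norm.get(normalize_identifier(disease))
        return set(self.records[key]) if key is not None else set()

    def unmapped(self, diseases: Iterable[str]) -> list[str]:
        """Diseases with no hierarchy record (no semantic information)."""
        return [d for d in diseases if not self.codes_for(d)]


def read_association_pairs(path: str | Path, sep: str = "\t") -> AssociationPairList:
    """Read a two-column (lncRNA, disease) pair list; drop duplicates, keep order.

    Raises ``ValueError`` on malformed rows (with line number) and on empty
    files; logs the number of duplicates removed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed pair row: {line!r}")
            pair = (parts[0].strip(), parts[1].strip())
            if pair in seen:
                n_dup += 1
                continue
            seen.add(pair)
            pairs.append(pair)
    if not pairs:
        raise ValueError(f"{path}: no pairs")
    if n_dup:
        logger.info("read_association_pairs: removed %d duplicate pairs", n_dup)
    return AssociationPairList(pairs)


def build_interaction_matrix(
    pairs: AssociationPairList, sort_ids: bool = False
) -> InteractionMatrix:
    """Build the binary disease x lncRNA adjacency from a pair list.

    Entity order is first appearance in the pair list; ``sort_ids`` switches
    to lexicographic. The sum of entries equals the number of distinct pairs.
    """
    if not pairs.pairs:
        raise ValueError("empty pair list")
    lncrnas = list(dict.fromkeys(l for l, _ in pairs.pairs))
    diseases = list(dict.fromkeys(d for _, d in pairs.pairs))
    if sort_ids:
        lncrnas, diseases = sorted(lncrnas), sorted(diseases)
    index = EntityIndex(diseases=diseases, lncrnas=lncrnas)
    values = np.zeros((index.n_diseases, index.n_lncrnas), dtype=np.int8)
    for lnc, dis in pairs.pairs:
        values[index.disease_position(dis), index.lncrna_position(lnc)] = 1
    return InteractionMatrix(values=values, index=index)


def read_hierarchy(path: str | Path, sep: str = "\t") -> HierarchyRecordSet:
    """Read a flat ``disease<TAB>tree-code`` hierarchy file.

    Malformed codes are skipped with a warning; diseases appearing on several
    rows accumulate a code set. A full code names its disease, so shared
    ancestors that are themselves diseases resolve to the same DAG node.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                logger.warning("%s:%d: malformed hierarchy row skipped: %r", path, lineno, line)
                continue
            disease, code = parts[0].strip(), parts[1].strip()
            if not disease or not _TREE_CODE_RE.match(code):
                logger.warning("%s:%d: malformed tree code skipped: %r", path, lineno, code)
                continue
            records.setdefault(disease, set()).add(code)
            term_names[code] = disease
    return HierarchyRecordSet(records=records, term_names=term_names)


def write_matrix(matrix, path: str | Path) -> None:
    """Write a labeled matrix as TSV (12 significant digits for reals)."""
    frame = matrix.to_frame() if hasattr(matrix, "to_frame") else pd.DataFrame(matrix)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled TSV matrix back into a DataFrame; validates the shape."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"{path}: empty or shape-mismatched matrix")
    return frame


def pair_positions(
    pairs: Sequence[tuple[str, str]], index: EntityIndex
) -> list[tuple[int, int]]:
    """Map (lncRNA, disease) identifier pairs to (disease_row, lncrna_col) positions."""
    return [(index.disease_position(d), index.lncrna_position(l)) for l, d in pairs]
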