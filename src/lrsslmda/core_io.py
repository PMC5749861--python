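"""On-disk formats and the shared name <-> index containers.

Every matrix in the pipeline is addressed by entity *names* externally and
by dense 0-based indices internally. All files are UTF-8, tab-delimited;
lines starting with '#' are comments. Entity order is first appearance in
the source file so that ranks are reproducible from a fixed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NameIndex",
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseDAG",
    "ParseError",
    "load_associations",
    "write_associations",
    "load_similarity",
    "write_similarity",
    "load_dags",
    "write_dags",
    "write_scores",
    "load_scores",
]


class ParseError(ValueError):
    """Malformed input file (carries path and line number where known)."""


@dataclass(frozen=True)
class NameIndex:
    """Ordered, unique entity identifiers with their 0-based positions."""

    names: tuple[str, ...]
    position: dict[str, int] = field(compare=False)

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "NameIndex":
        names = tuple(names)
        position = {n: i for i, n in enumerate(names)}
        if len(position) != len(names):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))
            raise ValueError(f"duplicate entity name {dup!r}")
        return cls(names=names, position=position)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.position

    def __getitem__(self, name: str) -> int:
        return self.position[name]


@dataclass
class AssociationMatrix:
    """Binary nm x nd adjacency of known miRNA-disease associations."""

    values: np.ndarray  # (nm, nd) of {0,1}, dtype float64
    mirnas: NameIndex
    diseases: NameIndex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirnas), len(self.diseases)):
            raise ValueError(
                f"association shape {self.values.shape} does not match "
                f"{len(self.mirnas)} miRNAs x {len(self.diseases)} diseases"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association entries must be 0 or 1")

    @property
    def n_pairs(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.values.copy(), self.mirnas, self.diseases)

    def pairs(self) -> list[tuple[int, int]]:
        """Known (miRNA index, disease index) pairs in row-major order."""
        return [tuple(ij) for ij in np.argwhere(self.values == 1.0)]


@dataclass
class SimilarityMatrix:
    """Square similarity in [0,1] with a mask of source-defined entries."""

    values: np.ndarray  # (n, n) float64; undefined cells hold 0.0
    index: NameIndex
    known_mask: np.ndarray  # (n, n) bool

    def __post_init__(self) -> None:
        n = len(self.index)
        self.values = np.asarray(self.values, dtype=float)
        self.known_mask = np.asarray(self.known_mask, dtype=bool)
        if self.values.shape != (n, n) or self.known_mask.shape != (n, n):
            raise ValueError("similarity matrix must be square and match its index")
        defined = self.values[self.known_mask]
        if defined.size and (defined.min() < -1e-9 or defined.max() > 1 + 1e-9):
            raise ValueError("defined similarity entries must lie in [0, 1]")
        if not np.array_equal(self.known_mask, self.known_mask.T):
            raise ValueError("known_mask must be symmetric")
        asym = np.abs(self.values - self.values.T)[self.known_mask]
        if asym.size and asym.max() > 1e-9:
            raise ValueError("similarity values asymmetric on defined entries")

    @classmethod
    def fully_defined(cls, values: np.ndarray, index: NameIndex) -> "SimilarityMatrix":
        values = np.asarray(values, dtype=float)
        return cls(values, index, np.ones_like(values, dtype=bool))

    @property
    def fully_known(self) -> bool:
        return bool(self.known_mask.all())


@dataclass
class DiseaseDAG:
    """A disease's ancestor graph: the disease's own term plus all ancestors.

    ``parent_edges`` holds (child, parent) pairs; the disease's own term is
    the unique sink (it has no child within the DAG).
    """

    disease: str
    nodes: frozenset[str]
    parent_edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for child, parent in self.parent_edges:
            if child not in self.nodes or parent not in self.nodes:
                raise ValueError(
                    f"DAG for {self.disease!r}: edge ({child!r}, {parent!r}) "
                    "references an undeclared node"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        indeg = {n: 0 for n in self.nodes}
        for child, parent in self.parent_edges:
            children[child].append(parent)
            indeg[parent] += 1
        stack = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while stack:
            n = stack.pop()
            seen += 1
            for p in children[n]:
                indeg[p] -= 1
                if indeg[p] == 0:
                    stack.append(p)
        if seen != len(self.nodes):
            raise ValueError(f"cycle detected in DAG for disease {self.disease!r}")


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def load_associations(path: str | Path) -> AssociationMatrix:
    """Read a two-column (miRNA, disease) pair list into a binary matrix.

    Duplicate pairs collapse to a single 1. Name order is first appearance.
    """
    path = Path(path)
    mirna_names: list[str] = []
    disease_names: list[str] = []
    mpos: dict[str, int] = {}
    dpos: dict[str, int] = {}
    pairs: list[tuple[int, int]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        m, d = fields[0].strip(), fields[1].strip()
        if not m or not d:
            raise ParseError(f"{path}:{lineno}: empty entity name")
        if m not in mpos:
            mpos[m] = len(mirna_names)
            mirna_names.append(m)
        if d not in dpos:
            dpos[d] = len(disease_names)
            disease_names.append(d)
        pairs.append((mpos[m], dpos[d]))
    if not pairs:
        raise ParseError(f"{path}: no association pairs found")
    values = np.zeros((len(mirna_names), len(disease_names)))
    for i, j in pairs:
        values[i, j] = 1.0
    assoc = AssociationMatrix(
        values, NameIndex.from_names(mirna_names), NameIndex.from_names(disease_names)
    )
    logger.info(
        "loaded %d associations between %d miRNAs and %d diseases from %s",
        assoc.n_pairs, len(assoc.mirnas), len(assoc.diseases), path,
    )
    return assoc


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write known pairs as two-column TSV; exact inverse of load_associations."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# miRNA\tdisease\n")
        for i, j in assoc.pairs():
            fh.write(f"{assoc.mirnas.names[i]}\t{assoc.diseases.names[j]}\n")


def load_similarity(path: str | Path) -> SimilarityMatrix:
    """Read a labeled (n+1)x(n+1) similarity grid; empty cells are undefined."""
    path = Path(path)
    rows = list(_data_lines(path))
    if not rows:
        raise ParseError(f"{path}: empty similarity file")
    _, header_line = rows[0]
    header = header_line.split("\t")[1:]
    n = len(header)
    if len(rows) - 1 != n:
        raise ParseError(
            f"{path}: non-square grid ({len(rows) - 1} data rows, {n} header columns)"
        )
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    labels: list[str] = []
    for r, (lineno, line) in enumerate(rows[1:]):
        fields = line.split("\t")
        if len(fields) != n + 1:
            raise ParseError(f"{path}:{lineno}: expected {n + 1} fields, got {len(fields)}")
        labels.append(fields[0])
        for c, cell in enumerate(fields[1:]):
            cell = cell.strip()
            if cell == "":
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell {cell!r}") from exc
            values[r, c] = v
            mask[r, c] = True
    if labels != header:
        raise ParseError(f"{path}: row labels do not match header order")
    if (mask != mask.T).any():
        raise ParseError(f"{path}: cells defined in only one of (i,j)/(j,i)")
    return SimilarityMatrix(values, NameIndex.from_names(header), mask)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    path = Path(path)
    names = sim.index.names
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(names) + "\n")
        for i, name in enumerate(names):
            cells = [
                repr(float(sim.values[i, j])) if sim.known_mask[i, j] else ""
                for j in range(len(names))
            ]
            fh.write(name + "\t" + "\t".join(cells) + "\n")


def load_dags(path: str | Path) -> list[DiseaseDAG]:
    """Read per-disease ancestor edge lists.

    Each row is (disease, child_term, parent_term); a parent of '-' declares
    a node without adding an edge (roots and the disease's own term use it).
    """
    path = Path(path)
    nodes: dict[str, set[str]] = {}
    edges: dict[str, set[tuple[str, str]]] = {}
    order: list[str] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        disease, child, parent = (f.strip() for f in fields)
        if disease not in nodes:
            nodes[disease] = set()
            edges[disease] = set()
            order.append(disease)
        # closure under parents: both endpoints become nodes
        nodes[disease].add(child)
        if parent != "-":
            nodes[disease].add(parent)
            edges[disease].add((child, parent))
    if not order:
        raise ParseError(f"{path}: no DAG rows found")
    return [
        DiseaseDAG(d, frozenset(nodes[d]), frozenset(edges[d])) for d in order
    ]


def write_dags(dags: Sequence[DiseaseDAG], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# disease\tchild_term\tparent_term\n")
        for dag in dags:
            parents = {c for c, _ in dag.parent_edges}
            for node in sorted(dag.nodes):
                if node not in parents:
                    fh.write(f"{dag.disease}\t{node}\t-\n")
            for child, parent in sorted(dag.parent_edges):
                fh.write(f"{dag.disease}\t{child}\t{parent}\n")


def write_scores(scores, path: str | Path) -> None:
    """Write predicted scores as (miRNA, disease, score, within-disease rank).

    Rows are grouped by disease and sorted by descending score within each
    disease; scores are written with 17 significant digits so a read-back
    is bit-exact.
    """
    from .predictor import ScoreMatrix  # local import to avoid a cycle

    if not isinstance(scores, ScoreMatrix):
        raise TypeError("write_scores expects a ScoreMatrix")
    if not np.isfinite(scores.values).all():
        raise ValueError("scores contain non-finite values")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# miRNA\tdisease\tscore\trank\n")
        for j, dname in enumerate(scores.diseases.names):
            col = scores.values[:, j]
            order = np.lexsort((np.arange(len(col)), -col))
            for rank, i in enumerate(order, start=1):
                fh.write(
                    f"{scores.mirnas.names[i]}\t{dname}\t{float(col[i])!r}\t{rank}\n"
                )


def load_scores(path: str | Path):
    """Read a score file back into a ScoreMatrix (inverse of write_scores)."""
    from .predictor import ScoreMatrix

    path = Path(path)
    entries: list[tuple[str, str, float]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
        entries.append((fields[0], fields[1], float(fields[2])))
    mirnas: list[str] = []
    diseases: list[str] = []
    for m, d, _ in entries:
        if m not in mirnas:
            mirnas.append(m)
        if d not in diseases:
            diseases.append(d)
    midx = NameIndex.from_names(mirnas)
    didx = NameIndex.from_names(diseases)
    values = np.zeros((len(midx), len(didx)))
    for m, d, s in entries:
        values[midx[m], didx[d]] = s
    return ScoreMatrix(values, midx, didx, provenance="final")
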