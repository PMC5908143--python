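"""Reading and writing the delimited-text formats used by the pipeline.

All inputs are plain text: a two-column miRNA/disease association list, a
square miRNA functional-similarity matrix with a header row and column, a
disease-descriptor file mapping disease names to dot-separated hierarchical
tree codes, and the bundled top-50 evidence tables used by the case-study
checks.  Names are whitespace-trimmed but case is preserved: miRNA precursor
and mature identifiers differ only by case ("hsa-mir-21" vs "hsa-miR-21")
and must not be merged.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssociationTable",
    "AssociationMatrix",
    "DescriptorTable",
    "EvidenceTable",
    "read_associations",
    "build_adjacency",
    "read_similarity_matrix",
    "read_descriptors",
    "read_evidence_table",
    "write_predictions",
]

_TREE_CODE_RE = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+)*$")

#: Case-insensitive token marking an evidence-table row with no database support.
UNCONFIRMED = "unconfirmed"


@dataclass
class AssociationTable:
    """An ordered, de-duplicated list of (miRNA, disease) association pairs."""

    records: list[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for pair in self.records:
            m, d = pair
            if not m or not d:
                raise ValueError(f"empty name in association record {pair!r}")
            if pair in seen:
                raise ValueError(f"duplicate association record {pair!r}")
            seen.add(pair)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def mirnas(self) -> list[str]:
        """miRNA names in order of first appearance."""
        return list(dict.fromkeys(m for m, _ in self.records))

    @property
    def diseases(self) -> list[str]:
        """Disease names in order of first appearance."""
        return list(dict.fromkeys(d for _, d in self.records))

    def write(self, path, delimiter: str = "\t") -> None:
        with open(path, "w") as fh:
            for m, d in self.records:
                fh.write(f"{m}{delimiter}{d}\n")


@dataclass
class AssociationMatrix:
    """Binary adjacency Y (miRNAs x diseases) with name indices.

    ``values[i, j] == 1`` iff miRNA ``mirna_index[i]`` has a recorded
    association with disease ``disease_index[j]``.
    """

    values: np.ndarray
    mirna_index: list[str]
    disease_index: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.mirna_index), len(self.disease_index)):
            raise ValueError("adjacency shape does not match index lengths")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_index)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_index)

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    @property
    def density(self) -> float:
        """Fraction of the miRNA x disease grid that carries a known association."""
        return self.n_associations / (self.n_mirnas * self.n_diseases)

    def mirna_richness(self) -> np.ndarray:
        """Number of known associated diseases per miRNA (row sums)."""
        return self.values.sum(axis=1)

    def disease_richness(self) -> np.ndarray:
        """Number of known associated miRNAs per disease (column sums)."""
        return self.values.sum(axis=0)

    def to_table(self, provenance: str = "") -> AssociationTable:
        rows, cols = np.nonzero(self.values)
        records = [
            (self.mirna_index[i], self.disease_index[j]) for i, j in zip(rows, cols)
        ]
        return AssociationTable(records=records, provenance=provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.mirna_index, columns=self.disease_index
        )


@dataclass
class DescriptorTable:
    """Disease name -> set of hierarchical tree codes (e.g. ``C04.588.180``)."""

    entries: dict[str, set[str]]

    def __post_init__(self) -> None:
        for name, codes in self.entries.items():
            if not codes:
                raise ValueError(f"disease {name!r} has no tree codes")
            for code in codes:
                if not _TREE_CODE_RE.match(code):
                    raise ValueError(f"invalid tree code {code!r} for {name!r}")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.entries:
                fh.write(f"{name}\t{','.join(sorted(self.entries[name]))}\n")


@dataclass
class EvidenceTable:
    """A ranked top-k list of predicted miRNAs with literature-evidence labels.

    ``rows`` are (rank, miRNA name, evidence label) with ranks 1..50 and no
    gaps; a label is a semicolon-joined list of database tags or the literal
    token "Unconfirmed" (matched case-insensitively).
    """

    disease_name: str
    rows: list[tuple[int, str, str]]

    def __post_init__(self) -> None:
        ranks = [r for r, _, _ in self.rows]
        if ranks != list(range(1, 51)):
            raise ValueError(
                f"evidence table for {self.disease_name!r} must have ranks 1..50 "
                f"without gaps (got {len(ranks)} rows)"
            )

    def confirmed_mask(self) -> list[bool]:
        return [label.strip().lower() != UNCONFIRMED for _, _, label in self.rows]

    def n_confirmed(self, top_k: int = 50) -> int:
        """Number of the top ``top_k`` rows carrying database evidence."""
        return sum(self.confirmed_mask()[:top_k])


def _iter_data_lines(path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_associations(path, delimiter: str = "\t") -> AssociationTable:
    """Read a two-column miRNA/disease association list.

    Lines starting with ``#`` are comments.  Duplicate pairs are collapsed,
    names are whitespace-trimmed and case is preserved.
    """
    records: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_lines = 0
    for lineno, line in _iter_data_lines(path):
        n_lines += 1
        fields = line.split(delimiter)
        if len(fields) < 2:
            raise ValueError(
                f"{path}:{lineno}: expected at least 2 fields separated by "
                f"{delimiter!r}, got {len(fields)}"
            )
        mirna, disease = fields[0].strip(), fields[1].strip()
        if not mirna or not disease:
            raise ValueError(f"{path}:{lineno}: empty miRNA or disease name")
        pair = (mirna, disease)
        if pair not in seen:
            seen.add(pair)
            records.append(pair)
    if n_lines == 0:
        raise ValueError(f"{path}: no association records found")
    return AssociationTable(records=records, provenance=str(path))


def build_adjacency(
    table: AssociationTable,
    mirna_order: Sequence[str] | None = None,
    disease_order: Sequence[str] | None = None,
) -> AssociationMatrix:
    """Assemble the binary adjacency Y from an association table.

    Row/column order defaults to first appearance in the table; explicit
    orders may add names absent from the table (all-zero rows/columns) but
    must cover every name that is present.
    """
    mirnas = list(mirna_order) if mirna_order is not None else table.mirnas
    diseases = list(disease_order) if disease_order is not None else table.diseases
    m_pos = {name: i for i, name in enumerate(mirnas)}
    d_pos = {name: j for j, name in enumerate(diseases)}
    missing_m = sorted({m for m, _ in table.records} - m_pos.keys())
    missing_d = sorted({d for _, d in table.records} - d_pos.keys())
    if missing_m or missing_d:
        raise ValueError(
            "supplied orders do not cover all names in the table; "
            f"missing miRNAs: {missing_m}; missing diseases: {missing_d}"
        )
    values = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for m, d in table.records:
        values[m_pos[m], d_pos[d]] = 1
    return AssociationMatrix(values, mirnas, diseases)


def read_similarity_matrix(path, delimiter: str = "\t"):
    """Read a square similarity matrix with matching header row and column.

    The result is symmetrized by averaging with its transpose (warning if the
    asymmetry exceeds 1e-8) and the diagonal is forced to 1 (warning if it was
    not).  Values outside [0, 1] beyond a 1e-9 tolerance are an error.
    """
    from .similarity import SimilarityMatrix

    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity matrix is not square {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: header row and column names do not match")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in similarity matrix") from exc
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite value in similarity matrix")
    if values.min() < -1e-9 or values.max() > 1 + 1e-9:
        raise ValueError(
            f"{path}: similarity values outside [0, 1] "
            f"(min {values.min():.3g}, max {values.max():.3g})"
        )
    values = np.clip(values, 0.0, 1.0)
    asym = np.abs(values - values.T).max()
    if asym > 1e-8:
        warnings.warn(
            f"{path}: similarity matrix asymmetric (max |S - S.T| = {asym:.3g}); "
            "symmetrized by averaging",
            stacklevel=2,
        )
    values = (values + values.T) / 2.0
    if np.abs(np.diag(values) - 1.0).max() > 1e-9:
        warnings.warn(f"{path}: diagonal forced to 1", stacklevel=2)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        values=values, index=[str(n) for n in df.index], space="unknown", source="file"
    )


def read_descriptors(path) -> DescriptorTable:
    """Read a disease-descriptor file: ``name<TAB>code[,code...]`` per line."""
    entries: dict[str, set[str]] = {}
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'name<TAB>codes'")
        name = fields[0].strip()
        codes = {c.strip() for c in fields[1].split(",") if c.strip()}
        if not name or not codes:
            raise ValueError(f"{path}:{lineno}: empty disease name or code list")
        for code in codes:
            if not _TREE_CODE_RE.match(code):
                raise ValueError(f"{path}:{lineno}: invalid tree code {code!r}")
        entries.setdefault(name, set()).update(codes)
    if not entries:
        raise ValueError(f"{path}: no descriptor records found")
    return DescriptorTable(entries=entries)


def read_evidence_table(path, disease_name: str | None = None) -> EvidenceTable:
    """Read a bundled top-50 evidence table (rank, miRNA, evidence columns)."""
    rows: list[tuple[int, str, str]] = []
    name = disease_name
    for lineno, line in _iter_data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if fields[0].lower() == "rank":  # header
            continue
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 'rank<TAB>miRNA<TAB>evidence'")
        try:
            rank = int(fields[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad rank {fields[0]!r}") from exc
        rows.append((rank, fields[1], fields[2]))
    rows.sort(key=lambda r: r[0])
    if len(rows) != 50:
        raise ValueError(f"{path}: expected 50 evidence rows, found {len(rows)}")
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return EvidenceTable(disease_name=name, rows=rows)


def write_predictions(scores, path, top_k: int) -> None:
    """Write the top-``top_k`` miRNAs per disease, ranked by final score.

    Output columns: disease, rank, miRNA, score.  Ties are broken
    alphabetically by miRNA name so output files are reproducible.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    final = scores.to_frame()
    with open(path, "w") as fh:
        fh.write("disease\trank\tmirna\tscore\n")
        for disease in final.columns:
            col = final[disease]
            order = sorted(col.index, key=lambda m: (-col[m], m))
            for rank, mirna in enumerate(order[:top_k], start=1):
                fh.write(f"{disease}\t{rank}\t{mirna}\t{col[mirna]:.10g}\n")


def read_predictions(path) -> pd.DataFrame:
    """Read a predictions file written by :func:`write_predictions`."""
    df = pd.read_csv(path, sep="\t")
    expected = {"disease", "rank", "mirna", "score"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {expected - set(df.columns)}")
    return df
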