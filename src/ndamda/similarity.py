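"""Similarity layers: disease semantic models, Gaussian profile kernels, integration.

Two semantic-similarity models operate on per-disease ancestor DAGs built by
prefix truncation of hierarchical descriptor tree codes.  Model 1 assigns
each ancestor a contribution that decays geometrically (factor ``delta``)
with distance from the disease term; model 2 weights each term by its
information content, -log of the fraction of disease DAGs that contain it.
A Gaussian kernel over binary interaction profiles (rows or columns of the
association matrix Y) supplies similarity for pairs lacking curated scores,
and the integration step stitches the two sources into a single matrix per
space (miRNA or disease).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import AssociationMatrix, DescriptorTable

__all__ = [
    "DiseaseDAG",
    "SemanticContributionMap",
    "SimilarityMatrix",
    "build_dags",
    "semantic_contribution_model1",
    "semantic_similarity_model1",
    "semantic_contribution_model2",
    "semantic_similarity_model2",
    "gaussian_kernel",
    "integrate_similarity",
]


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over a named index.

    ``space`` records whether the index holds miRNA or disease names, and
    ``source`` which layer produced the values (FS, SS1, SS2, KS, integrated).
    """

    values: np.ndarray
    index: list[str]
    space: str = "unknown"
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match index length")

    @property
    def n(self) -> int:
        return len(self.index)

    def loc(self, a: str, b: str) -> float:
        ia, ib = self.index.index(a), self.index.index(b)
        return float(self.values[ia, ib])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.index, columns=self.index)

    def write(self, path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, float_format="%.10g")


@dataclass
class DiseaseDAG:
    """Ancestor DAG of one disease: the disease's own tree codes plus every
    prefix-truncated ancestor code, with parent->child edges.

    A term reached through several codes appears once (node identity is the
    code string), so the structure is a DAG rather than a tree.  ``terminal``
    holds the disease's own (deepest) codes, which receive contribution 1 in
    the decayed model.
    """

    root_disease: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]  # (parent, child)
    terminal: frozenset[str]

    def children_of(self, node: str) -> set[str]:
        return {c for p, c in self.edges if p == node}

    def layer(self, node: str) -> int:
        """Minimum number of child-ward steps from a terminal code up to ``node``."""
        depth = {t: 0 for t in self.terminal}
        frontier = set(self.terminal)
        d = 0
        while frontier:
            if node in frontier:
                return d
            d += 1
            frontier = {
                p for p, c in self.edges if c in frontier and p not in depth
            }
            for p in frontier:
                depth[p] = d
        raise KeyError(f"{node!r} not reachable from terminal codes")


@dataclass
class SemanticContributionMap:
    """Per-node semantic contributions D(t) (model 1) or D*(t) (model 2)."""

    dag: DiseaseDAG
    contributions: dict[str, float]
    model: Literal[1, 2]
    delta: float | None = None

    @property
    def semantic_value(self) -> float:
        """DV: the sum of contributions over the DAG's node set."""
        return float(sum(self.contributions[t] for t in self.dag.nodes))


def _ancestors_of_code(code: str) -> list[str]:
    parts = code.split(".")
    return [".".join(parts[:k]) for k in range(1, len(parts))]


def build_dags(descriptors: DescriptorTable) -> dict[str, DiseaseDAG]:
    """Build each disease's ancestor DAG by prefix truncation of its tree codes.

    Every dot-separated prefix of a code is an ancestor node; edges run from
    each prefix (parent) to its one-segment extension (child).  Codes sharing
    a prefix contribute that prefix once.
    """
    dags: dict[str, DiseaseDAG] = {}
    for disease, codes in descriptors.entries.items():
        nodes: set[str] = set()
        edges: set[tuple[str, str]] = set()
        for code in codes:
            chain = _ancestors_of_code(code) + [code]
            nodes.update(chain)
            for parent, child in zip(chain, chain[1:]):
                edges.add((parent, child))
        dags[disease] = DiseaseDAG(
            root_disease=disease,
            nodes=frozenset(nodes),
            edges=frozenset(edges),
            terminal=frozenset(codes),
        )
    return dags


def semantic_contribution_model1(dag: DiseaseDAG, delta: float = 0.5) -> SemanticContributionMap:
    """Decayed contributions: D(t)=1 on the disease's own codes, and for an
    ancestor the maximum over its children in the DAG of ``delta`` times the
    child's contribution (so multiple paths resolve to the shortest one).
    """
    if not (0 < delta <= 1):
        raise ValueError("delta must be in (0, 1]")
    contributions: dict[str, float] = {t: 1.0 for t in dag.terminal}
    # process ancestors from deepest code upward; deeper codes have more segments
    pending = sorted(
        (n for n in dag.nodes if n not in contributions),
        key=lambda n: -n.count("."),
    )
    for node in pending:
        children = dag.children_of(node)
        contributions[node] = max(delta * contributions[c] for c in children)
    return SemanticContributionMap(dag=dag, contributions=contributions, model=1, delta=delta)


def semantic_similarity_model1(
    dags: Mapping[str, DiseaseDAG], delta: float = 0.5
) -> SimilarityMatrix:
    """Pairwise semantic similarity from shared ancestors with decayed weights.

    SS1(i, j) sums, over terms in both DAGs, each disease's contribution to
    the term, normalized by the two semantic values DV(i) + DV(j).
    """
    if not dags:
        raise ValueError("no disease DAGs supplied")
    names = list(dags)
    maps = {d: semantic_contribution_model1(dags[d], delta) for d in names}
    dv = {d: maps[d].semantic_value for d in names}
    n = len(names)
    values = np.eye(n)
    for i in range(n):
        ci = maps[names[i]].contributions
        ti = dags[names[i]].nodes
        for j in range(i + 1, n):
            cj = maps[names[j]].contributions
            shared = ti & dags[names[j]].nodes
            if shared:
                num = sum(ci[t] + cj[t] for t in shared)
                values[i, j] = values[j, i] = num / (dv[names[i]] + dv[names[j]])
    return SimilarityMatrix(values=values, index=names, space="disease", source="SS1")


def semantic_contribution_model2(
    dags: Mapping[str, DiseaseDAG], log_base: float | None = None
) -> dict[str, SemanticContributionMap]:
    """Information-content contributions D*(t) = -log(c(t)/N).

    c(t) counts the disease DAGs whose node set contains term t and N is the
    number of diseases; a term present in every DAG contributes nothing.
    Natural log by default.
    """
    if not dags:
        raise ValueError("no disease DAGs supplied")
    n_diseases = len(dags)
    counts: dict[str, int] = {}
    for dag in dags.values():
        for t in dag.nodes:
            counts[t] = counts.get(t, 0) + 1
    log = math.log if log_base is None else (lambda x: math.log(x, log_base))
    star = {t: -log(c / n_diseases) for t, c in counts.items()}
    return {
        d: SemanticContributionMap(
            dag=dag, contributions={t: star[t] for t in dag.nodes}, model=2
        )
        for d, dag in dags.items()
    }


def semantic_similarity_model2(
    dags: Mapping[str, DiseaseDAG], log_base: float | None = None
) -> SimilarityMatrix:
    """Pairwise semantic similarity with information-content term weights.

    Mirrors model 1 but D*(t) is shared across DAGs.  A disease whose every
    term is ubiquitous has DV=0; it keeps unit self-similarity and scores 0
    against everything else.
    """
    if not dags:
        raise ValueError("no disease DAGs supplied")
    names = list(dags)
    maps = semantic_contribution_model2(dags, log_base=log_base)
    dv = {d: maps[d].semantic_value for d in names}
    n = len(names)
    values = np.eye(n)
    for i in range(n):
        ti = dags[names[i]].nodes
        ci = maps[names[i]].contributions
        for j in range(i + 1, n):
            denom = dv[names[i]] + dv[names[j]]
            if denom <= 0:
                continue
            shared = ti & dags[names[j]].nodes
            if shared:
                cj = maps[names[j]].contributions
                num = sum(ci[t] + cj[t] for t in shared)
                values[i, j] = values[j, i] = num / denom
    return SimilarityMatrix(values=values, index=names, space="disease", source="SS2")


def gaussian_kernel(
    profiles: AssociationMatrix,
    axis: Literal["disease", "miRNA", "mirna"],
    gamma_prime: float = 1.0,
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over rows or columns of Y.

    KS(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2) with the bandwidth gamma set
    to ``gamma_prime`` divided by the mean squared profile norm, so the scale
    adapts to the density of the association network.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    if axis == "disease":
        ip = profiles.values.T.astype(float)  # columns of Y
        index = list(profiles.disease_index)
        space = "disease"
    elif axis in ("miRNA", "mirna"):
        ip = profiles.values.astype(float)  # rows of Y
        index = list(profiles.mirna_index)
        space = "miRNA"
    else:
        raise ValueError(f"unknown axis {axis!r}")
    mean_sq_norm = float((ip * ip).sum()) / ip.shape[0]
    if mean_sq_norm == 0:
        raise ValueError("all interaction profiles are zero; kernel bandwidth undefined")
    gamma = gamma_prime / mean_sq_norm
    sq = squareform(pdist(ip, metric="sqeuclidean")) if ip.shape[0] > 1 else np.zeros((1, 1))
    values = np.exp(-gamma * sq)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values=values, index=index, space=space, source="KS")


def integrate_similarity(
    primary: SimilarityMatrix,
    kernel: SimilarityMatrix,
    has_primary: np.ndarray,
) -> SimilarityMatrix:
    """Combine curated similarity with the kernel fallback.

    Where ``has_primary[i, j]`` is true the curated value is used (functional
    similarity for miRNAs, the SS1/SS2 average for diseases); elsewhere the
    Gaussian kernel value fills in.  A curated value of zero still counts as
    present.
    """
    if primary.index != kernel.index:
        raise ValueError("primary and kernel similarity indices do not match")
    has_primary = np.asarray(has_primary, dtype=bool)
    if has_primary.shape != primary.values.shape:
        raise ValueError("has_primary mask shape does not match similarity matrices")
    values = np.where(has_primary, primary.values, kernel.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        values=values, index=list(primary.index), space=primary.space, source="integrated"
    )


def average_similarity(a: SimilarityMatrix, b: SimilarityMatrix) -> SimilarityMatrix:
    """Elementwise mean of two similarity layers on the same index."""
    if a.index != b.index:
        raise ValueError("similarity indices do not match")
    return SimilarityMatrix(
        values=(a.values + b.values) / 2.0,
        index=list(a.index),
        space=a.space,
        source=f"mean({a.source},{b.source})",
    )
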