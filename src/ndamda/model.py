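"""The network-distance association model and its fitted results.

:class:`NDAMDA` bundles the three data layers (binary association matrix Y,
curated miRNA functional similarity, disease descriptor DAGs) with the
method's tunable parameters, in the style of a statsmodels model object.
``fit()`` runs the full pipeline -- Gaussian profile kernels, semantic
similarity, integration, adjusted network distances, confidence scoring and
precision conversion -- and returns an :class:`NDAMDAResults` carrying the
score matrix, the intermediate layers, ranked prediction accessors and a
``summary()`` table.  Cross-validation lives in :mod:`ndamda.evaluation`
and operates on the model object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import core, similarity as sim
from .io import (
    AssociationMatrix,
    AssociationTable,
    DescriptorTable,
    build_adjacency,
    read_associations,
    read_descriptors,
    read_similarity_matrix,
    write_predictions,
)
from .similarity import DiseaseDAG, SimilarityMatrix

__all__ = ["NDAMDA", "NDAMDAResults"]

logger = logging.getLogger(__name__)


class NDAMDA:
    """Network-distance model for ranking candidate miRNA-disease pairs.

    Parameters
    ----------
    associations
        Binary adjacency (miRNAs x diseases) or an association table; the
        table's first-appearance order fixes the indices.
    functional_similarity
        Curated miRNA functional-similarity matrix.  Pairs whose both names
        appear in it use the curated value; all other miRNA pairs fall back
        to the Gaussian profile kernel.  ``None`` uses the kernel throughout.
    descriptors
        Disease descriptor table (or prebuilt DAG mapping).  Disease pairs
        with descriptors on both sides use the average of the two semantic
        models; others fall back to the kernel.
    delta
        Semantic-contribution decay factor of model 1, in (0, 1].
    gamma_prime_m, gamma_prime_d
        Original adjustment coefficients of the two Gaussian kernels.
    epsilon
        Floor applied to similarities before inversion into distances.
    log_base
        Base of the information-content log in semantic model 2 (natural
        log when ``None``).
    include_self_distance
        Whether a node's self-distance enters its mean raw distance sigma.
    standard_precision
        Use conventional precision-at-H instead of the R/H rank conversion
        (sensitivity analysis only).
    """

    def __init__(
        self,
        associations: AssociationMatrix | AssociationTable,
        functional_similarity: SimilarityMatrix | None = None,
        descriptors: DescriptorTable | Mapping[str, DiseaseDAG] | None = None,
        *,
        delta: float = 0.5,
        gamma_prime_m: float = 1.0,
        gamma_prime_d: float = 1.0,
        epsilon: float = core.DEFAULT_EPSILON,
        log_base: float | None = None,
        include_self_distance: bool = True,
        standard_precision: bool = False,
    ) -> None:
        if isinstance(associations, AssociationTable):
            associations = build_adjacency(associations)
        self.adjacency = associations
        self.functional_similarity = functional_similarity
        if isinstance(descriptors, DescriptorTable):
            self.dags: dict[str, DiseaseDAG] | None = sim.build_dags(descriptors)
        else:
            self.dags = dict(descriptors) if descriptors is not None else None
        if not (0 < delta <= 1):
            raise ValueError("delta must be in (0, 1]")
        if gamma_prime_m <= 0 or gamma_prime_d <= 0:
            raise ValueError("gamma_prime coefficients must be positive")
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        self.delta = delta
        self.gamma_prime_m = gamma_prime_m
        self.gamma_prime_d = gamma_prime_d
        self.epsilon = epsilon
        self.log_base = log_base
        self.include_self_distance = include_self_distance
        self.standard_precision = standard_precision
        self._primary_cache: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_files(
        cls,
        associations_path,
        fs_path=None,
        descriptors_path=None,
        delimiter: str = "\t",
        **params,
    ) -> "NDAMDA":
        """Build the model from the delimited-text input files."""
        table = read_associations(associations_path, delimiter=delimiter)
        fs = read_similarity_matrix(fs_path, delimiter=delimiter) if fs_path else None
        desc = read_descriptors(descriptors_path) if descriptors_path else None
        return cls(table, fs, desc, **params)

    def params(self) -> dict:
        """The model's tunable parameters as a plain dict (for config echoes)."""
        return {
            "delta": self.delta,
            "gamma_prime_m": self.gamma_prime_m,
            "gamma_prime_d": self.gamma_prime_d,
            "epsilon": self.epsilon,
            "log_base": self.log_base,
            "include_self_distance": self.include_self_distance,
            "standard_precision": self.standard_precision,
        }

    # ------------------------------------------------------------------ #
    # pipeline pieces (reused by evaluation with masked copies of Y)

    def _primaries(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Curated-layer values and presence masks aligned to Y's indices.

        These do not depend on Y, so they are computed once and reused
        across cross-validation folds.
        """
        if self._primary_cache is not None:
            return self._primary_cache
        Y = self.adjacency
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}

        n_m = Y.n_mirnas
        fs_vals = np.zeros((n_m, n_m))
        fs_has = np.zeros((n_m, n_m), dtype=bool)
        if self.functional_similarity is not None:
            fs = self.functional_similarity
            pos = {name: k for k, name in enumerate(fs.index)}
            present = np.array([m in pos for m in Y.mirna_index])
            idx = np.array([pos.get(m, 0) for m in Y.mirna_index])
            fs_has = present[:, None] & present[None, :]
            fs_vals[np.ix_(present, present)] = fs.values[
                np.ix_(idx[present], idx[present])
            ]
        out["miRNA"] = (fs_vals, fs_has)

        n_d = Y.n_diseases
        sem_vals = np.zeros((n_d, n_d))
        sem_has = np.zeros((n_d, n_d), dtype=bool)
        if self.dags:
            ss1 = sim.semantic_similarity_model1(self.dags, delta=self.delta)
            ss2 = sim.semantic_similarity_model2(self.dags, log_base=self.log_base)
            avg = sim.average_similarity(ss1, ss2)
            pos = {name: k for k, name in enumerate(avg.index)}
            present = np.array([d in pos for d in Y.disease_index])
            idx = np.array([pos.get(d, 0) for d in Y.disease_index])
            sem_has = present[:, None] & present[None, :]
            sem_vals[np.ix_(present, present)] = avg.values[
                np.ix_(idx[present], idx[present])
            ]
            self._ss1, self._ss2 = ss1, ss2
        out["disease"] = (sem_vals, sem_has)
        self._primary_cache = out
        return out

    def _integrated_similarities(
        self, Y: AssociationMatrix
    ) -> tuple[SimilarityMatrix, SimilarityMatrix, SimilarityMatrix, SimilarityMatrix]:
        """(S_m, S_d, KS_m, KS_d) for a (possibly masked) adjacency."""
        primaries = self._primaries()
        ks_m = sim.gaussian_kernel(Y, "miRNA", self.gamma_prime_m)
        ks_d = sim.gaussian_kernel(Y, "disease", self.gamma_prime_d)
        fs_vals, fs_has = primaries["miRNA"]
        sem_vals, sem_has = primaries["disease"]
        s_m = sim.integrate_similarity(
            SimilarityMatrix(fs_vals, list(Y.mirna_index), "miRNA", "FS"), ks_m, fs_has
        )
        s_d = sim.integrate_similarity(
            SimilarityMatrix(sem_vals, list(Y.disease_index), "disease", "SS"),
            ks_d,
            sem_has,
        )
        return s_m, s_d, ks_m, ks_d

    def _distances_for(
        self, Y: AssociationMatrix
    ) -> tuple[core.AdjustedDistanceMatrix, core.AdjustedDistanceMatrix]:
        s_m, s_d, _, _ = self._integrated_similarities(Y)
        dist_m = core.compute_distances(s_m, self.epsilon, self.include_self_distance)
        dist_d = core.compute_distances(s_d, self.epsilon, self.include_self_distance)
        return dist_m, dist_d

    def _masked(self, pairs) -> AssociationMatrix:
        """Copy of Y with the given (row, col) pairs zeroed."""
        values = self.adjacency.values.copy()
        for i, j in pairs:
            values[i, j] = 0
        return AssociationMatrix(
            values, list(self.adjacency.mirna_index), list(self.adjacency.disease_index)
        )

    # ------------------------------------------------------------------ #

    def fit(self) -> "NDAMDAResults":
        """Run the full scoring pipeline on the supplied data."""
        Y = self.adjacency
        s_m, s_d, ks_m, ks_d = self._integrated_similarities(Y)
        dist_m = core.compute_distances(s_m, self.epsilon, self.include_self_distance)
        dist_d = core.compute_distances(s_d, self.epsilon, self.include_self_distance)
        scores = core.score_all(dist_m, dist_d, Y, self.standard_precision)
        return NDAMDAResults(
            model=self,
            scores=scores,
            dist_m=dist_m,
            dist_d=dist_d,
            similarities={"S_m": s_m, "S_d": s_d, "KS_m": ks_m, "KS_d": ks_d},
        )


@dataclass
class NDAMDAResults:
    """Fitted scores and intermediates, with ranked-prediction accessors."""

    model: NDAMDA
    scores: core.ScoreMatrix
    dist_m: core.AdjustedDistanceMatrix
    dist_d: core.AdjustedDistanceMatrix
    similarities: dict[str, SimilarityMatrix] = field(default_factory=dict)

    @property
    def final(self) -> pd.DataFrame:
        """Final pair scores (miRNAs x diseases)."""
        return self.scores.to_frame()

    def top_predictions(
        self, disease: str, k: int = 50, exclude_known: bool = True
    ) -> pd.DataFrame:
        """Top-k candidate miRNAs for a disease by descending final score.

        Known associated miRNAs are excluded by default (they are training
        positives, not candidates).  Ties break alphabetically.
        """
        Y = self.model.adjacency
        j = Y.disease_index.index(disease)
        col = self.final[disease]
        if exclude_known:
            known = {Y.mirna_index[i] for i in np.nonzero(Y.values[:, j])[0]}
            col = col.drop(index=list(known))
        order = sorted(col.index, key=lambda m: (-col[m], m))[:k]
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(order) + 1),
                "mirna": order,
                "score": [col[m] for m in order],
            }
        )

    def predict_new_disease(
        self, disease: str, kernel_mode: str = "refit"
    ) -> pd.Series:
        """Rank all miRNAs for a disease treated as having no known partners.

        The disease's column of Y is zeroed; with ``kernel_mode="refit"``
        (default) the Gaussian kernels and distances are recomputed from the
        masked network, avoiding information leakage from the removed
        associations; ``"frozen"`` reuses the fitted distances.
        """
        Y = self.model.adjacency
        j = Y.disease_index.index(disease)
        pairs = [(int(i), j) for i in np.nonzero(Y.values[:, j])[0]]
        y_masked = self.model._masked(pairs)
        if kernel_mode == "refit":
            dist_m, dist_d = self.model._distances_for(y_masked)
        elif kernel_mode == "frozen":
            dist_m, dist_d = self.dist_m, self.dist_d
        else:
            raise ValueError(f"unknown kernel_mode {kernel_mode!r}")
        return core.predict_new_disease(
            dist_m, dist_d, y_masked, disease, self.model.standard_precision
        )

    def write_predictions(self, path, top_k: int = 50) -> None:
        write_predictions(self.scores, path, top_k)

    def summary(self) -> str:
        """Plain-text summary of the data, parameters and score layers."""
        Y = self.model.adjacency
        p = self.model.params()
        lines = [
            "Network-distance association model (NDAMDA)",
            "=" * 44,
            f"miRNAs:            {Y.n_mirnas}",
            f"diseases:          {Y.n_diseases}",
            f"known associations:{Y.n_associations:>6}  "
            f"(density {100 * Y.density:.2f}%)",
            f"delta:             {p['delta']}",
            f"gamma' (miRNA):    {p['gamma_prime_m']}",
            f"gamma' (disease):  {p['gamma_prime_d']}",
            f"epsilon:           {p['epsilon']}",
            f"precision rule:    {'standard' if p['standard_precision'] else 'R/H'}",
            "-" * 44,
            f"final score: min {np.nanmin(self.scores.final):.4f}  "
            f"median {np.nanmedian(self.scores.final):.4f}  "
            f"max {np.nanmax(self.scores.final):.4f}",
        ]
        return "\n".join(lines)

    def plot_score_heatmap(self, ax=None):
        """Heatmap of final scores (diseases on x, miRNAs on y)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(self.scores.final, aspect="auto", cmap="viridis")
        ax.set_xlabel("disease index")
        ax.set_ylabel("miRNA index")
        ax.figure.colorbar(im, ax=ax, label="final score")
        return ax
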