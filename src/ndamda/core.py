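"""Adjusted network distances, confidences and precision-converted scores.

The scoring pipeline: similarities become raw network distances D = 1/S;
each node's mean raw distance sigma normalizes D into an adjusted distance
D_adj = D / (sigma_i * sigma_j); for a fixed disease (or miRNA) a
candidate's confidence is its mean adjusted distance to the whole network
minus its mean adjusted distance to the context's known partners; and a
rank-based conversion (precision = R/H, richness over at-or-above-rank
count) makes confidences comparable across contexts of different richness.
The final score of a pair averages its two one-sided precisions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .io import AssociationMatrix
from .similarity import SimilarityMatrix

__all__ = [
    "AdjustedDistanceMatrix",
    "ConfidenceVector",
    "ScoreMatrix",
    "compute_distances",
    "confidence_mirnas",
    "confidence_diseases",
    "precision_convert",
    "score_all",
    "predict_new_disease",
]

logger = logging.getLogger(__name__)

#: Floor applied to similarities before inversion; Gaussian kernels can
#: underflow to exactly zero.
DEFAULT_EPSILON = 1e-12


@dataclass
class AdjustedDistanceMatrix:
    """Raw (1/S) and mean-normalized network distances with the sigma factors."""

    raw: np.ndarray
    sigma: np.ndarray
    adjusted: np.ndarray
    index: list[str]
    space: str = "unknown"

    @property
    def n(self) -> int:
        return len(self.index)


@dataclass
class ConfidenceVector:
    """Per-candidate confidences for one fixed context (disease or miRNA)."""

    context: str
    values: np.ndarray
    richness: int
    index: list[str]


@dataclass
class ScoreMatrix:
    """Final pair scores plus the two one-sided precision layers.

    ``precision_m[i, j]`` converts the miRNA-side confidence of miRNA i given
    disease j; ``precision_d[i, j]`` the disease-side confidence of disease j
    given miRNA i; ``final`` is their elementwise mean, falling back to the
    defined side alone where one context has no known partners.
    """

    precision_m: np.ndarray
    precision_d: np.ndarray
    final: np.ndarray
    mirna_index: list[str]
    disease_index: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.final, index=self.mirna_index, columns=self.disease_index
        )


def compute_distances(
    S: SimilarityMatrix,
    epsilon: float = DEFAULT_EPSILON,
    include_self: bool = True,
) -> AdjustedDistanceMatrix:
    """Invert similarities into distances and normalize by mean node distance.

    ``sigma_i`` is the mean of row i of the raw distance matrix, including
    the self-distance by default (``include_self=False`` excludes it).  The
    adjusted distance is invariant under uniform rescaling of S because the
    sigma product cancels the scale.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    values = np.asarray(S.values, dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("similarity matrix must be square")
    raw = 1.0 / np.maximum(values, epsilon)
    n = raw.shape[0]
    if include_self or n == 1:
        sigma = raw.mean(axis=1)
    else:
        sigma = (raw.sum(axis=1) - np.diag(raw)) / (n - 1)
    adjusted = raw / np.outer(sigma, sigma)
    return AdjustedDistanceMatrix(
        raw=raw, sigma=sigma, adjusted=adjusted, index=list(S.index), space=S.space
    )


def _confidence(adjusted: np.ndarray, known: np.ndarray) -> np.ndarray:
    """Mean adjusted distance to everyone minus mean to the known partners."""
    r = int(known.sum())
    if r < 1:
        raise ValueError("context has no known partners (richness R = 0)")
    return adjusted.mean(axis=1) - adjusted[:, known.astype(bool)].mean(axis=1)


def confidence_mirnas(
    dist_m: AdjustedDistanceMatrix, Y: AssociationMatrix, disease: str
) -> ConfidenceVector:
    """Confidence of every miRNA for one disease.

    Larger values mean the miRNA sits closer (in adjusted network distance)
    to the disease's known miRNAs than to the network at large.
    """
    j = Y.disease_index.index(disease)
    known = Y.values[:, j]
    values = _confidence(dist_m.adjusted, known)
    return ConfidenceVector(
        context=disease, values=values, richness=int(known.sum()), index=list(dist_m.index)
    )


def confidence_diseases(
    dist_d: AdjustedDistanceMatrix, Y: AssociationMatrix, mirna: str
) -> ConfidenceVector:
    """Confidence of every disease for one miRNA (mirror of the miRNA side)."""
    i = Y.mirna_index.index(mirna)
    known = Y.values[i, :]
    values = _confidence(dist_d.adjusted, known)
    return ConfidenceVector(
        context=mirna, values=values, richness=int(known.sum()), index=list(dist_d.index)
    )


def _rank_at_or_above(values: np.ndarray) -> np.ndarray:
    """H per entry: how many entries have a value >= this one (ties share the
    rank of the last tied member)."""
    order = np.sort(values)  # ascending
    # H = n - (# strictly below) = n - searchsorted(left)
    return len(values) - np.searchsorted(order, values, side="left")


def precision_convert(
    conf: ConfidenceVector, standard: bool = False, known: np.ndarray | None = None
) -> np.ndarray:
    """Convert confidences to precision scores R/H aligned to candidate order.

    Candidates are sorted by descending confidence; H counts candidates with
    confidence at-or-above each one (tied candidates share the worst rank of
    their group), and precision = R/H.  The score exceeds 1 at ranks above the
    richness R; it is a rank conversion, not a calibrated probability.

    ``standard=True`` instead computes the conventional precision-at-H
    (known positives within the top H over H) for sensitivity analysis; it
    requires the ``known`` indicator vector.
    """
    h = _rank_at_or_above(conf.values)
    if not standard:
        return conf.richness / h
    if known is None:
        raise ValueError("standard precision requires the known-positive indicator")
    known = np.asarray(known, dtype=bool)
    order = np.argsort(-conf.values, kind="stable")
    hits_by_rank = np.cumsum(known[order])
    # map each candidate's H (a rank) to hits within the top H
    return hits_by_rank[h - 1] / h


def _precision_matrix_columns(
    adjusted: np.ndarray, Y: np.ndarray, richness: np.ndarray, standard: bool = False
) -> np.ndarray:
    """Vectorized one-sided precision for every context column of Y.

    Column j of the result is the precision-converted confidence of all rows
    for context j; columns with richness 0 are NaN (undefined).
    """
    n_rows, n_ctx = Y.shape
    out = np.full((n_rows, n_ctx), np.nan)
    row_mean = adjusted.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        known_mean = (adjusted @ Y) / richness[None, :]
    conf = row_mean[:, None] - known_mean
    for j in range(n_ctx):
        r = richness[j]
        if r < 1:
            continue
        h = _rank_at_or_above(conf[:, j])
        if standard:
            kn = Y[:, j].astype(bool)
            order = np.argsort(-conf[:, j], kind="stable")
            hits = np.cumsum(kn[order])
            out[:, j] = hits[h - 1] / h
        else:
            out[:, j] = r / h
    return out


def score_all(
    dist_m: AdjustedDistanceMatrix,
    dist_d: AdjustedDistanceMatrix,
    Y: AssociationMatrix,
    standard_precision: bool = False,
) -> ScoreMatrix:
    """Score every miRNA-disease pair.

    The miRNA-side precision is computed per disease column, the disease-side
    per miRNA row, and the final score is their mean.  Contexts with no known
    partners leave their side undefined; such pairs fall back to the defined
    side alone (and to 0 if neither side is defined, which is logged).
    """
    if dist_m.index != Y.mirna_index or dist_d.index != Y.disease_index:
        raise ValueError("distance matrix indices do not match adjacency indices")
    yv = Y.values.astype(float)
    r_d = yv.sum(axis=0)
    r_m = yv.sum(axis=1)
    prm = _precision_matrix_columns(dist_m.adjusted, yv, r_d, standard_precision)
    prd_t = _precision_matrix_columns(dist_d.adjusted, yv.T, r_m, standard_precision)
    prd = prd_t.T
    both_nan = np.isnan(prm) & np.isnan(prd)
    if both_nan.any():
        logger.info(
            "%d pairs have no defined confidence on either side; scored 0",
            int(both_nan.sum()),
        )
    final = np.where(
        np.isnan(prm), prd, np.where(np.isnan(prd), prm, (prm + prd) / 2.0)
    )
    final = np.where(both_nan, 0.0, final)
    return ScoreMatrix(
        precision_m=prm,
        precision_d=prd,
        final=final,
        mirna_index=list(Y.mirna_index),
        disease_index=list(Y.disease_index),
    )


def predict_new_disease(
    dist_m: AdjustedDistanceMatrix,
    dist_d: AdjustedDistanceMatrix,
    Y_masked: AssociationMatrix,
    disease: str,
    standard_precision: bool = False,
) -> pd.Series:
    """Rank all miRNAs for a disease with no known associations.

    With the disease's column of Y all zero the miRNA-side confidence is
    undefined, so the ranking uses the disease-side precision alone: each
    miRNA's converted confidence in the investigated disease, given that
    miRNA's known diseases.  Returns a Series of scores indexed by miRNA
    name, sorted by descending score with alphabetical tie-break.
    """
    j = Y_masked.disease_index.index(disease)
    if Y_masked.values[:, j].any():
        raise ValueError(f"disease {disease!r} still has known associations in Y")
    yv = Y_masked.values.astype(float)
    r_m = yv.sum(axis=1)
    prd_t = _precision_matrix_columns(dist_d.adjusted, yv.T, r_m, standard_precision)
    scores = prd_t.T[:, j]
    if np.isnan(scores).any():
        logger.info(
            "%d miRNAs have no known diseases; ranked last with score NaN->-inf",
            int(np.isnan(scores).sum()),
        )
    ser = pd.Series(scores, index=Y_masked.mirna_index, name=disease)
    key = ser.fillna(-np.inf)
    order = sorted(ser.index, key=lambda m: (-key[m], m))
    return ser.loc[order]
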