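"""Cross-validation: global/local leave-one-out, repeated k-fold, ROC/AUC.

In leave-one-out cross-validation each known association is zeroed in turn
and its recomputed score is ranked against the candidate pairs (pairs with
no known association in the full network).  "Global" ranks against every
candidate pair; "local" only against the held-out disease's own candidates.
The AUC is the mean, over validation samples, of the fraction of candidates
the sample outranks (a Mann-Whitney statistic with mid-rank ties), which
coincides with the area under the rank-threshold ROC curve.

Kernels may be refit inside each fold (``kernel_mode="refit"``, the default
-- no information leaks from the held-out pair into the Gaussian profiles)
or computed once from the full network (``"frozen"``, faster).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd

from . import core
from .io import AssociationMatrix

__all__ = [
    "CVResult",
    "RocCurve",
    "auc_from_ranks",
    "roc_from_ranks",
    "global_loocv",
    "local_loocv",
    "kfold_cv",
    "degree_baseline_loocv",
]

logger = logging.getLogger(__name__)


@dataclass
class RocCurve:
    """ROC points from a rank-threshold sweep over validation samples."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def auc_trapezoid(self) -> float:
        """Area under the curve by trapezoidal integration."""
        return float(np.trapezoid(self.tpr, self.fpr))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        ).to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, label: str | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.fpr, self.tpr, label=label)
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("false-positive rate")
        ax.set_ylabel("true-positive rate")
        if label:
            ax.legend()
        return ax


@dataclass
class CVResult:
    """Per-sample rank records and the resulting AUC for one CV scheme."""

    scheme: str
    records: pd.DataFrame  # columns: mirna, disease, score, candidates, rank
    auc: float
    repeats: list[float] = field(default_factory=list)
    seed: int | None = None

    @property
    def auc_std(self) -> float:
        """Across-repeat spread of the AUC (k-fold only; 0 otherwise)."""
        return float(np.std(self.repeats)) if len(self.repeats) > 1 else 0.0

    def roc(self) -> RocCurve:
        return roc_from_ranks(
            self.records["rank"].to_numpy(), self.records["candidates"].to_numpy()
        )


def auc_from_ranks(ranks, candidate_counts) -> float:
    """AUC from per-sample ranks among their candidate sets.

    A sample with mid-rank r among c candidates outranks (c + 1 - r)/c of
    them; the AUC is the mean of that fraction over samples.  This equals
    the Mann-Whitney statistic of validation vs candidate scores (mid-rank
    tie handling) and the trapezoidal area under the normalized
    rank-threshold ROC curve.
    """
    ranks = np.asarray(ranks, dtype=float)
    counts = np.asarray(candidate_counts, dtype=float)
    if ranks.size == 0:
        raise ValueError("no validation samples")
    if (counts < 1).any():
        raise ValueError("every sample needs at least one candidate")
    if (ranks < 1).any() or (ranks > counts + 1).any():
        raise ValueError("ranks must lie in [1, candidate count + 1]")
    return float(np.mean((counts + 1.0 - ranks) / counts))


def roc_from_ranks(ranks, candidate_counts) -> RocCurve:
    """ROC curve from per-sample normalized rank positions.

    Each sample's position p = (rank - 1)/candidates lies in [0, 1]; at
    threshold t the true-positive rate is the fraction of samples with
    p <= t while candidates, uniform over rank positions, give a
    false-positive rate of t.  Jump points are duplicated so trapezoidal
    integration reproduces the exact step-function area.
    """
    ranks = np.asarray(ranks, dtype=float)
    counts = np.asarray(candidate_counts, dtype=float)
    p = (ranks - 1.0) / counts
    n = p.size
    jumps = np.unique(p)
    fpr = [0.0, 0.0]
    tpr = [0.0, float((p <= 0).mean())]
    for t in jumps:
        before = float((p < t).mean())
        after = float((p <= t).mean())
        if t > 0:
            fpr.extend([t, t])
            tpr.extend([before, after])
    if not fpr or fpr[-1] < 1.0:
        fpr.append(1.0)
        tpr.append(1.0)
    fpr_a = np.asarray(fpr)
    return RocCurve(fpr=fpr_a, tpr=np.asarray(tpr), thresholds=fpr_a.copy())


# --------------------------------------------------------------------- #
# scoring callables


def _model_score_fn(model, kernel_mode: str) -> Callable[[AssociationMatrix], np.ndarray]:
    """Final-score matrix as a function of a (masked) adjacency."""
    if kernel_mode not in ("refit", "frozen"):
        raise ValueError(f"unknown kernel_mode {kernel_mode!r}")
    if kernel_mode == "frozen":
        dist_m, dist_d = model._distances_for(model.adjacency)

        def fn(y: AssociationMatrix) -> np.ndarray:
            return core.score_all(dist_m, dist_d, y, model.standard_precision).final

    else:

        def fn(y: AssociationMatrix) -> np.ndarray:
            dm, dd = model._distances_for(y)
            return core.score_all(dm, dd, y, model.standard_precision).final

    return fn


def _degree_score_fn(y: AssociationMatrix) -> np.ndarray:
    """Degree-product baseline: score(i, j) = richness(m_i) * richness(d_j)."""
    r_m = y.values.sum(axis=1).astype(float)
    r_d = y.values.sum(axis=0).astype(float)
    return np.outer(r_m, r_d)


# --------------------------------------------------------------------- #
# schemes


def _rank_against(v: float, cand: np.ndarray) -> float:
    return 1.0 + float((cand > v).sum()) + 0.5 * float((cand == v).sum())


def _loocv(
    Y: AssociationMatrix,
    score_fn: Callable[[AssociationMatrix], np.ndarray],
    local: bool,
) -> tuple[pd.DataFrame, float]:
    yv = Y.values
    ki, kj = np.nonzero(yv)
    if ki.size < 2:
        raise ValueError("leave-one-out needs at least 2 known associations")
    zero = yv == 0
    zi, zj = np.nonzero(zero)
    rows = []
    for i, j in zip(ki, kj):
        values = yv.copy()
        values[i, j] = 0
        y_masked = AssociationMatrix(
            values, list(Y.mirna_index), list(Y.disease_index)
        )
        final = score_fn(y_masked)
        v = float(final[i, j])
        if local:
            cand = final[zero[:, j], j]
        else:
            cand = final[zi, zj]
        if cand.size == 0:
            warnings.warn(
                f"disease {Y.disease_index[j]!r} has no candidate pairs; "
                "validation sample skipped",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "mirna": Y.mirna_index[i],
                "disease": Y.disease_index[j],
                "score": v,
                "candidates": int(cand.size),
                "rank": _rank_against(v, cand),
            }
        )
    records = pd.DataFrame(rows)
    auc = auc_from_ranks(records["rank"], records["candidates"])
    return records, auc


def global_loocv(
    model, kernel_mode: Literal["refit", "frozen"] = "refit"
) -> CVResult:
    """Leave each known association out; rank it against all candidate pairs."""
    records, auc = _loocv(
        model.adjacency, _model_score_fn(model, kernel_mode), local=False
    )
    return CVResult(scheme="global_loocv", records=records, auc=auc)


def local_loocv(
    model, kernel_mode: Literal["refit", "frozen"] = "refit"
) -> CVResult:
    """As global LOOCV, but candidates restricted to the held-out disease."""
    records, auc = _loocv(
        model.adjacency, _model_score_fn(model, kernel_mode), local=True
    )
    return CVResult(scheme="local_loocv", records=records, auc=auc)


def degree_baseline_loocv(Y: AssociationMatrix, local: bool = False) -> CVResult:
    """LOOCV of the degree-product baseline (no similarity information)."""
    records, auc = _loocv(Y, _degree_score_fn, local=local)
    return CVResult(scheme="degree_baseline", records=records, auc=auc)


def kfold_cv(
    model,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    kernel_mode: Literal["refit", "frozen"] = "refit",
) -> CVResult:
    """Repeated k-fold CV over the known associations.

    Associations are shuffled (``seed``) and split into k folds of sizes
    differing by at most one; each fold is masked jointly and its samples
    are ranked against all candidate pairs of the full network.  Reported
    AUC is the mean over repeats, with per-repeat values retained.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    Y = model.adjacency
    yv = Y.values
    ki, kj = np.nonzero(yv)
    n = ki.size
    if k > n:
        raise ValueError(f"k={k} exceeds the number of known associations ({n})")
    zero = yv == 0
    zi, zj = np.nonzero(zero)
    score_fn = _model_score_fn(model, kernel_mode)
    rng = np.random.default_rng(seed)
    repeat_aucs: list[float] = []
    all_rows = []
    for rep in range(repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        rep_ranks, rep_counts = [], []
        for fold in folds:
            values = yv.copy()
            values[ki[fold], kj[fold]] = 0
            y_masked = AssociationMatrix(
                values, list(Y.mirna_index), list(Y.disease_index)
            )
            final = score_fn(y_masked)
            cand = final[zi, zj]
            for idx in fold:
                i, j = ki[idx], kj[idx]
                v = float(final[i, j])
                rank = _rank_against(v, cand)
                rep_ranks.append(rank)
                rep_counts.append(cand.size)
                all_rows.append(
                    {
                        "repeat": rep,
                        "mirna": Y.mirna_index[i],
                        "disease": Y.disease_index[j],
                        "score": v,
                        "candidates": int(cand.size),
                        "rank": rank,
                    }
                )
        repeat_aucs.append(auc_from_ranks(rep_ranks, rep_counts))
    records = pd.DataFrame(all_rows)
    return CVResult(
        scheme="kfold",
        records=records,
        auc=float(np.mean(repeat_aucs)),
        repeats=repeat_aucs,
        seed=seed,
    )
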