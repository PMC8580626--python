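"""Reconstruction-error anomaly scores, top-N flagging, and precision-at-N.

A fitted model reconstructs each sample from its deep codes; samples the
factorization cannot reconstruct well — those off the structure shared by
the bulk of the data — receive large squared residuals and are ranked as
anomalies.  With a flag budget N (conventionally the number of true
outliers when labels exist), precision-at-N is the fraction of flagged
samples that are labelled outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import NotFittedError
from .model import ModelState, reconstruct

__all__ = [
    "AnomalyResult",
    "score_samples",
    "rank_and_flag",
    "precision_at_n",
    "detect",
    "write_scores_tsv",
]


@dataclass
class AnomalyResult:
    """Per-sample scores with ranking, flags, and optional precision."""

    scores: np.ndarray  # squared reconstruction error per sample
    ranking: np.ndarray  # sample indices, descending score
    flags: np.ndarray  # boolean, exactly N True
    N: int
    p_at_n: float | None = None


def score_samples(X: np.ndarray, state: ModelState) -> np.ndarray:
    """Squared per-sample reconstruction error ``O_j = ||x_j - x'_j||^2``.

    The scores sum exactly to the squared Frobenius reconstruction error.
    """
    if not (state.fitted or state.objective_trace):
        raise NotFittedError("model has not been fitted")
    X = np.asarray(X, dtype=float)
    R = X - reconstruct(state)
    if R.shape != X.shape:
        raise ValueError("model reconstruction shape does not match X")
    return np.einsum("ij,ij->j", R, R)


def rank_and_flag(scores: np.ndarray, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Descending-score ranking and boolean top-N flags.

    Ties are broken by ascending sample index so results are deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    N = int(N)
    if not 0 < N <= n:
        raise ValueError(f"N must satisfy 0 < N <= {n}; got {N}")
    # lexsort: last key is primary -> sort by -score, then by index
    ranking = np.lexsort((np.arange(n), -scores))
    flags = np.zeros(n, dtype=bool)
    flags[ranking[:N]] = True
    return ranking, flags


def precision_at_n(
    ranking: np.ndarray, labels: np.ndarray, N: int | None = None
) -> float:
    """Fraction of true outliers among the N top-ranked samples.

    ``N`` defaults to the number of positive labels.
    """
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("precision@N undefined: no positive labels")
    if N is None:
        N = n_pos
    N = int(N)
    ranking = np.asarray(ranking)
    if not 0 < N <= ranking.size:
        raise ValueError(f"N must satisfy 0 < N <= {ranking.size}; got {N}")
    return float(labels[ranking[:N]].sum()) / N


def detect(
    X: np.ndarray,
    state: ModelState,
    labels: np.ndarray | None = None,
    N: int | None = None,
) -> AnomalyResult:
    """Score, rank and flag; computes precision-at-N when labels are given."""
    scores = score_samples(X, state)
    if N is None:
        if labels is not None:
            N = int(np.asarray(labels).sum())
            if N == 0:
                raise ValueError("cannot default N: labels contain no outliers")
        else:
            raise ValueError("N is required when labels are absent")
    ranking, flags = rank_and_flag(scores, N)
    p = precision_at_n(ranking, labels, N) if labels is not None else None
    return AnomalyResult(scores=scores, ranking=ranking, flags=flags, N=N, p_at_n=p)


def write_scores_tsv(result: AnomalyResult, path, sample_ids=None) -> None:
    """TSV with columns sample_id, score, rank, flagged."""
    n = result.scores.size
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    rank_of = np.empty(n, dtype=int)
    rank_of[result.ranking] = np.arange(1, n + 1)
    with open(path, "w") as fh:
        fh.write("sample_id\tscore\trank\tflagged\n")
        for j in range(n):
            fh.write(
                f"{sample_ids[j]}\t{result.scores[j]:.10g}\t{rank_of[j]}\t"
                f"{int(result.flags[j])}\n"
            )
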