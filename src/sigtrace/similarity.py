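"""Cohort-level similarity of exposure profiles.

Between two cohorts M (m samples) and N (n samples), the pairwise matrix
rho holds the cosine similarity of every sample pair's exposure vectors.
The cohort-level similarity aggregates rho over all m*n pairs; for
non-negative exposures every entry, and hence the aggregate, lies in [0,1],
and same-type cohorts score near 1.

A type-by-type aggregate matrix can be normalized for display by the
four-step sequence: row centering, column centering, within-row average
ranks divided by the number of columns, then within-column average ranks
divided by the number of rows.
"""

from __future__ import annotations

import numpy as np
import scipy.stats

from .signature_fit import cosine


class DegenerateInputError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


def pairwise_rho(exposures_m: np.ndarray, exposures_n: np.ndarray) -> np.ndarray:
    """m x n matrix of cosine similarities between the rows of two cohorts."""
    A = np.atleast_2d(np.asarray(exposures_m, dtype=float))
    B = np.atleast_2d(np.asarray(exposures_n, dtype=float))
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    for norms, side in ((na, "first"), (nb, "second")):
        if (norms == 0).any():
            bad = int(np.argmax(norms == 0))
            raise DegenerateInputError(
                f"all-zero exposure row {bad} in the {side} cohort"
            )
    return (A / na[:, None]) @ (B / nb[:, None]).T


def aggregate_similarity(rho: np.ndarray, variant: str = "mean") -> float:
    """Aggregate a pairwise similarity matrix to one cohort-level scalar.

    ``variant="mean"`` (default) averages rho over all pairs;
    ``variant="mean_square"`` averages rho squared.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.size == 0:
        raise DegenerateInputError("empty similarity matrix")
    if variant == "mean":
        return float(rho.mean())
    if variant == "mean_square":
        return float((rho**2).mean())
    raise ConfigurationError(f"unknown variant {variant!r}")


def normalize_similarity(matrix: np.ndarray) -> np.ndarray:
    """Four-step normalization of a type-by-type aggregate similarity matrix.

    Applied strictly in order: (1) subtract row means; (2) subtract column
    means; (3) replace each row by its average ranks divided by the number
    of columns; (4) replace each column by its average ranks divided by the
    number of rows.  Ties receive average ranks.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise DegenerateInputError("normalization needs at least a 2x2 matrix")
    M = M - M.mean(axis=1, keepdims=True)
    M = M - M.mean(axis=0, keepdims=True)
    M = np.vstack([scipy.stats.rankdata(row, method="average") for row in M])
    M = M / M.shape[1]
    M = np.column_stack(
        [scipy.stats.rankdata(col, method="average") for col in M.T]
    )
    return M / M.shape[0]


def primary_met_concordance(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    background: list[np.ndarray],
) -> tuple[list[float], list[float], float]:
    """Matched primary-metastasis similarity against a cross-type background.

    ``within``: cosine of each matched (primary, metastasis) exposure pair.
    ``between``: cosine of each primary against every background sample
    (exposures of other tumor types).  Returns both lists and the two-sided
    rank-sum p value comparing them.
    """
    if not pairs:
        raise DegenerateInputError("no primary-metastasis pairs supplied")
    if not background:
        raise ConfigurationError("empty cross-type background pool")
    within = [cosine(p, m) for p, m in pairs]
    between = [cosine(p, b) for p, _ in pairs for b in background]
    res = scipy.stats.mannwhitneyu(within, between, alternative="two-sided")
    return within, between, float(res.pvalue)


def pca_project(exposures: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Plain PCA projection of exposure rows (plotting helper)."""
    from sklearn.decomposition import PCA

    return PCA(n_components=n_components).fit_transform(np.asarray(exposures, float))
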