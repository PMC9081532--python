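"""Signature refitting and de novo extraction.

Refitting estimates, for one sample, the non-negative mixture of reference
signatures that best reconstructs its normalized 96-channel spectrum:

    minimize ||p - S^T w||^2   subject to  w >= 0,  sum(w) <= 1,

where p is the spectrum as proportions and S the catalog matrix.  The solver
is greedy forward selection over signatures with the active-set weights
re-solved jointly by non-negative least squares at every step, followed by a
small-weight cutoff (default 0.06) below which contributions are considered
noise and zeroed.

De novo extraction factorizes a cohort's normalized spectra by NMF and maps
each learned signature to its closest catalog entry by cosine similarity;
matches above 0.75 are treated as the same signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import scipy.optimize
from sklearn.decomposition import NMF

from .catalog import SignatureCatalog
from .spectrum import Spectrum96


class DegenerateInputError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two non-negative vectors; errors on zero input."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateInputError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


@dataclass
class ExposureProfile:
    """Per-sample signature weights ("contributions") from refitting.

    Weights are non-negative, sum to at most 1, and each is either 0 or at
    least the configured cutoff.  ``residual_error`` is the squared
    reconstruction error on the normalized spectrum; any unexplained mass is
    reflected there rather than as an explicit pseudo-signature.
    """

    sample_id: str
    weights: dict[str, float]
    residual_error: float

    def as_vector(self, names: list[str]) -> np.ndarray:
        return np.array([self.weights.get(n, 0.0) for n in names])


def _solve_active(S: np.ndarray, active: list[int], p: np.ndarray) -> tuple[np.ndarray, float]:
    """NNLS on the active signature set, rescaled so the weights sum <= 1."""
    if not active:
        return np.zeros(0), float(p @ p)
    A = S[active].T  # (96, k)
    w, _ = scipy.optimize.nnls(A, p)
    s = w.sum()
    if s > 1.0:
        w = w / s
    resid = p - A @ w
    return w, float(resid @ resid)


def _apply_cutoff(
    S: np.ndarray, active: list[int], p: np.ndarray, cutoff: float
) -> tuple[list[int], np.ndarray, float]:
    """Zero weights below the cutoff and re-solve until all survivors pass."""
    w, sse = _solve_active(S, active, p)
    while True:
        keep = [i for i, wi in zip(active, w) if wi >= cutoff]
        if len(keep) == len(active):
            return active, w, sse
        active = keep
        w, sse = _solve_active(S, active, p)


def refit_exposures(
    spectrum: Spectrum96,
    catalog: SignatureCatalog,
    cutoff: float = 0.06,
    tol: float = 1e-3,
) -> ExposureProfile:
    """Fit one sample's exposures by forward selection + constrained NNLS.

    Signatures are added greedily, each addition re-solving all active
    weights, until the relative SSE improvement drops below ``tol``.
    Weights below ``cutoff`` are then zeroed and the survivors re-solved.
    SSE ties break toward the lowest catalog index.
    """
    if len(catalog) == 0:
        raise ConfigurationError("empty signature catalog")
    if spectrum.total == 0:
        raise DegenerateInputError(f"sample {spectrum.sample_id}: empty spectrum")
    p = spectrum.normalized()
    S = catalog.matrix
    n = len(catalog)

    active: list[int] = []
    sse = float(p @ p)
    while len(active) < n:
        best_idx, best_sse, best_w = -1, sse, None
        for j in range(n):
            if j in active:
                continue
            w_j, sse_j = _solve_active(S, active + [j], p)
            if sse_j < best_sse - 1e-15:
                best_idx, best_sse, best_w = j, sse_j, w_j
        if best_idx < 0:
            break
        improvement = (sse - best_sse) / sse if sse > 0 else 0.0
        if active and improvement < tol:
            break  # the first signature is always admitted
        active = active + [best_idx]
        sse = best_sse
        if sse <= 1e-15:
            break

    active, w, sse = _apply_cutoff(S, active, p, cutoff)
    weights = {catalog.names[i]: float(wi) for i, wi in zip(active, w)}
    return ExposureProfile(spectrum.sample_id, weights, sse)


def refit_cohort(
    spectra: list[Spectrum96],
    catalog: SignatureCatalog,
    cutoff: float = 0.06,
    tol: float = 1e-3,
):
    """Refit every spectrum; returns a samples x signatures DataFrame."""
    import pandas as pd

    profiles = [refit_exposures(s, catalog, cutoff=cutoff, tol=tol) for s in spectra]
    return pd.DataFrame(
        [pr.as_vector(catalog.names) for pr in profiles],
        index=pd.Index([pr.sample_id for pr in profiles], name="sample_id"),
        columns=catalog.names,
    )


def nnls_subset_oracle(
    spectrum: Spectrum96,
    catalog: SignatureCatalog,
    max_subset: int,
    cutoff: float = 0.06,
) -> ExposureProfile:
    """Exhaustive-subset constrained-least-squares reference solver.

    Enumerates every signature subset of size <= max_subset, solves the same
    constrained problem on each, and returns the global SSE minimizer after
    the same cutoff rule.  Only feasible for catalogs of <= 12 signatures.
    """
    if len(catalog) > 12:
        raise ConfigurationError(
            "catalog too large for exhaustive enumeration; use refit_exposures"
        )
    if spectrum.total == 0:
        raise DegenerateInputError(f"sample {spectrum.sample_id}: empty spectrum")
    p = spectrum.normalized()
    S = catalog.matrix
    best: tuple[float, list[int], np.ndarray] = (float(p @ p), [], np.zeros(0))
    for k in range(1, max_subset + 1):
        for subset in combinations(range(len(catalog)), k):
            w, sse = _solve_active(S, list(subset), p)
            if sse < best[0] - 1e-15:
                best = (sse, list(subset), w)
    active, w, sse = _apply_cutoff(S, best[1], p, cutoff)
    weights = {catalog.names[i]: float(wi) for i, wi in zip(active, w)}
    return ExposureProfile(spectrum.sample_id, weights, sse)


@dataclass
class DeNovoResult:
    """NMF-extracted signatures with their catalog assignment."""

    signatures: np.ndarray  # (k, 96), rows sum to 1
    sample_loadings: np.ndarray  # (n_samples, k), non-negative
    k: int
    reconstruction_error: float
    mapping: dict[int, tuple[str | None, float]] = field(default_factory=dict)


def extract_denovo(
    spectra: list[Spectrum96], k: int, n_restarts: int = 10, seed: int = 0
) -> DeNovoResult:
    """Extract k de novo signatures by NMF on the normalized cohort matrix.

    Multiplicative updates minimizing Frobenius error; the best of
    ``n_restarts`` seeded random initializations is kept.  Signature rows
    are renormalized to sum 1 with the loadings rescaled compensatorily.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > len(spectra):
        raise ConfigurationError(f"k={k} exceeds the {len(spectra)} samples")
    V = np.vstack([s.normalized() for s in spectra])
    best = None
    for r in range(n_restarts):
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=2000,
            tol=1e-6,
            random_state=seed + r,
        )
        W = model.fit_transform(V)
        if best is None or model.reconstruction_err_ < best[0]:
            best = (model.reconstruction_err_, W, model.components_)
    err, W, H = best
    row_sums = H.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    H = H / row_sums[:, None]
    W = W * row_sums[None, :]
    return DeNovoResult(signatures=H, sample_loadings=W, k=k, reconstruction_error=float(err))


def map_to_catalog(
    denovo: DeNovoResult, catalog: SignatureCatalog, threshold: float = 0.75
) -> DeNovoResult:
    """Assign each de novo signature to its most-similar catalog entry.

    Similarity strictly above the threshold is required; otherwise the
    signature is left unmapped (None).  Many-to-one mapping is permitted.
    """
    mapping: dict[int, tuple[str | None, float]] = {}
    for i, row in enumerate(denovo.signatures):
        sims = [cosine(row, cat_row) for cat_row in catalog.matrix]
        j = int(np.argmax(sims))
        best = sims[j]
        mapping[i] = (catalog.names[j], best) if best > threshold else (None, best)
    denovo.mapping = mapping
    return denovo
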