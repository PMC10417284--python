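"""Site-based tissue-of-origin deconvolution.

Models the observed per-site methylation vector b as a mixture of reference
tissue profiles (columns of the atlas matrix A) and estimates tissue
proportions x by bounded least squares:

    minimize  || A x - b ||^2
    subject to 0 <= x_i <= 1  and  sum(x) <= 1

solved with sequential least squares programming (SLSQP).  The inequality
sum constraint leaves room for an *undetermined* fraction, 1 - sum(x):
methylation signal not explained by any reference tissue — whether from
unrepresented cell types or from technical artifacts such as end-repair
fill-in — accumulates there instead of being forced onto real tissues.

:func:`brute_force_deconv` evaluates the same objective exhaustively on a
simplex grid and exists as an independent check of the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from .atlas import ReferenceAtlas
from .errors import DeconvolutionError, DegenerateDataError, ValidationError
from .methprofile import SiteCounts

__all__ = [
    "SampleBeta",
    "DeconvolutionResult",
    "sample_beta_from_counts",
    "deconvolve_site",
    "brute_force_deconv",
]


@dataclass
class SampleBeta:
    """Observed methylation fractions aligned to an atlas' site order.

    ``beta`` holds NaN where a site is missing (insufficient coverage);
    ``coverage`` holds the informative call count per site.
    """

    beta: np.ndarray
    coverage: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=int)
        if self.beta.shape != self.coverage.shape:
            raise ValidationError("beta and coverage must have equal length")
        finite = self.beta[np.isfinite(self.beta)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("observed methylation fractions must lie in [0, 1]")

    @property
    def n_observed(self) -> int:
        return int(np.isfinite(self.beta).sum())


@dataclass
class DeconvolutionResult:
    """Estimated tissue proportions plus the undetermined remainder."""

    proportions: dict[str, float]
    undetermined: float
    residual_norm: float
    n_sites_used: int

    def __post_init__(self):
        s = sum(self.proportions.values())
        if s > 1 + 1e-8 or self.undetermined < -1e-8:
            raise ValidationError("proportions must sum to <= 1")

    def as_vector(self, tissues: list[str]) -> np.ndarray:
        return np.array([self.proportions[t] for t in tissues])


def sample_beta_from_counts(
    counts: SiteCounts, atlas: ReferenceAtlas, min_coverage: int = 1
) -> SampleBeta:
    """Turn site counts into an atlas-aligned observed methylation vector.

    Sites with fewer than ``min_coverage`` informative calls are marked
    missing (NaN) and excluded from the fit.
    """
    beta = np.full(atlas.n_sites, np.nan)
    cov = np.zeros(atlas.n_sites, dtype=int)
    hit = 0
    for i, site in enumerate(atlas.sites):
        m, t = counts.counts.get((site.chrom, site.pos), (0, 0))
        cov[i] = t
        if t > 0:
            hit += 1
        if t >= min_coverage and t > 0:
            beta[i] = m / t
    if hit == 0:
        raise DegenerateDataError("no overlap between observed sites and atlas")
    return SampleBeta(beta=beta, coverage=cov)


def _design(sample: SampleBeta, atlas: ReferenceAtlas, coverage_weight: bool):
    rows = np.isfinite(sample.beta) & np.all(np.isfinite(atlas.beta), axis=1)
    A = atlas.beta[rows]
    b = sample.beta[rows]
    if coverage_weight:
        w = np.sqrt(sample.coverage[rows].astype(float))
        A = A * w[:, None]
        b = b * w
    return A, b, int(rows.sum())


def deconvolve_site(
    sample: SampleBeta,
    atlas: ReferenceAtlas,
    coverage_weight: bool = False,
    tol: float = 1e-9,
    maxiter: int = 500,
) -> DeconvolutionResult:
    """Bounded least-squares deconvolution with an undetermined fraction.

    Missing sites (NaN in the observation or the atlas) are dropped
    row-wise.  Optionally rows are weighted by sqrt(coverage).  Raises
    :class:`DeconvolutionError` if the optimizer does not converge.
    """
    A, b, n_used = _design(sample, atlas, coverage_weight)
    T = atlas.n_tissues
    if n_used < T:
        raise DegenerateDataError(
            f"only {n_used} usable sites for {T} tissues; fit is underdetermined"
        )

    AtA = A.T @ A
    Atb = A.T @ b

    def objective(x):
        r = A @ x - b
        return float(r @ r)

    def grad(x):
        return 2.0 * (AtA @ x - Atb)

    x0 = np.full(T, 1.0 / T)
    res = minimize(
        objective,
        x0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * T,
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum(), "jac": lambda x: -np.ones(T)}],
        options={"maxiter": maxiter, "ftol": tol},
    )
    if not res.success:
        raise DeconvolutionError(f"SLSQP failed: {res.message}", status=res.status)
    x = np.clip(res.x, 0.0, 1.0)
    total = float(x.sum())
    if total > 1.0:
        x = x / total
        total = 1.0
    return DeconvolutionResult(
        proportions={t: float(v) for t, v in zip(atlas.tissues, x)},
        undetermined=max(0.0, 1.0 - total),
        residual_norm=float(np.linalg.norm(A @ x - b)),
        n_sites_used=n_used,
    )


@lru_cache(maxsize=8)
def _simplex_grid(T: int, steps: int) -> np.ndarray:
    """All grid points x in steps^-1 * Z^T with x >= 0 and sum(x) <= 1.

    Enumerated without materialising the full hypercube, so T = 4 at step
    0.01 stays tractable.
    """
    pts = np.zeros((1, 0), dtype=np.int32)
    remaining = np.array([steps], dtype=np.int32)
    for _ in range(T):
        reps = remaining + 1
        new_col = np.concatenate([np.arange(r, dtype=np.int32) for r in reps])
        pts = np.repeat(pts, reps, axis=0)
        pts = np.column_stack([pts, new_col])
        remaining = np.repeat(remaining, reps) - new_col
    return pts.astype(float) / steps


def brute_force_deconv(
    sample: SampleBeta,
    atlas: ReferenceAtlas,
    step: float = 0.01,
    coverage_weight: bool = False,
) -> DeconvolutionResult:
    """Exhaustive simplex-grid minimizer of the deconvolution objective.

    Only practical for T <= 4 tissues; intended as an independent oracle
    for :func:`deconvolve_site`.
    """
    T = atlas.n_tissues
    if T > 4:
        raise ValidationError("brute-force grid search is limited to <= 4 tissues")
    steps = int(round(1.0 / step))
    if abs(steps * step - 1.0) > 1e-9:
        raise ValidationError("step must divide 1 evenly")
    A, b, n_used = _design(sample, atlas, coverage_weight)
    grid = _simplex_grid(T, steps)
    resid = grid @ A.T - b  # (N, S)
    obj = np.einsum("ij,ij->i", resid, resid)
    k = int(np.argmin(obj))
    x = grid[k]
    return DeconvolutionResult(
        proportions={t: float(v) for t, v in zip(atlas.tissues, x)},
        undetermined=float(max(0.0, 1.0 - x.sum())),
        residual_norm=float(np.sqrt(obj[k])),
        n_sites_used=n_used,
    )
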