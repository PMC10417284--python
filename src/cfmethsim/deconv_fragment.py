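"""Fragment-level (U/X/M) tissue-of-origin deconvolution.

Each fragment overlapping a marker block is classified by its fraction of
methylated CpG calls within the block: U (mostly unmethylated), M (mostly
methylated) or X (mixed); fragments with too few informative CpGs are NA.
The per-block observed U fractions are then regressed onto the reference
U-fraction matrix by non-negative least squares and the weights normalized
to proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.optimize import nnls

from .atlas import MarkerBlock, UFractionAtlas
from .errors import DeconvolutionError, DegenerateDataError
from .simulate import FragmentRecord

__all__ = [
    "UXMCounts",
    "FragmentDeconvResult",
    "classify_fragment",
    "count_uxm",
    "deconvolve_uxm",
    "DEFAULT_U_THRESH",
    "DEFAULT_M_THRESH",
    "DEFAULT_MIN_CPGS",
]

DEFAULT_U_THRESH = 0.25
DEFAULT_M_THRESH = 0.75
DEFAULT_MIN_CPGS = 3


@dataclass
class UXMCounts:
    """Per-block U/X/M/NA fragment tallies."""

    blocks: list[MarkerBlock]
    n_u: np.ndarray
    n_x: np.ndarray
    n_m: np.ndarray
    n_na: np.ndarray

    def u_fraction(self) -> np.ndarray:
        """Observed U fraction per block; NaN where no classified fragments."""
        denom = self.n_u + self.n_x + self.n_m
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.n_u / np.maximum(denom, 1), np.nan)

    def n_classified(self) -> np.ndarray:
        return self.n_u + self.n_x + self.n_m


@dataclass
class FragmentDeconvResult:
    """Normalized cell-type proportions from the NNLS fit."""

    proportions: dict[str, float]
    raw_weights: dict[str, float]
    residual_norm: float
    n_blocks_used: int

    def as_vector(self, cell_types: list[str]) -> np.ndarray:
        return np.array([self.proportions[c] for c in cell_types])


def classify_fragment(
    pattern: str,
    u_thresh: float = DEFAULT_U_THRESH,
    m_thresh: float = DEFAULT_M_THRESH,
    min_cpgs: int = DEFAULT_MIN_CPGS,
) -> str:
    """Classify one fragment's within-block pattern as U, X, M or NA.

    With k informative calls of which m are methylated: NA if k < min_cpgs,
    U if m/k <= u_thresh, M if m/k >= m_thresh, else X.  '.' characters are
    uninformative and ignored.
    """
    k = sum(c != "." for c in pattern)
    if k < min_cpgs:
        return "NA"
    m = pattern.count("C")
    frac = m / k
    if frac <= u_thresh:
        return "U"
    if frac >= m_thresh:
        return "M"
    return "X"


def count_uxm(
    fragments: Iterable[FragmentRecord],
    atlas: UFractionAtlas,
    u_thresh: float = DEFAULT_U_THRESH,
    m_thresh: float = DEFAULT_M_THRESH,
    min_cpgs: int = DEFAULT_MIN_CPGS,
) -> UXMCounts:
    """Tally U/X/M classifications per marker block.

    A fragment contributes to every block in which it has at least
    ``min_cpgs`` informative CpG calls (marker blocks are disjoint in
    practice, so multiple assignment is rare).
    """
    B = atlas.n_blocks
    n_u = np.zeros(B, dtype=np.int64)
    n_x = np.zeros(B, dtype=np.int64)
    n_m = np.zeros(B, dtype=np.int64)
    n_na = np.zeros(B, dtype=np.int64)
    for frag in fragments:
        pos = frag.cpg_positions
        for b, block in enumerate(atlas.blocks):
            if frag.chrom != block.chrom or frag.end <= block.start or frag.start >= block.end:
                continue
            lo = int(np.searchsorted(pos, block.start, side="left"))
            hi = int(np.searchsorted(pos, block.end, side="left"))
            if hi <= lo:
                continue
            sub = frag.pattern[lo:hi]
            label = classify_fragment(sub, u_thresh, m_thresh, min_cpgs)
            if label == "U":
                n_u[b] += 1
            elif label == "X":
                n_x[b] += 1
            elif label == "M":
                n_m[b] += 1
            else:
                n_na[b] += 1
    return UXMCounts(blocks=atlas.blocks, n_u=n_u, n_x=n_x, n_m=n_m, n_na=n_na)


def deconvolve_uxm(
    counts: UXMCounts,
    atlas: UFractionAtlas,
    min_fragments_per_block: int = 10,
) -> FragmentDeconvResult:
    """Non-negative least squares on observed vs reference block U fractions.

    Blocks with fewer than ``min_fragments_per_block`` classified fragments
    are dropped; at least as many blocks as cell types must remain.  Raw
    NNLS weights are normalized to sum to 1.
    """
    u_obs = counts.u_fraction()
    keep = np.isfinite(u_obs) & (counts.n_classified() >= min_fragments_per_block)
    C = atlas.n_cell_types
    if keep.sum() < C:
        raise DegenerateDataError(
            f"only {int(keep.sum())} usable blocks for {C} cell types"
        )
    A = atlas.u_ref[keep]
    b = u_obs[keep]
    w, rnorm = nnls(A, b)
    total = w.sum()
    if total <= 0:
        raise DeconvolutionError("NNLS returned an all-zero weight vector")
    props = w / total
    return FragmentDeconvResult(
        proportions={c: float(v) for c, v in zip(atlas.cell_types, props)},
        raw_weights={c: float(v) for c, v in zip(atlas.cell_types, w)},
        residual_norm=float(rnorm),
        n_blocks_used=int(keep.sum()),
    )
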