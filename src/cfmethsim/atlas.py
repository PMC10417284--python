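"""Reference atlases for tissue-of-origin deconvolution.

Two kinds of reference are supported:

* a *site atlas* (:class:`ReferenceAtlas`): a tissues x CpG-sites matrix of
  methylation fractions, the design matrix of the bounded least-squares
  site-based deconvolution;
* a *marker-block atlas* (:class:`UFractionAtlas`): genomic blocks of
  tissue-specific hypomethylation together with the reference fraction of
  mostly-Unmethylated fragments expected from each cell type in each block,
  the design matrix of the fragment-level (U/X/M) deconvolution.

All genomic coordinates in this package are 0-based half-open (BED
convention).  A CpG site is identified by the position of the C of the CpG
dinucleotide on the forward strand; calls from either strand are collapsed
onto that position.

:func:`make_toy_atlas` builds a matched pair of synthetic atlases over a
small synthetic genome, one hypomethylated marker block per tissue, which is
the reference used throughout the simulation studies in this package.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "CpGSite",
    "ReferenceAtlas",
    "MarkerBlock",
    "UFractionAtlas",
    "load_site_atlas",
    "write_site_atlas",
    "load_marker_blocks",
    "write_marker_blocks",
    "make_toy_atlas",
]


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True, order=True)
class CpGSite:
    """A single CpG dinucleotide, addressed by the forward-strand C."""

    chrom: str
    pos: int

    def __post_init__(self):
        if self.pos < 0:
            raise ValidationError(f"CpG position must be >= 0, got {self.pos}")


@dataclass
class ReferenceAtlas:
    """Tissues x CpG-sites methylation-fraction matrix.

    Parameters
    ----------
    sites
        Ordered CpG sites (length S), sorted by (chrom, pos), unique.
    tissues
        Ordered tissue names (length T), unique.
    beta
        S x T matrix of methylation fractions in [0, 1].  NaN marks a
        missing reference value; missing entries are excluded pairwise at
        deconvolution time.
    """

    sites: list[CpGSite]
    tissues: list[str]
    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        S, T = len(self.sites), len(self.tissues)
        if self.beta.shape != (S, T):
            raise ValidationError(
                f"beta shape {self.beta.shape} does not match {S} sites x {T} tissues"
            )
        if len(set(self.tissues)) != T:
            raise ValidationError("duplicated tissue names in atlas")
        keys = [(s.chrom, s.pos) for s in self.sites]
        if len(set(keys)) != S:
            raise ValidationError("duplicated CpG sites in atlas")
        if keys != sorted(keys):
            raise ValidationError("atlas sites must be sorted by (chrom, pos)")
        finite = self.beta[np.isfinite(self.beta)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("atlas beta values must lie in [0, 1]")
        if S < T:
            warnings.warn(
                f"atlas has fewer sites ({S}) than tissues ({T}); "
                "deconvolution is not identifiable",
                stacklevel=2,
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def site_index(self) -> dict[tuple[str, int], int]:
        """Map (chrom, pos) -> row index."""
        return {(s.chrom, s.pos): i for i, s in enumerate(self.sites)}


@dataclass(frozen=True)
class MarkerBlock:
    """A genomic interval of tissue-specific hypomethylation."""

    chrom: str
    start: int
    end: int
    target_cell_type: str
    cpg_count: int = 1

    def __post_init__(self):
        if not self.start < self.end:
            raise ValidationError(
                f"marker block must have start < end, got [{self.start}, {self.end})"
            )
        if self.cpg_count < 1:
            raise ValidationError("marker block must contain at least one CpG")


@dataclass
class UFractionAtlas:
    """Blocks x cell-types reference matrix of U-fragment fractions.

    ``u_ref[b, c]`` is the expected fraction of fragments from cell type
    ``c`` overlapping block ``b`` that are classified U (mostly
    unmethylated).
    """

    blocks: list[MarkerBlock]
    cell_types: list[str]
    u_ref: np.ndarray

    def __post_init__(self):
        self.u_ref = np.asarray(self.u_ref, dtype=float)
        B, C = len(self.blocks), len(self.cell_types)
        if self.u_ref.shape != (B, C):
            raise ValidationError(
                f"u_ref shape {self.u_ref.shape} does not match {B} blocks x {C} cell types"
            )
        if len(set(self.cell_types)) != C:
            raise ValidationError("duplicated cell-type names")
        if np.any(self.u_ref < 0) or np.any(self.u_ref > 1):
            raise ValidationError("u_ref values must lie in [0, 1]")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_site_atlas(path, dialect: str = "tsv") -> ReferenceAtlas:
    """Read a site atlas from a TSV with columns chrom, pos, <tissue...>.

    '.' denotes a missing methylation value.  Gzip input is accepted.
    """
    if dialect != "tsv":
        raise ValueError(f"unknown site-atlas dialect: {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"chrom": str})
    except Exception as exc:  # malformed file
        raise ParseError(f"could not parse site atlas {path}: {exc}") from exc
    if df.columns[:2].tolist() != ["chrom", "pos"]:
        raise ParseError(
            f"{path}: first two columns must be 'chrom' and 'pos', "
            f"got {df.columns[:2].tolist()}"
        )
    tissues = df.columns[2:].tolist()
    if not tissues:
        raise ParseError(f"{path}: no tissue columns found")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad_pos = pos.isna() | (pos % 1 != 0)
    if bad_pos.any():
        raise ParseError(
            f"{path}: non-integer position at line {int(df.index[bad_pos][0]) + 2}"
        )
    df["pos"] = pos.astype(int)
    beta = df[tissues].to_numpy(dtype=float)
    finite = beta[np.isfinite(beta)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        rows = np.where((beta < 0) | (beta > 1))[0]
        raise ValidationError(
            f"{path}: methylation fraction outside [0, 1] at line {rows[0] + 2}"
        )
    sites = [CpGSite(c, int(p)) for c, p in zip(df["chrom"], df["pos"])]
    return ReferenceAtlas(sites=sites, tissues=tissues, beta=beta)


def write_site_atlas(atlas: ReferenceAtlas, path) -> None:
    """Write a site atlas as TSV (inverse of :func:`load_site_atlas`)."""
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in atlas.sites],
            "pos": [s.pos for s in atlas.sites],
        }
    )
    for j, t in enumerate(atlas.tissues):
        df[t] = atlas.beta[:, j]
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


def load_marker_blocks(bed_path, u_ref_path) -> UFractionAtlas:
    """Read a marker-block atlas from BED4 + companion U-fraction TSV.

    The BED file has columns (chrom, start, end, target_cell_type) and an
    optional fifth column with the CpG count of the block.  The TSV has one
    row per block in matching order; an optional leading ``block`` column is
    ignored, the remaining columns are cell types.
    """
    blocks: list[MarkerBlock] = []
    with _open_text(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{bed_path}: line {lineno}: expected >= 4 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{bed_path}: line {lineno}: non-integer interval") from exc
            cpg_count = int(parts[4]) if len(parts) > 4 else 1
            try:
                blocks.append(MarkerBlock(parts[0], start, end, parts[3], cpg_count))
            except ValidationError as exc:
                raise ParseError(f"{bed_path}: line {lineno}: {exc}") from exc
    df = pd.read_csv(u_ref_path, sep="\t")
    if df.columns[0] == "block":
        df = df.drop(columns="block")
    if len(df) != len(blocks):
        raise ValidationError(
            f"block count mismatch: {len(blocks)} blocks in {bed_path} but "
            f"{len(df)} rows in {u_ref_path}"
        )
    return UFractionAtlas(
        blocks=blocks,
        cell_types=df.columns.tolist(),
        u_ref=df.to_numpy(dtype=float),
    )


def write_marker_blocks(atlas: UFractionAtlas, bed_path, u_ref_path) -> None:
    """Write a marker-block atlas (inverse of :func:`load_marker_blocks`)."""
    with _open_text(bed_path, "wt") as fh:
        for b in atlas.blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.target_cell_type}\t{b.cpg_count}\n")
    df = pd.DataFrame(atlas.u_ref, columns=atlas.cell_types)
    df.insert(0, "block", [f"{b.chrom}:{b.start}-{b.end}" for b in atlas.blocks])
    with _open_text(u_ref_path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Toy atlas construction
# ---------------------------------------------------------------------------

#: spacing between CpG sites within a marker block (bp)
TOY_CPG_SPACING = 10
#: gap between consecutive marker blocks (bp); larger than any simulated
#: fragment so that a fragment never spans two blocks
TOY_BLOCK_GAP = 1000
TOY_CHROM = "chrS1"


def make_toy_atlas(
    n_tissues: int,
    n_sites_per_tissue: int = 10,
    high_beta: float = 0.9,
    low_beta: float = 0.1,
    seed: int = 0,
) -> tuple[ReferenceAtlas, UFractionAtlas]:
    """Build a matched synthetic (site atlas, marker-block atlas) pair.

    Each tissue owns one marker block of ``n_sites_per_tissue`` CpG sites on
    a synthetic chromosome.  Within its own block a tissue is hypomethylated
    (``low_beta``); every other tissue is ``high_beta`` there.  Encoding
    specificity as hypomethylation keeps the two atlases mutually
    consistent: the fragment-level method counts mostly-Unmethylated
    fragments, so the reference U fraction of the target cell type in its
    block is high and near zero elsewhere.

    ``u_ref`` is derived analytically from the beta values: a pure fragment
    covering all ``k`` CpGs of a block with per-CpG methylation probability
    ``beta`` is classified U when its methylated fraction is at most the U
    threshold, i.e. with probability ``BinomCDF(floor(u_thresh*k); k, beta)``.

    The construction is deterministic; ``seed`` currently only jitters
    nothing and is kept for interface stability.
    """
    from scipy.stats import binom

    from .deconv_fragment import DEFAULT_U_THRESH

    if n_tissues < 2:
        raise ValidationError("a toy atlas needs at least 2 tissues")
    if not (0 <= low_beta < high_beta <= 1):
        raise ValidationError("need 0 <= low_beta < high_beta <= 1")
    if n_sites_per_tissue < 1:
        raise ValidationError("need at least one site per tissue")

    tissues = [f"tissue{chr(ord('A') + t)}" if t < 26 else f"tissue{t}" for t in range(n_tissues)]
    sites: list[CpGSite] = []
    blocks: list[MarkerBlock] = []
    beta = np.full((n_tissues * n_sites_per_tissue, n_tissues), high_beta)
    block_span = (n_sites_per_tissue - 1) * TOY_CPG_SPACING + 2
    pos0 = TOY_BLOCK_GAP
    for t in range(n_tissues):
        first = pos0 + t * (block_span + TOY_BLOCK_GAP)
        positions = [first + i * TOY_CPG_SPACING for i in range(n_sites_per_tissue)]
        sites.extend(CpGSite(TOY_CHROM, p) for p in positions)
        # block interval covers both bases of the last CpG
        blocks.append(
            MarkerBlock(TOY_CHROM, positions[0], positions[-1] + 2, tissues[t], n_sites_per_tissue)
        )
        beta[t * n_sites_per_tissue : (t + 1) * n_sites_per_tissue, t] = low_beta

    k = n_sites_per_tissue
    u_cut = int(np.floor(DEFAULT_U_THRESH * k))
    u_ref = np.empty((n_tissues, n_tissues))
    for b in range(n_tissues):
        for c in range(n_tissues):
            p = low_beta if b == c else high_beta
            u_ref[b, c] = binom.cdf(u_cut, k, p)

    site_atlas = ReferenceAtlas(sites=sites, tissues=tissues, beta=beta)
    block_atlas = UFractionAtlas(blocks=blocks, cell_types=tissues, u_ref=u_ref)
    return site_atlas, block_atlas
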