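"""Mechanistic generator of cfDNA methylation-sequencing fragments.

The model produces per-fragment methylation call records as they would come
out of alignment + methylation extraction, skipping base-level sequence:

1. **Fragment origins** — each double-stranded cfDNA fragment is assigned a
   tissue of origin drawn from a mixture, placed on the synthetic genome of
   a :class:`~cfmethsim.atlas.ReferenceAtlas`, and given CpG methylation
   states drawn Bernoulli per site from the tissue's reference methylation
   fraction.  Both strands carry the same (complementary) truth.
2. **Jagged ends** — each fragment end independently carries a 5' overhang
   (single-stranded protrusion of the strand whose 5' terminus lies at that
   end) with probability ``jag_prob``; overhang lengths are geometric by
   default, reflecting that overhangs range from none to almost the whole
   fragment.
3. **Library preparation** —

   * *dsLP* (double-stranded, end repair + A-tailing): the recessed 3' end
     of the complementary strand is filled in across each 5' overhang; every
     cytosine synthesized during fill-in is unmethylated and flagged in the
     repair mask.  Both strands then span the full fragment.
   * *ssLP* (single-stranded, splint-adapter ligation): the duplex is
     denatured and each strand becomes an independent molecule of its own
     physical length; nothing is altered.

   Sequencing samples one strand per fragment uniformly; the prepared
   single-stranded molecule is read from both ends (read 1 from its 5' end,
   read 2 from its 3' end), so fill-in product always lands at the 5' start
   of read 2 — the geometric source of the read-2 M-bias of end-repaired
   libraries.
4. **Enzymatic conversion** — unmethylated cytosines read as T with
   probability ``conversion_rate``; methylated cytosines are protected and
   read as C with probability ``protection_rate``.  Fully methylated pUC19
   and unmethylated lambda spike-ins pass through the same channel and
   anchor the conversion QC.

All randomness flows from ``SimConfig.seed`` through spawned child streams
(fragments / jagged ends / library+conversion / spike-ins), so matched-seed
runs of the two library methods share the identical latent fragment set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import yaml

from .atlas import ReferenceAtlas
from .errors import ValidationError

__all__ = [
    "LengthSpec",
    "JagSpec",
    "SimConfig",
    "RawFragment",
    "Molecule",
    "FragmentRecord",
    "SpikeinSet",
    "SampleDataset",
    "sample_fragments",
    "apply_jagged_ends",
    "library_prep",
    "convert_and_read",
    "simulate_spikeins",
    "simulate_sample",
    "downsample",
]


@dataclass
class LengthSpec:
    """Truncated-normal fragment length distribution (bp)."""

    mean: float = 165.0
    sd: float = 20.0
    min: int = 50


@dataclass
class JagSpec:
    """Distribution of 5' overhang lengths (bp), conditional on presence.

    ``kind='geometric'`` (default) draws from a geometric distribution with
    the given mean; ``kind='constant'`` uses the mean rounded to an integer.
    """

    mean: float = 8.0
    kind: str = "geometric"

    def __post_init__(self):
        if self.kind not in ("geometric", "constant"):
            raise ValidationError(f"unknown jag length distribution: {self.kind!r}")
        if self.mean < 0:
            raise ValidationError("jag length mean must be >= 0")


@dataclass
class SimConfig:
    """Full parameterization of one simulated sample."""

    mixture: dict[str, float]
    n_fragments: int = 10_000
    fragment_length: LengthSpec = field(default_factory=LengthSpec)
    jag_prob: float = 0.0
    jag_length: JagSpec = field(default_factory=JagSpec)
    library: str = "ssLP"
    conversion_rate: float = 0.994
    protection_rate: float = 0.99
    chh_meth: float = 0.003
    n_chh_per_fragment: int = 20
    read_length: int = 100
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.fragment_length, dict):
            self.fragment_length = LengthSpec(**self.fragment_length)
        if isinstance(self.jag_length, dict):
            self.jag_length = JagSpec(**self.jag_length)
        props = np.array(list(self.mixture.values()), dtype=float)
        if props.size and (props.min() < 0 or abs(props.sum() - 1.0) > 1e-9):
            raise ValidationError("mixture proportions must be >= 0 and sum to 1")
        for name in ("jag_prob", "conversion_rate", "protection_rate", "chh_meth"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.library not in ("ssLP", "dsLP"):
            raise ValidationError(f"library must be 'ssLP' or 'dsLP', got {self.library!r}")
        if self.read_length <= 30:
            raise ValidationError("read_length must exceed 30 bp (jagged-index window)")
        if self.n_fragments < 0:
            raise ValidationError("n_fragments must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RawFragment:
    """A double-stranded fragment with latent methylation truth."""

    chrom: str
    start: int
    end: int
    tissue: str
    cpg_pos: np.ndarray  # forward-strand C positions covered
    meth: np.ndarray  # latent truth, bool per CpG (identical on both strands)
    j_left: int = 0  # 5' overhang length at the left fragment end
    j_right: int = 0  # 5' overhang length at the right fragment end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Molecule:
    """A prepared single-stranded molecule entering conversion.

    Site arrays stay aligned to the parent fragment's CpG list; ``in_mol``
    marks sites physically present on this strand after preparation.
    ``state`` is the methylation state entering conversion (fill-in product
    is unmethylated); ``repair`` marks fill-in-synthesized positions.
    """

    chrom: str
    strand: str  # '+' or '-'
    mstart: int
    mend: int
    tissue: str
    frag_start: int
    frag_end: int
    cpg_pos: np.ndarray
    in_mol: np.ndarray
    state: np.ndarray
    repair: np.ndarray

    @property
    def length(self) -> int:
        return self.mend - self.mstart


@dataclass
class FragmentRecord:
    """Observed per-fragment methylation calls with read bookkeeping.

    ``pattern`` is a string over {C = methylated call, T = unmethylated
    call, . = no call} aligned to ``cpg_positions``.  ``read1_pos`` /
    ``read2_pos`` give the bp offset of each CpG from the respective read's
    5' start, or -1 if the read does not cover it.  ``repair_mask`` is True
    where the reported base was synthesized during end repair (dsLP only).
    """

    chrom: str
    start: int
    end: int
    tissue_origin: str
    cpg_positions: np.ndarray
    pattern: str
    repair_mask: np.ndarray
    read1_pos: np.ndarray
    read2_pos: np.ndarray
    chh_meth_calls: int = 0
    chh_total_calls: int = 0

    def __post_init__(self):
        n = len(self.cpg_positions)
        if not (len(self.pattern) == len(self.repair_mask) == n):
            raise ValidationError("pattern, repair_mask and cpg_positions must align")


@dataclass
class SpikeinSet:
    """Reported states of spike-in control cytosines.

    lambda DNA is fully unmethylated, pUC19 fully methylated; each array
    element is True where the cytosine was reported as C (methylated call).
    """

    lambda_is_c: np.ndarray
    puc19_is_c: np.ndarray

    @property
    def n_lambda(self) -> int:
        return len(self.lambda_is_c)

    @property
    def n_puc19(self) -> int:
        return len(self.puc19_is_c)


@dataclass
class SampleDataset:
    """An end-to-end simulated sample."""

    fragments: list[FragmentRecord]
    spikeins: SpikeinSet
    truth: SimConfig
    realized_counts: dict[str, int]

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


# ---------------------------------------------------------------------------
# Generative steps
# ---------------------------------------------------------------------------

def sample_fragments(
    config: SimConfig, atlas: ReferenceAtlas, rng: np.random.Generator
) -> list[RawFragment]:
    """Draw fragment origins, placements and latent CpG methylation.

    Each fragment is anchored on a uniformly chosen atlas CpG site and
    placed uniformly among positions covering that anchor, so every fragment
    covers at least one reference site.  Methylation states are Bernoulli
    with the tissue's reference beta at each covered site.
    """
    unknown = set(config.mixture) - set(atlas.tissues)
    if unknown:
        raise ValidationError(f"mixture references unknown tissues: {sorted(unknown)}")
    n = config.n_fragments
    if n == 0:
        return []
    tissue_names = list(config.mixture)
    probs = np.array([config.mixture[t] for t in tissue_names])
    t_idx_in_atlas = np.array([atlas.tissues.index(t) for t in tissue_names])

    draws = rng.choice(len(tissue_names), size=n, p=probs)
    ls = config.fragment_length
    lengths = np.maximum(np.rint(rng.normal(ls.mean, ls.sd, size=n)).astype(int), ls.min)
    anchors = rng.integers(0, atlas.n_sites, size=n)
    offsets = (rng.random(n) * lengths).astype(int)

    all_pos = np.array([s.pos for s in atlas.sites])
    all_chrom = np.array([s.chrom for s in atlas.sites])
    # contiguous runs per chromosome (atlas sites are sorted)
    chrom_bounds: dict[str, tuple[int, int]] = {}
    for i, c in enumerate(all_chrom):
        lo, hi = chrom_bounds.get(c, (i, i))
        chrom_bounds[c] = (min(lo, i), max(hi, i) + 1)

    frags: list[RawFragment] = []
    for i in range(n):
        a = int(anchors[i])
        chrom = all_chrom[a]
        L = int(lengths[i])
        start = max(0, int(all_pos[a]) - int(offsets[i]))
        end = start + L
        lo, hi = chrom_bounds[chrom]
        cpos = all_pos[lo:hi]
        # a CpG is covered when both its bases lie inside the fragment
        j0 = int(np.searchsorted(cpos, start, side="left"))
        j1 = int(np.searchsorted(cpos, end - 1, side="left"))
        idx = np.arange(lo + j0, lo + j1)
        tissue = tissue_names[draws[i]]
        beta = atlas.beta[idx, t_idx_in_atlas[draws[i]]]
        meth = rng.random(len(idx)) < np.nan_to_num(beta, nan=0.5)
        frags.append(
            RawFragment(
                chrom=chrom,
                start=start,
                end=end,
                tissue=tissue,
                cpg_pos=all_pos[idx].copy(),
                meth=meth,
            )
        )
    return frags


def apply_jagged_ends(
    frag: RawFragment, jag_prob: float, jag_length: JagSpec, rng: np.random.Generator
) -> RawFragment:
    """Draw per-end 5' overhang lengths for one fragment (in place).

    Each end independently carries an overhang with probability
    ``jag_prob``; lengths are truncated at fragment length - 1 so a
    double-stranded core always remains.
    """
    has_left = rng.random() < jag_prob
    has_right = rng.random() < jag_prob
    frag.j_left = _draw_jag(jag_length, rng) if has_left else 0
    frag.j_right = _draw_jag(jag_length, rng) if has_right else 0
    cap = frag.length - 1
    frag.j_left = min(frag.j_left, cap)
    frag.j_right = min(frag.j_right, cap)
    return frag


def _draw_jag(spec: JagSpec, rng: np.random.Generator) -> int:
    if spec.mean <= 0:
        return 0
    if spec.kind == "constant":
        return int(round(spec.mean))
    return int(rng.geometric(1.0 / spec.mean))


def _build_molecule(frag: RawFragment, strand: str, method: str) -> Molecule:
    pos = frag.cpg_pos
    if method == "dsLP":
        # fill-in extends the recessed 3' ends across both overhang regions;
        # the filled strand carries unmethylated C throughout the region
        mstart, mend = frag.start, frag.end
        in_mol = np.ones(len(pos), dtype=bool)
        if strand == "+":
            repair = pos >= frag.end - frag.j_right
        else:
            repair = pos < frag.start + frag.j_left
        state = frag.meth & ~repair
    else:  # ssLP: denature, ligate each strand at its own physical length
        if strand == "+":
            mstart, mend = frag.start, frag.end - frag.j_right
        else:
            mstart, mend = frag.start + frag.j_left, frag.end
        in_mol = (pos >= mstart) & (pos + 2 <= mend)
        repair = np.zeros(len(pos), dtype=bool)
        state = frag.meth.copy()
    return Molecule(
        chrom=frag.chrom,
        strand=strand,
        mstart=mstart,
        mend=mend,
        tissue=frag.tissue,
        frag_start=frag.start,
        frag_end=frag.end,
        cpg_pos=pos,
        in_mol=in_mol,
        state=state,
        repair=repair,
    )


def library_prep(
    frag: RawFragment,
    method: str,
    rng: np.random.Generator | None = None,
    emit: str = "sampled",
) -> list[Molecule]:
    """Prepare one fragment for sequencing.

    ``emit='sampled'`` (default) returns one molecule from a uniformly
    chosen strand, modelling which strand the sequencer happens to sample;
    ``emit='both'`` returns both strand molecules.
    """
    if method not in ("ssLP", "dsLP"):
        raise ValidationError(f"unknown library method: {method!r}")
    if emit == "both":
        return [_build_molecule(frag, "+", method), _build_molecule(frag, "-", method)]
    if emit != "sampled":
        raise ValidationError(f"unknown emit mode: {emit!r}")
    if rng is None:
        raise ValueError("emit='sampled' requires an rng")
    strand = "+" if rng.random() < 0.5 else "-"
    return [_build_molecule(frag, strand, method)]


def convert_and_read(
    molecule: Molecule, config: SimConfig, rng: np.random.Generator
) -> FragmentRecord:
    """Pass a molecule through enzymatic conversion and paired-end reading."""
    pos = molecule.cpg_pos
    k = len(pos)
    u = rng.random(k)
    reported_c = np.where(
        molecule.state, u < config.protection_rate, u < 1.0 - config.conversion_rate
    )

    if molecule.strand == "+":
        off5 = pos - molecule.mstart
    else:
        off5 = molecule.mend - 1 - pos
    off3 = (molecule.length - 1) - off5
    rl = config.read_length
    r1 = np.where((off5 >= 0) & (off5 < rl), off5, -1)
    r2 = np.where((off3 >= 0) & (off3 < rl), off3, -1)
    called = molecule.in_mol & ((r1 >= 0) | (r2 >= 0))
    r1 = np.where(called, r1, -1)
    r2 = np.where(called, r2, -1)

    pattern = "".join(
        "." if not c else ("C" if rc else "T") for c, rc in zip(called, reported_c)
    )
    repair_mask = molecule.repair & called

    n_chh = config.n_chh_per_fragment
    m = rng.binomial(n_chh, config.chh_meth) if n_chh else 0
    chh_meth_calls = (
        int(rng.binomial(m, config.protection_rate))
        + int(rng.binomial(n_chh - m, 1.0 - config.conversion_rate))
        if n_chh
        else 0
    )

    return FragmentRecord(
        chrom=molecule.chrom,
        start=molecule.frag_start,
        end=molecule.frag_end,
        tissue_origin=molecule.tissue,
        cpg_positions=pos,
        pattern=pattern,
        repair_mask=repair_mask,
        read1_pos=r1.astype(int),
        read2_pos=r2.astype(int),
        chh_meth_calls=chh_meth_calls,
        chh_total_calls=n_chh,
    )


def simulate_spikeins(
    config: SimConfig,
    n_lambda: int = 10_000,
    n_puc19: int = 10_000,
    rng: np.random.Generator | None = None,
) -> SpikeinSet:
    """Generate spike-in control calls through the conversion channel."""
    if n_lambda <= 0 or n_puc19 <= 0:
        raise ValidationError("spike-in call counts must be positive")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    lambda_is_c = rng.random(n_lambda) < 1.0 - config.conversion_rate
    puc19_is_c = rng.random(n_puc19) < config.protection_rate
    return SpikeinSet(lambda_is_c=lambda_is_c, puc19_is_c=puc19_is_c)


def simulate_sample(
    config: SimConfig,
    site_atlas: ReferenceAtlas,
    n_lambda: int = 10_000,
    n_puc19: int = 10_000,
) -> SampleDataset:
    """Run the full generative pipeline for one sample.

    Child random streams are spawned per stage so that two configs differing
    only in ``library`` share identical latent fragments and jagged ends.
    """
    root = np.random.SeedSequence(config.seed)
    s_frag, s_jag, s_read, s_spike = root.spawn(4)
    rng_frag = np.random.default_rng(s_frag)
    rng_jag = np.random.default_rng(s_jag)
    rng_read = np.random.default_rng(s_read)
    rng_spike = np.random.default_rng(s_spike)

    frags = sample_fragments(config, site_atlas, rng_frag)
    for f in frags:
        apply_jagged_ends(f, config.jag_prob, config.jag_length, rng_jag)

    records: list[FragmentRecord] = []
    for f in frags:
        for mol in library_prep(f, config.library, rng_read):
            records.append(convert_and_read(mol, config, rng_read))

    spikeins = simulate_spikeins(config, n_lambda, n_puc19, rng_spike)
    counts: dict[str, int] = {t: 0 for t in config.mixture}
    for f in frags:
        counts[f.tissue] += 1
    return SampleDataset(
        fragments=records, spikeins=spikeins, truth=config, realized_counts=counts
    )


def downsample(dataset: SampleDataset, target_n: int, seed: int) -> SampleDataset:
    """Uniform subsample of fragments without replacement; spike-ins kept."""
    n = dataset.n_fragments
    if target_n > n:
        raise ValidationError(f"cannot downsample {n} fragments to {target_n}")
    if target_n == n:
        kept = dataset.fragments
    else:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=target_n, replace=False))
        kept = [dataset.fragments[i] for i in idx]
    counts: dict[str, int] = {t: 0 for t in dataset.truth.mixture}
    for f in kept:
        counts[f.tissue_origin] = counts.get(f.tissue_origin, 0) + 1
    return SampleDataset(
        fragments=kept,
        spikeins=dataset.spikeins,
        truth=dataset.truth,
        realized_counts=counts,
    )
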