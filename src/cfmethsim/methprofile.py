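"""Methylation metrics from fragment call records.

Covers per-CpG-site counting (with 5' read trimming and mate-overlap
deduplication, mirroring standard methylation-extractor behaviour), global
CpG and CHH methylation, within-read M-bias profiles, and conversion-rate
QC from spike-in controls.

M-bias is computed on untrimmed calls (it is the diagnostic that motivates
trimming), whereas site counts honour the trim policy (they feed the
downstream analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .simulate import FragmentRecord, SpikeinSet

__all__ = [
    "TrimPolicy",
    "SiteCounts",
    "MBiasProfile",
    "extract_site_counts",
    "global_methylation",
    "chh_methylation",
    "mbias",
    "mbias_flatness",
    "mbias_monotone_residual",
    "conversion_qc",
]


@dataclass(frozen=True)
class TrimPolicy:
    """Base pairs ignored from the 5' end of each read.

    Typical analysis settings trim 2 bp from both reads for single-stranded
    libraries and 2/5 bp (read 1 / read 2) for end-repaired double-stranded
    libraries; how far the read-2 trim must reach depends on the overhang
    length distribution and is left to the user.
    """

    ignore_r1: int = 0
    ignore_r2: int = 0

    def __post_init__(self):
        if self.ignore_r1 < 0 or self.ignore_r2 < 0:
            raise ValidationError("trim lengths must be >= 0")


@dataclass
class SiteCounts:
    """Methylated / total call counts per CpG site."""

    counts: dict[tuple[str, int], list[int]] = field(default_factory=dict)

    def add(self, chrom: str, pos: int, methylated: bool, times: int = 1) -> None:
        rec = self.counts.setdefault((chrom, pos), [0, 0])
        rec[0] += times if methylated else 0
        rec[1] += times

    def n_meth(self, chrom: str, pos: int) -> int:
        return self.counts.get((chrom, pos), [0, 0])[0]

    def n_total(self, chrom: str, pos: int) -> int:
        return self.counts.get((chrom, pos), [0, 0])[1]

    @property
    def total_calls(self) -> int:
        return sum(v[1] for v in self.counts.values())

    def to_dataframe(self) -> pd.DataFrame:
        """bedGraph-style table: chrom, start, end, meth_fraction, n_meth, n_total."""
        rows = [
            (c, p, p + 1, (m / t if t else np.nan), m, t)
            for (c, p), (m, t) in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "meth_fraction", "n_meth", "n_total"]
        )

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class MBiasProfile:
    """Methylation fraction by position within a read.

    ``meth_fraction[p]`` is NaN (undefined, not zero) where no call was
    observed at position ``p``.
    """

    read_number: int
    meth_fraction: np.ndarray
    call_count: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read": self.read_number,
                "position": np.arange(len(self.call_count)),
                "meth_fraction": self.meth_fraction,
                "call_count": self.call_count,
            }
        )

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def extract_site_counts(
    fragments: Iterable[FragmentRecord],
    trim: TrimPolicy = TrimPolicy(0, 0),
    dedup_overlap: bool = True,
) -> SiteCounts:
    """Tally per-site methylated/total calls.

    A call survives on read 1 if its read-1 position is at or beyond the
    read-1 trim, likewise for read 2.  When ``dedup_overlap`` is set, a CpG
    surviving on both mates is counted once (the read-1 call wins, mirroring
    common extractor behaviour); otherwise it contributes twice.
    """
    counts = SiteCounts()
    for frag in fragments:
        for i, call in enumerate(frag.pattern):
            if call == ".":
                continue
            on_r1 = frag.read1_pos[i] >= trim.ignore_r1
            on_r2 = frag.read2_pos[i] >= trim.ignore_r2
            if not (on_r1 or on_r2):
                continue
            times = 1 if dedup_overlap else int(on_r1) + int(on_r2)
            counts.add(frag.chrom, int(frag.cpg_positions[i]), call == "C", times)
    return counts


def global_methylation(counts: SiteCounts) -> float:
    """Overall CpG methylation: sum(n_meth) / sum(n_total)."""
    total = counts.total_calls
    if total == 0:
        raise DegenerateDataError("no informative CpG calls; global methylation undefined")
    meth = sum(v[0] for v in counts.counts.values())
    return meth / total


def chh_methylation(fragments: Iterable[FragmentRecord]) -> float:
    """Apparent CHH methylation: methylated CHH calls / total CHH calls.

    Human CHH methylation is near zero, so this fraction is dominated by
    conversion failure and serves as an internal conversion check.
    """
    meth = tot = 0
    for frag in fragments:
        meth += frag.chh_meth_calls
        tot += frag.chh_total_calls
    if tot == 0:
        raise DegenerateDataError("no CHH calls present")
    return meth / tot


def mbias(
    fragments: Iterable[FragmentRecord], read_number: int, read_length: int
) -> MBiasProfile:
    """Within-read methylation profile for read 1 or read 2 (untrimmed)."""
    if read_number not in (1, 2):
        raise ValueError("read_number must be 1 or 2")
    n_meth = np.zeros(read_length, dtype=np.int64)
    n_tot = np.zeros(read_length, dtype=np.int64)
    for frag in fragments:
        rpos = frag.read1_pos if read_number == 1 else frag.read2_pos
        for i, call in enumerate(frag.pattern):
            p = rpos[i]
            if call == "." or p < 0:
                continue
            n_tot[p] += 1
            if call == "C":
                n_meth[p] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_tot > 0, n_meth / np.maximum(n_tot, 1), np.nan)
    return MBiasProfile(read_number=read_number, meth_fraction=frac, call_count=n_tot)


def mbias_flatness(profile: MBiasProfile) -> tuple[float, np.ndarray]:
    """Per-position z-scores of the profile against its pooled mean.

    Returns ``(max_abs_z, z)`` where ``z[p] = (f[p] - fbar) / SE(f[p])``
    with the binomial standard error at the pooled mean.  Positions with no
    calls are NaN and excluded from the maximum.
    """
    tot = profile.call_count
    if tot.sum() == 0:
        raise DegenerateDataError("empty M-bias profile")
    fbar = np.nansum(profile.meth_fraction * tot) / tot.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(fbar * (1 - fbar) / np.maximum(tot, 1))
        z = np.where(tot > 0, (profile.meth_fraction - fbar) / se, np.nan)
    return float(np.nanmax(np.abs(z))), z


def mbias_monotone_residual(
    profile: MBiasProfile, upto: int | None = None
) -> tuple[float, np.ndarray]:
    """Residual of the best monotone non-decreasing fit over positions [0, upto).

    Fits weighted isotonic regression (pool-adjacent-violators) to the
    profile and returns the call-weighted RMS residual in units of the
    per-position binomial SE, plus the fitted values.  A read-2 profile
    shaped by 5'-overhang fill-in is monotone non-decreasing over the
    fill-in region, so small residuals indicate the expected shape.
    """
    stop = len(profile.call_count) if upto is None else upto
    sel = slice(0, stop)
    w = profile.call_count[sel].astype(float)
    y = profile.meth_fraction[sel]
    ok = (w > 0) & np.isfinite(y)
    if ok.sum() < 2:
        raise DegenerateDataError("too few informative positions for a shape test")
    fit = _pava(y[ok], w[ok])
    se = np.sqrt(np.maximum(fit * (1 - fit), 1e-12) / w[ok])
    z = (y[ok] - fit) / se
    rms = float(np.sqrt(np.average(z**2, weights=w[ok])))
    fitted = np.full(stop, np.nan)
    fitted[ok] = fit
    return rms, fitted


def _pava(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators for a non-decreasing weighted LS fit."""
    y = y.astype(float).copy()
    w = w.astype(float).copy()
    # blocks as (value, weight, count)
    vals: list[float] = []
    wts: list[float] = []
    cnt: list[int] = []
    for yi, wi in zip(y, w):
        vals.append(yi)
        wts.append(wi)
        cnt.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wts[-2] += wts[-1]
            cnt[-2] += cnt[-1]
            vals[-2] = v
            vals.pop()
            wts.pop()
            cnt.pop()
    return np.repeat(vals, cnt)


def conversion_qc(spikeins: SpikeinSet) -> tuple[float, float]:
    """Estimate (conversion rate, protection rate) from spike-ins.

    Conversion rate = fraction of unmethylated lambda cytosines reported T;
    protection rate = fraction of methylated pUC19 cytosines reported C.
    """
    if spikeins.n_lambda == 0 or spikeins.n_puc19 == 0:
        raise DegenerateDataError("empty spike-in set")
    conversion = 1.0 - float(np.mean(spikeins.lambda_is_c))
    protection = float(np.mean(spikeins.puc19_is_c))
    return conversion, protection
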