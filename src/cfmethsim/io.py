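"""Text serialization of fragment call records (PAT-like TSV).

One row per sequenced molecule.  Columns extend the compact per-fragment
pattern format (chrom, first CpG position, pattern, count) with everything
needed to reproduce read-position bookkeeping:

    chrom, pos, pattern, count, offsets, repair_rle, r1_pos, r2_pos,
    frag_start, frag_end, tissue, chh_meth, chh_total

* ``offsets`` — comma-separated CpG offsets from ``pos`` (first is 0);
* ``repair_rle`` — run-length encoding of the end-repair mask, e.g.
  ``0:3,1:2`` for three unrepaired then two repaired positions;
* ``r1_pos`` / ``r2_pos`` — comma-separated bp offsets from each read's 5'
  start, ``*`` where the read does not cover the CpG.

A ``#read_length=N`` header line records the simulated read length.  Gzip
is used when the path ends in ``.gz``.
"""

from __future__ import annotations

import gzip
from typing import Iterable

import numpy as np

from .errors import ParseError
from .simulate import FragmentRecord, SpikeinSet

__all__ = ["write_pat", "read_pat", "write_spikeins", "read_spikeins"]

_COLUMNS = [
    "chrom", "pos", "pattern", "count", "offsets", "repair_rle",
    "r1_pos", "r2_pos", "frag_start", "frag_end", "tissue", "chh_meth", "chh_total",
]


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _rle_encode(mask: np.ndarray) -> str:
    if len(mask) == 0:
        return "-"
    runs = []
    cur, count = bool(mask[0]), 0
    for v in mask:
        if bool(v) == cur:
            count += 1
        else:
            runs.append(f"{int(cur)}:{count}")
            cur, count = bool(v), 1
    runs.append(f"{int(cur)}:{count}")
    return ",".join(runs)


def _rle_decode(text: str, n: int) -> np.ndarray:
    if text == "-":
        return np.zeros(n, dtype=bool)
    out = []
    for run in text.split(","):
        val, count = run.split(":")
        out.extend([bool(int(val))] * int(count))
    if len(out) != n:
        raise ParseError(f"repair RLE length {len(out)} does not match {n} CpGs")
    return np.array(out, dtype=bool)


def _pos_encode(arr: np.ndarray) -> str:
    if len(arr) == 0:
        return "-"
    return ",".join("*" if p < 0 else str(int(p)) for p in arr)


def _pos_decode(text: str, n: int) -> np.ndarray:
    if text == "-":
        return np.full(n, -1, dtype=int)
    vals = [-1 if tok == "*" else int(tok) for tok in text.split(",")]
    if len(vals) != n:
        raise ParseError(f"read-span spec length {len(vals)} does not match {n} CpGs")
    return np.array(vals, dtype=int)


def write_pat(fragments: Iterable[FragmentRecord], path, read_length: int | None = None) -> None:
    """Write fragment records to a PAT-like TSV (gzip by '.gz' suffix)."""
    with _open_text(path, "wt") as fh:
        if read_length is not None:
            fh.write(f"#read_length={read_length}\n")
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for f in fragments:
            first = int(f.cpg_positions[0]) if len(f.cpg_positions) else f.start
            offsets = (
                ",".join(str(int(p) - first) for p in f.cpg_positions)
                if len(f.cpg_positions)
                else "-"
            )
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        str(first),
                        f.pattern if f.pattern else "-",
                        "1",
                        offsets,
                        _rle_encode(f.repair_mask),
                        _pos_encode(f.read1_pos),
                        _pos_encode(f.read2_pos),
                        str(f.start),
                        str(f.end),
                        f.tissue_origin,
                        str(f.chh_meth_calls),
                        str(f.chh_total_calls),
                    ]
                )
                + "\n"
            )


def read_pat(path) -> tuple[list[FragmentRecord], int | None]:
    """Read fragment records written by :func:`write_pat`.

    Returns (fragments, read_length); read_length is None if the header is
    absent.
    """
    fragments: list[FragmentRecord] = []
    read_length: int | None = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#read_length="):
                read_length = int(line.split("=", 1)[1])
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(_COLUMNS)} columns, got {len(parts)}"
                )
            try:
                first = int(parts[1])
                pattern = "" if parts[2] == "-" else parts[2]
                count = int(parts[3])
                if parts[4] == "-":
                    cpg_pos = np.array([], dtype=int)
                else:
                    cpg_pos = first + np.array([int(o) for o in parts[4].split(",")])
                n = len(cpg_pos)
                rec = FragmentRecord(
                    chrom=parts[0],
                    start=int(parts[8]),
                    end=int(parts[9]),
                    tissue_origin=parts[10],
                    cpg_positions=cpg_pos,
                    pattern=pattern,
                    repair_mask=_rle_decode(parts[5], n),
                    read1_pos=_pos_decode(parts[6], n),
                    read2_pos=_pos_decode(parts[7], n),
                    chh_meth_calls=int(parts[11]),
                    chh_total_calls=int(parts[12]),
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            fragments.extend([rec] * count)
    return fragments, read_length


def write_spikeins(spikeins: SpikeinSet, path) -> None:
    """Write spike-in calls as TSV: control, true_state, reported_state."""
    with _open_text(path, "wt") as fh:
        fh.write("control\ttrue_state\treported_state\n")
        for is_c in spikeins.lambda_is_c:
            fh.write(f"lambda\tunmethylated\t{'C' if is_c else 'T'}\n")
        for is_c in spikeins.puc19_is_c:
            fh.write(f"pUC19\tmethylated\t{'C' if is_c else 'T'}\n")


def read_spikeins(path) -> SpikeinSet:
    lam, puc = [], []
    with _open_text(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns")
            is_c = parts[2] == "C"
            (lam if parts[0] == "lambda" else puc).append(is_c)
    return SpikeinSet(
        lambda_is_c=np.array(lam, dtype=bool), puc19_is_c=np.array(puc, dtype=bool)
    )
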