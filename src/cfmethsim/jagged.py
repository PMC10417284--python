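"""Jagged Index-Unmethylated (JI-U).

End repair in double-stranded library preparation fills 5' overhangs with
unmethylated cytosines.  Because the prepared molecule is read from both
ends, the fill-in product sits at the 3' terminus of the molecule — the
region covered by the *first* bases sequenced of read 2.  Contrasting the
mean CpG methylation there (M2) against the matched window at the 5' start
of read 1 (M1, untouched by repair) quantifies jaggedness:

    JI-U = (M1 - M2) / M1 * 100   [percent]

Both window readings of "the 30 bp at the 3' end via read 2" are supported:

* ``r2_window='five_prime'`` (default): the first 30 sequenced bp of read 2,
  which physically lie at the molecule's 3' end and carry the fill-in
  signal;
* ``r2_window='three_prime'``: the last 30 sequenced bp of read 2, i.e. the
  window nearest read 2's own 3' end, which lies in the molecule interior
  and is insensitive to fill-in by construction.

Calls are pooled across all fragments within each window before the ratio
is formed, which keeps the statistic stable when individual reads carry few
CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import ValidationError
from .simulate import FragmentRecord

__all__ = ["JaggedIndexResult", "jagged_index_u"]

DEFAULT_WINDOW = 30
DEFAULT_MIN_CALLS = 50


@dataclass
class JaggedIndexResult:
    """Pooled window methylation and the resulting jagged index.

    ``ji_u`` is None when undefined (M1 = 0 or fewer than ``min_calls``
    informative calls in either window); it is never silently reported as 0.
    """

    m1: float
    m2: float
    ji_u: float | None
    n_calls_1: int
    n_calls_2: int

    @property
    def defined(self) -> bool:
        return self.ji_u is not None


def jagged_index_u(
    fragments: Iterable[FragmentRecord],
    window: int = DEFAULT_WINDOW,
    min_calls: int = DEFAULT_MIN_CALLS,
    r2_window: str = "five_prime",
    read_length: int | None = None,
) -> JaggedIndexResult:
    """Compute JI-U from fragment records.

    M1 pools CpG calls at read-1 positions [0, window); M2 pools read-2
    calls in the selected window (see module docstring).  For
    ``r2_window='three_prime'`` the read length must be given to locate the
    window.
    """
    if window <= 0:
        raise ValidationError("window must be positive")
    if r2_window not in ("five_prime", "three_prime"):
        raise ValidationError(f"unknown r2_window: {r2_window!r}")
    if r2_window == "three_prime" and read_length is None:
        raise ValidationError("r2_window='three_prime' requires read_length")

    meth1 = tot1 = meth2 = tot2 = 0
    for frag in fragments:
        for i, call in enumerate(frag.pattern):
            if call == ".":
                continue
            p1 = frag.read1_pos[i]
            if 0 <= p1 < window:
                tot1 += 1
                meth1 += call == "C"
            p2 = frag.read2_pos[i]
            if p2 >= 0:
                if r2_window == "five_prime":
                    in_w2 = p2 < window
                else:
                    in_w2 = p2 >= read_length - window
                if in_w2:
                    tot2 += 1
                    meth2 += call == "C"

    m1 = meth1 / tot1 if tot1 else 0.0
    m2 = meth2 / tot2 if tot2 else 0.0
    if tot1 < min_calls or tot2 < min_calls or m1 == 0.0:
        ji = None
    else:
        ji = (m1 - m2) / m1 * 100.0
    return JaggedIndexResult(m1=m1, m2=m2, ji_u=ji, n_calls_1=tot1, n_calls_2=tot2)
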