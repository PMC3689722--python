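"""Time-unit kappa: chance-corrected inter-coder agreement over seconds.

Two coders assign one category per second to the same recording.  Plain
Cohen's kappa over seconds punishes small temporal misalignments (a coder
marking a behavior change one second late), so agreement is assessed with
a tolerance window: second ``t`` of coder A counts as agreeing when coder B
holds the same code at any second within ``tolerance_seconds`` of ``t``.

An agreement confusion tally is built over all seconds: agreeing seconds
land on the diagonal under A's code; disagreeing seconds land in cell
(A's code, B's code at t).  Kappa is then the usual
``(po - pe) / (1 - pe)`` with the expected agreement ``pe`` computed from
the tally's marginals.  Tolerant matches are not consumed: one B-second may
justify agreement for several A-seconds (the one-to-one alternative is a
documented open choice; this scheme is the simpler and is stated in the
methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["KappaResult", "time_unit_kappa"]


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    tolerance_seconds: int


def time_unit_kappa(
    codes_a: Sequence[int],
    codes_b: Sequence[int],
    tolerance_seconds: int = 2,
) -> KappaResult:
    """Compute time-unit kappa between two equally long code sequences.

    Parameters
    ----------
    codes_a, codes_b
        The two coders' per-second code sequences (same length, same domain).
    tolerance_seconds
        Symmetric window, in whole seconds, within which a matching code in
        the other stream counts as agreement.  Default 2.
    """
    if len(codes_a) != len(codes_b):
        raise ValueError("sequences must have equal length")
    n = len(codes_a)
    if n == 0:
        raise ValueError("sequences must be non-empty")
    if tolerance_seconds < 0:
        raise ValueError("tolerance_seconds must be >= 0")

    codes = sorted(set(codes_a) | set(codes_b))
    index = {c: k for k, c in enumerate(codes)}
    k = len(codes)
    tally = [[0] * k for _ in range(k)]
    for t in range(n):
        a = codes_a[t]
        lo = max(0, t - tolerance_seconds)
        hi = min(n, t + tolerance_seconds + 1)
        if any(codes_b[u] == a for u in range(lo, hi)):
            tally[index[a]][index[a]] += 1
        else:
            tally[index[a]][index[codes_b[t]]] += 1

    po = sum(tally[i][i] for i in range(k)) / n
    row = [sum(tally[i]) for i in range(k)]
    col = [sum(tally[i][j] for i in range(k)) for j in range(k)]
    pe = sum(row[i] * col[i] for i in range(k)) / (n * n)
    if pe >= 1.0:  # both coders constant and identical
        kappa = 1.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    return KappaResult(kappa, po, pe, tolerance_seconds)
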