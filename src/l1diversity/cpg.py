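"""CpG dinucleotide analytics for L1 components.

CpG dinucleotides erode quickly in mammalian genomes (methyl-C deaminates
to T), so the CpG/GpC ratio of a component is a methylation-robust proxy
for CpG retention, and CpG islands mark regions that escaped erosion.
Islands follow the classical definition: at least 200 bp with GC fraction
above 50% and observed/expected CpG above 0.6, located by a sliding
window and merged into maximal intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CpGReport",
    "count_dinucleotides",
    "cpg_gpc_ratio",
    "find_cpg_islands",
    "pearson_p_from_r",
    "correlate_cpg_vs_rate",
]


@dataclass
class CpGReport:
    """CpG/GpC counts, their ratio and island calls for one component."""

    component: str
    cpg_count: int
    gpc_count: int
    ratio: float | None  # None when gpc_count == 0
    islands: list[tuple[int, int]]


def count_dinucleotides(seq: str) -> tuple[int, int]:
    """(CpG count, GpC count) by an overlapping scan of adjacent pairs.

    Pairs containing anything but A/C/G/T (e.g. N) do not count.
    """
    if not seq:
        raise ValueError("empty sequence")
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    cpg = int(((arr[:-1] == b"C") & (arr[1:] == b"G")).sum())
    gpc = int(((arr[:-1] == b"G") & (arr[1:] == b"C")).sum())
    return cpg, gpc


def cpg_gpc_ratio(seq: str) -> float | None:
    """CpG/GpC ratio of a sequence; None when there is no GpC."""
    cpg, gpc = count_dinucleotides(seq)
    return cpg / gpc if gpc > 0 else None


def _window_stats(seq_arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative counts of C, G and CpG starts (for O(1) window queries)."""
    is_c = (seq_arr == b"C").astype(np.int64)
    is_g = (seq_arr == b"G").astype(np.int64)
    is_cpg = np.zeros(len(seq_arr), dtype=np.int64)
    is_cpg[:-1] = (seq_arr[:-1] == b"C") & (seq_arr[1:] == b"G")
    return np.cumsum(is_c), np.cumsum(is_g), np.cumsum(is_cpg)


def _interval_ok(
    start: int,
    end: int,
    cum_c: np.ndarray,
    cum_g: np.ndarray,
    cum_cpg: np.ndarray,
    gc_min: float,
    oe_min: float,
) -> bool:
    length = end - start
    n_c = cum_c[end - 1] - (cum_c[start - 1] if start else 0)
    n_g = cum_g[end - 1] - (cum_g[start - 1] if start else 0)
    # CpG starts fully inside [start, end): start positions start..end-2
    n_cpg = cum_cpg[end - 2] - (cum_cpg[start - 1] if start else 0)
    if (n_c + n_g) / length <= gc_min:
        return False
    expected = n_c * n_g / length
    if expected == 0:
        return False
    return n_cpg / expected > oe_min


def find_cpg_islands(
    seq: str, min_len: int = 200, gc_min: float = 0.50, oe_min: float = 0.60
) -> list[tuple[int, int]]:
    """CpG islands as 0-based half-open intervals.

    A ``min_len`` window starting at every position qualifies iff its GC
    fraction exceeds ``gc_min`` and its observed/expected CpG — with
    expected = (#C x #G) / window length — exceeds ``oe_min`` (strict
    inequalities).  Overlapping or adjacent qualifying windows merge into
    maximal intervals; each merged interval is re-verified against both
    criteria and trimmed from its 3' end until it passes (dropped if it
    shrinks below ``min_len``).
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    L = len(seq)
    if L < min_len:
        return []
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    cum_c, cum_g, cum_cpg = _window_stats(arr)
    qualifying = [
        s
        for s in range(L - min_len + 1)
        if _interval_ok(s, s + min_len, cum_c, cum_g, cum_cpg, gc_min, oe_min)
    ]
    if not qualifying:
        return []
    # merge runs of starts whose windows overlap or touch
    merged: list[list[int]] = [[qualifying[0], qualifying[0] + min_len]]
    for s in qualifying[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = s + min_len
        else:
            merged.append([s, s + min_len])
    islands: list[tuple[int, int]] = []
    for start, end in merged:
        while end - start >= min_len and not _interval_ok(
            start, end, cum_c, cum_g, cum_cpg, gc_min, oe_min
        ):
            end -= 1
        if end - start >= min_len:
            islands.append((start, end))
    return islands


def cpg_report(
    component: str,
    seq: str,
    min_len: int = 200,
    gc_min: float = 0.50,
    oe_min: float = 0.60,
) -> CpGReport:
    cpg, gpc = count_dinucleotides(seq)
    return CpGReport(
        component=component,
        cpg_count=cpg,
        gpc_count=gpc,
        ratio=cpg / gpc if gpc > 0 else None,
        islands=find_cpg_islands(seq, min_len, gc_min, oe_min) if len(seq) >= min_len else [],
    )


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r at sample size n.

    Uses t = r sqrt((n-2)/(1-r^2)) against Student's t with n-2 df.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def correlate_cpg_vs_rate(cpg_ratios, ages) -> tuple[float, float]:
    """Pearson correlation of per-component CpG content against age/rate.

    Returns (r, two-tailed p).  Requires equal-length vectors with n >= 3.
    """
    x = np.asarray(cpg_ratios, dtype=float)
    y = np.asarray(ages, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, pearson_p_from_r(r, n)
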