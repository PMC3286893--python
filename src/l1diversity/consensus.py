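"""Subfamily consensus building and diagnostic classification.

Elements are brought into a common consensus coordinate frame by global
pairwise alignment against a reference, a majority-rule consensus is
voted per column, and copies are assigned to subfamilies by their
diagnostic substitutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align

from .io import L1Element

__all__ = [
    "ColumnAlignment",
    "DiagnosticSet",
    "ClassificationResult",
    "align_to_reference",
    "majority_consensus",
    "classify",
    "read_diagnostics",
]


@dataclass
class ColumnAlignment:
    """Equal-length gapped rows in reference (consensus) coordinates."""

    member_ids: list[str]
    rows: list[str]
    reference: str | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(widths)}")
        if len(self.member_ids) != len(self.rows):
            raise ValueError("member_ids and rows differ in length")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def slice(self, start: int, end: int) -> "ColumnAlignment":
        return ColumnAlignment(
            member_ids=list(self.member_ids),
            rows=[r[start:end] for r in self.rows],
            reference=self.reference[start:end] if self.reference else None,
        )

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(
            self.n_rows, self.width
        )


@dataclass(frozen=True)
class DiagnosticSet:
    """Diagnostic substitutions defining one subfamily."""

    subfamily: str
    sites: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.sites]
        if len(positions) != len(set(positions)):
            raise ValueError(f"diagnostics for {self.subfamily!r}: duplicate positions")


@dataclass(frozen=True)
class ClassificationResult:
    subfamily: str
    matched_fraction: float
    ambiguous: bool


def _make_aligner(
    match: float = 1.0, mismatch: float = -1.0, gap_open: float = -5.0, gap_extend: float = -1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_to_reference(
    elements: Sequence[L1Element],
    reference: str,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> ColumnAlignment:
    """Globally align each element to the reference, in reference coordinates.

    Affine-gap Needleman-Wunsch (default +1/-1, open -5, extend -1).
    Columns where the reference carries a gap (insertions in the element)
    are dropped so every row has exactly the reference's length.  Elements
    whose length already equals the reference's are taken as collinear —
    indel-free input therefore reproduces itself exactly.  An element
    shorter than half the reference elicits a warning but is still aligned.
    """
    if not reference:
        raise ValueError("reference sequence is empty")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    ids, rows = [], []
    for el in elements:
        if len(el.sequence) < 0.5 * len(reference):
            warnings.warn(
                f"element {el.id!r} is shorter than 50% of the reference "
                f"({len(el.sequence)} vs {len(reference)} bp)",
                stacklevel=2,
            )
        if len(el.sequence) == len(reference):
            row = el.sequence
        else:
            aln = aligner.align(reference, el.sequence)[0]
            ref_aln, el_aln = str(aln[0]), str(aln[1])
            row = "".join(q for r, q in zip(ref_aln, el_aln) if r != "-")
        ids.append(el.id)
        rows.append(row)
    return ColumnAlignment(member_ids=ids, rows=rows, reference=reference)


def majority_consensus(alignment: ColumnAlignment) -> str:
    """Majority-rule consensus: per column the most frequent of A/C/G/T.

    Gaps and N never vote; a column with no A/C/G/T votes emits N.  Ties
    resolve by the fixed base order A < C < G < T.
    """
    arr = alignment.to_array()
    counts = np.stack([(arr == bytes(b, "ascii")).sum(axis=0) for b in "ACGT"])
    best = counts.argmax(axis=0)  # argmax takes the first maximum: A<C<G<T
    consensus = np.frombuffer(b"ACGT", dtype="S1")[best].copy()
    consensus[counts.sum(axis=0) == 0] = b"N"
    return consensus.tobytes().decode()


def classify(
    row: str | L1Element, diagnostics: Sequence[DiagnosticSet]
) -> ClassificationResult:
    """Assign a copy (aligned to the consensus frame) to a subfamily.

    The subfamily whose diagnostic sites all match wins; among several
    full matches the one with the most diagnostic sites (most derived)
    wins.  With no full match, the best-matching fraction wins and the
    result is flagged ambiguous.  Ties resolve by subfamily name.
    """
    if not diagnostics:
        raise ValueError("empty diagnostics")
    seq = row.sequence if isinstance(row, L1Element) else row
    scored: list[tuple[float, int, str]] = []
    for dset in diagnostics:
        if not dset.sites:
            raise ValueError(f"diagnostics for {dset.subfamily!r} are empty")
        hits = sum(
            1 for pos, base in dset.sites if pos < len(seq) and seq[pos] == base
        )
        scored.append((hits / len(dset.sites), len(dset.sites), dset.subfamily))
    full = [s for s in scored if s[0] == 1.0]
    if full:
        _, _, name = max(full, key=lambda s: (s[1], s[2]))
        frac = 1.0
        ambiguous = False
    else:
        frac, _, name = max(scored, key=lambda s: (s[0], s[1], s[2]))
        ambiguous = True
    return ClassificationResult(subfamily=name, matched_fraction=frac, ambiguous=ambiguous)


def read_diagnostics(path: str | Path) -> list[DiagnosticSet]:
    """Read diagnostic sets from TSV (subfamily, position, base)."""
    sites: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, pos, base = line.split("\t")[:3]
            sites.setdefault(name, []).append((int(pos), base.upper()))
    if not sites:
        raise ValueError(f"no diagnostic sites in {path}")
    return [DiagnosticSet(subfamily=k, sites=tuple(v)) for k, v in sites.items()]
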