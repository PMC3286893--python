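"""Reading and writing the formats the pipeline touches.

Sequences travel as FASTA, component intervals and transcription-factor
binding-site windows as BED-like TSV (0-based, half-open), reports and
ground truth as JSON.  The record types defined here (:class:`L1Element`,
:class:`RegionAnnotation`) are the currency of every downstream module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "L1Element",
    "RegionAnnotation",
    "read_fasta",
    "write_fasta",
    "read_regions",
    "write_regions",
    "read_components",
    "write_components",
]

# IUPAC nucleotide one-letter codes.  Ambiguity codes are accepted on input
# and collapsed to N; anything outside this set is rejected.
_IUPAC = set("ACGTUNRYSWKMBDHV")
_AMBIGUOUS = set("RYSWKMBDHV")

COMPONENT_ORDER = ("5UTR", "ORF1", "ORF2", "3UTR")


@dataclass
class L1Element:
    """One L1 sequence copy.

    Parameters
    ----------
    id : str
        Unique identifier of the copy.
    subfamily : str or None
        Subfamily label (e.g. ``Ta1``); ``None`` when unknown.
    sequence : str
        Uppercase nucleotides over ``{A, C, G, T, N}``.
    components : mapping of str -> (int, int)
        Component label -> 0-based half-open interval on the element's own
        coordinates.  Intervals must be in range and non-overlapping.
    """

    id: str
    subfamily: str | None
    sequence: str
    components: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"element {self.id!r}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"element {self.id!r}: non-ACGTN characters {sorted(bad)}"
            )
        ivs = sorted(self.components.values())
        for start, end in ivs:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(
                    f"element {self.id!r}: interval ({start}, {end}) outside "
                    f"[0, {len(self.sequence)})"
                )
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"element {self.id!r}: overlapping component intervals")

    def component_seq(self, name: str) -> str:
        start, end = self.components[name]
        return self.sequence[start:end]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RegionAnnotation:
    """A named window on the 5' UTR consensus (e.g. a YY1 binding site)."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.name!r}: start {self.start} >= end {self.end}")
        if self.start < 0:
            raise ValueError(f"region {self.name!r}: negative start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"region {self.name!r}: strand must be + or -")

    @property
    def width(self) -> int:
        return self.end - self.start


def _clean_sequence(raw: str, record_name: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _IUPAC - {"-"}
    if bad:
        raise ValueError(
            f"record {record_name!r}: non-IUPAC characters {sorted(bad)}"
        )
    return "".join("N" if c in _AMBIGUOUS else c for c in seq if c != "-")


def read_fasta(path: str | Path) -> list[L1Element]:
    """Read a multi-FASTA of L1 copies.

    Headers of the form ``subfamily|id`` populate the subfamily label;
    plain headers give elements with unknown subfamily.  Sequences are
    uppercased and U is mapped to T; IUPAC ambiguity codes become N.
    Raises ``ValueError`` on an empty file, a duplicate id or a
    non-IUPAC character, naming the offending record.
    """
    path = Path(path)
    elements: list[L1Element] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "|" in header:
            subfamily, elem_id = header.split("|", 1)
        else:
            subfamily, elem_id = None, header
        if header in seen:
            raise ValueError(f"duplicate FASTA header {header!r} in {path}")
        seen.add(header)
        seq = _clean_sequence(str(rec.seq), header)
        elements.append(L1Element(id=elem_id, subfamily=subfamily, sequence=seq))
    if not elements:
        raise ValueError(f"no FASTA records in {path}")
    return elements


def write_fasta(path: str | Path, elements: Sequence[L1Element]) -> None:
    """Write elements as multi-FASTA with ``subfamily|id`` headers."""
    records = []
    for el in elements:
        header = f"{el.subfamily}|{el.id}" if el.subfamily else el.id
        records.append(SeqRecord(Seq(el.sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_regions(path: str | Path, frame_length: int = 897) -> list[RegionAnnotation]:
    """Read a BED-like TSV of annotated windows (name, start, end, strand).

    Coordinates are 0-based half-open on the 5' UTR consensus frame of
    length ``frame_length``.  Regions may overlap each other (TF sites sit
    inside the promoter window) but must fit the frame and carry unique
    names.  The result is sorted by start.
    """
    path = Path(path)
    regions: list[RegionAnnotation] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected name<TAB>start<TAB>end[<TAB>strand]")
            name, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[3] if len(parts) > 3 else "+"
            if name in names:
                raise ValueError(f"{path}:{lineno}: duplicate region name {name!r}")
            names.add(name)
            region = RegionAnnotation(name=name, start=start, end=end, strand=strand)
            if region.end > frame_length:
                raise ValueError(
                    f"{path}:{lineno}: region {name!r} end {end} exceeds frame length {frame_length}"
                )
            regions.append(region)
    return sorted(regions, key=lambda r: (r.start, r.name))


def write_regions(path: str | Path, regions: Sequence[RegionAnnotation]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.name}\t{r.start}\t{r.end}\t{r.strand}\n")


def read_components(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a components TSV (name, start, end; 0-based half-open)."""
    out: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, start, end = line.split("\t")[:3]
            if name in out:
                raise ValueError(f"{path}:{lineno}: duplicate component {name!r}")
            start_i, end_i = int(start), int(end)
            if start_i >= end_i or start_i < 0:
                raise ValueError(f"{path}:{lineno}: bad interval ({start_i}, {end_i})")
            out[name] = (start_i, end_i)
    if not out:
        raise ValueError(f"no components in {path}")
    return out


def write_components(path: str | Path, components: Mapping[str, tuple[int, int]]) -> None:
    with open(path, "w") as fh:
        for name, (start, end) in components.items():
            fh.write(f"{name}\t{start}\t{end}\n")


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
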