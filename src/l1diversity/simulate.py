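"""Synthetic L1 family generator with known ground truth.

Emulates a family of full-length LINE-1 retrotransposons: an ancestral
consensus partitioned into the four canonical components (5'UTR, ORF1,
ORF2, 3'UTR), a set of subfamilies that each descend from the consensus
plus their diagnostic substitutions, and independently evolved copies
under a neutral per-site molecular clock with optional CpG
hypermutability.  Because every copy is an independent descendant of the
subfamily founder (a star genealogy), the divergence-based and
network-based age estimators downstream are estimating a quantity the
generator knows exactly.

Mutation model
--------------
Each site of a copy receives ``k ~ Poisson(mu)`` substitution events,
where ``mu = age_myr * base_rate * relative_rate`` of the component.
Events are applied as a jump chain: at ordinary sites each event moves
uniformly to one of the 3 alternative bases; at the cytosine of an
ancestral CpG the C->T transition is ``cpg_rate_multiplier``-fold
elevated (and mirrored as G->A at the guanine), so the event rate there
is ``mu * (2 + m) / 3``.  Multiple hits collapse to the final state.
There are no indels: copy coordinates equal consensus coordinates by
construction, and a separate alignment stressor is deliberately out of
scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.linalg import expm

from .io import L1Element, write_components, write_fasta

__all__ = [
    "ComponentSpec",
    "SubfamilySpec",
    "SimulationConfig",
    "default_config",
    "generate_ancestral_consensus",
    "evolve_copies",
    "simulate_family",
    "SimulationResult",
    "write_simulation",
    "load_config",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

# Default component lengths of a full-length human L1 element (bp).
DEFAULT_LENGTHS = {"5UTR": 897, "ORF1": 1017, "ORF2": 3828, "3UTR": 202}

# Default relative substitution rates per component, scaled so the
# neutrally evolving reference segment (partial ORF2 + 3'UTR) has rate 1.
# The 5'UTR clocks fastest, the 3'UTR next, the ORFs near-neutral.
DEFAULT_RELATIVE_RATES = {"5UTR": 1.787, "ORF1": 1.114, "ORF2": 1.058, "3UTR": 1.399}

# Default CpG dinucleotide densities (per 100 bp): highest in the
# promoter-bearing 5'UTR, lowest in ORF2.
DEFAULT_CPG_DENSITY = {"5UTR": 3.0, "ORF1": 1.0, "ORF2": 0.5, "3UTR": 0.8}

# Six-subfamily taxonomy: (name, copy count, age in myr).  Ages follow the
# neutral insertion-age ladder of the human-specific subfamilies, youngest
# (Ta1) to oldest (PA3).
DEFAULT_SUBFAMILIES = [
    ("Ta1", 58, 1.94),
    ("Ta0", 38, 2.73),
    ("preTa", 62, 3.13),
    ("1AB", 32, 5.09),
    ("PA2", 147, 7.62),
    ("PA3", 106, 12.71),
]

# Nested diagnostic substitutions (position on the full consensus, derived
# base): each younger subfamily carries all diagnostics of its ancestors
# plus one of its own, mirroring how L1 subfamilies accrue diagnostic sites.
_DIAGNOSTIC_LADDER = [
    (2000, "T"),
    (2100, "A"),
    (2200, "C"),
    (2300, "G"),
    (2400, "T"),
    (2500, "A"),
]


@dataclass
class ComponentSpec:
    """One structural component of the consensus."""

    name: str
    length: int
    relative_rate: float = 1.0
    cpg_density: float = 1.0  # CpG dinucleotides per 100 bp

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"component {self.name!r}: length must be > 0")
        if self.relative_rate < 0:
            raise ValueError(f"component {self.name!r}: relative_rate must be >= 0")
        if self.cpg_density < 0:
            raise ValueError(f"component {self.name!r}: cpg_density must be >= 0")
        if self.cpg_density > 50:
            raise ValueError(
                f"component {self.name!r}: cpg_density {self.cpg_density} per 100 bp "
                "is impossible (a CpG occupies 2 bp, so the ceiling is 50)"
            )


@dataclass
class SubfamilySpec:
    """A subfamily: copy count, age, and its diagnostic substitutions."""

    name: str
    n_copies: int
    age_myr: float
    diagnostic_subs: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError(f"subfamily {self.name!r}: n_copies must be >= 1")
        if self.age_myr < 0:
            raise ValueError(f"subfamily {self.name!r}: age_myr must be >= 0")
        positions = [p for p, _ in self.diagnostic_subs]
        if len(positions) != len(set(positions)):
            raise ValueError(f"subfamily {self.name!r}: duplicate diagnostic positions")
        for pos, base in self.diagnostic_subs:
            if base not in "ACGT":
                raise ValueError(f"subfamily {self.name!r}: diagnostic base {base!r}")


@dataclass
class SimulationConfig:
    components: list[ComponentSpec]
    subfamilies: list[SubfamilySpec]
    base_rate: float = 0.0015  # substitutions / site / myr
    cpg_rate_multiplier: float = 10.0
    seed: int = 0
    # Zero-rate windows on the full consensus (0-based half-open), emulating
    # purifying selection on e.g. TF binding sites.
    protected_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if self.cpg_rate_multiplier < 1:
            raise ValueError("cpg_rate_multiplier must be >= 1")
        if not self.components:
            raise ValueError("at least one component required")
        names = [c.name for c in self.components]
        if len(names) != len(set(names)):
            raise ValueError("duplicate component names")
        total = self.total_length
        for sub in self.subfamilies:
            for pos, _ in sub.diagnostic_subs:
                if not (0 <= pos < total):
                    raise ValueError(
                        f"subfamily {sub.name!r}: diagnostic position {pos} outside "
                        f"[0, {total})"
                    )
        for start, end in self.protected_intervals:
            if not (0 <= start < end <= total):
                raise ValueError(f"protected interval ({start}, {end}) out of range")

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.components)

    @property
    def component_intervals(self) -> dict[str, tuple[int, int]]:
        out, offset = {}, 0
        for c in self.components:
            out[c.name] = (offset, offset + c.length)
            offset += c.length
        return out


def default_config(seed: int = 0, cpg_rate_multiplier: float = 10.0) -> SimulationConfig:
    """The standard six-subfamily study configuration."""
    components = [
        ComponentSpec(
            name,
            DEFAULT_LENGTHS[name],
            DEFAULT_RELATIVE_RATES[name],
            DEFAULT_CPG_DENSITY[name],
        )
        for name in ("5UTR", "ORF1", "ORF2", "3UTR")
    ]
    subfamilies = []
    # Oldest subfamily carries the first diagnostic only; each younger one
    # adds the next rung of the ladder.
    order = ["PA3", "PA2", "1AB", "preTa", "Ta0", "Ta1"]
    by_name = {name: (n, age) for name, n, age in DEFAULT_SUBFAMILIES}
    for i, name in enumerate(order):
        n, age = by_name[name]
        subfamilies.append(
            SubfamilySpec(name, n, age, diagnostic_subs=list(_DIAGNOSTIC_LADDER[: i + 1]))
        )
    return SimulationConfig(
        components=components,
        subfamilies=subfamilies,
        cpg_rate_multiplier=cpg_rate_multiplier,
        seed=seed,
    )


def default_diagnostics() -> dict[str, list[tuple[int, str]]]:
    """Diagnostic sets of the default synthetic taxonomy."""
    return {s.name: list(s.diagnostic_subs) for s in default_config().subfamilies}


# ---------------------------------------------------------------------------
# Ancestral consensus


def generate_ancestral_consensus(config: SimulationConfig) -> tuple[str, dict[str, tuple[int, int]]]:
    """Draw the family consensus with per-component CpG targeting.

    Each component is drawn uniformly over A/C/G/T, scrubbed of incidental
    CG dinucleotides, and then seeded with exactly
    ``round(cpg_density * length / 100)`` non-overlapping CG placements, so
    the realized CpG count hits the target (comfortably within the +/-10%
    contract).  Diagnostic positions are forced to a fixed ancestral base
    that differs from every subfamily's derived base, keeping the shipped
    diagnostic table valid for any seed.
    """
    rng = np.random.default_rng(config.seed)
    parts: list[np.ndarray] = []
    for comp in config.components:
        arr = _BASES[rng.integers(0, 4, size=comp.length)].copy()
        _scrub_cpg(arr)
        target = round(comp.cpg_density * comp.length / 100)
        if target > comp.length // 2:
            raise ValueError(
                f"component {comp.name!r}: cpg_density {comp.cpg_density} needs "
                f"{target} CpGs in {comp.length} bp — impossible"
            )
        _place_cpgs(arr, target, rng)
        parts.append(arr)
    seq = np.concatenate(parts)
    # Force ancestral bases at diagnostic positions (distinct from the
    # derived base so a diagnostic really is a substitution).
    for sub in config.subfamilies:
        for pos, derived in sub.diagnostic_subs:
            if seq[pos].decode() == derived:
                seq[pos] = b"G" if derived != "G" else b"A"
    return seq.tobytes().decode(), config.component_intervals


def _scrub_cpg(arr: np.ndarray) -> None:
    """Remove every CG dinucleotide in place (left-to-right single pass)."""
    for i in range(len(arr) - 1):
        if arr[i] == b"C" and arr[i + 1] == b"G":
            arr[i + 1] = b"A"  # CG -> CA never creates a new CG


def _place_cpgs(arr: np.ndarray, target: int, rng: np.random.Generator) -> None:
    placed: list[int] = []
    for pos in rng.permutation(len(arr) - 1):
        if len(placed) >= target:
            break
        if all(abs(pos - q) >= 2 for q in placed):
            placed.append(int(pos))
    if len(placed) < target:
        raise ValueError(f"could not place {target} non-overlapping CpGs in {len(arr)} bp")
    for pos in placed:
        arr[pos] = b"C"
        arr[pos + 1] = b"G"


def count_cpg_positions(seq: str) -> np.ndarray:
    """Start positions of CG dinucleotides."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    return np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))


# ---------------------------------------------------------------------------
# Copy evolution


def _site_rates(
    ancestor: str, spec: SubfamilySpec, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Poisson event means and site classes for a subfamily.

    Site classes: 0 ordinary, 1 CpG cytosine, 2 CpG guanine.  Diagnostic
    positions and protected intervals get rate 0, so every copy keeps its
    diagnostic bases and protected windows stay pristine.
    """
    L = len(ancestor)
    mu = np.empty(L)
    for comp, (start, end) in zip(config.components, config.component_intervals.values()):
        mu[start:end] = spec.age_myr * config.base_rate * comp.relative_rate
    classes = np.zeros(L, dtype=np.int8)
    cpg_starts = count_cpg_positions(ancestor)
    classes[cpg_starts] = 1
    classes[cpg_starts + 1] = 2
    m = config.cpg_rate_multiplier
    mu[classes > 0] *= (2.0 + m) / 3.0
    for start, end in config.protected_intervals:
        mu[start:end] = 0.0
    for pos, _ in spec.diagnostic_subs:
        mu[pos] = 0.0
    return mu, classes


def _apply_jumps(
    anc_base: str, k: int, site_class: int, m: float, rng: np.random.Generator
) -> str:
    """Apply k substitution events at one site and return the final base."""
    current = anc_base
    for _ in range(k):
        if site_class == 1 and current == "C":
            r = rng.random() * (m + 2.0)
            current = "T" if r < m else ("A" if r < m + 1.0 else "G")
        elif site_class == 2 and current == "G":
            r = rng.random() * (m + 2.0)
            current = "A" if r < m else ("C" if r < m + 1.0 else "T")
        else:
            alts = [b for b in "ACGT" if b != current]
            current = alts[rng.integers(0, 3)]
    return current


def evolve_copies(
    ancestor: str,
    spec: SubfamilySpec,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[L1Element]:
    """Draw ``spec.n_copies`` independent descendants of the family ancestor.

    The subfamily founder is the ancestor with ``spec.diagnostic_subs``
    applied; each copy then accumulates substitutions under the per-site
    Poisson model.  Substitution only — all copies have the ancestor's
    length and coordinates.
    """
    if not ancestor:
        raise ValueError("ancestor sequence is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    founder = list(ancestor)
    for pos, base in spec.diagnostic_subs:
        founder[pos] = base
    founder_str = "".join(founder)
    mu, classes = _site_rates(founder_str, spec, config)
    intervals = config.component_intervals
    m = config.cpg_rate_multiplier
    copies: list[L1Element] = []
    for i in range(spec.n_copies):
        k = rng.poisson(mu)
        seq = founder.copy()
        for pos in np.flatnonzero(k):
            seq[pos] = _apply_jumps(founder_str[pos], int(k[pos]), int(classes[pos]), m, rng)
        copies.append(
            L1Element(
                id=f"{spec.name}_{i:04d}",
                subfamily=spec.name,
                sequence="".join(seq),
                components={name: iv for name, iv in intervals.items()},
            )
        )
    return copies


# ---------------------------------------------------------------------------
# Ground-truth expectations

_UNIFORM_T = (np.ones((4, 4)) - np.eye(4)) / 3.0


def _jump_matrix(site_class: int, m: float) -> np.ndarray:
    T = _UNIFORM_T.copy()
    if site_class == 1:  # CpG cytosine: C->T elevated
        c, a, g, t = (_BASE_INDEX[b] for b in "CAGT")
        T[c] = 0.0
        T[c, a] = T[c, g] = 1.0 / (m + 2.0)
        T[c, t] = m / (m + 2.0)
    elif site_class == 2:  # CpG guanine: G->A elevated
        g, a, c, t = (_BASE_INDEX[b] for b in "GACT")
        T[g] = 0.0
        T[g, c] = T[g, t] = 1.0 / (m + 2.0)
        T[g, a] = m / (m + 2.0)
    return T


def expected_mismatch_fraction(mu: float, site_class: int, m: float, anc_base: str) -> float:
    """Exact P(final base != ancestral base) under the generator's model.

    With k ~ Poisson(mu) jumps through chain T the final-state law is
    ``expm(mu (T - I))`` applied to the ancestral state; for ordinary sites
    this reduces to the familiar ``3/4 (1 - exp(-4 mu / 3))``.
    """
    if mu == 0:
        return 0.0
    T = _jump_matrix(site_class, m)
    P = expm(mu * (T - np.eye(4)))
    i = _BASE_INDEX[anc_base]
    return float(1.0 - P[i, i])


def expected_component_divergence(
    founder: str, spec: SubfamilySpec, config: SimulationConfig, component: str
) -> float:
    """Mean expected per-copy divergence of one component of a subfamily."""
    mu, classes = _site_rates(founder, spec, config)
    start, end = config.component_intervals[component]
    total = 0.0
    for pos in range(start, end):
        total += expected_mismatch_fraction(
            mu[pos], int(classes[pos]), config.cpg_rate_multiplier, founder[pos]
        )
    return total / (end - start)


# ---------------------------------------------------------------------------
# Whole-family simulation


@dataclass
class SimulationResult:
    elements: list[L1Element]
    consensus: str
    components: dict[str, tuple[int, int]]
    ground_truth: dict
    config: SimulationConfig

    def by_subfamily(self) -> dict[str, list[L1Element]]:
        out: dict[str, list[L1Element]] = {}
        for el in self.elements:
            out.setdefault(el.subfamily, []).append(el)
        return out


def simulate_family(config: SimulationConfig) -> SimulationResult:
    """Generate consensus + all subfamily copies, with ground truth attached.

    Ground truth records, per subfamily and component: the simulated age,
    the effective clock age (age x relative_rate), the exact expected
    per-copy divergence under the mutation model (including CpG elevation
    and multiple-hit saturation), and the age the divergence clock is
    expected to read back (expected divergence / base_rate).
    """
    consensus, intervals = generate_ancestral_consensus(config)
    rng = np.random.default_rng(config.seed)
    elements: list[L1Element] = []
    truth: dict = {
        "seed": config.seed,
        "base_rate": config.base_rate,
        "cpg_rate_multiplier": config.cpg_rate_multiplier,
        "components": {
            c.name: {
                "interval": list(intervals[c.name]),
                "relative_rate": c.relative_rate,
                "cpg_density": c.cpg_density,
            }
            for c in config.components
        },
        "subfamilies": {},
    }
    for spec in config.subfamilies:
        copies = evolve_copies(consensus, spec, config, rng=rng)
        elements.extend(copies)
        founder = list(consensus)
        for pos, base in spec.diagnostic_subs:
            founder[pos] = base
        founder_str = "".join(founder)
        sub_truth = {
            "n_copies": spec.n_copies,
            "age_myr": spec.age_myr,
            "diagnostic_subs": [[p, b] for p, b in spec.diagnostic_subs],
            "per_component": {},
        }
        for comp in config.components:
            exp_div = expected_component_divergence(founder_str, spec, config, comp.name)
            sub_truth["per_component"][comp.name] = {
                "effective_age_myr": spec.age_myr * comp.relative_rate,
                "expected_divergence": exp_div,
                "expected_age_estimate_myr": exp_div / config.base_rate,
            }
        truth["subfamilies"][spec.name] = sub_truth
    return SimulationResult(elements, consensus, intervals, truth, config)


def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    """Write per-subfamily FASTA, components TSV and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, members in result.by_subfamily().items():
        write_fasta(outdir / f"{name}.fasta", members)
    write_fasta(outdir / "all_subfamilies.fasta", result.elements)
    write_fasta(
        outdir / "consensus.fasta",
        [L1Element(id="consensus", subfamily=None, sequence=result.consensus)],
    )
    write_components(outdir / "components.tsv", result.components)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(result.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Config file I/O


def load_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML (or JSON) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    components = [ComponentSpec(**c) for c in raw["components"]]
    subfamilies = [
        SubfamilySpec(
            name=s["name"],
            n_copies=s["n_copies"],
            age_myr=s["age_myr"],
            diagnostic_subs=[(int(p), str(b)) for p, b in s.get("diagnostic_subs", [])],
        )
        for s in raw["subfamilies"]
    ]
    return SimulationConfig(
        components=components,
        subfamilies=subfamilies,
        base_rate=raw.get("base_rate", 0.0015),
        cpg_rate_multiplier=raw.get("cpg_rate_multiplier", 10.0),
        seed=raw.get("seed", 0),
        protected_intervals=[tuple(iv) for iv in raw.get("protected_intervals", [])],
    )


def save_config(config: SimulationConfig, path: str | Path) -> None:
    raw = {
        "components": [asdict(c) for c in config.components],
        "subfamilies": [
            {
                "name": s.name,
                "n_copies": s.n_copies,
                "age_myr": s.age_myr,
                "diagnostic_subs": [[p, b] for p, b in s.diagnostic_subs],
            }
            for s in config.subfamilies
        ],
        "base_rate": config.base_rate,
        "cpg_rate_multiplier": config.cpg_rate_multiplier,
        "seed": config.seed,
        "protected_intervals": [list(iv) for iv in config.protected_intervals],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
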