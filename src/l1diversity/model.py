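"""Model/Results front end tying the analysis stages together.

:class:`L1DiversityModel` holds the data (L1 copies with component
intervals, optional TF-region annotations and diagnostic sets);
:meth:`L1DiversityModel.fit` runs classification, consensus building,
substitution profiling, component age estimation, CpG analytics and the
component comparisons, returning an :class:`L1DiversityResults` that
carries the tables and renders a text summary.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .age import (
    DEFAULT_RATE,
    age_table_wide,
    component_age_table,
    estimate_age_consensus,
)
from .consensus import (
    ColumnAlignment,
    DiagnosticSet,
    align_to_reference,
    classify,
    majority_consensus,
    read_diagnostics,
)
from .cpg import CpGReport, correlate_cpg_vs_rate, cpg_report
from .io import (
    L1Element,
    RegionAnnotation,
    read_components,
    read_fasta,
    read_regions,
)
from .profile import SubstitutionProfile, profile, sum_profiles, summarize_regions
from .stats import welch_t

__all__ = ["L1DiversityModel", "L1DiversityResults"]


class L1DiversityModel:
    """Sequence-diversity and age model for a family of L1 elements.

    Parameters
    ----------
    elements : sequence of L1Element
        The copies to analyse.  Elements lacking component intervals
        receive ``components`` (consensus coordinates).
    components : mapping, optional
        Component label -> (start, end), applied to elements without
        their own intervals.
    regions : sequence of RegionAnnotation, optional
        Windows on the 5' UTR consensus (promoter, TF binding sites) for
        the region summaries.
    diagnostics : sequence of DiagnosticSet, optional
        Used to classify elements that carry no subfamily label.
    reference : str, optional
        Consensus frame for global alignment; only needed when element
        lengths differ from the frame (indel-bearing input).
    """

    def __init__(
        self,
        elements: Sequence[L1Element],
        *,
        components: Mapping[str, tuple[int, int]] | None = None,
        regions: Sequence[RegionAnnotation] | None = None,
        diagnostics: Sequence[DiagnosticSet] | None = None,
        reference: str | None = None,
    ) -> None:
        if not elements:
            raise ValueError("no elements")
        self.elements = list(elements)
        if components:
            self.elements = [
                el
                if el.components
                else L1Element(el.id, el.subfamily, el.sequence, dict(components))
                for el in self.elements
            ]
        missing = [el.id for el in self.elements if not el.components]
        if missing:
            raise ValueError(
                f"elements without component intervals: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        self.regions = list(regions) if regions else []
        self.diagnostics = list(diagnostics) if diagnostics else []
        self.reference = reference

    @classmethod
    def from_files(
        cls,
        fasta: str | Path | Sequence[str | Path],
        components: str | Path,
        *,
        regions: str | Path | None = None,
        diagnostics: str | Path | None = None,
        reference_fasta: str | Path | None = None,
    ) -> "L1DiversityModel":
        """Build the model from FASTA + BED-like TSV inputs."""
        paths = [fasta] if isinstance(fasta, (str, Path)) else list(fasta)
        elements: list[L1Element] = []
        for p in paths:
            elements.extend(read_fasta(p))
        comp = read_components(components)
        utr5 = comp.get("5UTR")
        regs = (
            read_regions(regions, frame_length=utr5[1] - utr5[0] if utr5 else 897)
            if regions
            else None
        )
        diags = read_diagnostics(diagnostics) if diagnostics else None
        ref = read_fasta(reference_fasta)[0].sequence if reference_fasta else None
        return cls(
            elements, components=comp, regions=regs, diagnostics=diags, reference=ref
        )

    def fit(
        self,
        rate: float = DEFAULT_RATE,
        *,
        exclude_prefix: int = 9,
        epsilon: int = 0,
        island_min_len: int = 200,
        gc_min: float = 0.50,
        oe_min: float = 0.60,
        include_network: bool = True,
        combined_component: tuple[str, int] | None = ("pORF2+3UTR", 662),
    ) -> "L1DiversityResults":
        """Run the full analysis and return the results object."""
        elements = self._aligned_elements()
        elements, n_classified, n_ambiguous = self._classified(elements)

        groups: dict[str, list[L1Element]] = {}
        for el in elements:
            groups.setdefault(el.subfamily or "unknown", []).append(el)

        # 5' UTR substitution profile, per subfamily then summed
        per_sub_profiles = []
        utr_name = "5UTR" if "5UTR" in elements[0].components else next(iter(elements[0].components))
        for sub, members in groups.items():
            aln = ColumnAlignment(
                member_ids=[el.id for el in members],
                rows=[el.component_seq(utr_name) for el in members],
            )
            cons = majority_consensus(aln)
            per_sub_profiles.append(profile(aln, cons, exclude_prefix=exclude_prefix))
        pooled = sum_profiles(per_sub_profiles)
        region_summaries, overall = (
            summarize_regions(pooled, self.regions) if self.regions else ([], pooled.mean_percent())
        )

        # component x subfamily ages
        age_table = component_age_table(
            elements,
            rate,
            epsilon=epsilon,
            include_network=include_network,
            combined_component=combined_component,
        )

        # per-copy age vectors per component (pooled over subfamilies) for
        # the pairwise component comparisons
        per_copy_ages: dict[str, list[float]] = {}
        comp_names = list(elements[0].components)
        for sub, members in groups.items():
            for comp in comp_names:
                aln = ColumnAlignment(
                    member_ids=[el.id for el in members],
                    rows=[el.component_seq(comp) for el in members],
                )
                cons = majority_consensus(aln)
                est = estimate_age_consensus(aln, cons, rate=rate)
                per_copy_ages.setdefault(comp, []).extend(
                    m / e / rate for _, m, e, _ in est.divergence.per_copy
                )
        welch_records = []
        for a, b in itertools.combinations(comp_names, 2):
            res = welch_t(per_copy_ages[a], per_copy_ages[b])
            welch_records.append(
                {"component_a": a, "component_b": b, "t": res.t, "df": res.df, "p": res.p}
            )
        welch_df = pd.DataFrame.from_records(welch_records)

        # CpG analytics on the family-wide consensus of each component
        cpg_reports: list[CpGReport] = []
        family_consensus_parts: dict[str, str] = {}
        for comp in comp_names:
            aln = ColumnAlignment(
                member_ids=[el.id for el in elements],
                rows=[el.component_seq(comp) for el in elements],
            )
            cons = majority_consensus(aln)
            family_consensus_parts[comp] = cons
            cpg_reports.append(
                cpg_report(comp, cons, min_len=island_min_len, gc_min=gc_min, oe_min=oe_min)
            )

        # CpG content vs apparent component age (mutation-rate proxy)
        avg = age_table[
            (age_table["subfamily"] == "Average")
            & (age_table["method"] == "consensus-divergence")
            & (age_table["component"].isin(comp_names))
        ]
        ages_by_comp = dict(zip(avg["component"], avg["age_myr"]))
        ratios = [r.ratio for r in cpg_reports]
        if all(r is not None for r in ratios) and len(comp_names) >= 3:
            r_val, p_val = correlate_cpg_vs_rate(
                ratios, [ages_by_comp[c] for c in comp_names]
            )
        else:
            r_val, p_val = float("nan"), float("nan")

        return L1DiversityResults(
            model=self,
            n_elements=len(elements),
            n_classified=n_classified,
            n_ambiguous=n_ambiguous,
            subfamily_sizes={k: len(v) for k, v in groups.items()},
            profile=pooled,
            region_summaries=region_summaries,
            overall_mean_percent=overall,
            age_table=age_table,
            per_copy_ages={k: np.asarray(v) for k, v in per_copy_ages.items()},
            welch=welch_df,
            cpg_reports=cpg_reports,
            cpg_age_correlation=(r_val, p_val),
            params={
                "rate": rate,
                "exclude_prefix": exclude_prefix,
                "epsilon": epsilon,
                "island_min_len": island_min_len,
                "gc_min": gc_min,
                "oe_min": oe_min,
                "combined_component": list(combined_component) if combined_component else None,
                "version": __version__,
            },
        )

    # -- helpers ---------------------------------------------------------

    def _aligned_elements(self) -> list[L1Element]:
        if self.reference is None:
            return self.elements
        needs = [el for el in self.elements if len(el.sequence) != len(self.reference)]
        if not needs:
            return self.elements
        aln = align_to_reference(self.elements, self.reference)
        comps = self.elements[0].components
        return [
            L1Element(el.id, el.subfamily, row.replace("-", "N"), dict(comps))
            for el, row in zip(self.elements, aln.rows)
        ]

    def _classified(
        self, elements: list[L1Element]
    ) -> tuple[list[L1Element], int, int]:
        if not self.diagnostics:
            return elements, 0, 0
        out, n_classified, n_ambiguous = [], 0, 0
        for el in elements:
            if el.subfamily is None:
                res = classify(el.sequence, self.diagnostics)
                out.append(
                    L1Element(el.id, res.subfamily, el.sequence, dict(el.components))
                )
                n_classified += 1
                n_ambiguous += int(res.ambiguous)
            else:
                out.append(el)
        return out, n_classified, n_ambiguous


@dataclass
class L1DiversityResults:
    """Fitted results: tables, profiles and reports with a text summary."""

    model: L1DiversityModel
    n_elements: int
    n_classified: int
    n_ambiguous: int
    subfamily_sizes: dict[str, int]
    profile: SubstitutionProfile
    region_summaries: list
    overall_mean_percent: float
    age_table: pd.DataFrame
    per_copy_ages: dict[str, np.ndarray]
    welch: pd.DataFrame
    cpg_reports: list[CpGReport]
    cpg_age_correlation: tuple[float, float]
    params: dict = field(default_factory=dict)

    def age_table_wide(self, method: str = "consensus-divergence") -> pd.DataFrame:
        return age_table_wide(self.age_table, method=method)

    def summary(self) -> str:
        lines = []
        lines.append("L1 sequence diversity analysis")
        lines.append("=" * 62)
        sizes = ", ".join(f"{k}: {v}" for k, v in self.subfamily_sizes.items())
        lines.append(f"elements: {self.n_elements}  ({sizes})")
        if self.n_classified:
            lines.append(
                f"classified from diagnostics: {self.n_classified} "
                f"({self.n_ambiguous} ambiguous)"
            )
        lines.append("")
        lines.append(
            f"5' UTR substitution frequency, overall mean: "
            f"{self.overall_mean_percent:.2f}% "
            f"(first {self.params.get('exclude_prefix', 9)} bp excluded)"
        )
        if self.region_summaries:
            lines.append("region summaries (mean % substitution per position):")
            for rs in self.region_summaries:
                lines.append(f"  {rs.name:<16} {rs.mean_percent:6.2f}%  ({rs.n_positions} bp)")
        lines.append("")
        lines.append(
            f"component ages (divergence clock at {self.params.get('rate', DEFAULT_RATE)*100:.2f}%/site/myr):"
        )
        wide = self.age_table_wide()
        lines.append(wide.round(2).to_string())
        lines.append("")
        lines.append("CpG analytics (family consensus per component):")
        for rep in self.cpg_reports:
            ratio = f"{rep.ratio:.3f}" if rep.ratio is not None else "undefined"
            isl = ", ".join(f"[{a}, {b})" for a, b in rep.islands) or "none"
            lines.append(
                f"  {rep.component:<10} CpG {rep.cpg_count:4d}  GpC {rep.gpc_count:4d}  "
                f"ratio {ratio}  islands: {isl}"
            )
        r, p = self.cpg_age_correlation
        if not np.isnan(r):
            lines.append(f"CpG/GpC ratio vs component age: r = {r:.4f}, P = {p:.4f} (two-tailed)")
        lines.append("")
        lines.append("pairwise component age comparisons (Welch's t, raw two-tailed p):")
        for _, row in self.welch.iterrows():
            lines.append(
                f"  {row.component_a:<10} vs {row.component_b:<10} "
                f"t = {row.t:8.2f}  df = {row.df:8.1f}  p = {row.p:.3g}"
            )
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "n_elements": self.n_elements,
            "subfamily_sizes": self.subfamily_sizes,
            "overall_mean_percent": self.overall_mean_percent,
            "region_summaries": [
                {
                    "name": rs.name,
                    "mean_percent": rs.mean_percent,
                    "pooled_percent": rs.pooled_percent,
                    "n_positions": rs.n_positions,
                }
                for rs in self.region_summaries
            ],
            "age_table": self.age_table.to_dict(orient="records"),
            "welch": self.welch.to_dict(orient="records"),
            "cpg_reports": [
                {
                    "component": r.component,
                    "cpg_count": r.cpg_count,
                    "gpc_count": r.gpc_count,
                    "ratio": r.ratio,
                    "islands": [list(iv) for iv in r.islands],
                }
                for r in self.cpg_reports
            ],
            "cpg_age_correlation": {
                "r": self.cpg_age_correlation[0],
                "p": self.cpg_age_correlation[1],
            },
        }

    def save(self, outdir: str | Path) -> None:
        """Write the report bundle: TSV tables + machine-readable JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prof_df = pd.DataFrame(
            {
                "position": self.profile.positions,
                "count": self.profile.counts,
                "denominator": self.profile.denominators,
                "frequency_percent": self.profile.frequency_percent,
            }
        )
        prof_df.to_csv(outdir / "substitution_profile.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "region": rs.name,
                    "mean_percent": rs.mean_percent,
                    "pooled_percent": rs.pooled_percent,
                    "n_positions": rs.n_positions,
                }
                for rs in self.region_summaries
            ]
            + [
                {
                    "region": "overall",
                    "mean_percent": self.overall_mean_percent,
                    "pooled_percent": self.profile.mean_percent(pooled=True),
                    "n_positions": len(self.profile.positions),
                }
            ]
        ).to_csv(outdir / "region_summary.tsv", sep="\t", index=False)
        self.age_table.to_csv(outdir / "age_table.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "component": r.component,
                    "cpg_count": r.cpg_count,
                    "gpc_count": r.gpc_count,
                    "ratio": r.ratio,
                    "islands": ";".join(f"{a}-{b}" for a, b in r.islands),
                }
                for r in self.cpg_reports
            ]
        ).to_csv(outdir / "cpg_report.tsv", sep="\t", index=False)
        stats_rows = self.welch.copy()
        stats_rows["test"] = "welch"
        r, p = self.cpg_age_correlation
        stats_df = pd.concat(
            [
                stats_rows,
                pd.DataFrame(
                    [
                        {
                            "component_a": "cpg_ratio",
                            "component_b": "age",
                            "t": np.nan,
                            "df": np.nan,
                            "p": p,
                            "test": f"pearson r={r:.4f}" if not np.isnan(r) else "pearson",
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
        stats_df.to_csv(outdir / "stats.tsv", sep="\t", index=False)
        with open(outdir / "results.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")

    def plot_profile(self, ax=None):
        """Minimal per-position substitution-frequency track (optional)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        ax.plot(self.profile.positions, self.profile.frequency_percent, lw=0.8)
        for rs in self.model.regions:
            ax.axvspan(rs.start, rs.end, alpha=0.2)
        ax.set_xlabel("5' UTR consensus position")
        ax.set_ylabel("substitutions (%)")
        return ax
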