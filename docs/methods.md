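# Methods

## Scope and data model

The package analyses families of full-length LINE-1 (L1) elements: copies
~6 kb long carrying a 5′ UTR (897 bp by default, with the internal RNA
polymerase II promoter and TF binding sites), ORF1 (1017 bp), ORF2
(3828 bp) and a 3′ UTR (202 bp). Copies belong to subfamilies defined by
diagnostic substitutions — bases at fixed consensus positions shared by
all members. All coordinates are 0-based half-open throughout; `N` bases
are accepted on input and excluded from every count downstream.

Input is FASTA (headers `subfamily|id`, or bare ids plus a diagnostics
table for classification), a BED-like TSV of component intervals, and
optionally a BED-like TSV of annotated 5′ UTR windows. Elements whose
length differs from the consensus frame are brought into frame by global
affine-gap alignment (match +1, mismatch −1, gap open −5, gap extend −1,
via Biopython's PairwiseAligner); columns where the reference gaps are
dropped, so indel-free input passes through unchanged. Consensus building
is per-column majority over A/C/G/T — gaps and N never vote, a voteless
column emits N, and ties resolve by the fixed order A<C<G<T for
determinism.

## Substitution profiling

For each subfamily, every member is compared with the subfamily consensus
position by position; a position contributes to a member's denominator
only when both bases are unambiguous, and counts a substitution when they
differ. Subfamily profiles are summed positionwise. For the 5′ UTR the
first 9 bp are excluded (`exclude_prefix=9`): the extreme 5′ end of human
L1s is hypervariable and would swamp the profile; for other components the
exclusion is 0.

Region summaries average *per-position frequencies* over the window
(matching a frequency track averaged over a region); the pooled
counts/denominators alternative is reported alongside, since the two
differ whenever denominators vary across positions. Per-position
denominators are tracked explicitly rather than assuming every member
evaluable everywhere.

An "active" vs "dead" (or any other) group comparison needs no special
code path: profile the two FASTA groups separately.

## Age estimation

Both estimators assume neutral post-insertion divergence at
`μ = 0.0015` substitutions/site/myr and a star-like genealogy within each
subfamily (each copy an independent descendant of the founder).

* **Consensus clock** (headline): per-copy divergence to the subfamily
  consensus, `age = divergence / μ`; the subfamily value is the mean
  per-copy age ± the standard error of that mean. A single copy yields an
  age with the uncertainty flagged undefined.
* **Network ρ**: identical sequences collapse to haplotypes with
  multiplicities; the median-joining network is built by iterating
  minimum-spanning-network (MSN) construction with tolerance ε (default
  0) and adding median vectors of triplets that share links, keeping
  candidates within ε of the cheapest connection cost; links once
  established are retained, so the final network provably contains the
  MSN of the observed haplotypes, and median vectors with fewer than
  three links are pruned as obsolete. ρ is the multiplicity-weighted mean
  shortest-path distance from observed haplotypes to the root — the
  subfamily consensus, added with multiplicity 0 when unobserved, as the
  best available proxy for the founder — and `age = ρ/(L·μ)` with
  `σ² = Σ_e w_e (n_e/n)²` on the shortest-path tree. All tie-breaks
  (median three-way ties, node order, shortest-path parents) are
  lexicographic, making the construction deterministic regardless of
  input order. `max_iterations` (25) and a cap on added medians (2× the
  observed count + 8) bound runtime on adversarial inputs; neither cap is
  reached on star-like data.

The component age table reports both methods per subfamily × component,
plus the classic partial-ORF2 + 3′ UTR dating segment (the last 662 bp of
ORF2 joined to the 3′ UTR, 864 bp) as a neutral reference. The Average row
is the unweighted mean over subfamilies of the ages and of their
uncertainties. Because components of one subfamily share a single
insertion age, the ratio of apparent component ages estimates the ratio of
component substitution rates.

The divergence clock reads low at high divergence: with per-site Poisson
substitution and uniform base choice, the expected mismatch fraction is
`(3/4)(1 − e^(−4λ/3))` for per-site mean λ, not λ itself. No saturation
correction is applied — the estimator is kept as the plain
divergence-over-rate clock — but the simulator's ground truth records the
exact expected clock reading so recovery tests compare the estimator to
its estimand. At the divergences relevant here (≤ ~3.5%) the deflection is
under 2.5%.

Welch's t (unequal variances, Welch–Satterthwaite df, two-tailed) compares
the pooled per-copy age vectors between components. Which per-element
quantities feed such a comparison is genuinely ambiguous when only
subfamily summaries are published; the pipeline tests per-copy age vectors
and labels the p-values raw (no multiple-testing correction is applied,
and none is claimed).

## CpG analytics

CpG and GpC are counted by an overlapping scan of adjacent pairs (pairs
containing N skipped); the CpG/GpC ratio per component is a
methylation-robust retention proxy (both dinucleotides are palindromes, so
the counts are strand-stable under reverse complement). CpG islands
follow the classical sliding-window definition: windows of `min_len = 200`
qualify when GC fraction > 0.50 **and** observed/expected CpG > 0.60 with
expected = #C·#G/length (strict inequalities, per the printed
definition); overlapping or adjacent qualifying windows merge into maximal
intervals, each re-verified and trimmed from the 3′ end until it passes
or falls below `min_len`. The merge-then-reverify-then-trim behaviour is a
design decision — published island finders differ in this detail — and is
pinned by an exhaustive all-windows oracle in the tests.

The correlation of CpG content with component age uses Pearson's r and the
two-tailed p from `t = r√((n−2)/(1−r²))` against Student's t with n−2 df.
With only four components this test has one to two degrees of freedom and
essentially no power; it is reported for completeness, not inference.

## The synthetic family generator

The generator emulates the study conditions of a human-specific L1
dataset: six subfamilies of sizes 106/147/32/62/38/58; component lengths
897/1017/3828/202 bp; subfamily ages 12.71/7.62/5.09/3.13/2.73/1.94 myr
(the neutral insertion-age ladder, oldest to youngest); per-component
relative rates 1.787 (5′ UTR), 1.114 (ORF1), 1.058 (ORF2), 1.399 (3′
UTR), scaled so the neutral pORF2+3′ UTR reference is 1 — together these
reproduce the published component-age pattern (5′ UTR > 3′ UTR > ORF1 ≈
ORF2) as ground truth. Default CpG densities (3.0/1.0/0.5/0.8 per 100 bp)
make the 5′ UTR the CpG-richest component and ORF2 the poorest, mirroring
the observed CpG landscape.

The ancestral consensus is drawn uniformly over A/C/G/T, scrubbed of
incidental CG dinucleotides, then seeded with exactly the target number of
non-overlapping CG placements, so realized CpG counts hit the target.
Diagnostic positions are forced to a fixed ancestral base distinct from
every derived base, keeping the shipped diagnostic table
(`data/synthetic_diagnostics.tsv`, a nested ladder in ORF2) valid for any
seed. The shipped `data/synthetic_regions.tsv` is an *example* annotation
for the synthetic consensus, not a genomic annotation.

Evolution is substitution-only on a star genealogy: per site,
`k ~ Poisson(age·μ·relative_rate)` events applied as a jump chain with
uniform choice among the three alternative bases; multiple hits collapse
to the final state. At cytosines of ancestral CpGs the C→T jump is
`cpg_rate_multiplier`-fold elevated (default 10, within the 10–50-fold
range typical of primate genomes; mirrored as G→A), making the event rate
there `μ(2+m)/3`. CpG status is assessed on the ancestor and not
re-evaluated after mutation — a single-generation approximation adequate
at these divergences. Diagnostic positions and user-declared
`protected_intervals` (zero-rate windows emulating purifying selection on
TF binding sites) do not mutate, so every copy carries its diagnostics at
any age. The ground truth JSON records, per subfamily × component, the
simulated age, the effective clock age (age × relative rate), and the
exact expected per-copy divergence `1 − [e^(μ(T−I))]_aa` under the
generator's jump matrix T, hence the expected clock reading.

What the generator deliberately does not emulate: indels and 5′
truncation (the dominant real-world L1 lesion), gene conversion,
recombination, within-subfamily tree structure (master-gene bursts),
selection beyond hard zero-rate windows, and base-composition
heterogeneity beyond CpG placement. Passing recovery tests therefore
demonstrates correctness of the estimators under their own assumptions,
not robustness to alignment error or non-star genealogies in genomic
data.

## Numerical and design choices

* Identical seed and configuration give byte-identical FASTA output; the
  single `numpy` Generator is threaded through consensus generation and
  copy evolution in a fixed order.
* The classifier prefers the subfamily whose diagnostics all match, among
  several the one with the most sites (most derived); with no full match
  it returns the best-matching fraction flagged ambiguous. With nested
  diagnostic ladders a copy can, rarely, mutate into a more derived
  subfamily's full set; at ages ≤ 5 myr this affects < 1% of copies.
* Equal-length inputs to the aligner are taken as collinear (the
  simulator emits no indels, so consensus coordinates equal copy
  coordinates); length-discordant inputs are aligned, and elements
  shorter than half the reference elicit a warning.
* Profile frequencies are NaN where a position has no evaluable member
  bases, rather than silently 0.
* Degenerate Welch inputs (both variances zero) return t = 0, p = 1 for
  equal means and p = 0 flagged degenerate otherwise.
* Problem sizes in the test suite are scaled (hundreds of copies,
  components of a few hundred bp) to keep the suite fast while leaving
  every estimator in its asymptotic regime; the acceptance script runs
  the full 443-copy, 5944-bp study configuration.

## Known limitations

* The median-joining construction targets intraspecific, low-divergence
  data; on highly divergent or recombining haplotype sets the median
  ladder can grow until the caps bite, and ρ-based ages inherit the
  star-genealogy assumption.
* The divergence clock is uncorrected for saturation and for consensus
  error at very small subfamily sizes (a sample consensus built from few,
  divergent copies biases divergence downward).
* CpG-island calls depend on the merge/trim convention; other tools'
  island boundaries will differ in edge cases even under identical
  thresholds.
* The CpG-content-vs-rate correlation at n = 4 components is descriptive
  only.
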