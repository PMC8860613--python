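# Methods

## Coordinate system and reference construction

Every chromosome end is analysed in *region coordinates*: 1-based, closed
intervals, position 1 at the outermost chromosome base, increasing inward.
Right arms are reverse-complemented on construction, so the C-rich
telomeric strand is always the forward region strand and both arms of a
chromosome read identically. The mapping back to input-FASTA coordinates
(strand flip plus the offset of trimmed repeats) is stored per end and is
exactly invertible.

Telomere truncation keeps exactly 10 perfect CCCTAAA repeats (70 bp).
The detection threshold `min_run` defaults to 10: interstitial loci in
the Arabidopsis genome reach at most 8 consecutive perfect repeats, so a
run of ten or more unambiguously marks a telomere. An end whose outermost
run is shorter than `min_run` is rejected rather than truncated to fewer
repeats, because downstream tilings assume a 70-bp block; the error
carries the observed run length. Ns are permitted inward of the telomere
but terminate any repeat run. The unassembled rDNA-bearing arms (2L, 4L)
are refused with a clear error.

## Repeat variants and ITS calling

A degenerate telomeric repeat is a 7-mer at Hamming distance exactly 1
from a canonical unit: 7 positions × 3 substitutions = 21 variants per
orientation, 42 in total, and the two orientation sets are disjoint
because CCCTAAA and TTTAGGG differ at all seven positions.

Scanning is a greedy left-to-right tiling of non-overlapping 7-mers:
perfect matches are preferred over degenerate at the same offset, then
leftmost, then lowest mismatch position — fully deterministic. ITSs are
chains of same-orientation hits with inter-hit gaps of at most `max_gap`
(default 21 bp = 3 unit lengths) and at least `min_hits` (default 3)
members. These two parameters are the package's own choices: no published
gap rule exists for delimiting an ITS, and the defaults reproduce
"interspersed" composition without merging distant loci. Hits inside the
retained telomere block are excluded before chaining, so ITS intervals
never overlap the telomere span.

## Methylomes

Context is defined by the two bases 3′ of the cytosine on its own strand:
CG; CHG (subcontexts CAG/CTG/CCG); CHH (CAH/CTH/CCH). Contexts stated in
call files are never trusted — they are re-derived from the reference and
disagreements are counted and logged, because callers disagree near
contig edges and on strand conventions. Cytosines with fewer than two
downstream bases have undefined context and are skipped (counted).

Coverage of one read suffices for a record, matching the upstream calling
convention; a `min_cov` override exists because single-read levels are
noisy, but the default stays 1 for fidelity. Replicate combination is
explicit and two-stage capable: `pool_counts` sums read counts,
`mean_levels` averages per-cytosine percentages unweighted, and the two
can be nested (e.g. pool two runs, then average with a third). Base
quality filtering belongs to the upstream aligner/caller (e.g.
`bsbolt Align` followed by `bsbolt CallMethylation`, with duplicates
marked by samtools) and is not re-implemented.

## Tiled profiling

Tiles are consecutive fixed-width windows anchored at position 71 (the
first subtelomeric base), 40 bp for the main analysis and 35 bp at the
boundary, with trailing partial tiles dropped. A tile's level per context
is the *unweighted mean of per-cytosine level percentages* over covered
cytosines on both strands — not a pooled-count ratio — so deeply covered
sites do not dominate; a pooled mode exists for sensitivity checks. Site
counts come from the reference regardless of coverage, and densities are
sites × 1000 / width (site counts × 25 for 40-bp tiles). A tile with no
covered site of a context has an undefined (NaN) level, never zero.

The inward extent of subtelomeric methylation has no canonical
definition, so the border is an explicit heuristic: walk the tiles for
the first run of `window` (default 5) consecutive tiles below `min_level`
(default 20 %) in every context; the border is the last CG site inside
the last preceding tile with CGm ≥ `min_level`. Defaults reproduce a
1–2-kbp extent on generator data shaped like real subtelomeres; a manual
per-end override always wins and is logged.

## Boundary and read analysis

The first 700 bp are tiled at 35 bp: tiles ending at 35 and 70 lie inside
the retained telomere block (zone `Tel`), the remaining 18 are `Subtel`.
Note a rank test on a single end compares 2 against 18 tiles, whose
minimum achievable two-sided Mann–Whitney p is 2/190 ≈ 0.0105; detecting
the boundary drop at stringent significance requires pooling tiles across
ends, as the package's tests do with six simulated ends.

Within perfect CCCTAAA units the three cytosines occupy distinct
subcontexts — the first two are CCH sites, the third is CTH — and their
methylation is reported per unit offset over units whose three cytosines
are all covered.

A bisulfite read is classified telomeric when, at some phase offset 0–6,
its entire length matches tandem (YYYTAAA) with Y ∈ {C, T}, allowing
partial units at both edges, and contains at least `min_units` (default
4) complete units — so 100-bp reads must be near-pure repeat. Y positions
of partial edge units still count toward the methylation fraction.
Reads matching (TTTAGGG)n arise from the G-rich strand, carry no Y
positions, and are tallied separately without entering the fraction. The
methylated fraction of telomeric reads is bounded below by the bisulfite
non-conversion rate ε; on simulated unmethylated telomeres it converges
to ε as read count grows.

## Differential analysis

Tiles with at least 20 % wild-type methylation in a context are
*labelled* for it; unlabelled tiles are excluded from that context's
differential analysis. A labelled tile is a DMT for a mutant when the
mutant is below the wild type by at least 20 (CG), 15 (CHG) or 10 (CHH)
percentage points. The thresholds are read as absolute percentage-point
differences, consistent with levels being expressed in percent
throughout; a relative mode exists behind a flag. Lowering a mutant level
can never un-call a DMT (monotonicity).

The contribution of a methyltransferase to a methylation type is
100 × (m_WT − m_mut)/m_WT over the unweighted per-cytosine mean in scope
(one end, all ends, or an arbitrary reference locus given as an
interval — the generalisation of comparing against a reference
heterochromatic element). It is undefined when m_WT = 0, negative when
the mutant gains methylation, and clipped to [−100, 100] for reporting
with the raw value retained.

At 20× coverage, a tile containing a single CHG site crosses the
15-point threshold by binomial noise alone roughly 12–17 % of the time in
a genotype with no planted CHG effect. Differential calls are therefore
only as reliable as the replicate design behind them; the package's DMT
validation pools three simulated experiments for the wild type and two
per mutant, the typical design for this kind of comparison, and reaches
precision ≥ 0.96 and recall ≈ 1 against planted truth.

## Statistics

Two-sample comparisons apply Shapiro–Wilk to both groups (gate α = 0.05,
a choice of this package; the gate's level is rarely reported) and use
the equal-variance Student t only when both pass, otherwise the
two-sided Mann–Whitney U. Constant groups make Shapiro undefined and
fall back to Mann–Whitney, flagged. No multiple-testing correction is
applied by default — each comparison is judged at p < 0.05 — with
Benjamini–Hochberg available but off.

PCA standardizes columns (z-score; required for mixed-unit features),
decomposes the correlation matrix, retains components with eigenvalue
> 1, and varimax-rotates them with Kaiser row normalization
(convergence 1e-6, ≤ 500 iterations, via statsmodels). A retained
component is *selected* when it correlates with a named anchor column
(wild-type CGm/CHGm/CHHm) at p < 0.05 with |r| ≥ 0.3, where the
correlation is computed leave-one-out: the component's scores are
re-derived without the anchor's own loading, so a component must share
variance with the anchor through other features. This is the package's
own criterion — selecting on the plain score–anchor correlation is
vacuous, because on pure-noise tables varimax reliably produces a
component that simply recapitulates an anchor column (|r| up to ~0.8).
Under the leave-one-out rule noise-only tables select nothing.

Genotype clustering computes Euclidean distances between samples over
the per-cytosine level vectors of all sites covered in every sample (CG,
CHG and CHH together) and builds a single-linkage (nearest point) tree;
trees export to Newick and cut into flat groups.

## The synthetic-data generator

The generator emulates one chromosome end: `telomere_repeats` (40)
perfect units; an ITS of `its_length` (400 bp) whole units, each
independently degenerated with probability `degenerate_fraction` (0.4);
then `subtelomere_length` (3000 bp) of unique sequence at 36 % GC
(AT-rich, as in the organism). Truncation of the generated end leaves
the canonical 70-bp block, and since leading perfect ITS units are
indistinguishable from telomeric repeats and absorbed into the terminal
run, the planted ITS begins with its first degenerate unit at position
71.

The methylation surface per subcontext is: a plateau (CG 85; CAG/CTG 50;
CCG 25 — lower than CAG/CTG, as CCG sites methylate less efficiently;
CAH 16; CTH 18; CCH 12 %), an exponential decay across the telomere
block toward the terminus (e-folding `boundary_decay` = 25 bp, making
the drop progressive rather than abrupt), a hard stop beyond `extent`
(1500 bp), and a ×2 CHH boost inside the ITS. Genotypes act through a
multiplicative retained-activity matrix whose WT row is all ones, so a
knockout's planted contribution equals 100 × (1 − activity) by
construction. The preset activities emulate the known division of labour
qualitatively — the CG maintenance enzyme ablates CG and most CCG; the
CHG enzymes ablate CAG/CTG strongly; the de-novo enzyme ablates CHH and
essentially all CCH; the second CHH enzyme is mild — and were chosen so
the expected pairwise distances reproduce the empirical three-group
structure (CG mutant alone; the two CHG-machinery mutants; the CHH
mutants with wild type). They are presets, not measurements.

Observed data: coverage ~ Poisson(λ = 20), resampled to ≥ 1; methylated
reads ~ Binomial(cov, p_true + (1 − p_true)·ε) with non-conversion
ε = 0.008. Read simulation extends the telomere outward by 2 kbp of
perfect repeats so reads lying fully inside a telomere exist; each C is
emitted as C with probability p_obs, else T. All randomness flows from
one seeded generator: a seed fixes every output byte.

What the generator does *not* emulate — and hence what passing tests do
not certify about real data: sequencing errors and quality profiles, PCR
duplicates, mappability bias in repetitive DNA, coverage waves,
context-dependent conversion efficiency, biological replicate variance
beyond binomial sampling, and the mitochondrial insertion that separates
telomere from ITS on one real arm. Tests certify the *procedures* —
coordinate handling, context classification, threshold logic, estimator
consistency — under a faithful but idealised noise model.

## Problem sizes and numerical choices

Default analyses run on a single ~3.5-kbp synthetic end (≈ 1 250
cytosines), the scale of a real chromosome-end analysis; the
differential-call validation uses a ~5.5-kbp end giving > 100 tiles;
clustering robustness is measured over 50 seeds and read classification
over 10 000 reads. Varimax converges at 1e-6; correlation entries with
fewer than 3 complete cases are NaN rather than errors; degenerate
two-sample groups return None rather than raising; tile levels with no
covered sites are NaN and excluded from means. Reported percentages are
on the 0–100 scale throughout.

## Known limitations

The ITS caller models single-mismatch variants of a fixed-length unit
only. The extent heuristic is a convention, not an estimator with known
sampling properties, and its defaults matter near the domain edge. The
boundary analysis presumes the canonical 70-bp block; ends lacking it
are rejected. The telomeric-read classifier allows no mismatches inside
(YYYTAAA)n, so sequencing errors deflate the telomeric read count
(though not, to first order, the methylated fraction). The pipeline
consumes per-cytosine call files; it does not align reads or re-call
methylation from BAM.
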