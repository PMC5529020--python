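# Methods

## Data model

An experiment consists of a toxin set (sequences over the 20 standard
residues; ambiguity codes X, B, Z, J, U, O are replaced by glycine at
ingestion), a flat array layout assigning every unique 15-mer to
`replicates` fields plus `corner_field_count` control fields, and two
per-field intensity recordings in arbitrary fluorescence units (AFU): the
naive-IgG **background** incubation and the subsequent **antivenom**
incubation. Grid geometry is deliberately abstracted to a flat field list —
corner-ness is a flag, not a coordinate — because no stage of the analysis
uses 2-D position; the randomized permutation of field contents is retained
(seeded) only so that simulated layouts reproduce exactly.

Positions are 1-based throughout, and a 15-mer is indexed by its N-terminal
residue, so a toxin of length L has profile positions 1..L−14.

## Signal model and correction

Because the antivenom is recorded after the background incubation, residual
binding inflates the second recording multiplicatively (re-incubation
effect). The factor is estimated as

    rho = median(corner antivenom) / median(corner background)

and removed per peptide: `S = median_AV − rho · median_BG`. Replicate
medians (not means) are used for outlier robustness; lost replicate fields
are tolerated (median over the fields present). Corrected scores are *not*
clamped at zero — the downstream Z-test needs the full null distribution.
The ratio form is used because the effect acts multiplicatively on signal
scale; with corner channel medians of, say, 50 and 215 AFU the factor is
4.3, the magnitude reported for real arrays of this design.

Profiles are smoothed with a 3-wide running median (median of a window and
its two flanking windows). Terminal positions take the median (= mean) of
the two available values rather than being dropped: this preserves profile
length so that the "two successive significant 15-mers" recognition rule is
well defined at sequence termini. The cost is that an isolated elevated
window at position 1 or L−14 is averaged down — a deliberate bias toward
specificity.

## Null calibration and calling

The null SD sigma is bootstrapped from the two empirical corner-control
distributions: per repetition, three neighbouring pseudo-peptides each draw
`replicates` values per channel with replacement, channel medians form
corrected scores, and their 3-window running median gives one null score;
sigma is the SD over `n_boot = 50,000` repetitions. The scheme mirrors
every transformation applied to real scores, which is the property that
makes the calibration valid. It is conservative by construction: corner
peptides are chosen for their unusually strong unspecific binding, so sigma
over-estimates the noise of typical peptides and p-values are biased
upward. Empirically (see the acceptance experiment) the realized
false-discovery proportion on null arrays is far below the nominal
alpha = 0.05 — control is comfortably satisfied, not tight.

One-sided p-values `p = Phibar(S / sigma)` are corrected with the
Benjamini–Hochberg step-up over the family of **deduplicated
(peptide, running-median) pairs** — the same peptide can carry different
running medians in different sequence contexts, and each distinct pair is
one hypothesis. The smallest significant score becomes the array-wide
threshold (+infinity when nothing is rejected); per-position significance
is equivalent to clearing it because p is monotone in S. A toxin is called
recognized iff some maximal significant run has length >= 2.

## Epitope segments, cores, similarity

Scores anchor to subfamily MSA columns via the N-terminal residue; gap
columns carry no value, and rows are checked to ungap to their toxin
sequence. Segment borders are not sharply defined in this kind of data, so
a simple maximality rule is used: consecutive columns with at least one
above-threshold score merge into an interval, and the interval is reported
iff at least `min_share` toxins have an above-threshold score inside it.
`min_share` defaults to 10 and is exposed because "more than ten" and "ten
or more" are both defensible readings of the sharing rule.

The core motif comes from the member with the highest peak (ties broken by
accession order): its longest run of r consecutive significant 15-mers
overlapping the segment shares exactly the residues at positions
`start + r − 1 .. start + 14`, so `|core| = 15 − r + 1`. Runs longer than
15 would share nothing and are rejected as an error. Similarity is
evaluated at the core's alignment columns (anchored, not free-sliding,
consistent with the column-wise logic of the segment analysis): a toxin
whose residues there are within Hamming distance `max_mismatch = 3` of the
core (gaps count as mismatches) contributes the sum of running-median
scores of **all** its 15-mers containing the window — significance of the
individual 15-mers is not required, since the sum is a graded binding
measure, not a call.

## Residue associations and logos

Logo matrices use per-position frequencies over non-gap symbols and Shannon
information `log2(20) − H` in bits (0 to ~4.32); letter height is frequency
times information. The residue–binding association is a re-implementation
of the rank-based genotype–phenotype approach popularized by the SigniSite
server: sequences are ranked ascending by sum-of-scores (average ranks on
ties), and each (position, residue) carried by n_r of N sequences gets

    Z = (W − n_r (N+1)/2) / sqrt(n_r (N − n_r)(N+1)/12)

with W the carriers' rank-sum, so positive Z means association with high
binding. Conserved residues (n_r = N) and absent ones get no Z — a fully
conserved epitope residue is invisible to this statistic by design. Gaps
are kept as a 21st association category (a gap can associate with low
binding) but are excluded from logo frequencies. Two-sided normal p-values
over all defined pairs are BH-corrected at alpha = 0.05; the choice of
family and correction is made here, as the reference tool does not fix one.

## Structure painting

Per-residue scores are the per-core sums over the residues of each matched
core window; overlapping cores resolve to the per-residue **maximum** (the
alternative, summing, double-counts peptides shared by two cores). Scores
are linearly rescaled to [0, 99.99] and written into the PDB
temperature-factor column (fixed-width columns 61–66, two decimals), the
conventional carrier for score painting; all other bytes of the file are
preserved, and residue numbering maps to toxin positions through a
user-supplied offset since published structures rarely start at 1.

## Synthetic generator

The generator emulates exactly the structure the analysis assumes:

* **Families** are built from a random ancestor with independent per-site
  substitutions (rate 0.3), so members of a family share length and the
  identity alignment is a valid gap-free MSA. Real subfamily alignments
  have indels; the gap-handling code paths are exercised instead by
  hand-constructed alignments in the tests.
* **Planted epitopes** are motifs of 4–12 residues — the typical span of a
  linear epitope element — overwritten at a shared position in a random
  subset of a family (default 60% of members). The antivenom channel of
  every field whose peptide contains a motif is elevated by `effect_size`.
* **Noise** is log-normal per field (non-negative, heavy right tail;
  background median 50 AFU, log-SD 0.5), with a heavier, brighter corner
  distribution (median 150 AFU, log-SD 0.8) reflecting the corner peptide's
  stickiness. No distributional form is canonical for array fluorescence;
  log-normal is a standard defensible choice and is documented as such, not
  claimed as the true law.
* **Re-incubation** multiplies an *independent* fresh unspecific draw by
  the factor (default 4.3) rather than re-scaling the background draw:
  the analysis corrects with channel medians, not per-field pairing, so
  independence is the conservative model.

Under these defaults the bootstrap null SD is roughly 270 AFU, so the
default planted effect of 1500 AFU is a clear binder (~5.5 sigma), chosen
to represent the strong peptide series such arrays show for genuinely
recognized toxins. Passing tests on this generator demonstrate the
pipeline's statistical correctness (FDR control, recovery of planted
structure, oracle equivalence of each primitive); they do not demonstrate
robustness to spatial artefacts, scanner saturation, print-tip effects or
sequence-composition-dependent synthesis efficiency, none of which the
generator models.

## Problem sizes and numerical choices

* Calibration experiments use 200 null arrays of ~100 toxins
  (~2,000 unique peptides, lengths 30–38, 200 corner fields) and 100
  planted-recovery simulations of 40 toxins — sizes chosen so the whole
  suite runs in well under a minute while keeping Monte-Carlo error small
  relative to the margins tested.
* All randomness flows from explicit integer seeds; one global seed fans
  out to stage-specific children via `numpy.random.SeedSequence` (children
  kept below 2^31). Reruns are byte-identical.
* BH is hand-rolled (six lines) because the calling chain needs the
  rejection-set/threshold pair; tests verify it against an independent
  implementation and a brute-force step-up oracle.
* Degenerate inputs: constant corner distributions give sigma = 0 (and the
  Z-test then refuses to run rather than divide by zero); empty rejection
  sets give an infinite threshold and no recognized toxins; sequences
  shorter than 15 yield empty profiles and are skipped with a log entry.

## Known limitations

* The corner-based null is intentionally conservative; arrays whose
  controls are much stickier than their library peptides will under-call
  weak binders. No per-peptide variance model is attempted.
* Terminal motifs spanning a single 15-mer are suppressed by the running
  median (observed as the ~3% miss rate in the recovery experiment) — a
  real limitation of the two-successive-peptides design, not of the
  implementation.
* MSAs are consumed, not computed; alignment quality directly bounds
  segment quality.
* Only linear epitope elements are addressable; discontinuous epitopes are
  out of scope by the nature of the assay.
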