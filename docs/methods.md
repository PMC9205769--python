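# Methods

This note documents the models, conventions and numerical choices behind
`fourcscape`, in the order the pipeline applies them.

## Coordinates and builds

All intervals are 0-based, half-open. A *base* genome is edited by an
insertion manifest into a *modified* genome; the `CoordinateMap` records an
ordered list of blocks per chromosome, each either `collinear` (identical
sequence in both builds, equal lengths) or `insert` (present only in the
modified build, zero-length base interval at the insertion point). Blocks
tile the modified chromosome, so restricted to collinear blocks the map is
a bijection and base→modified→base is the identity everywhere.

Only insertions are supported. Large deletions (e.g. removing the
intervening sequence between a distal enhancer and the reporter) are
represented by constructing a second base genome rather than by deletion
blocks; this keeps the map monotone and the round-trip guarantee
unconditional.

## Digestion model

The first cutter partitions each chromosome at `motif_start + offset` for
every (possibly overlapping) motif occurrence; both strands are scanned,
and a reverse-strand occurrence of a non-palindromic motif cuts at the
mirrored offset `motif_start + len − offset`. Defaults are Csp6I
(`G^TAC`, offset 1) and NlaIII (`CATG^`, offset 4); both default motifs are
their own reverse complements, so the default digestion is
strand-symmetric, but the scanner handles arbitrary motifs. Offsets are
configuration, not constants, because the enzymes' cut chemistry is a
property of the protocol, not of the analysis.

Within a primary fragment, the left end region runs from the fragment start
to the first second-cutter cut in the fragment and the right end region
from the last such cut to the fragment end. A fragment with no internal
second-cutter cut is *blind*: both of its ends carry the full fragment
interval and are flagged blind (for blind ends, and only for them, the two
regions coincide). Zero-length end regions — a second-cutter cut exactly at
a primary cut — are likewise blind: they contain no sequence to map.

Uniqueness of an end is operationalized as exact duplication: an end is
non-unique if its full-length region sequence, or its reverse complement,
occurs more than once in the genome. This is deliberately the strictest,
oracle-checkable criterion; it is not an alignment-based mappability model,
and repeat-mediated multi-mapping below full-length identity is out of
scope.

## Common-end matching

Two ends from different builds are *common* when their primary cuts project
to the same base coordinate with the same side and neither end region
touches an insert block or a block junction in its own build. Ends whose
region spans an insertion junction are excluded from pairing (and flagged),
because their sequence differs between builds even though the cut position
survives projection. Zero-length regions are treated as points for the
junction test so that self-matching a build pairs every end.

## Normalization and smoothing

Raw counts are scaled so that the cis (viewpoint-chromosome) reads sum to
1,000,000 — excluding from the denominator the two fragments with the
highest cis coverage, summed per primary fragment over both ends. In real
viewpoint profiles these are the over-captured fragments at the viewpoint
(self-ligation and undigested products); excluding them makes the scale
robust to their arbitrary magnitude. The excluded fragments' ends are
*not* removed from the output: they are scaled by the same factor and
remain plottable; only the denominator ignores them. Ties in coverage are
broken by ascending genomic coordinate, which makes the exclusion
deterministic. Trans-chromosome ends are carried through, scaled by the
same cis-derived factor, and never enter the denominator.

Smoothing is a 21-fragment-end centered rolling mean over the retained
(non-blind) ends in genomic order. The window never crosses a chromosome
boundary and truncates at profile edges (the first end of a chromosome
averages the 11 available ends). The window is counted in retained ends,
not genomic fragments, because blind ends are removed before any analysis
step.

## Differential contact tracks

Differential contacts compare normalized, *unsmoothed* values: per-fragment
coverage is averaged within 5-kb bins for each profile and subtracted
(B − A). The bin grid is anchored at chromosome coordinate 0 — not at the
viewpoint — so tracks are reproducible without knowing the viewpoint; a
fragment end belongs to the bin containing the midpoint of its end region,
and all ends weigh equally regardless of length. Bins containing no
fragment end are blank (NaN), never zero: "no data" and "no difference"
are different statements. Only common (paired) ends contribute; smoothing
is used for profile overlays only.

Color classification: |Δ| < 50 normalized reads is white, 50 ≤ |Δ| ≤ 500
maps linearly to intensity (|Δ| − 50)/450, |Δ| > 500 saturates; the sign of
Δ gives the gained/lost direction. The boundary value 50 is the first
colored step (white is strictly "< 50").

## E–P quantification

The enhancer end set is an explicit input: the non-blind fragment ends
overlapping the enhancer insert interval that are uniquely mappable in
every compared build. Its size is therefore a property of the genomes (on
the preset synthetic landscapes it comes out at 11–14 ends), never a
hard-coded constant. E–P contact frequency is the mean normalized
(unsmoothed) value over the set, in reads per million cis reads;
equivalently the summed signal is expressed as a percentage of cis
contacts. Replicate profiles, when present, are averaged at the profile
level before end-level averaging.

## Assay formulas

*FACS.* The GFP-negative gate is the 0.999 quantile of the enhancer-less
(noE) control intensities, computed with linear interpolation between order
statistics — a deterministic substitute for a manually drawn gate. For
sample sizes where the interpolated quantile would leave more than 0.1% of
control cells above the gate, the threshold is raised to the next order
statistic, so "≥ 99.9% of control cells gate-negative" holds for every n.
Percent-positive counts cells strictly above the threshold. Relative
fluorescence under knockdown is
(median_KD − median_noE)/(median_ctrl − median_noE); medians, not means,
throughout. Whether the gate is drawn on untreated or hemin-treated control
cells is the caller's choice — the functions take whichever control sample
is supplied.

*ChIP–qPCR.* Percent input assumes amplification efficiency 2 per cycle
(configurable): the input Ct is first adjusted for its dilution
(`ct_input − log2(dilution)`), then percent input =
100 · 2^(adjusted_input − ct_ip). Reported enrichment is the ratio of
percent-input values between a target site and a known bound reference
site from the same immunoprecipitation, which cancels batch-wide Ct
offsets.

## Synthetic-data model

Per retained cis fragment end at end-region midpoint x, with viewpoint v:

    w(x) = (|x − v| + d0)^(−α) · Γ(x) · Λ(x) · K(x)

- Γ(x) = γ inside a domain interval, else 1 (enhancer-induced domain gain);
- Λ(x) = Π over anchors (1 + β · exp(−(x − a)²/2σ²)) (CTCF loop peaks);
- K(x) = κ on the over-captured viewpoint fragments, else 1.

Counts are a single multinomial draw of `n_cis_reads` over the weights, so
cis reads are conserved exactly; trans reads
(`n_cis · trans_fraction/(1 − trans_fraction)`) are uniform over trans
ends. Everything is driven by one seed.

Defaults: α = 1.0, d0 = 1,000 bp, κ = 1,000, capture radius 1,000 bp,
γ = 2, β = 5, σ = 2,500 bp, trans_fraction = 0.3, n_cis = 1e6. These are
simulator conventions chosen so that every pipeline rule is exercised:
κ = 1,000 guarantees the top-2 exclusion removes the viewpoint fragments,
γ = 2 produces domain gains comfortably above the 50-read color floor at
1e6 reads, and α = 1 gives the monotone decay the E–P distance analysis
expects. Over-capture is applied at the fragment level — the at most two
fragments nearest the viewpoint within the capture radius — because the
over-captured species in a real experiment (self-circle, undigested
neighbor) are whole fragments; a per-end radius could tag ends of a third
fragment and leave an over-captured fragment inside the normalization
denominator, which no real protocol exhibits. Pure-decay variants for
distance-response analyses set γ = 1 and anchor amplitude β = 0, which
makes Λ ≡ 1.

The preset landscape is a 600-kb segment with the reporter viewpoint at
500 kb and a 6.5-kb enhancer cassette ending 0/11/47/100/407 kb upstream of
it, mirroring the engineered integration series; each enhancer scenario
gains γ across the enhancer-to-viewpoint interval, and EC variants add two
loop anchors flanking that domain. A 60-kb trans chromosome receives the
trans read fraction. Toy genomes plant cutter motifs at jittered spacings
(first cutter every ~1 kb, second every ~300 bp) on a background scrubbed
of accidental motif occurrences, so fragment sizes are controlled.

What the simulator does **not** emulate: PCR duplicates and primer bias,
restriction/ligation efficiency variation between fragments, mappability
structure beyond exact duplication, biological replicate variance beyond
multinomial noise, and any mechanistic loop-extrusion dynamics. Passing
tests therefore demonstrate that the analysis rules are implemented
correctly and recover structure from data with the assumed statistics —
not that the assumed statistics describe any particular real experiment.

## Problem sizes and determinism

The bundled analyses run on 600-kb single-chromosome landscapes
(~1,200–1,400 fragment ends) with 1e6 cis reads per profile and ten seeds
per stochastic check; these sizes give per-end expected counts high enough
for the 50-read differential threshold to be meaningful while keeping any
run in seconds. All stochastic stages require an explicit seed; there is no
hidden global RNG, and identical scenario + seed reproduces profiles
byte-for-byte.

## Known limitations

- Insertions only in coordinate maps; deletions/inversions need a second
  base build.
- Exact-duplication uniqueness is stricter than aligner mappability.
- Differential tracks are descriptive (binned means), with no per-bin
  significance model — matching how such tracks are usually drawn.
- FCS binary files are not parsed; FACS samples are ingested as plain
  per-cell intensity columns.
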