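# Methods

## Data model and coordinate conventions

All genomic coordinates are 1-based inclusive, matching both GTF and the
9-column splice-junction table dialect (STAR `SJ.out.tab`); no half-open
intervals exist anywhere in the package. An intron is the closed interval
from its first to its last intronic base; on the minus strand the donor is
the interval's high end. Junction-table motif codes 5 and 6 carry the
non-canonical TT/AG intron class (UU/AG on RNA) and its reverse-complement
reading, occupying the slot the stock aligner dialect gives the minor-
spliceosome AT/AC pair — appropriate for *C. elegans*-like genomes that
have no minor spliceosome.

Junction "support" defaults to uniquely mapping reads only
(`count_policy="unique_only"`); whether multimappers should count is not
standardized, so `unique_plus_multi` is available. Strand-undefined
junctions (strand code 0) are retained in count matrices but excluded from
all motif and shift analyses, where orientation is required.

## Motif classes

An intron's motif class is determined solely by its first and last two
bases, read in transcript orientation from the genome: `GT_AG`, `GC_AG`,
`TT_AG`, or `OTHER` (any N in the four bases also gives `OTHER`). Labels are
kept in the DNA alphabet; RNA display (GU/UU) is a reporting concern only.
The aligner-level choice of treating UU/AG introns on the same footing as
GU/AG is represented as membership of `TT_AG` in the default allowed set of
`filter_by_motif` — this package consumes junction tables and never scores
alignments. Whether `OTHER`-class junctions should be dropped entirely is
configurable; the default excludes them.

## Event inference

De novo alternative 5'/3' events: junctions sharing (chromosome, strand,
shared boundary) are grouped and every unordered pair of alternative
boundaries is emitted as one event if (a) the boundaries are at most 50 nt
apart (inclusive) and (b) the two junctions together carry at least 5 reads
summed over all samples. The support threshold is deliberately read as the
sum over both alternative junctions: an event is only informative when both
forms are observed. A per-junction minimum can be imposed by the caller.
Multi-way sites decompose into all unordered pairs, each screened
independently. Form 1 is the higher-support form; ties break to the
upstream site in transcript orientation so output is deterministic.

Annotation-derived events come from pairwise comparison of a gene's
transcripts: skipped exon (SE) and multiple skipped exons (MS) when a run of
one or more introns in one transcript is replaced by a single intron with
the same outer boundaries in the other; mutually exclusive exons (MX) when
two consecutive-intron pairs share outer boundaries but have non-overlapping
middle exons; retained intron (RI) when one transcript's intron lies inside
a single exon of the other whose ends match the flanking exons' outer ends;
alternative first/last exon (AF/AL) when two introns share their inner
boundary but splice from non-overlapping terminal exons; and annotated A5/A3
when two introns share one end and their differing-side flanking exons
overlap (the overlap requirement prevents an SE pair, seen through one of
its junctions, from masquerading as an alternative-donor/acceptor event).
Duplicate events across transcript pairs are collapsed on their form sets,
and output is invariant to transcript input order.

## PSI

Form-level counts are the mean of a form's junction counts; a form with a
single junction contributes its count directly. The mean (rather than sum or
minimum) keeps a two-junction inclusion form on the same scale as a
one-junction skip form and is robust to one junction losing reads to
overhang filters. PSI = c1/(c1+c2), undefined when the informative total
falls below `min_denominator` (default 1 — the screen's event-level 5-read
support filter already guards against uninformative events; raise it to
mask low-coverage cells per sample). RI events quantify the spliced junction
against an intron-body coverage value supplied in an auxiliary retention
table; RI events without such a table are dropped with a warning rather
than misquantified.

## The screen

All ordered pairwise differences ΔPSI = mutant − control are computed
(9 for 3 vs 3 replicates). pairSum counts differences strictly exceeding
`min_pair_delta` (default 0.15) in the direction of the mean difference
(`signed_consistent`); an `absolute` policy that ignores direction is kept
for sensitivity analysis. An event passes when pairSum equals the number of
pairs (9) and |mean ΔPSI| strictly exceeds `min_mean_delta` (default 0.20).
Both thresholds are strict inequalities on fractions and are tested at
their boundaries. Events with any missing PSI cell in either group are
excluded, not imputed — exclusion is the conservative choice. No
multiple-testing correction is applied: requiring unanimous replicate
concordance is itself the false-positive gate, and adding an FDR step
silently would change the method. A Welch unequal-variance two-tailed
t-test on per-replicate PSI (`psi_t_test`) is provided for reporter-style
comparisons; the degenerate all-constant-equal case returns p = 1.

## Shift classification

For a passing A5/A3 event, the predominant form is the one with the higher
mean control-group PSI (the natural formalization of "the site favored in
control") and the promoted form is the one gaining PSI in the mutant. The
offset is the signed distance in nucleotides from predominant to promoted
site in transcript orientation (positive = downstream). Classes:

* `SLIP_UU`: offset +1, promoted intron starts TT, predominant intron
  starts GTT — the slip signature;
* `GU_SHIFT`: 5' offset of magnitude 2–4 with the promoted intron starting
  GT;
* `INFRAME_UPSTREAM_3P`: 3' offset negative and divisible by 3 (−6/−9
  being the typical cases);
* `OTHER`: everything else.

The call depends only on the control-PSI ordering and the sign of the mean
ΔPSI, never on which form was labelled form 1 at inference time. An event
whose control-predominant form is also the promoted one has no shift to
classify and is skipped with a logged warning.

## Logos, lengths, overlaps

Position-frequency matrices are built over transcript-oriented windows
around donor or acceptor sites; default windows are 3 exonic + 8 intronic
positions (donor) and 16 intronic + 3 exonic (acceptor). These defaults are
a declared package convention covering the informative positions of
metazoan splice sites, not an inference from any particular figure. Column
information content is R = 2 − H bits with H the Shannon entropy of the
column's base frequencies; no small-sample correction is applied (at the
site counts this pipeline produces the correction is negligible, and
applying it would need an arbitrary choice of estimator). Sites whose
window leaves the chromosome or contains N are excluded and logged.
Intron-length summaries report median (midpoint interpolation for even n)
and quartiles per labelled group; empty groups are omitted with a warning.
`overlap_counts` returns exact Euler-region cardinalities for two or three
event-id sets plus |A∩B|/|A|.

## Synthetic data

The generator is the package's definition of the study conditions, not a
test fixture. Each planted event occupies its own gene; genes are laid out
sequentially (so they cannot overlap) with 300-nt spacers, exon lengths
uniform on 80–200 nt, and intron lengths drawn from a two-component
log-normal mixture (short mode median 47 nt, σ = 0.35, weight 0.85; long
mode median 500 nt, σ = 0.6) emulating the strongly bimodal intron-length
distribution of compact genomes. Every constitutive intron receives a GT
donor and a TTTCAG acceptor end; planted events overwrite the donor (or
acceptor) context of their target intron: `GTTAAG` for the +1 slip
template, `GTGTAA` for the +2 GU shift, an extra AG 6 nt upstream of the
acceptor for the in-frame 3' template, and `GTAAGT` (two GT donors 4 nt
apart) for null events. SE and RI templates add a second annotated isoform
instead.

Replicate counts: per event and library, total depth is Poisson(depth) and
the form-1 count is beta-binomial with the planted true PSI as mean and
overdispersion ρ (mean-parametrized: α = ψ(1−ρ)/ρ, β = (1−ψ)(1−ρ)/ρ);
ρ = 0 reduces exactly to binomial sampling. Background junctions — the
constitutive introns, topped up with extra 3-exon genes until they number
`background_per_event` (default 10) times the planted events — receive
independent Poisson(depth) counts in every library, giving the screen
realistic negatives. Defaults are depth 200, ρ = 0.01, 3 replicates per
condition. Planted effects default to control PSI 0.05 and mutant PSI 0.35
(ΔPSI 0.30): promoted sites are near-silent in control, which is the
regime a slip-promoting mutant creates. All randomness flows from one seed;
identical configurations write byte-identical files.

A separate multinomial simulator (`simulate_reporter_assay`) emulates
splice-site competition reporters with 2–4 competing donors (the 3-choice,
2-choice doublet and 2×2 doubled-doublet designs).

What the generator does **not** emulate: read-level errors and alignment
artifacts, overhang-dependent junction losses, expression differences
between genes and conditions, NMD-driven isoform degradation, overlapping
genes, and sequence composition beyond the planted contexts (non-motif
bases are uniform). Passing tests therefore demonstrate the correctness of
the event/PSI/screen/classification machinery under the declared noise
model, not robustness to alignment pathology in real libraries.

## Problem sizes and numerical choices

The operating-characteristics check uses 200 planted alternative-donor
events (100 slip, 100 GU-shift, true ΔPSI 0.30) plus 200 nulls at depth
200 and ρ = 0.01 — large enough that recall and null pass-rate estimates
have standard errors under 2 percentage points, small enough to run in
seconds. A pre-hoc power calculation at these settings (per-sample PSI
standard deviation ≈ √(ψ(1−ψ)(1+(n−1)ρ)/n) ≈ 0.06 at ψ = 0.35) puts the
probability that all nine pairwise deltas clear 0.15 at roughly 0.94 per
event, so the ≥ 90 % recall requirement is expected to hold with margin
while remaining sensitive to regressions in the screen logic.

Ties and degenerate inputs: equal-support forms order by upstream site;
a mean ΔPSI of exactly 0 leaves the screen direction undefined and falls
back to the absolute pairSum (flagged); zero-variance equal-mean groups in
the Welch test return p = 1; empty junction tables, empty motif-filter
output and empty event sets are all legal and produce empty outputs rather
than errors.

## Known limitations

* RI quantification depends on an externally supplied intron-body coverage
  value; the package does not derive retention from raw coverage profiles.
* Annotation-derived event templates cover the eight standard classes but
  do not attempt full transcript-structure reconciliation; exotic isoform
  pairs (e.g. nested retained introns) may produce events in more than one
  class, which downstream deduplication treats independently.
* The screen requires complete PSI in both groups; at low depth this can
  discard true events rather than risk imputation bias.
* Logo output is numeric (PFM/TSV/TRANSFAC); graphical rendering is out of
  scope.
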