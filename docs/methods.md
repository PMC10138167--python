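# Methods

This note records the models, conventions and design choices behind
`aqpkit`, in the spirit of a package manual: what each procedure assumes,
which knobs matter, and what the synthetic-data tests do and do not show
about real data.

## Position templates and residue-level annotation

Aquaporin motif tables (NPA I/II, ar/R, Froger P1–P5, SDP1–SDP9) are
conventionally reported relative to a curated multiple alignment, never as
absolute coordinates. `aqpkit` supplies that anchor as one
`PositionTemplate` per subfamily: a synthetic reference sequence whose
feature columns are known exactly, ordered as in the canonical MIP fold
(ar/R H2 upstream of the loop-B NPA, then H5, Froger P1, the loop-E NPA,
LE1/LE2, Froger P2–P5, then the per-substrate SDP columns). Reference
residues at feature columns are the subfamily's representative signatures
from the packaged roster and SDP tables; filler positions cycle through a
fixed alphabet that deliberately excludes asparagine and proline, so a
degenerate `N-P-x` triplet can only occur at planted columns. The
templates are therefore a *construction*, not a reconstruction of any
published alignment; annotations of real proteins depend on how well they
align to this backbone and should be read as template-relative calls.

A query is annotated by global Needleman–Wunsch alignment (BLOSUM62; gap
of length k costs 10 + 0.5·(k−1); wildcard `X` scores 0 against
everything) and each template column is carried through the alignment.
Columns landing on gaps are reported missing rather than guessed.
Alignments with identity below 0.25 over aligned columns raise a
low-confidence error carrying the identity, instead of silently emitting
an annotation. Traceback ties are resolved by taking the aligner's first
optimal alignment, which is deterministic for fixed inputs.

`find_npa_motifs` scans with the degenerate grammar `N-P-[ASTLVI]`
(alanine plus the third-position variants observed in plant AQPs). When
fewer than two grammar hits exist and a template is available, the three
NPA columns of each motif are mapped through the alignment and vote on the
implied triplet start (majority over the three columns); this recovers
fully substituted variants such as the XIP SLV/SPA pair. The first
reported motif is labelled loop B, the second loop E, and overlapping
pairs are never reported. Limitation: when spacer regions carry insertions
or deletions immediately at a fully substituted triplet, the vote can
shift by a residue; recovery is exact when local flanks align without
gaps, which the oracle tests construct explicitly.

## Physicochemistry

Mw, pI and GRAVY follow ProtParam conventions via Biopython: average
residue masses plus one water (reported in kDa), the Bjellqvist pKa set
with bisection on net charge, and the mean Kyte–Doolittle hydropathy.
Wildcard residues are rejected unless an explicit skip policy is set, in
which case they are excluded from the average. Transmembrane segments use
a 19-residue window and a hydropathy threshold of 1.6 (classic
Kyte–Doolittle proposal for membrane-spanning stretches); reported spans
are unions of qualifying windows, so a detected segment extends up to one
window beyond a sharp hydrophobic block. This heuristic deliberately
replaces HMM topology prediction and is not expected to reproduce
HMM-derived domain counts; the roster's `tdp` column is carried as a
lookup field only.

## Subfamily and substrate inference

The subfamily tree tests, in order: P5 ≠ W → NIP; P4=F and P5=W → PIP when
P1 ∈ {E, Q}, XIP when P2 = C; P4=Y and P5=W → TIP when P1 ∈ {T, V},
otherwise SIP. On the packaged 28-member roster the tree resolves every
member without its fallback (nearest subfamily reference by Hamming
distance over Froger + ar/R, flagged `fallback`). The tree is a compact
summary of the family's observed signature patterns; in other species,
signatures outside these patterns will take the flagged fallback path
rather than fail.

Substrate inference compares a member's nine SDP residues against the
substrate's allowed sets and counts mismatch positions. The published
analyses classify some members *despite* named substitutions without
stating a numeric rule, so the default here is strict (tolerance 0) with
per-substrate overrides for prose-style lenient calls, and the mismatch
positions are always reported so lenient calls remain auditable. With the
packaged tables, the strict urea rule classifies exactly the four NIP
members, and CO₂ requires one mismatch of slack (all three tabulated PIP
vectors differ only at SDP3).

Distance trees use p-distance (1 − identity over aligned non-gap columns
of pairwise global alignments) and Saitou–Nei neighbor joining via
scikit-bio; NJ is exact on additive matrices, which the tests verify on
randomly generated 4–8-taxon trees. This desk-scale stand-in is
deterministic; no bootstrap is computed.

## Promoter cis-element scanning

The catalog holds one IUPAC consensus per element; the shipped YAML uses
PlantCARE-convention defaults (ARE `AAACCA`, WRE3 `CCACCT`, WUN
`AAATTTCCT`, STRE `AGGGG`, LTR `CCGAAA`, MBS `CAACTG`, DRE `GCCGAC`,
AT-rich `ATAGAAATCAA`, TC-rich `ATTTTCTTCA`) and is editable — these are
working definitions, not ground truth from any one source. Scanning
reports every position/strand match; coordinates are 0-based and refer to
the forward-strand leftmost base, with minus-strand hits meaning the
reverse complement matches. A promoter `N` matches nothing. Presence
matrices mark a gene/element pair true at ≥ 1 hit, and gene counts support
element groups (the wound pair WRE3 + WUN counts genes with at least one
of the two).

The packaged presence fixture encodes the published per-element gene
lists; because those lists name wound genes jointly (≥ 1 of WRE3/WUN),
the fixture marks both columns for those genes. One list-derived count
(MBS) disagrees with its prose total (17 stated, 18 implied by the
exception list); the fixture follows the exception list and the count is
not used as a check.

## Gene structure and Ka/Ks

Gene models use GFF3 1-based inclusive exon coordinates; introns are the
gaps between consecutive exons, and cohort extrema break ties by first
gene in input order. UTRs, when annotated as distinct features, are
carried but excluded from exon-length statistics.

Ka/Ks implements Nei–Gojobori (1986): per-codon synonymous site fractions
(each of the nine single-base neighbours contributes one third of a site;
mutations creating stop codons count as nonsynonymous, so S + N = 3 ×
codons), sites averaged over both sequences; observed differences averaged
over all orderings of a codon's changed positions with stop-containing
intermediates dropped before averaging (all orderings kept if every one
hits a stop); Jukes–Cantor correction applied to both proportions, and
declared undefined at proportions ≥ 3/4. Ka/Ks is undefined when Ks = 0.
The published family analysis used an unspecified web tool; no attempt is
made to match its printed per-gene values from sequences — only the
"ratio < 1 under purifying selection" behaviour is exercised, on simulated
codon pairs.

## Expression

Relative expression follows the efficiency-corrected ratio
`E_t^ΔCt_t / E_ref^ΔCt_ref` with ΔCt = Ct(calibrator) − Ct(sample) and
efficiencies in (1, 2] (2 = perfect doubling, the default). With both
efficiencies at 2 this reduces exactly to 2^ΔΔCt. Replicates are averaged
as technical-within-biological, then across biological replicates, before
ratios are formed. Not-detected cells are missing data — masked, never
imputed as zero. The calibrator is a configuration field: the source
protocols name both a 0 h baseline and a 6 h control as calibrators in
different places, so the choice is explicit per analysis, defaulting to
the baseline sample. Regulation calls use a configurable |log2FC| cutoff,
default 1 (2-fold), with closed boundaries (a value exactly at the cutoff
is called). Clustering is average linkage on Euclidean distance over
pairwise-complete unmasked cells; profiles that cannot be placed (fewer
than two shared unmasked cells) are excluded with a warning.

## Synthetic data: what it does and does not emulate

All generators are pure functions of (parameters, seed) with a single
NumPy PCG64 stream each, and every dataset ships machine-readable ground
truth. Defaults mirror the targeted study design: 28-member rosters built
from the packaged signatures, 2000 bp promoters, exon counts 1–5 (0–4
introns), codon pairs of 300 codons with 15 synonymous and 3
nonsynonymous planted changes (purifying regime), Ct tables with 3
biological × 2 technical replicates and 0.2-cycle Gaussian noise.
Protein spacers are the template backbone mutated at 15% substitution and
up to 15% net indels; promoter backgrounds are uniform A/C/G/T rejection
sampled to contain no catalog motif on either strand, which makes presence
lists exactly recoverable by construction.

What passing recovery tests show: the scanners, mappers and estimators
invert their own generators exactly under the stated conditions. What they
do not show: performance on real sequence data, where motif-free
backgrounds do not exist, promoters contain many more element families,
codon evolution is not independent across sites, and real AQP proteins
diverge from any fixed template in structured, lineage-specific ways.
The roster and SDP fixtures are transcriptions of published tables, so
checks against them validate the inference rules, not genome mining
(which is out of scope — no assembly is downloaded or parsed).

## Numerical conventions

Coordinates are 0-based half-open internally for promoters and 1-based
inclusive for GFF3 gene models. Tie-breaks are deterministic everywhere:
first optimal alignment, first gene in input order for extrema, input
order for clustering, `(distance, subfamily order)` for the classification
fallback. The pI bisection runs to Biopython's 0.01-pH default; alignment
scores are exact floats; NG86 oracle agreement is asserted to 1e−12.
Problem sizes in the test suite and acceptance script (≤ 8-residue
alignment enumeration, 4–8-taxon trees, 200 codon pairs, 100 recovery
seeds, 50 purifying replicates) were chosen as the smallest sizes that
exercise every code path and tie-break.
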