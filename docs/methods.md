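# Methods

## The classification model

HdrA proteins are represented as ordered strings of conserved domains
drawn from a small vocabulary: `FeS_N` (N-terminal [4Fe-4S] domain),
`TRX_FAD` (thioredoxin-reductase-like FAD-binding module), `TRX_FeS`
(the iron-sulfur half of that module), `Fd_ins` / `Fd_C` (inserted and
C-terminal ferredoxins, each binding two clusters), `MvhD` ([2Fe-2S]
electron-transfer subunit), `GltD` (glutamate synthase small subunit)
and `FeS_extra` (additional lone clusters).  The class catalog maps 28
such strings to class names, partitioned 13/5/7/3 over the four major
types.  Typing is rule-based and ordered: two `TRX_FAD` tokens decide
type II before anything else; `GltD` decides III; a terminal `MvhD`
decides Ia; a single `TRX_FAD` otherwise gives I; no `TRX_FAD` means
the protein is not an HdrA.  Twelve catalog entries are pinned by
published descriptions; the remaining templates complete the catalog
consistently with the global constraints (28 classes, the type
partition, 2–8 domains per class, pairwise-distinct templates,
type-consistency of every template under the typing rules).

Classification is exact ordered template matching within the assigned
type.  "Unassigned" is a first-class outcome: the scheme is closed, real
data need not be, and unmatched architectures report the nearest
template by token edit distance as evidence.

## Motif scanning and architecture assembly

Domains are found from deterministic fingerprints:

| motif      | pattern          | biology                                   |
|------------|------------------|-------------------------------------------|
| `FeS4`     | `C-X2-C-X2-C-X3-C` | one [4Fe-4S] cluster site               |
| `FeS2`     | `C-X2-C`         | half of a [2Fe-2S] site                   |
| `ROSS_NAD` | `G-X-G-X-X-G`    | Rossmann fingerprint, NAD⁺ preference     |
| `ROSS_NADP`| `G-X-G-X-X-A`    | Rossmann fingerprint, NADP⁺ preference    |

A match scores its number of constrained positions (patterns are
all-or-nothing); all occurrences are reported and resolved later.
Selenocysteine is scanned as cysteine.

Assembly rules (defaults; all configurable through `AssemblyRules`):
two Rossmann fingerprints 80–400 residues apart with no `FeS4` between
them form one `TRX_FAD`; a leftover Rossmann flanked by `FeS4` motifs on
both sides is an inserted `GltD`; two `FeS4` motifs whose starts are
≤60 residues apart form one ferredoxin domain; two `FeS2` half-sites
25–40 residues apart form `MvhD` (half-sites inside `FeS4` hits are
suppressed first).  Lone `FeS4` motifs are labelled positionally:
within the first 80 residues and before any `TRX_FAD` → `FeS_N`; within
90 residues after a `TRX_FAD` → `TRX_FeS`; otherwise `FeS_extra`.  With
two ferredoxin domains the last is `Fd_C` and the others `Fd_ins`; a
single ferredoxin is `Fd_ins` when it follows the previous domain within
160 residues, else `Fd_C` (a distant lone ferredoxin marks a collapsed
insertion region).  Overlaps resolve by higher score, then longer span,
then leftmost.  These thresholds are calibrated to the geometry of the
synthetic templates below; on real data the external evidence pathway
(CD-Search-style hit tables, which override built-in calls on the same
span) is authoritative, because the built-in fingerprints are
deliberately minimal.

## Residue calling

"Corresponding residues" are located by optimal global alignment
(Needleman-Wunsch with affine gaps, BLOSUM62, gap open 10 / extend 0.5,
where "open" is the cost of the first gap residue; `U` scores as `C`,
`X` scores 0 against everything) of the query to a reference sequence,
implemented on Biopython's `PairwiseAligner` and cross-checked in the
test suite against an independent recursion oracle.  Pairwise alignment
to the reference was chosen over calling from a full MSA: on conserved
cores both give the same answer, and pairwise keeps each call
independent of the composition of the rest of the data set.

Bifurcation competence requires *both* the lysine (409) and glutamate
(356) equivalents; the individual flags are always reported alongside,
since the two residues play distinct roles (the lysine contacts N5 of
FAD, the glutamate positions the lysine).  Queries below 15% alignment
identity to the reference are called "unalignable" — below the twilight
zone positional equivalence is meaningless.  The packaged anchors are
synthetic stand-ins generated by `hdrakit.synth` (no accession
downloads); real reference sequences can be supplied as FASTA + anchor
TSV.

The Molybdop frame (C118/P234/F235) maps to four statuses: `catalytic`
(Cys present), `serine_substituted` (the known non-catalytic Ser
replacement), `cofactor_blocked` (Cys absent and the occluding Pro or
Phe present) and `ambiguous`.

## Phylogeny preparation

Greedy identity clustering processes sequences by decreasing length
(ties by id, making the result independent of input order); identity is
identical alignment columns divided by the shorter sequence length, and
the first-founded matching cluster wins — the conventions of standard
greedy clustering tools at the 80% default cutoff.  Two-TRX (type II)
proteins are split at the floor midpoint of the linker between the two
TRX spans, a symmetric and deterministic boundary.  Inserted GltD spans
must be strictly internal to be excised.

The column trimmer keeps a column iff its Shannon entropy (bits,
computed over non-gap residues only) is ≤1.5 and its gap fraction is
≤0.2; all-gap columns are always removed.  This is a deliberate
simplification of BMGE-style trimming — no BLOSUM similarity smoothing,
no block gathering — so published core-region coordinates (e.g. a
252-residue automated core) are not expected to be reproduced
bit-exactly.  The trimmer is idempotent by construction.  Manually
curated cores are supported through `SegmentMask` (disjoint reference
segments; columns where the reference row is non-gap inside a segment),
shipped empty by default because no machine-readable coordinates exist
for the published manual selection.

## Gene neighborhoods

The manual criterion "transcription direction and gaps" is
operationalised as: same contig, same strand, intergenic gap ≤200 nt
(both configurable; defaults are stated in every output header, and
single intervening opposite-strand genes split a cluster by default).
Detection is a left-to-right scan producing a partition; for gap
thresholds g₁ ≤ g₂ the finer partition provably refines the coarser one.

The function rulebook is packaged data (TSV), one row per prediction
field (mid-potential carrier, high-potential arm, low-potential arm,
flags), evaluated most-specific-first per field: the type III/NADH rule
precedes the FdhB+blocked-Molybdop/F₄₂₀H₂ rule, which precedes
formate, plain FdhB/F₄₂₀H₂ and MvhAG/H₂.  Overall confidence is
"validated" only when the carrier row that fired is marked
experimentally validated.  Gene labels are normalised through an
editable synonym table (fwd/fmd subunits collapse to one token, vhu
names map to mvh).

## The synthetic generator

Generated proteins are concatenations of per-domain template instances
joined by random linkers of 20–60 residues (150–190 where a C-terminal
ferredoxin directly follows the TRX module, emulating the collapsed
insertion region).  Templates are synthetic consensus strings — not
real HdrA segments — with motifs at fixed offsets chosen so that every
assembly threshold above is satisfied with margin across the whole
linker range, and so that in the canonical reference layout the planted
lysine/glutamate fall at 1-based positions 409/356.  Linker, filler and
substitution alphabets exclude C and G, so point substitutions cannot
fabricate iron-sulfur or Rossmann fingerprints; motif-critical positions
are only substituted when `corrupt_motifs` is set, letting scanner
robustness and classifier robustness be tested independently.  All
generators draw from a single `numpy` RNG seeded per call and are
byte-deterministic under the seed.

What passing tests on these data do show: the scanner, assembler,
classifier, residue caller, trimmer and cluster detector implement their
stated contracts exactly, with 100% recovery of planted truth at zero
noise.  What they do not show: performance on real survey data, where
domain boundaries are fuzzy, motifs degenerate, and the built-in
fingerprints are no substitute for profile-based domain evidence — hence
the external-evidence pathway.  The generator also does not simulate
tree-structured sequence evolution, so phylogenetic signal in clustered
output is not meaningful.

## Problem sizes and numerical choices

The shipped acceptance computation uses 280 proteins (10 per class),
400 random 500-residue sequences for the scanner oracle, exhaustive
short pairs plus 300 random pairs (length ≤8) for the aligner oracle, a
10×150 alignment fixture, and 100 random neighborhood layouts — sizes at
which every quantity is stable across seeds.  Floating-point alignment
scores are compared at 1e-9; entropy uses base-2 logarithms; ties in
greedy clustering, overlap resolution and alignment traceback are broken
deterministically as described above.

## Known limitations

* The built-in motif set is minimal by design; variant iron-sulfur
  motifs (the family tolerates considerable cluster-count variation) are
  an extension point via the editable motif TSV.
* The catalog's 16 non-text-pinned templates are a consistent
  completion, not a transcription of published figure artwork; users
  with the figure at hand can edit `class_catalog.tsv` directly.
* Identity clustering is O(n × clusters) pairwise alignments and is
  intended for data-set sizes typical of single-family surveys, not
  metagenome-scale input.
* Survey-scale published counts (sequence totals, per-class abundances,
  structural RMSDs) require the original genome corpus and external
  tools and are out of scope.
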