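# Methods

## Scope and model

`cbcscope` implements the comparative-rDNA workflow used to delimit genera and
species of coccoid green algae (and similar taxa) from ribosomal RNA structure:

1. **Group I intron excision.** Algal rDNA cistrons are frequently interrupted
   by group I introns several hundred nt long. Against an intron-free homolog,
   each intron appears in a global alignment as a maximal run of columns where
   the reference is gapped and the query holds residues. Every such run of at
   least `min_insert` columns is excised and reported with 1-based inclusive
   coordinates on the original query. Runs below the threshold are treated as
   alignment slop and kept.
2. **Template-based structure transfer.** A curated secondary structure on a
   close homolog is projected through a pairwise alignment onto a query. A
   template pair survives iff the query holds residues at both partner columns;
   surviving pairs whose query bases no longer pair are *kept and flagged*, so
   the downstream classifier can call the site "uncoupled" instead of losing
   it. Helix labels (free text in the style of the eukaryotic SSU helix
   nomenclature, e.g. `43`, `49`, `E23_4`) ride along position-wise.
3. **Site-change classification.** For two aligned sequences with pairing
   context from a reference structure, every variable column receives exactly
   one class:
   * **CBC** — both partners of a pair differ, old and new pair both
     complementary (one event covering two columns);
   * **hemi-CBC** — exactly one partner differs, complementarity conserved;
   * **uncoupled** — a paired-site change leaving either state
     non-complementary;
   * **loop substitution** — a change at an unpaired column;
   * **indel** — a residue-vs-gap column.
   Complementary means A·U, G·C or G·U: the wobble is standard in rRNA helices
   and without it conserved stems would generate spurious uncoupled calls.
4. **Gap-aware p-distances.** Two conventions, matching how spacer divergence
   is quoted: *gaps counted* — every residue-vs-gap column is one differing
   site, denominator all retained columns; *gaps excluded* — gap-containing
   columns removed from numerator and denominator. The first never falls below
   the second ((m+g)/L >= m/(L−g) for g <= L).
5. **Synapomorphy calling.** Characters are polarised by direct comparison
   with the sister group on a supplied tree, not by ancestral-state
   reconstruction — the same reading used when diagnostic changes are marked
   on comparative structure diagrams. A clade state fixed at a column is
   synapomorphic unless its sister group is fixed for the same state; it is a
   **non-homoplasious synapomorphy (NHS)** when it additionally occurs in no
   tip outside the clade. Partner columns can be assessed as a unit, yielding
   CBC/hemi-CBC synapomorphies. Gap counts as a fifth state (diagnostic indels
   are reported, flagged).
6. **ITS2 motifs.** On a supplied ITS2 structure, helices are numbered I, II,
   III, ... by 5' order of their outermost pair, and the canonical eukaryotic
   hallmarks are verified: a pyrimidine–pyrimidine (typically U-U) 1x1
   internal loop in helix II, an A-rich stretch between helices II and III, a
   literal `GGU` on the 5' strand of helix III before its apex, and (typical of
   Sphaeroplealean algae) a branched, y-shaped helix I.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `min_insert` | 50 | nt | group I introns are hundreds of nt; 50 separates them cleanly from alignment slop |
| alignment scores | +2 / −1 / −10 / −0.5 | — | match / mismatch / gap open / gap extend; identity-level rDNA comparisons with long, rare gaps |
| `min_loop` | 3 | nt | minimal hairpin loop for the toy fold |
| `a_window`, `a_frac` | 4, 0.75 | nt, fraction | A-rich region threshold; no published numeric criterion exists, so both are exposed |
| gap policy | gaps counted | — | the stricter headline convention; the gap-excluding variant is always computed alongside |
| primer mask | excluded | — | lower-case 5' primer-binding runs carry no phylogenetic signal |
| ambiguity codes | excluded, logged | — | columns with IUPAC ambiguity in either row are removed from all counts |

Gap cost follows the aligner's convention (first gap residue scores the open
penalty, each further residue the extension). Alignment is delegated to a
C-implemented affine-gap global aligner; co-optimal alignments are resolved by
its deterministic first-optimal traceback, so identical inputs and parameters
always produce identical output.

## Counting conventions

* A CBC is counted **once per base pair** (not per column); the partition
  identity `2·CBC + hemiCBC + uncoupled + loop + indel = variable columns
  (gaps counted)` holds on every comparison and is property-tested.
* Each gap column counts as one site, so a 3-column indel contributes three
  sites under the gaps-counted policy. Per-helix tallies count substitution
  columns carrying the helix label (a CBC contributes its two columns).
* Gap-vs-gap columns and masked columns are removed before any numerator or
  denominator is formed. Pairwise alignments produced by the package's own
  aligner never contain gap-vs-gap columns; they can arise when rows are
  projected out of a multiple alignment.
* A paired column whose partner column is an indel is classed uncoupled: an
  indel in the partner cannot conserve pairing. The gap column itself is an
  indel site.
* An empty denominator (all columns masked or gapped) raises an
  undefined-distance error rather than returning 0.

## Toy maximum-pairing fold

`fold_max_pairing` maximises the number of complementary nested pairs
(Nussinov-style dynamic programming) with a deterministic traceback: the 5'
base of each subproblem is paired with the smallest admissible partner that
achieves the optimum, and left unpaired only when no pairing does. It is a
combinatorial stand-in used to build test structures and is not an energy
model; analyses of real molecules should supply structures from curation or
external energy-minimisation folding. Its optimality is verified against
exhaustive enumeration of all nested structures for sequences up to 12 nt.

## Synthetic data: what it emulates, and what it does not

The generators are first-class, tested code; their defaults encode the study
conditions the toolkit targets:

* a 2,724-nt rDNA cistron (SSU 1,767 / ITS1 180 / 5.8S 160 / ITS2 248 / 5' LSU
  369 nt);
* intron complements of five SSU + one LSU intron (5,052-nt cistron) and six
  SSU + one LSU intron (5,416-nt), with insertion points sampled at least
  20 nt apart so adjacent insertion blocks cannot merge into one gap run, and
  block boundary bases constrained to differ from the flanking reference bases
  so the optimal gap placement — hence coordinate recovery — is unique;
* an SSU-scale divergence of 39 variable sites comprising 8 CBCs, 7
  hemi-CBCs, 12 loop substitutions and 4 single-column indels (40 sites, with
  one more loop substitution, for the second comparison), planted on a
  stem-loop template of 38 ten-pair helices (~1,690 nt);
* a within-genus comparison of 5 displacements, all single-stranded;
* an ITS2-scale spacer alignment of 248 columns with 48 substitution and 40
  single-gap columns, i.e. 35.5% divergence with gaps counted and 23.1%
  without.

Planted events are mutually non-overlapping, avoid terminal and primer-masked
positions, and single-stranded events are never adjacent, so the planted truth
is unambiguous. Stems use Watson–Crick pairs only, which keeps every planted
class decision exact under the wobble-inclusive complementarity test.

Deliberately **not** emulated: branch-wise evolution under a substitution
model (changes are planted directly on one sequence of a pair), empirical
indel length distributions (indels are single-column), base composition bias,
rate heterogeneity among sites, and pseudoknots. Passing the closed-loop tests
therefore demonstrates that the detectors recover exactly what the definitions
say they detect — not that real alignments or curated structures are
error-free; on real data the site counts inherit the uncertainty of alignment
and structure curation (a few columns either way under different alignment
parameters).

## Degenerate inputs and tie-breaks

* A clade equal to the full tip set has no outside and is defined as
  not-synapomorphic, not an error; a polymorphic clade likewise.
* A polymorphic sister group does not veto a synapomorphy (only a sister fixed
  for the same state does); one consequence is that a column diagnostic for
  one clade may also score as a homoplasious retention for a clade whose
  sister it polymorphises.
* Paired-synapomorphy CBC/hemi-CBC sub-classification is attempted only when
  the sister group is fixed for a single gap-free pair; otherwise the call
  carries no paired subclass.
* Fewer than three helices in an ITS2 structure yields an all-false motif
  report with a warning rather than an error.
* Pseudoknotted input structures are rejected, not silently flattened.

## Verification

The test suite closes the generator→detector loop exactly over 100 seeds for
site classes, planted NHS and intron coordinates; verifies the fold against
brute-force enumeration on 500 random sequences (<= 12 nt); and checks the
distance dominance and partition identities on 1,000 random alignments.
`scripts/acceptance.py` re-runs the full pipeline at the study conditions
above and writes every headline quantity it computes to JSON. One test
(`test_study_accession_reproduction`) exercises the same pipeline on the
published rDNA accessions; it requires those three GenBank records to be
downloaded once into `data/accessions/` and fails with instructions when they
are absent. Reproducing the real-data CBC counts additionally requires a
curated structure sidecar for the SSU model, which only exists as a published
figure.

## Known limitations

* Pairwise comparisons only; multi-taxon column scoring lives in the
  synapomorphy module and is per-clade, not a full parsimony mapping.
* No evolutionary-distance corrections (JC/K2P): divergences are uncorrected
  p-distances, as customarily quoted for ITS comparisons.
* Helix boundaries and labels must be supplied (sidecar TSV); the package
  preserves but does not derive the eukaryotic helix numbering.
* The toy fold scales as O(n³) in pure Python and is intended for test-scale
  sequences, not full-length molecules.
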