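# Methods

## Screening model

The pipeline treats "accessible from the cell surface" as a decision over
two evidence channels: GO cellular-component annotation and predicted
membrane topology. The GO catalog is a fixed list of exact IDs — no
ontology-descendant expansion. This is deliberate: the screening protocol
enumerates its trigger terms explicitly (including the obsoleted
"anchored component of plasma membrane", retained because it denotes a
topology rather than a compartment), and expanding to descendants would
change the meaning of the published class columns that the tests re-encode.
An opt-in expansion hook is the natural extension point but is off by
default.

Class semantics:

* **surface classes** (CS, ESPM, ECESPM, ACESPM, ICESPM, ESCW, ESCOM) imply
  accessibility directly — topology is ignored for them, so a globular or
  signal-peptide-only protein with a cell-surface annotation is still a
  target (secreted/anchored surface proteins behave exactly this way);
* **membrane classes** (PM, ACPM, ICPM) and extracellular space (ES) are
  compatible with inaccessible localisations, so they promote to target
  only together with predicted transmembrane topology.
* ES alone additionally gates the *interest* call: an ES-only protein is of
  interest only if transmembrane.

ESCW and ESCOM cannot fire on mammalian data (cell wall / outer membrane);
they are kept for catalog completeness and validated as part of the
disjointness/coverage invariants.

BETA (beta-barrel) topology counts as transmembrane for the membrane
branch: the rule requires "transmembrane", not "alpha-helical". In
practice mammalian chromosome proteomes yield none, and the readers carry
BETA through as its own category so counts remain separable. Proteins with
no topology prediction are conservatively treated as non-transmembrane and
flagged (`topology_missing`) rather than guessed.

Experimental support: a target is marked experimentally supported iff at
least one *triggering* GO ID carries experimental evidence. Orthology-
transferred GO IDs are experimental by construction (the hit filter demands
it); UniProt-side evidence codes, when present in an export, are matched
against a configurable set defaulting to the manual experimental family
(EXP, IDA, IPI, IMP, IGI, IEP) plus their high-throughput variants. The
default set is a documented choice, not an assertion about any particular
database export.

## Redundancy filter

Rules, in order: (1) drop entries whose transcripts all lack a gene
association (including entries with no transcript mapping — they cannot be
gene-deduplicated); (2) resolve each entry to one transcript, preferring
the canonical one; (3) keep one entry per gene — reviewed first, then
canonical, then the lexicographically smallest accession. Two reviewed
entries for one gene is a warning plus deterministic tie-break, not an
error; one canonical transcript claimed by two genes is a hard integrity
error. The audit reconciles exactly: input = output + dropped, and the
filter is idempotent on its own output.

## Overrepresentation statistic

Fold enrichment (k/n)/(K/N); one-sided hypergeometric tails
(P[X ≥ k] over, P[X ≤ k] under) through scipy's log-space implementation;
Bonferroni over the number of terms tested in the run (both directions
share one m — conservative and simple). `direction="auto"` tests each term
on the side of its observed deviation, matching over/under reporting
conventions of enrichment services; a fixed direction is used wherever a
calibrated type-I level matters, because a data-chosen side is not a valid
p-value. Whether the upstream convention is one- or two-sided is genuinely
ambiguous, so sidedness is exposed as a parameter rather than hard-coded.

Discreteness: hypergeometric p-values cannot attain 0.05 exactly, so the
null-calibration test uses well-populated tables (N = 1000, n = 100, term
sizes 200–500, where the attainable one-sided level is ≈ 0.032–0.047 by
exact tail computation) and takes the 99 % binomial band at the number of
independent draws — terms within one draw share the sampled set and are
therefore correlated.

## Alignment and similarity

Three-state Gotoh dynamic program, BLOSUM62, gap open −11 and extend −1 (a
gap of length g costs −11 − (g−1)); end gaps are penalised, i.e. true
global alignment. A semiglobal variant (free end gaps) sits behind
`mode="semiglobal"` because library conventions differ on end-gap
treatment and the choice is worth exposing. The horizontal gap state is
vectorised with a running-max recurrence (gap costs are linear in length),
so row updates are O(n) numpy operations; with the integer-valued BLOSUM62
scores all DP arithmetic is exact in float64.

Traceback is deterministic: state preference M (diagonal) > up > left on
ties, applied both at the final cell and at every provenance step. Scores
are symmetric under argument exchange; aligned strings need not be, which
is why tests assert score symmetry but not column symmetry.

"Number of indels" in the similarity statistic is read as the number of
alignment columns containing a gap, making the statistic a percent identity
over residue–residue columns, bounded by 100. The alternative reading —
gap *events* — is implemented behind `indel_metric="events"`; it can exceed
100 and is off by default. Reported similarities round half-up to one
decimal when serialised; internal comparisons keep full precision.

Residues outside the matrix alphabet (U, O, J against BLOSUM62) score a
fixed −1 against everything; B, Z, X use the matrix's own ambiguity rows.
Non-letter characters are input errors that name the offending position.

## Cross-species mapping

One isoform per (gene, species): description containing "isoform X1", else
"isoform 1" (word-boundary matches, so "isoform 10" does not match), else
the longest sequence; ties break on the lexicographically smallest RefSeq
ID. Genes present only as aliases of other genes are flagged
(`alias_only`), never silently accepted — distinct genes sharing alias
names would otherwise contaminate the comparison. A missing gene yields a
`not_found` status, not an exception: absence is a recordable outcome.

Candidates below the 70 % similarity review threshold are flagged, never
auto-excluded; exclusion happens only through the four curation rules, in
order: removed entries, wrong-chromosome placements (unplaced genes are
retained — absence of placement is not evidence of absence), alias
duplicate-mappings (the gene for which the shared product is primary
wins), and unconfirmed orthologs, exempted when the ordered flanking-gene
lists of the two species (three genes each side by default) are identical.
Orthology flags, chromosome placements and flanking genes are *inputs*
(database facts), not re-derived.

Live retrieval is an optional adapter (stdlib urllib, 3 req/s, on-disk
cache) that writes the same store layout the fixture loader reads; all
tests run against local stores.

## Synthetic data

The generator's defaults are the study conditions: duplicate-entry rate
0.395 (the redundancy observed in the rabbit chromosome proteome; the
human value 0.62 is the other motivated setting), ~16 % of genes with a
localisation of interest, 60 % of those surface-accessible, ~19 %
transmembrane, geometric transcripts-per-gene with mean 1.5, sequence
lengths uniform on 60–400, ortholog substitution rate 0.10 with 1 %
single-residue indels. Duplicate entries are constructed unreviewed and
non-canonical so the intended survivor is unambiguous; planted targets
satisfy the decision rule by construction and planted non-targets violate
it, which is what makes exact ledger recovery a meaningful oracle.
Divergence is applied substitutions-first, then indels, so expected column
identity has the closed form 100(1−p) when indels are off.

What the generator does **not** emulate: GO DAG structure, realistic
residue composition (sequences are uniform over the 20 standard residues),
correlated annotation errors, or phylogenetic evolution models. Passing
tests therefore demonstrate correctness of the decision rules, accounting
and statistics on structurally faithful inputs — not robustness to the
annotation noise of real databases.

## Problem sizes

The test suite exercises the end-to-end ledger recovery at 500 genes, the
alignment-vs-enumeration oracle on 10⁴ random pairs of length ≤ 6 over a
reduced alphabet, the Fisher-vs-enumeration sweep on every table with
N ≤ 12, the null calibration on 500 draws × 5 terms, and similarity
recovery on 100 pairs of length 500; these sizes make every oracle exact
or tightly bounded while the whole suite stays fast.

## Known limitations

* The GO catalog matches exact IDs; proteins annotated only with
  descendants of the trigger terms are missed (by design, documented
  above).
* The duplicate-mapping curation rule consumes curation records; detecting
  shared-product mappings from raw store contents is out of scope.
* The reproduction of published accession-pair similarities needs the four
  sequence pairs (live retrieval or a pre-populated store); without network
  access those four tests fail rather than skip.
* Classification quality on real proteomes is bounded by annotation
  quality; the pipeline reports evidence provenance per GO ID precisely so
  downstream users can weigh it.
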