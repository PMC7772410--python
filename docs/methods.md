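# Methods

## Scope and model

The package implements a combined annotation procedure for hypothetical
proteins (HPs): candidate selection by description keywords, integration
of prediction evidence from six channels, a 12-level confidence score
with retention rules, sequence-derived physicochemical and topological
profiling, functional categorization, and operon-like gene-neighborhood
detection. The external prediction tools that would populate the
evidence channels in a real study (InterProScan/CDD/SMART/PROSITE-class
domain and motif scanners, homology modelling, phylogenomic function
transfer, localization predictors) are deliberately out of scope: their
*outputs* are the package's inputs, normalized to a six-column TSV. The
synthetic-data generator stands in for them during testing.

## Candidate selection

A protein is a candidate HP when its description contains any of the four
keywords — "hypothetical protein", "unknown", "uncharacterized",
"putative" — as a case-insensitive substring. The first keyword is kept
singular so both singular and plural forms match. Matching is restricted
to the description field; locus tags and sequences are never searched.
Selection is idempotent and order-preserving.

## Evidence filtering

Hits with e-value above 1e-5 are dropped; the bound is inclusive, so a
hit exactly at the cutoff survives. Hits whose label or identifier
matches `\bDUF\d+\b` (case-insensitive) are removed: a
domain-of-unknown-function match carries no functional information for
this procedure. Filtering preserves input order.

## The confidence scheme

Labels are canonicalized (casefold → strip punctuation → sort tokens →
apply synonym map) before counting. The prediction component is the
number of *distinct* channels supporting the winning label — multiple
hits within one channel count once, because the six channels, not the
individual hits, are the independent prediction tasks. Ties between
labels are broken by lowest best e-value, then lexicographically, so
output is deterministic. The physchem and localization channels are
supporting evidence: a label backed only by them can win only when no
competing label has support from a core channel (motif, domain,
structure, evolutionary). How partial agreement (2–5 channels) maps to
scores is not fixed by the source workflow; the distinct-channel count is
this package's documented rule.

The literature component is the maximum provenance level among records
matching the winning label on a fixed 6-level taxonomic scale
(6 same organism … 1 eukaryotes); the maximum is the only monotone choice
when several references exist. Combined score = sum of components
(≤ 12); retention requires both components ≥ 3. Increasing either
component never lowers the combined score and never flips a retained
protein to rejected.

### Model-quality composites

The QMEAN5 composite is implemented with coefficients
(0.3, 0.17, 0.7, 80, 45) on (torsion, pairwise, solvation, SSE, ACC).
These weights are markedly unbalanced — the SSE and ACC terms dominate —
and differ from the weighting in the original QMEAN literature; they are
kept as the pipeline's standard form for fidelity to its source workflow,
and `qmean5()` accepts any 5-tuple of coefficients as an override. The
noisy-OR combination `1 − Π(1 − s_i)` is validated against inclusion–
exclusion enumeration in the tests.

## Physicochemical descriptors

* **Instability index**: `(10/L)·Σ DIWV` over the L−1 overlapping
  dipeptides, with the published 400-entry Guruprasad weight table
  (loaded from Biopython's copy of the published values). Values < 40
  classify stable; 40 itself classifies unstable because the stable
  region is defined strictly as II < 40.
* **Aliphatic index**: mole percents over the full length with Ikai's
  volume coefficients a = 2.9 (Val), b = 3.9 (Ile+Leu).
* **GRAVY**: mean Kyte–Doolittle hydropathy (scale shipped as TSV data).
* **Molecular weight**: sum of average residue masses (standard ExPASy
  values, shipped as TSV) plus one water (18.01524 Da).
* **Theoretical pI**: bisection on [0, 14] to 1e-4 pH units for the zero
  of the Henderson–Hasselbalch net charge over both termini and the
  ionizable side chains (C, D, E, H, K, R, Y), with the EMBOSS pKa set
  shipped as TSV and swappable in `PhyschemConfig`. Net charge is
  strictly decreasing in pH, so the root is unique; the tests confirm
  bisection against a dense grid scan.

All formulas are defined over the 20 standard residues. Ambiguity codes
(B, Z, X, U) raise by default; a permissive mode excludes them from the
property sums — note that for the instability index this joins the
flanking residues into a dipeptide.

Reported TSV values carry 4 decimals; full precision is kept internally.

## Transmembrane calling and localization

Sliding-window mean hydropathy at every full-window center; maximal runs
of centers above threshold are extended to their window bounds, merged
when overlapping, and kept at ≥ min_len. Defaults window 19, threshold
1.6, min_len 15 — the classic Kyte–Doolittle heuristics, since the
source workflow names tools but not parameters. Window sums use exactly
rounded summation (`math.fsum`) so knife-edge windows whose mean ties the
threshold are decided reproducibly. Sequences shorter than the window
yield no call, with a warning rather than an error. Signal peptides are
ingested evidence (a column in the evidence TSV), never predicted.
Localization is a three-way rule: membrane if any TM segment, secreted if
signal-only, else cytoplasmic.

## Categorization

Ordered rules: EC number present → metabolic enzyme; else regulator /
transporter / binding / cell-division keyword families in that order;
else `other`. EC beats keywords because it is the strongest categorical
signal in the reference tables. Metabolic enzymes get a subsystem code
from a 16-code controlled vocabulary; the default label→code map is
seeded from the bundled metabolic table's section headings and can be
extended by the caller. Headings with no dedicated code (e.g. "Small
molecule reactions") map to OTR. Fold-class tallies are supported via an
optional `fold` evidence column, counted verbatim; no fold recognition is
performed. Multi-EC table cells keep their first EC in the typed field,
with the raw cell preserved.

## Neighborhood detection

A single linear scan over start-sorted loci. A run of HP genes breaks
when the intergenic gap (`next.start − prev.end − 1`) exceeds max_gap,
the strand flips (when same-strand is required), or a known-function gene
intervenes (configurable; breaking is the default because operon-like
organization implies contiguity). Runs ≥ min_size become clusters,
labelled by their most frequent member label (ties to the earliest
gene). Defaults max_gap 200 bp, min_size 2, same-strand — typical
prokaryotic operon heuristics; the source workflow defines
"operon-like" only qualitatively, so these thresholds are this package's
documented defaults. The tests check equivalence against an independent
all-pairs transitive-closure oracle and exact recovery of planted
layouts.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *statistical structure* the pipeline assumes:

* a proteome of `n_proteins = 756` (the reference study's HP count) with
  residue-i.i.d. sequences, lengths uniform on 60–600 (typical archaeal
  protein lengths), and HP-keyword descriptions;
* six evidence channels that each report the planted label independently
  with probability `channel_agreement = 0.5` (centering the binomial
  support count on 3, the retention boundary, so both outcomes are well
  represented), decoys otherwise;
* literature levels uniform over 0–6 (0 = no record), giving
  P(level ≥ 3) = 4/7;
* e-values log-uniform on [1e-30, 1e-6] and DUF identifiers only on decoy
  records, so default filtering never erodes planted support and
  retention truth stays exact — an explicit design choice that makes the
  planted-recovery property (`retained ⇔ support ≥ 3 ∧ level ≥ 3`)
  checkable without slack; a noise option can add super-cutoff records;
* six planted gene clusters of sizes (5, 4, 5, 4, 6, 8) — 32 genes, the
  six-arrangement structure of the reference genome analysis — with
  intra-cluster gaps ≤ 50 bp and 2 kb separations.

Decoy labels are unique per (protein, channel) by default so the planted
label's support count is unambiguous; a colliding-decoys mode draws them
from a small shared pool for stress testing, and an e-value-signal mode
ties lower e-values to true labels for tie-break testing.

What the generator does **not** emulate: sequence homology (decoys are
labels, not similar sequences), correlated channel errors (real tools
share databases and fail together), composition biases of real
proteomes, overlapping genes, and the long-tailed e-value distributions
of real search tools. Passing tests therefore demonstrate that the
*decision logic* is correct under the stated independence assumptions,
not that the pipeline's accuracy on a real proteome matches the
reference study — reproducing that would require the external tools
themselves, which are out of scope.

All draws go through numpy generator streams spawned as
`default_rng([seed, stream])` with a fixed stream index per operation, so
every `gen_*` call is deterministic under a fixed seed, independent of
call order and platform.

## Bundled reference data

`table1.tsv`–`table3.tsv` are verbatim machine-readable transcriptions of
the reference study's three printed annotation tables (cell division,
transcriptional regulation, metabolic subsystems); bare 4-digit locus
forms are expanded to `mru_XXXX` on load and multi-locus cells split on
`|`. `tables_meta.tsv` records the headline counts printed in the study
text as printed — including internally inconsistent pairs (756 HPs
described as "73%" of 2,278 coding genes where the arithmetic gives 33%;
96 vs 119 metabolic enzymes; 26 regulators in text vs 25 distinct table
entries) — without reconciling them; none of these is used as a test
oracle. `fig3_layout_synthetic.tsv` is a *synthetic* realization of the
six-cluster genome-neighborhood figure: the figure fixes the arrangement
(six separated same-strand runs, 32 HP genes) but prints no coordinates,
so the fixture invents coordinates honoring that adjacency structure.

## Problem sizes in the test suite

Oracle-agreement suites use 100 random sequences (lengths 10–300), 100
random gene layouts (10–100 genes), and noisy-OR enumeration up to 4
sources; the end-to-end planted-recovery suite runs 20 seeds at
n = 2000 proteins with all generator defaults. These sizes exercise every
code path and boundary while keeping the whole suite under a minute.

## Known limitations

* The confidence scheme assumes channel independence; correlated tools
  inflate the prediction component.
* Canonical-label matching is exact after normalization; near-miss labels
  ("ATPase subunit A" vs "ATPase subunit B") count as different
  functions unless a synonym map entry merges them.
* The TM caller is a hydropathy heuristic, not an HMM; it makes no
  inside/outside orientation calls and will over-call hydrophobic
  globular stretches.
* pI assumes model-compound pKa values and no charge interactions.
* Cluster detection uses gene coordinates only — no promoter/terminator
  signals, no expression data.
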