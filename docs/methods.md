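# Methods

## Screening model

Compounds are filtered on two precomputed pharmacokinetic axes. Oral
bioavailability (OB, percent of an oral dose reaching circulation) is an
input — predicting it is out of scope. Drug-likeness is the Tanimoto
coefficient

    T(A, B) = A·B / (‖A‖² + ‖B‖² − A·B)

between a compound's molecular-descriptor vector A and the mean descriptor
vector B of a reference drug library. Descriptors are treated as plain
non-negative reals in a fixed, caller-defined ordering; no standardisation
is applied before the formula, and which descriptor set (CDK, Dragon, …)
feeds it is the caller's choice. For non-negative vectors T lies in [0, 1];
it is undefined (an error) for two all-zero vectors. When a table supplies
DL directly *and* descriptors are present, the supplied value wins with a
warning — curated values take precedence over recomputation against a
possibly different reference library.

The default criteria are OB ≥ 25 %, DL ≥ 0.18, inclusive at the boundary
(an `inclusive=False` switch gives strict inequalities for sensitivity
checks). Records with missing OB/DL are a hard error rather than a silent
drop, so screening tallies stay auditable. The `_qt` name suffix marks a
glycoside's aglycone (deglycosylated) form; it is metadata only — the flag
is derived from the name and the name is kept verbatim.

## Target tables and merging

Target prediction itself (weighted ensemble similarity, random-forest/SVM
ensembles) is external; its outputs are consumed as three-column tables.
Normalisation maps aliases onto canonical UniProt accessions via a
user-supplied synonym table and collapses duplicates (strict mode errors on
unresolvable ids; lenient mode drops them with a warning). Merging several
predictors' tables takes the **union** of (compound, target) pairs —
multiple predictors are used to broaden coverage, so edges accumulate; an
`intersection` mode exists for sensitivity analysis. Provenance tags are
concatenated so every edge remembers which predictor(s) produced it.

The packaged 116-row target table contains one accession (P04798) printed
under two gene symbols (CYP19A1 and CYP1A1). The table is kept verbatim —
rows are unique by gene symbol — and accession-level normalisation
collapses it to 115 with a logged warning; which gene assignment is correct
cannot be decided from the table alone.

## Networks and degree statistics

C-T and T-P networks are simple bipartite graphs (no duplicate edges, no
self-loops, only isolated-free nodes); node ids are namespaced internally
(`cmpd:`, `tgt:`, `pway:`) so the two sides stay disjoint even if raw ids
collide. Degree is the only topology statistic computed — the analyses this
package supports use nothing else. The handshake identity (each side's
degree sum equals the edge count) is asserted on every constructed network.

Reporting conventions: mean degrees are reported half-up-rounded to
integers (8.19 → 8) with exact values always available; per-target coverage
(100 × degree / #compounds) reports the **truncated** integer percentage —
the convention under which degrees 23/19/18 over 37 compounds read as
62 %, 51 % and 48 %.

The T-P network admits a pathway when p ≤ 0.05 (raw p by default; an
FDR-filter switch exists because both conventions are common) and the
pathway contains ≥ 8 query targets. An `exclude` list drops named pathways;
the packaged pathway table is the motivating case: it lists 25 enriched
pathways whose degrees sum to 260, while the corresponding published
network has 24 pathways and 232 edges — exactly the table minus `hsa05200`
("Pathways in cancer", degree 28), the generic catch-all. The package
therefore keeps all 25 rows in the fixture and reproduces the 24/232
network by excluding `hsa05200` explicitly, making the discrepancy a
documented modelling choice rather than a mystery. The printed mean
*compound* degree of 31 in the same source is inconsistent with its own
edge and compound counts (950/37 ≈ 25.7); the package always reports the
computed value.

## Enrichment statistics

Over-representation of the query target set in each gene set uses the
right-tail hypergeometric probability P(X ≥ k) with X ~ Hypergeom(N, K, n)
— the one-sided Fisher exact test on the 2×2 overlap table. It is evaluated
as an exact integer ratio (`math.comb` over Python big ints, one final
float division), so results are correct to the last floating-point digit
for every feasible input; tests verify equality against brute-force draw
enumeration (N ≤ 10), an independent exact rational recurrence (N ≤ 25)
and `scipy.stats.hypergeom.sf` on random larger inputs. Only
over-representation is tested; depletion is out of scope.

Choices a user should know:

* **Background universe** defaults to the union of all gene-set members;
  an explicit background list may be supplied. Query ids outside the
  background are dropped with a logged count (strict mode errors).
* Only sets with overlap ≥ 1 are tested, and the BH correction's m is the
  number of *tested* sets.
* BH-FDR is the standard step-up (delegated to statsmodels behind the
  package's own validated surface); results are sorted by ascending p,
  ties broken by set id.

Published per-pathway p-values of this kind depend on the annotation
release and tool defaults used at the time and are not reproducible from
the degree tables alone; they are therefore never asserted.

## Synthetic benchmark generator

The generator emulates the *statistical shape* the pipeline assumes — no
chemistry or biology. All randomness flows through `numpy` generators
seeded from the config; identical configs give byte-identical files.

* **Library** (default 156 compounds): OB ~ LogNormal(μ = 3.11206,
  σ = 0.85) in percent and DL ~ Beta(0.89782, 2.8), independent. The
  parameters are solved analytically so that P(OB ≥ 25) = 0.45 and
  P(OB ≥ 25) · P(DL ≥ 0.18) = 37/156: the default screen passes a
  Binomial(156, 37/156) count of compounds, centred on 37. Six of the
  passing compounds are made multi-herb (the "shared compound" structure of
  a formula); every 13th name carries the `_qt` suffix. A correlation
  between OB and DL is not modelled — real ADME properties do correlate,
  but no joint structure is specified by the calibration source.
* **Interactions**: exactly `target_edge_total` (default 950) edges over
  the passing-compound × target grid (default 116 targets). Coverage is
  seeded by paired random permutations (no isolated node on either side);
  the rest are drawn without replacement with cell weight ∝ rank^(−0.55)
  over targets. The exponent 0.55 is a documented constant chosen so the
  degree profile matches the curated table's skew: top target hit by
  ≥ ~73 % of compounds, degrees spanning ~1–30, mean 950/116 ≈ 8.19.
* **Gene sets** (default 20 sets of 60–300 members over a 2000-id
  universe containing the targets): neutral sets sample the universe
  uniformly; a planted set samples with weight = fold (default one set at
  fold 5) on the query targets, inflating its expected overlap ~fold-fold.
  Ground-truth labels are emitted alongside for recovery tests.

What passing tests show — and do not show. The generator validates the
*statistics*: that screening counts concentrate at the calibrated rate,
that the network code preserves enforced edge totals and degree structure,
that planted 5-fold enrichment is recovered at FDR < 0.05 in ≥ 95 % of
replicates, and that the test is calibrated under the null. It says nothing
about real descriptor covariance, predictor accuracy, or annotation
quality; results on real tables inherit those upstream uncertainties.

### Null calibration of a discrete test

Under a uniform-query null the rejection rate at p ≤ 0.05 is *not* 0.05:
the hypergeometric support is discrete, so the achieved size at any nominal
threshold is the largest attainable p below it. For the generator's sizes
(universe 2000, query 116, sets 60–300) the achieved size averages ≈ 0.037
— exactly computable from the p-value grid, with no simulation. The
calibration test therefore checks (i) that the simulated rejection rate
matches this exact achieved size within binomial error, and (ii) that it
never exceeds the nominal 0.05 beyond binomial error (validity). Asserting
a literal 0.05 would fail for every correct implementation of an exact
discrete test.

## Pipeline

`run_pipeline` executes screen → merge → C-T network/stats → enrichment (or
a pre-filtered pathway-degree table) → T-P network → exports, writing one
`summary.json` that contains every count *and* every threshold that
produced it, so no result is separable from its criteria. An internal audit
re-reads the exported stage files and checks the summary counts against
them; re-running with identical inputs and seed is byte-identical. Any
stage failure aborts with the stage name attached.

Problem sizes used by the test suite and the acceptance script — 200 null
simulations, 100 recovery replicates, 40 recovery replicates in the script,
oracle enumeration to N = 25 — are chosen so the full chain validates in
seconds on one core while keeping binomial error bands tight enough to be
meaningful.

## Known limitations

* OB prediction, descriptor generation and target prediction are inputs,
  not components. The optional nearest-neighbour baseline predictor is
  plumbing for running the chain without external predictions — it copies
  the target list of the most descriptor-similar annotated compound and
  makes no accuracy claim.
* The packaged interaction table and per-pathway hit lists are synthetic
  *realisations* of published degree sequences (round-robin assignment):
  target-side degrees are exact, compound-side degrees and memberships are
  not published and are evenly distributed instead.
* GO term analysis, annotation-DAG traversal and figure rendering are not
  implemented; exports are SIF/GraphML for external viewers.
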