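# Methods

## The analysis

`karyosig` analyses the chromosomal (not band-level) anatomy of reciprocal
translocations in tumor karyotypes. The unit of analysis is the
*translocation type*: an unordered pair of distinct chromosomes drawn from
{1..22, X}. The Y chromosome is never counted and homologous pairs (e.g.
t(1;1)) are excluded, leaving 23 × 22 / 2 = 253 possible types, ordered
t(1;2), t(1;3), ..., t(21;22), then t(X;1) ... t(X;22). Canonical labels
follow ISCN convention: X first when present, otherwise the smaller autosome
first.

### Extraction from karyotypes

A case's ISCN-style karyotype is split into clones on `/` and into
abnormality terms on top-level commas. Standalone `t(c1;c2)(bands)` terms
are reduced to whole-chromosome types; bands are parsed past and discarded.
Three-or-more-way translocations, homologous pairs, Y-involving events, and
terms with `?` in a chromosome position are skipped with machine-readable
reason codes. A `t(...)` nested inside `der(...)`/`ider(...)` describes an
unbalanced derivative rather than a balanced reciprocal exchange and is
skipped by default (`count_nested=True` opts in; the underlying database
semantics are not documented, so both behaviours are exposed). A case
contributes each type at most once, however many clones repeat it — the
database records clonal abnormalities per case, and per-case counting makes
the spectrum insensitive to how many subclones were karyotyped. Everything
else in the ISCN grammar (gains, losses, inversions, markers, `idem`, ploidy
arithmetic) is deliberately passed over without error; only the subset
needed for translocation extraction is implemented.

### Spectra and inclusion

For each entity (or pooled group, or entity-by-sex stratum) the pipeline
counts all 253 types into an absolute-frequency vector and converts to
percentages of that stratum's total translocations. Strata enter the
comparative analysis only with ≥ 100 cases **and** ≥ 100 translocations
(both inclusive); smaller strata are reported but not compared. Frequency
summaries bin the 253 types at exact bounds 0%, (0, 1)%, [1, 10]%, > 10% —
1% belongs to the middle band, 10% is retained in it.

### Pairwise comparison

Entities are compared by the coefficient of determination R² — the squared
Pearson correlation of their two percentage vectors. This is the only
symmetric reading of "association between two spectra" and matches the
upper-triangular presentation of such matrices. Before correlating, every
*characteristic* translocation — a type strictly above the cutoff
(default 10%) in **either** member's own spectrum — is removed from both
vectors (the pairwise union keeps the vectors aligned). A type at exactly
10.0% is retained. Percentages are *not* recomputed after exclusion:
Pearson correlation is invariant to positive rescaling of either vector, so
renormalisation provably cannot change R² (asserted to 1e-12 in the tests);
it matters only for exported tables, where both raw and renormalised columns
can be derived.

Strength classes are assigned on R² rounded to one decimal —
insignificant/very weak (0.0–0.3), weak/moderate (0.4–0.6), strong/very
strong (0.7–1.0) — because the bins tile the unit interval only on
one-decimal values. Summary tallies additionally report the conventional
thresholds R² ≤ 0.3 and R² < 0.1 on the unrounded values. A retained vector
with zero variance yields a flagged, non-numeric cell rather than R² = 0:
absence of computable evidence is not evidence of no association. At the
default 10% cutoff at most 9 types per spectrum can exceed the threshold,
so at least 235 coordinates always remain; the "fewer than 3 retained"
error path is reachable only at user-supplied strict cutoffs.

The cutoff sensitivity analysis re-runs a comparison at progressively
stricter cutoffs (default 10, 5, 2, 1%); the retained-coordinate count is
non-increasing as the cutoff tightens.

## The synthetic cohort generator

Real source data are per-case karyotype records from a curated cytogenetic
database; the generator stands in for them with cohorts whose
signature structure is known exactly.

- **Signature**: a probability vector over the 253 types drawn from a
  symmetric Dirichlet with concentration 0.05 by default. At this
  concentration the vector is sparse — typically ≥ 80% of types sit below
  1% probability — emulating the long tail of rare translocations observed
  in real entities. An optional *spike* assigns an exact probability mass to
  one characteristic type (e.g. t(9;22) at 0.6 for a CML-like entity), with
  the remaining mass rescaled.
- **Cases**: per-case translocation counts follow a zero-inflated Poisson
  (defaults p_zero = 0.3, λ = 1.2, so most cases carry 0–2 translocations,
  loosely matching cytogenetic reality; these are configuration, not
  claims). Types are drawn i.i.d. from the signature and deduplicated
  within the case by redraw (bounded at 100 attempts), keeping per-case
  sets consistent with the parser's counting unit. Sex is Bernoulli
  (default 0.5). Each case is rendered as an ISCN string
  `46,XX,t(a;b)(q11;q22),...` with fixed placeholder bands (a
  `random_bands` flag exists only to exercise parser tolerance).
- **Emission log**: every emitted type is recorded, so re-parsing the
  rendered karyotypes must reproduce the log exactly — the round trip that
  pins the generator and parser to the same counting unit.
- **Studies**: `make_study` builds multi-entity panels in which designated
  entity pairs reuse one signature (the synthetic analog of comparing
  females and males within a single disease), while all other entities get
  independent signatures (the cross-entity analog).

One consequence of within-case deduplication is worth stating: when cases
carry several translocations, a high-mass spike is capped at one emission
per case, so its share of all emitted events falls below its probability
mass (at the defaults, a 0.6-mass spike lands near 43%; the expected share
is Σₖ P(k)(1−(1−m)ᵏ) / Σₖ P(k)·k, which the tests assert). The mass is
recovered exactly in the near-single-draw regime. Likewise, the default
synthetic signature concentrates more *mass* in its top types than real
tumor spectra do — what it reproduces is the shape of the type-count tail,
not the mass share of rare events. Passing tests therefore demonstrate the
machinery (extraction, counting, exclusion, correlation) on data of known
structure; they are not a claim about any real entity's spectrum.

## Problem sizes and numerical choices

- Signature-separation checks use cohorts of 2 500 cases (≥ 2 000
  translocations each, concentration 0.05): same-signature pairs reach
  R² ≥ 0.7 and independent pairs stay ≤ 0.3 in ≥ 19/20 replicates.
- Cutoff-sensitivity checks use 25 000-case cohorts (~21 000
  translocations): the depth at which sub-1% coordinates carry enough
  counts for the comparison to be meaningful at the strictest cutoff, and
  the scale of the most extensively studied real entities. At ~2 000
  translocations the 1% cutoff leaves near-pure sampling noise and R² is
  not stable across cutoffs.
- R² is computed via `scipy.stats.pearsonr` and squared; an independent
  least-squares oracle (residual sums via `numpy.linalg.lstsq`) agrees to
  1e-12 in the tests.
- Percentages are kept at full float precision internally; rounding (2
  decimals for percentages, 3 for R² in long tables, 3 in the triangle) is
  applied only at write time.
- All randomness flows through `numpy.random.Generator` seeded explicitly;
  identical seeds give byte-identical cohort tables and pipeline outputs.

## Limitations

- The parser covers only the ISCN subset needed for translocation
  extraction; it does not validate nomenclature, resolve complex
  derivatives, or handle insertions.
- Band-level breakpoint structure is out of scope by design — aggregation
  is to whole chromosomes.
- No significance tests or multiple-testing corrections accompany the R²
  values; the matrix is descriptive.
- The generator does not model numerical abnormalities, secondary-aberration
  co-occurrence, or band-level breakpoint distributions.
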