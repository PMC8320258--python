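# Methods

## Analysis model

The screen treats each stimulation condition of a specimen as an
independent droplet run sharing one underlying repertoire. Its atoms are:

* **Clonotype** — the set of cells with an identical CDR3β *nucleotide*
  junction. Nucleotide (not amino-acid) identity is deliberate: a silent
  substitution marks an independent rearrangement and must found a new
  clonotype. V/J gene labels are carried for reporting but do not enter
  the key.
* **Cell status** — *paired* (exactly one distinct productive β junction;
  one or two α chains), *mixed* (≥ 2 β junctions; almost always a doublet
  or chimera), *undetectable* (no productive β). Mixed cells are excluded
  from clonotype membership entirely rather than being assigned to their
  higher-UMI β; the cost is a small loss of cells, the benefit is that no
  doublet can vote for a receptor.
* **Activation** — IFN-γ or IL-2 UMIs at or above threshold. IL-2-only
  cells count as activated (they are real responders) and are logged
  separately because they are rare and behave differently across tumor
  types.

Candidate receptors are per `(condition, clonotype)`; a clonotype
stimulated by two different pools yields two candidate rows, deduplicated
by key in the frequency report. The shared/unique split (`support ≥ 2`
vs `= 1`) is the screen's reliability axis: a receptor confirmed by two
independent droplets is essentially never an artifact, while a singleton
may be a sequencing error or a doublet drop-out.

### Autoreactive removal

A clonotype with ≥ 1 activated cell in the unstimulated control is removed
from candidacy in *every* condition (clonotype-level, not cell-level).
The operation is idempotent; with no control condition present a warning
is emitted and nothing is removed.

### Ranking

Screens of this kind test all shared receptors but only the top few
unique ones, without stating the ordering rule. The rule implemented here
— shared before unique, descending support, descending summed IFN-γ UMIs,
ascending key — is a documented design choice of this package; the IFN-γ
tie-break encodes the intuition that stronger activation is better
evidence.

### Merged frequencies

Conditions of a specimen are pooled (barcodes namespaced by condition) and
clonotypes observed exactly once across the merge are dropped before
normalizing, since singletons are dominated by artifacts. The frequency
denominator is therefore the *retained* cell count; passing
`drop_singletons=False` to `compute_frequencies` switches to the all-cells
denominator. Mixed cells carry no key and never enter merged totals.
Shared candidates can never be dropped here (support ≥ 2 ⇒ merged count
≥ 2); reactive singletons legitimately end with frequency "NA".

### Somatic hard filter

All four criteria (tumor depth ≥ 10, normal depth ≥ 10, VAF ≥ 10%,
tumor variant reads ≥ 4) are inclusive at the boundary. "Read counts" is
interpreted as total site depth per sample. VAF columns with values > 1
are auto-normalized from percent. Non-synonymous-only filtering is an
optional flag because annotation engines are out of scope.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `ifng_min`, `il2_min` | 5, 5 UMIs | "high" cytokine cutoffs. Package defaults, not protocol constants: activated cells sit an order of magnitude above ambient background in the targeted-enrichment data this emulates, so any cutoff in the gap behaves identically. Configurable. |
| `lineage_min` | 2 UMIs | the two-or-more-UMI rule. CD8 positivity uses `cd8a + cd8b ≥ 2` (combined), the more permissive reading of the rule's wording. |
| `doublet_rate` | 0.04 | fraction of droplets holding two cells at 10 000 loaded / 6 000 recovered. |
| `cdr3_error_rate` | 5 × 10⁻⁴ /nt/contig | substitution rate generating singleton artifact clonotypes. |
| `ambient_marker_rate` | 0.05 UMIs | Poisson mean of spurious marker counts per barcode. P(ambient ≥ 5) ≈ 2.6 × 10⁻⁹, so ambient noise essentially never crosses the activation cutoff. |
| `dual_alpha_fraction` | 1/3 | fraction of clonotypes with two productive α chains. |
| `responder_fraction` | 1/3 | fraction of a reactive clonotype's cells that respond on cognate stimulation; motivated by observed 5/15 and 4/8 responder ratios. |
| `ifng_high_mean` | 50 UMIs (NB, dispersion 2) | cytokine burst in responders, floored at 10 UMIs — see below. |

## The simulator, and what it does not emulate

`simulate_repertoire` draws a power-law (exponent 1.5, truncated) or
log-normal clonotype frequency spectrum; junctions are stop-free in-frame
codon strings with the canonical C…F motif, unique across clonotypes.
`simulate_condition` samples cells multinomially, merges doublets into
single barcodes (contigs and marker counts summed), mutates every contig's
CDR3 per-nucleotide, adds ambient Poisson marker counts, Poisson
own-lineage marker counts, and negative-binomial cytokine bursts to the
responding fraction of reactive (and always of autoreactive) clonotypes.

The responder burst is left-truncated at 10 UMIs. An untruncated NB(50, 2)
puts ~1% of responders below any sensible cutoff, which would make planted
responder counts unrecoverable by *any* threshold; the truncation encodes
the design assumption that "high IFN-γ" cells are cleanly separated from
background, which is exactly the regime in which the screen's rule set is
well-defined. Consequently the tests cannot say how the pipeline degrades
when activation is marginal — that is a property of real data the
generator deliberately does not model. Other non-emulated features:
transcriptome-wide expression, cell-size/depth variation, barcode
collision structure, ambient *TCR* contamination, and read-level errors
(contigs are consumed post-assembly).

### Fixtures

The six named fixtures plant the per-specimen structure the screen must
recover (responder counts, shared/unique candidate splits, an autoreactive
clonotype in M2, the 15-cell/0.30%/5-responder top clonotype of M1 over a
5 000-cell retained denominator, reactive singletons in CC2/CC3 whose
frequency is uncalculable). Artifact candidates and capture-failed
responders are *placed deterministically* — explicit barcodes realizing
the same two mechanisms the stochastic model implements (CDR3 error
singletons; doublets in which the responder's TCR dropped out so the
bystander's receptor inherits the activation) — so the planted counts are
exact, while the stochastic processes themselves are validated by property
tests (e.g. the artifact-clonotype count matches C·(1−(1−e)^L) within
Monte-Carlo error). Each fixture has a documented seed; all planted counts
are seed-invariant by construction, and seeds only vary sequences,
barcodes and nuisance counts. Problem sizes (≈ 1 000–5 000 retained cells
per specimen) are chosen so the merged M1 denominator is exactly the
back-computed 5 000 while the full suite renders and analyzes in seconds.

Fixture truth tables record, per barcode, the generating clonotype(s), the
response flag, the *observable* V(D)J status and the observed β key. The
tested list mirrors the wet-lab validation subset such screens use: every shared
candidate, and a fixed list of unique candidates (for CC1, the top seven
by IFN-γ, which the generator guarantees by giving tested uniques
disjointly higher bursts). Precision is reactive/tested per class;
an empty class reports NA, never 0.

## Numerical and degenerate-input choices

* Ties in representative-β selection and α-variant ranking break by UMI
  count, then lexicographic sequence/contig id — the pipeline is invariant
  to input row order and reruns are byte-identical.
* Duplicate contigs (same barcode, chain, junction) keep the highest-UMI
  record; duplicate marker entries are summed with a warning.
* A merged table that loses everything to singleton removal yields an
  empty frequency table with a warning; precision with an empty tested
  class is NA; an unknown marker feature or missing contig column is a
  format error naming the offender.
* Frequencies are reported at full precision and printed at two decimals.

## Known limitations

* The activation cutoffs and the unique-candidate ranking are documented
  guesses where the protocol leaves the rule unstated; both are configurable.
* Clonotype keys ignore V/J genes, so two rearrangements converging on an
  identical junction nucleotide sequence (vanishingly rare) would merge.
* `evaluate_candidates` scores at clonotype level; it cannot credit a
  candidate whose observed key differs from its generating clonotype
  (doublet drop-outs are scored as failures by design — that is the
  phenomenon being measured).
* The pooled 39% unique reliability is a property of the planted artifact
  load, chosen to mirror the validation screens the fixtures emulate; it is not an estimate of
  any particular instrument's error rate.
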