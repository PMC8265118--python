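# Methods

## Coordinates

Positions around a start codon are signed and 1-based: +1 is the first
nucleotide of the start codon, −1 the last nucleotide of the 5′UTR, and
there is no position 0. Regions are inclusive on both ends in user
space, so −24:24 covers 48 nucleotides; internally everything is
converted once to half-open 0-based indices on the concatenated
UTR+CDS string. A region that extends past the available sequence is
clipped with a logged warning by default (an error when clipping is
disabled); a region entirely outside the sequence is always an error.
The +1..+24 span is taken to include the start codon itself.

## Secondary-structure ensemble and opening energy

The ensemble contains every nested (pseudoknot-free) set of base pairs
over {GC, AU, GU} with hairpin loops of at least 3 unpaired bases. Each
pair contributes a constant stabilisation energy — defaults GC −3.0,
AU −2.0, GU −1.0 kcal/mol — and a structure's energy is the sum over
its pairs; there are no stacking, bulge or multiloop terms. At the
default temperature of 310.15 K, RT = 1.98717×10⁻³ × 310.15 ≈ 0.6163
kcal/mol.

The partition function Z = Σ exp(−E/RT) is computed by an interval
dynamic programme (the classic O(n³) recursion over whether the last
base of an interval is unpaired or paired to a split point),
JIT-compiled and accumulated entirely in log space so that long
GC-rich windows cannot overflow. An optional mask forces chosen
positions to stay unpaired, which yields the constrained sum directly.
Opening energy is OE = RT·(ln Z_full − ln Z_constrained) ≥ 0; values
within rounding error below zero are clipped at 0.

Contexts longer than 210 nt are truncated to a 210-nt window centred on
the target region before folding, so each evaluation costs the same
regardless of gene length. The window anchor (centring) is a
convention of this package; the window never truncates the region
itself.

Two consequences of the simplified energetics are worth keeping in
mind. First, absolute opening energies are larger than
nearest-neighbour-model values (tens of kcal/mol for a 48-nt region)
because every pair carries its full constant weight; rankings and
differences, which drive the optimiser, behave sensibly. Second, the
exact high-temperature limit is OE/RT → ln(N_full/N_constrained) with N
the plain structure counts — the free-energy *cost* does not vanish at
high temperature, the energy *differences* do; the test suite checks
this correct limit. For full thermodynamics, per-position
unpaired-probability tables from an external folding tool can be read
(`load_external_openen`, −RT·ln p of the matching stretch), replacing
the internal model entirely.

An exhaustive structure enumerator (guarded to 25 nt) provides the
independent oracle: on random short sequences the DP and the
enumeration agree on OE to better than 1e−9 kcal/mol, and on Z to one
part in 10⁹.

## Expression score and annealer

Score = 100·σ(β₀ + β₁·OE), applicable to the *E. coli* T7 lac context.
The bundled defaults β₀ = 35.4593, β₁ = −0.7277 were fitted once by
logistic regression separating the opening-energy distributions of two
synthetic populations from the fixtures module (random-codon genes as
the "expressed" group, hairpin-planted genes as the "failed" group, 150
each, −24:24 region, fixed seed) and are explicitly non-canonical
configuration: anyone with calibration data for their own host should
replace them. For hosts/promoters other than *E. coli*+T7 the score is
suppressed and targets are binary (maximise/minimise).

The annealer proposes one synonymous codon substitution per step,
restricted to codons overlapping the optimisation region
(`scope=initiation_region`) or anywhere in the CDS (`full_cds`).
Proposals containing a forbidden motif on either strand are rejected
before scoring (filter-then-score). The objective is |score − target|
for numeric targets, else ±OE. The initial temperature is calibrated
from a 30-proposal burst so roughly half of average-sized uphill moves
would be accepted; cooling is geometric (×0.95, applied 100 times over
a run). `quick` = 1 restart × 1 000 iterations, `deep` = 8 restarts ×
5 000 iterations. Opening energies are memoised per codon assignment,
so on small synonymous spaces a deep run effectively enumerates the
space — on ≤256-variant genes it recovers the exhaustive optimum
essentially always. All evaluated feasible states form the candidate
pool; ranking is |score − target| (ties: fewer nucleotide changes, then
lexicographic sequence) for the default system, fewest changes first
otherwise. Determinism: one integer seed drives a single PCG64 stream.

Forbidden-motif defaults are the recognition sites AarI CACCTGC, BsaI
GGTCTC, BsmBI CGTCTC, screened on both strands; user motifs merge with
the defaults unless replacement is requested. If a forbidden site lies
outside the optimisable codons (e.g. in the UTR) no synonymous variant
can remove it; the input is returned with its motif hits and a warning.

The terminator screen is a deterministic heuristic for the intrinsic
(rho-independent) architecture: a perfect stem of ≥6 pairs with a
3–10-nt loop, the whole hairpin within a 60-nt window, immediately
followed by a 6-nt window containing ≥5 T. It is a coarse stand-in for
covariance-model searches; a table of externally computed hits can be
passed through verbatim instead. Hits trigger a warning suggesting
full-CDS optimisation.

The default 5′UTR is the 71-nt pET-style T7/lac-operator leader
commonly used with the T7 lac system; it is replaceable per run.

## Solubility

SWI is the arithmetic mean of per-residue weights; P(soluble) =
σ(a·SWI + b) with a > 0. The bundled weight set lives on [0, 1] (higher
= more solubility-promoting; e.g. E 0.9866, K 0.9267 at the top, C
0.5478, F 0.5821 at the bottom) and the logistic defaults a = 30,
b = −23 centre the curve at SWI ≈ 0.767 — near the mean weight — while
saturating at the extremes of the weight range. Both are configuration;
tests pin their own explicit test configurations so expected values are
self-contained. GRAVY uses the Kyte–Doolittle scale; flexibility uses a
normalised B-factor scale with a plain unweighted 9-residue window
(window size configurable) — the simplest standard choice.

The region-extension search looks for intervals that strictly contain
the query region with strictly higher P(soluble). Because P is monotone
in SWI, this is a search over (left, right) boundary pairs. When the
superset space has at most 20 000 candidates it is enumerated exactly
(cumulative-sum SWI makes each candidate O(1)); larger spaces are
explored by seeded simulated annealing over boundary moves of ±1..±5
with all visited improvements collected. The exact small-space path
guarantees desk-scale optimality; the annealing path keeps large
proteins fast. Results are sorted by P(soluble) descending with
deterministic tie-breaks.

Fusion-tag comparison concatenates tag + region and reports P(soluble)
per tag plus the untagged baseline. The bundled TRX/MBP/SUMO/GST
sequences are synthetic stand-ins (realistic length and composition,
generated once with a fixed seed, labelled synthetic in the FASTA);
users supply real tag sequences for production use. Domain annotations
come from a precomputed whitespace table (name, 1-based start/end,
description); no live web queries.

## Signal peptides

Sequence-level features (N-terminal 30 residues, neutral-padded when
shorter): fractions of hydrophobic/polar/positive/negative/proline
residues, the maximum 7-mer mean hydropathy, net charge of the first 5
residues, longest hydrophobic run, and mean flexibility — a
reconstruction of standard signal-peptide discriminators (charged
n-region, hydrophobic core, flexible mature start).

The cleavage-site weight matrix spans −15..+2 around the scissile bond
with +1 pseudocounts against the training background composition —
standard PWM practice. Candidate positions 6..35 are scored; each
candidate's features (scaled PWM score, position, upstream hydrophobic
fraction, context composition) feed the five cleavage classifiers.

Training splits the data into five seeded folds; model *i* trains on
the four folds other than *i*. The classifier family is pluggable —
anything exposing `predict_proba` satisfies the five-model contract;
the default is scikit-learn random forests (60 trees). Class
requirements: ≥100 per class, imbalance at most 1:50.

Score algebra, enforced exactly: Yᵢ = √(Sᵢ·max Cᵢ) per model, final =
median of the five Y; the per-model reading of "geometric mean of S and
max C" is isolated in `combine_scores` so the joint alternative is a
one-line change. Detection: any model with Yᵢ ≥ θ fires the secondary
tiers; the cleavage site is annotated when the final (median) score
reaches θ — both signals are reported since they can disagree near θ.
θ = 0.5 by default. Cleavage-model selection: the model whose max
C-score equals the median of the five maxima, ties to the lowest model
index; within the chosen series, the lowest-index argmax. Secondary
(toxin/fungal) tiers report the median of their five probabilities and
a star count of models ≥ θ. Model bundles serialise as a joblib payload
plus a versioned JSON manifest.

## Synthetic data

The fixtures module defines the study conditions for everything above.
Signal-peptide positives are built as Met + n-region (1–5 aa, ≥1 K/R) +
h-region (7–15 aa from AILVFM) + c-region (3–6 small residues) ending
A-X-A, then a 40-residue hydrophilic-biased mature tail; the cleavage
position (12..27 by construction) is recorded. Negatives are
composition-matched shuffles (Met kept first), so classifiers must use
positional structure, not composition alone. Toxin-like and fungal-like
variants re-write ~20% of the mature region to cysteine or ~33% to
Ser/Thr respectively. CDS fixtures back-translate random proteins with
uniform synonymous choice; the structured variant plants a 12-bp stem
between the UTR tail and CDS start (4-nt loop) across the −24:24
region. The solubility gradient interpolates composition between F/C
and E/K extremes, monotone in SWI under any sensible weighting.

What the generators do *not* emulate: real codon-usage bias, UTR
regulatory motifs, nearest-neighbour folding energetics, the true
diversity of signal peptides (Sec/Tat pathways, transmembrane
confusables) or experimentally measured solubility. Passing tests
therefore demonstrate algorithmic correctness and calibration on the
stated synthetic conditions, not predictive performance on biological
benchmark sets.

Seeding: one run seed splits into independent child streams via
`SeedSequence([seed, crc32(tag)])`, so subsystems are reproducible in
isolation; all randomness flows from explicit integer seeds.

## Problem sizes and numerics

The validation suite uses enumeration oracles up to 14 nt (structures),
4-codon genes (≤256 synonymous variants, 100 cases) for annealer
optimality, 20 proteins ≤60 aa for region-search optimality, and
1 000/500 train/test sequences for ensemble recovery — sizes chosen so
every oracle is exact and the whole suite runs in about a minute.
Tolerances: 1e−9 kcal/mol against the enumeration oracle (relative
1e−9 on Z itself, whose magnitude reaches 10⁶); 1e−12 on closed-form
means; exact identity on score algebra. Ties everywhere break
deterministically (lowest index / lexicographic) so repeated runs are
byte-identical.

## Known limitations

* Constant per-pair energies overstate absolute opening energies;
  use the external-backend reader when absolute kcal/mol matter.
* The terminator heuristic only finds perfect stems and will miss
  bulged terminators; it is a screen, not a predictor.
* The bundled expression-score and solubility coefficients are
  synthetic re-derivations, not fits to experimental corpora.
* The signal-peptide ensemble is only as good as its training set;
  the shipped generators produce idealised architectures.
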