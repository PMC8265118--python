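# exprkit

Sequence-engineering toolkit for recombinant protein expression. It
bundles three engines that practitioners typically need together when
moving a gene into an expression host:

1. **Initiation-region accessibility optimisation** — protein output
   correlates with how easily ribosomes can open the mRNA around the
   start codon. The cost of keeping a region unpaired across the
   Boltzmann ensemble of secondary structures is its *opening energy*

   *OE* = −RT·ln(Z<sub>constrained</sub>/Z<sub>full</sub>) [kcal/mol],

   where Z sums exp(−E/RT) over all nested structures and
   Z<sub>constrained</sub> over those leaving the region single-stranded.
   `exprkit` minimises (or tunes) the opening energy of a host-specific
   region — −24:24 for *E. coli*, −7:89 for *S. cerevisiae*, −8:11 for
   *M. musculus*, −24:89 otherwise — by **simulated annealing over
   synonymous codons**, so the encoded protein never changes. Candidates
   containing AarI/BsaI/BsmBI recognition sites (either strand) are
   rejected, and results are screened for intrinsic-terminator-like
   hairpin + U-tract elements. For the *E. coli* T7 lac system the
   opening energy maps to a 0–100 expression score through a logistic
   curve, 100·σ(β₀ + β₁·OE) with β₁ < 0.

2. **Solubility analysis** — the solubility-weighted index
   SWI = mean per-residue solubility weight, mapped to a probability of
   solubility P = σ(a·SWI + b), plus GRAVY (mean Kyte–Doolittle
   hydropathy) and sliding-window flexibility profiles. A boundary
   search returns regions that strictly contain a region of interest
   with strictly higher P(soluble), and fusion-tag comparison reports
   P(soluble) of TRX/MBP/SUMO/GST fusions versus the untagged region.

3. **Signal-peptide detection** — five probabilistic classifiers give
   sequence-level S-scores; a −15..+2 position-specific log-odds matrix
   scored along the N-terminus feeds five further classifiers giving
   per-position C-scores. Per model Yᵢ = √(Sᵢ·max Cᵢ); the final call is
   the median of the five Y-scores, and the cleavage site comes from the
   model whose max C-score is the median of the five maxima. Detected
   peptides pass through toxin- and fungal-origin tiers, each reporting
   a median score and a star count (models agreeing above threshold).
   Ensembles are trained locally from labelled sequences; the fixtures
   module generates seeded synthetic training sets with planted
   n/h/c-architecture signal peptides.

The secondary-structure energy model is deliberately simple (constant
energy per GC/AU/GU pair, minimum hairpin loop 3, no stacking) so that
the O(n³) partition-function dynamic programme can be validated exactly
against exhaustive structure enumeration; accessibility values from a
full-thermodynamics external folding tool can be supplied through a
tabular unpaired-probability reader.

## Worked example

Optimise three demo coding sequences toward an expression score of 90
for *E. coli* with the bundled T7 leader as 5′UTR:

```bash
exprkit optimize --cds src/exprkit/data/demo_cds.fasta \
    --target 90 --seed 42 --out results.csv
```

First-ranked solution per input (from `results.csv`):

```
          id  oe_before  oe_after  score_before  score_after  n_changes
random_cds_0    43.6030   45.6515         97.66        90.37          8
random_cds_1    44.8799   45.7071         94.27        90.01          6
random_cds_2    43.5790   45.7106         97.70        89.99          5
```

Each input starts above the requested score (opening energies ≈ 43.6–44.9
kcal/mol on the −24:24 region under the simplified energy model), so the
annealer *raises* the opening energy until the score lands next to 90;
5–8 synonymous nucleotide changes suffice, the protein sequence is
untouched, and no forbidden restriction site appears on either strand.
Solutions are ranked by |score − target|, ties by fewer changes.

Solubility and signal-peptide analyses run the same way:

```bash
exprkit solubility --seq protein.fasta --region 10:120 --tags --out sol.csv
exprkit signal --train 1000 --seq protein.fasta --seed 7 --out sp.csv
exprkit fixtures --kind sp_positive --n 100 --seed 1 --out train.fasta
```

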