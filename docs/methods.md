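# Methods

## The screening problem

Methionine gamma-lyase (methioninase) is a PLP-dependent enzyme whose
closest relatives — above all cystathionine gamma-synthase — are similar
enough that family-level profile HMMs and database annotations cannot
separate them. Two short active-site stretches can: Tyr-Gly-Cys
(positions 114–116 of the *P. putida* enzyme; Cys116 is the specificity
residue, and Cys116→His is the classic inactivating mutation) and
Lys-Asp (240–241). `mglscreen` encodes the screen as an ordered funnel —
model capture, optional annotation consensus, YGC presence, KD presence,
then positional validation against a reference — because the
intermediate counts are themselves the result of interest. Presence is
checked before position: a single-pass positional check would fold the
two presence stages into one and change the intermediate counts, so the
stage order is fixed.

## Profile HMM capture

`profile_hmm` implements a plan7-style profile (match/insert/delete
states, the seven transition classes per node) with two scorers:
Viterbi (best path) and forward (sum over paths), both as log2-odds
("bits") against an i.i.d. background null. Scoring is **global**: one
pass through the whole model emitting the whole sequence. This is
deliberately simpler than hmmscan's multihit local mode, which means
bit scores are *not* numerically comparable to hmmscan's. The classic
capture threshold of 150 bits is kept as the default constant, but any
serious use should calibrate the threshold on scored data (the test
suite places it at `min(true family scores) − 1`, which cleanly
separates family members from background at every seed tried).

Construction from a seed alignment follows the standard recipe: columns
with gap fraction < 0.5 become match states; emissions and transitions
are Laplace-smoothed observed counts, `P = (count + pc) / (total + k·pc)`
with pseudocount 1.0 and `k` the number of outcomes (20 for emissions,
3/2/2 for transitions out of M/I/D); the null model is the smoothed
overall residue frequency of the alignment. `X` residues are treated as
missing data when counting and contribute 0 bits when scoring (their
emission cancels against the null). Delete states beyond the last node
do not exist; ties in the Viterbi recursion resolve by the evaluation
order M, then I, then D (ties only affect path identity, never the
score). All DP is in log2 space; both scorers are checked against
exhaustive path enumeration on small models (M ≤ 3, length ≤ 4) to
1e-9 (Viterbi) / 1e-6 (forward).

HMMER3 ASCII profiles (`HMMER3/f`, e.g. the TIGRFAM methioninase
family model) are parsed via pyhmmer; because such files imply rather
than store their null model, the standard amino-acid background is
used. Emission rows are renormalized after parsing to absorb the
file's printed rounding.

## Alignment and coordinate transfer

`pairwise.global_align` is Gotoh affine-gap Needleman–Wunsch via
Biopython's `PairwiseAligner` (global mode, end gaps penalized); a gap
run of length L costs `gap_open + (L−1)·gap_extend`. Defaults are
BLOSUM62 with open 10.0 / extend 3.0, echoing the Kalign penalties used
for the published alignment of confirmed hits (the aligner itself
differs — a documented fidelity caveat). Traceback ties are resolved by
the aligner's deterministic first-alignment order; scores are
tie-independent and match a brute-force all-alignments oracle for
sequences up to length 6.

Percent identity divides identical columns by **total alignment
columns** (BLAST-style) and is reported to two decimals. The denominator
is configurable (`"shorter"` divides by the shorter sequence length)
because published identity figures rarely state their convention.

The positional filter needs only candidate↔reference coordinate
transfer, which pairwise alignment provides exactly; the multiple
alignment for tree building is therefore a star alignment around the
reference ("once a gap, always a gap" merge on reference columns)
rather than a progressive MSA. Degapping any row recovers the input
sequence exactly.

## The anchor filter

A candidate is CONFIRMED when (a) both motifs occur somewhere in its
sequence, and (b) mapping each anchor position of the reference through
the global alignment lands on non-gap, *consecutive* candidate positions
whose residues spell the motif. Consecutiveness means an insertion
inside the motif rejects — the strictest reading of "same position as
the reference". A `position_tolerance` knob (default 0) optionally
accepts motif starts within ±k of the mapped position, since published
pipelines rarely state whether small offsets were tolerated. Extra
motif occurrences elsewhere in the candidate are recorded in the
verdict but never confirm.

The annotation-consensus stage is a table-driven filter (id → label,
accepted set defaults to `{"methionine-gamma-lyase"}`): it emulates
checking candidates against external annotation services, which are
deliberately out of scope. Ids absent from the table pass through.

## Synthetic data: what it emulates and what it does not

The generator produces the mixture the funnel has to resolve, with
truth labels:

* `true_mgl` — reference mutants; every non-anchor position substitutes
  with probability `mutation_rate` to a uniformly drawn different
  residue; anchor positions are never touched.
* `decoy_no_ygc` / `decoy_no_kd` — the same mutants with the anchor Cys
  replaced by His (or Lys by Ala). Absence of the destroyed motif
  *anywhere* is the class definition, so accidental copies created
  elsewhere by mutation are scrubbed (one residue resampled until no
  occurrence remains).
* `decoy_misplaced` — YGC excised at the anchor and re-inserted at
  least 30 residues away, KD left intact: only the positional stage can
  reject it. The 30-residue displacement guarantees the alignment
  cannot re-map the anchor onto the moved copy.
* `background` — i.i.d. proteins, length uniform in [300, 500],
  residue frequencies uniform 1/20 by default (configurable). Random
  proteins *may* contain either motif by chance (~5 % carry a YGC), so
  a background record's truth is only "never confirmed", and fixtures
  that need a motif-free background verify that property for their seed
  (`background_is_motif_free`) rather than biasing the generator.

The synthetic reference is 398 residues (a typical bacterial
methioninase monomer) drawn from average natural residue composition —
so its predicted mass lands in the realistic ~44 kDa range — with the
two motifs planted at the *P. putida* coordinates and accidental copies
scrubbed. It is labelled synthetic everywhere; it is **not** the real
*P. putida* sequence, which users supply themselves.

Default class counts are 5/5/5/5/5 with mutation rate 0.02 and lineage
weights following the published phylum shares of confirmed
methioninases (Proteobacteria 0.50, Firmicutes 0.29, Firmicutes_A 0.13,
Fusobacteriota 0.08). All randomness flows from one explicit seed per
call (`numpy` Generator; screen sets derive per-class child seeds from
a `SeedSequence`), so outputs are byte-reproducible.

What passing tests on this data do *not* show: the generator has no
real family divergence structure (no rate heterogeneity, no indel
process beyond the engineered ones), no sequencing or assembly error,
and decoys are built from the same backbone as the positives. Synthetic
recovery being 100 % therefore validates the funnel's logic, not its
sensitivity/specificity on real metagenome ORFs, where capture
thresholds and annotation quality dominate.

## Taxonomy rollup

Lineages are GTDB-style seven-rank semicolon strings; `p__`-style
prefixes are stripped. The countable unit is the genome when a
record-to-genome mapping is given (a genome is positive if any of its
records is confirmed — multiple hits count once), otherwise the record.
Summaries report per-taxon positives, totals, the within-taxon fraction,
and the taxon's share of all positives; shares sum to 1 whenever any
positive exists, and are reported as 0 (with a logged warning) when
none does. Output includes a plain-text per-taxon table suitable for
external pie-chart rendering (e.g. iTOL).

## Neighbor-joining tree

Distances are p-distances over columns where both rows are ungapped,
optionally Poisson-corrected (`d = −ln(1−p)`; saturation `p ≥ 1` is an
error naming the pair). NJ is standard Saitou–Nei with Q-matrix
selection; ties break on the smallest index pair; negative branch
lengths are clamped to 0 with the deficit moved to the sibling edge;
the final three nodes form a trifurcating root (the tree is unrooted).
Two taxa yield a single edge split evenly. On additive matrices NJ
recovers the generating tree exactly (checked against path-length
matrices of random 4–8-taxon trees to 1e-9, and cross-checked against
scikit-bio's independent NJ implementation). NJ replaces the
approximate-ML step used for the published figure: the claims supported
here concern distribution and clustering structure, not branch support
— no bootstrap values are produced.

## Assay arithmetic

The ammonia standard curve is unweighted OLS (assumed linear over the
stated 0.01–0.4 mM range); `r² = 1 − SS_res/SS_tot`, with a flat
response flagged degenerate and reported as r² = 0. Back-calculated
concentrations outside the fitted range are flagged extrapolated;
negative ones clamp to 0 with a flag. One enzyme unit is 1 µmol of
methionine converted to ammonia per minute; specific activity is U/mg.
Replicate columns are summarized as mean ± sample SD (ddof 1). Protein
mass uses average (not monoisotopic) residue masses plus one water,
matching SDS-PAGE-scale comparisons; `X` makes the mass undefined and
is an error. Published specific-activity figures depend on reaction
volumes and dilution factors that are rarely printed, so no particular
published value is asserted — the module computes from its inputs only.

## Numerical and design choices, in brief

* All residue positions anywhere in the API are 1-based (Cys116
  convention); alphabet is the 20 standard residues plus X, with
  B/Z/U/O/J folded to X on input (logged).
* Funnel counts are validated monotone on every construction.
* The pipeline writes no timestamps; reruns with identical inputs and
  config are byte-identical (verified by SHA-256 in the tests and the
  acceptance script).
* Problem sizes in the shipped tests and acceptance script (25-record
  screen sets, ten-seed recovery sweeps, M ≤ 3 enumeration oracles,
  4–8-taxon trees) were chosen as the smallest sets that exercise every
  stage and decision branch of the method.

## Known limitations

* Global-mode HMM scores are not hmmscan-compatible; thresholds must be
  calibrated per model and dataset.
* The star MSA is exact for reference-anchored coordinate transfer but
  inferior to a progressive MSA for distant pairs' mutual alignment;
  tree distances between two highly diverged non-reference sequences
  inherit that approximation.
* The positional check assumes the reference anchors are correct for
  the clade screened; enzymes with genuinely shifted active-site
  architecture would be scored MISPLACED.
* No E-value calibration, domain envelopes, or local alignment; no
  nucleotide handling.
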