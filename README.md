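# mglscreen

An in-silico screening funnel for **methionine gamma-lyase**
(methioninase, MGL, EC 4.4.1.11) in collections of protein sequences —
predicted ORFs from genomes, MAGs/SAGs, or metagenome assemblies.

Methioninase degrades L-methionine to 2-oxobutyrate, methanethiol, and
ammonia. It is hard to annotate reliably: family models such as
TIGRFAM's methionine gamma-lyase profile also capture near-identical
PLP-dependent homologs, above all cystathionine gamma-synthase. What
separates a true methioninase is its active site: the conserved
Tyr114–Gly115–Cys116 ("YGC") and Lys240–Asp241 ("KD") stretches, in
*Pseudomonas putida* numbering. `mglscreen` implements the resulting
staged filter:

1. **Capture** — score candidates against a profile HMM (built from a
   seed alignment or loaded from a HMMER3 ASCII file) with global-mode
   Viterbi/forward bit scores against an i.i.d. null;
2. **Annotation consensus** (optional) — drop candidates whose external
   annotation label is not an accepted methioninase label;
3. **YGC presence**, then **KD presence** — exact motif scans;
4. **Positional validation** — globally align each surviving candidate
   to the reference enzyme (Gotoh affine gaps, BLOSUM62, gap open 10.0 /
   extend 3.0) and require both motifs at the candidate positions the
   reference anchor coordinates map to.

Each candidate receives a verdict (`NO_HMM_HIT`, `REJECTED_ANNOTATION`,
`NO_YGC`, `NO_KD`, `MISPLACED`, `CONFIRMED`) and the run reports the
monotone funnel counts. Downstream, confirmed hits can be rolled up a
GTDB-style taxonomy (per-phylum positives/totals/shares, genome-level
de-duplication), placed on a neighbor-joining protein tree (p-distance
or Poisson-corrected, Newick output), and characterized with the
standard assay arithmetic (Nessler ammonia standard curve, enzyme units,
specific activity in U/mg, sequence-predicted molecular mass).

A synthetic-data generator produces labelled screening sets — true
family mutants with protected anchors, decoys missing YGC (the classic
Cys116→His inactivation) or KD, decoys with a *displaced* YGC that only
the positional stage can reject, and unrelated background proteins — so
the whole funnel is testable without any database download.

## Worked example

```bash
mglscreen simulate --seed 7 --mutation-rate 0 --out demo/
mglscreen screen \
    --candidates demo/records.fasta \
    --reference demo/reference.fasta \
    --taxonomy demo/taxonomy.tsv \
    --out demo/run/
```

The screen prints (to stderr):

```
funnel: input=25 hmm_pass=25 ygc=15 ygc_kd=10 confirmed=5
```

reading: 25 candidates entered; all passed (no HMM gate configured); 15
contained YGC (the 5 no-YGC decoys and 5 motif-free background proteins
stopped); 10 of those also contained KD; and exactly the 5 true family
members carried both motifs at the reference-anchored active-site
positions. `demo/run/` then holds `verdicts.tsv`, `funnel.tsv`,
`confirmed.fasta`, the per-phylum `summary.tsv` and
`itol_annotation.txt`, the reference-anchored `confirmed_aligned.fasta`,
the NJ `tree.nwk`, and a `manifest.tsv` echoing the configuration.
Reruns with the same inputs and config are byte-identical.

The same machinery is available as a library:

```python
from mglscreen import synth
from mglscreen.anchors import screen_batch

reference, anchor = synth.make_synthetic_reference()
records, truth = synth.generate_screen_set(synth.SynthConfig(seed=7), reference, anchor)
verdicts, funnel = screen_batch(records, anchor)
print(funnel)   # FunnelCounts(n_input=25, n_hmm_pass=25, n_with_ygc=15, ...)
```

To screen against the real *P. putida* enzyme, load it from FASTA and
build a `ReferenceAnchor` from it (the package ships no third-party
sequence data).

## Layout

| module | contents |
| --- | --- |
| `mglscreen.io` | FASTA / Stockholm / aligned-FASTA / TSV readers and writers, `ProteinRecord`, `Msa` |
| `mglscreen.synth` | labelled synthetic screening sets and the synthetic reference |
| `mglscreen.profile_hmm` | profile construction, HMMER3 ASCII loading, Viterbi/forward bit scores, capture stage |
| `mglscreen.pairwise` | global affine-gap alignment, percent identity, coordinate transfer, star MSA |
| `mglscreen.anchors` | the YGC/KD presence + position filter and the screening funnel |
| `mglscreen.taxa` | taxonomic rollup and annotation tables for pie-chart rendering |
| `mglscreen.njtree` | protein distances, neighbor joining, Newick IO |
| `mglscreen.assay` | standard curve, enzyme units, specific activity, protein mass |
| `mglscreen.pipeline`, `mglscreen.cli` | end-to-end runs and the `mglscreen` command |

See `docs/methods.md` for the model assumptions, parameter choices, and
limitations.
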