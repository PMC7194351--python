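# epimap

Deductive epitope mapping for short linear motifs.

When an antibody raised against a synthetic peptide stains tissue, but the
endogenous antigen is unknown, the epitope can be mapped *deductively*: sift
a predicted proteome for the peptide's diagnostic motif, put exact numbers
on how often such matches arise by chance, compare the candidate peptides'
3-D conformers, and read the epitope off a panel of competing peptides in
antibody-preabsorption experiments. `epimap` implements that whole chain as
a tested Python library with a thin CLI, for protein chemists and
immunohistochemists who need the arithmetic behind such an argument to be
reproducible.

The worked case built into the package is the goat antibody G530 raised
against the Edman-derived 14-mer **EPL001** (`MKPLTGKVKEFNNI`), whose
blocking panel shows that a C-terminal `NNI` is the contiguous core of the
epitope, with the phenylalanine required non-contiguously.

## What it computes

**Proteome motif census ("motif-omics").** For a motif m (canonically the
tripeptide `NNI`), the census keeps the proteins with ≥ 1 occurrence (the
*motif-ome*) and counts total occurrences (overlaps included), C-terminal
occurrences, extended sub-motifs (`FNNI`, `EFNNI`), proteins < 100 aa, the
pool of non-initiator methionines, anchored `M` + 10×any + `NNI` 14-mer
windows, and the survivors of the **Method of Exclusion**: an M-initial
11-mer window survives only if positions 2–11 avoid every residue outside
the reference complement (`ARNDCQHISWY`, plus a second `M`), and survivors
are ranked by the number of distinct reference residues they carry.

**Chance-match calculus.** Under an i.i.d. residue model with composition
π (default uniform 1/20), a pattern with fixed slots r₁…r_f has per-window
probability p = Π π(rᵢ); a protein of length L gives
P(≥1 hit) = 1 − (1 − p)^(L−k+1). Independent match probabilities multiply,
and results render as "1 in N" at a magnitude-dependent granularity.
The *partial anagram* probability — that a random k-mer is an ordered
arrangement of k residues drawn from a reference multiset — is computed
exactly by sub-multiset enumeration with multinomial ordering counts: for
EPL001-minus-NNI (`MKPLTGKVKEF`, 11 residues) and k = 9 there are
3,507,840 admissible 9-mers out of 20⁹, i.e. ≈ 1 in 146,000; the chance
that a random ordered 9-permutation of that multiset starts with its
single methionine is 1/11.

**Conformer comparison.** Two peptide conformers, each summarised by
labelled interatomic distances (Å) between hand-selected atoms, are
compared with Σ(O−E)²/E over shared pairs, referred to the χ² distribution
with (pairs − 1) degrees of freedom, plus the fraction of pairs with
(O−E)² above a threshold (default 10 Ų).

**Preabsorption analysis.** Staining images are quantified as the pixel
fraction above a fixed threshold, normalised to percent of the
peptide-free control; groups are summarised as mean ± SEM with unpaired
t-tests (pooled or Welch, from raw replicates or summaries); IC50 is
bounded by the smallest tested dose reaching ≤ 50%. The epitope's
C-terminal pattern is inferred by exhaustively scoring fixed/wildcard
suffix patterns by the accuracy of "blocks iff the pattern matches the
peptide's C terminus", and a single-substitution scan classifies residues
as contiguous-core, required-non-contiguous, or dispensable.

**Synthetic data.** Seeded generators emit proteomes with exactly planted
motif occurrences (rejection-sampled backgrounds, truth manifests),
jittered distance tables, logistic dose-response panels, and images with
planted area fractions, so every analysis is testable offline.

## Worked example

```
$ epimap prob anagram --multiset MKPLTGKVKEF --k 9 --initial M
probability: 6.85125e-06
odds: 1 in 146,000
initial_M_prob: 0.0909091 (1 in 11)
```

A 9-residue ordered partial anagram of `MKPLTGKVKEF` is a ~1-in-146,000
per-window event, and conditioning on it starting with the multiset's one
methionine costs a further factor of 11 — together ≈ 1 in 1.6 million,
which is why a methionine-commencing nine-residue anagram found in a
candidate protein is strong evidence against coincidence. Combining two
independent published per-protein match odds:

```
$ epimap prob combine --odds 5247 --odds 2636
probability: 7.23009e-08
odds: 1 in 14m
```

Census of a synthetic proteome with a known plant plan (12 internal NNIs,
2 C-terminal, 3 anchored M+10x+NNI windows across 50 proteins):

```
$ epimap simulate proteome --n-proteins 50 --seed 1 --out demo/
wrote 50 proteins to demo/proteome.fasta
proteome_size: 50
motif_ome_size: 14
total_hits: 17
terminal_hits: 2
short_protein_count: 2
methionine_pool: 146
anchored_window_count: 3
exclusion_survivor_count: 0
sub_pattern_EFNNI: 0
sub_pattern_FNNI: 1
```

The 17 total hits are the 14 planted NNIs plus one inside each anchored
window; the single FNNI is an F that happened to precede one planted NNI —
sub-motif counts are census observations, not plants. Running
the same census via `epimap sift --fasta demo/proteome.fasta` reproduces
the manifest exactly.

Epitope inference from the built-in published blockade panel:

```python
>>> from epimap import infer_epitope
>>> from epimap.datasets import g530_panel, FNNI_SUBSTITUTION_CURVES
>>> res = infer_epitope(g530_panel(), max_len=6,
...                     substitution_results=FNNI_SUBSTITUTION_CURVES)
>>> str(res.best), res.best_score.accuracy
('NNI', 1.0)
>>> res.residue_classification
{1: 'contiguous-core', 2: 'contiguous-core', 3: 'contiguous-core',
 4: 'required-non-contiguous'}
```

C-terminal `NNI` separates blockers from non-blockers with accuracy 1.0,
and the alanine scan shows the preceding F is required without being part
of the contiguous core — a mixed contiguous/non-contiguous epitope.

## Layout

- `epimap.records`, `epimap.motifs`, `epimap.sift` — FASTA IO, motif
  patterns/scanning, census and Method of Exclusion
- `epimap.probability` — chance-match, anagram and conditional odds
- `epimap.conformers` — distance tables, χ² comparison, verdicts
- `epimap.preabsorption` — quantification, statistics, epitope inference
- `epimap.synthetic` — seeded generators with ground truth
- `epimap.datasets` — the bundled published panel, constants, printed
  distance subsets
- `epimap.cli`, `epimap.config` — `epimap` subcommands and run configs

See `docs/methods.md` for the models, conventions and limitations.
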