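# topper

Evidential fusion of transmembrane-protein topology predictors.

About a quarter of a typical proteome is α-helical membrane protein, and a
protein's *topology* — how many transmembrane (TM) helices it has, where they
sit in the sequence, and whether the N-terminus faces the cytoplasm ("in") or
the outside ("out") — is the first structural question asked about one.
Many per-residue predictors exist (hydrophobicity-based, statistical,
HMM/SVM-based), each labelling every residue `i` (intracellular), `M`
(membrane) or `o` (extracellular), and they disagree. `topper` is for
computational biologists who already have the outputs of two or more such
predictors and want a principled consensus: it fuses the per-residue labels
with Dempster-Shafer evidence theory, decodes the fused labels into a
topology, and scores predictions at residue, TM-region and topology level.

## The method

Work on the frame Ω = {i, M, o}. A predictor φ with confusion matrix
C<sub>φ</sub> = (n<sub>pq</sub>) (rows = true class, columns = predicted) has
overall recognition rate

&nbsp;&nbsp;&nbsp;&nbsp;Rc<sub>φ</sub> = Σ<sub>p</sub> n<sub>pp</sub> / Σ<sub>p,q</sub> n<sub>pq</sub>.

When φ labels a residue as class p, that observation becomes the basic
probability assignment (BPA)

&nbsp;&nbsp;&nbsp;&nbsp;m<sub>p</sub><sup>φ</sup>({p}) = Rc<sub>φ</sub>,&nbsp;&nbsp;
m<sub>p</sub><sup>φ</sup>(Ω∖{p}) = 1 − Rc<sub>φ</sub>,

i.e. the complement mass sits on the *doubleton* of the other two classes,
not on total ignorance. For each residue r, the N predictors' matched BPAs
are fused with Dempster's rule of combination (orthogonal sum)

&nbsp;&nbsp;&nbsp;&nbsp;m<sub>r</sub> = m<sup>φ1</sup> ⊕ m<sup>φ2</sup> ⊕ ⋯ ⊕ m<sup>φN</sup>,
&nbsp;&nbsp;(m₁ ⊕ m₂)(A) = (1−K)<sup>−1</sup> Σ<sub>B∩C=A</sub> m₁(B) m₂(C),

where K is the conflict mass; the pignistic transformation
BetP(x) = Σ<sub>A∋x</sub> m<sub>r</sub>(A)/|A| turns the fused mass into a
probability triple, and the residue class is its argmax (ties break in the
canonical order i, M, o). Maximal runs of `M` of at least 5 residues
(configurable) become TM segments; the N-terminal side is read off the first
non-M label.

Scoring follows the standard segment-overlap convention: a predicted and an
observed TM region match when they share ≥ 9 residues, and with N_obs
observed, N_prd predicted and N_cor matched regions, coverage M = N_cor/N_obs,
precision C = N_cor/N_prd, and the overall prediction power is the geometric
mean Q = 100·√(M·C). A topology is correct when all regions match one-to-one
and the N-terminal orientation agrees.

## Worked example

Two predictors with accuracies 0.80 and 0.70 both call a residue `M`
(`examples/01_fuse_one_residue.py`):

```
predictor 1 mass: {'M': 0.8, 'i|o': 0.2}
predictor 2 mass: {'M': 0.7, 'i|o': 0.3}
fused mass      : {'M': 0.9032, 'i|o': 0.0968}
pignistic BetP  : {'i': 0.0484, 'M': 0.9032, 'o': 0.0484}
decided class   : M
```

The conflict here is K = 0.8·0.3 + 0.2·0.7 = 0.38; the fused mass on {M} is
0.56/0.62 ≈ 0.9032 — two independent above-chance witnesses reinforce each
other beyond either one alone, while the residual 0.097 stays on the {i,o}
doubleton instead of being forced onto a single class.

`examples/02_benchmark_tables.py` recomputes, from the confusion matrices and
region counts bundled in `topper.benchmark`, the published residue- and
region-level scores of five predictors (OCTOPUS, PRO-TMHMM, PRODIV-TMHMM,
SCAMPI-msa, SCAMPI-seq) and their fusion on a 125-protein benchmark — e.g.
fusion residue accuracy 79.99 % vs. 78.69 % for the best individual
predictor, and fusion Q = 97.85 % vs. 97.37 %.

`examples/03_synthetic_crossval.py` simulates 125 proteins with five
conditionally independent ~78 %-accurate predictors and runs the tenfold
cross-validation harness (profiles estimated on training folds only):

```
fold sizes: [13, 13, 13, 13, 13, 12, 12, 12, 12, 12]
  P1 residue accuracy: 78.79%
  ...
ensemble residue accuracy: 95.05%
```

The ensemble gains ~16 points of residue accuracy over each individual — the
textbook benefit of fusing independent witnesses.

## Command line

```sh
topper simulate --out bundle/ --seed 42          # synthetic benchmark bundle
topper combine  --fasta seqs.fa --pred A=a.lab --cm A=a.cm.tsv ... -o fused.lab
topper eval     --fasta seqs.fa --observed obs.lab --predicted fused.lab -o report.tsv
topper crossval --config run.yaml                # seeded tenfold CV
```

Label files are FASTA-like (`>id` then lines of `i`/`M`/`o`); confusion
matrices are 4-line TSVs with a `truth  i  M  o` header. See
`docs/methods.md` for format and parameter details.

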