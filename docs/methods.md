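# Methods

This note records the model, the defaults and the open design choices of
`ascsite`, in the spirit of a methods section: what is computed, under what
assumptions, and what the synthetic validation does and does not show.

## Pipeline and assumptions

The central assumption is structural: substrate specificity within an
enzyme family is decided mainly by the residues lining the active site,
and one representative structure suffices to locate them for the whole
family.  The pipeline therefore needs (i) a template structure in which
the active site can be marked — by a bound het group (all copies count,
e.g. both chains of a homodimer), by a named residue, or by raw
coordinates — and (ii) an MSA of family members containing the template's
sequence, with class labels for the training subset.

Residue-to-column mapping requires the template's MSA row, gaps removed,
to equal the concatenated chain sequences in file order; up to 5% of
residues may disagree (non-standard residues read as `X`), anything more
is a hard error.  Multi-chain templates are handled by this concatenation,
so residues contributed by a second chain fall out naturally.

A residue joins the signature when the minimum distance between its heavy
atoms and the site atoms is at most the cutoff **and** its column's
reliability score reaches the threshold.  Waters and monoatomic het groups
(ions) never define the site; residues that themselves constitute a
residue-mode selector are excluded from the signature.  Distances are
Euclidean in Å on the coordinates as supplied — no symmetry expansion, the
user provides the biological assembly.

## Defaults and parameters

| parameter | default | rationale |
|---|---|---|
| distance cutoff | 6 Å | the conventional first-shell contact distance for a bound substrate; 5 Å is appropriate for tighter sites and is a per-run option |
| column reliability threshold (`core_min`) | 5 | midpoint of the 0–9 CORE scale of consistency-based aligners; exposed because no universally correct value exists |
| template identity prefilter | 0.20 | below ~20% identity to the template, the residue-to-column mapping itself becomes unreliable |
| guide representatives per class | 5 | greedy maximin (1 − identity) pick; enough diversity to anchor a profile without diluting it |
| sequence-to-profile gaps | open 10, extend 1 | standard affine penalties in BLOSUM62 half-bit units |
| soft-margin grid | 2⁻⁵…2¹⁵, step 2² | the standard libsvm model-selection grid; the protocol is insensitive to the exact endpoints |
| inner folds | 5 | stratified, shuffled with a fixed seed (42) for reproducible model selection |
| inner selection metric | accuracy | plain accuracy; macro-F is available as an option |
| RBF γ candidates | {0.25, 1, 4}/width | squared one-hot distances grow like the alignment width, so γ must scale inversely with it |

Inner-loop ties between (kernel, C) candidates resolve to the smallest C,
then to kernel order as configured — preferring stronger regularisation.
One-vs-one vote ties resolve by the larger sum of absolute decision values
supporting a tied class, then lexicographically; the vote vector is
reported so the tie-break is auditable.

When no aligner-produced column reliability scores are supplied, a proxy
is computed: the mean pairwise BLOSUM62 score of each column's residue
pairs, affinely rescaled to [0, 9] over the MSA (an MSA whose columns all
score identically maps to 9 everywhere — a degenerate alignment offers no
evidence of unreliability).  This proxy measures conservation, which is
related to but not the same as alignment reliability: genuinely
specificity-determining columns are variable by definition and can score
low.  Supplying real aligner scores is always preferable.

## Numerical choices

- **Kernels must be Mercer.**  String and z-scale kernels are explicit dot
  products.  The substitution matrices are made PSD by construction: the
  BLOSUM62 log-odds matrix is inverted to joint probabilities
  (q = p·pᵀ ⊙ 2^{B/2}, half-bit scale, Robinson–Robinson backgrounds),
  renormalised, and eigenvalue-clipped if any eigenvalue falls below
  −10⁻⁶; the McLachlan chemical matrix is clipped the same way if
  numerically indefinite.  Matrices carry a PSD certificate and the
  positionwise kernels refuse uncertified inputs.
- **Gaps and `X` carry no evidence**: their indicator/z-scale embeddings
  are zero vectors, so a position with a gap on either side contributes
  nothing to any signature kernel.  In the 1-NN mismatch distance, by
  contrast, `X` is an ordinary symbol and gap-vs-residue counts as a
  mismatch (double gaps are skipped).
- **Pairwise identity** is #identical/(columns where both rows carry a
  residue), 0 when no such column exists.
- The binary subproblems are solved exactly by libsvm (scikit-learn `SVC`
  on precomputed Gram matrices); dual coefficients, bias and support
  identities are exposed, and KKT conditions are asserted in tests.
- The sequence-to-profile aligner is a three-state (match / column-skip /
  insertion) affine DP against per-column average substitution scores;
  guide columns are never merged or split, insertions are dropped from the
  returned row, and ties prefer match over deletion over insertion, making
  the output deterministic.

## The synthetic generator

`FamilySpec` plants a ground truth the pipeline must recover: a consensus
sequence; a set of *signature columns* whose residues the toy structure
places within 6 Å of a four-atom pseudo-substrate at the origin (all other
residues ≥ 10 Å away, single Cα per residue); and *SDP columns* carrying
distinct per-class consensus residues.  Class members are the consensus
plus their SDP residues, i.i.d. substitution noise (default 5% per
column, uniform over the 19 alternatives) and sparse gaps (default 2%),
both applied only outside the SDP columns.  Everything is deterministic
from the seed, and the generated structure is written as PDB text and
re-read through the ordinary parser so fixtures exercise the real I/O
path.  Generated families carry column reliability 9 everywhere: the
generator produced the alignment, so reliability is maximal by
construction.

For the locality-contrast experiment the SDPs are deliberately planted
*outside* the signature columns; the generator permits this (range checks
only) because it is the mechanism behind the known failure mode of
site-restricted classifiers — signals carried by residues far from the
active site are invisible to the signature model while a whole-alignment
SVM still finds them.

What the generator does **not** emulate: phylogenetic correlation between
sequences, indel histories, alignment errors, or correlated substitutions.
Passing the synthetic checks therefore demonstrates correctness of the
machinery (geometry, mapping, kernels, protocol, ranking), not expected
accuracy on real families, whose difficulty is dominated by exactly those
unmodelled effects.

## Evaluation protocol notes

The outer loop is leave-one-out with the MTTSI cap applied per held-out
sequence; outer points whose cap empties the training pool (or leaves a
single class) are excluded from the metrics and counted in the report.
Macro precision treats a never-predicted class as precision 0.

Two protocol behaviours are worth knowing:

- **Seed sensitivity near the MTTSI boundary.**  With 5% noise the
  expected within-class identity of the synthetic families (~0.91) sits
  close to the 0.9 cap used in the planted-recovery experiments, so the
  retained training pool — and hence the macro F — varies noticeably
  between generator seeds.  The acceptance script therefore averages the
  stochastic quantities over three generator seeds (sample sizes are
  reported alongside).
- **Anti-learning under exactly balanced random labels.**  If the labels
  of a balanced two-class set are *exactly permuted*, leave-one-out
  evaluation is negatively biased: removing the held-out point tips the
  training majority against its class, and with no signal the chosen
  (heavily regularised) models track that majority, driving accuracy far
  below 0.5.  This is a known LOO artifact of sampling without
  replacement, not label leakage.  The null-calibration check therefore
  relabels points by independent fair coin flips — the regime in which
  the binomial 0.5 band is the correct null — and the measured accuracy
  falls inside 0.5 ± 3σ.

## Problem sizes

The validation suite runs entirely on generated data: planted-recovery
families of 3 × 20 sequences over 60 columns with an 8-residue site and
2 SDPs; a 2 × 100 family for null calibration; 50 random signature sets
for kernel validity.  These sizes keep the full nested protocol (LOO outer,
5-fold inner over an 11-point C grid) exact rather than subsampled.

## Known limitations

- The conservation proxy for column reliability penalises variable (hence
  potentially specificity-determining) columns; use aligner-produced
  scores when available.
- Structural alignment is out of scope: the MSA is taken as given (or
  sequences are aligned to it by the profile aligner); the package does
  not run consistency-based aligners itself.
- `X` residues and gaps are uninformative by design; families with many
  unknowns lose signal proportionally.
- The deployed model's final C (CLI `train`) is the mode of the C values
  chosen in the outer loop of the best kernel — a pragmatic rule; nested
  CV estimates generalisation but does not dictate a final
  hyperparameter.
- Single-position accuracy rankings reuse the full nested protocol
  (including the MTTSI cap) per column and class pair, which is exact but
  quadratic-ish in practice; expect minutes, not seconds, on hundreds of
  sequences.
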