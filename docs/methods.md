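# Methods

This note documents the models, conventions and numerical choices behind
`siftsim`, in the spirit of a statistics package's model documentation.

## Fingerprint model

An interaction fingerprint is a binary vector over an ordered
residue × interaction-type grid. The canonical interaction order is
`Any, BB, SC, Pol, Hyd, HBA, HBD, Aro, Chg` (any contact, backbone,
sidechain, polar, hydrophobic, H-bond acceptor, H-bond donor, aromatic,
charged); the bit index of (residue *i*, type *j*) is `i * n_types + j`.
Column names are `RESIDUE:INTERACTION` (e.g. `ASP86:HBA`), which makes the
layout round-trip losslessly through plain CSV. The reader accepts any
residue set (whole-protein or binding-site-only enumerations) and sniffs
comma/tab delimiters; the writer emits comma.

**Bit selection** (`ALL`/`WO1`/`WO3`) removes whole interaction types;
**filtering** removes data-driven dead columns: `RES` drops every residue
whose entire block is zero across the dataset, `INTS` drops every
individual all-zero column (a superset of `RES`). In the factorial grid,
selection is applied before filtering, mirroring a left-to-right
preprocessing pipeline; `INTS` commutes with selection, `RES` does not
quite (a residue alive only through a dropped type dies under
selection-first), which the tests pin down as a subset relation. Filtering
an entirely silent dataset is an error rather than an empty dataset,
because similarity on zero-length vectors is undefined. Filtering masks are
computed from the query dataset alone; the reference fingerprint is then
projected onto the surviving columns by name, so filtering remains a
property of the screened set.

## Similarity catalog

All 44 measures are functions of the confusion table (*a*, *b*, *c*, *d*,
*p*) of a fingerprint pair. The catalog is data-driven — abbreviation,
formula, scaling constants α/β, symmetricity, metricity, exchange
symmetry — so a correction is a one-line edit. Measures whose natural
range is not [0, 1] are rescaled by *s′ = (s + α)/β*:

- correlation-type coefficients on [−1, 1] use α = 1, β = 2;
- the dispersion coefficient lives on [−¼, ¼] (α = ¼, β = ½); Mountford's
  upper bound is 2 (β = 2);
- five measures have *p*-dependent attainable ranges and therefore
  *p*-dependent α/β: Forbes and Harris–Lahey (sup = *p*), Fossum
  (sup = (p−½)²/p), Dennis (range [−√p/2, (p−1)/√p]), and the two Cole
  coefficients (range [−(p−1), 1]).

Each bound was derived from the formula and is verified two ways in the
test suite: exhaustively over *every* confusion table up to p = 16, and on
randomized tables up to p = 512. A scaled value escaping [0, 1] by more
than 1e−9 raises an internal error (clamping applies only inside that
tolerance).

**Degenerate cases.** Two conventions, both logged:
identical fingerprints (*b = c = 0*) score the maximum *s′ = 1* for every
measure — including correlation-type measures whose raw formula would not
reach 1 — because under ranking semantics an identical interaction pattern
is maximally similar; any other zero denominator scores the minimum
*s′ = 0*.

**Classes.** Symmetricity follows the operational definition: `S` counts
*d* equally with *a* (invariant under simultaneous complement of both
fingerprints), `A` ignores *d* entirely (invariant under changes of *d*
alone), `I` underweights *d* — including measures such as Russel–Rao or
Consonni–Todeschini 3 where *d* enters only through *p* — and `Q` marks
correlation-based coefficients. Metricity `M` means 1 − *s′* satisfies the
metric axioms; this was verified by random-triple triangle-inequality
sweeps and holds for SM, RT, JT, SS1 and RR. (Baroni–Urbani–Buser fails
the triangle inequality for 1 − *s′* on concrete counterexamples and is
flagged `N`.) The Peirce and Cole coefficient pairs are directional —
swapping the two fingerprints maps Pe1↔Pe2 and Co1↔Co2 — and are the
documented exceptions to exchange symmetry.

The pairwise confusion counter packs bits and uses hardware popcount; the
similarity-matrix builder uses integer matrix products for the same counts,
which is faster when scoring a whole ligand set against one reference.

## Pretreatment

Even after α/β scaling, measures occupy very different sub-ranges of
[0, 1] (Mountford near 0, Yule near 1), which would bias row-wise min/max
fusion toward particular measures. Pretreatment therefore standardizes the
measure columns before fusion: autoscaling (mean 0, sample n−1 standard
deviation 1), range scaling (min 0, max 1), or rank transformation
(ascending, ties averaged). Constant columns carry no ranking information
and are set to zero with a warning. All three transforms are strictly
monotone within a column, so each measure's own ligand ranking is
untouched; what changes is only the cross-measure comparability that
fusion depends on. Fusion order (pretreat, then fuse) is a deliberate
choice: fusing raw values first would reintroduce exactly the range bias
pretreatment exists to remove.

## SRD

SRD is the Manhattan distance between rankings — the Spearman footrule
when there are no ties. Ranks are ascending with average ranks for ties;
normalization divides by the tie-free maximum (n²/2 even, (n²−1)/2 odd),
making normalized SRD a conservative percentage under ties. The maximum
and the distance itself are cross-checked against exhaustive-permutation
oracles for n ≤ 7.

The consensus reference is fused row-wise from the pretreated matrix:
row-maximum for actives, row-minimum for inactives — the hypothetical
ideal measure that scores actives as similar as any measure dares and
inactives as dissimilar.

**Randomization test.** The null distribution of SRD for random rankings
against a fixed reference is enumerated exactly for n ≤ 8 (40,320
permutations at the cutoff, sub-second) and sampled with a seeded
Monte-Carlo (default 10,000 draws) beyond. The tie-free null mean is
(n²−1)/3, which the tests verify exactly at n = 4 and within three
standard errors at n = 50. The reported p-value is one-sided:
P(random SRD ≤ observed).

**Cross-validation.** Fivefold by default: a seeded uniform permutation of
rows split into near-equal blocks (no stratification), each round dropping
one fold and rerunning fusion, ranking and normalization from scratch on
the remaining rows, plus a final round on all rows — six values per
measure. Fusion is recomputed inside every round so each round is a
self-contained SRD analysis.

## Evaluation grid and ANOVA

The grid crosses datasets × {ALL, WO1, WO3} × {NO, RES, INTS}; each
variant rebuilds the similarity matrix against the projected reference,
pretreats (autoscaling by default), runs CV-SRD, and scores each measure
column by ROC-AUC on the raw scaled similarities (AUC is rank-based and
pretreatment column-monotone, so pretreating first would change nothing).
A variant emptied by filtering is skipped with a warning and recorded in
the result. With 10 datasets, 44 measures and fivefold CV the long table
has 90 variants × 44 × 6 = 23,760 rows.

ROC-AUC uses the Mann–Whitney formulation with midrank ties (delegated to
scikit-learn, verified against a brute-force pairwise count). Factor
effects on normalized SRD are fixed-effects OLS ANOVA with sequential
(type-I) sums of squares — on the balanced full-factorial grid all SS
types coincide — with per-level means and 95% t-based confidence
half-widths, significance judged at α = 0.05.

## Synthetic data generator

The generator emulates a docking-based screening set: a reference
fingerprint drawn Bernoulli(p_ref = 0.25) over the possible columns;
actives obtained by flipping each reference bit independently with
probability 0.05; decoys likewise at 0.4 (chemically plausible but
differently bound); 40 actives and 120 decoys by default. Sparsity mirrors
real SIFt data, where the large majority of enumerated bits are
consistently zero: of 64 residues, 75% are silent (whole block zeroed in
reference and all ligands) and a further 30% of the remaining columns are
impossible by definition (never the `Any` column — a contact is possible
whenever the residue interacts at all). The reference-anchored flip model
was chosen over independent per-class Bernoulli bits because screening
actives share the reference's binding mode; a single flip rate per class
encodes graded overlap.

What the generator does *not* model: residue chemistry (which residues can
be aromatic or charged), correlations between interaction types within a
residue, docking-pose noise, and decoy-selection rules. Passing tests
therefore demonstrate the correctness and calibration of the pipeline and
the *direction* of filtering/selection effects under the assumed structure,
not the numeric effect sizes expected on any particular docked dataset.
With equal flip rates for the two classes the generator is exchangeable,
and every measure's AUC is ≈ 0.5 — the null calibration the tests check.

## Problem sizes and determinism

Default analysis sizes were chosen to keep a full run at desk scale: ten
synthetic datasets of 160 ligands, 10,000-draw Monte-Carlo nulls,
1,000-replicate AUC calibration. All stochastic components (generator,
fold assignment, permutation sampling) take explicit seeds;
`scripts/acceptance.py` derives independent substreams from a single CLI
seed via `numpy.random.SeedSequence`.

## Known limitations

- The catalog's α/β guarantee containment of the scaled value in [0, 1];
  for a few *p*-dependent measures the lower bound is not tight at odd
  *p*, so the scaled minimum may sit slightly above 0.
- Normalized SRD uses the tie-free maximum even when ties are present
  (conservative).
- ANOVA assumes the balanced grid; unbalanced tables (e.g. after skipped
  variants) make type-I SS order-dependent.
- The CV fold split is unstratified; with very few actives a fold can
  lose its active class, in which case fusion degenerates to row minima
  for the remaining rows.
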