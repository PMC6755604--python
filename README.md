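# siftsim

Binary similarity measures and rank-based method comparison for
protein–ligand **interaction fingerprints** (IFPs).

In structure-based virtual screening, an IFP encodes a docked 3D complex as
a bitstring: one bit per binding-site residue per interaction type (any
contact, backbone, sidechain, polar, hydrophobic, H-bond acceptor/donor,
aromatic, charged). Screening then ranks candidate molecules by the
similarity of their IFP to the IFP of a known active — almost always with
the Jaccard–Tanimoto coefficient. But dozens of binary similarity
coefficients exist, and the choice of coefficient, of interaction bits, and
of fingerprint filtering all change the ranking. `siftsim` implements the
full comparison stack needed to study these choices:

- **Fingerprint handling** — SIFt-style containers with plain-CSV I/O, the
  bit-selection schemes `ALL` / `WO1` (drop "Any contact") / `WO3` (drop
  "Any", backbone, sidechain), and the filtering rules `RES` (drop residues
  that never interact across the dataset) and `INTS` (drop every individual
  interaction column never established).
- **44 similarity measures** — a data-driven catalog from the binary
  similarity literature (Jaccard–Tanimoto, simple matching,
  Baroni–Urbani–Buser, Rogers–Tanimoto, Sokal–Sneath, Consonni–Todeschini,
  Yule, Pearson φ, …), each computed from the pairwise confusion table
  (*a* common on-bits, *b*/*c* exclusive on-bits, *d* common off-bits,
  *p = a+b+c+d*) and rescaled to [0, 1] via *s′ = (s + α)/β*, with
  symmetricity (S/I/A/Q) and metricity (M/N) class labels.
- **Pretreatment** — column-wise autoscaling, range scaling, or rank
  transformation of the similarity matrix.
- **Sum of ranking differences (SRD)** — comparison of every measure's
  ligand ranking to a consensus reference built by row-wise data fusion
  (row-maximum for actives, row-minimum for inactives):

  SRD(measure) = Σᵢ |rank_measure(i) − rank_reference(i)|,

  normalized to percent of the theoretical maximum (n²/2 for even n,
  (n²−1)/2 for odd n). The smaller the SRD, the closer the measure is to
  the ideal consensus. Validated by a randomization test (exact n! null up
  to n = 8, seeded Monte-Carlo beyond) and fivefold cross-validation plus
  an all-rows round.
- **Evaluation grid** — the full factorial dataset × bit-selection ×
  filtering protocol with ROC-AUC per measure and fixed-effects ANOVA
  factor summaries of the SRD values.
- **Synthetic data** — a seeded generator of realistic IFP datasets
  (reference-anchored actives, corrupted decoys, silent residues,
  impossible bits) so the whole stack runs without docking software.

## Worked example

```python
import pandas as pd
from siftsim import (SynthConfig, generate_dataset, similarity_matrix,
                     run_srd, roc_auc, max_srd)

cfg = SynthConfig(n_residues=16, n_actives=10, n_decoys=20, seed=5)
dataset, reference = generate_dataset(cfg)          # 30 ligands x 144 bits
frame = similarity_matrix(dataset, reference, ["SM", "JT", "BUB", "RR", "Phi"])
print(frame.head(3).round(4).to_string(index=False))

results = run_srd(frame, pretreatment="AUTO", k=5, perm_reps=10_000, seed=3)
for r in sorted(results, key=lambda r: r.srd_norm):
    print(f"{r.measure:>4} srd_norm={r.srd_norm:5.2f}%  p={r.p_value:.2e}")
perm = results[0].perm_summary
print(f"random-ranking SRD: mean {perm.mean:.1f}, "
      f"5-95% [{perm.p5:.0f}, {perm.p95:.0f}] of max {max_srd(len(frame))}")
print("JT AUC:", round(roc_auc(frame["JT"], frame["active"]), 3))
```

prints

```
ligand_id  active     SM     JT    BUB     RR    Phi
    ACT01       1 0.9792 0.7000 0.9262 0.0486 0.9137
    ACT02       1 1.0000 1.0000 1.0000 1.0000 1.0000
    ACT03       1 0.9861 0.7778 0.9497 0.0486 0.9377
 BUB srd_norm= 5.78%  p=0.00e+00
  SM srd_norm= 8.22%  p=0.00e+00
 Phi srd_norm= 8.67%  p=0.00e+00
  JT srd_norm= 9.33%  p=0.00e+00
  RR srd_norm=17.78%  p=0.00e+00
random-ranking SRD: mean 299.4, 5-95% [240, 356] of max 450
JT AUC: 1.0
```

Reading the output: each row of the similarity matrix is one ligand scored
against the reference fingerprint by five measures (`ACT02` happens to be
bit-identical to the reference, so every measure returns 1 by convention).
After autoscaling, the consensus reference is fused row-wise and each
measure's ligand ranking is compared to it: Baroni–Urbani–Buser agrees
best with the consensus (SRD 5.8% of the theoretical maximum), Russel–Rao
worst (17.8%). All five sit far below the random-ranking distribution
(mean 299 ≈ 66% of 450), so none of them ranks like noise; and the
Jaccard–Tanimoto column separates the 10 actives from the 20 decoys
perfectly (AUC = 1.0), as built into this synthetic contrast.

## Command line

```bash
siftsim synth --config synth.yaml --output fp.csv --reference-out ref.csv
siftsim sim   --input fp.csv --reference ref.csv --measures all --output sim.csv
siftsim srd   --input sim.csv --pretreat auto --folds 5 --seed 3 --output srd.csv
siftsim grid  --config grid.yaml --output results/
```

`grid` writes the long-format SRD table (`grid_srd.csv`), per-variant AUCs
(`grid_auc.csv`) and per-factor ANOVA level means (`anova_<factor>.csv`).

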