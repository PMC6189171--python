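# itamorigins

Computational analyses around receptor-independent phagocytosis: how a
degenerate immunoreceptor tyrosine-based activation motif (ITAM) hidden in a
membrane–cytoskeleton linker protein can be found by proteome screening, how
old that signaling platform is on a molecular clock, and how the physical
side of the story — lipid enrichment at particle contact sites and target
stiffness — is quantified.

Phagocytes engulf solid particles they have never co-evolved receptors for.
A candidate transducer for this receptor-independent uptake is an atypical
ITAM — two Tyr-X-X-(Leu/Ile) half-sites separated by a short spacer — carried
in the FERM domain of an ERM-family protein (moesin), recruited to the
membrane by locally enriched PIP2 and relaying to Syk. This package
implements the four quantitative procedures that support that account, each
testable end-to-end on synthetic data with known ground truth:

1. **Motif screen** (`motif_screen`) — scan a proteome for the probe
   `Y-X-X-[LI]-X(6,12)-Y-X-X-[LI]`, rank motif-bearing proteins by
   within-dataset abundance percentile averaged across RNA-seq tables, flag
   the top 25, and apply ordered exclusion predicates (secreted,
   nuclear-only, known ITAM receptor, ...) to reach a shortlist.
2. **Clock phylogenetics** (`phylo_clock`) — corrected amino-acid distances
   (p, Poisson −ln(1−p), or gamma α((1−p)^(−1/α)−1)), Saitou–Nei neighbor
   joining, column-bootstrap supports, outgroup rooting, and per-clade
   strict-clock dating: each clade's rate is the mean of patristic(i,j)/2t
   over calibrated pairs, and the root age is mean root-to-tip distance over
   that rate, reported as a two-sided interval across paralogous clades.
3. **Imaging ratios** (`imaging_quant`) — line profiles, kymographs,
   normalized fluorescence NF(t) = mean(contact)/mean(reference), pattern
   fold change, and generalized polarization GP = (I_o−I_d)/(I_o+I_d).
4. **Mechanics & statistics** (`mechanics_stats`) — the Hertz contact model
   F = (4/3)·E/(1−ν²)·√R·δ^{3/2} (ν = 0.33 for polystyrene) with
   least-squares recovery of E and the contact point, the exact-permutation
   Spearman rank test (full enumeration of n! permutations for n ≤ 9), bead
   volume/surface totals, and phagocytosis-efficiency summaries.

`synthetic_data` generates every input class with planted parameters, and
`pipeline`/`cli` orchestrate stages with per-stage seed streams and hashed
run manifests.

## Worked example

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_motif_screen.py
python analysis/03_phylo_clock.py
python analysis/04_imaging_ratios.py
python analysis/05_mechanics.py
```

Output (seed 1):

```
motif-bearing proteins: 50 (sensitivity on 50 planted motifs: 1.00)
top-flagged candidates: 25
shortlist after exclusions: 7 proteins
per-clade rates (subs/site/Mya): {'A': 0.00049, 'B': 0.00051}
root-age interval: 757-778 Mya (midpoint 767; planted 800, error 4.1%)
NF plateau after onset frame 10: 3.003 (planted enrichment 3.0)
pattern fold change on noisy vesicle: 3.00 (planted 3.0)
Hertz fits over 20 curves: mean E = 3.001 GPa (planted 3.0 GPa)
stiffness vs phagocytosis: Spearman r = 1, one-sided exact p = 0.0083 (n = 5)
```

Reading the numbers: all 50 planted motifs are recovered and the 30-ranked →
25-top → 7-shortlist funnel behaves as configured; the molecular clock dates
the planted 800 Mya duplication to within a few percent from 2000 aligned
sites; the imaging operators return the planted 3-fold contact enrichment;
the Hertz fit recovers the planted 3 GPa modulus from 1%-noise curves; and
five perfectly concordant stiffness/efficiency groups give the exact
one-sided permutation p of 1/120 ≈ 0.0083.

The same operations are available as a CLI (`itamorigins scan|rank|tree|
clock|rates|quantify|hertz|spearman|simulate|run`); see `--help`.

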