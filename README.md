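# linkerrf

Per-residue prediction of protein **inter-domain linkers** from primary
sequence alone, using amino-acid physiochemical profiles and a Random
Forest classifier — no PSSMs, no predicted secondary structure, no class
re-balancing.

Multi-domain proteins consist of independently folding domains (~25–500
residues) joined by short flexible linkers (~10–100 residues). Locating the
linkers is a standard first step toward domain decomposition, structure
prediction, and downsizing proteins into tractable functional units. The
classes are heavily imbalanced — in curated benchmarks roughly 95% of
residues sit inside domains — so recall and precision over linker residues,
not accuracy, are the metrics that matter.

## Method

For each residue the package builds a feature vector from seven property
groups:

- **Linker propensity index** `S_i = −ln(f_i^linker / f_i^domain)`, where
  `f_i^linker` and `f_i^domain` are the percentage compositions of amino
  acid *i* within linker and domain residues. Negative values mark
  linker-preferring residues (P, S, T, E, …). A published index table is
  packaged; the index can also be re-estimated from any labelled corpus
  (the default inside cross-validation, per training fold).
- **Hydrophobicity** — the signed five-bit SARAH1 code by default
  (exactly two non-zero entries per residue, ranked by the Rose scale);
  the scalar kcal/mol (pH 7) and Rose scales are selectable.
- **Side-chain charge, polarity, aromaticity, size, and electronic
  property** — categorical classifications, one-hot encoded, so that after
  averaging each block holds within-window category fractions.

The default configuration yields D = 1 + 5 + (3+2+3+3+5) = 22 features.
Vectors are averaged over an odd window `w` (default 41) sliding along the
sequence and clipped at both termini:

    X_j = mean of x_i over i in [max(1, j−(w−1)/2), min(L, j+(w−1)/2)]

A Random Forest (default `N_trees = 200`, `m = ⌊log2 M⌋ + 1` features per
node, Gini splits, trees grown to purity, bootstrap samples of size N)
classifies each residue by majority vote; the vote fraction is exposed so
other thresholds and a minimum-linker-run filter can be applied. Evaluation
is sequence-level k-fold cross-validation reporting accuracy, recall,
precision, and F1 (= 2PR/(P+R)) over residues, plus window-size and
tree-count sweeps and an information-gain-ordered feature-group ablation.

A synthetic corpus generator emulates the compositional structure the
method exploits: alternating domain–linker architectures with
Gamma-distributed segment lengths (domain mean 147.1 in [25, 500], linker
mean 12.7 in [10, 100]) and residues drawn i.i.d. from packaged linker and
domain compositions, with an optional divergence multiplier that amplifies
the compositional contrast between the partitions.

## Worked example

```sh
$ linkerrf simulate --n 20 --seed 7 --divergence 4 -o demo
$ linkerrf linker-index --pseudocount 0.05 demo/corpus.fasta demo/annotations.tsv
aa      linker_pct      domain_pct      linker_index
P       14.02   2.46    -1.725
S       11.03   4.66    -0.856
E       10.34   4.92    -0.739
T       7.82    4.21    -0.614
...
$ linkerrf cv --k 5 --trees 50 --window 21 --seed 7 demo/corpus.fasta demo/annotations.tsv
aggregation     accuracy        recall  precision       f1
fold_mean       0.9561  0.3152  0.7199  0.4200
pooled          0.9569  0.3264  0.6995  0.4451
```

The first command writes a 20-sequence synthetic corpus whose linker/domain
compositional contrast is amplified fourfold. The `linker-index` rows show
the estimated percentage compositions and the resulting propensity indices:
proline is strongly over-represented in the generated linkers
(14.0% vs 2.5%), hence its large negative index. The `cv` report gives
residue-level metrics under sequence-level 5-fold cross-validation: high
accuracy (0.96) merely reflects the ~95:5 class imbalance, while recall
0.32 / precision 0.70 describe actual linker retrieval on this small,
noisy corpus. Other subcommands: `stats`, `featurize`, `train`, `predict`,
`sweep-window`, `sweep-trees`, `ablate` (see `linkerrf --help`).

The same pipeline accepts real data as standard FASTA plus a tab-separated
annotation sidecar (`seq_id  start  end  label`, 1-based inclusive
intervals, linker segments only — everything else is domain).

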