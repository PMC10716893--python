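# Methods

`moltreegen` couples a learned distribution over molecular graphs with a
reward-guided tree search. This note records the model, the search
procedure, the parameter choices that matter, and the limits of what the
bundled synthetic corpus can demonstrate.

## Molecular graphs and featurization

A molecule with up to `max_atoms` heavy atoms (default 38, the maximum
heavy-atom count of common drug-like screening sets) is encoded as a pair
of fixed-size feature maps:

* a node matrix (`max_atoms x 21`): one-hot element over
  {C, N, O, F, P, S, Cl, Br, I}, one-hot heavy-atom degree (0–5), formal
  charge, an aromatic flag, and one-hot hybridization (sp/sp2/sp3/other);
* an edge tensor (`max_atoms x max_atoms x 4`): one-hot bond type
  (single/double/triple/aromatic), symmetric, zero diagonal, zero padding.

This is the de-facto standard atom/bond featurization for molecular graph
auto-encoders; every block is configurable through `FeatureConfig`.
Hydrogens are implicit; stereochemistry and isotopes are stripped, and atom
order follows the toolkit's canonical ranking so featurization is
deterministic.

During generation, partial molecules are `BuildState` objects. Every bond
addition is gated by `valence_ok`, which compares the atom's bond-order sum
(aromatic bonds count 1.5) against a fixed per-element maximum-valence
table at formal charge 0. Because no inadmissible action is ever applied,
any reachable state assembles into a molecule that sanitizes — structural
validity of the output is 1.0 by construction, not by filtering.

## The variational graph auto-encoder

The encoder applies three edge-conditioned graph-convolution layers
(hidden width 128; one weight matrix per bond type plus a self term, with
row-normalized per-bond-type adjacency), mean-pools node embeddings to a
graph vector, and maps it to the mean and log-variance of a 64-dimensional
diagonal Gaussian posterior. The decoder is a two-layer perceptron from
the latent vector to (i) a node feature map and (ii) an edge logit map
symmetrized as `(L + L^T)/2` and squashed through a logistic to edge
existence probabilities.

The loss is the negative evidence lower bound: elementwise binary
cross-entropy on the edge-existence map (all off-diagonal entries, so the
decoder learns that padding slots are unbonded) plus categorical
cross-entropy on the element one-hots of occupied slots, plus the
closed-form KL divergence `0.5 * sum(exp(logvar) + mu^2 - 1 - logvar)`
against the standard-normal prior. Training uses adaptive-moment gradient
descent with learning rate 0.001 and batch size 64, the reference
protocol; the latent dimension default is 64. Generation samples latents
from N(0, I), which the KL regularizer makes the model's own prior.

The network is implemented directly over NumPy with a small reverse-mode
automatic-differentiation core (`_autodiff.py`); a test checks its
gradients against central finite differences. One decoder variant is
supported: a single edge-existence map (the default); per-bond-type edge
maps were considered and rejected because candidate extraction only
consumes existence probabilities.

## Tree search

Each decoded feature map seeds one search. A search iteration is
selection → expansion → simulation → update:

* **Selection** minimizes `s/n − c · sqrt(ln N / n)` over children
  (`s` cumulative backed-up reward, `n` node visits, `N` parent visits,
  `c = 1.5`). Rewards are minimized ("1 − QED" style), so the exploration
  term is subtracted; unvisited children evaluate to −∞ and are explored
  first, with ties broken by lowest child index for determinism.
* **Expansion** enumerates candidate edges: feature-map entries with
  probability ≥ 0.10 (inclusive) that connect a placed atom to an empty
  slot or close a ring between placed atoms. One child is created per
  admissible (edge, bond type) action; the new atom's element is drawn
  from the softmax of the node map's element scores at the target slot,
  restricted to elements whose valence supports the bond. Ring closures
  larger than 7 atoms are created but filter-flagged.
* **Simulation** completes the partial molecule with uniformly random
  admissible actions until no action remains or the rollout atom cap
  (default `max_atoms`) is reached. The rollout policy is uniform because
  the reference procedure specifies none.
* **Update** adds the effective reward to every node on the path. A
  molecule caught by a realism filter has its reward multiplied by 10,
  which under minimization makes the branch unattractive; with the
  aromatic force-cycle mode on, a molecule containing an aromatic ring has
  its reward reduced by 0.5 (floored at 0). The raw "+0.5" additive
  variant is available behind `aromatic_bonus_additive` for comparison,
  but the default implements the stated intent — aromatic nodes become
  *more* likely to be selected under smallest-value selection.

After the configured number of iterations (8,000 by default; desk-scale
runs use far fewer), the lowest-reward unflagged molecule observed at each
heavy-atom count is emitted for every count ≥ `minimum_depth` (21 for
distribution-learning benchmarking, 17 for QED, 6 for penalized logP).
`minimum_depth` is read as a floor on molecule size: the harder
multi-property objective uses the smaller floor, so the floor
interpretation is the one consistent with the reference settings.
Node depth counts tree levels; emission depth is the molecule's heavy-atom
count. The two coincide for atom-adding actions and differ only for ring
closures.

### Aromatic seeding

With the force-cycle mode on (default), the search first looks for a 5- or
6-cycle among above-threshold edges; the cycle with the largest summed
probability becomes the root state — an all-carbon aromatic ring for
6-cycles, a furan-like ring (one oxygen at the slot scoring highest for
oxygen) for 5-cycles. On dense maps the cycle search is restricted to the
60 strongest edges and at most 20,000 enumerated cycles so it stays O(ms);
on trained, sparse maps these caps are never reached.

### Realism filters

* **Oversized rings**: any ring of more than 7 atoms, detected at closure
  time from the bond-path length.
* **Steric strain**: the package's strain score is the mean absolute
  deviation of all bond angles from the central atom's ideal
  hybridization angle (sp 180°, sp2 120°, sp3 109.47°), measured on an
  ETKDG-embedded, MMFF94-relaxed conformer and expressed in units of 20°.
  An ideal geometry scores 0; cubane (19.5° deviations at every carbon)
  scores ≈ 0.88. The default cutoff is 0.82. Molecules outside MMFF94
  parameter coverage, or failing to embed, return no score and are not
  flagged (a logged warning). Scores are cached by canonical structure;
  embedding uses a fixed seed so the filter is deterministic.

## Rewards

* `qed`: reward = 1 − QED.
* `plogp`: reward = 1 − sigmoid(penalized logP), with
  penalized logP = logP − SA − max(0, largest ring − 6). This is the
  un-normalized convention of the junction-tree auto-encoder lineage; the
  z-score-normalized variant (drug-like-corpus statistics) is available
  via `normalize="zinc"`. The SA score is the Ertl–Schuffenhauer
  synthetic-accessibility score [1, 10] from the toolkit's contributed
  implementation with its pinned fragment table.

Both rewards live in [0, 1] with lower = better, matching the minimizing
selection rule.

## Evaluation

Validity, uniqueness and novelty follow the standard distribution-learning
definitions on canonical structure strings (stereo stripped). The KL
score is the mean of `exp(−KL)` over a descriptor panel (molecular
weight, logP, Bertz complexity, TPSA, H-bond donors/acceptors, rotatable
bonds, aliphatic/aromatic ring counts, plus the within-set
nearest-neighbor Tanimoti similarity distribution on 2048-bit
diameter-4 circular fingerprints). Continuous descriptors use
kernel-density estimates on a shared 1000-point grid; integer descriptors
use shared unit bins; both sides are smoothed so degenerate samples never
divide by zero. The Fréchet ChemNet Distance requires an external
pretrained scorer and is reported only when one is importable.

Statistical comparison uses the two-sided Mann–Whitney U test with
Bonferroni correction; small tie-free samples take the exact null
(verified against exhaustive rank-permutation in the tests), larger or
tied samples the normal approximation with tie correction. The reference
protocol subsamples 500 molecules per group, seeded.

The drug-likeness filter keeps molecules passing Lipinski's rule of five,
SA ≤ 5, strain below 0.82, logP ≤ 5, and largest ring ≤ 6. Chemical-space
maps embed 2048-bit diameter-4 circular fingerprints to 2-D with UMAP
(Jaccard metric, fixed random state).

## Synthetic corpus and what desk-scale runs show

`make_fixture_set` enumerates ~640 small drug-like molecules by decorating
scaffold templates (benzene, pyridine, furan, cyclohexane, alkanes) with
common substituents, then draws a seeded permutation. It emulates the
size range and functional-group mix of a drug-like screening subset while
staying fully deterministic and dependency-free. It does **not** emulate
the scale (10^5–10^6 molecules) or structural diversity of real corpora,
so a model trained on it for a handful of epochs learns only a coarse
bond-density prior: latents drawn from N(0, I) decode to much denser edge
maps than a converged model would produce, and desk-scale searches
therefore explore a far wilder region of chemistry than the full protocol
would. Properties that are *guaranteed by construction* — structural
validity, novelty with respect to the training set, visit-count
conservation, the direction of reward shaping — transfer from desk scale
to full scale; distribution-matching quality (the KL score) does not, and
is exercised only mechanically.

Desk-scale problem sizes used by the test suite and the acceptance
script: 300–500 fixture molecules, 3–5 training epochs, 12–50 feature
maps, 100–300 search iterations per map. These are the package's chosen
desk-scale conditions; the full reference protocol (full corpora, 8,000
iterations, 3,000 generated molecules) is supported through the same API
and CLI.

## Numerical and degenerate-input choices

* Unvisited-node selection value is −∞ (forces one visit before the
  confidence bound is defined); tie-breaks take the lowest child index.
* A feature map whose thresholded edges cannot start a molecule backs up
  the worst reward (1.0) and emits nothing; the run logs and continues.
* Candidate-edge thresholding is inclusive (≥ 0.10).
* The search tree stores child actions, not child states; states are
  materialized lazily from the parent, bounding memory on dense maps.
* KL smoothing constant 1e-10; posterior log-variances are used as-is
  (no clamping) since the KL term keeps them finite in practice.
* All randomness flows from explicit integer seeds through independent
  spawned generators (one per feature map), so any per-map search is
  reproducible in isolation.

## Known limitations

* The encoder/decoder architecture is a minimal standard realization;
  no attempt was made to match an undocumented reference architecture
  beyond its stated latent size and training hyperparameters.
* The strain score is the package's own normalization of angle
  deviations; other strain definitions would rank borderline molecules
  differently. The cutoff semantics (flag strictly above 0.82) follow the
  stated default.
* Aromatic seeding places at most one heteroatom (oxygen) in 5-rings;
  nitrogen-containing aromatic seeds arise only through subsequent growth.
* Penalized-logP normalization constants are frozen literature values,
  not recomputed from a corpus at run time.
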