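# moltreegen

Molecular generation with a variational graph auto-encoder and Monte Carlo
tree search, for medicinal chemists and cheminformatics researchers who
want to explore drug-like chemical space beyond a training corpus while
keeping every generated structure chemically valid.

## The method

A variational graph auto-encoder (VGAE) is trained on drug-like molecules
represented as fixed-size graph feature maps (a node feature matrix and a
symmetric bond tensor over `max_atoms` slots). The loss is the negative
evidence lower bound

```
L = BCE(edge map) + CE(element map) + KL( N(μ, diag e^{logvar}) ‖ N(0, I) )
```

with a 64-dimensional latent space, learning rate 0.001 and batch size 64.
To generate, a latent z ~ N(0, I) is decoded into an edge-existence
probability map and a node feature map, and a Monte Carlo tree search
grows a molecule atom-by-atom on those maps. Selection picks the child
minimizing the UCB1-style value

```
s/n − c · sqrt(ln N / n),        c = 1.5
```

where `s` is the node's cumulative backed-up reward, `n` its visit count
and `N` the parent's. Candidate moves are feature-map edges with
probability ≥ 0.10; each addition is valence-checked, so every emitted
molecule sanitizes. Rewards are minimized: `1 − QED` for drug-likeness
optimization, or `1 − σ(penalized logP)` with
`penalized logP = logP − SA − max(0, largest ring − 6)` for
multi-property optimization. Molecules caught by realism filters (rings
of more than 7 atoms, steric strain above 0.82) have their reward
multiplied by 10; an aromatic force-cycle mode seeds searches with a 5- or
6-membered aromatic ring and favors aromatic-containing molecules. After
8,000 iterations per feature map (configurable), the best molecule at
each heavy-atom count ≥ `minimum_depth` is emitted.

The evaluation stack computes the standard distribution-learning metrics
(validity, uniqueness, novelty, descriptor-histogram KL score), the
Mann–Whitney U test with Bonferroni correction, a drug-likeness filter
(Lipinski, SA ≤ 5, strain, logP ≤ 5, ring ≤ 6), and 2-D chemical-space
maps from 2048-bit ECFP4 fingerprints via UMAP.

See `docs/methods.md` for the full model and parameter documentation.

## Worked example

```python
from moltreegen import MoleculeGenerator, make_fixture_set, distribution_benchmark

corpus = make_fixture_set(300, seed=1)           # small drug-like fixture set
gen = MoleculeGenerator(objective="qed", epochs=3, iterations=150,
                        minimum_depth=6, seed=2)
gen.fit(corpus)
table = gen.sample(n_feature_maps=12, seed=2)
print(table.head())
report = distribution_benchmark(list(table["smiles"]), corpus)
print(f"validity {report.validity:.3f}  uniqueness {report.uniqueness:.3f}  "
      f"novelty {report.novelty:.3f}")
```

Output (the `depth` column is the molecule's heavy-atom count, `reward`
is `1 − QED`, lower is better; your molecules will match exactly under the
same seeds):

```
   feature_map  depth                                   smiles    reward  property
0            0     11                   Fc1c2c(Cl)c(I)c(I)c1O2  0.625869  0.374131
1            0     15     N#P=NC(Cl)(Br)c1c(Cl)c2c(Cl)c(F)c1-2  0.693081  0.306919
2            0     17  O=C(Br)P12=Nc3c(Cl)c4c(c(c3Br)P1#C4)N2F  0.652285  0.347715
3            0     18    Fc1c(Cl)c(Cl)c(I)c(C#S(Br)=C=P#CI)c1I  0.912199  0.087801
4            0     19      FN=Nc1c(Br)c(F)c(N=NCl)c2c1N(I)ON2I  0.753262  0.246738

validity 1.000  uniqueness 1.000  novelty 1.000
```

Every emitted molecule parses and sanitizes — validity 1.0 is a
consequence of valence-protected construction, not post-filtering. At
this desk scale (a few hundred training molecules, a few epochs) the
model's prior samples decode to much denser feature maps than a converged
model's, so the example molecules are exotic; training on a real corpus
with the default 8,000 iterations produces drug-like output.

The same workflow is available from the shell:

```bash
moltreegen fixtures --n 300 --seed 1 --out train.smi
moltreegen train --input train.smi --epochs 3 --checkpoint model.npz
moltreegen generate --checkpoint model.npz --objective qed \
    --iterations 150 --minimum-depth 6 --n-maps 12 --seed 2 --out mols.smi
moltreegen evaluate --generated mols.smi --reference train.smi --out report.json
moltreegen map --in mols.smi --out coords.csv
moltreegen run --config run.yaml        # full pipeline with a manifest
```

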