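# scaffoldscope

Scaffold-architecture analysis of compound libraries.

Drug-discovery collections differ less in their atoms than in their
*scaffolds* — the ring-containing cores molecules are built on.  A library
of 30,000 compounds may concentrate on a few hundred frameworks or spread
over twenty thousand, and that difference drives what a screen can find.
`scaffoldscope` is a toolkit for chemoinformaticians who want to quantify
and compare that structure across libraries:

* **Decomposition** of each molecule into Murcko frameworks, graph
  frameworks, rings, ring assemblies, bridge assemblies, linkers and side
  chains.
* **Scaffold chains**: hierarchical pruning from the Murcko framework down
  to a single ring (Level n−1 … Level 0), one peripheral ring per level,
  under a fixed, documented priority cascade.
* **Diversity analysis**: scaffold frequency censuses and cumulative
  scaffold frequency (CSF) curves — the fraction of a library covered by
  its top-N scaffolds.
* **Similarity analysis**: cross-library overlap tables on
  extended-connectivity (diameter-6 Morgan) fingerprints at descending
  Tanimoto cutoffs.
* **Clustering + treemaps**: maxmin clustering of scaffolds (target average
  cluster size 50) and a squarified treemap whose region areas are exactly
  proportional to scaffold frequency.
* **Synthetic libraries with planted ground truth**: a generator that
  assembles molecules from curated ring/linker/side-chain pools and records
  every molecule's true framework and scaffold chain in a manifest, so the
  whole pipeline is testable without access to proprietary databases.

In the notation of the field: the Murcko framework of a molecule is the
union of its ring systems and linkers; the scaffold chain assigns each
ring-bearing molecule scaffolds at Levels 0…n−1 with Level k containing
k+1 rings (circuit rank); CSF(N) = 100 · Σᵢ₌₁..N fᵢ / |library| for counts
fᵢ sorted descending; and Tanimoto similarity of two fingerprint feature
sets is |A∩B|/|A∪B|.

## Worked example

```python
from scaffoldscope import (GeneratorConfig, generate_library, build_chain,
                           count_frequencies, coverage_at, cluster_scaffolds)

lib, manifest = generate_library(GeneratorConfig(
    n_molecules=2000, n_unique_scaffolds=50, frequency_law=("zipf", 1.2), seed=1))
chains = [build_chain(rec.mol, rec.id) for rec in lib.records]

murcko = count_frequencies(
    [(c.molecule_id, c.levels[-1]) for c in chains if c], len(lib), "murcko")
level1 = count_frequencies(
    [(c.molecule_id, c.levels[1]) for c in chains if c and c.n_levels > 1],
    len(lib), "level1")

print(f"unique Murcko:        {murcko.n_unique}")
print(f"CSF murcko @ top 10:  {coverage_at(murcko, 10):.2f}%")
print(f"CSF level1 @ top 10:  {coverage_at(level1, 10):.2f}%")
model = cluster_scaffolds(sorted(level1.counts), target_avg_size=10, seed=1)
print(f"level-1 clusters:     {model.n_clusters}")
```

prints

```
unique Murcko:        50
CSF murcko @ top 10:  73.25%
CSF level1 @ top 10:  59.50%
level-1 clusters:     4
```

Read: the generator planted 50 frameworks under a Zipf(1.2) law and the
pipeline recovered all 50; the ten most frequent frameworks already cover
73% of the library (a *redundant* collection — a diverse one would show a
few percent here); the 33 distinct two-ring Level-1 scaffolds fall into 4
fingerprint clusters at a target average cluster size of 10.  The planted
manifest (`manifest_census`, `manifest_murcko_census`) reproduces these
tables exactly, which is the core correctness check of the package.

## Command line

```bash
scaffoldscope synth --n 5000 --scaffolds 50 --law zipf:1.2 --seed 1 --out data/
scaffoldscope prepare --in data/synthetic.smi --max-mw 600 --out prep/
scaffoldscope run --config run.yaml        # full multi-library report bundle
scaffoldscope decompose / tree / csf / overlap / treemap ...
```

`run` executes prepare → decompose → scaffold-tree → census → CSF →
pairwise overlap → cluster → treemap for every configured library and
writes censuses, CSF curves (CSV + SVG), overlap tables, cluster tables and
treemaps (JSON + SVG), plus a machine-readable run log.  Identical config
and seed reproduce every CSV/JSON byte for byte.

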