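# Methods

## The problem

Compound collections — screening decks, vendor catalogs, natural-product
databases — differ strongly in how their molecules are distributed over
*scaffolds*: the ring-containing cores that determine a molecule's shape.
`scaffoldscope` quantifies and compares that distribution.  It decomposes
each molecule into a family of scaffold representations, counts how often
each scaffold occurs, summarizes the counts as cumulative scaffold frequency
(CSF) curves, measures cross-library scaffold overlap with fingerprint
similarity, and renders scaffold space as clustered, frequency-weighted
treemaps.

## Scaffold representations

For a sanitized molecule with at least one ring the package computes:

* **Murcko framework** — the union of all ring systems and the acyclic
  linkers connecting them.  Operationally: terminal atoms are pruned
  iteratively until only ring atoms and atoms on ring–ring paths remain.
* **Graph framework** — the Murcko framework with every atom relabeled
  carbon and every bond set to single; a pure topology signature.
* **Rings** — one fragment per ring of a smallest set of smallest rings
  (SSSR).  The ring count always equals the circuit rank
  (bonds − atoms + components), which is SSSR-invariant.
* **Ring assemblies** — connected components that remain after deleting
  every bond not in a ring.  Fused, spiro and bridged systems stay whole;
  biphenyl splits in two.
* **Bridge assemblies** — the subset of ring assemblies in which some pair
  of SSSR rings shares two or more bonds (norbornane yes, naphthalene no,
  spiro systems no).
* **Linkers** — acyclic atoms lying on a direct path between two ring
  systems.  A direct single bond between two rings is a *zero-atom* linker:
  the connection survives in the framework but emits no fragment.
* **Side chains** — the remaining acyclic substituents, emitted with their
  attachment atom marked by a dummy (`*C` for a methyl on a ring).

**Exocyclic multi-bond retention.**  A terminal atom attached to a ring or
linker atom by a double (or higher-order) bond — a carbonyl oxygen, an
exocyclic =NH — is kept with the framework/assembly rather than treated as
a side chain; this retains the functionalized form of ring systems
(a lactone stays a lactone).  Non-terminal multiply-bonded branches (vinyl,
nitrile) are ordinary side chains.  This matches the behavior of RDKit's
Murcko scaffold routine, which the test suite uses as an independent
cross-check.

**Identity conventions.**  Molecules are identified by stereo-bearing
canonical SMILES (cis/trans isomers are distinct molecules); scaffolds and
fragments by stereo-stripped canonical SMILES, so scaffold counting never
fragments on stereo annotations.  Side chains are counted per occurrence,
not per molecule.

## Scaffold chains (hierarchical ring removal)

Each molecule yields a single chain of scaffolds indexed Level 0 (one ring)
through Level n−1 (the whole Murcko framework), where n is the framework's
circuit rank.  Starting from the framework, one *peripheral* ring — an SSSR
ring whose deletion leaves the scaffold connected and reduces the circuit
rank by exactly one — is removed per step, followed by pruning of the
acyclic stubs (e.g. the dangling linker) it leaves behind.

The removal priority, applied to the peripheral rings at each step, is a
fixed deterministic cascade chosen to discard peripheral decoration first
and retain the most functionalized core:

1. remove a 3-membered heteroring first;
2. remove the ring whose deletion discards the fewest acyclic bonds;
3. remove the ring with the fewest ring heteroatoms (so quinoline keeps
   pyridine, indole keeps pyrrole);
4. remove the larger ring;
5. break remaining ties by the lexicographically smallest canonical SMILES
   of the resulting parent scaffold.

Published rule cascades for hierarchical scaffold classification differ in
detail between implementations; absolute Level-k counts are mildly
cascade-sensitive, which is why the test suite checks rule-invariant
structure (level arithmetic, nesting, census monotonicity) rather than any
particular external count.

Two numerical notes.  First, cutting a ring out of a fused aromatic system
legitimately changes the aromaticity of what remains (removing the benzo
ring of chromane leaves 3,4-dihydro-2H-pyran with an explicit double bond
at the former fusion bond), so "each level is a subgraph of the next" holds
in the element-labeled topology sense, which is what the tests check.
Second, fragments that are not independently aromatic (either ring of
azulene) are extracted from the canonical kekulized parent instead; and
aromatic nitrogens left without a substituent are repaired with one
explicit hydrogen before re-sanitization.  Scaffolds whose every candidate
removal fails sanitization terminate their chain early; none of the
curated generator chemistry triggers this.

## Diversity and similarity measures

The **frequency census** maps each distinct scaffold of a representation to
its occurrence count.  The **CSF curve** sorts counts descending (ties
broken by scaffold string for determinism) and reports the cumulative
percentage of the library covered by the top-N scaffolds.  The percentage
denominator is always the full prepared library, so molecules lacking a
representation cap the curve below 100% — this keeps "percent of molecules
with a Level-2 scaffold" and "top-N Level-2 coverage" on one scale.  The
denominator choice is configurable in the table type if a
representation-bearing denominator is preferred.

Scaffold similarity uses extended-connectivity (Morgan) fingerprints of
diameter 6 (radius 3) as sparse *binary* feature sets — the union of
radius-aware neighborhood hashes, not folded to a fixed width — and the
Tanimoto coefficient |A∩B|/|A∪B|.  Unfolded features keep the
"fingerprint-identical" row of an overlap table free of folding collisions;
a 1024/2048-bit folded variant would only be an optimization and is not
needed at these set sizes.  The **overlap table** reports, for an ordered
library pair (A, B) and each cutoff in {1.0, 0.9, …, 0.0}, how many unique
A-scaffolds have a best B-match at or above the cutoff; the 1.0 row uses
"identical fingerprint" semantics and the 0.0 row is |A| by definition.
Absolute overlap counts are fingerprint-implementation-sensitive; the
package asserts their monotone structure and brute-force consistency.

## Clustering and treemaps

Unique scaffolds (each once, regardless of frequency) are clustered by
maxmin selection: ⌈N/target⌉ centers with target average cluster size 50;
the first center drawn uniformly under the seed, each further center
maximizing the minimum Soergel distance (1 − Tanimoto) to the chosen
centers, ties broken by canonical-SMILES order; every scaffold then joins
its nearest center (ties toward the lower cluster number).  Seeded reruns
are bit-identical; changing the seed can shuffle assignments but never the
center count.  Frequencies enter only at display time.

The treemap is a nested *squarified rectangle* layout rather than a circle
pack: cluster regions are sized by summed member frequency and tiled by
per-scaffold regions sized by own frequency.  Rectangles were chosen
because they make the central invariant — region area exactly proportional
to frequency, regions tiling without overlap — testable to numerical
precision; the layout is emitted as a JSON region list and an SVG.

## Library preparation

Reading accepts SMILES (whitespace-separated SMILES + optional ID) and SDF
V2000.  Standardization is deliberately minimal and fully documented: keep
the largest covalently connected fragment, drop records with no carbon
atom, clear isotope labels, recanonicalize.  Tautomer canonicalization and
charge-state enumeration are out of scope.  The molecular-weight filter is
a strict `MW < 600 Da` cutoff (a record at exactly 600.0 is excluded).
MW-distribution matching draws a sample whose histogram over 25-Da bins in
[0, 600) matches a reference library's bin proportions via
largest-remainder integer quotas, with infeasible quotas redistributed to
adjacent bins; the achieved two-sample Kolmogorov–Smirnov distance is
reported.  The 25-Da default (24 bins) balances matching resolution against
per-bin sample depth at library sizes of 10³–10⁴.

## The synthetic-data generator

Real reference collections of this kind are proprietary, so the package
ships a generator whose libraries have *planted, fully known* scaffold
structure.  A library is built from **blueprints**: ring-bearing cores that
are either linear chains of monocyclic ring units joined by linkers, or
single fused/bridged/spiro systems from a curated pool (~45 ring systems
from benzene to adamantane, ~12 linkers including zero-atom, carbonyl and
amide, ~16 side chains).  Each molecule samples a blueprint under the
configured frequency law and is decorated with random single-bonded side
chains on ring atoms — decoration never touches the core, so the Murcko
framework and the entire scaffold chain of every molecule are known by
construction.

Defaults emulate desk-scale screening collections: 5000 molecules; ring
count per molecule distributed over 1–6 rings with mode at 2–3; 35% chance
that a 2–3-ring core is a fused/bridged system rather than a linked chain;
2% acyclic molecules (real collections show 1–3% ring-free entries); 0–3
side chains per molecule; all molecules under 600 Da.  A *redundant*
configuration (50 blueprints, Zipf s = 1.2) and a *diverse* one (2000
blueprints, uniform) reproduce the qualitative contrast between
scaffold-poor and scaffold-rich collections: fewer unique frameworks, a
steeper CSF curve and fewer fingerprint clusters for the redundant library.

The ground-truth manifest records each molecule's blueprint and each
blueprint's full scaffold chain, derived *independently of the analysis
code*: for linear unit chains by combinatorial simulation of the removal
cascade on the unit sequence (in a linear chain only terminal units are
peripheral, so the cascade reduces to end-unit bookkeeping over ring size,
ring heteroatom count and linker bond count), and for fused/bridged pool
units from hand-derived chains stored in the pool data.  Pipeline-vs-
manifest agreement is therefore an exact, zero-tolerance check, not an
approximate one.

What the generator does **not** emulate: synthesizability or medicinal
realism of the decorated molecules, branched core topologies, macrocycles,
stereochemistry, tautomerism, and charge states.  Passing the planted-
recovery tests shows the analysis machinery is exact on known structure;
it does not certify behavior on chemistry outside the pool vocabulary.

## Problem sizes and determinism

The shipped tests and the acceptance script use 5000-molecule libraries,
200-scaffold overlap sets and 30–200-scaffold clustering problems — sizes
at which every stage completes in seconds to a few minutes on one CPU while
still exercising the long-tail frequency structure the analysis targets.
Every stochastic step (subsampling, MW matching, generation, clustering)
is driven by an explicit integer seed through a dedicated RNG, and reruns
are bit-reproducible; report CSVs/JSONs contain no timestamps so identical
configs produce identical bytes.
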