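# nervenet

Structural analysis of neuronal wiring diagrams: adjacency-network
construction and validation, degree/multiplicity statistics with
distribution-tail fitting, giant-component analytics (empirical and
generating-function closed forms), small-world and centrality measures,
motif censuses against constrained rewiring nulls with min-P multiple-testing
correction, linear-dynamics spectral analysis with layouts and pseudospectra,
gap/chemical interaction statistics, and robustness-to-error ensembles.
A synthetic-connectome generator makes every stage testable without any
external dataset.

## Data model

The canonical input is a pair of CSV files:

* `neurons.csv` with header `name,category,gabaergic,side,class`
  (`category` in `S`/`I`/`M`, `gabaergic` in `0`/`1`, `side` in `L`/`R`/empty);
* `synapses.csv` with header `pre,post,type,contacts,polyadic`
  (`type` in `chem`/`gap`/`nmj`; gap-junction records must appear in both
  `(i,j)` and `(j,i)` directions).

`nervenet.wiring` loads this pair into a `WiringDiagram`, checks
self-consistency (`validate_consistency`), and builds weighted
`AdjacencyNetwork` views: a directed chemical matrix, a symmetric gap
matrix, or their binary/weighted combination.  Polyadic contacts can be
counted at full or reduced (`polyad_split`, default 1/2) strength.

## CLI

Every analysis is reachable from one entry point:

```sh
# generate a synthetic wiring diagram (CSV pair + parameter sidecar)
nervenet simulate --out-dir sim/ --n-neurons 280 --seed 1

nervenet validate      --neurons sim/neurons.csv --synapses sim/synapses.csv
nervenet stats         --neurons ... --synapses ... --network gap
nervenet fit           --neurons ... --synapses ... --quantity degree --family power_law
nervenet components    --neurons ... --synapses ... --network chem
nervenet gf-analytics  --neurons ... --synapses ... --network gap
nervenet smallworld    --neurons ... --synapses ... --network combined
nervenet motifs        --neurons ... --synapses ... --size 3 --samples 200
nervenet spectra       --neurons ... --synapses ... --network combined
nervenet layout        --neurons ... --synapses ...
nervenet simulate-response --neurons ... --synapses ... --stimulus N001L
nervenet interaction   --neurons ... --synapses ...
nervenet robustness    --neurons ... --synapses ... --p-gap 0.05 --p-chem 0.05 --n 20
nervenet report        --neurons ... --synapses ... --out report.json
```

All subcommands emit JSON (with a manifest recording inputs, seed, and
package version) and are reproducible from `(inputs, seed)`.

## Layout

```
src/nervenet/
  wiring.py        data model, CSV I/O, validation, adjacency networks
  synthetic.py     synthetic connectome generator + pinned 12-neuron fixture
  null_models.py   ER sampling, constrained degree/triangle/reciprocity rewiring
  components.py    connected components, ER giant (Lambert W), generating functions
  degree_stats.py  survival functions, discrete MLE tail fits, bootstrap GOF
  smallworld.py    geodesics, clustering, small-world-ness, closeness
  spectral.py      dynamics matrices, eigenmodes, layouts, pseudospectra
  motifs.py        subgraph censuses (brute force + ESU/identities), min-P
  interaction.py   gap/chemical likelihood ratios, degree correlations
  robustness.py    contact-relocation edit ensembles, spectral displacement
  cli.py           click entry point
```
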