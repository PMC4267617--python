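# ionscape

Analysis toolkit for the ion atmosphere around DNA/RNA duplexes, together
with synthetic ground-truth generators so every estimator can be validated by
parameter recovery.

## What it does

- **Core model** (`ionscape.core`): atoms/topology/trajectory types,
  multi-model PDB (CRYST1 box) and per-frame XYZ I/O, groove/backbone region
  classification (major, minor, O′ backbone oxygens, phosphate oxygens), and
  minimum-image geometry for orthorhombic boxes.
- **Helix axis** (`ionscape.helix`): per-frame global axis as the
  total-least-squares line through base-pair reference centers (midpoints of
  C1′ and the glycosidic-reference nitrogen per strand), plus cylindrical
  coordinates and a bend diagnostic.
- **Distributions** (`ionscape.distributions`): cylindrical concentration
  profiles (mol/L vs distance from the axis), site RDFs g(r), first-peak /
  first-minimum detection, coordination numbers, cumulative normalized ionic
  charge, and time-window convergence series.
- **Binding** (`ionscape.binding`): binary occupancy traces (default direct
  cutoffs Na⁺ 3.0 Å, K⁺ 3.5 Å, Mg²⁺ 5.0 Å; water-mediated 6.0 Å), occupancy
  percentages per nucleotide and region, residence times from the occupancy
  autocorrelation C(t) (lag grid 10 ps – 1 ns, step 10 ps, exponential fit),
  bound-distance statistics, and multi-atom binding-pocket detection.
- **Structure metrics** (`ionscape.structure`): glycosidic χ with anti/syn
  classification and sugar-pucker pseudorotation (phase, amplitude, conformer
  class).
- **Diffusion** (`ionscape.diffusion`): trajectory unwrapping, all-origin MSD
  and Einstein diffusion coefficients with ballistic-motion diagnostics.
- **Synthetic data** (`ionscape.synthetic`): idealized (CG)₆ duplex builder
  (B-DNA, A-RNA, Z-DNA, Z-RNA; 22 phosphates, net −22e; syn-G/anti-C and
  per-base pucker templates for the Z forms), a telegraph (two-state) binding
  simulator with ground-truth event lists, an overdamped Brownian ion
  simulator with optional attractive wells, and a hydration-shell sampler.
  All generators are seed-deterministic.

## CLI

A single entry point with subcommands:

```sh
ionscape simulate --kind duplex --out duplex.pdb
ionscape simulate --kind telegraph --config spec.yaml --seed 1 --out tele.pdb
ionscape cdf       --input traj.pdb --species Na+ --out cdf.tsv
ionscape rdf       --input traj.pdb --species Na+ --site-names O6 --out rdf.tsv
ionscape charge    --input traj.pdb --species Na+ --species Cl- --out q.tsv
ionscape occupancy --input traj.pdb --species Na+ --out occ.tsv
ionscape residence --input traj.pdb --species Na+ --site-names OP1 --dt 10 --out tau.tsv
ionscape pockets   --input traj.pdb --species Na+ --out pockets.tsv
ionscape bindstats --input traj.pdb --species Na+ --site-name O6 --out dist.tsv
ionscape structure --input duplex.pdb --out structure.tsv
ionscape diffusion --input traj.pdb --species Na+ --dt 10 --out msd.tsv
ionscape report    --config config.yaml --seed 1 --out report_dir
```

Outputs are TSV with `#`-prefixed metadata headers (times in ns, distances in
Å, occupancies in percent). `report` runs every applicable stage in one shot
and writes a manifest with the config hash; identical config + seed gives
byte-identical outputs.

A minimal report config:

```yaml
simulate: {kind: telegraph, k_on: 1.0, k_off: 1.0, T: 50.0, dt: 10.0}
species: [Na+]
seed: 11
```

or, for a real trajectory, `input: traj.pdb` plus `dt`, `species`, optional
`cutoffs`, `window`, `cdf`/`rdf` bin settings and `axis` options.

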