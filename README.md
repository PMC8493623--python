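# pixkit

Crystal-packing analysis tools built around condensed electron densities:

- **cif_io** — CIF reading/writing (CSD and SHELXL-era tag spellings),
  exact-rational symmetry-operation strings that round-trip forms like
  `1-x, 1-y, 2-z`, and the conventional Cartesian frame (a ∥ x, b in xy).
- **molecule_builder** — completion of chemically whole molecules from the
  asymmetric unit under space-group symmetry (coincident atoms on special
  positions merged, polymeric connectivity detected exactly), neutron
  normalization of X–H bond lengths, mass-weighted centroids, and the
  200-atom / two-residue Pixel-export capacity checks.
- **symmetry_pairs** — enumeration of all symmetry-related molecular pairs
  within a centroid cutoff (default 20 Å), ORTEP-type symmetry codes
  (`55501` = identity, no translation), translation into standard xyz
  strings, centroid matching against external distance lists, and orbit
  multiplicities for lattice-energy half-sums.
- **indicative_analysis** — geometry-only screening: hydrogen bonds inside
  the van der Waals radii with an exponential energy estimate, vdW contact
  fractions (vdW sum + 1 Å margin), 1D chain/stack motif detection via
  exact affine composition in the molecule-image graph, a ranked driver
  list, and the half-sum lattice-energy estimate.
- **density_pixels** — Gaussian-format cube I/O, condensation of n×n×n
  grid points into charge pixels (exact charge conservation), pruning, and
  pixel-sum Coulomb energies. Level-1 clouds on a common lattice are
  evaluated by an exact FFT cross-correlation; everything else goes
  through the direct double sum.
- **mlp_report** — whitespace energy-table (.MLP dialect) parsing,
  annotation of rows with ORTEP codes by centroid matching, verification
  of the half-sum total ("toto"), and spreadsheet-compatible CSV output.
- **fixtures** — synthetic inputs with independently computed ground
  truth: seven toy crystals covering P1/P-1/P2₁/c, special positions,
  screw-axis H-bond chains, translation stacks and Z′ = 4; Gaussian-blob
  cubes with closed-form (erf) interaction energies; and a programmatic
  155-atom tripalmitin molecule.

## CLI

All functionality is exposed through a single `pixkit` entry point
(exit codes: 0 success, 1 usage error, 2 data error; warnings on stderr
prefixed `PIXKIT-WARNING:`):

```sh
pixkit convert-cif IN.cif -o OUT.cif [--strict]   # SHELXL -> CSD dialect
pixkit normh IN.cif -o OUT.cif [--table t.toml]   # neutron X-H lengths
pixkit complete IN.cif -o OUT.cif                 # whole molecules as P1
pixkit pairs IN.cif --cutoff 20 -o pairs.csv      # coded pair list
pixkit indicative IN.cif -o report.txt            # H bonds/contacts/motifs
pixkit annotate run.mlp IN.cif -o table.csv       # code an energy table
pixkit condense IN.cube -n 4 --prune 1e-6 -o pixels.csv
pixkit coulomb A.cube B.cube -n 3 --shift "8,0,0"
pixkit fixtures p21c_small -o DIR                 # toy CIF + ground truth
pixkit --version                                  # defaults, for provenance
```

`--config FILE` (TOML, flat keys such as `cutoff`, `stack_threshold`)
merges under CLI flags on `pairs` and `indicative`.

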