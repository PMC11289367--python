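# helixforge

A toolkit for structural analysis of helical protein filaments and their
cryo-EM density maps:

- **Score-optimized high-boost sharpening** — real-space sharpening that
  subtracts a weighted 3×3×3 boxcar low-pass from the map, with the weight
  chosen by maximizing either a side-chain χ1 ring statistic (an
  EMRinger-style map/model score) or a masked real-space correlation.
  Classic Fourier B-factor sharpening is included as a baseline.
- **Helical symmetry analysis** — build filaments from a monomer plus
  (rise, twist), re-estimate screw parameters from consecutive-subunit
  superpositions, compute long-pitch cross-over distances
  (`rise × 180 / (180 − |twist|)`), and compare twist populations with a
  Welch t-test.
- **Metal-site geometry validation** — coordinating-atom search around a
  candidate cation, angle-RMSD against idealized coordination geometries
  (gRMSD, exhaustive ligand-to-vertex assignment), bond-valence vector sum
  (vecsum), unexplained difference-density peak picking, and a rule-based
  Mg²⁺ / K⁺ / water plausibility ranking.
- **Structure comparison** — Kabsch superposition, per-residue Cα deviation
  maps (global or locally windowed alignment), peptide-flip detection,
  salt-bridge search, named interface distances, and straight-vs-bent
  filament distance bookkeeping.
- **Synthetic fixtures** — seeded generators for toy monomers with
  idealized covalent geometry, helical filaments with known parameters,
  Gaussian-atom density maps with controlled blur/noise, perturbed metal
  sites, peptide-flip variants, and arc-bent filaments.  Every test input
  is generated; no downloads are required.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance suite.  The optional
real-data checks in `TestCriterion6RealDataChecks` need deposited models
(PDB 8TI3, 5ONV, 8D15, 8D16) placed in `tests/data/`; they are skipped
when the files are absent.

## Command line

All operations are exposed through one entry point:

```sh
helixforge crossover --rise 27.5 --twist -167.2
helixforge simulate --kind helical_filament --rise 27.5 --twist -167.2 \
    --n 9 --seed 1 --out fil.pdb
helixforge helix-estimate fil.pdb --chains A,B,C --out interfaces.tsv
helixforge sharpen map.mrc model.pdb --scorer chi1 --factors 0:1.5:0.1 \
    --out sharp.mrc --trace trace.tsv
helixforge chi1-score map.mrc model.pdb --out report.json
helixforge compare a.pdb b.pdb --mode local --out deviations.tsv
helixforge contacts model.pdb --pair "A/167/OE1,OE2:B/61/NZ"
helixforge metal-geom model.pdb --metal "MG/A/201" --cutoff 2.6 \
    --report site.json
helixforge peaks map.mrc model.pdb --sigma 3 --out peaks.tsv
```

A config file (INI, one section per subcommand) can pre-set options via
`helixforge --config run.ini <subcommand>`; explicit flags win.

## File formats and conventions

- Models: PDB (fixed-column v3.3) and mmCIF (atom_site), read/written via
  biotite.  HETATM records (ions, waters) are retained.
- Maps: MRC2014 via mrcfile.  Grids are normalized to canonical x, y, z
  axis order on read; the world origin uses the ORIGIN header when
  nonzero, otherwise nstart × voxel size (`origin_mode` overrides).
- Helical convention: the screw axis is oriented so rise > 0; twist is the
  signed right-handed rotation about it, so left-handed 1-start helices
  have negative twist.
- vecsum follows the standard bond-valence vector-sum convention:
  **smaller = more symmetric** (0 for a centrosymmetric site, 1 for a
  single ligand).
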