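# latticevibes

Lattice-disorder analysis for protein-crystal total scattering.

The package implements a complete workflow for interpreting the *diffuse
halos* in 3D diffuse-scattering maps of protein crystals:

* **Rigid-body crystalline elastic network** (`crystal_model`): read an
  atomic model (mmCIF/PDB), expand space-group symmetry to the unit cell,
  treat each chain image as a rigid body, find inter-body atomic contacts
  (4 Å cutoff by default), and assign symmetry-enforced spring-parameter
  groups (global / per-interface / per-residue-pair). Springs are hybrid:
  a Gaussian (isotropic) term plus a parallel (central-force) term.
* **Born/Von-Karman lattice dynamics** (`lattice_dynamics`): six
  generalized coordinates per body (translations + small rotations about
  the center of mass), dynamical matrices on a periodic supercell,
  equipartition covariances of the generalized coordinates (V-Cov), TLS
  matrices, per-atom ADPs, and center-of-mass joint-ADPs for body pairs.
* **One-phonon diffuse simulation** (`diffuse_sim`): per-body electron
  densities from Gaussian-sum form factors or Fourier synthesis, soft-mask
  density partitioning, oversampled FFT molecular transforms with spline
  Fourier interpolation, 6-component one-phonon structure factors, and
  halo maps on subdivided Miller-index grids.
* **Halo refinement** (`refinement`): staged least-squares fitting of
  spring constants to measured halos (global Gaussian → per-interface
  Gaussian → per-interface hybrid → per-residue hybrid) with an exactly
  profiled 4-coefficient linear background per halo and inverse-sigma
  weights; lattice subtraction for maps and ADPs.
* **Joint-ADP deconvolution** (`discoball`): FFT the variational
  diffuse map to a 3D-ΔPDF, extract lattice-node peaks, and deconvolve
  each against the Patterson origin peak by ordinary least squares for the
  six unique joint-ADP components; validation metrics (total/anisotropic
  Pearson correlations) against any model's joint-ADPs.
* **Map utilities** (`map_processing`): isotropic/variational split,
  six-neighbor missing-voxel fill, robust error-weighted Savitzky-Golay
  regridding with bisquare reweighting, MD-comparable target-map assembly,
  and resolution-shell statistics (mean/SD/CC).
* **Synthetic fixtures** (`synthetic_fixtures`): deterministic toy
  crystals (P1 and an orthorhombic 2₁-screw lattice), a protein-scale
  triclinic P1 surrogate, brute-force supercell-Hessian covariance and
  Monte-Carlo diffuse-scattering oracles, and seeded noise injection.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence of the two covariance paths, one-phonon vs Monte-Carlo
scattering, zero-mode structure, deconvolution forward–inverse
consistency, recovery fidelity, staged-refinement parameter recovery, and
the end-to-end workflow agreement). The full suite takes ~10 minutes on
one CPU; the heavy workflow experiment is shared across tests.

## Command line

```bash
latticevibes fixtures --out fixtures/ --seed 1          # toy data bundle
latticevibes build-enm --model cell.cif --out net.json
latticevibes refine --model cell.cif --map map.h5 --bragg bragg.tsv \
    --halos 400 --res 2.0:2.5 --stages 4 --supercell 8,8,8
latticevibes simulate --model cell.cif --network net.json --out sim.h5
latticevibes subtract --map map.h5 --lattice sim.h5 --out internal.h5
latticevibes discoball --map map.h5 --bragg bragg.tsv --radius 4 \
    --exclude 5 --out jadps.json
latticevibes target-map --map map.h5 --lattice sim.h5 --k0 k0.h5 --out target.h5
latticevibes stats --map a.h5 --map2 b.h5 --out shells.tsv
latticevibes run --config workflow.yaml                 # full pipeline
```

Maps travel as HDF5 (grid metadata + intensity + sigma + mask; see
`latticevibes.maps.VoxelMap`), with a minimal CCP4/MRC export for viewers.
Bragg lists are whitespace-delimited text (`h k l I sigma`). TLS matrices
export in the REFMAC convention.

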