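# cgagg

Trajectory-analysis toolkit for quantifying the aggregation of
lipid-anchored proteins in coarse-grained membrane simulations.  The
reference system is full-length H-Ras (186 residues: G-domain 1–166,
linker 167–179, lipidated anchor 180–186) diffusing on a ternary
DPPC/DLiPC/cholesterol bilayer, where proteins assemble into nanocluster-like
aggregates and the bilayer de-mixes into liquid-ordered (L_o) and
liquid-disordered (L_d) domains.

The package is aimed at simulators who have (or want to emulate) such
trajectories and need the standard observables computed reproducibly:

* **Cluster detection** — two proteins are in contact when any two of their
  backbone beads are within a cutoff r_c = 0.75 nm (minimum image); clusters
  are connected components of the per-frame contact graph, giving cluster
  counts, size histograms and an aggregation time.
* **Contact-probability map** — residue-pair contact counts C_ij accumulated
  over F frames and M proteins, normalized as
  P_ij = C_ij / (F · C(M,2) · N_r²), with high-P pair extraction
  (default threshold P > 10×10⁻⁹) and the ensemble contact ratio
  R = (Σ_ij C_ij^a/F_a) / (Σ_ij C_ij^b/F_b).
* **Lateral diffusion** — time-origin-averaged MSD of unwrapped
  center-of-mass tracks, MSD(t) = ⟨|r_i(τ₀+t) − r_i(τ₀)|²⟩, fitted by the
  Einstein relation D = slope/(2d) with d = 2, reported in 10⁻⁸ cm²/s with
  block-averaged uncertainties.
* **ΔSASA interface mapping** — coarse-grained Shrake–Rupley solvent-accessible
  surface area (probe 0.56 nm, about four times the atomistic 0.14 nm to match
  the ~4-heavy-atom bead scale); ΔSASA = SASA_late − SASA_early per residue,
  with residues buried by more than 0.75 nm² flagged as interface residues.
* **Lipid-domain statistics** — DPPC:DLiPC bead-contact ratio of the proteins
  (boundary dwellers score near 1) and the leaflet-resolved DPPC–DLiPC
  de-mixing contact ratio over time.
* **Synthetic generator** — quasi-2D sticky Brownian dynamics (irreversible
  merging, cluster mobility D ∝ size⁻ᵅ) and a striped ternary lipid field,
  with exact ground-truth records, so every stage is testable without
  external trajectory data.

## Worked example

`examples/02_diffusion.py` simulates 500 independent 2D Brownian walkers with
a known input D, then recovers it exactly the way a real trajectory is
analyzed (unwrap → MSD → Einstein fit over lags 8–48 ns):

```
input D : 10.50  (1e-8 cm^2/s)
fitted D: 10.68 +/- 0.50  (block std over 5 molecule blocks)
relative error: 1.8%
MSD curve (lag ns -> nm^2): {0: 0.0, 4: 0.17, 8: 0.34, 12: 0.51, 16: 0.68, 20: 0.85}
```

The MSD is linear with slope 4D (0.042 nm²/ns here), and the fitted value
agrees with the known input to within the block-averaged uncertainty.

`examples/01_simulate_and_cluster.py` shows the aggregation side: 16 sticky
proteins coalesce from 16 clusters to 9 over 2.4 μs, and the detected
per-frame partitions reproduce the generator's merge record exactly:

```
time (ns) -> clusters: {0: 16, 400: 13, 800: 11, 1200: 11, 1600: 9, 2000: 9, 2400: 9}
final cluster count: 9 (ground truth: 9 )
detection matches ground truth: True
```

The other examples cover the P map and R ratio (`03_contact_map.py`), ΔSASA
interface mapping on a monomer→dimer toy (`04_sasa_interface.py`), and lipid
de-mixing/domain preference (`05_lipid_domains.py`).  Each prints the
numbers it computes with a line on what they mean.

## Command line

A thin CLI wraps the library for shell use:

```bash
cgagg fixture --profile tiny --out data/         # synthetic dataset
cgagg clusters  --traj data/traj.gro --topo data/topology.tsv --out clusters.tsv
cgagg diffusion --traj ... --topo ... --fit 8:48 --out msd.tsv
cgagg sasa      --traj ... --topo ... --early 0:8 --late 780:796 --out dsasa.tsv
cgagg run       --out run_out --seed 1           # full pipeline + JSON report
```

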