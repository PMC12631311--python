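# mutadyn

Analysis toolkit for characterizing how a point mutation reshapes a protein
domain's conformational dynamics and solution behaviour. It was built around
the study design used for the alsin VPS9 domain and its pathogenic R1611W
variant — a GEF domain whose β1 element folds and unfolds in equilibrium and
whose oligomeric state shifts upon mutation — but every component is generic:

- **Collective variables** — total β-sheet content (βRMSD) of a residue
  region and the distance between a probe residue's Cα and the Cα centroid
  of a loop.
- **Free-energy surfaces** — block-averaged bivariate histograms of the two
  CVs, Boltzmann-inverted with propagated errors, plus 1D projections and
  basin free-energy differences.
- **Secondary structure** — DSSP assignment per frame, collapsed to
  helix/strand/turn/coil, with per-residue probabilities and replica
  statistics.
- **Interaction fingerprints** — per-frame hydrogen-bond, salt-bridge and
  hydrophobic contacts of a probe residue, occupancy probabilities and the
  strict >30 % filter.
- **CD spectroscopy** — millidegree → mean-residue-ellipticity conversion,
  replicate averaging, Savitzky–Golay smoothing, basis-set deconvolution
  into secondary-structure fractions with automatic basis selection.
- **SEC** — log-linear column calibration, peak/shoulder detection,
  apparent molecular weights and oligomeric orders.
- **Synthetic data** — generators with known ground truth (two-state
  trajectories, noisy CD mixtures, Gaussian-mixture chromatograms,
  interaction fixtures) so the whole stack is testable end to end.

## The model in brief

βRMSD scores every pair of non-overlapping 3-residue backbone segments in a
region against an ideal β-sheet segment-pair template. With r the best-fit
RMSD of the 30 backbone atoms (N, CA, CB, C, O per residue) to the template,

    S(r) = (1 − (r/r0)^n) / (1 − (r/r0)^m),   r0 = 0.1 nm, n = 8, m = 12,

and the CV is Σ S(r) over segment pairs (parallel + antiparallel sums for
`total` mode). Block averaging splits the post-equilibration trajectory into
N windows with per-window normalized histograms H(i, j):

    H̄_i = (1/N) Σ_j H_{i,j}
    F_i  = −k_B T [ln H̄_i − ln max(H̄_i)]        (min F = 0 kJ/mol)
    err_i = k_B T · sem_j(H_{i,·}) / H̄_i         (delta method)

CD spectra in millidegrees convert to mean residue ellipticity as
[θ] = mdeg·Mw/(10·L·C) with Mw in kDa, L in cm and C in mg/mL; fractions are
fit by sum-to-one nonnegative least squares jointly with a single positive
scale, and the basis set with the lowest post-scaling RMSD wins. SEC assumes
log10(MW) linear in elution volume; oligomeric order is the rounded
apparent-to-monomer mass ratio.

## Worked example

`examples/two_state_free_energy.py` generates a 200 ns two-state CV
trajectory (folded occupancy 0.6, sampled every 0.4 ns), discards the first
50 ns, block-averages 15 × 10 ns windows and recovers the designed basin
free-energy difference:

```
windows: 15 x 10 ns (discarded first 50 ns)
empirical folded fraction: 0.550
basin ΔG (unfolded − folded): 0.544 ± 0.313 kJ/mol (95% band ± 0.671)
designed ΔG:                  1.005 kJ/mol
recovered within the band
```

The designed value is k_B·T·ln(0.6/0.4) = 1.005 kJ/mol; the estimate
fluctuates between seeds and is covered by the 95 % block-averaging band in
~95 % of replicas. The other scripts in `examples/` walk through the βRMSD
calibration, CD deconvolution, SEC oligomer assignment, interaction
fingerprints and secondary-structure probabilities in the same style, each
printing the numbers it computes.

A thin CLI mirrors the library (`mutadyn mass|rmsd|asa|cv|ss|contacts|fes|cd|sec|simulate|run`);
`mutadyn run --config analysis.yaml` executes the full configured pipeline
and writes tidy TSV tables plus a JSON summary.

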