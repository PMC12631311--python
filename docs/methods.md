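# Methods

This note documents the models, parameter choices and numerical decisions
behind `mutadyn`, and what the synthetic-data validation does and does not
establish.

## Data model and units

Coordinates are Ångström, trajectory times nanoseconds, free energies
kJ/mol (k_B = 0.0083145 kJ/(mol·K)); conversions happen only at I/O
boundaries (mdtraj interop uses nm/ps). Residue identifiers are author
numbers (1513–1657 for the VPS9 construct) preserved end to end; internal
atom indexing is 0-based. PDB reading/writing is delegated to biotite;
multi-model files become trajectories with uniform atom counts and strictly
increasing times.

## Superposition, RMSD, surface area, masses

Rigid superposition uses the Kabsch SVD solution with the determinant
correction for proper rotations; selections with fewer than three points or
rank < 2 (collinear) are rejected because the in-line rotation is
undetermined. Batched template RMSDs use the equivalent singular-value form
of the residual, which avoids building per-pair rotation matrices.

Accessible surface area follows the rolling-probe point method: each atom's
expanded sphere (van der Waals radius from the Bondi table + probe, default
1.4 Å) is sampled with a deterministic golden-spiral grid (default 960
points) and points inside any neighbour's expanded sphere are occluded.
Relative per-residue exposure divides by the fixed table of theoretical
per-residue maxima (Tien et al. 2013); the discretization error decreases
with the point count, which a test verifies against the closed-form
two-sphere cap area.

Peptide masses are average (isotope-weighted) masses from Biopython plus
one water. The 145-residue expression construct is handled by editing
helpers (author-numbered slicing, point substitutions such as
C1551S/C1558S/C1647S, optional purification-tag prepend). The natural
sequence is not bundled: the packaged stand-in
(`SYNTHETIC_VPS9_LIKE_SEQUENCE`) is a randomly composed globular-like
sequence, clearly labelled synthetic, that carries the residue types needed
at the documented edit positions. Computations on it exercise the machinery;
they say nothing about the natural protein. The worked mass example assumes
the untagged construct, since whether the published monomer mass includes
the tag is not stated.

## βRMSD collective variable

The CV enumerates 3-residue segments at every offset in the configured
region (default 1532–1542; the strand motif is reported variously as
1533–1543/1533–1544 elsewhere, so the region is configurable) and scores
ordered pairs whose starts differ by ≥ 3 residues (no shared residues). The
30 template atoms per pair are N, CA, CB, C, O of both segments, with
glycine Cβ synthesized at the ideal tetrahedral position. The switching
function S(r) = (1 − x^8)/(1 − x^12), x = r/r0, r0 = 0.1 nm, is evaluated
with a derivative-ratio fallback within |x − 1| < 1e−7, giving the n/m
limit at r = r0 exactly.

Ideal segment-pair templates are constructed in-code rather than copied
from an external reference implementation: a 3-residue strand is built at
canonical β torsions (φ, ψ = −139°, 135°) with Engh–Huber-style backbone
geometry, and the partner strand's rigid placement is optimized
(Nelder–Mead, multi-start over axis flips and ± offsets, deterministic) to
satisfy the canonical inter-strand N···O hydrogen-bond registry (2.9 Å
targets; a1↔b3 for antiparallel, staggered for parallel), paired Cα–Cα
targets (4.9 Å) and a soft steric floor (3.4 Å). The resulting registry has
N···O ≈ 3.1–3.2 Å and Cα–Cα ≈ 4.9–5.0 Å, and DSSP recognizes the
antiparallel pair as a β bridge. Because the synthetic generator builds its
folded state from the same template, the calibration S(0) = 1 is exact by
construction.

Pairs whose segment-centre Cα atoms are farther apart than 10 Å (1 nm) are
skipped, following the reference implementations of this CV: segments that
far apart cannot form a sheet, and the cutoff is what drives an extended
chain's score to ~0. It is configurable and can be disabled.

## Secondary structure

Assignment is DSSP (Kabsch–Sander hydrogen-bond patterns) through mdtraj's
backend — the same engine used in the original analyses — and the eight
states collapse to four classes as {H,G,I}→helix, {E,B}→strand,
{T,S}→turn, rest→coil. The mapping is configurable because only the four
class names are prescribed. Tests verify the assignment independently by
evaluating the Kabsch–Sander energy E = q1·q2·f·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN) (f = 332 kcal·Å/mol, q1 = 0.42, q2 = 0.20, bond below −0.5
kcal/mol) on ideal helices and sheets with geometrically placed amide
hydrogens (1.01 Å, bisector convention). Probabilities are occurrence
frequencies over concatenated frames; overall class fractions are
additionally computed per replica and summarized as mean ± sd.

## Interaction fingerprints

Detection is geometric, with the cutoffs of the standard profiling tool:
hydrogen bond ≤ 4.1 Å donor–acceptor with D–H···A ≥ 100° when an explicit
hydrogen is present (distance-only otherwise, since MD-derived frames may
lack hydrogens); salt bridge ≤ 5.5 Å between oppositely charged group
centroids; hydrophobic ≤ 4.0 Å between apolar (C/H-bonded-only) carbons,
identified by per-residue name tables because frames carry no bond graph.
Donor–acceptor pairs between oppositely charged groups are classified as
salt bridges only, so one physical contact is not double-counted.
Protonation is fixed at standard states (Asp/Glu anionic, Lys/Arg cationic,
His neutral); frames carry no titration information. Metal complexes,
π-stacking, π–cation and halogen bonds are recognized record types with an
explicit not-implemented error. Occupancy is the fraction of frames with at
least one contact of a given (type, partner); the fingerprint filter is a
strict > threshold (default 30 %), read literally.

## Free-energy surfaces and errors

After discarding the equilibration span (default 50 ns) the series is cut
into complete windows (default 10 ns; a trailing remainder is dropped with
a warning; fewer than two complete windows is an error). Each window is
histogrammed on shared edges (default 50 × 50 over the observed ranges
padded 5 %) and normalized; the window mean H̄ is inverted with the maximum
as reference so min F = 0. Unvisited bins are masked (NaN), never zero or
capped.

The primary error estimate propagates the between-window standard error of
the mean through the logarithm (err = k_B·T·sem/H̄); an alternative
(invert each window, spread of the window surfaces) is available via
`fes_error(..., method="per-window")` and labelled in output metadata,
because the published description of the estimator is not specific. Basin
free-energy differences use per-window basin occupancies with the same
delta-method error and a t-based 95 % confidence half-width on N − 1
degrees of freedom; the coverage property ("the designed ΔG lies inside
the band in ≥ 95 % of replicas") is what the acceptance check measures, so
the band is a 95 % interval by construction, not a tuned width.

## CD deconvolution

Conversion, baseline subtraction and replicate averaging are pointwise;
smoothing is Savitzky–Golay (default order 3, window 9, polynomial-fit
endpoints) and requires a uniform grid. Deconvolution minimizes
‖s·y − B·f‖ over nonnegative sum-to-one fractions f and a single positive
scale s applied to the experimental spectrum (the literal reading of
"after spectrum scaling"). The solver alternates active-set NNLS (with the
sum constraint as a strongly weighted row) with the closed-form optimal
scale, then polishes with an exact equality-constrained KKT solve on the
detected support — noiseless mixtures are recovered to machine precision.
RMSDs are reported in spectrum units and as kMRE (unit/1000). Basis sets
are plain-text tables (wavelength column + one column per class, optional
grouping sidecar); the packaged synthetic sets are Gaussian caricatures of
far-UV class spectra (helix 208/222 nm double minimum with a positive lobe
below 200 nm; strand shallow 218 nm minimum, positive near 200 nm; coil
deep minimum near 198 nm) with amplitudes in the literature range, chosen
once for realistic class contrast. Published basis-set files can be loaded
through the same interface; none are bundled.

## SEC

Calibration is the classic log-linear simplification, log10(MW) = a·Ve + b,
fit by least squares (a must be negative); a Kav-based variant would need
the void and total column volumes, which the data model does not require.
Peaks are prominence-filtered local maxima of the smoothed signal.
Shoulders are local minima of the smoothed second derivative that do not
coincide with an apex, sit above baseline, and exceed 2 % of the strongest
apex curvature; positions are refined by parabolic interpolation and
near-duplicate troughs within the apex-exclusion radius are merged.
"~" style reported values are matched at their printed precision (integer
kDa, 0.1 mL). Oligomeric order reports both the raw apparent-to-monomer
ratio and its rounding so borderline assignments (e.g. ratio 2.9) stay
visible.

## Synthetic generators and what they show

All generators are pure functions of (spec, seed). The two-state generator
emulates a folded-hairpin/coil equilibrium: a stationary two-state Markov
chain (default occupancy 0.6/0.4, per-frame switch rate 0.5 giving dwell
times of 1–2 ns, well under the 10 ns windows so windows are approximately
independent) selects per frame between (a) a region whose terminal strands
sit exactly on the antiparallel template with an arc-interpolated turn and
(b) a freshly sampled coil (φ ∈ U(−160°, −50°), ψ ∈ U(−180°, 180°)), plus
isotropic coordinate noise (default 0.25 Å). The probe Cα is placed at
12 Å (folded) or 17.5 Å (unfolded) from the loop Cα centroid with 0.6 Å
in-basin spread, mirroring the basin geometry of the study system. Defaults
mirror the study scales: 200 ns span, 0.4 ns sampling (500 frames), discard
50 ns, 10 ns windows → N = 15. A CV-level twin (`gen_two_state_cv`) emits
the same Markov states as Gaussian basins directly and is used where many
replicas are needed.

These generators validate the estimators — binning, averaging, inversion,
error propagation, occupancy counting, deconvolution, calibration — under
known ground truth. They do not validate force fields, sampling
convergence, replica exchange, or any property of the real protein;
passing tests show the analysis stack is correct, not that a particular
biological conclusion is reproduced. Likewise the interaction fixtures are
minimal two-residue geometries probing the criteria, not realistic binding
sites.

## Problem sizes

The default test and acceptance runs use 500-frame CV series (15 windows),
100-seed coverage sweeps, ≤ 500-frame coordinate trajectories, 101-point
spectra and 800-point chromatograms — sizes chosen so every statistical
property is measurable with comfortable margins while the full suite runs
in seconds.

## Known limitations

- The natural alsin VPS9 sequence (UniProt Q96Q42) is not redistributed;
  mass checks against the published 16.6 kDa monomer need a user-supplied
  FASTA, and the packaged stand-in sequence is synthetic.
- βRMSD templates are built from ideal geometry, not copied from a
  published reference implementation; absolute CV values may differ
  slightly from other codes (the switching calibration and limits do not).
- Hydrogen-bond detection without explicit hydrogens is distance-only.
- The trajectory reader covers multi-model PDB; compact binary formats can
  be converted upstream (mdtraj interop is provided).
- No WHAM/MBAR reweighting across temperatures: only the single-temperature
  replica analysis is implemented.
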