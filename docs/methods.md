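# Methods

## Descriptors

Conformers are reduced to p signed torsion angles, computed with the
atan2 formulation of the IUPAC convention (cis = 0°, positive =
clockwise rotation of the far bond viewed along the central bond) and
wrapped to the half-open interval [−180°, 180°), so trans is represented
as −180° and every angle has exactly one canonical value. Degenerate
geometries (coincident points, collinear central bonds) raise rather than
returning a silent 0. Internal coordinates make the descriptors exactly
invariant under rigid-body motion; the test suite checks this to 1e−8°.

Snapshot thinning keeps interior local minima of a caller-chosen
per-frame scalar (typically the potential energy of the active surface;
the choice of surface is the caller's). The default comparison is strict
(`s[i] < s[i−1]` and `s[i] < s[i+1]`); an optional plateau mode returns
the first index of an interior flat minimum. Endpoints are never
returned.

## Pattern clustering

Metastable patterns are K-means clusters (Lloyd iteration, k-means++
seeding, n_init = 10, max_iter = 300, tol = 1e−6, mandatory seed;
scikit-learn's implementation, which also handles empty-cluster
relocation). Because dihedrals are periodic, the default embedding maps
each angle to (cos θ, sin θ) and clusters in the 2p-dimensional chord
metric; a "raw" mode clusters plain angle values for the case where the
slow coordinates stay far from the ±180° seam. The two modes genuinely
differ: a basin straddling ±180° is one circular cluster but splits in
raw mode, and the suite asserts exactly that.

k is chosen by sweeping candidates at fixed seed and reading the
per-cluster geometric spread (RMS over dihedrals of the circular
standard deviation, optionally heavy-atom coordinate RMSD after Kabsch
superposition): when k reaches the number of real basins the maximum
spread collapses and then stays flat. The config default is k = 12.

Molecules whose conformational motion is mirror-symmetric produce
cluster pairs (i, i′) with centroids related by elementwise angular
negation. `merge_symmetric_pairs` pairs centroids whose back-mapped
angles satisfy c′ ≈ −c within a tolerance (default 10°), greedily by
smallest mirror distance; a centroid at 0/±180° in every coordinate is
its own mirror and maps to itself. Merged labels take the smaller id.

Rigid superposition is Kabsch via SVD with a determinant correction
against improper rotations; an atom mask supports heavy-atom-only fits.
The unit tests cross-check the RMSD against an independent
quaternion-eigenvalue implementation.

## Kinetic network

Transitions are counted at lag 1 frame by default (lag is exposed for
coarser sampling), per trajectory, never across trajectory boundaries.
Self-transitions are kept in the counts — they are needed for
row-stochasticity — but never create graph edges, since the network of
interest shows inter-pattern connectivity. Rows with no observations are
flagged and left as zeros, never imputed. The undirected graph places an
edge (i, j) when max(P_ij, P_ji) clears a threshold (default 0: any
observed transition connects); components and articulation vertices come
from networkx and are validated against a brute-force remove-and-test
oracle. Ensemble populations at each time are the fraction of defined
trajectories in each pattern; for a simulated Markov ensemble they
converge to the chain's stationary distribution (leading left
eigenvector), which the tests verify.

No Markov-state-model validation machinery (implied timescales,
Chapman–Kolmogorov) is included; the network is a counting summary, not
a validated MSM.

## Property statistics

Gaussian fits default to method-of-moments with the population (1/n)
standard deviation, so that pooling per-pattern (μ, σ, n) weighted by n
reproduces the global moments exactly (the suite asserts this to
1e−12); a histogram least-squares mode exists for binned data. Intervals
are μ ± z·σ with z = 2.58 by default, covering Φ(2.58) − Φ(−2.58) ≈ 99 %
of a Gaussian. Emission spectra are sums of unit-area Gaussians (default
FWHM 0.2 eV, grid step FWHM/20, grid padded by 3 FWHM) with no
oscillator-strength weighting, so the spectrum integrates to the
snapshot count; all snapshot energies are treated as emissions from the
lowest excited state.

## PEM kernel

The printed form of the weight function has exponent 1 in its numerator
against 4 in its denominator and no normalisation; read together with
the stated requirements (continuity, decay with distance) and its
identification with Shepard interpolation, the intended kernel is the
normalised inverse-distance weight, so the default mode is

    ω_ij = u_ij^(−p_w) / Σ_kl u_kl^(−p_w),   p_w = 4,

with the sum running over all (i, j) reference entries, matching the
double sum of the ensemble equation. The literal form is retained as
mode "as-printed" for reproduction; its predictions are not convex
combinations and it is excluded from the convexity guarantees. At an
exact match (u = 0) the weight collapses onto the zero-distance
reference(s), split equally among ties — the continuous limit of the
kernel, preserving interpolation consistency; the suite probes
continuity through the collapse. Distances use wrapped angular
differences by default (consistent with the circular embedding); a raw
mode is available. As p_w → ∞ the prediction approaches the
nearest-neighbour value, which is tested as a monotone-locality
property.

Defaults M = all patterns and n = 10 ("mini-batch") follow the standard
protocol; batch and stochastic selection are provided for the cost /
variance extremes.

## Synthetic generator

The generator reproduces the *statistical* premises of the method, not
the energetics of any real molecule: (1) a lag-1 Markov chain over k
latent conformational states, initialised from its stationary
distribution; (2) von Mises dihedral emissions around state centers —
the exact circular analogue of Gaussian noise, with κ = 50 (≈ 8° spread)
for easy presets and κ = 8 for the noisy one; (3) properties as
first-harmonic Fourier surfaces T*(X) = a₀ + Σ_m (b_m cos θ_m + c_m sin
θ_m) plus N(0, σ_n) noise — smooth, periodic and cheaply differentiable,
so the smoothness premise ("similar conformations have similar
properties") holds by construction and prediction error can be bounded
by a Lipschitz argument; (4) per-atom charges as independent Fourier
surfaces whose harmonic coefficients sum to zero over atoms, making the
net charge exactly the configured total at every geometry. Cartesian
frames, when needed, realise the sampled angles as backbone torsions of
a toy (p + 3)-atom chain via NeRF placement (1.5 Å bonds, 109.47°
angles), and round-trip through the XYZ writer/reader to 1e−6°.

Presets: `two_state_easy` (k = 2, well separated), `twelve_state_mirror`
(6 mirror pairs, exercising the 12 → 6 merge), `noisy_overlap` (k = 3,
broad emissions, σ_n = 0.2). What passing tests show is that the
pipeline recovers planted structure under its own assumptions; they do
not show robustness to features real trajectories have and the generator
lacks — anharmonic couplings between dihedrals, fast degrees of freedom
folded into the property, non-Markovian memory, state-dependent noise.

## Benchmark scales and numerical choices

Clustering and PEM benchmarks use ensembles of 20–25 trajectories × 400
frames (8,000–10,000 snapshots); transition-matrix recovery uses 100 ×
2,000 frames, matching an ensemble-of-short-runs design. Recovery
tolerances are statistical, not tuned: entrywise 3 binomial standard
errors for transition probabilities, 3 ensemble standard errors for
stationary populations, ARI ≥ 0.95 for planted-label recovery. The PEM
skill bound is 2σ_n plus the planted surface's Lipschitz constant times
the mean nearest-reference distance. Kernel ties and K-means determinism
are handled by explicit seeds; nearest-centroid ties break to the lowest
index after rounding squared distances at 1e−12 to absorb float noise.

## Known limitations

- Descriptors are dihedrals only; properties depending on bond lengths
  or angles are invisible to the kernel and average out.
- The "as-printed" kernel mode is provided verbatim but without the
  interpolation/convexity guarantees of the Shepard mode.
- The kinetic network is descriptive; no statistical validation of
  Markovianity is attempted.
- Batch reference selection scales linearly in cluster size per query;
  for large ensembles use mini-batch.
- The local-minima filter assumes the scalar series is sampled finely
  enough that interior minima are meaningful; plateaus are only handled
  via the optional mode.
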