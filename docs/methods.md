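# Methods

## Molecular representation

A nucleotide is represented by the centroid of its six-membered base ring
and an orthonormal frame: the origin is the centroid of C2, C4 and C6; x̂
points from the origin toward C2; ẑ is the unit cross product of the
ordered pair (C2−origin, C4−origin) for pyrimidines and (C2−origin,
C6−origin) for purines; ŷ = ẑ × x̂. Only these three atoms are needed, so
the representation applies uniformly to all bases, to DNA, and to modified
residues mapped onto a parent base.

The purine/pyrimidine difference in the cross-product ordering compensates
for the mirrored arrangement of C4 and C6 around the glycosidic side of the
two base classes: with it, the Watson-Crick edge of *both* classes falls
near θ ≈ +60° in the base plane and the sugar side spans 190°–290°. Axis
conventions of this kind are only fixed up to a global sign by the picture
of the physical base; ours is pinned down by a property test that checks
both orderings of an ideal Watson-Crick pair land in the same θ sector and
that the sugar sector of an ideal duplex is empty of shell partners.

The relative position of base *k* seen from base *j* is
**r**_jk = A_j (o_k − o_j) (A_j = frame axes as rows, o = origins), kept in
three equivalent forms: Cartesian (Å), cylindrical (ρ, θ in degrees ∈
[0, 360), z), and ellipsoidally scaled r̃ = (r_x/a, r_y/a, r_z/b).

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| a | 5.0 | Å | in-plane scaling semi-axis |
| b | 3.0 | Å | normal scaling semi-axis |
| shell bounds | 1 … √2.5 | scaled | interaction shell containing essentially all contacts |
| z_split | 2.0 | Å | pairing (≤) vs stacking (>) zones |
| r̃_cutoff | 2.4 | scaled | locality cutoff of the G mapping |
| KDE bandwidth | 0.25 | Å | kernel width of the scoring density |

These constants are empirical properties of base–base contact statistics in
crystal structures and are exposed as a single immutable `ScalingParams`
object; the edge-sector bounds (WC 30–100°, Hoogsteen 100–190°, sugar
190–290°) are package choices anchored only at the WC peak and the sugar
span, and are configurable.

### Annotation

A pair is "in the shell" when either ordered scaled norm is below √2.5; the
`mutual` flag records the stricter both-orderings criterion used for
annotation statistics. When the two orderings would disagree, the zone and
sector are decided on the ordering with the smaller scaled norm — a
deterministic choice favouring the better-defined view. The inner shell
bound (r̃ > 1) is reported but not enforced in enumeration: the scoring
density and the deviation metric are defined without an inner cutoff, and
the excluded-volume hole means nothing falls there in practice.

## Scoring (eSCORE)

The density p(**r**) is a Gaussian kernel density estimate (isotropic,
bandwidth 0.25 Å, true normalized density) over the frame-coordinate
vectors of all ordered shell pairs of the training structures, ignoring
sequence. The score of a structure is the plain sum Σ p(**r**_jk) over
ordered pairs — the sum, not the product, so that unpopulated regions
(including steric clashes) cost a near-zero contribution instead of
dominating a log-likelihood. Pairs beyond the shell plus three bandwidths
(in scaled units, using the smaller semi-axis) are skipped as numerically
negligible; the cutoff error is below the 1e-9 tolerance used by the
invariance tests.

Two conventions are not fixed by the formulation and are exposed as
options, with defaults chosen for interpretability: (i) p is normalized (a
positive rescaling leaves all rankings unchanged); (ii) a training vector
is included iff its *own* scaled norm is inside the shell (`mutual=True`
applies the stricter rule). Models serialize to JSON (training vectors +
bandwidth), so re-evaluation is exactly reproducible across platforms.

The normalized rank of a native among decoys is the fraction of decoys
scoring strictly better; ties count as not-better.

## Deviation metrics

The eRMSD maps every scaled pair vector through

G(r̃) = (sin(γr̃) r̃_x/r̃, sin(γr̃) r̃_y/r̃, sin(γr̃) r̃_z/r̃, 1+cos(γr̃)) · Θ(r̃_cutoff−r̃)/γ

with γ = π/r̃_cutoff, then takes the RMS difference of the G arrays over
all ordered pairs, normalized by N = the number of nucleotides. The
normalization is a genuine design choice (the defining sum does not fix N);
nucleotide count is used because it puts typical values on an O(1) scale
where ≈ 0.8 separates near-native from non-native base networks. G is
continuous at the cutoff, |G| ≤ 2/γ, and for r̃ ≪ r̃_cutoff the map is
close to an isometry, so small deviations keep their metric meaning.
Because eRMSD is a Euclidean distance between fixed non-linear images of
the coordinates, it is symmetric, non-negative and satisfies the triangle
inequality. At exactly r̃ = r̃_cutoff, G ≡ 0 (Θ taken as right-continuous
zero); approaching from below |G| → 0 continuously, so the convention is
unobservable beyond floating-point dust.

Correspondence between structures is positional (i-th ↔ i-th nucleotide);
no alignment or gap handling is attempted.

The scalar variant replaces G by G_s(r̃) = (r̃_cutoff − r̃)Θ(r̃_cutoff−r̃),
a smoothed contact map. It degenerates for ≤ 4 nucleotides (too few pairs
to disambiguate orientation) but correlates strongly with the vector form
for larger structures — a property the test suite measures on 200 perturbed
12-nt duplexes.

Baselines: superposition RMSD uses the Kabsch least-squares proper rotation
(no reflections — a mirror image has nonzero RMSD) over heavy atoms by
default; dRMSD is the RMS difference of internal distance matrices over
one ring-centroid bead per nucleotide (heavy-atom variant via flag),
keeping all metrics on the same representation; INF is
sqrt(precision × sensitivity) of the annotated interaction sets, where an
interaction is identified by the unordered pair indices and the zone —
edge sectors are ignored by default because the internal sector bounds are
approximate.

## Kinetic proximity (CV analysis)

For a trajectory and a lag τ, the metric d is evaluated on every frame pair
(t, t+τ) and the coefficient of variation CV(τ) = σ_d/⟨d⟩ is reported. A
small CV means frames at equal temporal separation are at near-equal metric
distance, i.e. the metric is a good proxy for kinetic distance. CV is
scale-invariant (any positive rescaling of d cancels), and defined as 0
when the mean distance is 0 (constant trajectory). The standard deviation
uses the unbiased (n−1) estimator.

Error bars come from a block-doubling procedure for correlated series: the
per-lag distance series is cut into consecutive blocks of size 2^ℓ at the
largest doubling level that keeps at least 8 blocks; the CV is computed
inside each block and the reported error is the standard error of the
per-block CVs. With fewer than 8 usable blocks the error is NaN rather
than a misleading number.

## Motif search

A query is segmented at chain boundaries and backbone gaps (consecutive
ring centroids > 12 Å apart). Single-segment queries slide a window of the
segment length over every contiguous stretch of the target; with bulge
tolerance, windows one nucleotide longer are also tried with each internal
nucleotide deleted in turn. Multi-segment queries enumerate ordered,
non-overlapping window combinations (segment order preserved, at most one
bulge per search by default, combination count capped with a logged
warning). Each candidate window set is compared to the query by eRMSD over
the concatenated indices; matches below the threshold (default 0.7) are
deduplicated — candidates sharing at least half of the query length with a
better match are dropped — and returned sorted by eRMSD. The defaults
(threshold, bulge protocol, non-overlap rule) are package choices; search
results should be interpreted as candidate sites, with the threshold tuned
per motif family if reference annotations are available. Optional
per-segment sequence constraints (regular expressions over the window
sequence) are deliberately off by default, since the metric itself is
sequence-blind.

## Synthetic structures

The fixtures module emulates the geometric regimes the methods must
distinguish, not the physics of real RNA:

- **Ideal A-form duplex** — planar idealized base templates in the standard
  base reference frame; Watson-Crick partner generated by a 180° rotation
  about the pair x-axis; pairs stacked on an ideal screw with fiber-model
  A-RNA parameters: twist 32.7°/step, rise 2.81 Å/step, x-displacement
  −4.36 Å, inclination 16.9°. Templates carry all base heavy atoms plus
  C1′; no sugar–phosphate backbone is modelled, and propeller/buckle are
  zero. The register-shift RMSD of the GGGG/CCCC duplex under these
  parameters is 1.71 Å; published values of ≈ 1.9 Å for this comparison
  depend on the fiber parameters and atom set used, hence the ±0.3 Å
  tolerance carried by the corresponding test.
- **Register-shifted duplex** — the same strands re-paired one step off on
  the same helix: small RMSD, disjoint pair network.
- **Stem-loop** — an A-form stem capped by loop bases on a Bézier arc; a
  deterministic single-chain cap for segmentation and search tests, not an
  energy-minimized loop.
- **Decoys** — independent Gaussian displacement of every heavy atom;
  reproducible by seed.
- **Toy trajectories** — accumulated per-frame Gaussian random walks;
  diffusive, with no barriers, basins or re-folding events.

Passing tests on these fixtures demonstrates the geometric and statistical
machinery (frame construction, shell statistics, metric behaviour,
discrimination of noise from register shifts) — they do not certify scoring
performance on fragment-assembly decoys or CV behaviour on real MD, both of
which depend on data the user supplies. Test problem sizes (4–8 bp
duplexes, 50–60-frame trajectories, 100–200-member ensembles) were chosen as
the smallest ensembles on which the measured properties are stable.

## Input handling

PDB (and mmCIF) parsing uses Biopython. Residues are recognized by name
(A/C/G/U, DA/DC/DG/DT and common aliases); modified residues are skipped
with a warning unless a name→parent mapping is supplied — how modified
bases are best folded into the statistics is genuinely open, and silently
guessing parents was judged worse than an explicit opt-in. Residues missing
any of C2/C4/C6 are skipped with a logged reason. For alternate locations,
altloc 'A' or blank is kept, ignoring occupancy, so repeated reads are
deterministic. Multi-chain structures are concatenated in file order with
chain breaks recorded; multi-model files become trajectories after a
topology consistency check. The PDB writer round-trips coordinates to the
format's 10⁻³ Å precision.

## Known limitations

- No structure repair or missing-atom reconstruction; residues without
  frame atoms are dropped, which shifts positional indices.
- The sector bounds for Hoogsteen/sugar edges are coarse; fine-grained
  Leontis–Westhof classification (cis/trans families) is out of scope.
- The scoring density is sequence-agnostic by construction; systems whose
  discrimination hinges on base identity need a different model.
- Motif search cost grows combinatorially with segment count; the cap
  trades completeness for bounded runtime and logs when it bites.
- The G mapping is many-to-one at exactly the cutoff sphere; two structures
  differing only in pairs at or beyond the cutoff are eRMSD-equivalent
  (this is the intended locality, but it means eRMSD = 0 does not imply
  identical coordinates).
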