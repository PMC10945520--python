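# Methods

## Scope and data model

`statelipid` analyses MD trajectories of a membrane protein in a lipid
bilayer for state-dependent lipid binding. Inputs are a topology (PDB/GRO),
coordinate trajectories (multi-model PDB, XTC, DCD), a per-frame
conformational-state label table (TSV: `traj_id`, `frame`, `state`), and
optionally a per-frame 2D collective-variable table. Conformational-state
labels are an *input* — typically projections onto a previously built Markov
state model — and are never recomputed here; a geometric open/closed
classifier is provided only for the synthetic gate beads.

Internal conventions: lengths in Å, times in ns, diffusion coefficients
reported in nm²/µs (1 nm²/µs = 0.1 Å²/ns), frame indices 0-based, residue
numbers taken verbatim from input files, orthorhombic boxes with the
membrane normal along z. Lipid identity is decided by a configurable
residue-name list (default includes POPC and common
phosphatidyl-ethanolamine/glycerol names), so other bilayer compositions
need configuration only.

## Contact statistics

Residue r and lipid molecule l are in contact in a frame iff the minimum
over atom pairs of the minimum-image distance is ≤ the cutoff (default 4 Å,
all atoms, not heavy-atom-only; configurable). Contact runs are maximal
blocks of consecutive contact frames; with `gap_tolerance = g > 0`, runs
separated by ≤ g non-contact frames are merged and the gap counts toward the
duration. The default is strict (g = 0): it is the only choice that needs no
further justification and it makes durations reproducible across tools.

Per residue, the mean duration is the mean of all run lengths × dt pooled
over partner lipids; the exchange count is the number of distinct partner
molecules. Runs truncated by either trajectory end are included at their
observed length and flagged `censored`: durations of very stable sites are
therefore lower bounds, which is inherent to finite trajectories, not a
correctable artefact. Ensemble aggregation averages per-trajectory means,
matching residues by `(chain, resid)`; with `pool_subunits` the five chains
of a symmetric homopentamer enter as independent samples.

## Lateral diffusion

Lipids are partitioned once, at frame 0, into first shell (any atom within
4 Å of any protein atom) and bulk; the sets are fixed for the whole
trajectory even if lipids later exchange shells, so the two estimates
describe populations defined by their initial environment. MSD is computed
over x, y only, on unwrapped coordinates (nearest-image displacement
accumulation; it aborts if a per-frame displacement approaches box/2, since
the nearest image is then ambiguous), with the protein centre-of-mass
lateral displacement relative to frame 0 subtracted from every lipid
position. All sliding time origins are used, evaluated by the standard
FFT-based decomposition and cross-checked in the tests against the direct
O(N²) sum.

D is the least-squares slope of MSD versus lag over a fractional lag window,
divided by 4. The default window is 10–50% of the maximum lag: below ~10%
the curve still carries short-time structure, above ~50% too few origins
remain and the estimate variance grows. The window is configurable and
echoed in the output. √(4·D·t) converts an estimate into the expected 2D RMS
displacement over a trajectory of length t.

## Occupancy densities

For one state label, the pooled frames define a grid (default spacing 1 Å)
covering the protein plus an 8 Å margin. Per frame, the "proximal" selection
is every whole lipid with any atom within 3 Å of the protein; a voxel is
occupied if its centre lies inside any selected atom's van der Waals sphere
(per-atom radii; 1.7 Å for the synthetic beads). The voxel value is the
fraction of frames occupied — binary per frame, so grids from disjoint frame
subsets recombine exactly as frame-count-weighted averages, and values are
necessarily in [0, 1].

Thresholding keeps voxels with occupancy ≥ the level; the default 0.40 is
inclusive (the bordering phrasings "at least 40%" and ">40%" differ only on
a measure-zero set of voxel values, and inclusive is the reproducible
choice). Differencing two grids of identical geometry is voxelwise and
antisymmetric. Five-fold symmetry is quantified by the Pearson correlation
between a grid and its k·72° rotations about the pore axis (trilinear
resampling, computed over the union of nonzero voxels); the symmetrised grid
is the mean over the five rotations. Resampling error limits self-correlation
of an exactly symmetric grid to ≈ 0.98–1.0 at 1 Å spacing.

## Representative frames

Each candidate frame's binary single-frame density (same selection and
geometry as the reference grid) is correlated with the reference over the
nonzero-union mask. Frames are sorted by correlation descending — ties
broken by trajectory id then frame index, so selection is deterministic —
and accepted greedily, skipping frames from any trajectory that already
holds ⌊cap·n⌋ accepted frames (cap = 0.4, n = 100 ⇒ at most 40). The cap is
interpreted against the *requested* n, not the selected count; greedy
selection (not global optimisation) is used deliberately as the simplest
procedure consistent with the stated rule.

## Pore-axis geometry

The axis is the vertical through the protein centre of geometry (the
membrane normal is asserted to be z; a user-supplied rotation can be applied
upstream, no automatic principal-axis alignment is attempted). Leaflet slabs
are z-intervals relative to the axis origin; defaults split at the origin.
Radial quantities use the perpendicular distance to the axis. Penetration
fraction is the share of frames whose minimum slab radius is ≤ a threshold,
with empty-slab frames excluded and reported as missing. Azimuthal sectors
are anchored at the first subunit's azimuth, not at laboratory angles.
Landscape projection bins frames on two collective variables and averages a
scalar per bin, flagging empty bins. `symmetry_expand` rotates per-subunit
records by k·(360/n)° about the axis, turning five per-subunit lipid poses
into 25 records on a pentamer.

## The synthetic bilayer generator

The generator produces the study system every estimator is validated on: a
C5-symmetric pentameric cage (scaffold beads on a 17 Å cylinder across the
membrane, pore-lining gate beads whose radius tracks the scheduled state,
site beads at binding-site anchors), two leaflets of rigid head+tail bead
rods (head planes at ±19 Å), and lateral Brownian motion with per-axis step
variance 2·D·dt. Defaults mirror the conditions the estimators assume:
1.7 µs at 1 ns resolution and D_free = 1.47 nm²/µs, a typical fluid-phase
phosphatidylcholine value.

Binding sites are telegraph processes. A free lipid inside a site's capture
radius (default 5 Å) binds with per-frame probability 1 − exp(−k_on·dt) if
the site is active in the current state and unoccupied (one lipid per site);
bound lipids sit at the anchor plus 0.5 Å Gaussian jitter and unbind with
1 − exp(−k_off·dt), so completed bound intervals are exponential with mean
1/k_off exactly. Three deliberate hard-core rules keep the kinetics clean:

* on unbinding the lipid is ejected just outside the capture radius, so
  consecutive events are distinct intervals rather than one merged contact
  run;
* the capture zone is sterically exclusive — free lipids that fail to bind
  are pushed back to the capture boundary — so residue contacts at a site
  come from the bound lipid only and the contact-duration estimator sees
  the residence process undiluted by passers-by;
* the protein footprint (protein radius + 1 Å) is impenetrable to free
  lipids, which keeps radial penetration statistics meaningful.

Deactivating a site mid-bind (state switch) releases its lipid immediately,
modelling a conformational change that occludes the pocket; such truncated
intervals are flagged like censored runs and excluded from residence
statistics by default. Periodic boundaries apply in x, y only; leaflets are
fixed in z; lipids are rigid and never flip, and the protein is static
except for the gate beads. None of this pretends to be a force field — the
generator exists to give every downstream estimator an exact analytic
target, and passing on it demonstrates estimator correctness, not realism of
any particular membrane.

## Validation design and problem sizes

The test suite and `scripts/acceptance.py` use three synthetic regimes,
chosen so each estimate carries enough samples for its tolerance:

* diffusion: 280 lipids × 1000 frames per replica (estimator spread ≈ 5%;
  the acceptance script averages three independent replicas, analogous to
  ensemble-averaging over simulation seeds);
* residence: five sites with 1/k_off = 100 ns over 8 µs, ≈ 200 completed
  events per replica (standard error ≈ 7%; two replicas pooled in the
  acceptance script);
* state gating: one open-only site under an alternating 500-frame
  closed/open schedule over 4 µs.

Closed-form checks (√(4·D·t), the 25-fold symmetry expansion) are exact.
Grid round-trips are verified to 10⁻⁵ through OpenDX (ASCII) and MRC
(float32) with a single-voxel probe pinning the axis-order convention in
both formats.

## Known limitations

* Chain identity survives PDB but not GRO round-trips (the format has no
  chain field); GRO-only workflows therefore cannot distinguish subunits.
* Anisotropic grids and triclinic boxes are unsupported; minimum image
  assumes orthorhombic cells.
* Censored contact runs are included at observed length rather than handled
  by survival estimators; for residence ≪ trajectory length the bias is
  negligible, for near-trajectory-length interactions durations are lower
  bounds.
* The bound-fraction ground truth k_on/(k_on + k_off) describes the
  two-state gate in isolation; realised site occupancy in the spatial
  simulation is additionally limited by diffusive arrival, so occupancy
  levels are validated qualitatively (state ordering), not against that
  formula.
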