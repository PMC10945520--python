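# statelipid

State-resolved protein–lipid interaction analysis for molecular-dynamics
trajectories of membrane channels.

Pentameric ligand-gated ion channels sit in a phospholipid bilayer, and
individual lipids bind at specific sites on the transmembrane surface — some
persistently, some only in particular conformational states of the channel.
`statelipid` implements the trajectory-analysis toolchain used to find and
characterise such sites:

* **Contact fingerprinting** — a residue and a lipid molecule are in contact
  when any atom pair is within a cutoff (default 4 Å, minimum image).
  Contiguous contact frames form runs; the per-residue mean run length is the
  interaction duration, and the number of distinct partner lipids is the
  exchange count. Runs truncated by the trajectory ends are kept and flagged
  as censored.
* **Lateral diffusion** — lipids are split once, at the first frame, into the
  first lipid shell (any atom within 4 Å of the protein) and the bulk. Per
  set, the lateral mean squared displacement (protein centre-of-mass motion
  removed, sliding time origins) is fit to the Einstein relation
  MSD(t) = 4·D·t; the expected net displacement over a trajectory of length
  *t* is √(4·D·t).
* **State-classified occupancy densities** — frames carrying a given
  conformational-state label (e.g. from a Markov state model, supplied as a
  TSV) are pooled; each voxel records the fraction of frames in which it lies
  inside an atom of a "whole lipid within 3 Å of the protein". Grids are
  thresholded (default ≥ 0.40), differenced between states, and checked for
  five-fold symmetry by correlation with their 72° rotations.
* **Representative frames** — frames are ranked by the correlation between
  their instantaneous lipid density and a reference occupancy grid and
  selected greedily, with at most 40% of the requested frames from any one
  trajectory.
* **Pore-axis geometry** — radial distance of the closest lipid atom to the
  pore axis per leaflet slab, lipid penetration probabilities at a radial
  threshold, residue–lipid minimum distances with per-state contact
  fractions, and projection of any per-frame scalar onto a 2D
  collective-variable landscape.

Because the interesting quantities (residence times, diffusion coefficients,
state-dependent densities) have no closed-form answer on real data, the
package bundles a **synthetic bilayer generator**: a C5-symmetric pentamer in
a two-leaflet bilayer with Brownian lipids (known D), telegraph-process
binding sites (known k_on, k_off, hence exponential residence with mean
1/k_off), and a frame-indexed open/closed schedule that gates site
availability. Every estimator is validated against this exact ground truth.

## Worked example

```python
import numpy as np
import statelipid as sl

# state-gated site on subunit A, alternating closed/open schedule
schedule = tuple((k * 500, (k + 1) * 500, "closed" if k % 2 == 0 else "open")
                 for k in range(8))
cfg = sl.SyntheticConfig(
    n_lipids_per_leaflet=30, n_frames=4000, box=120.0,
    site_specs=(sl.SiteSpec(subunit=0, k_off=0.02, states_active=("open",)),),
    state_schedule=schedule, seed=2,
)
sim = sl.simulate(cfg)

# lateral diffusion of bulk lipids (Einstein relation)
shell, bulk = sl.assign_shells(sim.trajectory.coords[0], sim.topology,
                               sim.trajectory.box[0])
est = sl.fit_diffusion(sl.lateral_msd(sim.trajectory, sim.topology, bulk))

# contact durations at the binding-site residue
series = sl.contact_series(sim.trajectory, sim.topology, cutoff=4.0)
table = sl.duration_stats(series).table
site = table[table.resname == "STE"].iloc[0]

# state-resolved occupancy and the open-state difference density
geom = sl.geometry_for(sim.topology, sim.trajectory.coords[0])
g_closed = sl.state_occupancy_grid([sim.trajectory], sim.labels, "closed",
                                   sim.topology, geom)
g_open = sl.state_occupancy_grid([sim.trajectory], sim.labels, "open",
                                 sim.topology, geom)
diff = sl.state_difference(g_open, g_closed)
```

Output:

```
ground truth: D = 1.47 nm^2/us, site residence = 50 ns
bulk D = 1.51 nm^2/us (R^2 = 0.998, 59 lipids)
expected 1.7 us displacement: 3.21 nm
site residue mean contact duration = 42.2 ns (12 runs, 4 lipids)
open-minus-closed density peak 0.25 at x,y = (19.2, -0.2) A (site anchor at (19.0, 0.0) A)
```

The fitted bulk diffusion coefficient recovers the generator's 1.47 nm²/µs
within a few percent; the mean contact duration at the site residue tracks
the 50 ns kinetic ground truth (it is an estimate from 12 binding events);
and the open-minus-closed occupancy difference peaks at the open-gated site
anchor, the density signature of a state-dependent binding site.

The same stages run from the shell:

```sh
statelipid simulate --config synthetic.yaml --seed 2 --out sim/
statelipid contacts --top sim/system.pdb --traj sim/trajectory.pdb --dt 1 --out contacts.tsv
statelipid occupancy --top sim/system.pdb --traj sim/trajectory.pdb \
    --labels sim/labels.tsv --state open --dt 1 --out open.dx
statelipid run --config pipeline.yaml   # full pipeline + manifest
```

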