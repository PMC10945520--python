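"""Synthetic bilayer trajectories with known diffusion and binding kinetics.

The generator emulates the kind of system the pipeline is built for: a
C5-symmetric pentameric channel embedded in a two-leaflet phospholipid
bilayer, with laterally diffusing lipids and a handful of discrete binding
sites on the protein surface.  Every quantity the downstream estimators
measure has an exact, analytic ground truth here:

* free lipids perform 2D Brownian motion with lateral diffusion coefficient
  ``D_free`` (nm²/µs), so MSD slopes are known;
* each binding site is a two-state telegraph process — a free lipid inside
  the capture radius binds with per-frame probability ``1 - exp(-k_on dt)``
  (if the site is active in the current conformational state and unoccupied),
  and a bound lipid unbinds with ``1 - exp(-k_off dt)`` — so bound-interval
  durations are exponential with mean ``1/k_off``;
* a frame-indexed state schedule (closed/open/...) gates which sites can
  bind, emulating state-dependent lipid sites; deactivating a site mid-bind
  releases its lipid at once (the conformational change occludes the pocket),
  and such truncated intervals are flagged like censored runs.

Lipids are rigid head+tail bead rods; binding pins the lipid laterally at the
site anchor (plus 0.5 Å jitter).  On unbinding the lipid is ejected just
outside the capture radius so that consecutive binding events are distinct
and residence statistics stay exactly exponential.  The pore-lining gate
beads move radially with the scheduled state so that a purely geometric
classifier can recover the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trajio import StateLabelTable, Topology, Trajectory

import pandas as pd

#: 1 nm²/µs expressed in Å²/ns
NM2_PER_US_TO_A2_PER_NS = 0.1

CLOSED, OPEN = "closed", "open"


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent synthetic configurations."""


@dataclass(frozen=True)
class SiteSpec:
    """One lipid binding site on the protein surface.

    ``subunit`` indexes the subunit carrying the site residue; ``leaflet`` is
    ``"outer"`` (+z head plane) or ``"inner"``.  ``anchor_xy`` places the site
    laterally; if ``None`` it is put just outside the protein radius at the
    subunit's azimuth.  ``states_active`` lists the conformational-state
    labels in which the site can bind.
    """

    subunit: int = 0
    leaflet: str = "outer"
    anchor_xy: tuple[float, float] | None = None
    capture_radius: float = 5.0  # Å
    k_on: float = 10.0  # 1/ns
    k_off: float = 0.01  # 1/ns
    states_active: tuple[str, ...] = (CLOSED, OPEN)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic bilayer system.

    Defaults mirror a pentameric-channel/POPC setup: five subunits, a
    ~1.7 µs trajectory at 1 ns resolution, and a free-lipid lateral
    diffusion coefficient of 1.47 nm²/µs.
    """

    n_subunits: int = 5
    protein_radius: float = 17.0  # Å
    bilayer_halfwidth: float = 19.0  # Å, head-bead plane |z|
    n_lipids_per_leaflet: int = 40
    beads_per_lipid: int = 3
    D_free: float = 1.47  # nm²/µs
    site_specs: tuple[SiteSpec, ...] = ()
    state_schedule: tuple[tuple[int, int, str], ...] | None = None
    n_frames: int = 1700
    dt: float = 1.0  # ns
    box: float = 120.0  # lateral box length Å (square)
    seed: int = 0
    gate_radius_closed: float = 3.0  # Å
    gate_radius_open: float = 6.0  # Å
    bind_jitter: float = 0.5  # Å
    com_drift: tuple[float, float] = (0.0, 0.0)  # Å/frame whole-system drift
    protein_exclusion: bool = True  # free lipids cannot enter the footprint

    def schedule(self) -> tuple[tuple[int, int, str], ...]:
        if self.state_schedule is None:
            return ((0, self.n_frames, CLOSED),)
        return self.state_schedule

    def validate(self) -> None:
        if self.n_subunits < 1 or self.n_lipids_per_leaflet < 0:
            raise ConfigurationError("counts must be positive")
        if self.beads_per_lipid < 1:
            raise ConfigurationError("beads_per_lipid must be >= 1")
        if self.D_free < 0:
            raise ConfigurationError("D_free must be non-negative")
        if self.n_frames < 1 or self.dt <= 0:
            raise ConfigurationError("need n_frames >= 1 and dt > 0")
        for s in self.site_specs:
            if s.k_on <= 0 or s.k_off <= 0:
                raise ConfigurationError("k_on and k_off must be positive")
            if s.capture_radius <= 0:
                raise ConfigurationError("capture_radius must be positive")
            if not 0 <= s.subunit < self.n_subunits:
                raise ConfigurationError(f"site subunit {s.subunit} out of range")
            if s.leaflet not in ("outer", "inner"):
                raise ConfigurationError(f"unknown leaflet {s.leaflet!r}")
        max_capture = max((s.capture_radius for s in self.site_specs), default=0.0)
        if self.protein_radius + max_capture >= self.box / 2:
            raise ConfigurationError(
                "box too small: protein_radius + capture_radius must be < box/2"
            )
        sched = self.schedule()
        covered = 0
        for start, stop, _label in sched:
            if start != covered or stop <= start:
                raise ConfigurationError(
                    "state_schedule must cover [0, n_frames) contiguously"
                )
            covered = stop
        if covered != self.n_frames:
            raise ConfigurationError("state_schedule must cover [0, n_frames)")

    def state_labels(self) -> np.ndarray:
        labels = np.empty(self.n_frames, dtype=object)
        for start, stop, label in self.schedule():
            labels[start:stop] = label
        return labels

    def resolved_sites(self) -> list[SiteSpec]:
        """Site specs with concrete anchors filled in."""
        out = []
        for s in self.site_specs:
            if s.anchor_xy is None:
                phi = 2 * np.pi * s.subunit / self.n_subunits
                r = self.protein_radius + 2.0
                s = replace(s, anchor_xy=(r * np.cos(phi), r * np.sin(phi)))
            out.append(s)
        return out


@dataclass(frozen=True)
class GroundTruth:
    """Analytic ground truth for the generated system."""

    D_free: float  # nm²/µs
    mean_residence_ns: tuple[float, ...]  # per site, = 1/k_off
    bound_fraction: tuple[float, ...]  # per site, = k_on / (k_on + k_off)

    def __post_init__(self) -> None:
        if self.D_free < 0 or any(m < 0 for m in self.mean_residence_ns):
            raise ValueError("ground truth values must be non-negative")
        if any(not 0 <= f <= 1 for f in self.bound_fraction):
            raise ValueError("bound fraction must lie in [0, 1]")


@dataclass
class BindingEvent:
    """One bound interval at one site."""

    site: int
    lipid_id: int
    start_frame: int
    end_frame: int  # exclusive
    censored: bool  # truncated: still bound at the end, or gated off mid-bind

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class SimulationResult:
    topology: Topology
    trajectory: Trajectory
    labels: StateLabelTable
    ground_truth: GroundTruth
    events: list[BindingEvent]
    config: SyntheticConfig

    def bound_durations_ns(self, site: int | None = None,
                           include_censored: bool = False) -> np.ndarray:
        evs = [
            e for e in self.events
            if (site is None or e.site == site)
            and (include_censored or not e.censored)
        ]
        return np.array([e.n_frames * self.config.dt for e in evs])


def analytic_ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Closed-form ground truth implied by the configuration."""
    config.validate()
    sites = config.resolved_sites()
    return GroundTruth(
        D_free=config.D_free,
        mean_residence_ns=tuple(1.0 / s.k_off for s in sites),
        bound_fraction=tuple(s.k_on / (s.k_on + s.k_off) for s in sites),
    )


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------

N_SCAFFOLD_LEVELS = 5
GATE_RESID = 100
SITE_RESID_BASE = 200
MIN_SEPARATION = 2.0  # Å, placement sanity check
MIN_LIPID_SPACING = 6.0  # Å, lattice lower bound (~36 Å² headgroup area)


def build_system(config: SyntheticConfig) -> tuple[Topology, np.ndarray]:
    """Construct the topology and initial coordinates.

    The protein is a rigid pseudo-atom cage: per subunit, one scaffold bead
    ("SCF") per z level on a cylinder of ``protein_radius``, a pore-lining
    gate bead ("GAT") at z=0, and one site bead ("STE") per binding site at
    the site anchor in the leaflet head plane.  Lipids are head+tail bead
    rods placed on a lattice outside the protein footprint, head beads in the
    leaflet planes at ±``bilayer_halfwidth``.
    """
    config.validate()
    h = config.bilayer_halfwidth
    chains = [chr(ord("A") + k) for k in range(config.n_subunits)]
    sites = config.resolved_sites()

    resid: list[int] = []
    resname: list[str] = []
    chain: list[str] = []
    name: list[str] = []
    kind: list[str] = []
    lipid_id: list[int] = []
    coords: list[np.ndarray] = []

    z_levels = np.linspace(-h, h, N_SCAFFOLD_LEVELS)
    for k, ch in enumerate(chains):
        phi = 2 * np.pi * k / config.n_subunits
        for li, z in enumerate(z_levels):
            resid.append(1 + li)
            resname.append("SCF")
            chain.append(ch)
            name.append("BB")
            kind.append("protein")
            lipid_id.append(-1)
            coords.append(np.array([
                config.protein_radius * np.cos(phi),
                config.protein_radius * np.sin(phi),
                z,
            ]))
        # pore-lining gate bead; its radius tracks the scheduled state
        resid.append(GATE_RESID)
        resname.append("GAT")
        chain.append(ch)
        name.append("GB")
        kind.append("protein")
        lipid_id.append(-1)
        coords.append(np.array([
            config.gate_radius_closed * np.cos(phi),
            config.gate_radius_closed * np.sin(phi),
            0.0,
        ]))
        for si, s in enumerate(sites):
            if s.subunit != k:
                continue
            z_site = h if s.leaflet == "outer" else -h
            resid.append(SITE_RESID_BASE + si)
            resname.append("STE")
            chain.append(ch)
            name.append("SB")
            kind.append("protein")
            lipid_id.append(-1)
            coords.append(np.array([*s.anchor_xy, z_site]))

    # lipid lattice outside the protein footprint
    n_per_leaflet = config.n_lipids_per_leaflet
    L = config.box
    exclusion = config.protein_radius + 3.0
    n_side = int(np.ceil(np.sqrt(n_per_leaflet * 2.5))) + 2
    # never pack lipids tighter than a physical area per molecule
    n_side = min(n_side, int((L - 6.0) / MIN_LIPID_SPACING) + 1)
    xs = np.linspace(-L / 2 + 3.0, L / 2 - 3.0, max(n_side, 2))
    lattice = [
        (x, y) for x in xs for y in xs if np.hypot(x, y) > exclusion
    ]
    # fill annuli around the protein first so the first lipid shell is
    # populated and the arrangement is roughly isotropic
    lattice.sort(key=lambda p: (np.hypot(*p), np.arctan2(p[1], p[0])))
    if len(lattice) < n_per_leaflet:
        raise ConfigurationError(
            f"cannot place {n_per_leaflet} lipids per leaflet in a "
            f"{L:.0f} Å box with protein radius {config.protein_radius:.0f} Å"
        )
    tail_step = min(4.0, (2 * h - 2.0) / max(config.beads_per_lipid, 2))
    lid = 0
    for leaflet_sign in (+1, -1):
        z_head = leaflet_sign * h
        for x, y in lattice[:n_per_leaflet]:
            for b in range(config.beads_per_lipid):
                resid.append(1 + lid)
                resname.append("POPC")
                chain.append("L")
                name.append("HD" if b == 0 else f"T{b}")
                kind.append("lipid")
                lipid_id.append(lid)
                coords.append(np.array([x, y, z_head - leaflet_sign * b * tail_step]))
            lid += 1

    top = Topology(
        np.array(resid), np.array(resname, dtype=object),
        np.array(chain, dtype=object), np.array(name, dtype=object),
        np.array(kind, dtype=object), np.array(lipid_id),
        np.full(len(resid), 1.7),
    )
    xyz = np.asarray(coords)
    _check_min_separation(xyz, top)
    return top, xyz


def _check_min_separation(xyz: np.ndarray, top: Topology) -> None:
    """No two beads of different molecules closer than MIN_SEPARATION."""
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    pairs = tree.query_pairs(MIN_SEPARATION, output_type="ndarray")
    for i, j in pairs:
        same_lipid = (
            top.lipid_id[i] == top.lipid_id[j] and top.lipid_id[i] >= 0
        )
        same_protein_res = (
            top.kind[i] == "protein" and top.kind[j] == "protein"
        )
        if not (same_lipid or same_protein_res):
            raise ConfigurationError(
                f"initial placement puts atoms {i} and {j} closer than "
                f"{MIN_SEPARATION} Å"
            )


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def simulate(config: SyntheticConfig) -> SimulationResult:
    """Run the kinetic Monte-Carlo / Brownian-dynamics generator.

    Returns wrapped and unwrapped coordinates, the per-frame state label
    table, the analytic ground truth, and the full binding-event log.
    Exactly reproducible for a fixed ``config.seed``.
    """
    config.validate()
    top, xyz0 = build_system(config)
    rng = np.random.default_rng(config.seed)
    sites = config.resolved_sites()
    labels = config.state_labels()
    F = config.n_frames
    n_lip = config.n_lipids_per_leaflet * 2
    dt = config.dt
    L = config.box
    h = config.bilayer_halfwidth
    step_sigma = np.sqrt(2.0 * config.D_free * NM2_PER_US_TO_A2_PER_NS * dt)

    lip_atoms = top.lipid_atom_indices()
    gate_atoms = np.flatnonzero(top.resname == "GAT")
    gate_phis = np.arctan2(xyz0[gate_atoms, 1], xyz0[gate_atoms, 0])

    # per-lipid lateral anchor position (head bead x, y), unwrapped
    head_atoms = np.array([lip_atoms[l][0] for l in range(n_lip)])
    lip_xy = xyz0[head_atoms, :2].copy()
    leaflet = np.where(xyz0[head_atoms, 2] > 0, 1, -1)
    bead_dz = {
        l: xyz0[lip_atoms[l], 2].copy() for l in range(n_lip)
    }

    anchors = np.array([s.anchor_xy for s in sites]).reshape(-1, 2)
    site_leaflet = np.array([1 if s.leaflet == "outer" else -1 for s in sites])
    p_on = np.array([1.0 - np.exp(-s.k_on * dt) for s in sites])
    p_off = np.array([1.0 - np.exp(-s.k_off * dt) for s in sites])
    capture = np.array([s.capture_radius for s in sites])
    active_sets = [frozenset(s.states_active) for s in sites]

    bound_site = np.full(n_lip, -1)  # site index per lipid, -1 = free
    occupant = np.full(len(sites), -1)  # lipid id per site, -1 = empty
    start_frame = np.full(len(sites), -1)
    events: list[BindingEvent] = []

    n_atoms = top.n_atoms
    coords = np.empty((F, n_atoms, 3))
    unwrapped = np.empty((F, n_atoms, 3))
    box = np.tile([L, L, 2 * (h + 20.0)], (F, 1))
    drift = np.asarray(config.com_drift, dtype=float)

    def minimg(d: np.ndarray) -> np.ndarray:
        return d - L * np.round(d / L)

    def fill_frame(f: int) -> None:
        gate_r = (config.gate_radius_open if labels[f] == OPEN
                  else config.gate_radius_closed)
        frame = np.empty((n_atoms, 3))
        prot = top.protein_mask
        frame[prot] = xyz0[prot]
        frame[gate_atoms, 0] = gate_r * np.cos(gate_phis)
        frame[gate_atoms, 1] = gate_r * np.sin(gate_phis)
        frame[gate_atoms, 2] = 0.0
        for l in range(n_lip):
            ai = lip_atoms[l]
            frame[ai, 0] = lip_xy[l, 0]
            frame[ai, 1] = lip_xy[l, 1]
            frame[ai, 2] = bead_dz[l]
        frame[:, :2] += drift * f
        unwrapped[f] = frame
        wrapped = frame.copy()
        wrapped[:, :2] = minimg(wrapped[:, :2])
        coords[f] = wrapped

    r_excl = config.protein_radius + 1.0 if config.protein_exclusion else 0.0

    def safe_capture_exit(si: int, direction: np.ndarray,
                          distance: float) -> np.ndarray:
        """Point at ``distance`` from site ``si``'s anchor, outside the
        protein footprint (falls back to the radially-outward direction)."""
        if np.linalg.norm(direction) < 1e-9:
            direction = anchors[si] if np.linalg.norm(anchors[si]) > 1e-9 \
                else np.array([1.0, 0.0])
        direction = direction / np.linalg.norm(direction)
        pos = anchors[si] + distance * direction
        if np.hypot(*pos) < r_excl:
            outward = anchors[si] / max(np.hypot(*anchors[si]), 1e-9)
            pos = anchors[si] + distance * outward
        return pos

    fill_frame(0)
    for f in range(1, F):
        free = bound_site < 0
        if np.any(free):
            lip_xy[free] += rng.normal(0.0, step_sigma, size=(free.sum(), 2))
        # bound lipids jitter around their anchor
        for si in range(len(sites)):
            l = occupant[si]
            if l >= 0:
                lip_xy[l] = anchors[si] + rng.normal(
                    0.0, config.bind_jitter, size=2
                )
        # unbinding: eject just outside the capture radius so that the next
        # binding event is a distinct interval; a site deactivated by the
        # current conformational state releases its lipid immediately (the
        # interval is flagged truncated, like a censored run)
        label = labels[f]
        for si in range(len(sites)):
            l = occupant[si]
            if l < 0:
                continue
            forced = label not in active_sets[si]
            if forced or rng.random() < p_off[si]:
                theta = rng.uniform(0, 2 * np.pi)
                lip_xy[l] = safe_capture_exit(
                    si, np.array([np.cos(theta), np.sin(theta)]),
                    capture[si] + 1.0,
                )
                events.append(BindingEvent(si, int(l), int(start_frame[si]),
                                           f, forced))
                occupant[si] = -1
                bound_site[l] = -1
        # the protein footprint is impenetrable to free lipids
        if r_excl > 0:
            freei = np.flatnonzero(bound_site < 0)
            r_ax = np.hypot(lip_xy[freei, 0], lip_xy[freei, 1])
            inside = r_ax < r_excl
            for l, r in zip(freei[inside], r_ax[inside]):
                if r < 1e-9:
                    theta = rng.uniform(0, 2 * np.pi)
                    lip_xy[l] = r_excl * np.array([np.cos(theta),
                                                   np.sin(theta)])
                else:
                    lip_xy[l] = lip_xy[l] * (r_excl / r)
        # binding attempts, nearest candidate first
        for si in range(len(sites)):
            if occupant[si] >= 0 or label not in active_sets[si]:
                continue
            cand = np.flatnonzero(
                (bound_site < 0) & (leaflet == site_leaflet[si])
            )
            if cand.size == 0:
                continue
            d = np.hypot(*minimg(lip_xy[cand] - anchors[si]).T)
            in_mask = d < capture[si]
            inside = cand[in_mask]
            if inside.size == 0:
                continue
            order = inside[np.argsort(d[in_mask])]
            for l in order:
                if rng.random() < p_on[si]:
                    occupant[si] = l
                    bound_site[l] = si
                    start_frame[si] = f
                    lip_xy[l] = anchors[si] + rng.normal(
                        0.0, config.bind_jitter, size=2
                    )
                    break
        # the capture zone is sterically exclusive: free lipids that did not
        # bind (site occupied, inactive, or a failed attempt) are pushed back
        # to the capture radius, so residue contacts at a site come from the
        # bound lipid only
        for si in range(len(sites)):
            cand = np.flatnonzero(
                (bound_site < 0) & (leaflet == site_leaflet[si])
            )
            if cand.size == 0:
                continue
            delta = minimg(lip_xy[cand] - anchors[si])
            d = np.hypot(delta[:, 0], delta[:, 1])
            intr = d < capture[si]
            for l, dd in zip(cand[intr], delta[intr]):
                lip_xy[l] = safe_capture_exit(si, dd, capture[si])
        fill_frame(f)

    for si in range(len(sites)):
        if occupant[si] >= 0:
            events.append(BindingEvent(si, int(occupant[si]),
                                       int(start_frame[si]), F, True))

    traj = Trajectory(
        traj_id=f"synthetic-{config.seed}",
        coords=coords,
        box=box,
        dt=dt,
        unwrapped=unwrapped,
    )
    label_df = pd.DataFrame({
        "traj_id": traj.traj_id,
        "frame": np.arange(F),
        "state": labels,
    })
    vocab = tuple(sorted(set(labels)))
    return SimulationResult(
        topology=top,
        trajectory=traj,
        labels=StateLabelTable(label_df, vocab),
        ground_truth=analytic_ground_truth(config),
        events=events,
        config=config,
    )
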