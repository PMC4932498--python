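"""Seeded synthetic configurations emulating AD self-assembly end states.

These generators build frames and trajectories with the statistical
structure the analysis stages assume — spherical or rod micelles with
core-packed tails, siRNA-micelle complexes, 4:1-mapped water and 150 mM
NaCl ion beads, and scripted two-micelle fusion approaches — without
running molecular dynamics.  Trajectories are scripted fixtures, not
physics: there is no force evaluation and no kinetics.

Radial micelle construction: hydrophobic beads (ring + tail) of each AD are
placed along the molecule's radial axis with distances from the centre
drawn from the cube-root law r = R (j/n)^(1/3), which reproduces the
uniform-density solid-sphere profile so the sqrt(5/3)-Rg core-radius
estimator recovers the target radius.  The terminal tail bead's signed
radius is set from an interdigitation target I_d: a terminal placed past
the centre (negative signed radius) emulates tails interpenetrating the
core, giving ring-to-terminal distances l0 = I_d * R without disturbing the
radial density profile.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import cg_builder as cg
from .frames import BEAD_MASS, Frame, Trajectory, group_com, wrap_positions

#: Avogadro-derived conversion: mM -> beads per nm^3.
_MM_TO_PER_NM3 = 6.02214076e-4

#: MARTINI water bead density (4 waters per bead, 55.5 M water).
WATER_BEAD_DENSITY = 8.35  # beads / nm^3

#: Default per-frame positional noise (nm), small enough to preserve
#: cluster identity while exercising the estimators.
NOISE_SIGMA = 0.05

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

#: Minimum core surface area per AD anchor (nm^2); below this the ring
#: beads cannot tile the core surface and packing is infeasible.
_MIN_AREA_PER_ANCHOR = 0.2

#: Radial spacing of dendron head shells (nm).
HEAD_SHELL = 0.25


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = _GOLDEN_ANGLE * k
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _local_frame(u: np.ndarray):
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _ad_molecule_positions(
    spec: cg.ADSpec,
    anchor: np.ndarray,
    u: np.ndarray,
    core_radius: float,
    interdigitation: float,
    psi: float,
    magnitudes_exponent: float,
) -> np.ndarray:
    """Bead positions for one AD in topology order (ring, tails, head).

    ``anchor`` is the point on the core surface/axis the radial axis passes
    through minus the radial origin — positions are ``anchor + r * u`` for
    signed radius r.  ``magnitudes_exponent`` is 1/3 for spherical cores
    (solid-sphere density) and 1/2 for cylindrical cores (uniform disc).
    """
    T = spec.n_tail_beads
    n_core = T + 1
    R = core_radius
    signed = [R]  # ring
    for t in range(1, T):
        j = n_core - t
        signed.append(R * (j / n_core) ** magnitudes_exponent)
    signed.append(R * (1.0 - interdigitation))  # terminal tail bead

    e1, e2 = _local_frame(u)
    positions = [anchor + r * u for r in signed]

    # dendron head outward: nodes by tree level, terminals fanned out.  The
    # 0.25 nm shell spacing reproduces overall micelle radii ~2.1 nm for a
    # 1.1 nm core (heads pack more tightly than the bonded rest length).
    g = spec.generation
    _parents, levels, _tp = cg.dendron_nodes(g)
    for i, level in enumerate(levels):
        h = i - (2 ** level - 1)
        phi = 2.0 * math.pi * (h + 0.5) / 2 ** level + psi
        tang = 0.30 * level / (g + 1)
        radial = R + HEAD_SHELL * (level + 1)
        positions.append(
            anchor + radial * u + tang * (math.cos(phi) * e1 + math.sin(phi) * e2)
        )
    M = spec.n_terminal
    for m in range(M):
        phi = 2.0 * math.pi * (m + 0.5) / M + psi
        radial = R + HEAD_SHELL * (g + 2)
        positions.append(
            anchor + radial * u + 0.35 * (math.cos(phi) * e1 + math.sin(phi) * e2)
        )
    return np.asarray(positions)


def ad_outer_radius(spec: cg.ADSpec, core_radius: float) -> float:
    """Approximate outermost head-bead radius of a generated micelle."""
    return core_radius + HEAD_SHELL * (spec.generation + 2) + 0.35


def generate_micelle(
    spec: cg.ADSpec,
    n_ads: int,
    shape: str = "sphere",
    core_radius_target: float = 1.1,
    seed: int = 0,
    interdigitation: float = 1.4,
    jitter: float = 0.02,
    rod_half_length: float | None = None,
    box: np.ndarray | None = None,
) -> Frame:
    """A single pre-assembled micelle: tails inward, ring beads at the core
    surface, dendron heads outward.  Deterministic for a given seed.
    """
    if n_ads < 2:
        raise ValueError("a micelle needs at least 2 ADs")
    if shape not in ("sphere", "rod"):
        raise ValueError(f"unknown shape {shape!r}")
    R = float(core_radius_target)
    if R <= 0:
        raise ValueError("core_radius_target must be positive")

    ads_per_ring = 8
    ring_spacing = 0.4  # nm between rings of AD anchors along the rod axis
    if shape == "sphere":
        area = 4.0 * math.pi * R * R
        if area / n_ads < _MIN_AREA_PER_ANCHOR:
            raise ValueError(
                f"infeasible packing: {n_ads} ADs on a sphere core of radius "
                f"{R} nm ({area / n_ads:.3f} nm^2 per AD)"
            )
    else:
        n_rings = math.ceil(n_ads / ads_per_ring)
        if rod_half_length is not None:
            hl = float(rod_half_length)
            ring_spacing = 2.0 * hl / max(n_rings - 1, 1)
        else:
            hl = ring_spacing * (n_rings - 1) / 2.0
        ring_area = 2.0 * math.pi * R * ring_spacing / ads_per_ring
        if ring_area < _MIN_AREA_PER_ANCHOR:
            raise ValueError(
                f"infeasible packing: rod core radius {R} nm leaves only "
                f"{ring_area:.3f} nm^2 per AD anchor"
            )
    rng = np.random.default_rng(seed)
    outer = ad_outer_radius(spec, R)
    if shape == "sphere":
        hl = 0.0
    if box is None:
        # comfortably larger than twice the extent so unwrapping is unambiguous
        side = 4.4 * (outer + hl) + 2.0
        box = np.array([side, side, side])
    else:
        box = np.asarray(box, dtype=float)
    center = box / 2.0

    all_pos = []
    psis = rng.uniform(0.0, 2.0 * math.pi, size=n_ads)
    if shape == "sphere":
        dirs = fibonacci_sphere(n_ads)
        for k in range(n_ads):
            all_pos.append(
                _ad_molecule_positions(
                    spec, center, dirs[k], R, interdigitation, psis[k], 1.0 / 3.0
                )
            )
    else:
        # staggered rings of anchors along z; tails converge on the axis so
        # successive rings stay single-linkage connected
        for k in range(n_ads):
            ring, pos_in_ring = divmod(k, ads_per_ring)
            z = -hl + ring * ring_spacing
            phi = 2.0 * math.pi * (pos_in_ring + 0.5) / ads_per_ring + ring * _GOLDEN_ANGLE
            u = np.array([math.cos(phi), math.sin(phi), 0.0])
            anchor = center + np.array([0.0, 0.0, z])
            all_pos.append(
                _ad_molecule_positions(
                    spec, anchor, u, R, interdigitation, psis[k], 0.5
                )
            )

    positions = np.concatenate(all_pos)
    positions = positions + rng.normal(0.0, jitter, size=positions.shape)

    topo = cg.build_ad_topology(spec)
    one = topo.bead_dataframe()
    tables = []
    for k in range(n_ads):
        t = one.copy()
        t["molecule_id"] = k
        t["molecule_kind"] = "AD"
        tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    return Frame(positions, box, table)


def _pad_nucleic_columns(table: pd.DataFrame) -> pd.DataFrame:
    for col, default in (("resid", 0), ("strand", -1), ("basepair", -1)):
        if col not in table.columns:
            table[col] = default
        table[col] = table[col].fillna(default).astype(int)
    return table


def merge_frames(frames: list, box: np.ndarray) -> Frame:
    """Concatenate frames, renumbering molecule ids to stay unique."""
    offset = 0
    tables = []
    positions = []
    for f in frames:
        t = f.beads.copy()
        t["molecule_id"] = t["molecule_id"] + offset
        offset = int(t["molecule_id"].max()) + 1
        tables.append(_pad_nucleic_columns(t))
        positions.append(f.positions)
    table = pd.concat(tables, ignore_index=True)
    return Frame(np.concatenate(positions), np.asarray(box, float), table)


def generate_complex(
    micelle_specs: list,
    duplex: cg.NucleicDuplexSpec,
    com_distances: list,
    seed: int = 0,
    box: np.ndarray | None = None,
    min_separation: float = 0.3,
) -> Frame:
    """siRNA at the box centre with micelles at requested COM distances.

    ``micelle_specs`` is a list of dicts of :func:`generate_micelle` keyword
    arguments (``spec``, ``n_ads``, ``core_radius_target``, ...), one per
    micelle; ``com_distances`` gives the target siRNA-micelle COM distance
    for each.  Raises if the requested geometry would overlap beads closer
    than ``min_separation``.
    """
    if len(micelle_specs) != len(com_distances):
        raise ValueError("need one COM distance per micelle")
    rng = np.random.default_rng(seed)

    _topo, sirna = cg.build_sirna_topology(duplex)

    micelles = []
    outer_max = 0.0
    for i, kwargs in enumerate(micelle_specs):
        kw = dict(kwargs)
        kw.setdefault("seed", int(rng.integers(2 ** 31)))
        mic = generate_micelle(**kw)
        micelles.append(mic)
        outer_max = max(outer_max, ad_outer_radius(kw["spec"], kw.get("core_radius_target", 1.1)))

    if box is None:
        reach = (max(com_distances) if com_distances else 0.0) + outer_max + 3.0
        box = np.array([2.0 * reach] * 3)
    else:
        box = np.asarray(box, dtype=float)
    center = box / 2.0

    sirna_com = group_com(sirna.positions, sirna.beads["mass"].to_numpy())
    sirna_shift = Frame(sirna.positions - sirna_com + center, None, sirna.beads)

    # Micelles surround the duplex (axis along z) beads-on-string style:
    # spread in azimuth and modestly along the axis, keeping the
    # perpendicular offset large enough that dendron heads reach the
    # backbone without interpenetrating it.
    placed = [sirna_shift]
    n_mic = len(micelles)
    if n_mic:
        helix_extent = float(
            sirna.positions[:, 2].max() - sirna.positions[:, 2].min()
        )
        d_min = min(com_distances)
        perp_req = 0.9 + (outer_max - 0.35) + 0.3
        h_spread = min(
            helix_extent - 1.0,
            2.0 * math.sqrt(max(d_min ** 2 - perp_req ** 2, 0.0)),
        )
        h_spread = max(h_spread, 0.0)
    for i, (mic, d) in enumerate(zip(micelles, com_distances)):
        com = group_com(mic.positions, mic.beads["mass"].to_numpy())
        phi = 2.0 * math.pi * i / n_mic
        z = ((i + 0.5) / n_mic - 0.5) * h_spread
        z = float(np.clip(z, -abs(d) + 1e-9, abs(d) - 1e-9))
        perp = math.sqrt(max(d * d - z * z, 0.0))
        target = center + np.array(
            [perp * math.cos(phi), perp * math.sin(phi), z]
        )
        placed.append(Frame(mic.positions - com + target, None, mic.beads))

    merged = merge_frames(placed, box)

    # overlap check across molecules from different components
    labels = np.concatenate(
        [np.full(f.n_beads, i) for i, f in enumerate(placed)]
    )
    tree = cKDTree(wrap_positions(merged.positions, box), boxsize=box)
    for i, j in tree.query_pairs(min_separation):
        if labels[i] != labels[j]:
            raise ValueError(
                "geometric infeasibility: requested COM distances place beads "
                f"closer than {min_separation} nm"
            )
    return merged


def solvate_and_neutralize(
    frame: Frame,
    nacl_mM: float = 150.0,
    seed: int = 0,
    include_water: bool = True,
    exclusion: float = 0.45,
    water_density: float = WATER_BEAD_DENSITY,
    lattice_jitter: float = 0.12,
) -> Frame:
    """Add 4:1-mapped water beads and NaCl at the given concentration.

    Water beads sit on a jittered cubic lattice at the MARTINI water bead
    density, excluding sites within ``exclusion`` of any solute bead.  Ion
    pairs are drawn at ``nacl_mM`` for the box volume, plus counterions so
    the total system charge is exactly zero.
    """
    if frame.box is None:
        raise ValueError("solvation requires a frame with a box")
    box = frame.box
    rng = np.random.default_rng(seed)

    spacing = water_density ** (-1.0 / 3.0)
    n_cells = np.maximum(1, np.floor(box / spacing).astype(int))
    axes = [
        (np.arange(n) + 0.5) * (box[d] / n)
        for d, n in enumerate(n_cells)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    sites = sites + rng.uniform(
        -lattice_jitter * spacing, lattice_jitter * spacing, size=sites.shape
    )
    sites = wrap_positions(sites, box)

    if frame.n_beads:
        solute_tree = cKDTree(wrap_positions(frame.positions, box), boxsize=box)
        d, _ = solute_tree.query(sites, k=1)
        sites = sites[d > exclusion]

    volume = float(np.prod(box))
    n_pairs = int(round(nacl_mM * _MM_TO_PER_NM3 * volume))
    net = int(round(frame.total_charge()))
    n_na = n_pairs + max(-net, 0)
    n_cl = n_pairs + max(net, 0)
    if n_na + n_cl > len(sites):
        raise ValueError(
            f"not enough solvent sites ({len(sites)}) for {n_na + n_cl} ions"
        )
    order = rng.permutation(len(sites))
    na_sites = sites[order[:n_na]]
    cl_sites = sites[order[n_na:n_na + n_cl]]
    water_sites = sites[order[n_na + n_cl:]] if include_water else np.empty((0, 3))

    next_id = int(frame.beads["molecule_id"].max()) + 1 if frame.n_beads else 0

    def _rows(pos, name, mtype, charge, role, kind, start):
        n = len(pos)
        return pd.DataFrame(
            {
                "name": name,
                "martini_type": mtype,
                "charge": charge,
                "mass": BEAD_MASS,
                "role": role,
                "molecule_id": np.arange(start, start + n),
                "molecule_kind": kind,
            }
        )

    parts = [_pad_nucleic_columns(frame.beads.copy())] if frame.n_beads else []
    pos_parts = [frame.positions] if frame.n_beads else []
    na_tab = _rows(na_sites, "NA", "Qd", 1, "ion-Na", "Na", next_id)
    next_id += len(na_sites)
    cl_tab = _rows(cl_sites, "CL", "Qa", -1, "ion-Cl", "Cl", next_id)
    next_id += len(cl_sites)
    parts += [_pad_nucleic_columns(na_tab), _pad_nucleic_columns(cl_tab)]
    pos_parts += [na_sites, cl_sites]
    if include_water:
        w_tab = _rows(water_sites, "W", "P4", 0, "water", "water", next_id)
        parts.append(_pad_nucleic_columns(w_tab))
        pos_parts.append(water_sites)

    table = pd.concat(parts, ignore_index=True)
    return Frame(np.concatenate(pos_parts), box, table)


def _fusion_schedule(n_frames: int) -> np.ndarray:
    """Scripted COM-distance series: 9 -> plateau 6 -> plateau 2 -> merge."""
    n1 = max(1, round(0.25 * n_frames))
    n2 = max(1, round(0.20 * n_frames))
    n3 = max(1, round(0.25 * n_frames))
    n4 = max(1, round(0.20 * n_frames))
    n5 = n_frames - (n1 + n2 + n3 + n4)
    while n5 < 1:
        n1 -= 1
        n5 = n_frames - (n1 + n2 + n3 + n4)
    return np.concatenate(
        [
            np.linspace(9.0, 6.0, n1, endpoint=False),
            np.full(n2, 6.0),
            np.linspace(6.0, 2.0, n3, endpoint=False),
            np.full(n4, 2.0),
            np.linspace(2.0, 0.8, n5),
        ]
    )


def generate_fusion_trajectory(
    micelle_a: Frame,
    micelle_b: Frame,
    n_frames: int = 60,
    seed: int = 0,
    include_water: bool = True,
    nacl_mM: float = 150.0,
    noise_sigma: float = NOISE_SIGMA,
    n_bridge: int = 8,
    total_time_ns: float = 100.0,
) -> Trajectory:
    """A scripted two-micelle fusion approach with a shared ion cloud.

    Micelle B approaches micelle A along x following the plateau structure
    of a counterion-mediated fusion: start at ~9 nm COM distance, plateau
    near 6 nm (counterion bridging), approach, plateau near 2 nm, merge.
    ``n_bridge`` designated chloride beads track the inter-micelle midpoint
    each frame so shared-counterion contacts precede hydrophobic tail
    contacts deterministically.  Molecule ids: micelle A keeps its ids,
    micelle B's ids follow; isotropic Gaussian noise (sigma
    ``noise_sigma``) is added per bead per frame.
    """
    if n_frames < 5:
        raise ValueError("a fusion trajectory needs at least 5 frames")
    rng = np.random.default_rng(seed)

    com_a_0 = group_com(micelle_a.positions, micelle_a.beads["mass"].to_numpy())
    com_b_0 = group_com(micelle_b.positions, micelle_b.beads["mass"].to_numpy())
    r_a = float(np.linalg.norm(micelle_a.positions - com_a_0, axis=1).max())
    r_b = float(np.linalg.norm(micelle_b.positions - com_b_0, axis=1).max())

    d0 = 9.0
    # x length must exceed twice the initial separation so the scripted
    # distance is also the minimum-image distance
    lx = max(d0 + r_a + r_b + 4.0, 2.0 * d0 + 2.0)
    ly = 2.0 * max(r_a, r_b) + 4.0
    box = np.array([lx, ly, ly])
    a_pos = np.array([r_a + 2.0, ly / 2.0, ly / 2.0])
    b_pos0 = a_pos + np.array([d0, 0.0, 0.0])

    fa = Frame(micelle_a.positions - com_a_0 + a_pos, None, micelle_a.beads)
    fb = Frame(micelle_b.positions - com_b_0 + b_pos0, None, micelle_b.beads)
    solute = merge_frames([fa, fb], box)
    n_a_mols = int(micelle_a.beads["molecule_id"].nunique())
    b_mask = (solute.beads["molecule_id"] >= n_a_mols).to_numpy()

    system = solvate_and_neutralize(
        solute, nacl_mM=nacl_mM, seed=int(rng.integers(2 ** 31)),
        include_water=include_water,
    )
    cl_idx = system.select(role="ion-Cl")
    if len(cl_idx) < n_bridge:
        n_bridge = len(cl_idx)
    mid0 = (a_pos + b_pos0) / 2.0
    order = np.argsort(np.linalg.norm(system.positions[cl_idx] - mid0, axis=1))
    bridge = cl_idx[order[:n_bridge]]

    b_beads = np.flatnonzero(
        ((system.beads["molecule_kind"] == "AD").to_numpy())
        & (system.beads["molecule_id"].to_numpy() >= n_a_mols)
    )
    assert b_mask.sum() == len(b_beads)

    distances = _fusion_schedule(n_frames)
    times = np.linspace(0.0, total_time_ns, n_frames)
    frames = []
    for f, d in enumerate(distances):
        pos = system.positions.copy()
        pos[b_beads, 0] += d - d0
        mid = (a_pos + (a_pos + np.array([d, 0.0, 0.0]))) / 2.0
        offsets = rng.normal(0.0, 0.25, size=(len(bridge), 3))
        pos[bridge] = mid + offsets
        pos = pos + rng.normal(0.0, noise_sigma, size=pos.shape)
        frames.append(Frame(wrap_positions(pos, box), box, system.beads))
    return Trajectory(frames, times)


def static_trajectory(
    frame: Frame,
    n_frames: int,
    seed: int = 0,
    noise_sigma: float = NOISE_SIGMA,
    dt_ns: float = 1.0,
) -> Trajectory:
    """n_frames noisy copies of one configuration (an equilibrated window)."""
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        pos = frame.positions + rng.normal(0.0, noise_sigma, size=frame.positions.shape)
        if frame.box is not None:
            pos = wrap_positions(pos, frame.box)
        frames.append(Frame(pos, frame.box, frame.beads))
    return Trajectory(frames, np.arange(n_frames) * dt_ns)
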