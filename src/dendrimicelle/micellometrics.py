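"""Micelle descriptors: radii, packing parameter, shape, interdigitation.

The Israelachvili packing parameter P = v0 / (a l0) predicts aggregate
shape from the hydrophobic-chain volume v0, the core area per molecule a,
and the critical tail length l0: P <= 0.33 spherical micelle,
0.33 < P <= 0.50 cylinder, larger values bilayer.  For a spherical core of
radius R made of N molecules,

    V = (4/3) pi R^3,  A = 4 pi R^2,  R = 3 V / A = 3 v0 / a,

so P reduces to R / (3 l0).  Radii are estimated from radii of gyration
with the uniform-solid-sphere factor sqrt(5/3) (configurable): the micelle
radius from all aggregate beads, the core radius from hydrophobic beads
only.  Derived indices: interdigitation I_d = l0 / R (tails interpenetrate
the core when I_d > 1), surface charge density sigma_m = e N_agg / S_m,
area per amine S_m / (N_agg * amines-per-AD), and the N/P ratio of a
complex counted as (total bound ADs) / (core phosphates) — the convention
the source data tabulates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aggregation as agg_mod
from . import interactions as inter
from .cg_builder import ADSpec, NucleicDuplexSpec
from .frames import HYDROPHOBIC_ROLES, Frame, Trajectory

#: Rg -> radius conversion for a uniform solid sphere.
RG_TO_RADIUS = math.sqrt(5.0 / 3.0)

#: Relative shape anisotropy above which an aggregate is reported rod-like.
KAPPA2_ROD_THRESHOLD = 0.2

SPHERE_P_MAX = 0.33
CYLINDER_P_MAX = 0.50


@dataclass
class MicelleGeometry:
    """All per-micelle shape/packing quantities (nm, nm^2, nm^3)."""

    n_agg: int
    rg: float = math.nan
    micelle_radius: float = math.nan
    core_radius: float = math.nan
    tail_length: float = math.nan
    core_volume: float = math.nan
    core_area: float = math.nan
    surface_area: float = math.nan
    headgroup_volume: float = math.nan
    v0: float = math.nan
    area_per_molecule: float = math.nan
    packing_parameter: float = math.nan
    shape_class: str = "degenerate"
    kappa2: float = math.nan
    rod_radii: tuple | None = None
    interdigitation: float = math.nan
    surface_charge_density: float = math.nan
    area_per_amine: float = math.nan
    degenerate: bool = False

    @property
    def rodlike(self) -> bool:
        return bool(self.kappa2 > KAPPA2_ROD_THRESHOLD)


@dataclass
class DerivedIndices:
    interdigitation: float
    surface_charge_density: float
    area_per_amine: float
    np_ratio: float | None = None


@dataclass
class ComplexReport:
    bound_micelles: list
    amines_in_contact: list
    total_amines_in_contact: float
    np_ratio: float
    sirna_sasa: float


def sphere_core_descriptors(core_radius: float) -> tuple:
    """(V, A) of a spherical core; satisfies R = 3V/A identically."""
    if core_radius <= 0:
        raise ValueError("core radius must be positive")
    V = 4.0 / 3.0 * math.pi * core_radius ** 3
    A = 4.0 * math.pi * core_radius ** 2
    return V, A


def packing_and_shape(v0: float, a: float, l0: float) -> tuple:
    """Packing parameter P = v0/(a l0) and its shape class.

    For a spherical core P reduces to R/(3 l0).  Thresholds are closed at
    the sphere side: P = 0.33 -> sphere, P = 0.34 -> cylinder."""
    if v0 <= 0 or a <= 0 or l0 <= 0:
        raise ValueError("v0, a and l0 must all be positive")
    P = v0 / (a * l0)
    if P <= SPHERE_P_MAX:
        shape = "sphere"
    elif P <= CYLINDER_P_MAX:
        shape = "cylinder"
    else:
        shape = "bilayer"
    return P, shape


def _gyration(coords: np.ndarray, masses: np.ndarray) -> tuple:
    """(Rg, kappa^2, eigenvalues desc, principal axis)."""
    w = masses / masses.sum()
    com = (coords * w[:, None]).sum(axis=0)
    rel = coords - com
    tensor = (w[:, None, None] * rel[:, :, None] * rel[:, None, :]).sum(axis=0)
    evals, evecs = np.linalg.eigh(tensor)
    evals = evals[::-1]
    axis = evecs[:, -1]
    rg = math.sqrt(max(evals.sum(), 0.0))
    s = evals.sum()
    if s <= 0:
        return rg, 0.0, evals, axis
    kappa2 = 1.0 - 3.0 * (
        evals[0] * evals[1] + evals[1] * evals[2] + evals[2] * evals[0]
    ) / s ** 2
    return rg, float(kappa2), evals, axis


def _rod_cross_radii(coords: np.ndarray, axis: np.ndarray, n_segments: int = 3) -> tuple:
    """(min, max) cylinder cross-section radii along the principal axis."""
    t = coords @ axis
    centroid = coords.mean(axis=0)
    rel = (coords - centroid) - np.outer((coords - centroid) @ axis, axis)
    r_perp2 = (rel * rel).sum(axis=1)
    order = np.argsort(t)
    segs = np.array_split(order, n_segments)
    radii = [math.sqrt(2.0 * r_perp2[s].mean()) for s in segs if len(s)]
    return (min(radii), max(radii))


def micelle_geometry(
    frame: Frame,
    aggregate,
    spec: ADSpec,
    rg_factor: float = RG_TO_RADIUS,
    cluster_cutoff: float = agg_mod.CLUSTER_CUTOFF,
) -> MicelleGeometry:
    """Compute all geometric descriptors of one aggregate.

    Aggregates of fewer than 2 molecules are marked degenerate (a lone AD
    has no meaningful core geometry)."""
    members = aggregate.members if hasattr(aggregate, "members") else frozenset(aggregate)
    geo = MicelleGeometry(n_agg=len(members))
    if len(members) < 2:
        geo.degenerate = True
        return geo

    idx, coords, _ok = agg_mod.unwrap_aggregate_members(frame, members, cluster_cutoff)
    masses = frame.masses(idx)
    roles = frame.beads["role"].to_numpy()[idx]
    mols = frame.beads["molecule_id"].to_numpy()[idx]

    rg, kappa2, _evals, axis = _gyration(coords, masses)
    geo.rg = rg
    geo.kappa2 = kappa2
    geo.micelle_radius = rg_factor * rg

    hydro = np.isin(roles, list(HYDROPHOBIC_ROLES))
    rg_core, _k2c, _e, _ax = _gyration(coords[hydro], masses[hydro])
    R = rg_factor * rg_core
    geo.core_radius = R
    geo.core_volume, geo.core_area = sphere_core_descriptors(R)
    geo.v0 = geo.core_volume / geo.n_agg
    geo.area_per_molecule = geo.core_area / geo.n_agg

    # l0: mean ring-to-terminal-tail-bead distance per molecule
    lengths = []
    for m in members:
        in_mol = mols == m
        ring = np.flatnonzero(in_mol & (roles == "ring"))
        tails = np.flatnonzero(in_mol & (roles == "tail"))
        if ring.size == 0 or tails.size == 0:
            continue
        terminal = tails.max()  # tail beads are ordered ring -> terminus
        lengths.append(float(np.linalg.norm(coords[ring[0]] - coords[terminal])))
    geo.tail_length = float(np.mean(lengths)) if lengths else math.nan

    geo.surface_area = 4.0 * math.pi * geo.micelle_radius ** 2
    geo.headgroup_volume = (
        4.0 / 3.0 * math.pi * geo.micelle_radius ** 3 - geo.core_volume
    )
    geo.packing_parameter, geo.shape_class = packing_and_shape(
        geo.v0, geo.area_per_molecule, geo.tail_length
    )
    if geo.rodlike:
        geo.rod_radii = _rod_cross_radii(coords[hydro], axis)
        if geo.shape_class == "sphere":
            geo.shape_class = "cylinder"

    d = derived_indices(geo, spec)
    geo.interdigitation = d.interdigitation
    geo.surface_charge_density = d.surface_charge_density
    geo.area_per_amine = d.area_per_amine
    return geo


def derived_indices(
    geometry: MicelleGeometry,
    spec: ADSpec,
    duplex: NucleicDuplexSpec | None = None,
    bound_micelles=None,
) -> DerivedIndices:
    """Interdigitation, surface charge density, area per amine, N/P ratio.

    I_d = l0 / R;  sigma_m = e N_agg / S_m with e = amines per AD;
    area per amine = S_m / (N_agg e).  When a duplex and the bound micelle
    aggregation numbers are given, N/P = (sum of bound N_agg) / core
    phosphates."""
    if not geometry.surface_area > 0:
        raise ValueError("surface area must be positive")
    if not geometry.core_radius > 0:
        raise ValueError("core radius must be positive")
    e = spec.n_terminal
    np_ratio = None
    if duplex is not None and bound_micelles is not None:
        total = sum(
            m.n_agg if hasattr(m, "n_agg") else int(m) for m in bound_micelles
        )
        np_ratio = total / duplex.n_phosphates_core
    return DerivedIndices(
        interdigitation=geometry.tail_length / geometry.core_radius,
        surface_charge_density=e * geometry.n_agg / geometry.surface_area,
        area_per_amine=geometry.surface_area / (geometry.n_agg * e),
        np_ratio=np_ratio,
    )


def hydrophobic_sasa_fraction(
    frame: Frame,
    aggregate,
    probe_radius: float = inter.DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = inter.DEFAULT_SPHERE_POINTS,
) -> float:
    """SASA of tail+ring beads over SASA of all beads of the aggregate,
    both computed on the isolated (unwrapped) aggregate."""
    members = aggregate.members if hasattr(aggregate, "members") else frozenset(aggregate)
    idx, coords, _ok = agg_mod.unwrap_aggregate_members(frame, members)
    roles = frame.beads["role"].to_numpy()[idx]
    radii = inter.bead_radii(frame, idx)
    hydro = np.flatnonzero(np.isin(roles, list(HYDROPHOBIC_ROLES)))
    total = inter.shrake_rupley(coords, radii, probe_radius, n_sphere_points)
    core = inter.shrake_rupley(coords, radii, probe_radius, n_sphere_points, subset=hydro)
    return core / total


# ---------------------------------------------------------------------------
# table-style reports
# ---------------------------------------------------------------------------

def micelle_table(
    source,
    spec: ADSpec,
    cluster_cutoff: float = agg_mod.CLUSTER_CUTOFF,
    last_fraction: float = 0.25,
    min_size: int = 2,
) -> pd.DataFrame:
    """Per-micelle geometry report (one row per micelle, mean row appended).

    ``source`` is a Frame or a Trajectory; for trajectories, descriptors
    are averaged per lineage over the final ``last_fraction`` of frames."""
    if isinstance(source, Frame):
        frames = [source]
    else:
        frames = source.window(last_fraction).frames

    per_lineage: dict = {}
    for f, frame in enumerate(frames):
        for aggregate in agg_mod.detect_aggregates(frame, cluster_cutoff, frame_index=f):
            if aggregate.n_agg < min_size:
                continue
            geo = micelle_geometry(frame, aggregate, spec, cluster_cutoff=cluster_cutoff)
            key = min(aggregate.members)
            per_lineage.setdefault(key, []).append(geo)

    rows = []
    for key in sorted(per_lineage):
        geos = per_lineage[key]
        rows.append(
            {
                "n_ads": int(round(np.mean([g.n_agg for g in geos]))),
                "micelle_radius_nm": np.mean([g.micelle_radius for g in geos]),
                "core_radius_nm": np.mean([g.core_radius for g in geos]),
                "tail_length_nm": np.mean([g.tail_length for g in geos]),
                "surface_area_nm2": np.mean([g.surface_area for g in geos]),
                "core_volume_nm3": np.mean([g.core_volume for g in geos]),
                "headgroup_volume_nm3": np.mean([g.headgroup_volume for g in geos]),
                "packing_parameter": np.mean([g.packing_parameter for g in geos]),
                "shape": geos[-1].shape_class,
                "interdigitation": np.mean([g.interdigitation for g in geos]),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        mean_row = table.drop(columns=["shape"]).mean(numeric_only=True)
        mean_row["shape"] = "mean"
        table = pd.concat([table, mean_row.to_frame().T], ignore_index=True)
    return table


def amine_table(
    window: Trajectory,
    micelle_members: list,
    spec: ADSpec,
    bound_cutoff: float = inter.BOUND_COM_CUTOFF,
    contact_cutoff: float = inter.CONTACT_CUTOFF,
) -> pd.DataFrame:
    """Per-micelle amine-binding report (amines per micelle, mean +/- sem
    amines bound to siRNA, surface area per amine)."""
    stats = inter.amine_binding_stats(
        window, micelle_members, bound_cutoff, contact_cutoff
    )
    frame = window.frames[-1]
    areas = []
    for members in micelle_members:
        aggregate = frozenset(members)
        geo = micelle_geometry(frame, aggregate, spec)
        areas.append(
            geo.surface_area / (geo.n_agg * spec.n_terminal)
            if not geo.degenerate
            else math.nan
        )
    stats["area_per_amine_nm2"] = areas
    return stats


def complex_report(
    window: Trajectory,
    micelle_members: list,
    spec: ADSpec,
    duplex: NucleicDuplexSpec,
    bound_cutoff: float = inter.BOUND_COM_CUTOFF,
    sasa_points: int = 240,
) -> ComplexReport:
    """Bound-micelle summary: amine contacts, N/P ratio, siRNA SASA."""
    stats = inter.amine_binding_stats(window, micelle_members, bound_cutoff)
    bound = stats[stats["bound"]]
    frame = window.frames[-1]
    sirna = frame.select(molecule_kind="siRNA")
    solute = np.concatenate(
        [sirna, frame.select(molecule_kind="AD")]
    )
    sirna_sasa = inter.sasa(
        frame, sirna, n_sphere_points=sasa_points, context=solute
    )
    np_ratio = float(bound["n_agg"].sum()) / duplex.n_phosphates_core
    return ComplexReport(
        bound_micelles=bound["micelle"].tolist(),
        amines_in_contact=bound["mean_amines_bound"].tolist(),
        total_amines_in_contact=float(bound["mean_amines_bound"].sum()),
        np_ratio=np_ratio,
        sirna_sasa=sirna_sasa,
    )
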