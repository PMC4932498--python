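"""Aggregate detection and tracking under periodic boundaries.

An aggregate is a single-linkage connected component of AD molecules: two
ADs are linked when any pair of their hydrophobic (tail + ring) beads lies
within the clustering cutoff under the minimum-image convention.  The
cutoff (default 0.6 nm, the first MARTINI neighbour shell) is a knob — the
underlying simulations never state their aggregate criterion.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .frames import (
    HYDROPHOBIC_ROLES,
    HEAD_ROLES,
    Frame,
    Trajectory,
    group_com,
    minimum_image,
    wrap_positions,
)

#: Single-linkage clustering cutoff between hydrophobic beads (nm).
CLUSTER_CUTOFF = 0.6
#: Shared-solvent (solvation shell) cutoff (nm).
SOLVATION_CUTOFF = 0.65
#: Bead-bead contact cutoff (nm).
CONTACT_CUTOFF = 0.75


@dataclass(frozen=True)
class Aggregate:
    """One cluster of AD molecules in one frame."""

    frame_index: int
    members: frozenset
    centroid: np.ndarray = field(compare=False)
    unwrappable: bool = field(default=True, compare=False)

    @property
    def n_agg(self) -> int:
        """Aggregation number: ADs in the micelle."""
        return len(self.members)


@dataclass
class FusionProfile:
    """Per-frame observables of a two-aggregate fusion event."""

    times: np.ndarray
    com_distance: np.ndarray
    shared_chloride: np.ndarray
    shared_water: np.ndarray
    hydrophilic_contacts: np.ndarray
    hydrophobic_contacts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in (
            "com_distance",
            "shared_chloride",
            "shared_water",
            "hydrophilic_contacts",
            "hydrophobic_contacts",
        ):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length differs from times")
            setattr(self, name, arr)


def _linkage_pairs(frame: Frame, cutoff: float):
    """(molecule ids array, bead-level linked molecule pairs) at the cutoff."""
    hydro = frame.select(role=HYDROPHOBIC_ROLES, molecule_kind="AD")
    mols = frame.beads["molecule_id"].to_numpy()
    ad_mols = np.unique(mols[frame.select(molecule_kind="AD")])
    if len(hydro) == 0:
        return ad_mols, np.empty((0, 2), dtype=int)
    pos = frame.positions[hydro]
    if frame.box is not None:
        if cutoff >= frame.box.min() / 2:
            raise ValueError("cutoff must be below half the smallest box length")
        tree = cKDTree(wrap_positions(pos, frame.box), boxsize=frame.box)
    else:
        tree = cKDTree(pos)
    pairs = np.array(sorted(tree.query_pairs(cutoff)), dtype=int).reshape(-1, 2)
    mol_pairs = np.column_stack([mols[hydro[pairs[:, 0]]], mols[hydro[pairs[:, 1]]]])
    mol_pairs = mol_pairs[mol_pairs[:, 0] != mol_pairs[:, 1]]
    return ad_mols, mol_pairs


def detect_aggregates(
    frame: Frame, cutoff: float = CLUSTER_CUTOFF, frame_index: int = 0
) -> list:
    """Partition AD molecules into single-linkage aggregates.

    Every AD belongs to exactly one aggregate; singletons are aggregates of
    one.  Aggregates are returned sorted by their smallest member id.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ad_mols, mol_pairs = _linkage_pairs(frame, cutoff)
    if len(ad_mols) == 0:
        raise ValueError("frame contains no AD molecules")
    index = {m: i for i, m in enumerate(ad_mols)}
    if len(mol_pairs):
        rows = np.array([index[a] for a in mol_pairs[:, 0]])
        cols = np.array([index[b] for b in mol_pairs[:, 1]])
        data = np.ones(len(rows))
        adj = coo_matrix((data, (rows, cols)), shape=(len(ad_mols), len(ad_mols)))
    else:
        adj = coo_matrix((len(ad_mols), len(ad_mols)))
    _n, labels = connected_components(adj, directed=False)

    aggregates = []
    for lab in np.unique(labels):
        members = frozenset(int(m) for m in ad_mols[labels == lab])
        idx, coords, ok = unwrap_aggregate_members(frame, members, cutoff)
        centroid = np.average(coords, axis=0, weights=frame.masses(idx))
        aggregates.append(Aggregate(frame_index, members, centroid, ok))
    aggregates.sort(key=lambda a: min(a.members))
    return aggregates


def unwrap_aggregate_members(frame: Frame, members, cutoff: float = CLUSTER_CUTOFF):
    """Unwrapped coordinates of all beads of the member molecules.

    Each molecule is first made whole around its own first bead; molecules
    are then placed by breadth-first traversal of the linkage graph so every
    linked pair sits at its minimum-image separation.  Returns
    (bead_indices, coords, unwrappable_flag); the flag is False when the
    unwrapped extent exceeds half the box in every dimension (ambiguous
    periodic image choice).
    """
    members = frozenset(members)
    mols = frame.beads["molecule_id"].to_numpy()
    bead_idx = np.flatnonzero(np.isin(mols, list(members)))
    box = frame.box
    positions = frame.positions
    if box is None:
        return bead_idx, positions[bead_idx].copy(), True

    # make each molecule whole around its first bead
    local = {}
    for m in members:
        bi = np.flatnonzero(mols == m)
        ref = positions[bi[0]]
        local[m] = (bi, ref + minimum_image(positions[bi] - ref, box))

    # molecule-level linkage graph from hydrophobic contacts
    _ads, mol_pairs = _linkage_pairs(frame, cutoff)
    neighbours = {m: set() for m in members}
    for a, b in mol_pairs:
        if a in neighbours and b in neighbours:
            neighbours[a].add(int(b))
            neighbours[b].add(int(a))

    placed = {}
    start = min(members)
    placed[start] = local[start][1]
    queue = [start]
    while queue:
        cur = queue.pop(0)
        cur_ref = placed[cur][0]
        for nb in sorted(neighbours[cur]):
            if nb in placed:
                continue
            nb_coords = local[nb][1]
            # position neighbour so its reference bead is at the minimum
            # image relative to the current molecule's reference bead
            delta = minimum_image(nb_coords[0] - cur_ref, box)
            placed[nb] = nb_coords - nb_coords[0] + cur_ref + delta
            queue.append(nb)
    # disconnected members (shouldn't happen for detected aggregates) are
    # placed at their minimum image relative to the start molecule
    for m in sorted(members):
        if m not in placed:
            coords = local[m][1]
            delta = minimum_image(coords[0] - placed[start][0], box)
            placed[m] = coords - coords[0] + placed[start][0] + delta

    out = np.empty((len(bead_idx), 3))
    pos_of = {int(b): i for i, b in enumerate(bead_idx)}
    for m in members:
        bi, _ = local[m]
        for b, c in zip(bi, placed[m]):
            out[pos_of[int(b)]] = c

    extent = out.max(axis=0) - out.min(axis=0)
    ok = not bool(np.all(extent > box / 2.0))
    if not ok:
        warnings.warn(
            "aggregate spans more than half the box in all dimensions; "
            "unwrapped geometry is ambiguous",
            stacklevel=2,
        )
    return bead_idx, out, ok


def unwrap_aggregate(frame: Frame, aggregate: Aggregate, cutoff: float = CLUSTER_CUTOFF):
    """Unwrapped (bead_indices, coords) for a detected aggregate."""
    idx, coords, _ok = unwrap_aggregate_members(frame, aggregate.members, cutoff)
    return idx, coords


def track_aggregates(trajectory: Trajectory, cutoff: float = CLUSTER_CUTOFF):
    """Link aggregates across frames by maximal member overlap.

    Returns (lineage_table, merge_events): the table has one row per
    (frame, lineage) with columns time, lineage, n_agg, members; merge
    events are rows (frame, time, winner, absorbed) recorded when two
    lineages map onto one aggregate.  Matching is greedy by overlap size,
    ties broken toward the lower lineage id.
    """
    if len(trajectory) < 2:
        raise ValueError("tracking needs at least 2 frames")
    rows = []
    merges = []
    prev: dict = {}
    next_lineage = 0
    for f, frame in enumerate(trajectory.frames):
        aggs = detect_aggregates(frame, cutoff, frame_index=f)
        assignments = {}
        if prev:
            candidates = []
            for ai, agg in enumerate(aggs):
                for lid, members in prev.items():
                    ov = len(agg.members & members)
                    if ov:
                        candidates.append((-ov, lid, ai))
            used_lineages = set()
            overlapping = {}
            for negov, lid, ai in sorted(candidates):
                overlapping.setdefault(ai, []).append(lid)
                if ai in assignments or lid in used_lineages:
                    continue
                assignments[ai] = lid
                used_lineages.add(lid)
            for ai, lids in overlapping.items():
                if ai in assignments:
                    winner = assignments[ai]
                    for lid in lids:
                        if lid != winner and lid not in used_lineages:
                            merges.append(
                                {
                                    "frame": f,
                                    "time": trajectory.times[f],
                                    "winner": winner,
                                    "absorbed": lid,
                                }
                            )
                            used_lineages.add(lid)
        current: dict = {}
        for ai, agg in enumerate(aggs):
            lid = assignments.get(ai)
            if lid is None:
                lid = next_lineage
                next_lineage += 1
            current[lid] = agg.members
            rows.append(
                {
                    "frame": f,
                    "time": trajectory.times[f],
                    "lineage": lid,
                    "n_agg": agg.n_agg,
                    "members": tuple(sorted(agg.members)),
                }
            )
        prev = current
    table = pd.DataFrame(rows)
    events = pd.DataFrame(merges, columns=["frame", "time", "winner", "absorbed"])
    return table, events


def _group_beads(frame: Frame, members) -> np.ndarray:
    mols = frame.beads["molecule_id"].to_numpy()
    return np.flatnonzero(np.isin(mols, list(members)))


def fusion_profile(
    trajectory: Trajectory,
    members_a,
    members_b,
    solvation_cutoff: float = SOLVATION_CUTOFF,
    contact_cutoff: float = CONTACT_CUTOFF,
) -> FusionProfile:
    """Fusion observables between two molecule groups over a trajectory.

    Per frame: COM distance between the groups; chloride/water beads within
    ``solvation_cutoff`` of beads of BOTH groups (shared solvation shell);
    hydrophilic (head-head) and hydrophobic (tail/ring) cross-group bead
    pairs within ``contact_cutoff``.
    """
    members_a = frozenset(members_a)
    members_b = frozenset(members_b)
    if not members_a or not members_b:
        raise ValueError("both groups must be non-empty")
    if members_a & members_b:
        raise ValueError("groups must be disjoint")

    frame0 = trajectory.frames[0]
    beads_a = _group_beads(frame0, members_a)
    beads_b = _group_beads(frame0, members_b)
    if len(beads_a) == 0 or len(beads_b) == 0:
        raise ValueError("groups do not exist over a common window")
    roles = frame0.beads["role"].to_numpy()
    head_a = beads_a[np.isin(roles[beads_a], list(HEAD_ROLES))]
    head_b = beads_b[np.isin(roles[beads_b], list(HEAD_ROLES))]
    hydro_a = beads_a[np.isin(roles[beads_a], list(HYDROPHOBIC_ROLES))]
    hydro_b = beads_b[np.isin(roles[beads_b], list(HYDROPHOBIC_ROLES))]
    cl_idx = frame0.select(role="ion-Cl")
    w_idx = frame0.select(role="water")

    n = len(trajectory)
    out = {
        "com": np.zeros(n),
        "cl": np.zeros(n, dtype=int),
        "w": np.zeros(n, dtype=int),
        "phil": np.zeros(n, dtype=int),
        "phob": np.zeros(n, dtype=int),
    }
    for f, frame in enumerate(trajectory.frames):
        box = frame.box
        masses = frame.beads["mass"].to_numpy()
        com_a = group_com(frame.positions[beads_a], masses[beads_a], box)
        com_b = group_com(frame.positions[beads_b], masses[beads_b], box)
        out["com"][f] = np.linalg.norm(minimum_image(com_a - com_b, box))

        wrapped = frame.wrapped() if box is not None else frame.positions
        kw = {"boxsize": box} if box is not None else {}
        tree_a = cKDTree(wrapped[beads_a], **kw)
        tree_b = cKDTree(wrapped[beads_b], **kw)
        for key, solvent in (("cl", cl_idx), ("w", w_idx)):
            if len(solvent) == 0:
                continue
            da, _ = tree_a.query(wrapped[solvent], k=1)
            db, _ = tree_b.query(wrapped[solvent], k=1)
            out[key][f] = int(np.sum((da <= solvation_cutoff) & (db <= solvation_cutoff)))
        for key, sel_a, sel_b in (
            ("phil", head_a, head_b),
            ("phob", hydro_a, hydro_b),
        ):
            ta = cKDTree(wrapped[sel_a], **kw)
            tb = cKDTree(wrapped[sel_b], **kw)
            out[key][f] = int(sum(len(hits) for hits in ta.query_ball_tree(tb, contact_cutoff)))

    return FusionProfile(
        times=np.asarray(trajectory.times),
        com_distance=out["com"],
        shared_chloride=out["cl"],
        shared_water=out["w"],
        hydrophilic_contacts=out["phil"],
        hydrophobic_contacts=out["phob"],
    )
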