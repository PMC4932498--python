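"""siRNA-micelle interaction metrics.

Contact counting, solvation-shell composition and per-base-pair radial
distribution functions all use minimum-image distances; SASA uses
Shrake-Rupley point sampling over per-bead spheres.  Default cutoffs follow
one consistent convention: 0.65 nm for solvation shells, 0.75 nm for
bead-bead contacts.  Default bead radius 0.26 nm (half the MARTINI
Lennard-Jones sigma of 0.47 nm, rounded up) and probe radius 0.26 nm (half
a water-bead diameter); both configurable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .frames import Frame, Trajectory, group_com, minimum_image, wrap_positions

DEFAULT_BEAD_RADIUS = 0.26  # nm
DEFAULT_PROBE_RADIUS = 0.26  # nm
DEFAULT_SPHERE_POINTS = 960
CONTACT_CUTOFF = 0.75  # nm
SOLVATION_CUTOFF = 0.65  # nm
BOUND_COM_CUTOFF = 5.0  # nm, micelle counts as siRNA-bound below this

_SPECIES_ROLE = {"water": "water", "Na": "ion-Na", "Cl": "ion-Cl"}


@dataclass
class RdfMap:
    """g(r) per siRNA base pair: rows are pairs 1..n, columns radial bins."""

    gr: np.ndarray  # (n_basepairs, n_bins)
    r_edges: np.ndarray
    species: str
    reference_density: float  # beads / nm^3
    window_ns: tuple = (0.0, 0.0)

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.gr, columns=np.round(self.r_centers, 4))
        df.insert(0, "basepair", np.arange(1, len(self.gr) + 1))
        return df


@dataclass
class ContactSeries:
    times: np.ndarray
    counts: np.ndarray
    selection_a: str = ""
    selection_b: str = ""
    cutoff: float = CONTACT_CUTOFF
    semantics: str = "pairs"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.counts):
            raise ValueError("times and counts must align")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("contact counts cannot be negative")


@dataclass
class SolvationSummary:
    species: str
    cutoff: float
    mean_count: float
    per_frame: np.ndarray
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.mean_count < 0:
            raise ValueError("mean count cannot be negative")


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _unit_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    subset: np.ndarray | None = None,
) -> float:
    """Solvent-accessible surface area (nm^2) of ``subset`` within the
    context of all ``coords``.

    Each bead's extended sphere (radius + probe) is sampled at
    ``n_sphere_points`` quasi-uniform points; points falling inside any
    other context bead's extended sphere are buried.  Exactly coincident
    spheres are resolved toward the lower bead index so a fully overlapping
    pair contributes a single sphere's area.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(coords),))
    if np.any(radii <= 0) or probe_radius < 0:
        raise ValueError("bead radii must be positive and probe non-negative")
    if len(coords) == 0:
        raise ValueError("selection is empty")
    subset = np.arange(len(coords)) if subset is None else np.asarray(subset)

    pts = _unit_sphere(n_sphere_points)
    extended = radii + probe_radius
    tree = cKDTree(coords)
    eps = 1e-9
    total = 0.0
    for i in subset:
        Ri = extended[i]
        sample = coords[i] + Ri * pts
        neigh = [j for j in tree.query_ball_point(coords[i], Ri + extended.max())
                 if j != i]
        if not neigh:
            total += 4.0 * np.pi * Ri * Ri
            continue
        nb = np.asarray(neigh)
        d = np.linalg.norm(sample[:, None, :] - coords[nb][None, :, :], axis=2)
        rj = extended[nb][None, :]
        buried = d < rj - eps
        # tie-break for points exactly on a neighbour's extended surface
        # (coincident identical spheres): the lower index keeps the area
        ties = np.abs(d - rj) <= eps
        buried |= ties & (nb[None, :] < i)
        exposed = ~np.any(buried, axis=1)
        total += 4.0 * np.pi * Ri * Ri * exposed.mean()
    return float(total)


def bead_radii(frame: Frame, indices: np.ndarray, radii=None) -> np.ndarray:
    """Per-bead SASA radii: scalar, or a dict keyed by MARTINI type."""
    if radii is None:
        return np.full(len(indices), DEFAULT_BEAD_RADIUS)
    if np.isscalar(radii):
        return np.full(len(indices), float(radii))
    types = frame.beads["martini_type"].to_numpy()[indices]
    return np.array([radii.get(t, DEFAULT_BEAD_RADIUS) for t in types])


def sasa(
    frame: Frame,
    selection: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    radii=None,
    context: np.ndarray | None = None,
) -> float:
    """SASA (nm^2) of ``selection`` beads, occluded by ``context`` beads
    (defaults to the selection itself)."""
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("selection is empty")
    context = selection if context is None else np.asarray(context)
    merged = np.unique(np.concatenate([selection, context]))
    sub = np.searchsorted(merged, selection)
    coords = frame.positions[merged]
    r = bead_radii(frame, merged, radii)
    return shrake_rupley(coords, r, probe_radius, n_sphere_points, subset=sub)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _tree(frame: Frame, indices: np.ndarray):
    if frame.box is not None:
        return cKDTree(frame.wrapped()[indices], boxsize=frame.box)
    return cKDTree(frame.positions[indices])


def count_contacts(
    frame: Frame,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    cutoff: float = CONTACT_CUTOFF,
    unique: bool = False,
) -> int:
    """Number of cross-selection bead pairs within ``cutoff`` (minimum
    image).  With ``unique=True``, counts distinct selection_a beads having
    at least one partner instead of pairs."""
    selection_a = np.asarray(selection_a)
    selection_b = np.asarray(selection_b)
    if selection_a.size == 0 or selection_b.size == 0:
        raise ValueError("selections must be non-empty")
    if np.intersect1d(selection_a, selection_b).size:
        raise ValueError("selections must be disjoint")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ta = _tree(frame, selection_a)
    tb = _tree(frame, selection_b)
    hits = ta.query_ball_tree(tb, cutoff)
    if unique:
        return int(sum(1 for h in hits if h))
    return int(sum(len(h) for h in hits))


def contact_series(
    trajectory: Trajectory,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    cutoff: float = CONTACT_CUTOFF,
    semantics: str = "pairs",
    label_a: str = "",
    label_b: str = "",
) -> ContactSeries:
    """Per-frame contact counts; ``semantics`` is 'pairs' (all cross pairs)
    or 'unique' (distinct selection_a beads in contact)."""
    if semantics not in ("pairs", "unique"):
        raise ValueError("semantics must be 'pairs' or 'unique'")
    counts = np.array(
        [
            count_contacts(f, selection_a, selection_b, cutoff, unique=semantics == "unique")
            for f in trajectory.frames
        ]
    )
    return ContactSeries(
        np.asarray(trajectory.times), counts, label_a, label_b, cutoff, semantics
    )


# ---------------------------------------------------------------------------
# solvation shell composition
# ---------------------------------------------------------------------------

def solvation_counts(
    window: Trajectory,
    target_selection: np.ndarray,
    species: str,
    cutoff: float = SOLVATION_CUTOFF,
    reference: float | None = None,
) -> SolvationSummary:
    """Mean number of species beads within ``cutoff`` of any target bead.

    ``species`` is one of 'water', 'Na', 'Cl'.  A missing species yields a
    zero count with a warning rather than an error."""
    if len(window) == 0:
        raise ValueError("empty analysis window")
    target_selection = np.asarray(target_selection)
    if target_selection.size == 0:
        raise ValueError("target selection is empty")
    role = _SPECIES_ROLE.get(species, species)
    counts = np.zeros(len(window))
    for f, frame in enumerate(window.frames):
        sp = frame.select(role=role)
        if sp.size == 0:
            continue
        tree = _tree(frame, target_selection)
        pos = frame.wrapped() if frame.box is not None else frame.positions
        d, _ = tree.query(pos[sp], k=1)
        counts[f] = int(np.sum(d <= cutoff))
    if all(frame.select(role=role).size == 0 for frame in window.frames):
        warnings.warn(f"species {species!r} absent from the window", stacklevel=2)
    return SolvationSummary(species, cutoff, float(counts.mean()), counts, reference)


# ---------------------------------------------------------------------------
# per-base-pair RDF
# ---------------------------------------------------------------------------

def basepair_coms(frame: Frame) -> np.ndarray:
    """Mass-weighted COM of each base pair (both paired nucleotides)."""
    beads = frame.beads
    if "basepair" not in beads.columns:
        raise ValueError("frame lacks base-pair annotation (assign_basepairs)")
    pairs = sorted(p for p in beads["basepair"].unique() if p > 0)
    if not pairs:
        raise ValueError("no base-pair annotation found (is siRNA present?)")
    coms = np.empty((len(pairs), 3))
    for i, p in enumerate(pairs):
        idx = np.flatnonzero((beads["basepair"] == p).to_numpy())
        coms[i] = group_com(frame.positions[idx], frame.masses(idx), frame.box)
    return coms


def rdf_per_basepair(
    window: Trajectory,
    species: str,
    bin_width: float = 0.1,
    r_max: float = 2.5,
) -> RdfMap:
    """g(r) of a species around each siRNA base-pair COM.

    Shell counts are normalized by shell volume and the species' bulk
    density (N/V per frame), averaged over the window; an ideal-gas species
    gives g ~= 1 outside the excluded core."""
    if len(window) == 0:
        raise ValueError("empty analysis window")
    frame0 = window.frames[0]
    if frame0.box is None:
        raise ValueError("RDF requires a periodic box")
    if r_max > frame0.box.min() / 2.0:
        raise ValueError("r_max must not exceed half the smallest box length")
    role = _SPECIES_ROLE.get(species, species)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    n_bins = len(edges) - 1
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    n_pairs = None
    acc = None
    density = 0.0
    n_sp_total = 0
    for frame in window.frames:
        coms = basepair_coms(frame)
        if n_pairs is None:
            n_pairs = len(coms)
            acc = np.zeros((n_pairs, n_bins))
        sp = frame.select(role=role)
        n_sp_total += sp.size
        if sp.size == 0:
            continue
        volume = float(np.prod(frame.box))
        density += sp.size / volume
        sp_pos = frame.positions[sp]
        for i, com in enumerate(coms):
            d = np.linalg.norm(minimum_image(sp_pos - com, frame.box), axis=1)
            hist, _ = np.histogram(d, bins=edges)
            acc[i] += hist
    if n_sp_total == 0:
        warnings.warn(f"species {species!r} absent: RDF map is all zero", stacklevel=2)
        return RdfMap(np.zeros((n_pairs, n_bins)), edges, species, 0.0,
                      (window.times[0], window.times[-1]))
    mean_density = density / len(window)
    gr = acc / (len(window) * shell_vol[None, :] * mean_density)
    return RdfMap(gr, edges, species, mean_density, (window.times[0], window.times[-1]))


# ---------------------------------------------------------------------------
# COM distances and plateaus
# ---------------------------------------------------------------------------

def com_distance_series(
    trajectory: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> np.ndarray:
    """Per-frame minimum-image distance between group centres of mass."""
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("groups must be non-empty")
    out = np.empty(len(trajectory))
    for f, frame in enumerate(trajectory.frames):
        masses = frame.beads["mass"].to_numpy()
        ca = group_com(frame.positions[group_a], masses[group_a], frame.box)
        cb = group_com(frame.positions[group_b], masses[group_b], frame.box)
        out[f] = np.linalg.norm(minimum_image(ca - cb, frame.box))
    return out


def find_plateaus(
    times: np.ndarray,
    values: np.ndarray,
    slope_tol: float = 0.01,
    min_frames: int = 10,
) -> list:
    """Plateau intervals: maximal runs where every sliding window of
    ``min_frames`` frames has |slope| < ``slope_tol`` (nm/ns).

    Returns a list of (start_index, end_index_inclusive, mean_value)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < min_frames:
        return []
    flat = np.zeros(n, dtype=bool)
    for s in range(0, n - min_frames + 1):
        e = s + min_frames
        slope = np.polyfit(times[s:e], values[s:e], 1)[0]
        if abs(slope) < slope_tol:
            flat[s:e] = True
    plateaus = []
    s = None
    for i in range(n):
        if flat[i] and s is None:
            s = i
        elif not flat[i] and s is not None:
            plateaus.append((s, i - 1, float(values[s:i].mean())))
            s = None
    if s is not None:
        plateaus.append((s, n - 1, float(values[s:].mean())))
    return plateaus


# ---------------------------------------------------------------------------
# amine binding statistics
# ---------------------------------------------------------------------------

def amine_binding_stats(
    window: Trajectory,
    micelle_members: list,
    bound_cutoff: float = BOUND_COM_CUTOFF,
    contact_cutoff: float = CONTACT_CUTOFF,
    stride: int = 1,
) -> pd.DataFrame:
    """Per-micelle mean +/- sem of terminal amines contacting siRNA.

    ``micelle_members`` is a list of molecule-id sets (one per micelle).
    A micelle is bound when its window-mean COM distance to siRNA is at
    most ``bound_cutoff``; per frame the number of distinct terminal-amine
    beads of the micelle within ``contact_cutoff`` of any siRNA bead is
    counted.  ``stride`` sub-samples frames for the sem (a crude
    decorrelation control)."""
    if len(window) == 0:
        raise ValueError("empty analysis window")
    frame0 = window.frames[0]
    sirna = frame0.select(molecule_kind="siRNA")
    if sirna.size == 0:
        raise ValueError("no siRNA in the frame")
    mols = frame0.beads["molecule_id"].to_numpy()
    roles = frame0.beads["role"].to_numpy()

    rows = []
    for mi, members in enumerate(micelle_members):
        members = frozenset(members)
        beads = np.flatnonzero(np.isin(mols, list(members)))
        amines = beads[roles[beads] == "terminal-amine"]
        com_d = com_distance_series(window, beads, sirna)
        counts = np.array(
            [
                count_contacts(f, amines, sirna, contact_cutoff, unique=True)
                for f in window.frames
            ],
            dtype=float,
        )
        sub = counts[::stride]
        sem = float(sub.std(ddof=1) / np.sqrt(len(sub))) if len(sub) > 1 else 0.0
        rows.append(
            {
                "micelle": mi,
                "n_agg": len(members),
                "total_amines": int(len(amines)),
                "mean_com_distance": float(com_d.mean()),
                "bound": bool(com_d.mean() <= bound_cutoff),
                "mean_amines_bound": float(counts.mean()),
                "sem_amines_bound": sem,
            }
        )
    return pd.DataFrame(rows)
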