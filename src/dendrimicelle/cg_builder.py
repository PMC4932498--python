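"""Coarse-grained topology builders for amphiphilic dendrimers and siRNA.

Amphiphilic dendrimers (ADs) are lipid/dendrimer hybrids: a PAMAM dendron
head of generation g (2^(g+1) protonated terminal amines) joined through a
single hydrophobic ring bead to an alkyl tail mapped at ~4 methylene units
per bead (13C -> 3, 15C -> 4, 18C -> 5 tail beads).  The siRNA duplex is
mapped one Qa bead per phosphate, one P1 bead per ribose, and 2-3 small
polar beads per base, with duplex shape maintained by an elastic network
(harmonic restraints, 1500 kJ mol^-1 nm^-2, between all bead pairs within
0.7 nm).

All distances are nm, forces kJ mol^-1 nm^-2 (angles: degrees and
kJ mol^-1 rad^-2).  Bead indices are 0-based in memory and 1-based in
exported GRO/ITP text.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .frames import BEAD_MASS, Frame

# ---------------------------------------------------------------------------
# constants: mapping rules and bonded defaults
# ---------------------------------------------------------------------------

#: Alkyl tail length (carbons) -> number of C1 tail beads (4:1 mapping).
TAIL_BEAD_COUNT = {13: 3, 15: 4, 18: 5}

SUPPORTED_GENERATIONS = (0, 1, 2)

#: Base identity -> MARTINI bead types of the base beads.
BASE_BEAD_TYPES = {
    "A": ("Na", "Na", "Nda"),
    "G": ("Nda", "Nda", "Na"),
    "C": ("Na", "Nd"),
    "U": ("Na", "Na"),
    # dT overhangs are mapped with the uridine bead complement; thymine has
    # no entry in the RNA mapping table and the extra methyl is below CG
    # resolution.
    "T": ("Na", "Na"),
}

RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# Bonded defaults adapted from the MARTINI polymer/lipid parameter sets.
BOND_R0 = 0.47          # nm, standard 4:1 bead-bead bond
BOND_K = 1250.0         # kJ mol^-1 nm^-2
NUCLEIC_BOND_R0 = 0.35  # nm, backbone/base links in the nucleic mapping
BASE_BOND_R0 = 0.30     # nm, base-base intra-nucleotide link
ANGLE_THETA = 180.0     # degrees, aliphatic chain
ANGLE_K = 25.0          # kJ mol^-1 rad^-2

ELASTIC_CUTOFF = 0.7    # nm
ELASTIC_K = 1500.0      # kJ mol^-1 nm^-2

# Idealized A-form duplex geometry used when no structure is supplied.
A_FORM_RISE = 0.28          # nm per base pair
A_FORM_TWIST = 32.7         # degrees per base pair
A_FORM_BACKBONE_RADIUS = 0.9  # nm, phosphate radius at CG resolution
A_FORM_STRAND_OFFSET = 165.0  # degrees between the two backbones

_HYDROPHOBIC_ROLES = {"tail", "ring"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained interaction site."""

    index: int
    name: str
    martini_type: str
    charge: int
    mass: float
    role: str

    def __post_init__(self) -> None:
        if self.charge not in (-1, 0, 1):
            raise ValueError(f"bead charge must be -1, 0 or +1, got {self.charge}")
        if self.role == "terminal-amine" and (self.charge != 1 or self.martini_type != "Qd"):
            raise ValueError("terminal amines are protonated: charge +1, type Qd")
        if self.role == "phosphate" and (self.charge != -1 or self.martini_type != "Qa"):
            raise ValueError("phosphates carry charge -1 and type Qa")
        if self.role in _HYDROPHOBIC_ROLES and self.charge != 0:
            raise ValueError("hydrophobic beads are neutral")

    @property
    def hydrophobic(self) -> bool:
        return self.role in _HYDROPHOBIC_ROLES


@dataclass(frozen=True)
class BondedTerm:
    """A bond, angle or elastic-network restraint."""

    kind: str  # bond | angle | elastic
    bead_indices: tuple
    equilibrium: float  # nm (bond/elastic) or degrees (angle)
    force_constant: float

    def __post_init__(self) -> None:
        if self.kind not in ("bond", "angle", "elastic"):
            raise ValueError(f"unknown bonded kind {self.kind!r}")
        n = 3 if self.kind == "angle" else 2
        if len(self.bead_indices) != n:
            raise ValueError(f"{self.kind} needs {n} bead indices")
        if self.equilibrium <= 0:
            raise ValueError("equilibrium value must be positive")

    def key(self) -> tuple:
        return (self.kind, tuple(sorted(self.bead_indices)))


@dataclass(frozen=True)
class ADSpec:
    """An amphiphilic dendrimer variant: dendron generation x tail length."""

    generation: int
    tail_carbons: int

    def __post_init__(self) -> None:
        if self.generation not in SUPPORTED_GENERATIONS:
            raise ValueError(
                f"unsupported dendron generation {self.generation}; "
                f"supported: {SUPPORTED_GENERATIONS}"
            )
        if self.tail_carbons not in TAIL_BEAD_COUNT:
            raise ValueError(
                f"unsupported tail length {self.tail_carbons}C; "
                f"supported: {sorted(TAIL_BEAD_COUNT)}"
            )

    @property
    def n_terminal(self) -> int:
        """Number of terminal amines, 2^(g+1)."""
        return 2 ** (self.generation + 1)

    @property
    def n_tail_beads(self) -> int:
        return TAIL_BEAD_COUNT[self.tail_carbons]

    @property
    def charge(self) -> int:
        """Net charge e per AD (all terminal amines protonated)."""
        return self.n_terminal

    @property
    def label(self) -> str:
        return f"G{self.generation}-{self.tail_carbons}C"


@dataclass(frozen=True)
class NucleicDuplexSpec:
    """A double-stranded RNA with optional 3' dT overhangs ("T" residues)."""

    sense_seq: str
    antisense_seq: str
    include_overhangs: bool = True

    def __post_init__(self) -> None:
        for seq in (self.sense_seq, self.antisense_seq):
            bad = set(seq) - set("AUGCT")
            if bad:
                raise ValueError(f"unknown residues {sorted(bad)} in sequence {seq}")
            if not self.include_overhangs and "T" in seq:
                raise ValueError(
                    "sequence contains dT residues but include_overhangs is False"
                )
        sense_core, anti_core = self.core_strands()
        if set(sense_core + anti_core) & {"T"}:
            raise ValueError("dT residues are only allowed as 3' overhangs")
        rc = "".join(RNA_COMPLEMENT[b] for b in reversed(anti_core))
        if sense_core != rc:
            raise ValueError("core strands are not reverse-complementary")

    def core_strands(self) -> tuple:
        """Strand sequences with 3' dT overhangs stripped."""
        return tuple(s.rstrip("T") if self.include_overhangs else s
                     for s in (self.sense_seq, self.antisense_seq))

    @property
    def n_basepairs(self) -> int:
        return len(self.core_strands()[0])

    @property
    def n_phosphates_core(self) -> int:
        """Phosphates in the paired core (overhang phosphates excluded)."""
        return 2 * self.n_basepairs


def paper_duplex() -> NucleicDuplexSpec:
    """The 20-bp anti-Hsp27 siRNA duplex with dTdT overhangs."""
    return NucleicDuplexSpec(
        sense_seq="GCUGCAAAAUCCGAUGAGAC" + "TT",
        antisense_seq="GUCUCAUCGGAUUUUGCAGC" + "TT",
    )


@dataclass
class MoleculeTopology:
    """Beads plus bonded terms for one molecule."""

    name: str
    beads: list
    bonded: list

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def net_charge(self) -> int:
        return int(sum(b.charge for b in self.beads))

    def bonded_of(self, kind: str) -> list:
        return [t for t in self.bonded if t.kind == kind]

    def bead_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [b.name for b in self.beads],
                "martini_type": [b.martini_type for b in self.beads],
                "charge": [b.charge for b in self.beads],
                "mass": [b.mass for b in self.beads],
                "role": [b.role for b in self.beads],
            }
        )

    def validate(self) -> None:
        seen = set()
        for term in self.bonded:
            k = term.key()
            if k in seen:
                raise ValueError(f"duplicate bonded term {k}")
            seen.add(k)
            if any(i < 0 or i >= self.n_beads for i in term.bead_indices):
                raise ValueError("bonded term references a missing bead")


# ---------------------------------------------------------------------------
# amphiphilic dendrimer builder
# ---------------------------------------------------------------------------

def dendron_nodes(generation: int):
    """Branch-point tree of a dendron in heap (breadth-first) order.

    Returns (parents, levels, terminal_parents): ``parents[i]`` is the node
    index of node i's parent (-1 for the root, which bonds to the ring bead);
    ``terminal_parents[m]`` is the node index each terminal amine attaches to.
    """
    n_nodes = 2 ** (generation + 1) - 1
    parents = [-1] + [(i - 1) // 2 for i in range(1, n_nodes)]
    levels = [int(math.floor(math.log2(i + 1))) for i in range(n_nodes)]
    deepest_start = 2 ** generation - 1
    terminal_parents = [deepest_start + m // 2 for m in range(2 ** (generation + 1))]
    return parents, levels, terminal_parents


def build_ad_topology(spec: ADSpec) -> MoleculeTopology:
    """CG topology of one AD: ring + linear tail + dendritic head.

    Bead order: ring (index 0), tail beads T1..Tn from the ring outward,
    branch-point nodes in breadth-first order, then the terminal amines.
    Net charge is +2^(g+1) (every terminal amine protonated, Qd).
    """
    spec = ADSpec(spec.generation, spec.tail_carbons)  # re-validate
    beads = [BeadSpec(0, "RNG", "C1", 0, BEAD_MASS, "ring")]
    bonded: list = []

    # alkyl tail, bonded linearly from the ring
    t0 = 1
    for t in range(spec.n_tail_beads):
        beads.append(BeadSpec(t0 + t, f"T{t + 1}", "C1", 0, BEAD_MASS, "tail"))
    chain = [0] + list(range(t0, t0 + spec.n_tail_beads))
    for a, b in zip(chain[:-1], chain[1:]):
        bonded.append(BondedTerm("bond", (a, b), BOND_R0, BOND_K))
    for a, b, c in zip(chain[:-2], chain[1:-1], chain[2:]):
        bonded.append(BondedTerm("angle", (a, b, c), ANGLE_THETA, ANGLE_K))

    # dendron head: one neutral node bead per branch point
    parents, _levels, terminal_parents = dendron_nodes(spec.generation)
    node0 = t0 + spec.n_tail_beads
    for i, parent in enumerate(parents):
        beads.append(BeadSpec(node0 + i, f"ND{i + 1}", "Nda", 0, BEAD_MASS, "head-node"))
        attach = 0 if parent < 0 else node0 + parent
        bonded.append(BondedTerm("bond", (attach, node0 + i), BOND_R0, BOND_K))

    term0 = node0 + len(parents)
    for m, parent in enumerate(terminal_parents):
        beads.append(BeadSpec(term0 + m, f"NT{m + 1}", "Qd", 1, BEAD_MASS, "terminal-amine"))
        bonded.append(BondedTerm("bond", (node0 + parent, term0 + m), BOND_R0, BOND_K))

    topo = MoleculeTopology(f"AD_{spec.label.replace('-', '_')}", beads, bonded)
    topo.validate()
    assert topo.net_charge == spec.n_terminal
    return topo


# ---------------------------------------------------------------------------
# siRNA builder
# ---------------------------------------------------------------------------

def nucleotide_bead_count(base: str) -> int:
    """Beads per nucleotide: phosphate + sugar + base beads."""
    return 2 + len(BASE_BEAD_TYPES[base])


def _strand_records(spec: NucleicDuplexSpec):
    """Per-nucleotide records: (strand, index-in-strand, base, level, basepair).

    ``level`` is the helical rung (sense 5'->3' ascending); ``basepair`` is
    the 1-based pair index, -1 for overhang nucleotides.
    """
    n_bp = spec.n_basepairs
    records = []
    for strand, seq in enumerate((spec.sense_seq, spec.antisense_seq)):
        core_len = len(seq.rstrip("T")) if spec.include_overhangs else len(seq)
        for i, base in enumerate(seq):
            overhang = i >= core_len
            if strand == 0:
                level = i
                pair = i + 1 if not overhang else -1
            else:
                level = (n_bp - 1 - i) if not overhang else -(i - core_len + 1)
                pair = n_bp - i if not overhang else -1
            records.append((strand, i, base, level, pair))
    return records


def ideal_a_form_positions(
    spec: NucleicDuplexSpec,
    rise: float = A_FORM_RISE,
    twist_deg: float = A_FORM_TWIST,
    backbone_radius: float = A_FORM_BACKBONE_RADIUS,
) -> np.ndarray:
    """Idealized A-form duplex bead coordinates (nm), axis along z.

    The geometry only needs to be helically plausible: neighbouring beads
    fall inside the 0.7 nm elastic-network cutoff and paired bases meet near
    the axis.
    """
    out = []
    for strand, _i, base, level, _pair in _strand_records(spec):
        phi0 = math.radians(twist_deg) * level
        if strand == 1:
            phi0 += math.radians(A_FORM_STRAND_OFFSET)
        z = rise * level
        n_base = len(BASE_BEAD_TYPES[base])
        radii = [backbone_radius, 0.62] + list(np.linspace(0.42, 0.14, n_base))
        dphis = [0.0, math.radians(10.0)] + [
            math.radians(20.0 + 8.0 * k) for k in range(n_base)
        ]
        sgn = 1.0 if strand == 0 else -1.0
        for r, dphi in zip(radii, dphis):
            phi = phi0 + sgn * dphi
            out.append((r * math.cos(phi), r * math.sin(phi), z))
    return np.asarray(out, dtype=float)


def _map_atomistic_duplex(coords, spec: NucleicDuplexSpec) -> np.ndarray:
    """Centre-of-mass mapping of grouped heavy atoms to CG bead positions.

    ``coords`` is a path to an atomistic PDB whose residues follow the
    duplex sequence (sense strand then antisense, 5'->3').  Heavy atoms of
    each nucleotide are split into phosphate, sugar and 2-3 base groups and
    each group is reduced to its mass-weighted centre (standard MARTINI
    practice).
    """
    import MDAnalysis as mda

    u = mda.Universe(str(coords))
    residues = list(u.residues)
    records = _strand_records(spec)
    if len(residues) != len(records):
        raise ValueError(
            f"atomistic structure has {len(residues)} residues; the duplex "
            f"spec expects {len(records)} nucleotides"
        )
    phosphate_names = {"P", "OP1", "OP2", "O1P", "O2P", "O5'"}
    sugar_names = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'", "O3'"}
    # base heavy-atom groups per ring system (COM-mapped per group)
    purine_groups = [
        ("N9", "C8", "N7"),
        ("C5", "C6", "N6", "O6"),
        ("N1", "C2", "N2", "N3", "C4"),
    ]
    pyrimidine_groups = [
        ("N1", "C2", "O2", "N3"),
        ("C4", "O4", "N4", "C5", "C7", "C6"),
    ]
    positions = []
    for residue, (_s, _i, base, _lvl, _pair) in zip(residues, records):
        groups = [phosphate_names, sugar_names]
        groups += [set(g) for g in (purine_groups if base in "AG" else pyrimidine_groups)]
        for names in groups:
            sel = residue.atoms[[a.name in names for a in residue.atoms]]
            if len(sel) == 0:
                raise ValueError(
                    f"residue {residue.resid} has no atoms for group {sorted(names)}"
                )
            positions.append(sel.center_of_mass() / 10.0)  # A -> nm
    return np.asarray(positions, dtype=float)


def build_sirna_topology(
    spec: NucleicDuplexSpec,
    coords=None,
) -> tuple:
    """Topology and coordinates for the CG siRNA duplex.

    Per nucleotide: one Qa phosphate (-1), one P1 sugar, and 2-3 base beads
    (A/G: 3, C/U/dT: 2).  5' termini carry a phosphate bead so the 20-bp
    core holds exactly 2 x 20 = 40 phosphates.  ``coords`` may be an
    (n_beads, 3) array of CG positions or a path to an atomistic PDB; when
    absent an idealized A-form geometry is generated.

    Returns (MoleculeTopology, Frame); the frame's bead table carries
    ``resid`` (nucleotide serial), ``strand`` and ``basepair`` columns.
    """
    records = _strand_records(spec)
    beads: list = []
    bonded: list = []
    meta = {"resid": [], "strand": [], "basepair": []}
    prev_sugar_by_strand = {0: None, 1: None}
    serial = 0
    for strand, i, base, _level, pair in records:
        serial += 1
        p = len(beads)
        beads.append(BeadSpec(p, "P", "Qa", -1, BEAD_MASS, "phosphate"))
        beads.append(BeadSpec(p + 1, "SU", "P1", 0, BEAD_MASS, "sugar"))
        base_types = BASE_BEAD_TYPES[base]
        for k, bt in enumerate(base_types):
            beads.append(BeadSpec(p + 2 + k, f"B{k + 1}", bt, 0, BEAD_MASS, "base"))
        n_nt = 2 + len(base_types)
        meta["resid"] += [serial] * n_nt
        meta["strand"] += [strand] * n_nt
        meta["basepair"] += [pair] * n_nt

        bonded.append(BondedTerm("bond", (p, p + 1), NUCLEIC_BOND_R0, BOND_K))
        bonded.append(BondedTerm("bond", (p + 1, p + 2), NUCLEIC_BOND_R0, BOND_K))
        for k in range(len(base_types) - 1):
            bonded.append(BondedTerm("bond", (p + 2 + k, p + 3 + k), BASE_BOND_R0, BOND_K))
        if prev_sugar_by_strand[strand] is not None:
            # previous sugar -> this 5' phosphate, along the backbone
            bonded.append(
                BondedTerm("bond", (prev_sugar_by_strand[strand], p), NUCLEIC_BOND_R0, BOND_K)
            )
        prev_sugar_by_strand[strand] = p + 1

    topo = MoleculeTopology("siRNA", beads, bonded)
    topo.validate()

    if coords is None:
        positions = ideal_a_form_positions(spec)
    elif isinstance(coords, (str, Path)):
        positions = _map_atomistic_duplex(coords, spec)
    else:
        positions = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(positions) != topo.n_beads:
        raise ValueError(
            f"coordinates supply {len(positions)} beads, topology has {topo.n_beads}"
        )

    table = topo.bead_dataframe()
    table["molecule_id"] = 0
    table["molecule_kind"] = "siRNA"
    for col, vals in meta.items():
        table[col] = vals
    frame = Frame(positions, None, table)
    return topo, frame


# ---------------------------------------------------------------------------
# elastic network
# ---------------------------------------------------------------------------

def apply_elastic_network(
    topology: MoleculeTopology,
    frame,
    cutoff: float = ELASTIC_CUTOFF,
    k: float = ELASTIC_K,
) -> MoleculeTopology:
    """Add harmonic restraints between all non-bonded pairs within ``cutoff``.

    Every bead pair (i < j) not already covalently bonded whose distance is
    at most ``cutoff`` receives an elastic term whose equilibrium is the
    observed distance; pairs beyond the cutoff interact only non-bondedly.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    positions = frame.positions if isinstance(frame, Frame) else np.asarray(frame, float)
    positions = positions.reshape(-1, 3)
    if len(positions) != topology.n_beads:
        raise ValueError(
            f"need one position per bead: got {len(positions)} positions for "
            f"{topology.n_beads} beads"
        )
    covalent = {t.key()[1] for t in topology.bonded if t.kind in ("bond", "elastic")}
    tree = cKDTree(positions)
    new_terms = list(topology.bonded)
    for i, j in sorted(tree.query_pairs(cutoff)):
        if (i, j) in covalent:
            continue
        r0 = float(np.linalg.norm(positions[i] - positions[j]))
        new_terms.append(BondedTerm("elastic", (i, j), r0, k))
    out = MoleculeTopology(topology.name, list(topology.beads), new_terms)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# file export / import
# ---------------------------------------------------------------------------

_ROLE_FROM_NAME = (
    ("NT", "terminal-amine"),
    ("ND", "head-node"),
    ("RNG", "ring"),
    ("T", "tail"),
    ("SU", "sugar"),
    ("P", "phosphate"),
    ("B", "base"),
)

_ROLE_DEFAULTS = {
    "terminal-amine": ("Qd", 1),
    "head-node": ("Nda", 0),
    "ring": ("C1", 0),
    "tail": ("C1", 0),
    "phosphate": ("Qa", -1),
    "sugar": ("P1", 0),
    "base": ("Na", 0),
    "water": ("P4", 0),
    "ion-Na": ("Qd", 1),
    "ion-Cl": ("Qa", -1),
}


def _residue_layout(frame: Frame):
    """Group beads into residues for coordinate files.

    One residue per molecule, except siRNA where each nucleotide is a
    residue (resname R<base-type placeholder> 'RNA')."""
    beads = frame.beads
    keys = []
    resnames = []
    for idx in range(len(beads)):
        kind = beads.at[idx, "molecule_kind"]
        mol = beads.at[idx, "molecule_id"]
        if kind == "siRNA" and "resid" in beads.columns:
            keys.append((kind, mol, int(beads.at[idx, "resid"])))
            resnames.append("RNA")
        else:
            keys.append((kind, mol, 0))
            resnames.append(
                {"AD": "AD", "siRNA": "RNA", "water": "W", "Na": "NA", "Cl": "CL"}.get(
                    kind, str(kind)[:5]
                )
            )
    codes, _uniq = pd.factorize(pd.Series(keys))
    res_resname = {}
    for code, name in zip(codes, resnames):
        res_resname.setdefault(code, name)
    return np.asarray(codes), [res_resname[c] for c in sorted(res_resname)]


def _frame_to_universe(frame: Frame):
    import MDAnalysis as mda

    resindex, resnames = _residue_layout(frame)
    n_res = len(resnames)
    u = mda.Universe.empty(
        frame.n_beads,
        n_residues=n_res,
        atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", frame.beads["name"].astype(str).tolist())
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", (np.arange(n_res) % 99999) + 1)
    u.atoms.positions = frame.positions * 10.0  # nm -> Angstrom
    if frame.box is not None:
        box = frame.box
    else:
        span = frame.positions.max(axis=0) - frame.positions.min(axis=0)
        box = span + 2.0
    u.dimensions = [box[0] * 10.0, box[1] * 10.0, box[2] * 10.0, 90.0, 90.0, 90.0]
    return u


def write_gro(frame: Frame, path) -> None:
    """Write a frame as GROMACS .gro (nm, 3-decimal convention)."""
    try:
        u = _frame_to_universe(frame)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.atoms.write(str(path))
    except OSError as exc:
        raise OSError(f"failed to write GRO file {path}: {exc}") from exc


def write_pdb(frame: Frame, path) -> None:
    try:
        u = _frame_to_universe(frame)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.atoms.write(str(path))
    except OSError as exc:
        raise OSError(f"failed to write PDB file {path}: {exc}") from exc


def _role_from_name(name: str, resname: str) -> str:
    if resname == "W":
        return "water"
    if resname == "NA":
        return "ion-Na"
    if resname == "CL":
        return "ion-Cl"
    for prefix, role in _ROLE_FROM_NAME:
        if name.startswith(prefix):
            return role
    raise ValueError(f"cannot infer bead role from name {name!r} (resname {resname!r})")


def read_coordinates(path) -> Frame:
    """Read GRO/PDB (or any MDAnalysis-readable coordinates) back to a Frame.

    Bead roles, charges and masses are reconstructed from the bead/residue
    naming convention used by :func:`write_gro`.  All consecutive RNA
    residues are grouped into one siRNA molecule; strand/base-pair columns
    can be restored afterwards with :func:`assign_basepairs`.
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except OSError as exc:
        raise OSError(f"failed to read coordinate file {path}: {exc}") from exc

    names, resnames = [], []
    roles, charges, types, mol_ids, kinds, resids = [], [], [], [], [], []
    mol = -1
    rna_mol = None
    rna_serial = 0
    prev_res = None
    for atom in u.atoms:
        name = str(atom.name)
        resname = str(atom.resname)
        role = _role_from_name(name, resname)
        mtype, charge = _ROLE_DEFAULTS[role]
        if resname == "RNA":
            if rna_mol is None:
                mol += 1
                rna_mol = mol
            if atom.resindex != prev_res:
                rna_serial += 1
            mol_ids.append(rna_mol)
            kinds.append("siRNA")
            resids.append(rna_serial)
        else:
            if atom.resindex != prev_res:
                mol += 1
            mol_ids.append(mol)
            kinds.append(
                {"AD": "AD", "W": "water", "NA": "Na", "CL": "Cl"}.get(resname, resname)
            )
            resids.append(0)
        prev_res = atom.resindex
        names.append(name)
        resnames.append(resname)
        roles.append(role)
        charges.append(charge)
        types.append(mtype)

    table = pd.DataFrame(
        {
            "name": names,
            "martini_type": types,
            "charge": charges,
            "mass": BEAD_MASS,
            "role": roles,
            "molecule_id": mol_ids,
            "molecule_kind": kinds,
            "resid": resids,
        }
    )
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = np.asarray(u.dimensions[:3], dtype=float) / 10.0
    return Frame(u.atoms.positions / 10.0, box, table)


def assign_basepairs(frame: Frame, spec: NucleicDuplexSpec) -> Frame:
    """Restore strand/basepair columns on a frame read from disk."""
    records = _strand_records(spec)
    beads = frame.beads.copy()
    strand_col = np.full(len(beads), -1)
    pair_col = np.full(len(beads), -1)
    sel = beads.index[beads["molecule_kind"] == "siRNA"]
    serials = beads.loc[sel, "resid"].to_numpy()
    if serials.size:
        if serials.max() != len(records):
            raise ValueError(
                f"frame has {serials.max()} nucleotides; spec expects {len(records)}"
            )
        for pos, (strand, _i, _b, _lvl, pair) in enumerate(records, start=1):
            mask = sel[serials == pos]
            strand_col[mask] = strand
            pair_col[mask] = pair
    beads["strand"] = strand_col
    beads["basepair"] = pair_col
    return Frame(frame.positions, frame.box, beads)


# --- ITP-style topology text ----------------------------------------------

def write_itp(topologies, path) -> None:
    """Serialize topologies as GROMACS-style ITP text.

    Elastic-network restraints are written in a dedicated second
    ``[ bonds ]`` section tagged ``; elastic network``.
    """
    if isinstance(topologies, MoleculeTopology):
        topologies = [topologies]
    lines = []
    for topo in topologies:
        lines.append("[ moleculetype ]")
        lines.append("; name  nrexcl")
        lines.append(f"{topo.name}  1")
        lines.append("")
        lines.append("[ atoms ]")
        lines.append(";  nr  type  resnr  resname  atom  cgnr  charge  mass")
        for b in topo.beads:
            lines.append(
                f"{b.index + 1:6d}  {b.martini_type:<4s}  1  {topo.name[:5]:<5s}  "
                f"{b.name:<5s}  {b.index + 1:6d}  {b.charge: d}  {b.mass:.1f}"
                f"  ; role={b.role}"
            )
        bonds = topo.bonded_of("bond")
        if bonds:
            lines.append("")
            lines.append("[ bonds ]")
            lines.append(";  i  j  funct  r0(nm)  k(kJ/mol/nm2)")
            for t in bonds:
                i, j = t.bead_indices
                lines.append(
                    f"{i + 1:6d} {j + 1:6d}  1  {t.equilibrium:.5f}  {t.force_constant:.1f}"
                )
        elastic = topo.bonded_of("elastic")
        if elastic:
            lines.append("")
            lines.append("[ bonds ] ; elastic network")
            lines.append(";  i  j  funct  r0(nm)  k(kJ/mol/nm2)")
            for t in elastic:
                i, j = t.bead_indices
                lines.append(
                    f"{i + 1:6d} {j + 1:6d}  1  {t.equilibrium:.5f}  {t.force_constant:.1f}"
                )
        angles = topo.bonded_of("angle")
        if angles:
            lines.append("")
            lines.append("[ angles ]")
            lines.append(";  i  j  k  funct  theta0(deg)  k(kJ/mol/rad2)")
            for t in angles:
                i, j, k = t.bead_indices
                lines.append(
                    f"{i + 1:6d} {j + 1:6d} {k + 1:6d}  2  "
                    f"{t.equilibrium:.3f}  {t.force_constant:.1f}"
                )
        lines.append("")
    try:
        Path(path).write_text("\n".join(lines))
    except OSError as exc:
        raise OSError(f"failed to write ITP file {path}: {exc}") from exc


def read_itp(path) -> list:
    """Parse ITP text written by :func:`write_itp` back into topologies."""
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise OSError(f"failed to read ITP file {path}: {exc}") from exc

    topologies: list = []
    section = None
    elastic_section = False
    name = None
    beads: list = []
    bonded: list = []

    def _flush():
        nonlocal beads, bonded, name
        if name is not None:
            topo = MoleculeTopology(name, beads, bonded)
            topo.validate()
            topologies.append(topo)
        beads, bonded, name = [], [], None

    expect_name = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("["):
            header = line.split("]")[0].strip("[ ").strip()
            comment = line.split("]", 1)[1]
            if header == "moleculetype":
                _flush()
                expect_name = True
            section = header
            elastic_section = "elastic" in comment
            continue
        body, _, comment = line.partition(";")
        body = body.strip()
        if not body:
            continue
        if expect_name and section == "moleculetype":
            name = body.split()[0]
            expect_name = False
            continue
        fields = body.split()
        if section == "atoms":
            role = "unknown"
            if "role=" in comment:
                role = comment.split("role=")[1].split()[0]
            beads.append(
                BeadSpec(
                    int(fields[0]) - 1,
                    fields[4],
                    fields[1],
                    int(fields[6]),
                    float(fields[7]),
                    role,
                )
            )
        elif section == "bonds":
            kind = "elastic" if elastic_section else "bond"
            bonded.append(
                BondedTerm(
                    kind,
                    (int(fields[0]) - 1, int(fields[1]) - 1),
                    float(fields[3]),
                    float(fields[4]),
                )
            )
        elif section == "angles":
            bonded.append(
                BondedTerm(
                    "angle",
                    (int(fields[0]) - 1, int(fields[1]) - 1, int(fields[2]) - 1),
                    float(fields[4]),
                    float(fields[5]),
                )
            )
    _flush()
    return topologies


def export_system(topologies, frame: Frame, paths: dict) -> dict:
    """Write topology + coordinates; ``paths`` may hold gro/pdb/itp keys.

    The frame must supply exactly one position per topology bead (topologies
    listed once per molecule instance)."""
    if isinstance(topologies, MoleculeTopology):
        topologies = [topologies]
    expected = sum(t.n_beads for t in topologies)
    if expected != frame.n_beads:
        raise ValueError(
            f"topologies define {expected} beads but the frame has {frame.n_beads}"
        )
    written = {}
    if paths.get("itp"):
        write_itp(topologies, paths["itp"])
        written["itp"] = paths["itp"]
    if paths.get("gro"):
        write_gro(frame, paths["gro"])
        written["gro"] = paths["gro"]
    if paths.get("pdb"):
        write_pdb(frame, paths["pdb"])
        written["pdb"] = paths["pdb"]
    return written


def ad_frame(spec: ADSpec, positions: np.ndarray, molecule_id: int = 0,
             box=None) -> Frame:
    """Wrap AD bead positions (in topology order) into a Frame."""
    topo = build_ad_topology(spec)
    table = topo.bead_dataframe()
    table["molecule_id"] = molecule_id
    table["molecule_kind"] = "AD"
    return Frame(np.asarray(positions, float), box, table)
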