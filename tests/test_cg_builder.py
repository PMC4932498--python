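"""Topology builders: bead counts, charges, elastic network, file I/O."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dendrimicelle as dm
from dendrimicelle import cg_builder as cg
from conftest import brute_force_elastic_pairs


@pytest.mark.parametrize(
    "generation,tail,n_terminal,n_tail",
    [(0, 18, 2, 5), (1, 18, 4, 5), (2, 18, 8, 5), (2, 15, 8, 4), (2, 13, 8, 3)],
)
def test_ad_closed_form_counts_and_charge(generation, tail, n_terminal, n_tail):
    """Terminal amines 2^(g+1), tail beads {13:3,15:4,18:5}, one ring bead,
    net charge +2^(g+1) for every supported variant."""
    spec = dm.ADSpec(generation, tail)
    topo = dm.build_ad_topology(spec)
    roles = [b.role for b in topo.beads]
    assert roles.count("terminal-amine") == n_terminal
    assert roles.count("tail") == n_tail
    assert roles.count("ring") == 1
    assert topo.net_charge == n_terminal
    # all terminals are protonated Qd beads
    for b in topo.beads:
        if b.role == "terminal-amine":
            assert b.martini_type == "Qd" and b.charge == 1
    # hydrophobic beads: tail + ring
    assert sum(b.hydrophobic for b in topo.beads) == n_tail + 1


def test_ad_tail_is_linear_chain_from_ring():
    topo = dm.build_ad_topology(dm.ADSpec(2, 18))
    bonds = {t.key()[1] for t in topo.bonded_of("bond")}
    # ring (0) bonded to first tail bead (1), then a linear chain
    for a, b in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]:
        assert (a, b) in bonds


@pytest.mark.parametrize("generation,tail", [(3, 18), (-1, 18), (2, 16), (2, 12)])
def test_unsupported_variant_rejected(generation, tail):
    with pytest.raises(ValueError, match="unsupported"):
        dm.ADSpec(generation, tail)


def test_sirna_bead_tally_per_table():
    """Per-nucleotide bead complements: A/G 3 base beads, C/U 2, plus one
    phosphate and one sugar each; sense core strand totals 92 beads."""
    assert cg.nucleotide_bead_count("A") == 5
    assert cg.nucleotide_bead_count("G") == 5
    assert cg.nucleotide_bead_count("C") == 4
    assert cg.nucleotide_bead_count("U") == 4
    duplex = dm.paper_duplex()
    _topo, frame = dm.build_sirna_topology(duplex)
    sense_core = frame.beads[
        (frame.beads["strand"] == 0) & (frame.beads["basepair"] > 0)
    ]
    assert len(sense_core) == 92
    assert sum(cg.nucleotide_bead_count(b) for b in duplex.core_strands()[0]) == 92


def test_sirna_core_charge_and_phosphate_count():
    duplex = dm.paper_duplex()
    topo, frame = dm.build_sirna_topology(duplex)
    assert duplex.n_basepairs == 20
    assert duplex.n_phosphates_core == 40
    core = frame.beads[frame.beads["basepair"] > 0]
    assert int(core["charge"].sum()) == -40
    assert (core["role"] == "phosphate").sum() == 40
    # whole molecule: one phosphate per nucleotide including overhangs
    assert topo.net_charge == -44


def test_single_adenine_nucleotide_maps_to_five_beads():
    spec = dm.NucleicDuplexSpec("A", "U", include_overhangs=False)
    _topo, frame = dm.build_sirna_topology(spec)
    sense = frame.beads[frame.beads["strand"] == 0]
    assert len(sense) == 5
    assert list(sense["role"]) == ["phosphate", "sugar", "base", "base", "base"]
    assert list(sense["martini_type"]) == ["Qa", "P1", "Na", "Na", "Nda"]


def test_non_complementary_strands_rejected():
    with pytest.raises(ValueError, match="complementary"):
        dm.NucleicDuplexSpec("GCAU", "AUGG")


def test_unknown_residue_without_overhang_flag_rejected():
    with pytest.raises(ValueError):
        dm.NucleicDuplexSpec("GCAUTT", "AUGCTT", include_overhangs=False)
    with pytest.raises(ValueError, match="overhang"):
        # dT inside the strand, not a 3' suffix
        dm.NucleicDuplexSpec("GCTAU", "AUGCTT")


def test_elastic_network_basic_cases():
    """0.5 nm pair restrained at k=1500; 0.8 nm pair is not; an equilateral
    0.6 nm triangle gains all three terms."""
    beads = [
        cg.BeadSpec(i, f"B{i+1}", "Na", 0, 72.0, "base") for i in range(2)
    ]
    topo = cg.MoleculeTopology("pair", beads, [])
    near = dm.apply_elastic_network(topo, np.array([[0, 0, 0], [0.5, 0, 0]]))
    terms = near.bonded_of("elastic")
    assert len(terms) == 1
    assert terms[0].equilibrium == pytest.approx(0.5)
    assert terms[0].force_constant == 1500.0

    far = dm.apply_elastic_network(topo, np.array([[0, 0, 0], [0.8, 0, 0]]))
    assert far.bonded_of("elastic") == []

    tri_beads = [cg.BeadSpec(i, f"B{i+1}", "Na", 0, 72.0, "base") for i in range(3)]
    tri = cg.MoleculeTopology("tri", tri_beads, [])
    s = 0.6
    coords = np.array([[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]])
    assert len(dm.apply_elastic_network(tri, coords).bonded_of("elastic")) == 3


def test_elastic_network_skips_covalent_and_requires_coords():
    beads = [cg.BeadSpec(i, f"B{i+1}", "Na", 0, 72.0, "base") for i in range(2)]
    bonded = [cg.BondedTerm("bond", (0, 1), 0.35, 1250.0)]
    topo = cg.MoleculeTopology("pair", beads, bonded)
    out = dm.apply_elastic_network(topo, np.array([[0, 0, 0], [0.5, 0, 0]]))
    assert out.bonded_of("elastic") == []
    with pytest.raises(ValueError, match="position"):
        dm.apply_elastic_network(topo, np.zeros((1, 3)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_elastic_network_equals_bruteforce_enumeration(seed):
    """The KD-tree-built elastic network equals O(n^2) enumeration."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 120))
    coords = rng.uniform(0, 2.5, size=(n, 3))
    beads = [cg.BeadSpec(i, f"B{i+1}", "Na", 0, 72.0, "base") for i in range(n)]
    topo = cg.MoleculeTopology("rand", beads, [])
    built = {
        t.key()[1]: t.equilibrium
        for t in dm.apply_elastic_network(topo, coords).bonded_of("elastic")
    }
    expected = brute_force_elastic_pairs(coords, 0.7)
    assert set(built) == expected
    for (i, j), r0 in built.items():
        assert r0 == pytest.approx(np.linalg.norm(coords[i] - coords[j]))


def test_sirna_elastic_network_on_ideal_helix(duplex):
    """The idealized A-form geometry produces a connected elastic network:
    every bead is restrained to at least one partner within 0.7 nm."""
    topo, frame = dm.build_sirna_topology(duplex)
    en = dm.apply_elastic_network(topo, frame)
    touched = set()
    for t in en.bonded_of("elastic") + en.bonded_of("bond"):
        touched.update(t.bead_indices)
    assert touched == set(range(topo.n_beads))


def test_itp_round_trip_identity(tmp_path, g2_18c, duplex):
    """Write-then-read preserves bead metadata and all bonded terms."""
    ad = dm.build_ad_topology(g2_18c)
    sirna, frame = dm.build_sirna_topology(duplex)
    sirna = dm.apply_elastic_network(sirna, frame)
    path = tmp_path / "topol.itp"
    dm.write_itp([ad, sirna], path)
    back = dm.read_itp(path)
    assert [t.name for t in back] == [ad.name, sirna.name]
    for orig, rt in zip((ad, sirna), back):
        assert [(b.name, b.martini_type, b.charge, b.role) for b in rt.beads] == [
            (b.name, b.martini_type, b.charge, b.role) for b in orig.beads
        ]
        assert sorted(t.key() for t in rt.bonded) == sorted(
            t.key() for t in orig.bonded
        )
        # elastic constants survive in their dedicated bonds section
        ks = {t.force_constant for t in rt.bonded_of("elastic")}
        assert ks <= {1500.0}


def test_gro_round_trip_positions_and_metadata(tmp_path, micelle_19):
    dm.write_gro(micelle_19, tmp_path / "m.gro")
    back = dm.read_coordinates(tmp_path / "m.gro")
    assert back.n_beads == micelle_19.n_beads
    # GRO stores nm to 3 decimals
    assert np.abs(back.positions - micelle_19.positions).max() < 1e-3
    assert (back.beads["role"] == micelle_19.beads["role"]).all()
    assert (back.beads["molecule_id"] == micelle_19.beads["molecule_id"]).all()
    assert (back.beads["charge"] == micelle_19.beads["charge"]).all()


def test_gro_single_bead_precision(tmp_path):
    from conftest import single_bead_ad_frame

    frame = single_bead_ad_frame([[1.0, 1.0, 1.0]], np.array([5.0, 5.0, 5.0]))
    dm.write_gro(frame, tmp_path / "one.gro")
    back = dm.read_coordinates(tmp_path / "one.gro")
    assert np.allclose(back.positions[0], [1.0, 1.0, 1.0], atol=1e-3)
    assert np.allclose(back.box, [5.0, 5.0, 5.0], atol=1e-3)


def test_sirna_gro_round_trip_restores_basepairs(tmp_path, duplex):
    _topo, frame = dm.build_sirna_topology(duplex)
    dm.write_gro(frame, tmp_path / "s.gro")
    back = cg.assign_basepairs(dm.read_coordinates(tmp_path / "s.gro"), duplex)
    assert (back.beads["basepair"] == frame.beads["basepair"]).all()
    assert (back.beads["strand"] == frame.beads["strand"]).all()


def test_export_system_checks_bead_counts(tmp_path, g2_18c, duplex):
    topo, frame = dm.build_sirna_topology(duplex)
    with pytest.raises(ValueError, match="beads"):
        dm.export_system([topo, dm.build_ad_topology(g2_18c)], frame, {})
    out = dm.export_system(
        topo, frame, {"itp": tmp_path / "s.itp", "gro": tmp_path / "s.gro"}
    )
    assert set(out) == {"itp", "gro"}


def test_atomistic_com_mapping(tmp_path):
    """A synthetic atomistic adenosine maps to 5 beads at the group COMs."""
    pdb = tmp_path / "synthetic_nt.pdb"  # synthetic fixture, not a real PDB entry
    atoms = [  # name, x, y, z (Angstrom); one A nucleotide + paired U
        ("P", 0, 0, 0), ("OP1", 1, 0, 0), ("OP2", 0, 1, 0), ("O5'", 0, 0, 1),
        ("C1'", 4, 0, 0), ("C2'", 5, 0, 0), ("C3'", 4, 1, 0), ("C4'", 4, 0, 1),
        ("O4'", 5, 1, 0), ("C5'", 5, 0, 1), ("O2'", 4, 1, 1), ("O3'", 5, 1, 1),
        ("N9", 8, 0, 0), ("C8", 9, 0, 0), ("N7", 8, 1, 0),
        ("C5", 12, 0, 0), ("C6", 13, 0, 0), ("N6", 12, 1, 0),
        ("N1", 16, 0, 0), ("C2", 17, 0, 0), ("N2", 16, 1, 0), ("N3", 16, 0, 1),
        ("C4", 17, 1, 0),
    ]
    atoms_u = [
        ("P", 0, 20, 0), ("OP1", 1, 20, 0), ("OP2", 0, 21, 0), ("O5'", 0, 20, 1),
        ("C1'", 4, 20, 0), ("C2'", 5, 20, 0), ("C3'", 4, 21, 0), ("C4'", 4, 20, 1),
        ("O4'", 5, 21, 0), ("C5'", 5, 20, 1), ("O2'", 4, 21, 1), ("O3'", 5, 21, 1),
        ("N1", 8, 20, 0), ("C2", 9, 20, 0), ("O2", 8, 21, 0), ("N3", 8, 20, 1),
        ("C4", 12, 20, 0), ("O4", 13, 20, 0), ("C5", 12, 21, 0), ("C6", 12, 20, 1),
    ]
    lines = []
    serial = 1
    for resid, resname, alist in [(1, "A", atoms), (2, "U", atoms_u)]:
        for name, x, y, z in alist:
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {resname:<3s} A{resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
            serial += 1
    pdb.write_text("\n".join(lines) + "\nEND\n")

    spec = dm.NucleicDuplexSpec("A", "U", include_overhangs=False)
    _topo, frame = dm.build_sirna_topology(spec, coords=pdb)
    # phosphate bead = COM of the 4 phosphate-group atoms (equal masses here
    # would give (0.25, 0.25, 0.25) A; heavy-atom masses shift it slightly)
    assert np.linalg.norm(frame.positions[0] - np.array([0.025, 0.025, 0.025])) < 0.01
    # base bead 1 of adenine = COM of N9/C8/N7 ring atoms
    b1 = frame.positions[2]
    assert abs(b1[0] - 0.8333) < 0.02 and abs(b1[1] - 0.0333) < 0.02
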