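"""SASA, contacts, solvation shells, RDF maps and COM series."""
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dendrimicelle as dm
from dendrimicelle import interactions as it
from dendrimicelle.frames import Frame, Trajectory
from conftest import brute_force_contacts, single_bead_ad_frame


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_sasa_isolated_bead_is_analytic_sphere():
    """One bead of radius 0.26 with probe 0.26 exposes 4 pi 0.52^2 nm^2."""
    area = it.shrake_rupley(np.zeros((1, 3)), 0.26, 0.26, 960)
    assert area == pytest.approx(4 * math.pi * 0.52 ** 2, rel=1e-9)


def test_sasa_coincident_beads_count_once():
    area = it.shrake_rupley(np.zeros((2, 3)), 0.26, 0.26, 960)
    assert area == pytest.approx(4 * math.pi * 0.52 ** 2, rel=1e-9)


def test_sasa_two_sphere_union_analytic():
    """Two partially overlapping equal spheres: union area from the
    spherical-cap formula, matched within 0.5%."""
    d, rho = 0.4, 0.52
    analytic = 2 * (4 * math.pi * rho ** 2) - 2 * (2 * math.pi * rho * (rho - d / 2))
    coords = np.array([[0, 0, 0], [0, 0, d]])
    area = it.shrake_rupley(coords, 0.26, 0.26, 2000)
    assert abs(area - analytic) / analytic < 0.005


def test_sasa_trimer_matches_refined_sampling():
    """Default sampling agrees with a 20x denser sampling within 2%."""
    coords = np.array([[0, 0, 0], [0, 0, 0.4], [0, 0, 0.8]])
    coarse = it.shrake_rupley(coords, 0.26, 0.26, 960)
    refined = it.shrake_rupley(coords, 0.26, 0.26, 20000)
    assert abs(coarse - refined) / refined < 0.02


def test_sasa_rigid_motion_invariant():
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(1)
    coords = rng.uniform(0, 2, (25, 3))
    base = it.shrake_rupley(coords, 0.26, 0.26, 960)
    R = Rotation.from_euler("zyx", [31.0, -57.0, 113.0], degrees=True).as_matrix()
    moved = coords @ R.T + np.array([7.0, -3.0, 11.0])
    assert abs(it.shrake_rupley(moved, 0.26, 0.26, 960) - base) / base < 0.005


def test_sasa_rejects_bad_radii():
    with pytest.raises(ValueError):
        it.shrake_rupley(np.zeros((1, 3)), 0.0, 0.26, 100)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def test_contact_cutoff_boundaries():
    box = np.array([10.0] * 3)
    frame = single_bead_ad_frame([[1, 1, 1], [1.5, 1, 1]], box)
    assert dm.count_contacts(frame, [0], [1], cutoff=0.75) == 1
    frame2 = single_bead_ad_frame([[1, 1, 1], [1.76, 1, 1]], box)
    assert dm.count_contacts(frame2, [0], [1], cutoff=0.75) == 0
    with pytest.raises(ValueError, match="disjoint"):
        dm.count_contacts(frame, [0, 1], [1])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_contacts_match_bruteforce_under_wrapping(seed):
    """Pair counts equal the O(n^2) oracle on randomly wrapped frames."""
    rng = np.random.default_rng(seed)
    box = np.array([3.0, 3.0, 3.0])
    n_a, n_b = int(rng.integers(2, 50)), int(rng.integers(2, 50))
    pos = rng.uniform(-3, 6, (n_a + n_b, 3))  # deliberately unwrapped input
    frame = single_bead_ad_frame(pos, box)
    sel_a = np.arange(n_a)
    sel_b = np.arange(n_a, n_a + n_b)
    cutoff = float(rng.uniform(0.3, 1.2))
    got = dm.count_contacts(frame, sel_a, sel_b, cutoff)
    assert got == brute_force_contacts(pos[sel_a], pos[sel_b], box, cutoff)


def test_unique_contact_semantics():
    box = np.array([10.0] * 3)
    # one A bead near two B beads: 2 pairs but 1 unique A bead in contact
    frame = single_bead_ad_frame([[1, 1, 1], [1.5, 1, 1], [1, 1.5, 1]], box)
    assert dm.count_contacts(frame, [0], [1, 2], cutoff=0.75) == 2
    assert dm.count_contacts(frame, [0], [1, 2], cutoff=0.75, unique=True) == 1


# ---------------------------------------------------------------------------
# solvation shells
# ---------------------------------------------------------------------------

def _solvation_fixture(water_at):
    table = pd.DataFrame(
        [
            dict(name="P", martini_type="Qa", charge=-1, mass=72.0,
                 role="phosphate", molecule_id=0, molecule_kind="siRNA"),
            dict(name="W", martini_type="P4", charge=0, mass=72.0,
                 role="water", molecule_id=1, molecule_kind="water"),
        ]
    )
    frame = Frame(np.array([[5.0, 5, 5], water_at]), np.array([10.0] * 3), table)
    return Trajectory([frame, frame], [0.0, 1.0])


def test_solvation_count_trivial():
    traj = _solvation_fixture([5.5, 5.0, 5.0])
    out = dm.solvation_counts(traj, np.array([0]), "water")
    assert out.mean_count == 1.0
    far = _solvation_fixture([6.0, 5.0, 5.0])
    assert dm.solvation_counts(far, np.array([0]), "water").mean_count == 0.0


def test_missing_species_warns_not_errors():
    traj = _solvation_fixture([5.5, 5.0, 5.0])
    with pytest.warns(UserWarning, match="absent"):
        out = dm.solvation_counts(traj, np.array([0]), "Na")
    assert out.mean_count == 0.0


def test_empty_window_rejected():
    traj = _solvation_fixture([5.5, 5.0, 5.0])
    empty = Trajectory([], np.array([]))
    with pytest.raises(ValueError, match="empty"):
        dm.solvation_counts(empty, np.array([0]), "water")


def test_coated_sirna_displaces_sodium(g2_18c, duplex, complex_window):
    """Sodium within the siRNA shell in a dendrimer-coated complex is below
    the free-siRNA reference (amines displace the counterion cloud)."""
    frame = complex_window.frames[0]
    sirna_sel = frame.select(molecule_kind="siRNA")
    coated = dm.solvation_counts(complex_window, sirna_sel, "Na")

    _topo, free = dm.build_sirna_topology(duplex)
    table = free.beads.copy()
    for c, d in (("resid", 0), ("strand", -1), ("basepair", -1)):
        table[c] = table[c] if c in table else d
    free_frame = Frame(free.positions + 6.0, np.array([14.0] * 3), table)
    free_solv = dm.solvate_and_neutralize(free_frame, seed=8, include_water=False)
    free_traj = dm.static_trajectory(free_solv, 4, seed=9, noise_sigma=0.02)
    reference = dm.solvation_counts(
        free_traj, free_traj.frames[0].select(molecule_kind="siRNA"), "Na"
    )
    assert coated.mean_count < reference.mean_count


# ---------------------------------------------------------------------------
# per-base-pair RDF
# ---------------------------------------------------------------------------

def _sirna_with_water(duplex, n_water, n_frames, seed, exclude_zone=None):
    _topo, sf = dm.build_sirna_topology(duplex)
    box = np.array([12.0, 12.0, 12.0])
    rng = np.random.default_rng(seed)
    wtab = pd.DataFrame(
        {
            "name": "W", "martini_type": "P4", "charge": 0, "mass": 72.0,
            "role": "water", "molecule_id": np.arange(1, n_water + 1),
            "molecule_kind": "water",
        }
    )
    base = pd.concat([sf.beads, wtab], ignore_index=True)
    for c, d in (("resid", 0), ("strand", -1), ("basepair", -1)):
        base[c] = base[c].fillna(d).astype(int)
    frames = []
    spos = sf.positions + np.array([6.0, 6.0, 3.0])
    for _ in range(n_frames):
        wpos = rng.uniform(0, 12.0, (n_water, 3))
        if exclude_zone is not None:
            centers, radius = exclude_zone
            for c in centers:
                bad = np.linalg.norm(wpos - c, axis=1) < radius
                while bad.any():
                    wpos[bad] = rng.uniform(0, 12.0, (int(bad.sum()), 3))
                    bad = np.linalg.norm(wpos - c, axis=1) < radius
        frames.append(Frame(np.concatenate([spos, wpos]), box, base))
    return Trajectory(frames, np.arange(float(n_frames)))


def test_rdf_uniform_species_converges_to_one(duplex):
    """An ideal-gas water distribution gives g(r) = 1 +/- 0.05 over the
    outer half of the radial range (averaged across base pairs)."""
    traj = _sirna_with_water(duplex, 4000, 4, seed=0)
    rmap = dm.rdf_per_basepair(traj, "water", bin_width=0.2, r_max=3.0)
    outer = rmap.r_centers > 1.5
    profile = rmap.gr[:, outer].mean(axis=0)  # average the 20 base pairs
    assert np.abs(profile - 1.0).mean() < 0.05
    assert np.all(rmap.gr >= 0)


def test_rdf_detects_excluded_zone(duplex):
    """Water excluded from 1 nm around base pairs 10-15 shows g ~ 0 there
    while other pairs stay near 1."""
    probe = _sirna_with_water(duplex, 2000, 2, seed=1)
    coms = it.basepair_coms(probe.frames[0])
    centers = coms[9:15]
    traj = _sirna_with_water(duplex, 2000, 2, seed=1, exclude_zone=(centers, 1.0))
    rmap = dm.rdf_per_basepair(traj, "water", bin_width=0.2, r_max=2.0)
    inner = rmap.r_centers < 0.8
    assert rmap.gr[10:14][:, inner].mean() < 0.05
    far_pair_outer = rmap.gr[0, rmap.r_centers > 1.4]
    assert abs(far_pair_outer.mean() - 1.0) < 0.3


def test_rdf_zero_species_and_rmax_guard(duplex):
    traj = _sirna_with_water(duplex, 10, 1, seed=2)
    with pytest.raises(ValueError, match="half the smallest"):
        dm.rdf_per_basepair(traj, "water", r_max=7.0)
    with pytest.warns(UserWarning, match="absent"):
        rmap = dm.rdf_per_basepair(traj, "Na", r_max=2.0)
    assert np.all(rmap.gr == 0)


# ---------------------------------------------------------------------------
# COM series and plateaus
# ---------------------------------------------------------------------------

def test_com_series_static_and_pbc_invariant():
    box = np.array([10.0] * 3)
    frame = single_bead_ad_frame([[2, 5, 5], [5, 5, 5]], box)
    traj = dm.static_trajectory(frame, 3, seed=0, noise_sigma=0.0)
    d = dm.com_distance_series(traj, np.array([0]), np.array([1]))
    assert np.allclose(d, 3.0, atol=1e-6)

    shifted_frames = []
    for f in traj.frames:
        g = f.copy()
        g.positions = g.positions + box * np.array([2.0, -1.0, 5.0])
        shifted_frames.append(g)
    traj2 = Trajectory(shifted_frames, traj.times)
    d2 = dm.com_distance_series(traj2, np.array([0]), np.array([1]))
    assert np.allclose(d, d2, atol=1e-9)
    with pytest.raises(ValueError, match="non-empty"):
        dm.com_distance_series(traj, np.array([]), np.array([1]))


def test_plateau_finder_on_synthetic_series():
    times = np.arange(40.0)
    values = np.concatenate(
        [np.linspace(9, 6, 10), np.full(10, 6.0), np.linspace(6, 2, 10),
         np.full(10, 2.0)]
    )
    plateaus = dm.find_plateaus(times, values, slope_tol=0.01, min_frames=5)
    means = [v for _s, _e, v in plateaus]
    assert any(abs(v - 6.0) < 0.2 for v in means)
    assert any(abs(v - 2.0) < 0.2 for v in means)


# ---------------------------------------------------------------------------
# amine binding
# ---------------------------------------------------------------------------

def test_amine_stats_fixed_contacts_have_zero_sem(g2_18c, duplex):
    """10 amines pinned inside the cutoff in every frame: mean 10, sem 0."""
    _topo, sf = dm.build_sirna_topology(duplex)
    mic = dm.generate_micelle(g2_18c, 2, core_radius_target=1.1, seed=0)
    from dendrimicelle.synthetic_data import merge_frames

    box = np.array([20.0] * 3)
    sf_shift = Frame(sf.positions + np.array([8.0, 8.0, 5.0]), None, sf.beads)
    frame = merge_frames([sf_shift, mic], box)
    # park the micelle far away, then pin 10 amines next to a phosphate
    ad = frame.select(molecule_kind="AD")
    frame.positions[ad] += 100.0 - frame.positions[ad].mean(axis=0)
    frame.positions[ad] = np.mod(frame.positions[ad], box)
    amines = frame.select(role="terminal-amine")[:10]
    p0 = frame.positions[frame.select(role="phosphate")[0]]
    for k, a in enumerate(amines):
        frame.positions[a] = p0 + np.array([0.3 + 0.01 * k, 0, 0])
    traj = Trajectory([frame, frame, frame], [0.0, 1.0, 2.0])
    members = [set(frame.beads.loc[ad, "molecule_id"].unique())]
    stats = dm.amine_binding_stats(traj, members, bound_cutoff=50.0)
    assert stats["mean_amines_bound"].iloc[0] == 10.0
    assert stats["sem_amines_bound"].iloc[0] == 0.0


def test_micelle_beyond_com_threshold_not_bound(g2_18c, duplex):
    _topo, sf = dm.build_sirna_topology(duplex)
    mic = dm.generate_micelle(g2_18c, 5, core_radius_target=1.1, seed=0)
    from dendrimicelle.synthetic_data import merge_frames

    box = np.array([30.0] * 3)
    sf_shift = Frame(sf.positions + np.array([5.0, 5.0, 3.0]), None, sf.beads)
    frame = merge_frames([sf_shift, mic], box)
    ad = frame.select(molecule_kind="AD")
    target = np.array([5.0, 5.0, 5.0]) + np.array([8.0, 0.0, 0.0])
    frame.positions[ad] += target - frame.positions[ad].mean(axis=0)
    traj = Trajectory([frame], [0.0])
    members = [set(frame.beads.loc[ad, "molecule_id"].unique())]
    stats = dm.amine_binding_stats(traj, members)
    assert stats["mean_com_distance"].iloc[0] > 5.0
    assert not stats["bound"].iloc[0]


def test_per_micelle_amine_sums_match_union_count(complex_window):
    """Summed per-micelle unique-amine contacts equal the same count taken
    over the union of all micelles (amine beads belong to one micelle)."""
    frame = complex_window.frames[0]
    aggs = dm.detect_aggregates(frame)
    members = [a.members for a in aggs]
    stats = dm.amine_binding_stats(complex_window, members, bound_cutoff=np.inf)
    sirna = frame.select(molecule_kind="siRNA")
    union_counts = []
    for f in complex_window.frames:
        amines = f.select(role="terminal-amine")
        union_counts.append(
            dm.count_contacts(f, amines, sirna, 0.75, unique=True)
        )
    assert stats["mean_amines_bound"].sum() == pytest.approx(
        np.mean(union_counts)
    )


def test_contact_series_semantics(complex_window):
    frame = complex_window.frames[0]
    amines = frame.select(role="terminal-amine")
    sirna = frame.select(molecule_kind="siRNA")
    pairs = dm.contact_series(complex_window, amines, sirna, semantics="pairs")
    uniq = dm.contact_series(complex_window, amines, sirna, semantics="unique")
    assert np.all(pairs.counts >= uniq.counts)
    assert np.all(uniq.counts >= 0)
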