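"""Shared fixtures and brute-force oracles for the test suite."""
import numpy as np
import pandas as pd
import pytest

import dendrimicelle as dm
from dendrimicelle.frames import Frame, minimum_image


@pytest.fixture(scope="session")
def g2_18c():
    return dm.ADSpec(2, 18)


@pytest.fixture(scope="session")
def duplex():
    return dm.paper_duplex()


@pytest.fixture(scope="session")
def micelle_19(g2_18c):
    """A 19-AD spherical micelle, a typical G2-18C aggregation number."""
    return dm.generate_micelle(g2_18c, 19, core_radius_target=1.1, seed=11)


@pytest.fixture(scope="session")
def fusion_traj(g2_18c):
    """Scripted two-micelle fusion with ions and water (session-cached)."""
    a = dm.generate_micelle(g2_18c, 19, core_radius_target=1.1, seed=1)
    b = dm.generate_micelle(g2_18c, 19, core_radius_target=1.1, seed=2)
    return dm.generate_fusion_trajectory(a, b, n_frames=40, seed=3)


@pytest.fixture(scope="session")
def complex_window(g2_18c, duplex):
    """A 4-micelle siRNA complex with ions, as a short noisy window."""
    specs = [
        dict(spec=g2_18c, n_ads=n, core_radius_target=1.1)
        for n in (13, 19, 24, 26)
    ]
    frame = dm.generate_complex(specs, duplex, [3.5, 3.5, 3.5, 3.5], seed=5)
    frame = dm.solvate_and_neutralize(frame, seed=5, include_water=False)
    return dm.static_trajectory(frame, 4, seed=6, noise_sigma=0.02)


def single_bead_ad_frame(positions, box):
    """A frame of one-bead 'AD' molecules (ring role), for clustering tests."""
    n = len(positions)
    table = pd.DataFrame(
        {
            "name": "RNG",
            "martini_type": "C1",
            "charge": 0,
            "mass": 72.0,
            "role": "ring",
            "molecule_id": np.arange(n),
            "molecule_kind": "AD",
        }
    )
    return Frame(np.asarray(positions, float), box, table)


def brute_force_clusters(positions, box, cutoff):
    """O(n^2) union-find single linkage on minimum-image distances."""
    n = len(positions)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(minimum_image(positions[i] - positions[j], box))
            if d <= cutoff:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(frozenset(g) for g in groups.values())


def brute_force_contacts(pos_a, pos_b, box, cutoff):
    count = 0
    for a in pos_a:
        for b in pos_b:
            if np.linalg.norm(minimum_image(a - b, box)) <= cutoff:
                count += 1
    return count


def brute_force_elastic_pairs(positions, cutoff):
    pairs = set()
    n = len(positions)
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(positions[i] - positions[j]) <= cutoff:
                pairs.add((i, j))
    return pairs
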