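"""Shared fixtures and independent numerical oracles."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from sdscore import load_example_cohort
from sdscore.io_formats import Structure
from sdscore.structfeat import PROBE_RADIUS, VDW_DEFAULT, VDW_RADII, ThresholdConfig


@pytest.fixture(scope="session")
def example_cohort():
    return load_example_cohort()


@pytest.fixture()
def config():
    return ThresholdConfig()


def numerical_sasa(structure, n_points=10000, probe=PROBE_RADIUS, seed=0):
    """Independent Monte-Carlo solvent-accessible surface area oracle.

    Uses uniformly random (not deterministic-lattice) sphere points and a
    plain neighbour scan, so it shares no code path with the production
    SASA routine.  Returns per-atom areas in Angstrom^2.
    """
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    radii = np.array([VDW_RADII.get(el, VDW_DEFAULT)
                      for el in structure.element]) + probe
    coords = structure.coords
    tree = cKDTree(coords)
    areas = np.zeros(structure.n_atoms)
    for i in range(structure.n_atoms):
        sphere = coords[i] + radii[i] * pts
        neighbours = [j for j in tree.query_ball_point(coords[i],
                                                       radii[i] + radii.max())
                      if j != i and np.linalg.norm(coords[j] - coords[i])
                      < radii[i] + radii[j]]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            accessible &= (np.linalg.norm(sphere - coords[j], axis=1)
                           >= radii[j])
        areas[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return areas


def exhaustive_sc_pairs(structure, min_separation=10, margin=1.0):
    """Brute-force O(n^2) stabilization-center oracle (no spatial index)."""
    radii = np.array([VDW_RADII.get(el, VDW_DEFAULT)
                      for el in structure.element])
    pairs = set()
    n = structure.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if structure.chain_id[i] != structure.chain_id[j]:
                continue
            si, sj = int(structure.res_seq[i]), int(structure.res_seq[j])
            if abs(si - sj) < min_separation:
                continue
            d = np.linalg.norm(structure.coords[i] - structure.coords[j])
            if d < radii[i] + radii[j] + margin:
                ch = structure.chain_id[i]
                pairs.add(((ch, min(si, sj)), (ch, max(si, sj))))
    return pairs


def ca_trace(positions, chain="A", res_name="GLY", start_seq=1):
    """Single-CA-per-residue Structure from a coordinate list."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return Structure(
        chain_id=[chain] * n,
        res_seq=np.arange(start_seq, start_seq + n),
        res_name=[res_name] * n,
        atom_name=["CA"] * n,
        element=["C"] * n,
        coords=positions,
    )


@pytest.fixture(scope="session")
def hairpin():
    """Two antiparallel strands 4 Angstrom apart: residues i and 25-i are
    in van der Waals contact and up to 23 apart in sequence."""
    fwd = [(3.8 * i, 0.0, 0.0) for i in range(12)]
    rev = [(3.8 * (11 - i), 4.0, 0.0) for i in range(12)]
    return ca_trace(fwd + rev)
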