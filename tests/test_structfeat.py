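"""Structure-derived features: RSA/burial, secondary-structure grouping,
stabilization centers, categorization thresholds."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sdscore import structfeat
from sdscore.io_formats import AnnotationBundle
from sdscore.structfeat import (
    DynamicsCutoffs, ThresholdConfig, classify_burial,
    classify_dynamics_and_flexibility, classify_optimality,
    classify_stability, compute_rsa, compute_sasa,
    derive_empirical_thresholds, detect_stabilization_centers,
    group_secondary_structure,
)
from sdscore.synthetic_data import build_peptide, generate_toy_structure
from conftest import ca_trace, exhaustive_sc_pairs, numerical_sasa


class TestBurial:
    @pytest.mark.parametrize("rsa,expected", [
        (2.05, "buried"), (20.0, "buried"), (20.01, "exposed"),
        (50.0, "exposed"), (0.0, "buried"),
    ])
    def test_boundary_inclusive_cutoff(self, rsa, expected, config):
        assert classify_burial(rsa, config) == expected

    def test_missing_rsa_gives_missing_class(self, config):
        assert classify_burial(None, config) is None

    def test_negative_rsa_rejected(self, config):
        with pytest.raises(ValueError):
            classify_burial(-1.0, config)


class TestSecondaryStructure:
    @pytest.mark.parametrize("code,group", [
        ("G", "GHI"), ("H", "GHI"), ("I", "GHI"), ("E", "E"),
        ("T", "TB"), ("B", "TB"), ("S", "S"), ("C", "C"),
    ])
    def test_grouping(self, code, group):
        assert group_secondary_structure(code) == group

    def test_unknown_letter_errors(self):
        with pytest.raises(ValueError):
            group_secondary_structure("X")


class TestStability:
    @pytest.mark.parametrize("ddg,expected", [
        (1.64, "mild_destabilizing"),      # worked example
        (-0.41, "no_change"),              # worked example
        (4.0, "strong_destabilizing"),     # boundary: >= 4
        (0.5, "mild_destabilizing"),       # boundary: >= 0.5
        (-0.5, "mild_stabilizing"),
        (-2.0, "strong_stabilizing"),
        (0.0, "no_change"),
        (None, None),
    ])
    def test_band_assignment(self, ddg, expected, config):
        assert classify_stability(ddg, config) == expected

    def test_step_function_no_gaps_no_overlaps(self, config):
        """Scanning a fine ddG grid, the class sequence is monotone with
        exactly four boundaries and every value classified."""
        order = ["strong_stabilizing", "mild_stabilizing", "no_change",
                 "mild_destabilizing", "strong_destabilizing"]
        grid = np.linspace(-8, 8, 100001)
        indices = [order.index(classify_stability(x, config)) for x in grid]
        steps = np.diff(indices)
        assert np.all(steps >= 0)
        assert np.sum(steps) == 4


class TestOptimality:
    @pytest.mark.parametrize("gamma,expected", [
        (-5.2, "highly_nonoptimal"), (-5.0, "highly_nonoptimal"),
        (-4.14, "normal"), (0.0, "normal"), (None, None),
    ])
    def test_cutoff(self, gamma, expected, config):
        assert classify_optimality(gamma, config) == expected


class TestEmpiricalThresholds:
    def test_matches_sorting_oracle(self):
        values = list(range(1, 1001))
        lo, hi = derive_empirical_thresholds(values, 2.5, 97.5)
        # oracle: linear interpolation between order statistics
        arr = np.sort(np.array(values, dtype=float))

        def pct(q):
            pos = q / 100 * (len(arr) - 1)
            lo_i, frac = int(np.floor(pos)), pos - int(np.floor(pos))
            return arr[lo_i] * (1 - frac) + arr[min(lo_i + 1, len(arr) - 1)] * frac

        assert lo == pytest.approx(pct(2.5), abs=1e-9)
        assert hi == pytest.approx(pct(97.5), abs=1e-9)

    def test_large_uniform_sample(self):
        rng = np.random.default_rng(1)
        lo, hi = derive_empirical_thresholds(rng.uniform(0, 1, 10000),
                                             2.5, 97.5)
        assert lo == pytest.approx(0.025, abs=0.01)
        assert hi == pytest.approx(0.975, abs=0.01)

    def test_constant_list_degenerates(self):
        lo, hi = derive_empirical_thresholds([3.0] * 100, 2.5, 97.5)
        assert lo == hi == 3.0

    def test_small_sample_falls_back(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="sdscore.structfeat"):
            lo, hi = derive_empirical_thresholds([1.0] * 10, 2.5, 97.5,
                                                 fallback=(-0.537, 1.17))
        assert (lo, hi) == (-0.537, 1.17)
        assert any("fallback" in r.message for r in caplog.records)

    def test_small_sample_without_fallback_errors(self):
        with pytest.raises(ValueError):
            derive_empirical_thresholds([1.0, 2.0], 2.5, 97.5)

    @pytest.mark.parametrize("q", [0.5, 2.5])
    def test_tail_coverage_near_nominal(self, q):
        """Fraction flagged in each tail is within 1/n of q/100."""
        rng = np.random.default_rng(5)
        values = rng.normal(size=2000)
        lo, hi = derive_empirical_thresholds(values, q, 100 - q)
        n = len(values)
        assert np.mean(values <= lo) == pytest.approx(q / 100, abs=1 / n)
        assert np.mean(values >= hi) == pytest.approx(q / 100, abs=1 / n)


class TestDynamicsClassification:
    def test_fixed_cutoffs(self, config):
        cutoffs = DynamicsCutoffs(config.bfactor_fixed_cutoffs,
                                  config.rmsf_fixed_cutoffs,
                                  config.pflexible_fixed_cutoffs)
        b, r, f = classify_dynamics_and_flexibility(
            AnnotationBundle(bfactor_norm=-0.60, rmsf_norm=0.0,
                             p_flexible=0.90), cutoffs)
        assert b == "highly_rigid"
        assert r == "normal"
        assert f == "conformationally_flexible"

    def test_boundaries_inclusive(self, config):
        cutoffs = DynamicsCutoffs(config.bfactor_fixed_cutoffs,
                                  config.rmsf_fixed_cutoffs,
                                  config.pflexible_fixed_cutoffs)
        b, r, f = classify_dynamics_and_flexibility(
            AnnotationBundle(bfactor_norm=1.17, rmsf_norm=-0.607,
                             p_flexible=0.158), cutoffs)
        assert b == "highly_dynamic"
        assert r == "highly_rigid"
        assert f == "conformationally_rigid"

    def test_missing_inputs_give_missing_classes(self, config):
        cutoffs = DynamicsCutoffs(config.bfactor_fixed_cutoffs,
                                  config.rmsf_fixed_cutoffs,
                                  config.pflexible_fixed_cutoffs)
        assert classify_dynamics_and_flexibility(AnnotationBundle(),
                                                 cutoffs) == (None, None, None)


class TestRsa:
    def test_extended_tripeptide_is_reference(self):
        """The central residue of an extended Ala-X-Ala is the normalization
        reference, so its RSA is ~100 by construction."""
        for res in ("ALA", "LEU", "TRP"):
            tri = build_peptide(["ALA", res, "ALA"], phi=180.0, psi=180.0)
            assert compute_rsa(tri, "A", 2) == pytest.approx(100.0, abs=5.0)

    def test_enclosed_residue_is_fully_buried(self):
        shell = generate_toy_structure("shell")
        rsa = compute_rsa(shell, "A", 1)
        assert rsa is not None and rsa < 1.0
        oracle = numerical_sasa(shell)
        assert oracle[shell.atom_mask("A", 1)].sum() < 1.0

    def test_absent_residue_gives_missing(self):
        tri = generate_toy_structure("extended", 3)
        assert compute_rsa(tri, "A", 99) is None

    def test_sasa_matches_numerical_oracle(self):
        """Per-residue SASA within 2% of an independent Monte-Carlo
        estimate with 20000 sphere points per atom."""
        for structure in (build_peptide(["ALA", "ARG", "GLY", "LEU", "ALA"],
                                        phi=180.0, psi=180.0),
                          generate_toy_structure("helix", 8)):
            per_atom = compute_sasa(structure)
            oracle = numerical_sasa(structure, n_points=20000)
            for ch, seq, _ in structure.residues():
                mask = structure.atom_mask(ch, seq)
                assert per_atom[mask].sum() == pytest.approx(
                    oracle[mask].sum(), rel=0.02)


class TestStabilizationCenters:
    def test_contact_with_sufficient_separation(self):
        """Two residues 12 apart with closest atoms at 3.0 A (vdW sum 3.4
        + 1.0 margin) form a pair; the oracle is a direct distance scan."""
        structure = ca_trace([(0, 0, 0), (100, 0, 0), (3.0, 0, 0)],
                             res_name="GLY")
        structure.res_seq = np.array([1, 7, 13])
        pairs, residues = detect_stabilization_centers(structure)
        assert pairs == {(("A", 1), ("A", 13))}
        assert residues == {("A", 1), ("A", 13)}
        assert pairs == exhaustive_sc_pairs(structure)

    def test_close_contact_but_short_separation_is_not_a_pair(self):
        structure = ca_trace([(0, 0, 0), (3.0, 0, 0)])
        structure.res_seq = np.array([1, 6])
        pairs, _ = detect_stabilization_centers(structure)
        assert pairs == set()

    def test_distant_residues_give_empty_set(self):
        structure = ca_trace([(20.0 * i, 0, 0) for i in range(15)])
        pairs, residues = detect_stabilization_centers(structure)
        assert pairs == set() and residues == set()

    def test_matches_exhaustive_oracle_on_hairpin(self, hairpin):
        pairs, _ = detect_stabilization_centers(hairpin)
        assert pairs == exhaustive_sc_pairs(hairpin)
        assert pairs  # the hairpin does contain long-range contacts

    def test_invariant_under_rigid_motion(self, hairpin):
        rotation = Rotation.from_euler("xyz", [30, -60, 110],
                                       degrees=True).as_matrix()
        moved = hairpin.transformed(rotation, np.array([5.0, -3.0, 12.0]))
        assert detect_stabilization_centers(moved)[0] == \
            detect_stabilization_centers(hairpin)[0]

    def test_helix_has_no_long_range_contacts(self):
        helix = generate_toy_structure("helix", 30)
        pairs, _ = detect_stabilization_centers(helix)
        assert pairs == exhaustive_sc_pairs(helix) == set()


def test_threshold_config_validates_band_order():
    with pytest.raises(ValueError):
        ThresholdConfig(ddg_destabilizing_min=5.0,
                        ddg_strong_destabilizing_min=4.0)
    with pytest.raises(ValueError):
        ThresholdConfig(bfactor_tails=(97.5, 2.5))
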