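"""MSF/B-factor statistics, affine rescaling and region reports."""

import numpy as np
import pytest

import enmflex as ef
from enmflex.elastic_network import NodeLabel, NodeSet, build_network, hessian
from enmflex.flexibility import (
    BFACTOR_CONSTANT,
    DegenerateFitError,
    bfactor,
    compare_profiles,
    flexibility_profile,
    msf,
    region_layer_report,
    relative_rmsf,
    rescale_to_experiment,
    residue_values,
)
from enmflex.rtb_nma import solve_modes
from enmflex.structure_io import RegionAssignment
from enmflex import synthetic_data as sd


def _cloud_modes(n=15, seed=0, cutoff=14.0):
    rng = np.random.default_rng(seed)
    nodes = NodeSet(positions=rng.uniform(0, 10, size=(n, 3)))
    h = hessian(build_network(nodes, cutoff=cutoff))
    return solve_modes(h, nodes=nodes), h


class TestMsf:
    def test_two_node_closed_form(self):
        """Single internal mode: MSF_i = |u_i|^2 / lambda, equal on both
        nodes of the symmetric pair."""
        nodes = NodeSet(positions=[[0, 0, 0], [3, 0, 0]])
        ms = solve_modes(hessian(build_network(nodes, cutoff=5.0)), nodes=nodes)
        vals = msf(ms, n_v=10)
        assert vals[0] == pytest.approx(vals[1])
        assert vals[0] == pytest.approx(0.5 / 2.0)  # |u_i|^2=1/2, lambda=2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_modes_equals_hessian_pseudoinverse(self, seed):
        """With every internal mode included, MSF_i equals the 3x3-trace of
        the Moore-Penrose pseudo-inverse of the Hessian."""
        ms, h = _cloud_modes(seed=seed)
        vals = msf(ms, n_v=3 * 15)
        pinv = np.linalg.pinv(h, rcond=1e-10)
        diag = np.einsum("ii->i", pinv).reshape(-1, 3).sum(axis=1)
        assert np.abs(vals - diag).max() < 1e-8

    def test_monotone_in_mode_count(self):
        ms, _ = _cloud_modes(seed=3)
        prev = None
        for n_v in (1, 5, 10, 20, 39):
            cur = msf(ms, n_v=n_v)
            if prev is not None:
                assert np.all(cur >= prev - 1e-14)
            prev = cur

    def test_mass_weighting(self):
        ms, _ = _cloud_modes(seed=4)
        base = msf(ms, n_v=10)
        heavy = msf(ms, n_v=10, masses=np.full(15, 2.0))
        assert np.allclose(heavy, base / 2.0)

    def test_kbt_scaling(self):
        ms, _ = _cloud_modes(seed=5)
        assert np.allclose(msf(ms, n_v=10, kBT=2.0), 2 * msf(ms, n_v=10))


class TestBfactor:
    def test_zero_maps_to_zero_and_constant_inverts(self):
        assert bfactor(np.array([0.0]))[0] == 0.0
        assert bfactor(np.array([3 / (8 * np.pi**2)]))[0] == pytest.approx(1.0)

    def test_linear_map_preserves_profile(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0.1, 2.0, 50)
        b = bfactor(m)
        assert np.corrcoef(m, b)[0, 1] == pytest.approx(1.0)
        assert np.allclose(b, BFACTOR_CONSTANT * m)


class TestRescaleToExperiment:
    def test_exact_affine_recovery(self):
        rng = np.random.default_rng(1)
        b_calc = rng.uniform(5, 50, 100)
        fit = rescale_to_experiment(b_calc, 2.0 * b_calc + 5.0)
        assert fit.scale == pytest.approx(2.0)
        assert fit.shift == pytest.approx(5.0)
        assert np.abs(fit.fitted - (2 * b_calc + 5)).max() < 1e-9
        assert fit.r == pytest.approx(1.0)

    def test_noisy_recovery_within_three_standard_errors(self):
        """OLS recovery of a planted affine transform at n=452, sigma=2,
        against the closed-form OLS standard errors."""
        rng = np.random.default_rng(42)
        b_calc = rng.uniform(5, 50, 452)
        sigma = 2.0
        b_exp = 2.0 * b_calc + 5.0 + rng.normal(0, sigma, 452)
        fit = rescale_to_experiment(b_calc, b_exp)
        sxx = np.sum((b_calc - b_calc.mean()) ** 2)
        se_scale = sigma / np.sqrt(sxx)
        se_shift = sigma * np.sqrt(1 / 452 + b_calc.mean() ** 2 / sxx)
        assert abs(fit.scale - 2.0) < 3 * se_scale
        assert abs(fit.shift - 5.0) < 3 * se_shift

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateFitError):
            rescale_to_experiment(np.full(10, 3.0), np.arange(10.0))


class TestRelativeRmsf:
    def test_uniform_msf_gives_unit_profile(self):
        rel = relative_rmsf(np.full(20, 0.7))
        assert np.allclose(rel, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(0.1, 3.0, 30)
        assert np.allclose(relative_rmsf(m), relative_rmsf(2 * m))

    def test_mean_one_normalization_exact(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0.01, 5.0, 100)
        assert relative_rmsf(m).mean() == pytest.approx(1.0, abs=1e-10)

    def test_reporting_subset_normalization(self):
        m = np.array([1.0, 1.0, 4.0, 4.0])
        rel = relative_rmsf(m, reporting_set=[0, 1])
        assert rel[0] == pytest.approx(1.0)
        assert rel[2] == pytest.approx(2.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_rmsf(np.zeros(5))


class TestResidueAggregation:
    def test_backbone_average_in_all_heavy_mode(self):
        labels = [
            NodeLabel("A", 1, "", "ALA", "N", False),
            NodeLabel("A", 1, "", "ALA", "CA", False),
            NodeLabel("A", 1, "", "ALA", "C", False),
            NodeLabel("A", 1, "", "ALA", "CB", False),
        ]
        nodes = NodeSet(positions=np.zeros((4, 3)) + np.arange(4)[:, None],
                        labels=labels)
        vals = np.array([1.0, 2.0, 3.0, 100.0])
        keys, out = residue_values(vals, nodes, scheme="all_heavy")
        assert out[0] == pytest.approx(2.0)  # CB excluded

    def test_calpha_mode_uses_calpha_value(self):
        labels = [NodeLabel("A", 1, "", "ALA", "CA", False),
                  NodeLabel("A", 2, "", "GLY", "CA", False)]
        nodes = NodeSet(positions=np.array([[0., 0, 0], [3., 0, 0]]),
                        labels=labels)
        keys, out = residue_values(np.array([1.5, 2.5]), nodes)
        assert list(out) == [1.5, 2.5]


class TestRegionLayerReport:
    def _assignment(self, n):
        return RegionAssignment(
            region_members={"heme": np.array([0, 1]),
                            "cleft": np.array([2, 3, 4])},
            layer_index=np.array([0] * (n // 2) + [2] * (n - n // 2)),
        )

    def test_uniform_profile_reports_unit_means(self):
        asn = self._assignment(10)
        df = region_layer_report(np.ones(10), asn)
        assert np.allclose(df["mean_rel_rmsf"], 1.0)

    def test_planted_region_means_reproduced(self):
        rel = np.zeros(10)
        rel[[0, 1]] = 0.5
        rel[[2, 3, 4]] = 1.4
        asn = self._assignment(10)
        df = region_layer_report(rel, asn).set_index("region")
        assert df.loc["heme", "mean_rel_rmsf"] == pytest.approx(0.5)
        assert df.loc["cleft", "mean_rel_rmsf"] == pytest.approx(1.4)
        assert df.loc["heme", "n"] == 2

    def test_deterministic_row_order(self):
        asn = self._assignment(10)
        df1 = region_layer_report(np.ones(10), asn)
        df2 = region_layer_report(np.ones(10), asn)
        assert list(df1["region"]) == list(df2["region"])
        assert list(df1["region"])[:2] == ["cleft", "heme"]  # sorted


class TestCompareProfiles:
    def _profile(self, rel):
        nodes = NodeSet(positions=np.arange(len(rel) * 3, dtype=float
                                            ).reshape(-1, 3))
        return ef.FlexibilityProfile(
            nodes=nodes, msf=rel**2, rel_rmsf=rel, b_calc=rel
        )

    def test_self_comparison_is_zero(self):
        p = self._profile(np.linspace(0.5, 1.5, 10))
        out = compare_profiles(p, p, np.arange(10), np.arange(10))
        assert np.allclose(out["per_node"], 0.0)

    def test_planted_uniform_shift_recovered(self):
        rel = np.linspace(0.5, 1.5, 10)
        out = compare_profiles(
            self._profile(rel), self._profile(rel + 0.1),
            np.arange(10), np.arange(10),
        )
        assert np.allclose(out["per_node"], 0.1)

    def test_region_deltas(self):
        rel = np.ones(10)
        asn = RegionAssignment(
            region_members={"core": np.array([0, 1, 2])},
            layer_index=np.full(10, -1),
        )
        out = compare_profiles(
            self._profile(rel), self._profile(rel + 0.2),
            np.arange(10), np.arange(10), assignment=asn,
        )
        assert out["per_region"]["core"] == pytest.approx(0.2)

    def test_empty_intersection_rejected(self):
        p = self._profile(np.ones(5))
        with pytest.raises(ValueError):
            compare_profiles(p, p, [], [])


def test_symmetric_dimer_msf_profiles_identical(dumbbell_structure,
                                                dumbbell_modes):
    """The mirror-symmetric dumbbell's two domains fluctuate identically."""
    n = 12
    vals = msf(dumbbell_modes, n_v=1000)
    total = len(dumbbell_modes.nodes)
    assert np.abs(vals[:n] - vals[total - n:]).max() < 1e-8


def test_flexibility_profile_pipeline(dumbbell_modes):
    profile = flexibility_profile(dumbbell_modes, n_v=50)
    assert profile.rel_rmsf.mean() == pytest.approx(1.0, abs=1e-10)
    assert np.all(profile.msf >= 0)
    df = profile.table()
    assert {"msf", "rel_rmsf", "b_calc"} <= set(df.columns)


def test_substrate_removal_increases_cleft_mobility():
    """Removing the 'substrate' nodes from a toy pocket raises the relative
    RMSF of the residues that enclosed it (unliganded > liganded)."""
    st = sd.make_helix(25)
    nodes = ef.select_nodes(st)
    center = nodes.positions[10:15].mean(axis=0)
    # a small rigid 'ligand' plug inside the helix groove
    lig = center + np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0],
                             [0, 0, 1.5]])
    pos_with = np.vstack([nodes.positions, lig])
    with_nodes = NodeSet(positions=pos_with)
    ms_with = solve_modes(
        hessian(build_network(with_nodes, 10.0)), nodes=with_nodes)
    ms_free = solve_modes(
        hessian(build_network(nodes, 10.0)), nodes=nodes)
    rel_with = relative_rmsf(msf(ms_with, n_v=100))[:len(nodes)]
    rel_free = relative_rmsf(msf(ms_free, n_v=100))
    pocket = np.arange(10, 15)
    assert rel_free[pocket].mean() >= rel_with[pocket].mean()
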