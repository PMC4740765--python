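"""AMOVA / R_ST tests, including an independent brute-force oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ystrkit.errors import (
    DegreesOfFreedomError,
    EmptyComparisonError,
    ValidationError,
)
from ystrkit.haplotypes import PanelDefinition
from ystrkit.structure import (
    DistanceMatrix,
    DistancePolicy,
    amova_grouped,
    amova_two_level,
    haplotype_distance,
    pairwise_rst,
    permutation_p,
)

from conftest import make_pop, simple_panel, single_locus_pop


# ----------------------------------------------------------------------
# Independent oracle: enumerate all pairwise squared-size distances with
# plain loops and solve the two-level moment equations directly.
# ----------------------------------------------------------------------

def brute_force_two_level(value_lists):
    """value_lists: one list of single-locus allele sizes per population."""
    all_vals = [v for vals in value_lists for v in vals]
    N = len(all_vals)
    P = len(value_lists)

    def ssd(vals):
        return sum(
            (a - b) ** 2 for a, b in itertools.combinations(vals, 2)
        ) / len(vals)

    ssd_total = ssd(all_vals)
    ssd_within = sum(ssd(vals) for vals in value_lists)
    msd_among = (ssd_total - ssd_within) / (P - 1)
    msd_within = ssd_within / (N - P)
    n_bar = (N - sum(len(v) ** 2 for v in value_lists) / N) / (P - 1)
    sigma_a = (msd_among - msd_within) / n_bar
    denom = sigma_a + msd_within
    phi = 0.0 if denom == 0 else sigma_a / denom
    return sigma_a, msd_within, phi


class TestHaplotypeDistance:
    def test_identical_zero(self):
        panel = simple_panel(3)
        pop = make_pop("P", panel, [[10, 11, 12], [10, 11, 12]])
        d = haplotype_distance(pop.haplotypes[0], pop.haplotypes[1], panel)
        assert d.value == 0.0
        assert d.included_loci == panel.loci

    def test_single_locus_squared(self):
        pop1 = single_locus_pop("A", [10])
        pop2 = single_locus_pop("B", [14])
        d = haplotype_distance(pop1.haplotypes[0], pop2.haplotypes[0], pop1.panel)
        assert d.value == 16.0

    def test_null_locus_excluded(self):
        panel = simple_panel(3)
        a = make_pop("A", panel, [["10", "15", "null"]]).haplotypes[0]
        b = make_pop("B", panel, [["12", "15", "17"]]).haplotypes[0]
        d = haplotype_distance(a, b, panel)
        assert d.value == 4.0
        assert d.included_loci == ("L1", "L2")

    def test_duplicated_excluded_at_single_copy(self):
        panel = simple_panel(2)
        a = make_pop("A", panel, [["10", "13,14"]]).haplotypes[0]
        b = make_pop("B", panel, [["11", "13"]]).haplotypes[0]
        assert haplotype_distance(a, b, panel).value == 1.0

    def test_intermediate_uses_decimal_size(self):
        panel = simple_panel(1)
        a = make_pop("A", panel, [["34.1"]]).haplotypes[0]
        b = make_pop("B", panel, [["34"]]).haplotypes[0]
        assert haplotype_distance(a, b, panel).value == pytest.approx(0.01)

    def test_empty_comparison_error(self):
        panel = simple_panel(1)
        a = make_pop("A", panel, [["null"]]).haplotypes[0]
        b = make_pop("B", panel, [["10"]]).haplotypes[0]
        with pytest.raises(EmptyComparisonError):
            haplotype_distance(a, b, panel)

    def test_multi_copy_policy(self):
        panel = PanelDefinition("p", ("DYS385ab",), frozenset({"DYS385ab"}))
        a = make_pop("A", panel, [["13,14"]]).haplotypes[0]
        b = make_pop("B", panel, [["14,16"]]).haplotypes[0]
        with pytest.raises(EmptyComparisonError):
            haplotype_distance(a, b, panel)  # excluded by default
        d = haplotype_distance(a, b, panel, DistancePolicy(include_multi_copy=True))
        assert d.value == 1.0 + 4.0


class TestAmovaTwoLevel:
    def test_degenerate_zero(self):
        pops = [single_locus_pop("A", [10, 10]), single_locus_pop("B", [10, 10])]
        res = amova_two_level(pops)
        assert res.phi == 0.0
        assert res.sigma2_among == res.sigma2_within == 0.0

    def test_complete_separation(self):
        pops = [single_locus_pop("A", [10] * 5), single_locus_pop("B", [14] * 5)]
        res = amova_two_level(pops)
        assert res.phi == pytest.approx(1.0)
        assert res.sigma2_within == 0.0
        assert (res.df_among, res.df_within) == (1, 8)

    def test_hand_computed_case(self):
        # SSD decomposition worked by hand: phi = 49/52
        pops = [single_locus_pop("A", [10, 10, 11]), single_locus_pop("B", [13, 14, 14])]
        assert amova_two_level(pops).phi == pytest.approx(49 / 52, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 5, size=rng.integers(2, 4))
        value_lists = [list(rng.integers(8, 16, size=n)) for n in sizes]
        pops = [single_locus_pop(f"P{i}", v) for i, v in enumerate(value_lists)]
        res = amova_two_level(pops)
        sigma_a, sigma_w, phi = brute_force_two_level(value_lists)
        assert res.sigma2_among == pytest.approx(sigma_a, abs=1e-9)
        assert res.sigma2_within == pytest.approx(sigma_w, abs=1e-9)
        assert res.phi == pytest.approx(phi, abs=1e-9)

    def test_df_error(self):
        pops = [single_locus_pop("A", [10]), single_locus_pop("B", [11])]
        with pytest.raises(DegreesOfFreedomError):
            amova_two_level(pops)


class TestPairwiseRst:
    def test_relabeled_copy_near_zero(self):
        vals = [10, 11, 12, 13, 11, 12]
        m = pairwise_rst([single_locus_pop("A", vals), single_locus_pop("B", vals)])
        assert m["A", "B"] <= 0.05

    def test_three_populations_symmetric(self):
        pops = [
            single_locus_pop("A", [10, 11, 10]),
            single_locus_pop("B", [14, 15, 14]),
            single_locus_pop("C", [20, 21, 20]),
        ]
        m = pairwise_rst(pops)
        assert np.allclose(m.values, m.values.T)
        assert np.count_nonzero(np.triu(m.values, 1)) == 3

    def test_negative_values_retained(self):
        # balanced noise with no real structure often yields phi < 0
        rng = np.random.default_rng(0)
        found_negative = False
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = list(rng.integers(10, 14, size=6))
            b = list(rng.integers(10, 14, size=6))
            m = pairwise_rst([single_locus_pop("A", a), single_locus_pop("B", b)])
            if m["A", "B"] < 0:
                found_negative = True
                break
        assert found_negative


class TestPermutation:
    def test_complete_separation_min_p(self):
        # groups large enough that no permutation recreates the split
        pops = [single_locus_pop("A", [10] * 20), single_locus_pop("B", [14] * 20)]
        assert permutation_p(pops, n_perm=999, seed=1) == pytest.approx(1 / 1000)

    def test_seed_reproducibility(self):
        pops = [single_locus_pop("A", [10, 11, 12, 11]), single_locus_pop("B", [11, 12, 13, 12])]
        p1 = permutation_p(pops, n_perm=200, seed=42)
        p2 = permutation_p(pops, n_perm=200, seed=42)
        assert p1 == p2

    def test_different_seed_can_differ(self):
        pops = [single_locus_pop("A", [10, 11, 12, 11]), single_locus_pop("B", [11, 12, 13, 12])]
        ps = {permutation_p(pops, n_perm=49, seed=s) for s in range(10)}
        assert len(ps) > 1


class TestGroupedAmova:
    def _pops(self):
        return [
            single_locus_pop("A1", [10, 11, 10]),
            single_locus_pop("A2", [11, 12, 11]),
            single_locus_pop("B1", [19, 20, 19]),
            single_locus_pop("B2", [20, 21, 20]),
        ]

    def test_single_group_error(self):
        pops = self._pops()
        with pytest.raises(DegreesOfFreedomError, match="two_level"):
            amova_grouped(pops, {p.population: "all" for p in pops})

    def test_own_group_reduces_to_two_level(self):
        pops = self._pops()
        grouped = amova_grouped(pops, {p.population: p.population for p in pops})
        two = amova_two_level(pops)
        assert grouped.sigma2_among_pops == 0.0
        assert grouped.phi_ct == pytest.approx(two.phi, abs=1e-12)
        assert grouped.sigma2_among_groups == pytest.approx(two.sigma2_among, abs=1e-12)

    def test_two_group_structure(self):
        pops = self._pops()
        res = amova_grouped(pops, {"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        assert res.phi_ct > 0.5  # groups are far apart
        assert res.df_among_groups == 1
        assert res.df_among_pops == 2
        assert res.df_within == 8
        # hierarchical decomposition dominated by the group split
        assert res.sigma2_among_groups > res.sigma2_among_pops >= 0


class TestDistanceMatrix:
    def test_tsv_round_trip(self, tmp_path):
        m = DistanceMatrix(("A", "B"), np.array([[0.0, -0.013], [-0.013, 0.0]]))
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = DistanceMatrix.from_tsv(path)
        assert back.labels == m.labels
        assert np.array_equal(back.values, m.values)

    def test_rejects_asymmetry(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(("A", "B"), np.array([[1.0, 1.0], [1.0, 0.0]]))


@settings(max_examples=20, deadline=None)
@given(
    st.integers(min_value=-5, max_value=5),
    st.integers(min_value=1, max_value=4),
)
def test_phi_invariance_translation_and_scale(shift, scale):
    """Phi is unchanged by adding a constant to, or scaling, allele sizes."""
    base_a = [10, 11, 10, 12]
    base_b = [14, 15, 14, 16]
    ref = amova_two_level(
        [single_locus_pop("A", base_a), single_locus_pop("B", base_b)]
    )
    moved = amova_two_level(
        [
            single_locus_pop("A", [v * scale + shift for v in base_a]),
            single_locus_pop("B", [v * scale + shift for v in base_b]),
        ]
    )
    assert moved.phi == pytest.approx(ref.phi, abs=1e-9)
    # distances scale by c^2
    assert moved.sigma2_within == pytest.approx(ref.sigma2_within * scale**2, abs=1e-9)


def test_ssd_additivity():
    """SSD(total) = SSD(among) + SSD(within), checked through components."""
    rng = np.random.default_rng(3)
    value_lists = [list(rng.integers(8, 20, size=5)) for _ in range(3)]
    pops = [single_locus_pop(f"P{i}", v) for i, v in enumerate(value_lists)]
    res = amova_two_level(pops)
    sigma_a, sigma_w, phi = brute_force_two_level(value_lists)
    assert res.phi == pytest.approx(phi, rel=1e-9)
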