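"""Product enumeration, exact masses, isotope envelopes, XIC matching and
the regiochemistry rule engine."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import halokin as hk
from halokin.products import (
    HALIDES,
    HalogenationProduct,
    formula_to_hill,
    parse_formula,
)
from halokin.reference import ASSIGNED_PRODUCTS, SUBSTRATES

PHLOROGLUCINOL = SUBSTRATES["1"]


def _counts(product: HalogenationProduct) -> dict[str, int]:
    return product.halogen_counts


class TestEnumeration:
    def test_chloride_iodide_pool_gives_five_products(self):
        """A Cl/I pool reaches all mono and di states including the
        hetero chloro-iodo product."""
        out = hk.enumerate_halogenation_states(PHLOROGLUCINOL, {"Cl", "I"})
        assert len(out) == 5
        combos = {tuple(sorted(_counts(p).items())) for p in out}
        assert (("Cl", 1), ("I", 1)) in combos

    def test_bromide_iodide_pool_with_observed_caps(self):
        """Bromination is a dead end on phloroglucinol: capping Br at one and
        forbidding the Br/I hetero state leaves Br, I and I2."""
        out = hk.enumerate_halogenation_states(
            PHLOROGLUCINOL,
            {"Br", "I"},
            per_halide_caps={"Br": 1},
            forbidden_combinations={frozenset({"Br", "I"})},
        )
        combos = {tuple(sorted(_counts(p).items())) for p in out}
        assert combos == {(("Br", 1),), (("I", 1),), (("I", 2),)}

    def test_fluoride_never_productive(self):
        assert hk.enumerate_halogenation_states(PHLOROGLUCINOL, {"F"}) == set()
        out = hk.enumerate_halogenation_states(PHLOROGLUCINOL, {"F", "Cl"})
        assert all("F" not in _counts(p) for p in out)

    def test_unknown_halide_rejected(self):
        with pytest.raises(ValueError, match="unknown halide"):
            hk.enumerate_halogenation_states(PHLOROGLUCINOL, {"Cl", "At"})

    def test_trihalogenation_impossible(self):
        with pytest.raises(ValueError, match="two halogens"):
            hk.enumerate_halogenation_states(PHLOROGLUCINOL, {"Cl"}, max_total=3)

    @given(n_pool=st.integers(1, 3))
    @settings(derandomize=True)
    def test_enumeration_size_closed_form(self, n_pool):
        """|pool| mono states plus C(|pool|+1, 2) di states before caps."""
        pool = set(h for h in HALIDES if h != "F")
        pool = set(sorted(pool)[:n_pool])
        out = hk.enumerate_halogenation_states(PHLOROGLUCINOL, pool)
        assert len(out) == n_pool + math.comb(n_pool + 1, 2)


class TestMasses:
    def test_phloroglucinol_monoisotopic_mass(self):
        assert PHLOROGLUCINOL.mass == pytest.approx(126.0317, abs=5e-4)

    def test_monochloro_deprotonated_mz(self):
        p = HalogenationProduct(PHLOROGLUCINOL, (("Cl", 1),))
        assert hk.adduct_mz(p, "negative").mz == pytest.approx(158.9854, abs=5e-4)

    def test_masses_agree_with_pyteomics(self):
        """Pinned atomic-mass table vs an independent reference library."""
        from pyteomics import mass as pyt_mass

        for sub in SUBSTRATES.values():
            expected = pyt_mass.calculate_mass(formula=formula_to_hill(sub.formula))
            assert sub.mass == pytest.approx(expected, abs=1e-4)

    @given(key=st.sampled_from(sorted(SUBSTRATES)), halide=st.sampled_from(["Cl", "Br", "I"]))
    @settings(derandomize=True)
    def test_halogenation_mass_shift(self, key, halide):
        """Installing one halogen always shifts mass by m(X) − m(H)."""
        sub = SUBSTRATES[key]
        p = HalogenationProduct(sub, ((halide, 1),))
        shift = hk.products.MONOISOTOPIC_MASS[halide] - hk.products.MONOISOTOPIC_MASS["H"]
        assert p.mass - sub.mass == pytest.approx(shift, abs=1e-9)

    def test_chlorine_shift_value(self):
        p = HalogenationProduct(PHLOROGLUCINOL, (("Cl", 1),))
        assert p.mass - PHLOROGLUCINOL.mass == pytest.approx(33.9611, abs=5e-4)

    def test_formula_bookkeeping(self):
        p = HalogenationProduct(PHLOROGLUCINOL, (("Cl", 1), ("I", 1)))
        assert p.formula == {"C": 6, "H": 4, "O": 3, "Cl": 1, "I": 1}

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="unknown element"):
            hk.monoisotopic_mass({"Xx": 1})

    def test_formula_parser_round_trip(self):
        assert parse_formula("C14H12O3") == {"C": 14, "H": 12, "O": 3}
        assert formula_to_hill({"C": 6, "H": 5, "Cl": 1, "O": 2}) == "C6H5ClO2"
        with pytest.raises(ValueError):
            parse_formula("C6H6-O3")


def brute_force_pattern(n_cl: int, n_br: int) -> dict[int, float]:
    """Oracle: enumerate every halogen isotopologue explicitly and aggregate
    abundance by nominal mass shift (0, 2, 4 Da)."""
    cl = [(0, 0.7576), (2, 0.2424)]
    br = [(0, 0.5069), (2, 0.4931)]
    acc: dict[int, float] = {}
    for combo in itertools.product(*([cl] * n_cl + [br] * n_br)):
        shift = sum(c[0] for c in combo)
        prob = math.prod(c[1] for c in combo)
        acc[shift] = acc.get(shift, 0.0) + prob
    base = max(acc.values())
    return {s: 100.0 * p / base for s, p in acc.items()}


class TestIsotopePatterns:
    def test_halogen_free_pattern_is_single_peak(self):
        p = HalogenationProduct(PHLOROGLUCINOL, (("I", 1),))
        pattern = hk.isotope_pattern(p)
        assert pattern.peaks == ((0.0, 100.0),)

    def test_one_chlorine_m_plus_2_ratio(self):
        p = HalogenationProduct(PHLOROGLUCINOL, (("Cl", 1),))
        pattern = hk.isotope_pattern(p)
        assert pattern.abundance_at(2) == pytest.approx(32.0, abs=0.05)

    def test_two_bromines_triplet(self):
        p = HalogenationProduct(PHLOROGLUCINOL, (("Br", 2),))
        pattern = hk.isotope_pattern(p)
        assert pattern.abundance_at(0) == pytest.approx(51.4, abs=0.05)
        assert pattern.abundance_at(2) == pytest.approx(100.0)
        # q²/(2pq) with p = 0.5069: 0.4931/(2·0.5069) = 0.48639
        assert pattern.abundance_at(4) == pytest.approx(48.64, abs=0.05)

    @pytest.mark.parametrize(
        "halogens",
        [(("Cl", 1),), (("Cl", 2),), (("Br", 1),), (("Br", 2),), (("Br", 1), ("Cl", 1))],
    )
    def test_binomial_matches_brute_force_convolution(self, halogens):
        p = HalogenationProduct(PHLOROGLUCINOL, halogens)
        pattern = hk.isotope_pattern(p)
        counts = dict(halogens)
        oracle = brute_force_pattern(counts.get("Cl", 0), counts.get("Br", 0))
        for shift, abundance in oracle.items():
            assert pattern.abundance_at(shift) == pytest.approx(abundance, rel=1e-9)

    def test_full_mode_includes_carbon_13(self):
        p = HalogenationProduct(PHLOROGLUCINOL, (("Cl", 1),))
        pattern = hk.isotope_pattern(p, mode="full")
        # six carbons: M+1 ≈ 6 × 1.07/98.93 ≈ 6.5% of base
        assert pattern.abundance_at(1) == pytest.approx(6.49, abs=0.1)


class TestXicMatch:
    def test_exact_mass_always_assigned(self):
        cands = hk.enumerate_halogenation_states(PHLOROGLUCINOL, {"Cl"})
        mono = next(p for p in cands if p.total_halogens == 1)
        mz = hk.adduct_mz(mono, "negative").mz
        hits = hk.xic_match([mz], cands, "negative", tolerance=1e-6)
        assert any(p is mono for _, p, _ in hits)

    def test_closed_interval_boundary(self):
        cands = hk.enumerate_halogenation_states(PHLOROGLUCINOL, {"Cl"})
        mono = next(p for p in cands if p.total_halogens == 1)
        mz = hk.adduct_mz(mono, "negative").mz
        inside = hk.xic_match([mz + 0.049], {mono}, "negative", tolerance=0.05)
        outside = hk.xic_match([mz + 0.051], {mono}, "negative", tolerance=0.05)
        assert len(inside) == 1 and len(outside) == 0

    def test_synthetic_peak_list_with_decoys(self):
        """Five true peaks from the Cl/I enumeration plus three 0.2-Da decoys
        yield exactly five assignments at ±0.05 Da."""
        cands = hk.enumerate_halogenation_states(PHLOROGLUCINOL, {"Cl", "I"})
        true_mzs = [hk.adduct_mz(p, "negative").mz for p in cands]
        decoys = [true_mzs[0] + 0.2, true_mzs[2] - 0.2, true_mzs[4] + 0.2]
        hits = hk.xic_match(true_mzs + decoys, cands, "negative", tolerance=0.05)
        assert len(hits) == 5

    def test_out_of_instrument_range_never_assigned(self):
        # diiodophloroglucinol [M-H]- is ~376.8; with an artificial 80-300
        # window it must be dropped
        cands = hk.enumerate_halogenation_states(PHLOROGLUCINOL, {"I"})
        di = next(p for p in cands if p.total_halogens == 2)
        mz = hk.adduct_mz(di, "negative").mz
        hits = hk.xic_match([mz], {di}, "negative", 0.05, mz_range=(80.0, 300.0))
        assert hits == []

    def test_empty_candidates_warn(self):
        with pytest.warns(UserWarning, match="empty candidate"):
            assert hk.xic_match([100.0], set(), "negative", 0.05) == []


class TestRegiochemistry:
    @pytest.mark.parametrize("key", sorted(ASSIGNED_PRODUCTS))
    def test_reproduces_every_nmr_assigned_product(self, key):
        """The site rules reproduce all nine NMR-assigned halogenation
        products, in each parent's input numbering."""
        sub_key = key.split("+")[0]
        _, positions = ASSIGNED_PRODUCTS[key]
        sub = SUBSTRATES[sub_key]
        predicted = hk.predict_positions(sub, len(positions))
        assert positions in predicted

    def test_resorcinol_dihalogenation_avoids_between_position(self):
        assert hk.predict_positions(SUBSTRATES["3"], 2) == {frozenset({4, 6})}

    def test_orcinol_methyl_meta_exception(self):
        """A methyl group meta to both hydroxyls re-admits the position
        between them with top priority."""
        assert hk.predict_positions(SUBSTRATES["9"], 2) == {frozenset({2, 4})}

    def test_resveratrol_styrenyl_meta_exception(self):
        assert hk.predict_positions(SUBSTRATES["23"], 1) == {frozenset({4})}

    def test_phloroglucinol_between_only_candidates_allowed(self):
        """When every candidate lies between activating groups the exclusion
        cannot apply; symmetry collapses the answer to lowest locants."""
        assert hk.predict_positions(SUBSTRATES["1"], 2) == {frozenset({2, 4})}

    def test_nitro_ring_not_halogenated(self):
        assert hk.predict_positions(SUBSTRATES["19"], 1) == set()

    def test_no_activating_group_rejected(self):
        bare = hk.RingSubstrate("toluene", {1: "CH3"}, {"C": 7, "H": 8})
        with pytest.raises(ValueError, match="activating"):
            hk.predict_positions(bare, 1)

    def test_three_halogens_impossible(self):
        with pytest.raises(ValueError, match="never more"):
            hk.predict_positions(SUBSTRATES["3"], 3)
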