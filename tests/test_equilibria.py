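import numpy as np
import pytest
from scipy.optimize import root

from igpepi import (
    coexistence_solve,
    eco_equilibria,
    epi_equilibria,
    r0_boundary,
    r0_coexistence,
    rhs_eco,
    rhs_epi,
    totals,
)
from igpepi.equilibria import EPI_LABELS, catalogue_to_json, endemic_slice_1


class TestCoexistenceSolve:
    def test_decoupled_species_rest_at_carrying_capacity(self, params):
        star = coexistence_solve(params.replace(p=0.0, q=0.0, a=0.0))
        assert star == pytest.approx((params.k1, params.k2))

    def test_matches_independent_nonlinear_root_finder(self, params):
        star = coexistence_solve(params)

        def per_capita_growth(x):
            # zero exactly at the interior equilibrium (axis roots excluded)
            n1, n2 = x
            return [
                params.r1 * (1 - (n1 + params.p * n2) / params.k1)
                + params.epsilon * params.a * n2,
                params.r2 * (1 - (n2 + params.q * n1) / params.k2) - params.a * n1,
            ]

        sol = root(per_capita_growth, x0=[params.k1 / 2, params.k2 / 2])
        assert sol.success
        np.testing.assert_allclose(star, sol.x, rtol=1e-10)
        assert np.max(np.abs(rhs_eco(star, params))) <= 1e-10

    def test_infeasible_when_predator_pressure_excludes_prey(self, params):
        pr = params.replace(a=0.02)  # alpha2*k1 = 2.2 > r2 = 1
        assert pr.alpha2 * pr.k1 > pr.r2
        assert coexistence_solve(pr) is None


class TestEcoCatalogue:
    def test_boundary_equilibria_always_present(self, params):
        cat = {e.label: e for e in eco_equilibria(params.replace(a=0.05, q=0.8))}
        for label in ("E0", "E1", "E2"):
            assert cat[label].exists
        assert not cat["Estar_eco"].exists

    def test_canonical_catalogue_is_complete_with_tiny_residuals(self, params):
        cat = eco_equilibria(params)
        assert [e.label for e in cat] == ["E0", "E1", "E2", "Estar_eco"]
        assert all(e.exists for e in cat)
        assert max(e.residual(params) for e in cat) <= 1e-9


class TestEpiCatalogue:
    def test_nine_entries_in_table_order(self, params):
        assert tuple(e.label for e in epi_equilibria(params)) == EPI_LABELS

    def test_exclusion_equilibria_always_present(self, small_ensemble):
        for _, pr, _ in small_ensemble[:16]:
            cat = {e.label: e for e in epi_equilibria(pr)}
            assert cat["E1e"].exists
            np.testing.assert_array_equal(cat["E1e"].state, [pr.k1, 0, 0, 0])
            assert cat["E2e"].exists

    def test_threshold_transmission_coincides_with_infection_free(self, params):
        pr = params.replace(beta1=params.b1 / params.k1)  # R0 exactly 1
        cat = {e.label: e for e in epi_equilibria(pr)}
        assert cat["E3"].exists and cat["E3"].marginal
        np.testing.assert_allclose(cat["E3"].state, cat["E1e"].state, atol=1e-12)

    def test_fully_endemic_state_matches_4d_root_finder(self, endemic_params):
        pr = endemic_params
        cat = {e.label: e for e in epi_equilibria(pr)}
        estar = cat["Estar"]
        assert estar.exists
        assert estar.residual(pr) <= 1e-9
        sol = root(
            lambda x: rhs_epi(np.abs(x), pr), x0=np.abs(estar.state) * 1.1, tol=1e-13
        )
        assert sol.success
        np.testing.assert_allclose(estar.state, np.abs(sol.x), rtol=1e-8)

    def test_every_existing_equilibrium_is_a_fixed_point(self, small_ensemble):
        for _, pr, _ in small_ensemble:
            for eq in epi_equilibria(pr):
                if eq.exists:
                    assert eq.residual(pr) <= 1e-9, (eq.label, pr)

    def test_totals_sit_at_an_abundance_equilibrium(self, small_ensemble):
        for _, pr, _ in small_ensemble[:16]:
            eco_states = [
                e.state for e in eco_equilibria(pr) if e.exists
            ]
            for eq in epi_equilibria(pr):
                if not eq.exists:
                    continue
                tot = np.array(totals(eq.state))
                dists = [np.max(np.abs(tot - s)) for s in eco_states]
                assert min(dists) <= 1e-8 * max(pr.k1, pr.k2)

    def test_endemic_iff_reproduction_number_exceeds_one(self, small_ensemble):
        for _, pr, _ in small_ensemble:
            cat = {e.label: e for e in epi_equilibria(pr)}
            r0_11, r0_12 = r0_boundary(pr)
            assert cat["E3"].exists == (r0_11 >= 1)
            if cat["E3"].exists:
                assert (cat["E3"].state[1] > 0) == (r0_11 > 1)
            assert cat["E4"].exists == (r0_12 >= 1)
            star = coexistence_solve(pr)
            if star is not None:
                r0_21, r0_22 = r0_coexistence(pr, *star)
                assert cat["E6"].exists == (r0_21 >= 1)
                assert cat["E7"].exists == (r0_22 >= 1)
                assert cat["Estar"].exists == (r0_21 >= 1 and r0_22 >= 1)

    def test_endemic_predator_identity_with_reproduction_number(self, endemic_params):
        # R0^(2,1) equals N1*/S1* (consequence of the equilibrium relations)
        star = coexistence_solve(endemic_params)
        r0_21, _ = r0_coexistence(endemic_params, *star)
        s1, _ = endemic_slice_1(endemic_params, *star)
        assert r0_21 == pytest.approx(star.n1 / s1, rel=1e-10)


def test_catalogue_serializes_to_json(params, tmp_path):
    import json

    path = tmp_path / "catalogue.json"
    catalogue_to_json(params, path)
    payload = json.loads(path.read_text())
    assert len(payload["eco"]) == 4
    assert len(payload["epi"]) == 9
    for entry in payload["epi"]:
        if entry["exists"]:
            assert entry["residual"] <= 1e-9
        assert set(entry) >= {"label", "state", "exists", "conditions", "source"}
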