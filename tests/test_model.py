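import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rootflux as rf
from rootflux.geometry import build_template_from_rectangles
from rootflux.model import (
    GAS_RT_OVER_F,
    ModelError,
    PhysicalParams,
    ScenarioConfig,
    assemble_system,
    deposit_and_track,
    effective_efflux_permeability,
    flux_field,
    membrane_flux,
    scenario,
    simulate,
    steady_state,
)
from rootflux.transporters import CarrierCounts, TransporterDistribution
from .conftest import rect

P = 0.56


def counts(abcb1=0.0, abcb4=0.0, abcb19=0.0, n_pin=0.0, influx=0.0):
    return CarrierCounts(
        abcb1=abcb1,
        abcb4=abcb4,
        abcb19=abcb19,
        pins={"PIN": n_pin} if n_pin else {},
        influx={"AUX1": influx} if influx else {},
    )


class TestScenarioAlgebra:
    def test_independent_scenario_sums_components(self):
        # one PIN plus two ABCBs at equal permeability P give 3P
        c = counts(abcb1=1, abcb19=1, n_pin=1)
        assert effective_efflux_permeability(c, scenario("I", P)) == pytest.approx(3 * P)

    def test_codependent_scenario_needs_both(self):
        c = counts(n_pin=1)  # no ABCB present
        assert effective_efflux_permeability(c, scenario("II", P)) == 0.0

    def test_synergistic_scenario_adds_product_term(self):
        c = counts(abcb1=1, n_pin=1)
        assert effective_efflux_permeability(c, scenario("III", P)) == pytest.approx(3 * P)

    def test_abcb4_excluded_from_efflux_in_influx_mode(self):
        c = counts(abcb4=2, n_pin=1)
        assert effective_efflux_permeability(
            c, scenario("IV", P), abcb4_mode="influx"
        ) == pytest.approx(0.0)

    def test_antagonism_floors_at_zero(self):
        c = counts(abcb1=3, n_pin=3)
        scn = ScenarioConfig("V", p_pin=P, p_syn=P, codependent_sign="antagonistic")
        assert effective_efflux_permeability(c, scn) == 0.0

    def test_negative_counts_rejected(self):
        c = CarrierCounts(abcb1=-1.0)
        with pytest.raises(ModelError):
            effective_efflux_permeability(c, scenario("I"))

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ModelError, match="VI"):
            scenario("VI")

    @pytest.mark.parametrize(
        "reduced, kwargs, reference",
        [
            ("III", dict(p_syn=0.0), "I"),
            ("IV", dict(p_abcb=0.0), "II"),
            ("V", dict(p_pin=0.0), "II"),
        ],
    )
    def test_scenario_equivalences_exact(self, reduced, kwargs, reference, small_template, small_distribution):
        """III with P_SYN=0 equals I; IV with P_ABCB=0 and V with P_PIN=0 equal II."""
        base = dict(p_abcb=P, p_pin=P, p_syn=P)
        base.update(kwargs)
        a = assemble_system(
            small_template, small_distribution, ScenarioConfig(reduced, **base), PhysicalParams()
        )
        b = assemble_system(
            small_template, small_distribution, scenario(reference, P), PhysicalParams()
        )
        assert (a.matrix != b.matrix).nnz == 0
        np.testing.assert_array_equal(a.source, b.source)


class TestMembraneFlux:
    def test_zero_concentrations_zero_flux(self):
        assert membrane_flux(0.0, 0.0, counts(abcb1=1, n_pin=1), PhysicalParams(), scenario("I")) == 0.0

    def test_passive_equilibrium_is_fluxless(self):
        prm = PhysicalParams(p_background=0.0)
        a_cell = 1.0
        a_wall = a_cell * prm.f_cyt / prm.f_wall
        j = membrane_flux(a_cell, a_wall, counts(), prm, scenario("I"))
        assert j == pytest.approx(0.0, abs=1e-15)

    def test_matches_independent_term_by_term_expression(self):
        """Oracle: a from-scratch evaluation of the weak-acid + carrier terms."""
        prm = PhysicalParams()
        c = counts(abcb1=1, abcb19=1, n_pin=2, influx=1.5)
        scn = ScenarioConfig("III", p_abcb=0.3, p_pin=0.7, p_syn=0.2)
        a_cell, a_wall = 1.7, 0.4

        f = lambda ph: 1.0 / (1.0 + 10 ** (ph - prm.pka))
        n = -prm.membrane_potential / GAS_RT_OVER_F
        g = n / (1 - math.exp(-n))
        p_eff = 0.3 * 2 + 0.7 * 2 + 0.2 * 2 * 2 + prm.p_background
        expected = (
            prm.p_iaah * (f(prm.ph_cytoplasm) * a_cell - f(prm.ph_wall) * a_wall)
            + p_eff * g * (1 - f(prm.ph_cytoplasm)) * a_cell
            - prm.p_aux * 1.5 * g * (1 - f(prm.ph_wall)) * a_wall
        )
        assert membrane_flux(a_cell, a_wall, c, prm, scn) == pytest.approx(expected)

    def test_invalid_ph_rejected(self):
        with pytest.raises(ModelError):
            PhysicalParams(ph_wall=15.0)


def closed_params(**kw):
    """Transport-only closed system: no synthesis, degradation or boundary."""
    defaults = dict(
        synthesis=0.0, degradation=0.0, shoot_influx=0.0,
        shoot_outflow=0.0, surface_outflow=0.0,
    )
    defaults.update(kw)
    return PhysicalParams(**defaults)


def uniform_distribution(template, **counts_kw):
    c = counts(**counts_kw)
    return TransporterDistribution(
        counts={s.key: c.copy() for s in template.membrane_segments},
        pd_permeability={w.id: 0.0 for w in template.walls.values()},
    )


class TestAssembly:
    def test_two_cell_fixture_state_dimension(self, two_cell_template):
        dist = uniform_distribution(two_cell_template)
        system = assemble_system(two_cell_template, dist, scenario("I"), closed_params())
        assert system.n == 2 + 7

    def test_closed_system_conserves_mass_at_any_state(self, small_template, small_distribution):
        system = assemble_system(
            small_template, small_distribution, scenario("III"), closed_params()
        )
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.uniform(0, 5, system.n)
            dx = system.matrix @ x + system.source
            assert abs(np.dot(system.capacities, dx)) < 1e-9 * np.abs(
                system.capacities * x
            ).sum()

    def test_zero_state_derivative_is_synthesis(self, two_cell_template):
        dist = uniform_distribution(two_cell_template)
        prm = closed_params(synthesis=0.25)
        system = assemble_system(two_cell_template, dist, scenario("I"), prm)
        dx = system.matrix @ np.zeros(system.n) + system.source
        np.testing.assert_allclose(dx[:2], 0.25)
        np.testing.assert_allclose(dx[2:], 0.0)

    def test_distribution_mismatch_rejected(self, two_cell_template, small_template, small_distribution):
        dist = uniform_distribution(two_cell_template)
        with pytest.raises(ModelError, match="segments"):
            assemble_system(small_template, dist, scenario("I"), closed_params())


class TestSteadyState:
    def test_pd_only_uniform_synthesis_gives_alpha_over_mu(self, two_cell_template):
        dist = uniform_distribution(two_cell_template)
        dist.pd_permeability = {
            w.id: (1.0 if not w.is_boundary else 0.0)
            for w in two_cell_template.walls.values()
        }
        prm = closed_params(synthesis=0.4, degradation=2e-3, p_iaah=0.0, p_aux=0.0,
                            p_background=0.0)
        system = assemble_system(two_cell_template, dist, scenario("I"), prm)
        x = steady_state(system)
        np.testing.assert_allclose(x[:2], 0.4 / 2e-3, rtol=1e-8)

    def test_two_compartment_analytic_solution(self):
        """Hand-solved 2x2 linear system for one cell + one wall.

        dA_c/dt = -(out L / area) A_c + (in L / area) A_w + alpha - mu A_c
        dA_w/dt =  (out / d) A_c - (in / d) A_w
        At steady state the wall balance gives A_w = (out/in) A_c, and the
        cell balance then leaves alpha = mu A_c.
        """
        tpl = build_template_from_rectangles([("cortex", rect(0, 10, 0, 10))])
        dist = uniform_distribution(tpl, abcb1=1)
        prm = closed_params(synthesis=0.3, degradation=1e-3)
        system = assemble_system(tpl, dist, scenario("I"), prm)
        x = steady_state(system, tol=1e-12)
        a_cell = 0.3 / 1e-3
        g = prm.goldman_factors()[1]
        out = prm.p_iaah * prm.f_cyt + (P + prm.p_background) * g * (1 - prm.f_cyt)
        inn = prm.p_iaah * prm.f_wall
        a_wall = out / inn * a_cell
        np.testing.assert_allclose(x[0], a_cell, rtol=1e-8)
        np.testing.assert_allclose(x[1:], a_wall, rtol=1e-8)

    def test_steady_state_matches_long_integration(self, small_template, small_distribution):
        system = assemble_system(
            small_template, small_distribution, scenario("IV"), PhysicalParams()
        )
        x_ss = steady_state(system)
        ts, states = simulate(system, np.zeros(system.n), 2e5, [2e5], rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(states[-1], x_ss, rtol=1e-4, atol=1e-9)

    def test_nonpositive_tolerance_rejected(self, small_template, small_distribution):
        system = assemble_system(
            small_template, small_distribution, scenario("I"), PhysicalParams()
        )
        with pytest.raises(ModelError):
            steady_state(system, tol=0.0)

    def test_linearity_in_sources(self, small_template, small_distribution):
        """Doubling synthesis and boundary influx doubles the steady state."""
        p1 = PhysicalParams()
        p2 = PhysicalParams(synthesis=2 * p1.synthesis, shoot_influx=2 * p1.shoot_influx)
        s1 = assemble_system(small_template, small_distribution, scenario("IV"), p1)
        s2 = assemble_system(small_template, small_distribution, scenario("IV"), p2)
        np.testing.assert_allclose(2 * steady_state(s1), steady_state(s2), rtol=1e-8)


class TestDynamics:
    def test_steady_state_is_a_fixed_point(self, small_template, small_distribution):
        system = assemble_system(
            small_template, small_distribution, scenario("I"), PhysicalParams()
        )
        x = steady_state(system)
        ts, states = simulate(system, x, 600.0, [600.0])
        np.testing.assert_allclose(states[-1], x, rtol=1e-5, atol=1e-10)

    def test_closed_transport_conserves_mass_over_time(self, small_template, small_distribution):
        system = assemble_system(
            small_template, small_distribution, scenario("III"), closed_params()
        )
        rng = np.random.default_rng(1)
        x0 = rng.uniform(0, 2, system.n)
        ts, states = simulate(system, x0, 1800.0, np.linspace(0, 1800, 7))
        masses = [system.total_mass(s) for s in states]
        np.testing.assert_allclose(masses, masses[0], rtol=1e-6)

    def test_pure_decay_mass_strictly_decreasing(self, small_template, small_distribution):
        system = assemble_system(
            small_template, small_distribution, scenario("I"), closed_params(degradation=1e-3)
        )
        x0 = np.ones(system.n)
        ts, states = simulate(system, x0, 3600.0, np.linspace(0, 3600, 5))
        masses = np.array([system.total_mass(s) for s in states])
        assert np.all(np.diff(masses) < 0)

    @settings(max_examples=5, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_nonnegativity_preserved(self, small_template, small_distribution, seed):
        system = assemble_system(
            small_template, small_distribution, scenario("V"), PhysicalParams()
        )
        x0 = np.random.default_rng(seed).uniform(0, 3, system.n)
        ts, states = simulate(system, x0, 900.0, [300.0, 900.0])
        assert states.min() >= 0.0

    def test_negative_initial_condition_rejected(self, small_template, small_distribution):
        system = assemble_system(
            small_template, small_distribution, scenario("I"), PhysicalParams()
        )
        with pytest.raises(ModelError):
            simulate(system, -np.ones(system.n), 10.0)


class TestDeposition:
    def test_zero_amount_stays_at_steady_state(self, small_template, small_distribution):
        system = assemble_system(
            small_template, small_distribution, scenario("IV"), PhysicalParams()
        )
        region = list(small_template.shoot_boundary_cells)
        res = deposit_and_track(system, region, 0.0, 600.0, [0.0, 600.0])
        np.testing.assert_allclose(res["states"][-1], res["baseline"])
        assert np.all(res["readout_mean"] == 0.0)

    def test_initial_mass_is_steady_plus_amount(self, small_template, small_distribution):
        system = assemble_system(
            small_template, small_distribution, scenario("IV"), PhysicalParams()
        )
        region = list(small_template.shoot_boundary_cells)
        amount = 123.0
        res = deposit_and_track(system, region, amount, 60.0, [0.0, 60.0])
        m0 = system.total_mass(res["initial"])
        mb = system.total_mass(res["baseline"])
        assert m0 - mb == pytest.approx(amount, rel=1e-9)

    def test_empty_region_rejected(self, small_template, small_distribution):
        system = assemble_system(
            small_template, small_distribution, scenario("IV"), PhysicalParams()
        )
        with pytest.raises(ModelError, match="empty"):
            deposit_and_track(system, [], 1.0, 60.0)

    def test_mutant_apex_arrival_smaller_than_wild_type(self, small_template, small_distribution):
        """Shoot-boundary deposition under the co-dependent-only-PIN scenario:
        losing both stele ABCBs shuts down rootward delivery."""
        from rootflux.transporters import apply_genotype, genotype

        region = list(small_template.shoot_boundary_cells)
        apex = sorted(
            small_template.cells,
            key=lambda c: small_template.axial_distance(small_template.cells[c]),
        )[:20]
        out = {}
        for g in ("WT", "abcb1 abcb19"):
            dist = apply_genotype(small_distribution, genotype(g))
            system = assemble_system(small_template, dist, scenario("IV"), PhysicalParams())
            res = deposit_and_track(
                system, region, 100.0, 3600.0, np.linspace(0, 3600, 13), readout_region=apex
            )
            out[g] = res["readout_mean"].max()
        assert out["abcb1 abcb19"] < 0.05 * out["WT"]


class TestFluxField:
    def test_uniform_carrierless_equal_ph_system_is_fluxless(self, two_cell_template):
        dist = uniform_distribution(two_cell_template)
        prm = closed_params(ph_wall=7.0, ph_cytoplasm=7.0, p_background=0.0)
        system = assemble_system(two_cell_template, dist, scenario("I"), prm)
        ff = flux_field(np.ones(system.n), system)
        assert all(abs(v) < 1e-14 for v in ff.segment.values())
        assert all(abs(v) < 1e-14 for v in ff.cell_pair.values())

    def test_segment_fluxes_reconstruct_cell_balance(self, small_template, small_distribution):
        """The assembled cell derivative equals the sum of the membrane-segment
        fluxes plus plasmodesmatal exchange, synthesis and degradation."""
        prm = PhysicalParams()
        system = assemble_system(small_template, small_distribution, scenario("III"), prm)
        x = np.random.default_rng(2).uniform(0, 2, system.n)
        ff = flux_field(x, system)
        dx = system.matrix @ x + system.source
        for cid in list(small_template.cells)[::17]:
            cell = small_template.cells[cid]
            total = -sum(
                ff.segment[(cid, s.wall_id)] * s.length
                for s in small_template.segments_of_cell(cid)
            )
            for s in small_template.segments_of_cell(cid):
                w = small_template.walls[s.wall_id]
                if len(w.cell_ids) == 2:
                    other = next(c for c in w.cell_ids if c != cid)
                    rho = small_distribution.pd_permeability[w.id]
                    total += rho * w.length * (
                        x[system.cell_index[other]] - x[system.cell_index[cid]]
                    )
            total = total / cell.area + prm.synthesis_for(cell.cell_type)
            total -= prm.degradation * x[system.cell_index[cid]]
            assert dx[system.cell_index[cid]] == pytest.approx(total, rel=1e-9, abs=1e-12)

    def test_wild_type_reverse_fountain(self, full_template, full_distribution):
        """Net pair flux is rootward in the stele and shootward in the EZ
        epidermis at the wild-type steady state."""
        system, x = rf.simulate_genotype(full_template, scenario("IV"), dist=full_distribution)
        ff = flux_field(x, system)
        tpl = full_template

        def axial_pairs(tissue, zone=None):
            # pair flux is signed from the lower to the higher cell id;
            # reorient it as shootward-positive using the centroids
            for (i, j), f in ff.cell_pair.items():
                ci, cj = tpl.cells[i], tpl.cells[j]
                if ci.cell_type == cj.cell_type == tissue and (
                    zone is None or ci.zone == zone == cj.zone
                ):
                    dy = cj.centroid[1] - ci.centroid[1]  # j is the higher id
                    if abs(dy) > 1.0:  # longitudinal neighbour pair
                        yield f if dy > 0 else -f

        stele = list(axial_pairs("stele"))
        assert stele and sum(1 for f in stele if f < 0) > 0.8 * len(stele)
        epi = list(axial_pairs("epidermis", "EZ"))
        assert epi and sum(1 for f in epi if f > 0) > 0.8 * len(epi)
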