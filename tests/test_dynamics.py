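"""ODE evaluation, integration, and the scaling-symmetry invariance."""

import numpy as np
import pytest

from grnsets.dynamics import (
    DynamicsError,
    IntegrationFailure,
    ParameterSet,
    apply_scaling_symmetry,
    compile_model,
    production_value,
    reduce_parameters,
    rhs,
    simulate,
    simulate_mrna,
)
from grnsets.terms import ACTIVATION, ProductionTerm, named_models


def minimal_params(genes, proteins, translation_rate=None):
    return ParameterSet(
        alpha={g: 1.0 for g in genes},
        k_tx={g: 1.0 for g in genes},
        k_m=0.5,
        k_p=1.0,
        K={i: 1.0 for i in range(1, 7)},
        m0={g: 2.0 for g in genes},
        p0={p: 1.0 for p in proteins},
        translation_rate=translation_rate,
    )


class TestProductionValue:
    def test_activation_at_zero_is_zero_and_repression_is_one(self):
        act = ProductionTerm((("N", ACTIVATION),))
        rep = ProductionTerm((("N", "repression"),))
        assert production_value(act, {"N": 0.0}, (1.0, None)) == 0.0
        assert production_value(rep, {"N": 0.0}, (1.0, None)) == 1.0

    def test_half_max_definition_and_squaring(self):
        act = ProductionTerm((("E", ACTIVATION),))
        sq = ProductionTerm((("E", ACTIVATION),), exponent=2)
        assert production_value(act, {"E": 3.0}, (3.0, None)) == pytest.approx(0.5)
        assert production_value(sq, {"E": 3.0}, (3.0, None)) == pytest.approx(0.25)

    def test_two_factor_term_is_product_and_requires_second_halfmax(self):
        pair = ProductionTerm((("E", ACTIVATION), ("N", ACTIVATION)))
        value = production_value(pair, {"E": 1.0, "N": 1.0}, (1.0, 3.0))
        assert value == pytest.approx(0.5 * 0.25)
        with pytest.raises(DynamicsError):
            production_value(pair, {"E": 1.0, "N": 1.0}, (1.0, None))

    def test_knockout_emptied_term_produces_nothing(self):
        assert production_value(None, {}, (1.0, None)) == 0.0


class TestRhs:
    def test_mrna_balance(self):
        # production factor 0 (activation at zero protein), alpha=1, k_m=0.5, Me=2
        model = named_models()["model_11574"]
        params = minimal_params(model.genes, model.proteins)
        state = np.array([2.0, 2.0, 2.0, 0.0, 0.0, 0.0])
        derivative = rhs(model, state, params)
        assert derivative[:3] == pytest.approx([0.0, 0.0, 0.0])

    def test_protein_balance(self):
        model = named_models()["model_11574"]
        params = minimal_params(model.genes, model.proteins)
        state = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        derivative = rhs(model, state, params)
        assert derivative[3:] == pytest.approx([0.0, 0.0, 0.0])  # dP = M - k_p P = 0

    def test_unified_rhs_matches_hand_coded_equations(self):
        """The packed kernel must reproduce a direct transcription of the structure."""
        model = named_models()["unified"]
        p = ParameterSet(
            alpha={"eud-1": 0.3, "nhr-40": 0.2, "sult-1": 0.1},
            k_tx={"eud-1": 1.5, "nhr-40": 2.0, "sult-1": 0.7},
            k_m=0.4,
            k_p=0.9,
            K={1: 2.0, 2: 3.0, 3: 4.0, 4: 5.0, 5: 6.0, 6: 7.0},
            m0={"eud-1": 1.0, "nhr-40": 1.0, "sult-1": 1.0},
            p0={"E": 1.0, "N": 1.0, "S": 1.0},
        )
        Me, Mn, Ms, E, N, S = 0.8, 1.1, 0.5, 2.5, 1.7, 3.3
        got = rhs(model, np.array([Me, Mn, Ms, E, N, S]), p)
        expected = np.array(
            [
                0.3 + 1.5 * (E / (2 + E)) * (N / (5 + N)) - 0.4 * Me,
                0.2 + 2.0 * (E / (3 + E)) * (N / (6 + N)) - 0.4 * Mn,
                0.1 + 0.7 * (N / (4 + N)) * (S / (7 + S)) - 0.4 * Ms,
                Me - 0.9 * E,
                Mn - 0.9 * N,
                Ms - 0.9 * S,
            ]
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_term_referencing_absent_protein_rejected(self):
        from grnsets.terms import RegulatoryModel, _act

        model = RegulatoryModel(terms={"nhr-40": _act("E"), "sult-1": _act("N")}, knockout=None)
        params = minimal_params(model.genes, model.proteins)
        with pytest.raises(DynamicsError):
            rhs(model, np.ones(4), params)


class TestSimulate:
    def test_closed_form_decay(self):
        """With alpha = k_tx = 0-ish production, Me(t) = Me0 * exp(-k_m t)."""
        model = named_models()["model_11574"]
        params = minimal_params(model.genes, model.proteins)
        # activation terms at ~zero protein levels: set protein ICs tiny
        params.alpha = {g: 1e-300 for g in model.genes}
        params.k_tx = {g: 1e-300 for g in model.genes}
        params.validate = lambda: None  # bypass positivity floor for the analytic limit
        times = np.linspace(0, 72, 25)
        traj = simulate(model, params, times)
        expected = 2.0 * np.exp(-0.5 * times)
        for g in range(3):
            assert np.max(np.abs(traj.mrna[g] - expected)) < 1e-6

    def test_fixed_point_stays_constant(self):
        """Root-find rhs = 0, then integration from the root stays there."""
        from scipy.optimize import fsolve

        model = named_models()["unified"]
        params = minimal_params(model.genes, model.proteins)
        compiled = compile_model(model, params)
        root = fsolve(lambda y: compiled.rhs(0.0, y), np.ones(6), full_output=False)
        assert np.max(np.abs(compiled.rhs(0.0, root))) < 1e-9
        params.m0 = dict(zip(model.genes, root[:3]))
        params.p0 = dict(zip(model.proteins, root[3:]))
        traj = simulate(model, params, np.linspace(0, 72, 10))
        assert np.max(np.abs(traj.mrna - root[:3, None][:3])) < 1e-6

    def test_observables_exclude_hidden_proteins(self, true_params):
        model = named_models()["model_11574"]
        traj = simulate(model, true_params, np.linspace(0, 72, 5))
        assert traj.mrna.shape == (3, 5)
        assert set(traj.genes) == {"eud-1", "nhr-40", "sult-1"}
        frame = traj.to_frame()
        assert set(frame["state"].str.split(":").str[0]) == {"mRNA", "protein"}

    def test_boundedness_of_mrna(self, true_params):
        """M_g(t) <= max(M_g(0), (alpha_g + k_tx_g) / k_m): production factors <= 1."""
        model = named_models()["unified"]
        traj = simulate(model, true_params, np.linspace(0, 200, 50))
        for g, gene in enumerate(traj.genes):
            bound = max(
                true_params.m0[gene],
                (true_params.alpha[gene] + true_params.k_tx[gene]) / true_params.k_m,
            )
            assert traj.mrna[g].max() <= bound * (1 + 1e-9)

    def test_fast_path_agrees_with_reference_integrator(self, true_params):
        model = named_models()["model_11574"]
        times = np.linspace(0, 72, 20)
        reference = simulate(model, true_params, times)
        fast = simulate_mrna(compile_model(model, true_params), times)
        assert np.max(np.abs(fast - reference.mrna)) < 1e-4

    def test_integration_failure_is_reported_not_clipped(self):
        model = named_models()["model_11574"]
        params = minimal_params(model.genes, model.proteins)
        params.k_m = 1e300  # absurd stiffness must fail loudly
        params.validate = lambda: None
        with pytest.raises((IntegrationFailure, DynamicsError)):
            simulate(model, params, np.linspace(0, 72, 5))


class TestScalingSymmetry:
    def test_identity_and_group_composition(self):
        model = named_models()["model_11574"]
        params = minimal_params(model.genes, model.proteins, translation_rate=2.0)
        assert apply_scaling_symmetry(params, 1.0) == params
        twice_thrice = apply_scaling_symmetry(apply_scaling_symmetry(params, 2.0), 3.0)
        assert twice_thrice == apply_scaling_symmetry(params, 6.0)
        with pytest.raises(DynamicsError):
            apply_scaling_symmetry(params, 0.0)

    def test_reduced_params_reject_symmetry(self):
        model = named_models()["model_11574"]
        params = minimal_params(model.genes, model.proteins)
        with pytest.raises(DynamicsError):
            apply_scaling_symmetry(params, 2.0)

    def test_mrna_observables_invariant_under_symmetry(self):
        """Random parameter draws: xi in {0.01, 1, 100} leaves mRNA unchanged."""
        model = named_models()["unified"]
        rng = np.random.default_rng(7)
        times = np.linspace(0, 72, 13)
        for _ in range(5):
            params = ParameterSet(
                alpha={g: rng.uniform(0.01, 0.5) for g in model.genes},
                k_tx={g: rng.uniform(0.1, 2.0) for g in model.genes},
                k_m=rng.uniform(0.05, 0.5),
                k_p=rng.uniform(0.02, 0.5),
                K={i: rng.uniform(0.5, 20.0) for i in range(1, 7)},
                m0={g: rng.uniform(0.05, 1.0) for g in model.genes},
                p0={p: rng.uniform(0.1, 5.0) for p in model.proteins},
                translation_rate=rng.uniform(0.2, 3.0),
            )
            reference = simulate(model, params, times).mrna
            for xi in (1e-2, 1e2):
                transformed = apply_scaling_symmetry(params, xi)
                moved = simulate(model, transformed, times).mrna
                assert np.max(np.abs(moved - reference)) < 1e-6

    def test_reduction_equals_unit_translation_rate(self):
        """Reduced coordinates = the unreduced model at k_t = 1, exactly in the rhs."""
        model = named_models()["unified"]
        params = minimal_params(model.genes, model.proteins, translation_rate=1.0)
        reduced = reduce_parameters(params)
        state = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        assert rhs(model, state, params) == pytest.approx(rhs(model, state, reduced), rel=1e-14)
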