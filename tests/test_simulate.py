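"""Steady-state labeling: convolution, EMU solve, enrichment, oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import emuflux as ef
from emuflux.simulate import MID, isotopomer_mid

mid_strategy = st.lists(
    st.floats(0.0, 1.0, allow_nan=False), min_size=2, max_size=7
).filter(lambda xs: sum(xs) > 1e-6).map(lambda xs: MID(tuple(xs)))


def test_convolution_worked_example():
    dhap = MID((0.3, 0.0, 0.7, 0.0))
    gap = MID((0.5, 0.0, 0.5, 0.0))
    out = ef.convolve(dhap, gap)
    assert out[0] == pytest.approx(0.15)
    assert out[2] == pytest.approx(0.50)
    assert out[4] == pytest.approx(0.35)


def test_convolution_identity_and_full_label():
    x = MID((0.2, 0.3, 0.5))
    ident = MID((1.0, 0.0))
    out = ef.convolve(x, ident)
    assert out.as_array()[:3] == pytest.approx(x.as_array())
    assert out[3] == 0.0
    both = ef.convolve(MID((0.0, 1.0)), MID((0.0, 1.0)))
    assert both.fractions == (0.0, 0.0, 1.0)


@given(a=mid_strategy, b=mid_strategy, c=mid_strategy)
def test_convolution_commutative_associative(a, b, c):
    ab = ef.convolve(a, b)
    ba = ef.convolve(b, a)
    assert np.allclose(ab.as_array(), ba.as_array(), atol=1e-12)
    left = ef.convolve(ab, c).as_array()
    right = ef.convolve(a, ef.convolve(b, c)).as_array()
    assert np.allclose(left, right, atol=1e-12)


@given(a=mid_strategy, b=mid_strategy)
def test_enrichment_of_convolution_is_weighted_average(a, b):
    na, nb = a.n_atoms, b.n_atoms
    combined = ef.enrichment(ef.convolve(a, b))
    expected = (ef.enrichment(a) * na + ef.enrichment(b) * nb) / (na + nb)
    assert combined == pytest.approx(expected, abs=1e-10)


def test_steady_state_matches_matrix_solution(glycolysis):
    """The four size-3 MIDs match the closed-form matrix inversion."""
    net = ef.decompose(glycolysis.model, ["FBP[1-6]"])
    mids = {str(e): m for e, m in ef.solve_steady(net, glycolysis.fluxes, glycolysis.tracer).items()}
    assert mids["FBP[1-3]"].as_array() == pytest.approx([0.1, 0, 0.9, 0], abs=1e-9)
    assert mids["FBP[4-6]"].as_array() == pytest.approx([5 / 6, 0, 1 / 6, 0], abs=1e-9)
    assert mids["DHAP[1-3]"].as_array() == pytest.approx([0.3, 0, 0.7, 0], abs=1e-9)
    assert mids["GAP[1-3]"].as_array() == pytest.approx([0.5, 0, 0.5, 0], abs=1e-9)
    fbp = mids["FBP[1-6]"].as_array()
    assert fbp[0] == pytest.approx(0.05, abs=1e-9)
    assert fbp[2] == pytest.approx(0.83333, abs=1e-4)
    assert fbp[4] == pytest.approx(0.11667, abs=1e-4)


def test_steady_state_derived_flux_setting(glycolysis):
    """At f3=48, f5=210 the FBP MID matches the independently solved system."""
    spec = ef.derive_free_fluxes(glycolysis.model, {"f1": 100.0})
    fluxes = spec.flux_state([48.0, 210.0])
    net = ef.decompose(glycolysis.model, ["FBP[1-6]"])
    mids = ef.solve_steady(net, fluxes, glycolysis.tracer)
    fbp = mids[ef.EMU("FBP", tuple(range(1, 7)))].as_array()
    # frozen from a hand-built 4-unknown linear solve of the balance system
    assert fbp[[0, 2, 4]] == pytest.approx([0.054926, 0.837838, 0.107236], abs=1e-5)


def test_unlabeled_tracer_gives_all_m0(glycolysis):
    tracer = ef.TracerSpec({})
    net = ef.decompose(glycolysis.model, ["FBP[1-6]"])
    for mid in ef.solve_steady(net, glycolysis.fluxes, tracer).values():
        assert mid[0] == pytest.approx(1.0, abs=1e-12)


def test_zero_inflow_emu_raises(glycolysis):
    net = ef.decompose(glycolysis.model, ["FBP[1-6]"])
    dead = dict(glycolysis.fluxes)
    dead["f1"] = 0.0
    dead["f3"] = 0.0
    with pytest.raises(ef.ModelError, match="zero total inflow"):
        ef.solve_steady(net, dead, glycolysis.tracer)


@pytest.mark.parametrize(
    "mid, n, expected",
    [
        (MID((0.05, 0.0, 0.8333, 0.0, 0.1167, 0.0, 0.0)), 6, 0.35556),
        (MID((1.0, 0.0, 0.0)), 2, 0.0),
        (MID((0.0, 0.0, 1.0)), 2, 1.0),
    ],
)
def test_enrichment(mid, n, expected):
    assert mid.n_atoms == n
    assert ef.enrichment(mid) == pytest.approx(expected, abs=1e-4)


def test_positional_enrichment(glycolysis):
    b = glycolysis
    # C2 of DHAP receives label, C3 never does under the C1/C2 tracer
    assert ef.positional_enrichment(b.model, b.fluxes, b.tracer, "DHAP", 2) == pytest.approx(0.7, abs=1e-9)
    assert ef.positional_enrichment(b.model, b.fluxes, b.tracer, "DHAP", 3) == pytest.approx(0.0, abs=1e-9)
    unlabeled = ef.TracerSpec({})
    assert ef.positional_enrichment(b.model, b.fluxes, unlabeled, "DHAP", 1) == pytest.approx(0.0, abs=1e-12)


def test_flux_scaling_leaves_mids_invariant(glycolysis):
    net = ef.decompose(glycolysis.model, ["FBP[1-6]"])
    base = ef.solve_steady(net, glycolysis.fluxes, glycolysis.tracer)
    for lam in (0.37, 5.0):
        scaled = {k: lam * v for k, v in glycolysis.fluxes.items()}
        mids = ef.solve_steady(net, scaled, glycolysis.tracer)
        for e in base:
            assert np.allclose(mids[e].as_array(), base[e].as_array(), atol=1e-12)


def test_producer_only_dependence(glycolysis):
    """Changing the sink drain (a pure consumption flux of GAP's ancestors'
    non-producing path) leaves measured MIDs unchanged."""
    net = ef.decompose(glycolysis.model, ["FBP[1-6]"])
    base = ef.solve_steady(net, glycolysis.fluxes, glycolysis.tracer)
    altered = dict(glycolysis.fluxes)
    altered["f6"] = 123.0  # breaks GAP's balance but f6 produces nothing measured
    mids = ef.solve_steady(net, altered, glycolysis.tracer)
    for e in base:
        assert np.allclose(mids[e].as_array(), base[e].as_array(), atol=1e-12)


@pytest.mark.parametrize("f3,f5", [(50.0, 150.0), (48.0, 210.0), (70.0, 90.0)])
def test_oracle_equivalence(glycolysis, f3, f5):
    """EMU solver matches the brute-force full-isotopomer fixed point."""
    spec = ef.derive_free_fluxes(glycolysis.model, {"f1": 100.0})
    fluxes = spec.flux_state([f3, f5])
    dists = ef.brute_force_isotopomer_steady(glycolysis.model, fluxes, glycolysis.tracer)
    net = ef.decompose(glycolysis.model, ["FBP[1-6]", "DHAP[1-3]", "GAP[1-3]"])
    mids = {str(e): m for e, m in ef.solve_steady(net, fluxes, glycolysis.tracer).items()}
    for met, label in [("FBP", "FBP[1-6]"), ("DHAP", "DHAP[1-3]"), ("GAP", "GAP[1-3]")]:
        oracle = isotopomer_mid(dists[met]).as_array()
        assert np.allclose(mids[label].as_array(), oracle, atol=1e-6)


def test_oracle_equivalence_u13c_mixture(glycolysis):
    tracer = ef.tracer_u13c_mixture(0.5)
    dists = ef.brute_force_isotopomer_steady(glycolysis.model, glycolysis.fluxes, tracer)
    net = ef.decompose(glycolysis.model, ["FBP[1-6]"])
    mids = ef.solve_steady(net, glycolysis.fluxes, tracer)
    fbp = mids[ef.EMU("FBP", tuple(range(1, 7)))].as_array()
    assert np.allclose(fbp, isotopomer_mid(dists["FBP"]).as_array(), atol=1e-6)


def test_oracle_single_carbon_chain():
    model = ef.parse_model(
        "A, 1, source\nB, 1, balanced\nOut, 1, sink\n"
        "f1: A (a) -> B (a)\nf2: B (a) -> Out (a)\n"
    )
    tracer = ef.TracerSpec({"A": ((frozenset({1}), 0.5), (frozenset(), 0.5))})
    dists = ef.brute_force_isotopomer_steady(model, {"f1": 1.0, "f2": 1.0}, tracer)
    assert dists["B"] == pytest.approx([0.5, 0.5])
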