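"""Network parsing, balance constraints, and free-flux parameterization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import emuflux as ef
from emuflux.fixtures import UPPER_GLYCOLYSIS_TEXT


def test_parse_upper_glycolysis():
    model = ef.parse_model(UPPER_GLYCOLYSIS_TEXT)
    assert len(model.metabolites) == 5
    assert model.flux_ids == ("f1", "f2", "f3", "f4", "f5", "f6")
    assert model.metabolite("Glc").role == "source"
    assert model.metabolite("FBP").n_atoms == 6
    assert model.metabolite("Lower").role == "sink"


@pytest.mark.parametrize(
    "text, fragment",
    [
        ("A, 2, source\nB, 2, sink\n", "no reactions"),
        (
            "A, 2, source\nB, 3, sink\nfX: A (ab) -> B (abc)\n",
            "not present on the substrate side",
        ),
        (
            "A, 2, source\nB, 2, sink\nf1: A (ab) -> B (ab)\nf1: A (ab) -> B (ba)\n",
            "duplicate flux_id",
        ),
        ("A, 2, source\nB, 2, sink\nf1: A (abc) -> B (ab)\n", "expected 2"),
        ("A, 2, source\nf1: A (ab) -> C (ab)\n", "unknown metabolite"),
        (
            "A, 2, source\nB, 2, balanced\nf1: A (ab) -> B (ab)\n",
            "no consuming step",
        ),
    ],
)
def test_parse_errors(text, fragment):
    with pytest.raises(ef.ModelError, match=fragment):
        ef.parse_model(text)


def test_parse_error_carries_line_number():
    text = "A, 2, source\nB, 2, sink\nbroken line here\n"
    with pytest.raises(ef.ParseError, match="line 3"):
        ef.parse_model(text)


def test_symmetry_must_be_involution():
    with pytest.raises(ef.ModelError, match="involution"):
        ef.MetaboliteSpec("Suc", 4, "balanced", symmetry=(2, 3, 4, 1))
    # 4321 reversal is a valid involution
    ef.MetaboliteSpec("Suc", 4, "balanced", symmetry=(4, 3, 2, 1))


def test_model_roundtrip(glycolysis):
    text = ef.write_model(glycolysis.model)
    again = ef.parse_model(text)
    assert ef.balance_constraints(again) == ef.balance_constraints(glycolysis.model)
    assert again.flux_ids == glycolysis.model.flux_ids
    net_a = ef.decompose(glycolysis.model, ["FBP[1-6]"])
    net_b = ef.decompose(again, ["FBP[1-6]"])
    assert net_a.export_edges() == net_b.export_edges()


def test_balance_constraints_upper_glycolysis(glycolysis):
    eqs = ef.balance_constraints(glycolysis.model)
    assert set(eqs) == {"FBP", "DHAP", "GAP"}
    assert eqs["FBP"] == {"f1": 1.0, "f3": 1.0, "f2": -1.0}
    assert eqs["DHAP"] == {"f2": 1.0, "f5": 1.0, "f3": -1.0, "f4": -1.0}
    assert eqs["GAP"] == {"f2": 1.0, "f4": 1.0, "f3": -1.0, "f5": -1.0, "f6": -1.0}


def test_balance_constraints_trivial_cases():
    chain = ef.parse_model(
        "A, 1, source\nB, 1, balanced\nC, 1, sink\n"
        "fAB: A (a) -> B (a)\nfBC: B (a) -> C (a)\n"
    )
    assert ef.balance_constraints(chain) == {"B": {"fAB": 1.0, "fBC": -1.0}}
    no_balance = ef.parse_model("A, 1, source\nC, 1, sink\nf1: A (a) -> C (a)\n")
    assert ef.balance_constraints(no_balance) == {}


def test_free_fluxes_match_manual_elimination(glycolysis):
    spec = ef.derive_free_fluxes(glycolysis.model, {"f1": 100.0})
    assert spec.free_ids == ("f3", "f5")
    fs = spec.flux_state([50.0, 150.0])
    assert fs["f2"] == pytest.approx(150.0)
    assert fs["f4"] == pytest.approx(250.0)
    assert fs["f6"] == pytest.approx(200.0)
    fs2 = spec.flux_state([70.0, 90.0])
    assert fs2["f2"] == pytest.approx(170.0)
    assert fs2["f4"] == pytest.approx(190.0)
    assert fs2["f6"] == pytest.approx(200.0)


def test_all_fixed_gives_constant_map(glycolysis):
    fixed = {"f1": 100.0, "f2": 150.0, "f3": 50.0, "f4": 250.0, "f5": 150.0, "f6": 200.0}
    spec = ef.derive_free_fluxes(glycolysis.model, fixed)
    assert spec.free_ids == ()
    assert spec.flux_state([]) == pytest.approx(fixed)


def test_inconsistent_fixed_set_raises(glycolysis):
    with pytest.raises(ef.ModelError, match="inconsistent"):
        ef.derive_free_fluxes(glycolysis.model, {"f1": 100.0, "f6": 100.0})


@given(
    f3=st.floats(0.0, 1e3, allow_nan=False),
    f5=st.floats(0.0, 1e3, allow_nan=False),
)
def test_free_flux_map_always_satisfies_balance(f3, f5):
    bundle = ef.build_upper_glycolysis()
    spec = ef.derive_free_fluxes(bundle.model, {"f1": 100.0})
    full = spec.full_vector([f3, f5])
    fluxes = dict(zip(spec.all_ids, full))
    for eq in ef.balance_constraints(bundle.model).values():
        net = sum(c * fluxes[f] for f, c in eq.items())
        scale = max(abs(fluxes[f]) for f in eq)
        assert abs(net) <= 1e-9 * max(scale, 1.0)


def test_read_measurements_renormalizes():
    ms = ef.read_measurements(
        "emu,mass_shift,fraction,sd\n"
        "FBP[1-6],0,0.05,0.01\nFBP[1-6],2,0.8333,0.01\nFBP[1-6],4,0.1167,0.01\n"
    )
    assert len(ms) == 1
    assert len(ms[0].mids) == 3
    assert sum(f for _, f in ms[0].mids) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize(
    "body, fragment",
    [
        ("FBP[1-6],0,0.4,0.01\nFBP[1-6],2,0.5,0.01\n", "outside"),
        ("FBP[1-6],0,0.5,0.01\nFBP[1-6],0,0.5,0.01\n", "duplicate"),
        ("FBP[1-6],0,0.5,-0.01\nFBP[1-6],2,0.5,0.01\n", "positive"),
        ("FBP[1-6],0,abc,0.01\n", "bad measurement row"),
    ],
)
def test_read_measurements_rejects(body, fragment):
    with pytest.raises(ef.ModelError, match=fragment):
        ef.read_measurements("emu,mass_shift,fraction,sd\n" + body)
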