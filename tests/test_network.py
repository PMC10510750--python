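"""Reaction parsing, network construction, stoichiometry, flux splitting."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emuflux.network import (MetabolicNetwork, NetworkError, parse_reaction,
                             read_network, read_network_xlsx,
                             split_total_fluxes, validate_network)

TOY_TSV = """id\tequation\treversible
v1\tA{abc} -> B{abc}\t0
v2\tB{abc} -> D{abc}\t1
v3\tB{abc} -> C{bc} + E{a}\t0
v4\tB{abc} + C{de} -> D{bcd} + E{a} + E{e}\t0
v5\tD{abc} -> F{abc}\t0
"""


class TestParseReaction:
    def test_cleavage(self):
        r = parse_reaction("v3: B{abc} -> C{bc} + E{a}")
        assert r.id == "v3" and not r.reversible
        assert r.substrates == [("B", 1, "abc")]
        assert r.products == [("C", 1, "bc"), ("E", 1, "a")]

    def test_condensation(self):
        # phosphoenolpyruvate + CO2 -> oxaloacetate
        r = parse_reaction("ppc: PEP{abc} + CO2{d} -> OAA{abcd}")
        assert len(r.substrates) == 2
        assert r.products == [("OAA", 1, "abcd")]

    def test_unbalanced_letters_rejected(self):
        with pytest.raises(NetworkError):
            parse_reaction("bad: A{ab} -> B{abc}")

    def test_nocheck_flag_allows_imbalance(self):
        r = parse_reaction("biom: A{ab} -> B{abc} [nocheck]")
        assert not r.carbon_checked

    def test_duplicate_letter_within_molecule(self):
        with pytest.raises(NetworkError):
            parse_reaction("dup: A{aa} -> B{aa}")

    def test_malformed_inputs(self):
        with pytest.raises(NetworkError):
            parse_reaction("noarrow: A{a} B{a}")
        with pytest.raises(NetworkError):
            parse_reaction("A{a} -> B{a}")  # missing id
        with pytest.raises(NetworkError):
            parse_reaction("neg: -1 A{a} -> B{a}")

    def test_reversible_markers(self):
        assert parse_reaction("r: A{a} <-> B{a}").reversible
        assert parse_reaction("r: A{a} -> B{a} [rev]").reversible
        assert not parse_reaction("r: A{a} -> B{a}").reversible

    def test_fractional_coefficients(self):
        # symmetric product listed twice at coefficient 1/2
        r = parse_reaction("sym: S{abcd} -> 1/2 Fum{abcd} + 1/2 Fum{dcba}")
        assert [str(c) for _, c, _ in r.products] == ["1/2", "1/2"]


class TestReadNetwork:
    def test_toy_counts(self):
        net = read_network(io.StringIO(TOY_TSV))
        assert len(net.metabolites) == 6
        assert len(net.reactions) == 5
        assert net.total_flux_ids == ["v1", "v2_f", "v2_b", "v3", "v4", "v5"]

    def test_roles_inferred(self):
        net = read_network(io.StringIO(TOY_TSV))
        assert net.metabolites["A"].is_substrate
        assert net.metabolites["F"].is_excreted
        assert net.metabolites["E"].is_excreted
        assert sorted(net.balanced_metabolites) == ["B", "C", "D"]

    def test_role_override(self):
        net = read_network(io.StringIO(TOY_TSV), excreted=["D"])
        assert net.metabolites["D"].is_excreted
        assert not net.metabolites["D"].is_balanced

    def test_empty_file(self):
        with pytest.raises(NetworkError, match="no reactions"):
            read_network(io.StringIO("id\tequation\treversible\n"))

    @pytest.mark.parametrize("token", ["1", "TRUE", "yes", "Y"])
    def test_reversible_dialect(self, token):
        net = read_network(io.StringIO(
            f"id\tequation\treversible\nr\tA{{a}} -> B{{a}}\t{token}\n"))
        assert net.reactions["r"].reversible

    def test_inconsistent_carbon_count(self):
        text = ("id\tequation\treversible\n"
                "r1\tA{ab} -> B{ab}\t0\n"
                "r2\tB{abc} -> C{abc}\t0\n")
        with pytest.raises(NetworkError, match="atoms"):
            read_network(io.StringIO(text))

    def test_duplicate_reaction_id(self):
        text = ("id\tequation\treversible\n"
                "r\tA{a} -> B{a}\t0\n"
                "r\tB{a} -> C{a}\t0\n")
        with pytest.raises(NetworkError, match="duplicate"):
            read_network(io.StringIO(text))


class TestStoichiometricMatrix:
    def test_toy_rows_are_balanced_metabolites(self):
        net = read_network(io.StringIO(TOY_TSV))
        S = net.stoichiometric_matrix()
        assert sorted(S.index) == ["B", "C", "D"]  # A substrate, E/F excreted
        # hand-derived column of v4: B -1, C -1, D +1
        assert S.loc["B", "v4"] == -1 and S.loc["C", "v4"] == -1
        assert S.loc["D", "v4"] == 1

    def test_single_reaction_both_balanced(self):
        net = MetabolicNetwork()
        net.add_reaction(parse_reaction("r: A{a} -> B{a}"))
        net.set_roles(substrates=[], excreted=[])
        # force both balanced to read off the raw column
        net.metabolites["A"].is_balanced = True
        net.metabolites["B"].is_balanced = True
        S = net.stoichiometric_matrix()
        assert np.allclose(sorted(S["r"]), [-1.0, 1.0])

    def test_reversible_column_negation(self):
        net = read_network(io.StringIO(TOY_TSV))
        S = net.stoichiometric_matrix()
        assert np.allclose(S["v2_f"], -S["v2_b"])


@pytest.fixture(scope="module")
def toy_net_module():
    return read_network(io.StringIO(TOY_TSV))


class TestSplitTotalFluxes:
    @pytest.fixture()
    def net(self, toy_net_module):
        return toy_net_module

    def test_examples(self, net):
        v = split_total_fluxes(net, {"v1": 10, "v2": 10, "v3": 0.0,
                                     "v4": 0.0, "v5": 10}, {"v2": 0})
        assert v["v2_f"] == 10 and v["v2_b"] == 0
        v = split_total_fluxes(net, {"v1": 10, "v2": 10, "v3": 0.0,
                                     "v4": 0.0, "v5": 10}, {"v2": 5})
        assert v["v2_f"] == 15 and v["v2_b"] == 5
        v = split_total_fluxes(net, {"v1": 10, "v2": -4, "v3": 7,
                                     "v4": 7, "v5": 3}, {"v2": 5})
        assert v["v2_f"] == 5 and v["v2_b"] == 9
        assert v.net("v2") == -4  # v_f - v_b invariant

    def test_negative_exchange_rejected(self, net):
        with pytest.raises(NetworkError):
            split_total_fluxes(net, {"v1": 10, "v2": 0, "v3": 5, "v4": 5,
                                     "v5": 5}, {"v2": -1})

    def test_negative_irreversible_rejected(self, net):
        with pytest.raises(NetworkError):
            split_total_fluxes(net, {"v1": -10, "v2": 0, "v3": 5, "v4": 5,
                                     "v5": 5})

    @settings(derandomize=True, max_examples=50)
    @given(vnet=st.floats(-50, 50), vxch=st.floats(0, 50))
    def test_net_invariant_property(self, toy_net_module, vnet, vxch):
        v = split_total_fluxes(toy_net_module,
                               {"v1": 10, "v2": vnet, "v3": 1, "v4": 1,
                                "v5": 1}, {"v2": vxch})
        assert v.net("v2") == pytest.approx(vnet, abs=1e-12)
        assert v["v2_f"] >= 0 and v["v2_b"] >= 0


class TestValidateNetwork:
    def test_toy_ok(self):
        net = read_network(io.StringIO(TOY_TSV))
        assert validate_network(net).ok

    def test_orphan_balanced_metabolite_flagged(self):
        net = read_network(io.StringIO(TOY_TSV))
        net.metabolites["E"].is_balanced = True  # never consumed
        rep = validate_network(net)
        assert not rep.ok and "E" in rep.dead_end_metabolites

    def test_nocheck_reactions_listed(self):
        net = MetabolicNetwork()
        net.add_reaction(parse_reaction("r: A{a} -> B{a}"))
        net.add_reaction(parse_reaction("biom: B{a} -> X [nocheck]"))
        rep = validate_network(net)
        assert "biom" in rep.carbon_unbalanced_reactions


def test_xlsx_importer(tmp_path):
    import pandas as pd
    df = pd.DataFrame({
        "id": ["v1", "v2"],
        "reactants_with_atoms": ["A{ab}", "B{ab}"],
        "products_with_atoms": ["B{ab}", "F{ab}"],
        "reversible": [0, 0],
    })
    path = tmp_path / "net.xlsx"
    df.to_excel(path, index=False)
    net = read_network_xlsx(path)
    assert list(net.reactions) == ["v1", "v2"]
    assert net.metabolites["A"].is_substrate
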