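"""Parameter/cell validation and network wiring."""

import pytest

from canoncircuit import CellId, ModelParams, build_network, reference_params


class TestModelParams:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="decay_exc"):
            ModelParams(decay_exc=-1.0)

    def test_negative_eta_rejected(self):
        with pytest.raises(ValueError, match="eta_inh"):
            ModelParams(eta_inh=-0.1)

    def test_replace_returns_new_instance(self):
        p = reference_params()
        q = p.replace(W_inh=0.7)
        assert q.W_inh == 0.7
        assert p.W_inh != 0.7 or p is not q

    def test_zero_tau_rejected(self):
        with pytest.raises(ValueError, match="tau_gain"):
            ModelParams(tau_gain=0.0)


class TestCellId:
    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="role"):
            CellId("s", "exc_c")

    def test_unknown_location_rejected(self):
        with pytest.raises(ValueError, match="location"):
            CellId("t", "exc_a")

    def test_excitatory_flag(self):
        assert CellId("s", "exc_a").is_excitatory
        assert not CellId("s", "inh_ab").is_excitatory


class TestBuildNetwork:
    def test_single_location_wiring(self, ref_params):
        net = build_network(ref_params, locations=1)
        assert len(net.cells) == 4
        assert len(net.couplings) == 4
        kinds = sorted(c.kind for c in net.couplings)
        assert kinds == ["excitatory", "excitatory", "inhibitory", "inhibitory"]
        # disinhibition wiring: exc_a -> inh_ab -| exc_b and symmetric
        exc = {(c.pre.role, c.post.role) for c in net.couplings if c.kind == "excitatory"}
        inh = {(c.pre.role, c.post.role) for c in net.couplings if c.kind == "inhibitory"}
        assert exc == {("exc_a", "inh_ab"), ("exc_b", "inh_ba")}
        assert inh == {("inh_ab", "exc_b"), ("inh_ba", "exc_a")}

    def test_isolation_removes_inhibitory_couplings_only(self, ref_params):
        net = build_network(ref_params, isolation=True)
        assert len(net.cells) == 4
        assert len(net.couplings) == 2
        assert all(c.kind == "excitatory" for c in net.couplings)

    def test_two_locations_disjoint(self, ref_params):
        net = build_network(ref_params, locations=2)
        assert len(net.cells) == 8
        assert len(net.couplings) == 8
        assert all(c.pre.location == c.post.location for c in net.couplings)

    def test_bad_location_count_rejected(self, ref_params):
        with pytest.raises(ValueError, match="locations"):
            build_network(ref_params, locations=3)

    def test_couplings_carry_their_adaptation_parameters(self, ref_params):
        net = build_network(ref_params)
        for c in net.couplings:
            expected = ref_params.eta_inh if c.kind == "inhibitory" else ref_params.eta_exc
            assert c.eta == expected
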