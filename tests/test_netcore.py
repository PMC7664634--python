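"""Network containers, BIF I/O, ancestral sampling, synthetic generator."""

import io

import numpy as np
import pytest

import blockbn as bb
from blockbn.netcore import BifParseError

from conftest import make_random_net


class TestReadBif:
    def test_minimal_single_node(self, toy_bif_one):
        net = bb.read_bif(toy_bif_one)
        assert net.variables == ["A"]
        assert net.edges == set()
        np.testing.assert_allclose(net.cpts["A"], [[0.5, 0.5]])

    def test_two_node_edge_and_cpt_rows(self, toy_bif_two):
        net = bb.read_bif(toy_bif_two)
        assert net.edges == {("A", "B")}
        assert net.cpts["B"].shape == (2, 2)
        np.testing.assert_allclose(net.cpts["B"][0], [0.9, 0.1])

    def test_malformed_reports_line(self, tmp_path):
        bad = tmp_path / "bad.bif"
        bad.write_text("network x {\n}\nvariable A {\n  type discrete [ 2 ] "
                       "{ a, b };\n}\nprobability ( A ) {\n  table 0.5, 0.9;\n}\n")
        with pytest.raises(BifParseError, match="sums to"):
            bb.read_bif(bad)

    def test_unknown_variable_errors(self, tmp_path):
        bad = tmp_path / "bad.bif"
        bad.write_text("network x {\n}\nprobability ( Z ) {\n table 1.0;\n}\n")
        with pytest.raises(BifParseError, match="unknown variable"):
            bb.read_bif(bad)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip(self, seed):
        net = bb.generate_block_network(
            bb.SyntheticSpec(n_blocks=2, nodes_per_block=3,
                             intra_density=0.7, n_inter_edges=1, seed=seed))
        buf = io.StringIO()
        bb.write_bif(net, buf)
        back = bb.read_bif(io.StringIO(buf.getvalue()))
        assert back.variables == net.variables
        assert back.edges == net.edges
        for v in net.variables:
            np.testing.assert_allclose(back.cpts[v], net.cpts[v], atol=1e-9)


class TestForwardSample:
    def test_deterministic_cpts_force_configuration(self):
        net = bb.DiscreteBayesNet(
            ["A", "B"], {"A": 2, "B": 2}, {"A": (), "B": ("A",)},
            {"A": np.array([[0.0, 1.0]]),
             "B": np.array([[1.0, 0.0], [0.0, 1.0]])}).validate()
        data = bb.forward_sample(net, 50, seed=7)
        assert (data.values == [1, 1]).all()

    def test_binary_frequency_within_binomial_bound(self):
        net = bb.DiscreteBayesNet(["A"], {"A": 2}, {"A": ()},
                                  {"A": np.array([[0.5, 0.5]])})
        data = bb.forward_sample(net, 10000, seed=3)
        freq = data.values.mean()
        assert abs(freq - 0.5) <= 3 * np.sqrt(0.25 / 10000)

    def test_same_seed_bit_identical(self):
        net = make_random_net(4, 5)
        a = bb.forward_sample(net, 200, seed=11)
        b = bb.forward_sample(net, 200, seed=11)
        assert (a.values == b.values).all()

    def test_root_marginal_converges(self):
        """Empirical root marginal within 4 sigma of the CPT at n=50000."""
        net = make_random_net(3, 9)
        root = net.topological_order()[0]
        i = net.variables.index(root)
        probs = net.cpts[root][0]
        data = bb.forward_sample(net, 50000, seed=2)
        counts = np.bincount(data.values[:, i],
                             minlength=net.cardinalities[root])
        for s, p in enumerate(probs):
            se = np.sqrt(max(p * (1 - p), 1e-12) / 50000)
            assert abs(counts[s] / 50000 - p) <= 4 * se + 1e-9

    def test_rejects_nonpositive_n(self):
        net = make_random_net(2, 0)
        with pytest.raises(ValueError):
            bb.forward_sample(net, 0, seed=0)


class TestGenerateBlockNetwork:
    def test_density_one_gives_complete_dag(self):
        net = bb.generate_block_network(
            bb.SyntheticSpec(n_blocks=1, nodes_per_block=3,
                             intra_density=1.0, n_inter_edges=0, seed=0))
        assert len(net.edges) == 3

    def test_interblock_edge_count_exact(self):
        spec = bb.SyntheticSpec(n_blocks=2, nodes_per_block=3,
                                intra_density=0.5, n_inter_edges=1, seed=4)
        net = bb.generate_block_network(spec)
        crossing = [(u, v) for u, v in net.edges
                    if int(u[1:]) // 3 != int(v[1:]) // 3]
        assert len(crossing) == 1

    def test_seed_determinism(self):
        spec = bb.SyntheticSpec(seed=8)
        a = bb.generate_block_network(spec)
        b = bb.generate_block_network(spec)
        assert a.edges == b.edges
        for v in a.variables:
            np.testing.assert_array_equal(a.cpts[v], b.cpts[v])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            bb.SyntheticSpec(intra_density=1.5).validate()
        with pytest.raises(ValueError):
            bb.SyntheticSpec(n_blocks=1, n_inter_edges=2).validate()

    @pytest.mark.parametrize("seed", range(4))
    def test_output_passes_net_invariants_and_rows_nonuniform(self, seed):
        net = bb.generate_block_network(bb.SyntheticSpec(seed=seed))
        net.validate()
        for v in net.variables:
            cpt = net.cpts[v]
            r = net.cardinalities[v]
            tv = 0.5 * np.abs(cpt - 1.0 / r).sum(axis=1)
            assert (tv >= 0.1 - 1e-12).all()


class TestDataMatrix:
    def test_rejects_out_of_range_codes(self):
        with pytest.raises(ValueError, match="out of range"):
            bb.DataMatrix(np.array([[0, 2]]), np.array([2, 2]), ["a", "b"])

    def test_rejects_missing(self):
        import pandas as pd
        df = pd.DataFrame({"a": [0, None], "b": [1, 0]})
        with pytest.raises(ValueError, match="missing"):
            bb.DataMatrix.from_dataframe(df)

    def test_csv_roundtrip_with_sniffed_delimiter(self, tmp_path):
        net = make_random_net(3, 1)
        data = bb.forward_sample(net, 50, seed=0)
        for delim in (",", "\t"):
            path = tmp_path / f"d{ord(delim)}.csv"
            data.to_csv(path, delimiter=delim)
            back = bb.DataMatrix.read_csv(path)
            assert (back.values == data.values).all()
            assert back.names == data.names
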