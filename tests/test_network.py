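import numpy as np
import pytest

from cbgt.network import (
    BoundsError, ConfigurationError, ConnectionSpec, WeightConfig,
    VARIABLE_WEIGHT_NAMES, build_connectivity, build_populations,
    connection_table, population_slices, read_connection_table,
    synapse_frame, total_neurons, variable_groups, write_connection_table,
)


class TestPopulations:
    def test_default_sizes(self):
        pops = build_populations()
        by_label = {p.label: p for p in pops}
        assert by_label["dSPN_A"].n_neurons == 75
        assert by_label["GPe_B"].n_neurons == 750
        assert by_label["CxI"].channel == "shared"
        assert by_label["FSI"].channel == "shared"
        assert total_neurons(pops) == 4269

    def test_unit_sizes_give_16_subpopulations(self):
        pops = build_populations({r: 1 for r in
                                  ("CxI Cx dSPN iSPN FSI GPi GPe STN Th".split())})
        assert len(pops) == 16
        assert all(p.n_neurons == 1 for p in pops)

    @pytest.mark.parametrize("bad", [{"Purkinje": 10}, {"Cx": 0}, {"GPe": -5}])
    def test_invalid_configurations_rejected(self, bad):
        sizes = {r: 10 for r in ("CxI Cx dSPN iSPN FSI GPi GPe STN Th".split())}
        sizes.update(bad)
        with pytest.raises(ConfigurationError):
            build_populations(sizes)


class TestConnectionTable:
    def test_fourteen_variable_projections(self):
        groups = variable_groups()
        assert len(groups) == 14
        assert set(VARIABLE_WEIGHT_NAMES) == set(groups)
        for name, (ctl, lo, hi) in groups.items():
            assert lo <= ctl <= hi, name

    def test_cx_ispn_ampa_control_consistent_with_bounds(self):
        # the cortex->iSPN AMPA control conductance must sit inside its own
        # bounds and equal the cortex->dSPN AMPA control (equal in control)
        rows = {(r.pre, r.post, r.receptor): r for r in connection_table()}
        row = rows[("Cx", "iSPN", "AMPA")]
        assert row.g_lower <= row.g_control <= row.g_upper
        assert row.g_control == rows[("Cx", "dSPN", "AMPA")].g_control

    def test_variable_row_outside_bounds_rejected(self):
        with pytest.raises(BoundsError):
            ConnectionSpec(pre="Cx", post="Th", receptor="AMPA",
                           probability=1.0, g_control=0.9, g_lower=0.1,
                           g_upper=0.5, variable=True)

    def test_roundtrip_serialization(self, tmp_path):
        table = connection_table()
        path = tmp_path / "connections.tsv"
        write_connection_table(table, path)
        assert read_connection_table(path) == table

    def test_yoked_receptor_scaling(self):
        table = connection_table()
        w = WeightConfig.control(table)
        w.values["Cx-dSPN"] = 0.033  # NMDA upper bound
        rows = {(r.pre, r.post, r.receptor): r for r in table}
        g_nmda = w.row_conductance(rows[("Cx", "dSPN", "NMDA")], table)
        g_ampa = w.row_conductance(rows[("Cx", "dSPN", "AMPA")], table)
        assert g_nmda == pytest.approx(0.033)
        # AMPA row scales by the same factor relative to its own control
        assert g_ampa == pytest.approx(0.018 * 0.033 / 0.027)

    def test_weight_vector_roundtrip_and_validation(self):
        w = WeightConfig.control()
        v = w.to_vector()
        assert v.shape == (14,)
        assert WeightConfig.from_vector(v).values == w.values
        w.values["GPi-Th"] = 99.0
        with pytest.raises(BoundsError):
            w.validate()


class TestConnectivity:
    def test_full_probability_in_degree_exact(self):
        pops = build_populations()
        rows = [r for r in connection_table()
                if (r.pre, r.post, r.receptor) == ("Cx", "dSPN", "AMPA")]
        projs = build_connectivity(pops, rows, WeightConfig.control(), seed=3)
        by_branch = {(p.pre_label, p.post_label): p for p in projs}
        assert set(by_branch) == {("Cx_A", "dSPN_A"), ("Cx_B", "dSPN_B")}
        assert np.all(by_branch[("Cx_A", "dSPN_A")].in_degrees() == 204)

    def test_bernoulli_in_degree_mean(self):
        # GPe->STN at p=0.067: mean in-degree ~ 0.067*750 = 50.25
        pops = build_populations()
        rows = [r for r in connection_table()
                if (r.pre, r.post) == ("GPe", "STN")]
        degs = []
        for seed in range(100):
            projs = build_connectivity(pops, rows, seed=seed,
                                       channel_symmetric=False)
            degs.append(np.concatenate([p.in_degrees() for p in projs]))
        mean = np.concatenate(degs).mean()
        assert mean == pytest.approx(0.067 * 750, abs=0.15)

    def test_determinism_under_seed(self):
        pops = build_populations()
        table = connection_table()
        a = build_connectivity(pops, table, seed=11)
        b = build_connectivity(pops, table, seed=11)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.targets, pb.targets)
            assert np.array_equal(pa.indptr, pb.indptr)

    def test_zero_probability_row_has_no_synapses(self):
        pops = build_populations(
            {r: 5 for r in ("CxI Cx dSPN iSPN FSI GPi GPe STN Th".split())})
        row = ConnectionSpec(pre="Cx", post="Th", receptor="AMPA",
                             probability=0.0, g_control=0.1)
        projs = build_connectivity(pops, [row])
        assert all(p.n_synapses == 0 for p in projs)

    def test_channel_mirror_isomorphism(self):
        """Swapping A and B labels maps the realized synapse list onto itself."""
        pops = build_populations()
        projs = build_connectivity(pops, connection_table(), seed=5)
        sl = population_slices(pops)

        def local_pattern(p):
            return (p.indptr.tobytes(),
                    (p.targets - p.post_slice.start).tobytes())

        swap = {}
        for p in projs:
            key = (p.row.name, p.pre_label, p.post_label)
            swap[key] = p
        for p in projs:
            mirrored_label = lambda lb: (
                lb.replace("_A", "_X").replace("_B", "_A").replace("_X", "_B"))
            key = (p.row.name, mirrored_label(p.pre_label),
                   mirrored_label(p.post_label))
            assert local_pattern(swap[key]) == local_pattern(p)

    def test_no_self_connections(self):
        pops = build_populations(
            {r: 20 for r in ("CxI Cx dSPN iSPN FSI GPi GPe STN Th".split())})
        rows = [r for r in connection_table() if r.pre == r.post]
        frame = synapse_frame(build_connectivity(pops, rows, seed=9))
        assert not (frame["pre_neuron"] == frame["post_neuron"]).any()

    def test_focal_rows_stay_within_channel(self):
        pops = build_populations()
        sl = population_slices(pops)
        rows = [r for r in connection_table()
                if (r.pre, r.post, r.receptor) == ("Cx", "dSPN", "NMDA")]
        projs = build_connectivity(pops, rows, seed=1)
        for p in projs:
            ch = p.pre_label[-1]
            tgt = sl[f"dSPN_{ch}"]
            assert np.all((p.targets >= tgt.start) & (p.targets < tgt.stop))

    def test_diffuse_rows_cross_channels(self):
        pops = build_populations()
        rows = [r for r in connection_table() if (r.pre, r.post) == ("STN", "GPi")]
        projs = build_connectivity(pops, rows, seed=1)
        branches = {(p.pre_label, p.post_label) for p in projs}
        assert ("STN_A", "GPi_B") in branches and ("STN_B", "GPi_A") in branches

    def test_missing_weight_and_out_of_bounds_errors(self):
        pops = build_populations(
            {r: 5 for r in ("CxI Cx dSPN iSPN FSI GPi GPe STN Th".split())})
        table = connection_table()
        incomplete = WeightConfig({"GPi-Th": 0.33})
        with pytest.raises(ConfigurationError):
            build_connectivity(pops, table, incomplete)
        bad = WeightConfig.control()
        bad.values["GPe-STN"] = 1.0
        with pytest.raises(BoundsError):
            build_connectivity(pops, table, bad)
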