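import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dfcvar.io import SubjectTimeSeries
from dfcvar.partition import make_partition
from dfcvar.variability import (
    FCWindowStack,
    WindowError,
    WindowSpec,
    average_over_lengths,
    fc_window_stack,
    inter_network_variability,
    intra_network_variability,
    nodal_variability,
    nodal_variability_all,
    segment_windows,
    variability_set,
    window_fc,
    window_length_sweep,
)

import reference as ref
from conftest import make_random_stack


def _stack_from(mats, l=20):
    return FCWindowStack(subject_id="t", windows=np.stack(mats), window_length=l)


class TestSegmentation:
    def test_default_study_geometry(self, rng):
        ts = SubjectTimeSeries("s", rng.standard_normal((200, 8)), 2.0)
        blocks = segment_windows(ts, WindowSpec(20))
        assert blocks.shape == (10, 20, 8)
        np.testing.assert_array_equal(blocks[0], ts.data[:20])
        np.testing.assert_array_equal(blocks[-1], ts.data[180:200])

    def test_remainder_discarded(self, rng):
        ts = SubjectTimeSeries("s", rng.standard_normal((200, 5)), 2.0)
        blocks = segment_windows(ts, WindowSpec(11))
        assert blocks.shape == (18, 11, 5)
        np.testing.assert_array_equal(blocks.reshape(-1, 5), ts.data[:198])

    def test_single_window_is_error(self, rng):
        ts = SubjectTimeSeries("s", rng.standard_normal((25, 5)), 2.0)
        with pytest.raises(WindowError, match="at least 2"):
            segment_windows(ts, WindowSpec(20))

    def test_minimum_window_length_enforced(self):
        with pytest.raises(WindowError):
            WindowSpec(2)


class TestWindowFC:
    def test_identical_and_opposite_columns(self, rng):
        x = rng.standard_normal(20)
        block = np.column_stack([x, x, -x])
        C = window_fc(block)
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(-1.0)
        np.testing.assert_array_equal(np.diag(C), 1.0)

    def test_matches_naive_two_pass_oracle(self, rng):
        block = rng.standard_normal((20, 5))
        np.testing.assert_allclose(window_fc(block), ref.ref_window_fc(block), atol=1e-12)

    def test_zero_variance_column_names_window_and_node(self, rng):
        block = rng.standard_normal((20, 4))
        block[:, 2] = 7.0
        with pytest.raises(WindowError, match=r"\[3\].*window 5"):
            window_fc(block, window_index=5)


class TestNodalVariability:
    def test_identical_windows_give_zero(self, rng):
        C = ref.ref_window_fc(rng.standard_normal((30, 6)))
        stack = _stack_from([C, C, C])
        V = nodal_variability_all(stack)
        np.testing.assert_allclose(V, 0.0, atol=1e-12)

    def test_anticorrelated_profiles_give_two(self):
        """Two windows whose profiles for node 0 are exact reverses: corr -1, V = 2."""
        a = np.array([0.1, 0.2, 0.3])

        def mat(profile):
            m = np.zeros((4, 4))
            m[0, 1:] = profile
            m[1:, 0] = profile
            np.fill_diagonal(m, 1.0)
            return m

        stack = _stack_from([mat(a), mat(a[::-1])])
        assert nodal_variability(stack, 0) == pytest.approx(2.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, random_stack):
        V = nodal_variability_all(random_stack)
        for k in range(random_stack.n_nodes):
            expect = ref.ref_nodal_variability(random_stack.windows, k)
            assert V[k] == pytest.approx(expect, abs=1e-12)
            assert nodal_variability(random_stack, k) == pytest.approx(expect, abs=1e-12)

    def test_oracle_equivalence_over_random_instances(self, rng):
        """Nodal/intra/inter match loop-based references over many random stacks."""
        part = make_partition({"A": 3, "B": 4, "C": 3})
        pa = part.positions("A").tolist()
        pb = part.positions("B").tolist()
        for _ in range(100):
            n_win = int(rng.integers(2, 7))
            n_nodes = int(rng.integers(4, 11))
            stack = make_random_stack(rng, n_win, n_nodes)
            k = int(rng.integers(n_nodes))
            assert nodal_variability(stack, k) == pytest.approx(
                ref.ref_nodal_variability(stack.windows, k), abs=1e-12
            )
        for _ in range(20):
            stack = make_random_stack(rng, 4, part.n_nodes)
            assert intra_network_variability(stack, part, "A") == pytest.approx(
                ref.ref_intra_variability(stack.windows, pa), abs=1e-12
            )
            assert inter_network_variability(stack, part, "A", "B") == pytest.approx(
                ref.ref_inter_variability(stack.windows, pa, pb), abs=1e-12
            )


class TestModuleVariability:
    def test_identical_windows_zero(self, rng, small_partition):
        C = ref.ref_window_fc(rng.standard_normal((40, small_partition.n_nodes)))
        stack = _stack_from([C] * 3)
        assert intra_network_variability(stack, small_partition, "A") == pytest.approx(0, abs=1e-12)
        assert inter_network_variability(stack, small_partition, "A", "B") == pytest.approx(0, abs=1e-12)

    def test_inter_symmetric_bit_exact(self, small_partition, rng):
        stack = make_random_stack(rng, 4, small_partition.n_nodes)
        ab = inter_network_variability(stack, small_partition, "A", "B")
        ba = inter_network_variability(stack, small_partition, "B", "A")
        assert ab == ba

    def test_two_node_module_rejected(self, rng):
        part = make_partition({"T": 2, "R": 5})
        stack = make_random_stack(rng, 3, 7)
        with pytest.raises(WindowError, match="3"):
            intra_network_variability(stack, part, "T")

    def test_same_module_inter_rejected(self, small_partition, rng):
        stack = make_random_stack(rng, 3, small_partition.n_nodes)
        with pytest.raises(WindowError, match="distinct"):
            inter_network_variability(stack, small_partition, "A", "A")

    def test_intra_equals_whole_graph_oracle(self, rng):
        """Intra variability of a module spanning the whole graph matches the
        generic loop oracle on the full upper triangle."""
        part2 = make_partition({"W": 4, "Z": 3})
        stack2 = make_random_stack(rng, 3, 7)
        got = intra_network_variability(stack2, part2, "W")
        expect = ref.ref_intra_variability(stack2.windows, [0, 1, 2, 3])
        assert got == pytest.approx(expect, abs=1e-12)


class TestVariabilitySet:
    def test_tiled_series_gives_exact_zero(self, small_partition, rng):
        """A series built by tiling one 20-volume block has identical windows,
        so every variability value is exactly 0."""
        block = rng.standard_normal((20, small_partition.n_nodes))
        ts = SubjectTimeSeries("tile", np.tile(block, (10, 1)), 2.0)
        vs = variability_set(ts, small_partition, WindowSpec(20))
        np.testing.assert_allclose(vs.nodal, 0.0, atol=1e-10)
        np.testing.assert_allclose(vs.module_matrix.to_numpy(), 0.0, atol=1e-10)

    def test_values_in_range_and_matrix_symmetric(self, small_series, small_partition):
        vs = variability_set(small_series, small_partition, WindowSpec(15))
        assert np.nanmin(vs.nodal) >= 0.0
        assert np.nanmax(vs.nodal) <= 2.0
        mm = vs.module_matrix.to_numpy()
        np.testing.assert_array_equal(mm, mm.T)
        assert np.nanmin(mm) >= 0.0 and np.nanmax(mm) <= 2.0
        assert np.nanmean(vs.nodal) > 0.0

    def test_affine_invariance_per_node(self, small_series, small_partition):
        """Scaling a node's series by a positive constant and shifting it
        changes no variability value (Pearson invariance)."""
        vs0 = variability_set(small_series, small_partition, WindowSpec(15))
        data = small_series.data.copy()
        data[:, 3] = 2.5 * data[:, 3] - 7.0
        data[:, 8] = 0.1 * data[:, 8] + 100.0
        vs1 = variability_set(
            SubjectTimeSeries("s1b", data, 2.0), small_partition, WindowSpec(15)
        )
        np.testing.assert_allclose(vs0.nodal, vs1.nodal, atol=1e-10)
        np.testing.assert_allclose(
            vs0.module_matrix.to_numpy(), vs1.module_matrix.to_numpy(), atol=1e-10
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.01, 100.0, allow_nan=False),
        shift=st.floats(-50.0, 50.0, allow_nan=False),
        node=st.integers(0, 13),
    )
    def test_affine_invariance_property(self, scale, shift, node):
        rng = np.random.default_rng(99)
        part = make_partition({"A": 4, "B": 3, "C": 4, "D": 3})
        base = rng.standard_normal((60, part.n_nodes))
        vs0 = variability_set(SubjectTimeSeries("p", base, 2.0), part, WindowSpec(15))
        data = base.copy()
        data[:, node] = scale * data[:, node] + shift
        vs1 = variability_set(SubjectTimeSeries("p", data, 2.0), part, WindowSpec(15))
        np.testing.assert_allclose(vs0.nodal, vs1.nodal, atol=1e-10)

    def test_window_pair_denominator(self, rng):
        """The averaging denominator is exactly N(N-1)/2, checked by explicit
        enumeration against the package value for N up to 6."""
        for n_win in range(2, 7):
            stack = make_random_stack(rng, n_win, 5)
            got = nodal_variability(stack, 0)
            expect = ref.ref_nodal_variability(stack.windows, 0)
            assert got == pytest.approx(expect, abs=1e-12)

    def test_degenerate_window_policy(self, small_partition):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((60, small_partition.n_nodes))
        data[15:30, 4] = 42.0  # node constant within window 1 only
        ts = SubjectTimeSeries("deg", data, 2.0)
        with pytest.raises(WindowError, match="window 1"):
            variability_set(ts, small_partition, WindowSpec(15))
        vs = variability_set(
            ts, small_partition, WindowSpec(15), skip_degenerate_windows=True
        )
        assert np.isfinite(vs.nodal).all()


class TestSweepAndAveraging:
    def test_self_comparison_is_unity_and_table_symmetric(self, small_series, small_partition):
        per_len = window_length_sweep(small_series, small_partition, (10, 15))
        assert set(per_len) == {10, 15}
        from dfcvar.variability import cohort_sweep

        _, nodal_corr, module_corr = cohort_sweep(
            [small_series], small_partition, (10, 15, 15)
        )
        A = nodal_corr.to_numpy()
        np.testing.assert_array_equal(A, A.T)
        np.testing.assert_allclose(np.diag(A), 1.0)
        # duplicate length 15 vs 15 must correlate exactly 1
        assert A[1, 2] == pytest.approx(1.0, abs=1e-12)

    def test_sweep_lengths_positively_correlated_on_structured_data(self, rng):
        from dfcvar.cohort import simulate_subject
        from conftest import micro_spec

        spec = micro_spec(n_volumes=200)
        subj = simulate_subject(spec, "control", 0.0, seed=4)
        from dfcvar.variability import cohort_sweep

        _, nodal_corr, _ = cohort_sweep([subj.series], spec.partition, (10, 20))
        assert nodal_corr.loc[10, 20] > 0

    def test_average_over_lengths_matches_loop_oracle(self, small_series, small_partition):
        per_len = window_length_sweep(small_series, small_partition, (10, 12, 15))
        avg = average_over_lengths(list(per_len.values()))
        for pos in range(small_partition.n_nodes):
            expect = np.mean([per_len[l].nodal[pos] for l in (10, 12, 15)])
            assert avg.nodal[pos] == pytest.approx(expect, abs=1e-12)
        np.testing.assert_allclose(
            avg.module_matrix.to_numpy(),
            np.mean([per_len[l].module_matrix.to_numpy() for l in (10, 12, 15)], axis=0),
            atol=1e-12,
        )

    def test_average_identical_sets_is_identity(self, small_series, small_partition):
        vs = variability_set(small_series, small_partition, WindowSpec(15))
        avg = average_over_lengths([vs, vs])
        np.testing.assert_allclose(avg.nodal, vs.nodal, atol=1e-15)

    def test_average_missing_value_policy(self, small_series, small_partition):
        a = variability_set(small_series, small_partition, WindowSpec(10))
        b = variability_set(small_series, small_partition, WindowSpec(15))
        c = variability_set(small_series, small_partition, WindowSpec(20))
        na = a.nodal.copy()
        nb = b.nodal.copy()
        na[0] = np.nan  # one missing -> mean of the others
        na[1] = np.nan
        nb[1] = np.nan  # two missing -> missing
        a2 = VariabilityPatch(a, na)
        b2 = VariabilityPatch(b, nb)
        avg = average_over_lengths([a2, b2, c])
        assert avg.nodal[0] == pytest.approx((b.nodal[0] + c.nodal[0]) / 2)
        assert np.isnan(avg.nodal[1])


def VariabilityPatch(vs, new_nodal):
    from dfcvar.variability import VariabilitySet

    return VariabilitySet(
        subject_id=vs.subject_id,
        window_length=vs.window_length,
        nodal=new_nodal,
        module_matrix=vs.module_matrix,
        diagnostics=vs.diagnostics,
    )
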