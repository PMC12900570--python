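import numpy as np
import pytest

from gfssnet.nn import Tensor
from gfssnet.td_mamba import (Axis, ScanDirective, SSMBranch,
                              SSMParams, TDMamba, directional_flatten,
                              selective_scan, ssm_recurrence)


def random_params(rng, d_state, d_in=1, d_out=1, diagonal=True,
                  stable=True):
    if diagonal:
        A = rng.uniform(-0.9 if stable else -1.5,
                        0.9 if stable else 1.5, size=d_state)
    else:
        A = rng.normal(size=(d_state, d_state))
        if stable:
            A *= 0.9 / max(1e-9, np.abs(np.linalg.eigvals(A)).max())
    return SSMParams(A=A, B=rng.normal(size=(d_state, d_in)),
                     C=rng.normal(size=(d_out, d_state)))


class TestRecurrence:
    def test_memoryless(self):
        p = SSMParams(A=[0.0], B=[[1.5]], C=[[2.0]])
        x = np.array([1.0, -2.0, 3.0])
        y = ssm_recurrence(p, x)
        np.testing.assert_allclose(y[:, 0], 3.0 * x, atol=1e-12)

    def test_hand_iteration(self):
        # A=0.5, B=1, C=2, x=(1,0,0): h=(1, .5, .25) -> y=(2, 1, 0.5)
        p = SSMParams(A=[0.5], B=[[1.0]], C=[[2.0]])
        y = ssm_recurrence(p, np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(y[:, 0], [2.0, 1.0, 0.5], atol=1e-12)

    def test_zero_input(self):
        rng = np.random.default_rng(0)
        p = random_params(rng, 4, d_in=2, d_out=3, diagonal=False)
        y = ssm_recurrence(p, np.zeros((6, 2)))
        np.testing.assert_array_equal(y, 0.0)

    def test_dimension_mismatch(self):
        p = SSMParams(A=[0.5], B=[[1.0]], C=[[2.0]])
        with pytest.raises(ValueError):
            ssm_recurrence(p, np.zeros((4, 2)))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SSMParams(A=[np.inf], B=[[1.0]], C=[[1.0]])
        with pytest.raises(ValueError):
            SSMParams(A=np.zeros((2, 3)), B=np.zeros((2, 1)),
                      C=np.zeros((1, 2)))


class TestSelectiveScan:
    @pytest.mark.parametrize("diagonal", [True, False])
    def test_matches_recurrence_random(self, diagonal):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            d_state = int(rng.integers(1, 17))
            d_in = int(rng.integers(1, 4))
            d_out = int(rng.integers(1, 4))
            T = int(rng.integers(1, 129))
            p = random_params(rng, d_state, d_in, d_out, diagonal=diagonal)
            x = rng.normal(size=(T, d_in))
            worst = max(worst, np.abs(selective_scan(p, x)
                                      - ssm_recurrence(p, x)).max())
        assert worst < 1e-5

    def test_long_sequence(self):
        rng = np.random.default_rng(7)
        p = random_params(rng, 8, diagonal=True)
        x = rng.normal(size=(4096, 1))
        np.testing.assert_allclose(selective_scan(p, x),
                                   ssm_recurrence(p, x), atol=1e-5)

    def test_single_step_closed_form(self):
        rng = np.random.default_rng(8)
        p = random_params(rng, 5, d_in=2, d_out=3, diagonal=False)
        x = rng.normal(size=(1, 2))
        np.testing.assert_allclose(selective_scan(p, x)[0],
                                   p.C @ (p.B @ x[0]), atol=1e-10)

    def test_stability_bound(self):
        # |a_ii| <= rho < 1, |x| <= M -> |h_i| <= |B| M / (1 - rho)
        rng = np.random.default_rng(9)
        p = random_params(rng, 4, diagonal=True, stable=True)
        x = rng.uniform(-1, 1, size=(512, 1))
        rho = np.abs(p.A).max()
        bound = (np.abs(p.C).sum(axis=1)
                 * np.abs(p.B).max() / (1 - rho)).max()
        assert np.abs(selective_scan(p, x)).max() <= bound + 1e-9


class TestDirectionalFlatten:
    @pytest.mark.parametrize("axis", list(Axis))
    @pytest.mark.parametrize("rev", [False, True])
    def test_round_trip_identity(self, axis, rev):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2, 3, 4, 5, 6)).astype(np.float32)
        seq, unflatten = directional_flatten(X, ScanDirective(axis, rev))
        np.testing.assert_array_equal(unflatten(seq).numpy(), X)

    def test_sequence_length_is_axis_size(self):
        X = np.zeros((1, 2, 4, 5, 6), dtype=np.float32)
        for axis, T in [(Axis.DEPTH, 4), (Axis.HEIGHT, 5), (Axis.WIDTH, 6)]:
            seq, _ = directional_flatten(X, ScanDirective(axis))
            assert seq.shape[1] == T
            assert seq.shape[0] * T == 4 * 5 * 6
            assert seq.shape[2] == 2

    def test_voxel_identity_preserved(self):
        rng = np.random.default_rng(2)
        shape = (1, 2, 3, 4, 5)
        X = np.arange(np.prod(shape), dtype=np.float32).reshape(shape)
        for axis in Axis:
            seq, unflatten = directional_flatten(X, ScanDirective(axis))
            out = unflatten(seq).numpy()
            for _ in range(20):
                idx = tuple(rng.integers(0, s) for s in shape)
                assert out[idx] == X[idx]

    def test_gradient_flows_through_round_trip(self):
        X = Tensor(np.random.default_rng(3).normal(size=(1, 2, 3, 4, 5)),
                   requires_grad=True)
        seq, unflatten = directional_flatten(X, ScanDirective(Axis.HEIGHT))
        (unflatten(seq) * 2.0).sum().backward()
        np.testing.assert_allclose(X.grad, 2.0, atol=1e-12)


class TestTDMambaBlock:
    def test_output_shape(self):
        rng = np.random.default_rng(0)
        block = TDMamba(4, np.random.default_rng(0), d_state=3, d_conv=1)
        X = rng.normal(size=(1, 4, 4, 6, 5)).astype(np.float32)
        assert block(X).shape == X.shape

    def test_empty_directions_rejected(self):
        with pytest.raises(ValueError):
            TDMamba(4, np.random.default_rng(0), directions=())

    def test_single_direction_sagittal_variant(self):
        block = TDMamba(4, np.random.default_rng(0), d_state=3, d_conv=1,
                        directions=(ScanDirective(Axis.DEPTH),))
        assert len(block.branches) == 1
        X = np.random.default_rng(1).normal(size=(1, 4, 4, 6, 5)) \
            .astype(np.float32)
        assert block(X).shape == X.shape

    def test_memoryless_shift_equivariance(self):
        """With state decay forced to zero (no memory, no local conv) every
        position is mapped independently, so a spatial roll commutes."""
        block = TDMamba(3, np.random.default_rng(4), d_state=2, d_conv=1,
                        mode="lti")
        for br in block.branches:
            br.A_direct.data[...] = 0.0
        rng = np.random.default_rng(5)
        X = rng.normal(size=(1, 3, 4, 4, 4)).astype(np.float32)
        out = block(X).numpy()
        Xr = np.roll(X, 1, axis=3)
        out_r = block(Xr).numpy()
        np.testing.assert_allclose(out_r, np.roll(out, 1, axis=3), atol=1e-5)

    def test_gradients_reach_all_parameters(self):
        block = TDMamba(3, np.random.default_rng(6), d_state=2, d_conv=3)
        X = Tensor(np.random.default_rng(7).normal(size=(1, 3, 3, 4, 4)),
                   requires_grad=True)
        (block(X) ** 2).sum().backward()
        for name, p in block.named_parameters():
            assert p.grad is not None, name


class TestSSMBranchModes:
    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            SSMBranch(2, 2, 1, np.random.default_rng(0), mode="bogus")

    def test_lti_branch_matches_recurrence_oracle(self):
        """One LTI branch channel with frozen projections reproduces the
        literal recurrence."""
        rng = np.random.default_rng(8)
        br = SSMBranch(1, 3, 1, np.random.default_rng(8), mode="lti")
        br.D_skip.data[...] = 0.0
        a = rng.uniform(-0.8, 0.8, size=3)
        br.A_direct.data[...] = a
        x = rng.normal(size=(1, 10, 1)).astype(np.float32)
        got = br(Tensor(x)).numpy()[0, :, 0]
        B_eff = br.proj_B.weight.data  # (1, 3); bx = x * (x @ B) is bilinear
        C_eff = br.proj_C.weight.data
        h = np.zeros(3)
        ref = []
        for t in range(10):
            bt = x[0, t, 0] * (x[0, t] @ B_eff)
            ct = x[0, t] @ C_eff
            h = a * h + bt
            ref.append(float(ct @ h))
        np.testing.assert_allclose(got, np.array(ref), atol=1e-4)
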