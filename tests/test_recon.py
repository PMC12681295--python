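"""Channel preparation, coil handling, gridding and LLR reconstruction."""

import numpy as np
import pytest

from radialasl.nufft import RadialNufft3D, radial_trajectory
from radialasl.phantom import make_coil_sensitivities, make_digital_phantom, \
    simulate_kspace
from radialasl.protocol import AcquisitionProtocol, FrameBinning, \
    golden_ratio_direction
from radialasl.recon import (
    ChannelData,
    ReconConfig,
    compress_coils,
    density_weights,
    estimate_sensitivities,
    gridding_reconstruct,
    llr_reconstruct,
    prepare_channels,
    pipe_menon_weights,
    svt_patch,
)

from conftest import nrmse


def smooth_image(n, seed=0):
    ax = np.linspace(-1, 1, n)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (np.exp(-(x**2 + y**2 + z**2) / 0.08)
            * (1 + 0.3 * np.cos(3 * x) + 0.2 * np.sin(2 * y))) + 0j


def single_frame_channel(n=16, n_spokes=402, image=None, n_coils=1,
                         sens=None):
    dirs = golden_ratio_direction(np.arange(1, n_spokes + 1))
    traj = radial_trajectory(dirs, n, n / 2)
    plan = RadialNufft3D(traj.reshape(-1, 3), n)
    image = smooth_image(n) if image is None else image
    if sens is None:
        sens = np.ones((n_coils, n, n, n), dtype=complex) / np.sqrt(n_coils)
    y = np.stack([plan.forward(s * image) for s in sens])
    binning = FrameBinning(n_frames=1, spokes_per_frame_per_prep=1,
                           frame_duration=0.1)
    ch = ChannelData(y=[y], traj=[traj.reshape(-1, 3)], matrix_size=n,
                     binning=binning, pld=np.array([0.1]),
                     ti=np.array([0.1]), modality="structural", sign=1,
                     n_spokes=[n_spokes])
    return ch, image, sens, plan


@pytest.fixture(scope="module")
def desk_kspace():
    ph = make_digital_phantom(n=16, n_coils=3, seed=0)
    prot = AcquisitionProtocol(n_pairs=4, spokes_per_prep=24,
                               matrix_size=16, fov=224.0)
    return ph, prot, simulate_kspace(ph, prot, noise_sigma=0.0, seed=1)


class TestPrepareChannels:
    def test_static_only_difference_vanishes(self):
        ph = make_digital_phantom(n=16, n_coils=2, seed=0)
        ph.vessel_volume[:] = 0
        ph.cbf[:] = 0
        prot = AcquisitionProtocol(n_pairs=2, spokes_per_prep=6,
                                   matrix_size=16, fov=224.0)
        ks = simulate_kspace(ph, prot, noise_sigma=0.0, seed=0)
        for modality in ("angio", "perfusion"):
            ch = prepare_channels(ks, modality, 2)
            peak = max(np.abs(y).max() for y in ch.y)
            assert peak <= 1e-10 * np.abs(ks.data).max()

    def test_full_central_fraction_equals_angio_subset(self, desk_kspace):
        _, _, ks = desk_kspace
        perf = prepare_channels(ks, "perfusion", 2, central_fraction=1.0)
        angio = prepare_channels(ks, "angio", 2)
        for k in range(2):
            assert np.allclose(perf.y[k], angio.y[k])
        assert perf.matrix_size == angio.matrix_size

    def test_frame_spoke_counts(self, desk_kspace):
        _, prot, ks = desk_kspace
        ch = prepare_channels(ks, "angio", 4)
        assert ch.n_spokes == [prot.n_pairs * 6] * 4

    def test_structural_uses_mean(self, desk_kspace):
        _, _, ks = desk_kspace
        st = prepare_channels(ks, "structural", 2)
        sch = ks.schedule
        lab = ks.data[:, sch.condition == 0]
        ctl = ks.data[:, sch.condition == 1]
        total_mean = 0.5 * (lab + ctl)
        stacked = np.concatenate([y.reshape(y.shape[0], -1, ks.n_readout)
                                  for y in st.y], axis=1)
        assert stacked.shape[1] == total_mean.shape[1]
        assert np.allclose(np.sort(np.abs(stacked).sum(axis=(0, 2))),
                           np.sort(np.abs(total_mean).sum(axis=(0, 2))))


class TestCompressCoils:
    def test_identity_when_keeping_all(self, desk_kspace):
        _, _, ks = desk_kspace
        ch = prepare_channels(ks, "structural", 2)
        _, energy = compress_coils(ch, ch.n_coils)
        assert energy == pytest.approx(1.0, abs=1e-12)

    def test_exact_rank_retained(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((8, 4)) + 1j * rng.standard_normal((8, 4))
        coeff = rng.standard_normal((4, 500)) + 1j * rng.standard_normal((4, 500))
        data = basis @ coeff
        binning = FrameBinning(n_frames=1, spokes_per_frame_per_prep=1,
                               frame_duration=0.1)
        ch = ChannelData(y=[data], traj=[np.zeros((500, 3))], matrix_size=8,
                         binning=binning, pld=np.zeros(1), ti=np.zeros(1),
                         modality="structural", sign=1, n_spokes=[10])
        _, energy = compress_coils(ch, 4)
        assert energy >= 1 - 1e-10

    def test_smooth_coil_array_compresses_well(self):
        # 32 smooth coils sampling one object: 8 virtual coils keep >=95%
        n = 16
        sens = make_coil_sensitivities(32, n, seed=2)
        ch, *_ = single_frame_channel(n=n, n_spokes=150, n_coils=32,
                                      sens=sens)
        _, energy = compress_coils(ch, 8)
        assert energy >= 0.95


class TestEstimateSensitivities:
    def test_uniform_single_coil(self):
        img = smooth_image(12)
        maps = estimate_sensitivities(img[None], block=3)
        phase = maps[0][6, 6, 6] / abs(maps[0][6, 6, 6])
        assert np.allclose(maps[0], phase, atol=1e-10)

    def test_scaling_invariance(self):
        n = 12
        sens = make_coil_sensitivities(3, n, seed=1)
        imgs = sens * smooth_image(n)[None]
        a = estimate_sensitivities(imgs, block=3)
        b = estimate_sensitivities(100.0 * imgs, block=3)
        assert np.allclose(a, b, atol=1e-10)

    def test_recovers_true_maps_on_smooth_phantom(self):
        # noiseless coil images of a smooth object; the per-voxel coil
        # vector is exactly rank one, so block=1 recovers the maps exactly
        # (larger blocks trade accuracy for noise robustness)
        n = 16
        sens = make_coil_sensitivities(4, n, seed=3)
        obj = smooth_image(n)
        est = estimate_sensitivities(sens * obj[None], block=1)
        ref = np.argmax(np.abs(est).sum(axis=(1, 2, 3)))
        truth = sens * np.exp(-1j * np.angle(sens[ref]))[None]
        truth /= np.maximum(np.linalg.norm(truth, axis=0, keepdims=True),
                            1e-30)
        support = np.abs(obj) > 0.05 * np.abs(obj).max()
        err = np.abs(est - truth)[:, support]
        assert np.median(err) <= 0.02


class TestSvtPatch:
    def test_all_singular_values_below_threshold_gives_zero(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((6, 4)) * 0.01
        assert np.allclose(svt_patch(m, 10.0), 0.0)

    def test_rank_one_shrinks_singular_value(self):
        u = np.array([1.0, 0, 0])[:, None]
        v = np.array([0, 1.0])[None, :]
        m = 5.0 * u @ v
        out = svt_patch(m, 2.0)
        assert np.allclose(out, 3.0 * u @ v)

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(1)
        m = rng.standard_normal((5, 5)) + 1j * rng.standard_normal((5, 5))
        assert np.allclose(svt_patch(m, 0.0), m, atol=1e-12)


class TestGridding:
    def test_fully_sampled_smooth_phantom(self):
        n = 16
        ch, img, sens, _ = single_frame_channel(n=n, n_spokes=402)
        out = gridding_reconstruct(ch, sens)
        assert nrmse(out.data[..., 0], img) <= 0.05

    def test_zero_data_gives_zero_image(self):
        ch, img, sens, _ = single_frame_channel(n=12, n_spokes=100)
        ch.y[0][:] = 0
        out = gridding_reconstruct(ch, sens)
        assert np.abs(out.data).max() == 0

    def test_linearity(self):
        ch, img, sens, _ = single_frame_channel(n=12, n_spokes=100)
        a = gridding_reconstruct(ch, sens).data
        ch.y[0] *= 2.5
        b = gridding_reconstruct(ch, sens).data
        assert np.allclose(b, 2.5 * a, rtol=1e-10)


class TestLlrReconstruct:
    def test_least_squares_limit_matches_cg_oracle(self):
        # lambda = 0, fully sampled, single frame/coil: POGM converges to
        # the least-squares solution; conjugate gradients on the normal
        # equations is the independent oracle.  The object's spectrum lies
        # well inside the sampled radial ball, away from the ill-conditioned
        # band-edge modes.
        n = 12
        ax = np.linspace(-1, 1, n)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        img = np.exp(-(gx**2 + gy**2 + gz**2) / 0.3) + 0j
        ch, img, sens, plan = single_frame_channel(n=n, n_spokes=250,
                                                   image=img)
        cfg = ReconConfig(modality="structural", n_frames=1, lam=0.0,
                          patch_size=4, iterations=500, cycle_spinning=False,
                          seed=0)
        out = llr_reconstruct(ch, sens, cfg)
        assert nrmse(out.data[..., 0], img) <= 1e-3

        from scipy.sparse.linalg import LinearOperator, cg
        scale = 1.0 / np.sqrt(sens.shape[0])

        def normal(v):
            x = v.reshape(n, n, n)
            return plan.adjoint(plan.forward(x)).ravel() * scale**2

        op = LinearOperator((n**3, n**3), matvec=normal, dtype=complex)
        rhs = plan.adjoint(ch.y[0][0]).ravel() * scale
        x_cg, _ = cg(op, rhs, rtol=1e-10, maxiter=400)
        assert nrmse(out.data[..., 0].ravel(), x_cg) <= 2e-3

    def test_objective_trace_monotone_at_zero_lambda(self):
        ch, img, sens, _ = single_frame_channel(n=12, n_spokes=80)
        cfg = ReconConfig(modality="structural", n_frames=1, lam=0.0,
                          patch_size=4, iterations=40, cycle_spinning=False,
                          seed=0)
        out = llr_reconstruct(ch, sens, cfg)
        tr = out.meta["objective_trace"]
        assert all(tr[i + 1] <= tr[i] + 1e-9 * abs(tr[0])
                   for i in range(len(tr) - 1))

    def test_deterministic_under_fixed_seed(self):
        ch, img, sens, _ = single_frame_channel(n=12, n_spokes=80)
        cfg = ReconConfig(modality="structural", n_frames=1, lam=5e-2,
                          patch_size=4, iterations=8, seed=11)
        a = llr_reconstruct(ch, sens, cfg)
        b = llr_reconstruct(ch, sens, cfg)
        assert np.array_equal(a.data, b.data)

    def test_oversized_patch_rejected_and_non_divisor_falls_back(self):
        ch, img, sens, _ = single_frame_channel(n=12, n_spokes=40)
        cfg = ReconConfig(modality="structural", n_frames=1, lam=0.0,
                          patch_size=25, iterations=2, seed=0)
        with pytest.raises(ValueError):
            llr_reconstruct(ch, sens, cfg)
        cfg = ReconConfig(modality="structural", n_frames=1, lam=1e-3,
                          patch_size=5, iterations=2, seed=0)
        out = llr_reconstruct(ch, sens, cfg)   # tiles with patch 4 instead
        assert out.data.shape == (12, 12, 12, 1)


class TestDensityWeights:
    def test_pipe_menon_improves_fully_sampled_recon(self):
        n = 16
        ch, img, sens, plan = single_frame_channel(n=n, n_spokes=402)
        w0 = density_weights(ch.traj[0], n, n_spokes=402)
        rec0 = plan.adjoint(ch.y[0][0] * w0)
        w = pipe_menon_weights(plan, np.arange(plan.n_samples), w0)
        rec = plan.adjoint(ch.y[0][0] * w)
        assert nrmse(rec, img) < nrmse(rec0, img)
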