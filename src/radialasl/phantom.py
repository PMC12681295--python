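"""Digital brain phantom and multi-coil radial k-space synthesis.

The phantom is a deliberately simple, deterministic geometry that carries
the statistical structure the signal models assume: GM/WM/CSF compartments
with distinct T1 and proton density, a CBF/ATT map, two disjoint vessel
trees whose transit delay and dispersion increase distally, smooth complex
coil sensitivities, and complex Gaussian measurement noise in k-space.  It
is synthetic: no template anatomy is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import ndimage

from . import signals as sig
from .nufft import RadialNufft3D, radial_trajectory
from .protocol import AcquisitionProtocol, SpokeSchedule, build_spoke_schedule

__all__ = [
    "TISSUE_LABELS",
    "TissueClass",
    "DigitalPhantom",
    "KSpaceData",
    "make_digital_phantom",
    "make_coil_sensitivities",
    "simulate_kspace",
]

TISSUE_LABELS = {"background": 0, "wm": 1, "gm": 2, "csf": 3}

#: White matter / blood partition coefficient used to tie the phantom's WM
#: equilibrium magnetization to the blood M0 (so that reference-region
#: calibration is exact by construction).
WM_PARTITION_COEFFICIENT = 0.82


@dataclass
class TissueClass:
    t1: float
    m0: float           # equilibrium magnetization, a.u.
    cbf: float          # mL/100 g/min
    att: float          # s


def _default_tissues(m0_blood: float) -> dict[str, TissueClass]:
    return {
        "wm": TissueClass(t1=0.9, m0=WM_PARTITION_COEFFICIENT * m0_blood,
                          cbf=20.0, att=1.2),
        "gm": TissueClass(t1=1.3, m0=0.93 * m0_blood, cbf=60.0, att=0.8),
        "csf": TissueClass(t1=4.0, m0=1.11 * m0_blood, cbf=0.0, att=0.0),
    }


@dataclass
class DigitalPhantom:
    """Voxelized phantom with tissue, vessel and coil structure."""

    n: int
    labels: np.ndarray            # (n,n,n) uint8 per TISSUE_LABELS
    t1: np.ndarray                # (n,n,n) s
    m0: np.ndarray                # (n,n,n) a.u.
    cbf: np.ndarray               # (n,n,n) mL/100 g/min
    att: np.ndarray               # (n,n,n) s
    vessel_volume: np.ndarray     # (n,n,n) a.u., S0*v amplitude map
    vessel_dt: np.ndarray         # (n,n,n) s, transit delay
    vessel_s: np.ndarray          # (n,n,n) 1/s, dispersion sharpness
    vessel_p: np.ndarray          # (n,n,n) s, dispersion time-to-peak
    coil_sens: np.ndarray         # (C,n,n,n) complex
    m0_blood: float
    t1_blood: float
    inv_efficiency: float
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def vessel_mask(self) -> np.ndarray:
        return self.vessel_volume > 0

    def tissue_mask(self, name: str) -> np.ndarray:
        return self.labels == TISSUE_LABELS[name]

    def n_vessel_clusters(self) -> int:
        _, n = ndimage.label(self.vessel_mask,
                             structure=np.ones((3, 3, 3), dtype=bool))
        return n

    def downsample_mask(self, name: str, n_low: int,
                        threshold: float = 0.9) -> np.ndarray:
        """Partial-volume mask of one tissue at a coarser matrix size.

        The fine binary mask is box-averaged onto the coarse grid (linear
        resampling when the sizes are not commensurate) and thresholded at
        the given partial-volume fraction.
        """
        m = self.tissue_mask(name).astype(float)
        if self.n % n_low == 0:
            f = self.n // n_low
            pv = m.reshape(n_low, f, n_low, f, n_low, f).mean(axis=(1, 3, 5))
        else:
            pv = ndimage.zoom(ndimage.uniform_filter(m, self.n // n_low + 1),
                              n_low / self.n, order=1)
        return pv >= threshold

    def to_hdf5(self, grp) -> None:
        for name in ("labels", "t1", "m0", "cbf", "att", "vessel_volume",
                     "vessel_dt", "vessel_s", "vessel_p", "coil_sens"):
            grp.create_dataset(name, data=getattr(self, name))
        grp.attrs["n"] = self.n
        grp.attrs["m0_blood"] = self.m0_blood
        grp.attrs["t1_blood"] = self.t1_blood
        grp.attrs["inv_efficiency"] = self.inv_efficiency
        grp.attrs["seed"] = self.seed
        grp.attrs["config"] = json.dumps(self.config)

    @classmethod
    def from_hdf5(cls, grp) -> "DigitalPhantom":
        arrays = {name: grp[name][()] for name in
                  ("labels", "t1", "m0", "cbf", "att", "vessel_volume",
                   "vessel_dt", "vessel_s", "vessel_p", "coil_sens")}
        return cls(n=int(grp.attrs["n"]), m0_blood=float(grp.attrs["m0_blood"]),
                   t1_blood=float(grp.attrs["t1_blood"]),
                   inv_efficiency=float(grp.attrs["inv_efficiency"]),
                   seed=int(grp.attrs["seed"]),
                   config=json.loads(grp.attrs["config"]), **arrays)


def make_coil_sensitivities(n_coils: int, n: int, seed: int = 0,
                            uniform: bool = False) -> np.ndarray:
    """Smooth complex coil sensitivity maps, RSS roughly uniform.

    Each coil is a broad Gaussian magnitude profile centered outside the
    object with a slowly varying (low spatial order) phase.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if uniform or n_coils == 1:
        return np.ones((n_coils, n, n, n), dtype=complex)
    rng = np.random.default_rng(seed)
    ax = np.linspace(-1, 1, n)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    maps = np.empty((n_coils, n, n, n), dtype=complex)
    for c in range(n_coils):
        theta = 2 * np.pi * c / n_coils + rng.normal(0, 0.1)
        zc = rng.uniform(-0.5, 0.5)
        center = np.array([1.4 * np.cos(theta), 1.4 * np.sin(theta), zc])
        r2 = (x - center[0])**2 + (y - center[1])**2 + (z - center[2])**2
        mag = np.exp(-r2 / (2 * 1.1**2))
        phase = (rng.normal(0, 0.5) + rng.normal(0, 0.8) * x
                 + rng.normal(0, 0.8) * y + rng.normal(0, 0.8) * z
                 + rng.normal(0, 0.4) * x * y)
        maps[c] = mag * np.exp(1j * phase)
    return maps


def _draw_vessel_tree(n: int, side: float, rng: np.random.Generator,
                      ) -> list[dict]:
    """Polyline segments of one vessel tree rising from the base of the
    volume, with transit delay / dispersion interpolated along arc length."""
    x0 = np.array([side * 0.30, -0.15 + 0.05 * rng.normal(), -0.75])
    jitter = 0.04 * rng.normal(size=3)
    trunk_top = x0 + np.array([side * 0.08, 0.25, 0.85]) + jitter
    branch_a = trunk_top + np.array([side * 0.35, 0.18, 0.45])
    branch_b = trunk_top + np.array([side * 0.05, -0.42, 0.50])
    pts = [x0, trunk_top, branch_a, branch_b]
    segs = []
    # arc lengths from tree root set the distal increase of delay/dispersion
    def arclen(a, b):
        return float(np.linalg.norm(np.asarray(b) - np.asarray(a)))
    l_trunk = arclen(x0, trunk_top)
    for start, end, r in ((x0, trunk_top, 0.060), (trunk_top, branch_a, 0.045),
                          (trunk_top, branch_b, 0.045)):
        l0 = 0.0 if np.allclose(start, x0) else l_trunk
        segs.append({
            "start": np.asarray(start), "end": np.asarray(end),
            "radius": r, "arc0": l0, "arc1": l0 + arclen(start, end),
        })
    return segs


def make_digital_phantom(n: int = 32, n_coils: int = 6, seed: int = 0,
                         m0_blood: float = 100.0, t1_blood: float = 1.65,
                         inv_efficiency: float = 0.95,
                         tissues: dict[str, TissueClass] | None = None,
                         uniform_coils: bool = False) -> DigitalPhantom:
    """Build a deterministic digital phantom.

    Geometry: an ellipsoidal "brain" with a CSF core (ventricles), a GM
    shell and WM in between; two disjoint vessel trees (left/right) whose
    transit delay ``dt`` and time-to-peak ``p`` increase and sharpness ``s``
    decreases with distance from the tree root.  Transit delays span roughly
    0.15-0.9 s, sharpness 40 down to 8 /s, time-to-peak 0.05-0.35 s.
    """
    if n < 16:
        raise ValueError("matrix size must be >= 16 for the vessel geometry")
    rng = np.random.default_rng(seed)
    tissues = tissues or _default_tissues(m0_blood)

    ax = np.linspace(-1, 1, n)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    brain = (x / 0.82)**2 + (y / 0.92)**2 + (z / 0.82)**2 <= 1.0
    rho = np.sqrt((x / 0.82)**2 + (y / 0.92)**2 + (z / 0.82)**2)
    csf = brain & (np.sqrt((x / 0.30)**2 + ((y - 0.05) / 0.45)**2
                           + (z / 0.22)**2) <= 1.0)
    gm = brain & (rho >= 0.70) & ~csf
    wm = brain & ~gm & ~csf

    labels = np.zeros((n, n, n), dtype=np.uint8)
    labels[wm] = TISSUE_LABELS["wm"]
    labels[gm] = TISSUE_LABELS["gm"]
    labels[csf] = TISSUE_LABELS["csf"]

    t1 = np.zeros((n, n, n))
    m0 = np.zeros((n, n, n))
    cbf = np.zeros((n, n, n))
    att = np.zeros((n, n, n))
    for name, tc in tissues.items():
        m = labels == TISSUE_LABELS[name]
        t1[m], m0[m], cbf[m], att[m] = tc.t1, tc.m0, tc.cbf, tc.att

    # vessels: two disjoint trees; partial-volume weight from subvoxel
    # distance to the centerline
    vol = np.zeros((n, n, n))
    vdt = np.zeros((n, n, n))
    vs = np.zeros((n, n, n))
    vp = np.zeros((n, n, n))
    arc = np.full((n, n, n), np.inf)
    pos = np.stack([x, y, z], axis=-1)
    max_arc = 0.0
    for side in (-1.0, 1.0):
        for seg in _draw_vessel_tree(n, side, rng):
            a, b, r = seg["start"], seg["end"], seg["radius"]
            ab = b - a
            L2 = float(ab @ ab)
            t_par = np.clip(((pos - a) @ ab) / L2, 0.0, 1.0)
            d = np.linalg.norm(pos - (a + t_par[..., None] * ab), axis=-1)
            w = np.clip(1.0 - d / (r + 1.2 / n), 0.0, 1.0)
            seg_arc = seg["arc0"] + t_par * (seg["arc1"] - seg["arc0"])
            upd = w > vol       # strongest intersecting segment wins
            vol[upd] = w[upd]
            arc[upd] = seg_arc[upd]
            max_arc = max(max_arc, seg["arc1"])
    vm = vol > 0
    frac = np.zeros_like(arc)
    frac[vm] = arc[vm] / max_arc
    # distal voxels: longer delay, more dispersion (lower s, later peak)
    vdt[vm] = 0.15 + 0.75 * frac[vm]
    vs[vm] = 40.0 - 32.0 * frac[vm]
    vp[vm] = 0.05 + 0.30 * frac[vm]
    # amplitude: S0*v with S0 = 2 * efficiency * M0b (full label amplitude)
    vol = vol * (2.0 * 0.85 * m0_blood)

    coil_sens = make_coil_sensitivities(n_coils, n, seed=seed + 1,
                                        uniform=uniform_coils)
    config = {
        "n": n, "n_coils": n_coils, "m0_blood": m0_blood,
        "t1_blood": t1_blood, "inv_efficiency": inv_efficiency,
        "tissues": {k: vars(v) for k, v in tissues.items()},
    }
    return DigitalPhantom(
        n=n, labels=labels, t1=t1, m0=m0, cbf=cbf, att=att,
        vessel_volume=vol, vessel_dt=vdt, vessel_s=vs, vessel_p=vp,
        coil_sens=coil_sens, m0_blood=m0_blood, t1_blood=t1_blood,
        inv_efficiency=inv_efficiency, seed=seed, config=config)


def fourier_downsample(image: np.ndarray, n_out: int) -> np.ndarray:
    """Band-limit an image to an ``n_out``^3 matrix by central k-space crop
    (sinc resampling).

    The field of view is fixed, so a coarse voxel carries the *summed*
    signal of the fine voxels it covers; this keeps the result consistent
    with k-space sampled from the fine grid.
    """
    n = image.shape[0]
    if n_out > n:
        raise ValueError("n_out must be <= input size")
    spec = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(image)))
    lo = n // 2 - n_out // 2
    crop = spec[lo:lo + n_out, lo:lo + n_out, lo:lo + n_out]
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(crop)))


def ideal_frame_images(phantom: DigitalPhantom, protocol: AcquisitionProtocol,
                       n_frames: int, modality: str,
                       matrix_size: int | None = None) -> np.ndarray:
    """Noiseless reference frame images for one channel.

    The reference is the temporal mean of the per-excitation ideal objects
    over each frame window: the blood difference (with the inverted-contrast
    sign) for ``angio``/``perfusion``, the static tissue for ``structural``.
    For a coarser ``matrix_size`` the frames are band-limited by Fourier
    cropping.  Returns (n, n, n, n_frames).
    """
    from .protocol import bin_frames, build_spoke_schedule

    tissue, blood = _per_excitation_objects(phantom, protocol)
    per_exc = tissue if modality == "structural" else -blood
    sched = build_spoke_schedule(protocol)
    binning = bin_frames(sched, n_frames, tr=protocol.tr)
    frames = sig.frame_average(np.moveaxis(per_exc, 0, -1), binning)
    if matrix_size is not None and matrix_size != phantom.n:
        frames = np.stack([fourier_downsample(frames[..., k], matrix_size)
                           for k in range(n_frames)], axis=-1).real
    return frames


@dataclass
class KSpaceData:
    """Complex multi-coil radial k-space with trajectory and spoke metadata.

    ``data`` is (coils, spokes, readout points); ``traj`` is
    (spokes, readout points, 3) in cycles/FOV.  Noise convention: circular
    complex Gaussian with E|n|^2 = sigma^2 per sample per coil.
    """

    data: np.ndarray
    traj: np.ndarray
    schedule: SpokeSchedule
    protocol: AcquisitionProtocol
    sigma: float
    seed: int
    diff_sign: int = -1    # sign of (control - label) blood contrast
    # after the post-labeling inversion pulse the ASL contrast is inverted

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_readout(self) -> int:
        return self.data.shape[2]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("kspace/data", data=self.data)
            f.create_dataset("kspace/traj", data=self.traj)
            self.schedule.to_hdf5(f.create_group("schedule"))
            f.attrs["protocol"] = self.protocol.to_json()
            f.attrs["sigma"] = self.sigma
            f.attrs["seed"] = self.seed
            f.attrs["diff_sign"] = self.diff_sign

    @classmethod
    def from_hdf5(cls, path) -> "KSpaceData":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["kspace/data"][()], traj=f["kspace/traj"][()],
                schedule=SpokeSchedule.from_hdf5(f["schedule"]),
                protocol=AcquisitionProtocol.from_json(f.attrs["protocol"]),
                sigma=float(f.attrs["sigma"]), seed=int(f.attrs["seed"]),
                diff_sign=int(f.attrs["diff_sign"]))


def _per_excitation_objects(phantom: DigitalPhantom,
                            protocol: AcquisitionProtocol,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Ideal static-tissue and blood-difference objects per excitation.

    Returns ``(tissue, blood)`` with shape (spokes_per_prep, n, n, n):
    ``tissue`` is the mean-channel transverse signal; ``blood`` is the
    *magnitude* of the ASL difference signal (angiographic + perfusion).
    Signals depend only on the readout index, not on the preparation.
    """
    s = protocol.spokes_per_prep
    n = phantom.n
    t_i = protocol.excitation_times()
    flips = protocol.flip_angles()
    r_i = sig.rf_attenuation(flips)
    tau = protocol.labeling_duration

    tissue = np.zeros((s, n, n, n))
    for name in ("wm", "gm", "csf"):
        m = phantom.tissue_mask(name)
        if not m.any():
            continue
        t1 = phantom.t1[m][0]
        params = sig.TissueParams(m0=1.0, t1=t1,
                                  inv_efficiency=phantom.inv_efficiency)
        mxy, _ = sig.static_tissue_signal(params, protocol)
        tissue[:, m] = mxy[:, None] * phantom.m0[m][None, :]

    blood = np.zeros((s, n, n, n))
    # perfusion: per tissue class curve scaled by the voxel CBF is exact here
    # because ATT/T1 are constant within a class
    for name in ("wm", "gm"):
        m = phantom.tissue_mask(name)
        if not m.any():
            continue
        pp = sig.PerfusionParams(
            cbf=phantom.cbf[m][0], att=phantom.att[m][0],
            t1_tissue=phantom.t1[m][0], t1_blood=phantom.t1_blood,
            m0b=phantom.m0_blood)
        curve = sig.perfusion_signal(pp, t_i, flips, r_i, tau,
                                     label_efficiency=0.85)
        blood[:, m] += curve[:, None]
    # angiography: vectorized over vessel voxels x excitations
    vm = phantom.vessel_mask
    if vm.any():
        dt_v = phantom.vessel_dt[vm]
        s_v = phantom.vessel_s[vm]
        p_v = phantom.vessel_p[vm]
        amp_v = phantom.vessel_volume[vm]
        curves = np.empty((s, dt_v.size))
        for v in range(dt_v.size):
            ap = sig.AngioParams(s0v=amp_v[v], transit_delay=dt_v[v],
                                 sharpness=s_v[v], time_to_peak=p_v[v],
                                 t1_blood=phantom.t1_blood)
            curves[:, v] = sig.angio_signal_closed(ap, t_i, flips, r_i, tau)
        blood[:, vm] += curves
    return tissue, blood


def simulate_kspace(phantom: DigitalPhantom, protocol: AcquisitionProtocol,
                    schedule: SpokeSchedule | None = None,
                    noise_sigma: float = 0.0, seed: int = 0,
                    n_readout: int | None = None,
                    nufft_plan: RadialNufft3D | None = None) -> KSpaceData:
    """Synthesize noisy multi-coil radial k-space through the forward models.

    The ideal object at excitation ``i`` is
    ``tissue_i + diff_sign * (condition = control ? +1 : -1) * blood_i / 2``
    with ``diff_sign = -1``: the post-labeling inversion pulse inverts the
    ASL control-label contrast, so the noiseless control-minus-label k-space
    equals ``-blood`` and carries no static-tissue contribution.  Each
    excitation's spoke is sampled by NUFFT per coil, then independent
    circular complex Gaussian noise of std ``noise_sigma`` is added.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if schedule is None:
        schedule = build_spoke_schedule(protocol)
    if (schedule.n_pairs != protocol.n_pairs
            or schedule.spokes_per_prep != protocol.spokes_per_prep):
        raise ValueError("schedule does not match protocol")
    n = phantom.n
    if n_readout is None:
        n_readout = n
    traj = radial_trajectory(schedule.direction, n_readout, n / 2.0)
    if nufft_plan is None:
        nufft_plan = RadialNufft3D(traj.reshape(-1, 3), n)

    tissue, blood = _per_excitation_objects(phantom, protocol)
    n_coils = phantom.coil_sens.shape[0]
    m_spokes = schedule.n_spokes
    data = np.zeros((n_coils, m_spokes, n_readout), dtype=complex)

    sample_rows = np.arange(m_spokes * n_readout).reshape(m_spokes, n_readout)
    for i in range(protocol.spokes_per_prep):
        for cond, cond_sign in ((0, -1.0), (1, +1.0)):   # label, control
            # diff_sign * cond_sign: control gets -blood/2, label +blood/2
            obj = tissue[i] + 0.5 * cond_sign * (-1.0) * blood[i]
            rows = np.flatnonzero((schedule.readout_index == i + 1)
                                  & (schedule.condition == cond))
            flat = sample_rows[rows].ravel()
            for c in range(n_coils):
                y = nufft_plan.forward(phantom.coil_sens[c] * obj, rows=flat)
                data[c, rows] = y.reshape(rows.size, n_readout)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sigma / np.sqrt(2.0),
                           size=(2,) + data.shape)
        data = data + noise[0] + 1j * noise[1]
    return KSpaceData(data=data, traj=traj, schedule=schedule,
                      protocol=protocol, sigma=float(noise_sigma),
                      seed=seed, diff_sign=-1)
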