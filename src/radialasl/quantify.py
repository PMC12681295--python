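"""Post-reconstruction quantification.

Phase correction, vessel masking, voxelwise fitting of the angiographic
dispersion model (transit delay, sharpness, time-to-peak, amplitude), the
Buxton perfusion model (CBF, ATT) with white-matter self-calibration, and
the static-tissue T1 model, plus scan-rescan repeatability metrics.

All fits are bounded multi-start nonlinear least squares.  Where a model is
linear in its amplitude (S0*v, M0) the amplitude is profiled out in the
multi-start stage, which makes the gamma-variate and T1 sum-of-squares
surfaces effectively 2-3 dimensional and robust to their multimodality.
Data are fitted against frame-averaged model curves: each reconstructed
frame is the temporal mean over its excitation window, so the model is
averaged the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from . import signals as sig
from .protocol import AcquisitionProtocol, FrameBinning
from .recon import ImageSeries

__all__ = [
    "ParamMaps",
    "CalibrationResult",
    "phase_correct",
    "make_vessel_mask",
    "fit_angio",
    "fit_perfusion",
    "calibrate_m0b",
    "fit_structural",
    "repeatability_r2",
]

ANGIO_BOUNDS = {"transit_delay": (0.0, 3.0), "sharpness": (0.5, 1e3),
                "time_to_peak": (0.0, 2.0)}
ANGIO_MULTISTART = {"transit_delay": (0.1, 0.5, 1.0), "sharpness": (5.0, 50.0),
                    "time_to_peak": (0.05, 0.3)}
DEFAULT_WM_PARTITION = 0.82
DEFAULT_PCASL_EFFICIENCY = 0.85


@dataclass
class ParamMaps:
    """Voxelwise fitted parameter maps with per-voxel diagnostics."""

    maps: dict[str, np.ndarray]
    residual_norm: np.ndarray
    converged: np.ndarray
    mask: np.ndarray
    modality: str

    def __getitem__(self, key: str) -> np.ndarray:
        return self.maps[key]


@dataclass
class CalibrationResult:
    """White-matter self-calibration of the blood equilibrium magnetization."""

    m0_wm: float
    m0b: float
    partition_coefficient: float = DEFAULT_WM_PARTITION
    pcasl_efficiency: float = DEFAULT_PCASL_EFFICIENCY
    wm_fit: dict = field(default_factory=dict)


def phase_correct(series: ImageSeries | np.ndarray,
                  reference: np.ndarray | None = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Remove the smooth receive/background phase and take the real part.

    Each voxel is multiplied by ``exp(-i phi)`` where ``phi`` is the phase
    of ``reference`` (default: the series' own last frame, where the
    longitudinal magnetization has recovered to a positive state).  Returns
    ``(real_series, zero_phase_flags)``; voxels with zero reference
    magnitude keep ``phi = 0`` and are flagged.
    """
    data = series.data if isinstance(series, ImageSeries) else np.asarray(series)
    ref = data[..., -1] if reference is None else np.asarray(reference)
    zero = np.abs(ref) == 0
    phi = np.where(zero, 0.0, np.angle(np.where(zero, 1.0, ref)))
    corrected = (data * np.exp(-1j * phi)[..., None]).real
    return corrected, zero


def make_vessel_mask(angio: ImageSeries | np.ndarray, brain_mask: np.ndarray,
                     threshold: float, n_clusters: int = 2) -> np.ndarray:
    """Vessel mask from the temporal maximum intensity projection.

    Temporal max of |signal| -> restrict to the brain mask -> threshold ->
    26-connected component labeling -> keep the ``n_clusters`` largest
    components (vessels are thin oblique structures, hence the full
    26-neighbourhood).  Raises if nothing survives the threshold; warns via
    the return (single cluster kept) if fewer clusters than requested exist.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    data = angio.data if isinstance(angio, ImageSeries) else np.asarray(angio)
    tmip = np.abs(data).max(axis=-1) * brain_mask
    binary = tmip > threshold
    if not binary.any():
        raise ValueError("threshold exceeds the maximum projected intensity")
    lab, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        raise ValueError("no suprathreshold clusters")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:n_clusters] + 1
    return np.isin(lab, keep)


def _frame_average_model(curve_fn, binning: FrameBinning) -> np.ndarray:
    return sig.frame_average(curve_fn(), binning)


def _profiled_amplitude(y: np.ndarray, g: np.ndarray) -> float:
    denom = float(g @ g)
    if denom <= 0:
        return 0.0
    return max(0.0, float(y @ g) / denom)


def fit_angio(series: np.ndarray, mask: np.ndarray,
              protocol: AcquisitionProtocol,
              binning: FrameBinning | None = None,
              bias_field: np.ndarray | None = None,
              n_polish: int = 3) -> ParamMaps:
    """Voxelwise dispersed-bolus fit of the angiographic difference signal.

    ``series`` must be real-valued with positive blood contrast (phase
    corrected and sign flipped upstream).  Fits amplitude ``s0v``, transit
    delay, sharpness and time-to-peak per voxel by bounded least squares.
    The amplitude is profiled out on a multi-start grid over the three
    shape parameters, and the ``n_polish`` best starts each seed a full
    4-parameter refinement.  With a ``binning`` the model is frame-averaged
    (reconstructed frame series); with ``binning=None`` the data are
    per-excitation curves.
    """
    if binning is not None and binning.n_frames < 4:
        raise ValueError("need at least 4 frames for a 4-parameter fit")
    t_i = protocol.excitation_times()
    flips = protocol.flip_angles()
    r_i = sig.rf_attenuation(flips)
    tau = protocol.labeling_duration

    def model_curve(dt, s, p):
        ap = sig.AngioParams(s0v=1.0, transit_delay=dt, sharpness=s,
                             time_to_peak=p)
        c = sig.angio_signal_closed(ap, t_i, flips, r_i, tau)
        return sig.frame_average(c, binning) if binning is not None else c

    starts = [(dt, s, p)
              for dt in ANGIO_MULTISTART["transit_delay"]
              for s in ANGIO_MULTISTART["sharpness"]
              for p in ANGIO_MULTISTART["time_to_peak"]]
    start_curves = [model_curve(*st) for st in starts]

    lo = [0.0, ANGIO_BOUNDS["transit_delay"][0], ANGIO_BOUNDS["sharpness"][0],
          ANGIO_BOUNDS["time_to_peak"][0]]
    hi = [np.inf, ANGIO_BOUNDS["transit_delay"][1],
          ANGIO_BOUNDS["sharpness"][1], ANGIO_BOUNDS["time_to_peak"][1]]

    shape = mask.shape
    out = {k: np.zeros(shape) for k in
           ("s0v", "transit_delay", "sharpness", "time_to_peak")}
    res_norm = np.zeros(shape)
    conv = np.zeros(shape, dtype=bool)

    voxels = np.argwhere(mask)
    for vx in voxels:
        y = np.asarray(series[tuple(vx)], dtype=float)
        if not np.all(np.isfinite(y)) or np.all(y == 0):
            continue
        sses, amps = [], []
        for g in start_curves:
            a = _profiled_amplitude(y, g)
            amps.append(a if a > 0 else max(y.max(), 1e-12))
            sses.append(float(((y - a * g) ** 2).sum()))
        order = np.argsort(sses)[:n_polish]

        def resid(theta):
            a, dt, s, p = theta
            return a * model_curve(dt, s, p) - y

        sol = None
        for j in order:
            try:
                cand = optimize.least_squares(
                    resid, np.asarray([amps[j], *starts[j]]), bounds=(lo, hi),
                    xtol=1e-10, ftol=1e-10, max_nfev=200)
            except ValueError:
                continue
            if sol is None or cand.cost < sol.cost:
                sol = cand
        if sol is None:
            continue
        a, dt, s, p = sol.x
        idx = tuple(vx)
        out["s0v"][idx] = a
        out["transit_delay"][idx] = dt
        out["sharpness"][idx] = s
        out["time_to_peak"][idx] = p
        if bias_field is not None:
            out["s0v"][idx] /= max(bias_field[idx], 1e-12)
        res_norm[idx] = np.linalg.norm(sol.fun)
        conv[idx] = sol.success
    return ParamMaps(maps=out, residual_norm=res_norm, converged=conv,
                     mask=mask, modality="angio")


def _perfusion_frame_model(protocol: AcquisitionProtocol,
                           binning: FrameBinning):
    t_i = protocol.excitation_times()
    flips = protocol.flip_angles()
    r_i = sig.rf_attenuation(flips)
    tau = protocol.labeling_duration

    def curve(f, att, t1_tissue=1.3, t1_blood=1.65, lam=0.9):
        pp = sig.PerfusionParams(cbf=f, att=att, t1_tissue=t1_tissue,
                                 t1_blood=t1_blood, partition_coefficient=lam,
                                 m0b=1.0)
        return sig.frame_average(
            sig.perfusion_signal(pp, t_i, flips, r_i, tau), binning)

    return curve


def fit_perfusion(series: np.ndarray, mask: np.ndarray,
                  protocol: AcquisitionProtocol, binning: FrameBinning,
                  calibration: CalibrationResult,
                  mode: str = "multi_pld",
                  fixed_att: float = 1.3,
                  t1_tissue: float = 1.3, t1_blood: float = 1.65,
                  bias_field: np.ndarray | None = None) -> ParamMaps:
    """CBF (and ATT) quantification of the perfusion difference series.

    The input series must be phase-corrected and real.  Preparation follows
    the self-calibration convention: multiply by -1 (the post-labeling
    inversion flips the ASL contrast), divide by the bias field (if given),
    the calibrated blood magnetization ``m0b`` and the PCASL efficiency.
    ``multi_pld`` jointly fits (CBF, ATT) by bounded least squares;
    ``single_pld`` inverts the model at the final frame for CBF with ATT
    fixed (root-finding on the monotone CBF -> signal relation, which has
    no closed form once T1' depends on CBF through outflow).
    """
    if mode not in ("multi_pld", "single_pld"):
        raise ValueError(f"unknown mode {mode!r}")
    curve = _perfusion_frame_model(protocol, binning)
    prep = -np.asarray(series, dtype=float)
    prep = prep / (calibration.m0b * calibration.pcasl_efficiency)
    if bias_field is not None:
        prep = prep / np.maximum(bias_field[..., None], 1e-12)

    shape = mask.shape
    out = {"cbf": np.zeros(shape), "att": np.zeros(shape)}
    res_norm = np.zeros(shape)
    conv = np.zeros(shape, dtype=bool)

    if mode == "single_pld":
        pld_last = protocol.readout_start - protocol.labeling_duration \
            + binning.n_frames * binning.frame_duration
        t_last = protocol.labeling_duration + pld_last
        if t_last < fixed_att:
            raise ValueError(
                f"final-frame time {t_last:.3f}s precedes the assumed "
                f"arterial transit time {fixed_att:.3f}s")

        def last_frame_signal(f):
            return curve(f, fixed_att, t1_tissue, t1_blood)[-1]

        f_hi = 400.0
        for vx in np.argwhere(mask):
            y = float(prep[tuple(vx)][..., -1])
            if not np.isfinite(y) or y <= 0:
                conv[tuple(vx)] = np.isfinite(y)
                continue
            y_hi = last_frame_signal(f_hi)
            if y >= y_hi:
                out["cbf"][tuple(vx)] = f_hi
                continue
            sol = optimize.brentq(lambda f: last_frame_signal(f) - y,
                                  0.0, f_hi, xtol=1e-10)
            out["cbf"][tuple(vx)] = sol
            out["att"][tuple(vx)] = fixed_att
            conv[tuple(vx)] = True
        return ParamMaps(maps=out, residual_norm=res_norm, converged=conv,
                         mask=mask, modality="perfusion")

    starts = [(40.0, 0.6), (40.0, 1.2), (80.0, 0.9)]
    for vx in np.argwhere(mask):
        y = np.asarray(prep[tuple(vx)], dtype=float)
        if not np.all(np.isfinite(y)):
            continue
        if np.all(y == 0):
            # identifiable only up to the (f, att > t_max) degeneracy;
            # report zero flow
            conv[tuple(vx)] = True
            continue

        def resid(theta):
            return curve(theta[0], theta[1], t1_tissue, t1_blood) - y

        best, best_cost = None, np.inf
        for st in starts:
            sol = optimize.least_squares(resid, np.asarray(st),
                                         bounds=([0.0, 0.0], [400.0, 3.0]),
                                         xtol=1e-10, ftol=1e-10, max_nfev=100)
            if sol.cost < best_cost:
                best_cost, best = sol.cost, sol
        idx = tuple(vx)
        out["cbf"][idx], out["att"][idx] = best.x
        res_norm[idx] = np.linalg.norm(best.fun)
        conv[idx] = best.success
    return ParamMaps(maps=out, residual_norm=res_norm, converged=conv,
                     mask=mask, modality="perfusion")


def _structural_frame_model(protocol: AcquisitionProtocol,
                            binning: FrameBinning | None):
    def curve(m0, t1, alpha_inv, b1_rel):
        tp = sig.TissueParams(m0=m0, t1=t1, inv_efficiency=alpha_inv,
                              b1_rel=b1_rel)
        mxy, _ = sig.static_tissue_signal(tp, protocol)
        return sig.frame_average(mxy, binning) if binning is not None else mxy
    return curve


def _fit_tissue_curve(y: np.ndarray, curve, t1_starts=(0.5, 1.0, 2.0, 4.0),
                      alpha_starts=(0.8, 0.95),
                      init: tuple | None = None, n_polish: int = 3):
    """Bounded least squares of the static-tissue model to one curve.

    Starts are ranked cheaply by sum of squares with the (linear) amplitude
    profiled out; the ``n_polish`` best seed full 4-parameter refinements.
    """
    b = sig.TissueParams.BOUNDS
    lo = [b["m0"][0], b["t1"][0], b["inv_efficiency"][0], b["b1_rel"][0]]
    hi = [b["m0"][1], b["t1"][1], b["inv_efficiency"][1], b["b1_rel"][1]]

    def resid(theta):
        return curve(*theta) - y

    cands = []
    if init is not None:
        cands.append(np.clip(np.asarray(init), lo, hi))
    else:
        ranked = []
        for t1 in t1_starts:
            for ai in alpha_starts:
                g = curve(1.0, t1, ai, 1.0)
                a = _profiled_amplitude(y, g)
                a = a if a > 0 else max(y.max(), 1e-6)
                ranked.append((float(((y - a * g) ** 2).sum()),
                               np.array([a, t1, ai, 1.0])))
        ranked.sort(key=lambda r: r[0])
        cands = [x0 for _, x0 in ranked[:n_polish]]
    best = None
    for x0 in cands:
        sol = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                     xtol=1e-12, ftol=1e-12, max_nfev=300)
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def calibrate_m0b(structural_lowres: np.ndarray, wm_mask: np.ndarray,
                  protocol: AcquisitionProtocol, binning: FrameBinning,
                  partition_coefficient: float = DEFAULT_WM_PARTITION,
                  pcasl_efficiency: float = DEFAULT_PCASL_EFFICIENCY,
                  ) -> CalibrationResult:
    """Self-calibration of the blood equilibrium magnetization from the
    white-matter mean of the low-resolution structural series.

    The WM-mean frame curve (phase-corrected, real) is fitted with the
    static-tissue model; the fitted equilibrium magnetization is divided by
    the WM/blood partition coefficient to give ``m0b``.
    """
    if not wm_mask.any():
        raise ValueError("white-matter mask is empty")
    y = np.asarray(structural_lowres, dtype=float)[wm_mask].mean(axis=0)
    curve = _structural_frame_model(protocol, binning)
    sol = _fit_tissue_curve(y, curve)
    if sol is None or not sol.success:
        raise RuntimeError(
            "white-matter curve fit did not converge: "
            + (sol.message if sol is not None else "no solution"))
    m0_wm, t1, alpha_inv, b1 = sol.x
    return CalibrationResult(
        m0_wm=float(m0_wm), m0b=float(m0_wm / partition_coefficient),
        partition_coefficient=partition_coefficient,
        pcasl_efficiency=pcasl_efficiency,
        wm_fit={"t1": float(t1), "inv_efficiency": float(alpha_inv),
                "b1_rel": float(b1), "residual_norm": float(np.linalg.norm(sol.fun)),
                "mean_curve": [float(v) for v in y]})


def fit_structural(series: np.ndarray, mask: np.ndarray,
                   protocol: AcquisitionProtocol,
                   binning: FrameBinning | None = None,
                   coarse_init: ParamMaps | None = None) -> ParamMaps:
    """Voxelwise T1 fitting of the multi-TI structural series.

    Fits (M0, T1, alpha_inv, B1_rel) within their bound constraints per
    voxel.  With ``coarse_init`` (a fit at coarser resolution),
    nearest-neighbour upsampled parameters seed each voxel; otherwise a
    multi-start grid over T1 and inversion efficiency is used.  With
    ``binning=None`` the data are per-excitation curves instead of
    reconstructed frames.
    """
    if binning is not None and binning.n_frames < 4:
        raise ValueError("need at least 4 frames for a 4-parameter fit")
    curve = _structural_frame_model(protocol, binning)
    shape = mask.shape
    out = {k: np.zeros(shape) for k in ("m0", "t1", "inv_efficiency", "b1_rel")}
    res_norm = np.zeros(shape)
    conv = np.zeros(shape, dtype=bool)

    init_maps = None
    if coarse_init is not None:
        f = shape[0] // coarse_init.mask.shape[0]
        init_maps = {k: np.repeat(np.repeat(np.repeat(
            coarse_init.maps[k], f, 0), f, 1), f, 2) for k in out}

    for vx in np.argwhere(mask):
        idx = tuple(vx)
        y = np.asarray(series[idx], dtype=float)
        if not np.all(np.isfinite(y)) or np.all(y == 0):
            continue
        init = None
        if init_maps is not None and init_maps["m0"][idx] > 0:
            init = (init_maps["m0"][idx], init_maps["t1"][idx],
                    init_maps["inv_efficiency"][idx], init_maps["b1_rel"][idx])
        sol = _fit_tissue_curve(y, curve, init=init)
        if init is not None and not sol.success:
            sol = _fit_tissue_curve(y, curve)     # fall back to multi-start
        out["m0"][idx], out["t1"][idx] = sol.x[0], sol.x[1]
        out["inv_efficiency"][idx], out["b1_rel"][idx] = sol.x[2], sol.x[3]
        res_norm[idx] = np.linalg.norm(sol.fun)
        conv[idx] = sol.success
    return ParamMaps(maps=out, residual_norm=res_norm, converged=conv,
                     mask=mask, modality="structural")


def repeatability_r2(map_a: np.ndarray, map_b: np.ndarray,
                     mask: np.ndarray) -> dict:
    """Scan-rescan spatial repeatability: squared Pearson correlation of two
    maps over a region, plus the region means."""
    a = np.asarray(map_a, dtype=float)[mask]
    b = np.asarray(map_b, dtype=float)[mask]
    if a.size < 2:
        raise ValueError("mask must contain at least 2 voxels")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant map")
    r = float(np.corrcoef(a, b)[0, 1])
    return {"r2": r * r, "mean_a": float(a.mean()), "mean_b": float(b.mean())}
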