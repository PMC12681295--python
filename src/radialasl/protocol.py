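"""Acquisition protocol, golden-ratio spoke scheduling, frame binning, and
trajectory diagnostics.

The acquisition this module describes is a pseudo-continuous ASL (PCASL)
preparation followed by a long, continuous 3D golden-ratio radial ("koosh
ball") spoiled gradient-echo readout with a variable flip angle schedule.
Label/control preparation pairs are interleaved, and the golden-ratio
counter increments *down* the preparations first and then across the
readout, so that any contiguous group of readout indices contains a
perfectly golden-ratio-ordered set of spoke directions for every
preparation.  Retrospective binning of readout indices into temporal frames
therefore yields near-uniform spherical coverage at any chosen temporal
resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "GOLDEN_MEAN_1",
    "GOLDEN_MEAN_2",
    "AcquisitionProtocol",
    "SpokeSchedule",
    "FrameBinning",
    "SpoilerDiagnostics",
    "golden_ratio_direction",
    "build_spoke_schedule",
    "bin_frames",
    "undersampling_factor",
    "frame_timing",
    "spoiler_refocusing_check",
]


def _golden_means() -> tuple[float, float]:
    # Real root of x^3 = x^2 + 1 (3D generalization of the Fibonacci ratio);
    # the two 2D golden means are 1/x^2 and 1/x.
    roots = np.roots([1.0, -1.0, 0.0, -1.0])
    x = float(roots[np.isreal(roots)].real.max())
    return 1.0 / x**2, 1.0 / x


GOLDEN_MEAN_1, GOLDEN_MEAN_2 = _golden_means()  # 0.4656..., 0.6823...


@dataclass
class AcquisitionProtocol:
    """Timing, flip angle and geometry parameters of one acquisition.

    All times are seconds, angles degrees, distances mm.

    Parameters
    ----------
    labeling_duration:
        PCASL labeling train duration tau.
    n_pairs:
        Number of interleaved label/control preparation pairs.
    spokes_per_prep:
        Radial spokes (excitations) acquired during each preparation's readout.
    tr, te:
        Repetition and echo time of the spoiled gradient-echo readout.
    readout_start:
        Time of the first excitation relative to the start of labeling.
        Defaults to ``labeling_duration + pld_offset``.
    inversion_time:
        Center of the inversion pulse relative to the start of labeling; the
        pulse is played immediately after the PCASL train, so this defaults
        to ``labeling_duration``.
    flip_min, flip_max:
        End points of the variable flip angle schedule.
    flip_profile:
        Only ``"quadratic"`` is implemented: a monotone increasing quadratic
        ramp, which shifts signal usage toward later (lower ASL signal, higher
        structural signal) time points.
    matrix_size:
        Reconstructed/nominal matrix size N per dimension.
    fov:
        Field of view in mm.
    pld_offset:
        Dead time between the end of labeling and the first excitation; the
        minimum post-labeling delay is ``pld_offset + frame_duration / 2``.
    pcasl_efficiency:
        PCASL labeling (inversion) efficiency, dimensionless.
    """

    labeling_duration: float = 1.8
    n_pairs: int = 48
    spokes_per_prep: int = 216
    tr: float = 9.1e-3
    te: float = 4.74e-3
    flip_min: float = 2.0
    flip_max: float = 9.0
    flip_profile: str = "quadratic"
    matrix_size: int = 176
    fov: float = 193.6
    pld_offset: float = 33e-3
    pcasl_efficiency: float = 0.85
    readout_start: float | None = None
    inversion_time: float | None = None

    def __post_init__(self):
        if self.labeling_duration <= 0:
            raise ValueError("labeling_duration must be positive")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if not (0 < self.flip_min <= self.flip_max < 90):
            raise ValueError("flip angles must satisfy 0 < flip_min <= flip_max < 90 deg")
        if self.n_pairs < 1 or self.spokes_per_prep < 1:
            raise ValueError("n_pairs and spokes_per_prep must be >= 1")
        if self.matrix_size < 2:
            raise ValueError("matrix_size must be >= 2")
        if not (0 < self.pcasl_efficiency <= 1):
            raise ValueError("pcasl_efficiency must lie in (0, 1]")
        if self.flip_profile != "quadratic":
            raise ValueError(f"unknown flip profile {self.flip_profile!r}")
        if self.inversion_time is None:
            self.inversion_time = self.labeling_duration
        if self.readout_start is None:
            self.readout_start = self.labeling_duration + self.pld_offset
        if self.inversion_time < self.labeling_duration:
            raise ValueError("inversion pulse must come after the labeling train")
        if self.readout_start < self.inversion_time:
            raise ValueError("readout must start after the inversion pulse")

    # -- derived quantities ------------------------------------------------
    @property
    def readout_duration(self) -> float:
        return self.spokes_per_prep * self.tr

    @property
    def kmax(self) -> float:
        """Radial k-space extent in cycles/FOV."""
        return self.matrix_size / 2.0

    def excitation_times(self) -> np.ndarray:
        """Time of each excitation relative to the start of labeling (s)."""
        i = np.arange(self.spokes_per_prep)
        return self.readout_start + i * self.tr

    def flip_angles(self) -> np.ndarray:
        """Variable flip angle schedule in degrees (monotone quadratic ramp)."""
        n = self.spokes_per_prep
        if n == 1:
            return np.array([self.flip_min])
        i = np.arange(n) / (n - 1)
        return self.flip_min + (self.flip_max - self.flip_min) * i**2

    # -- serialization -----------------------------------------------------
    _MS_FIELDS = ("labeling_duration", "tr", "te", "pld_offset",
                  "readout_start", "inversion_time")

    def to_dict(self) -> dict:
        d = asdict(self)
        out = {}
        for k, v in d.items():
            if k in self._MS_FIELDS:
                out[f"{k}_ms"] = v * 1e3
            elif k in ("flip_min", "flip_max"):
                out[f"{k}_deg"] = v
            elif k == "fov":
                out["fov_mm"] = v
            else:
                out[k] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        kwargs = {}
        for k, v in d.items():
            if k.endswith("_ms"):
                kwargs[k[:-3]] = v * 1e-3
            elif k.endswith("_deg"):
                kwargs[k[:-4]] = v
            elif k == "fov_mm":
                kwargs["fov"] = v
            else:
                kwargs[k] = v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AcquisitionProtocol":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "AcquisitionProtocol":
        return cls.from_dict(json.loads(s))

    # -- presets -----------------------------------------------------------
    @classmethod
    def preset_48_pairs(cls, **overrides) -> "AcquisitionProtocol":
        """Full-scale 48-pair protocol (6 min 10 s scan)."""
        return cls(**overrides)

    @classmethod
    def preset_47_pairs(cls, **overrides) -> "AcquisitionProtocol":
        """Full-scale 47-pair protocol; exhibits spoiler-refocusing artifacts."""
        overrides.setdefault("n_pairs", 47)
        return cls(**overrides)

    @classmethod
    def preset_desk(cls, **overrides) -> "AcquisitionProtocol":
        """Small protocol for desk-scale simulation and reconstruction.

        16 pairs x 120 spokes on a 32^3 matrix: 12 angiographic frames of
        160 difference spokes each (~10x undersampled at N=32).
        """
        overrides.setdefault("n_pairs", 16)
        overrides.setdefault("spokes_per_prep", 120)
        overrides.setdefault("matrix_size", 32)
        overrides.setdefault("fov", 224.0)
        return cls(**overrides)


def golden_ratio_direction(m) -> np.ndarray:
    """Unit direction(s) of golden-ratio spoke counter ``m`` (>= 1).

    Uses the 2D golden means mapping on the full sphere:
    ``kz = 1 - 2 frac(m phi1)``, ``azimuth = 2 pi frac(m phi2)`` with
    ``phi1 = 0.4656...`` and ``phi2 = 0.6823...``.  Consecutive counters give
    low-discrepancy coverage of the sphere for any run length.
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 1):
        raise ValueError("golden-ratio counter m must be >= 1")
    kz = 1.0 - 2.0 * np.mod(m_arr * GOLDEN_MEAN_1, 1.0)
    az = 2.0 * np.pi * np.mod(m_arr * GOLDEN_MEAN_2, 1.0)
    r = np.sqrt(np.maximum(0.0, 1.0 - kz**2))
    d = np.stack([r * np.cos(az), r * np.sin(az), kz], axis=-1)
    return d


@dataclass
class SpokeSchedule:
    """Per-spoke golden-ratio counters, directions and acquisition metadata.

    Spokes are ordered as acquired: preparation pair 1 label readout,
    pair 1 control readout, pair 2 label, ...  ``counter`` obeys
    ``m = (readout_index - 1) * n_pairs + pair_index`` (1-based), identical
    for the label and control condition of the same pair.
    """

    counter: np.ndarray          # (M,) int, 1-based golden-ratio counter
    direction: np.ndarray        # (M, 3) float unit vectors
    prep_index: np.ndarray       # (M,) int, 1-based preparation pair
    condition: np.ndarray        # (M,) uint8: 0 = label, 1 = control
    readout_index: np.ndarray    # (M,) int, 1-based index within the readout
    time: np.ndarray             # (M,) float s, relative to labeling start
    n_pairs: int = 0
    spokes_per_prep: int = 0

    @property
    def n_spokes(self) -> int:
        return self.counter.size

    def to_hdf5(self, grp) -> None:
        for name in ("counter", "direction", "prep_index", "condition",
                     "readout_index", "time"):
            grp.create_dataset(name, data=getattr(self, name))
        grp.attrs["n_pairs"] = self.n_pairs
        grp.attrs["spokes_per_prep"] = self.spokes_per_prep

    @classmethod
    def from_hdf5(cls, grp) -> "SpokeSchedule":
        return cls(**{name: grp[name][()] for name in
                      ("counter", "direction", "prep_index", "condition",
                       "readout_index", "time")},
                   n_pairs=int(grp.attrs["n_pairs"]),
                   spokes_per_prep=int(grp.attrs["spokes_per_prep"]))


def build_spoke_schedule(protocol: AcquisitionProtocol) -> SpokeSchedule:
    """Build the full acquisition-ordered spoke schedule.

    Total spokes = 2 * n_pairs * spokes_per_prep.  Label and control spokes
    with the same (preparation, readout index) share the same direction.
    """
    np_, s = protocol.n_pairs, protocol.spokes_per_prep
    i = np.arange(1, s + 1)                        # readout index
    times = protocol.excitation_times()

    pair = np.repeat(np.arange(1, np_ + 1), 2 * s)          # (M,)
    cond = np.tile(np.repeat(np.array([0, 1], np.uint8), s), np_)
    ridx = np.tile(i, 2 * np_)
    m = (ridx - 1) * np_ + pair
    t = np.tile(times, 2 * np_)
    return SpokeSchedule(
        counter=m.astype(np.int64),
        direction=golden_ratio_direction(m),
        prep_index=pair.astype(np.int64),
        condition=cond,
        readout_index=ridx.astype(np.int64),
        time=t,
        n_pairs=np_,
        spokes_per_prep=s,
    )


@dataclass
class FrameBinning:
    """Retrospective binning of readout indices into temporal frames."""

    n_frames: int
    spokes_per_frame_per_prep: int
    frame_duration: float                 # s
    window_offset: float = 0.0            # s, shift of all frame windows
    n_pairs: int = 1

    @property
    def spokes_per_frame(self) -> int:
        """Spokes per frame per condition (matches per-frame spoke counts of
        difference or mean data)."""
        return self.spokes_per_frame_per_prep * self.n_pairs

    def frame_of_readout_index(self, readout_index: np.ndarray) -> np.ndarray:
        """Map 1-based readout indices to 0-based frame numbers."""
        return (np.asarray(readout_index) - 1) // self.spokes_per_frame_per_prep

    def readout_slices(self) -> list[slice]:
        """0-based readout-index slices for each frame."""
        spf = self.spokes_per_frame_per_prep
        return [slice(k * spf, (k + 1) * spf) for k in range(self.n_frames)]


def bin_frames(schedule: SpokeSchedule, n_frames: int,
               window_offset: float = 0.0, *, tr: float | None = None,
               ) -> FrameBinning:
    """Bin the readout into ``n_frames`` equal temporal frames.

    ``spokes_per_prep`` must be divisible by ``n_frames``; within every frame
    the golden-ratio counters form a contiguous integer run, preserving the
    low-discrepancy ordering at any temporal resolution.
    """
    s = schedule.spokes_per_prep
    if n_frames < 1 or s % n_frames:
        divisors = [d for d in range(1, s + 1) if s % d == 0]
        raise ValueError(
            f"n_frames={n_frames} does not divide spokes_per_prep={s}; "
            f"valid frame counts: {divisors}")
    if tr is None:
        # infer TR from schedule times (uniform by construction)
        t = np.unique(schedule.time)
        tr = float(t[1] - t[0]) if t.size > 1 else 0.0
    spf = s // n_frames
    return FrameBinning(
        n_frames=n_frames,
        spokes_per_frame_per_prep=spf,
        frame_duration=spf * tr,
        window_offset=window_offset,
        n_pairs=schedule.n_pairs,
    )


def undersampling_factor(matrix_size: int, spokes_per_frame: int) -> float:
    """Radial undersampling factor relative to the pi N^2 / 2 Nyquist spoke
    count for an N^3 matrix."""
    if matrix_size < 2:
        raise ValueError("matrix_size must be >= 2")
    if spokes_per_frame < 1:
        raise ValueError("spokes_per_frame must be >= 1")
    return (np.pi * matrix_size**2 / 2.0) / spokes_per_frame


def frame_timing(protocol: AcquisitionProtocol, binning: FrameBinning,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame effective PLD and TI (seconds), referenced to frame centers.

    ``PLD_k = pld_offset + (k - 1/2) * frame_duration + window_offset`` (time
    from the end of labeling to the frame center) and ``TI_k`` is measured
    from the center of the inversion pulse to the frame center.
    """
    k = np.arange(1, binning.n_frames + 1)
    center = (k - 0.5) * binning.frame_duration + binning.window_offset
    pld = (protocol.readout_start - protocol.labeling_duration) + center
    ti = (protocol.readout_start - protocol.inversion_time) + center
    return pld, ti


@dataclass
class SpoilerDiagnostics:
    """Result of the spoiler-refocusing path-tracing diagnostic."""

    excitation_index: np.ndarray   # (E,) 1-based readout index of excitation
    min_k: np.ndarray              # (E,) min |k| (cycles/FOV) on later spokes
    flagged: np.ndarray            # (E,) bool, min_k < threshold
    threshold: float
    spoiler_moment: float          # cycles/FOV
    lookahead: int

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def _fold_polarity(d: np.ndarray) -> np.ndarray:
    # Readout gradient polarity: traverse every spoke with kz >= 0 (the
    # sampled line is direction-agnostic, but the gradient path is not).
    return d * np.where(d[..., 2:3] < 0, -1.0, 1.0)


def _segment_min_norm(start: np.ndarray, end: np.ndarray) -> np.ndarray:
    seg = end - start
    denom = np.maximum((seg * seg).sum(-1), 1e-300)
    t = np.clip(-(start * seg).sum(-1) / denom, 0.0, 1.0)[..., None]
    return np.linalg.norm(start + t * seg, axis=-1)


def spoiler_refocusing_check(schedule: SpokeSchedule, kmax: float,
                             spoiler_moment: float = 1.0,
                             lookahead: int = 3,
                             threshold: float | None = None,
                             prep_index: int = 1,
                             condition: int = 0,
                             n_excitations: int | None = None,
                             ) -> SpoilerDiagnostics:
    """Trace residual-magnetization k-space paths and flag near-refocusing.

    For magnetization excited by pulse ``e`` of one continuous readout, the
    concatenated gradient path of spoke ``e`` (prewinder, readout, spoiler
    along the readout direction) and the following ``lookahead`` spokes is
    traced, and the minimum |k| reached during the *later* spokes' readouts
    is reported.  An excitation is flagged when that minimum drops below
    ``threshold`` (default ``kmax``): its stale transverse magnetization
    re-enters the sampled k-space ball and contributes artifactual signal.

    ``spoiler_moment`` is the spoiler gradient area as a fraction of
    ``kmax`` (cycles/FOV).
    """
    if lookahead < 1:
        raise ValueError("lookahead must be >= 1")
    sel = (schedule.prep_index == prep_index) & (schedule.condition == condition)
    ridx = schedule.readout_index[sel]
    order = np.argsort(ridx)
    dirs = _fold_polarity(schedule.direction[sel][order])
    ridx = ridx[order]
    n_spokes = dirs.shape[0]
    if n_spokes < 3:
        raise ValueError("need at least 3 consecutive spokes")
    n_exc = n_spokes - lookahead if n_excitations is None else \
        min(n_excitations, n_spokes - lookahead)
    if threshold is None:
        threshold = kmax
    s_mom = spoiler_moment * kmax

    e = np.arange(n_exc)
    k = np.zeros((n_exc, 3))
    min_k = np.full(n_exc, np.inf)
    for l in range(lookahead + 1):
        d = dirs[e + l]
        start = k - kmax * d
        end = start + 2 * kmax * d
        if l > 0:
            min_k = np.minimum(min_k, _segment_min_norm(start, end))
        k = end + s_mom * d
    flagged = min_k < threshold
    return SpoilerDiagnostics(
        excitation_index=ridx[:n_exc],
        min_k=min_k,
        flagged=flagged,
        threshold=float(threshold),
        spoiler_moment=float(s_mom),
        lookahead=lookahead,
    )
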