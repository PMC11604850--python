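"""Spoiled-gradient-echo (SPGR) sequence: timing, gradient lobes, RF, steady state.

Conventions
-----------
* All internal quantities are SI (s, m, T/m, rad).  The config loader in
  :mod:`pcmrisim.runner` accepts the customary ms / mm / degree units.
* The stored gyromagnetic ratio is gamma-bar = 42.58 MHz/T; every phase
  formula uses ``gamma_rad = 2 pi gamma_bar`` (rad/s/T).
* Gradient lobes are ideal rectangles.  Within one TR: the RF pulse fires at
  t = 0; the phase-encode lobe and the velocity-encoding bipolar pair are both
  centred at TC (they live on different axes and superpose); the readout
  prephaser (-GR, duration TS/2) immediately precedes the readout plateau
  (+GR, duration TS) centred on TE.  Echo therefore occurs at TE with zero net
  readout moment for static spins.
* TC defaults to ``TE - TS - TV`` — the latest placement that still clears the
  prephaser — so the velocity encoding sits adjacent to the readout, as in
  clinical phase-contrast sequences; it can be overridden per protocol.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "GAMMA_BAR_DEFAULT",
    "ProtocolError",
    "ScanProtocol",
    "GradientEvent",
    "EncodingSegment",
    "saturation_magnetization",
    "ernst_angle",
    "apply_rf_rotation",
    "apply_ideal_excitation",
    "build_segment",
    "field_at",
]

GAMMA_BAR_DEFAULT = 42.58e6  # Hz/T

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class ProtocolError(ValueError):
    """Sequence timing or parameter inconsistency."""


@dataclasses.dataclass(frozen=True)
class ScanProtocol:
    """All sequence parameters of one 2-D PC-MRI acquisition (SI units).

    Unspecified durations follow the defaults TS = Nx * dts, TP = TS / 2,
    TV = TP / 2 and TC = TE - TS - TV.
    """

    tr: float
    te: float
    matrix: tuple[int, int]  # (Nx, Ny)
    fov: tuple[float, float]  # (Lx, Ly), m
    slice_thickness: float
    flip_angle: float  # rad
    venc: float  # m/s
    encoding_directions: tuple[str, ...] = ("z",)
    sampling_pitch_dts: float = 1e-5
    ts: Optional[float] = None
    tp: Optional[float] = None
    tv: Optional[float] = None
    tc: Optional[float] = None
    slice_center: float = 0.0
    gamma_bar: float = GAMMA_BAR_DEFAULT

    def __post_init__(self) -> None:
        if self.ts is None:
            object.__setattr__(self, "ts", self.matrix[0] * self.sampling_pitch_dts)
        if self.tp is None:
            object.__setattr__(self, "tp", 0.5 * self.ts)
        if self.tv is None:
            object.__setattr__(self, "tv", 0.5 * self.tp)
        if self.tc is None:
            object.__setattr__(self, "tc", self.te - self.ts - self.tv)
        if not 0 < self.te < self.tr:
            raise ProtocolError("need 0 < TE < TR")
        if self.venc <= 0:
            raise ProtocolError("venc must be positive")
        if not 0 < self.flip_angle < np.pi:
            raise ProtocolError("flip angle must lie in (0, pi)")
        if min(self.matrix) < 1 or min(self.fov) <= 0:
            raise ProtocolError("matrix and FOV must be positive")
        for d in self.encoding_directions:
            if d not in _AXIS_INDEX:
                raise ProtocolError(f"unknown encoding direction {d!r}")

    @property
    def gamma_rad(self) -> float:
        return 2 * np.pi * self.gamma_bar

    @property
    def voxel_size(self) -> tuple[float, float]:
        return (self.fov[0] / self.matrix[0], self.fov[1] / self.matrix[1])

    # derived gradient amplitudes -------------------------------------------------
    @property
    def readout_amplitude(self) -> float:
        """GR such that one sampling pitch advances kx by 2 pi / Lx."""
        return 2 * np.pi / (self.gamma_rad * self.fov[0] * self.sampling_pitch_dts)

    @property
    def phase_encode_step(self) -> float:
        """Per-line phase-encode amplitude increment (one line = 2 pi / Ly in ky)."""
        return 2 * np.pi / (self.gamma_rad * self.fov[1] * self.tp)

    @property
    def bipolar_amplitude(self) -> float:
        """GV = pi / (gamma_rad venc TV^2); first moment GV TV^2 -> phase pi at venc."""
        return np.pi / (self.gamma_rad * self.venc * self.tv**2)

    def sample_times(self) -> np.ndarray:
        nx = self.matrix[0]
        return self.te + (np.arange(nx) - nx // 2) * self.sampling_pitch_dts

    def line_indices(self) -> np.ndarray:
        ny = self.matrix[1]
        return np.arange(-(ny // 2), ny - ny // 2)


@dataclasses.dataclass(frozen=True)
class GradientEvent:
    """One rectangular gradient lobe.  ``axis`` is the spatial direction the
    field varies along (Bz contribution = amplitude * coordinate)."""

    axis: int
    amplitude: float
    start: float
    stop: float

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ProtocolError("gradient lobe must have stop > start")


@dataclasses.dataclass(frozen=True)
class EncodingSegment:
    """Event list of one TR for one k-space line and one encoding state."""

    phase_line_index: int
    bpg_state: str  # 'off' or '+x','-x','+y','-y','+z','-z'
    events: tuple[GradientEvent, ...]
    rf_time: float
    echo_time: float
    tr: float
    sample_times: np.ndarray

    def gradient_vector(self, t: float) -> np.ndarray:
        """(Gx, Gy, Gz) active at time t (T/m).  Lobes are start-inclusive."""
        g = np.zeros(3)
        for ev in self.events:
            if ev.start <= t < ev.stop:
                g[ev.axis] += ev.amplitude
        return g

    def breakpoints(self) -> np.ndarray:
        """Times where the piecewise-constant gradient vector may change,
        merged with the readout sample times, spanning [0, TR]."""
        pts = {0.0, self.tr}
        for ev in self.events:
            pts.add(ev.start)
            pts.add(ev.stop)
        pts.update(float(t) for t in self.sample_times)
        out = np.array(sorted(pts))
        return out[(out >= 0) & (out <= self.tr + 1e-15)]


# ---------------------------------------------------------------------------
# magnetization primitives
# ---------------------------------------------------------------------------


def saturation_magnetization(m0: float, tr: float, t1: float, alpha: float) -> float:
    """Steady-state longitudinal magnetization of an ideally spoiled sequence,

    Ms = M0 (1 - E1) / (1 - cos(alpha) E1),  E1 = exp(-TR/T1).
    """
    if t1 <= 0 or tr <= 0:
        raise ValueError("TR and T1 must be positive")
    e1 = np.exp(-tr / t1)
    return m0 * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)


def ernst_angle(tr: float, t1: float) -> float:
    """Flip angle maximizing the spoiled steady-state signal: arccos(e^{-TR/T1})."""
    if t1 <= 0:
        raise ValueError("T1 must be positive")
    return float(np.arccos(np.exp(-tr / t1)))


def apply_rf_rotation(m: np.ndarray, alpha: float, azimuth: float = 0.0) -> np.ndarray:
    """Rotate magnetization vector(s) by ``alpha`` about the transverse-plane
    axis at the given azimuth.  Norm-preserving."""
    axis = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
    rot = Rotation.from_rotvec(alpha * axis)
    return rot.apply(np.atleast_2d(m)).reshape(np.shape(m))


def apply_ideal_excitation(mz_minus, alpha: float):
    """Ideal spoiled excitation (vectorized):

    Mz+ = Mz- cos(alpha),  Mr+ = Mz- sin(alpha),  phi+ = 0,

    valid under the spoiling assumption that Mr = 0 before the pulse.
    """
    mz_minus = np.asarray(mz_minus)
    return mz_minus * np.cos(alpha), mz_minus * np.sin(alpha), np.zeros_like(mz_minus)


# ---------------------------------------------------------------------------
# segment construction
# ---------------------------------------------------------------------------


def build_segment(
    protocol: ScanProtocol, line: int, bpg_state: str = "off"
) -> EncodingSegment:
    """Assemble the per-TR gradient event list for one phase-encode line.

    Events: phase-encode lobe (y axis, amplitude line * dGP) centred at TC;
    bipolar pair (+GV then -GV, each lobe TV long) centred at TC when the BPG
    is on; readout prephaser and plateau placing the gradient echo at TE.
    """
    nx, ny = protocol.matrix
    if not -(ny // 2) <= line <= ny - ny // 2 - 1:
        raise ProtocolError(f"phase line {line} outside matrix bounds")
    if bpg_state != "off" and (
        len(bpg_state) != 2
        or bpg_state[0] not in "+-"
        or bpg_state[1] not in _AXIS_INDEX
    ):
        raise ProtocolError(f"bad bpg_state {bpg_state!r}")

    tc, tp, tv, ts, te, tr = (
        protocol.tc,
        protocol.tp,
        protocol.tv,
        protocol.ts,
        protocol.te,
        protocol.tr,
    )
    events = []
    if line != 0:
        events.append(
            GradientEvent(1, line * protocol.phase_encode_step, tc - tp / 2, tc + tp / 2)
        )
    if bpg_state != "off":
        sign = 1.0 if bpg_state[0] == "+" else -1.0
        axis = _AXIS_INDEX[bpg_state[1]]
        gv = sign * protocol.bipolar_amplitude
        events.append(GradientEvent(axis, gv, tc - tv, tc))
        events.append(GradientEvent(axis, -gv, tc, tc + tv))
    gr = protocol.readout_amplitude
    events.append(GradientEvent(0, -gr, te - ts, te - ts / 2))
    events.append(GradientEvent(0, gr, te - ts / 2, te + ts / 2))

    for ev in events:
        if ev.start < 0 or ev.stop > tr + 1e-15:
            raise ProtocolError(
                f"gradient event [{ev.start:.6g}, {ev.stop:.6g}] s exceeds TR"
            )
    return EncodingSegment(
        phase_line_index=line,
        bpg_state=bpg_state,
        events=tuple(events),
        rf_time=0.0,
        echo_time=te,
        tr=tr,
        sample_times=protocol.sample_times(),
    )


def field_at(segment: EncodingSegment, position, time: float):
    """Bz(x, t): sum of active gradient amplitudes times coordinates."""
    pos = np.asarray(position, dtype=float)
    g = segment.gradient_vector(time)
    return pos @ g if pos.ndim > 1 else float(np.dot(pos, g))


def first_moment(segment: EncodingSegment, axis: int, t0: float, t1: float) -> float:
    """Analytic first gradient moment  m1 = int_{t0}^{t1} G_axis(t) t dt.

    Independent oracle used by tests: a spin moving at constant velocity v
    along ``axis`` accrues phase ``-gamma_rad * v * m1`` from that gradient.
    """
    m1 = 0.0
    for ev in segment.events:
        if ev.axis != axis:
            continue
        a, b = max(ev.start, t0), min(ev.stop, t1)
        if b > a:
            m1 += ev.amplitude * (b**2 - a**2) / 2.0
    return m1
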