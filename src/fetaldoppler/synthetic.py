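"""Synthetic feto-placental Doppler study generator.

Produces annotated spectral-Doppler screen captures with exact ground truth
for the four target views:

* **UA / MCA** — pulsatile one-sided flow (the whole waveform sits on one
  side of the Doppler zero line),
* **AoI** — mainly antegrade systolic flow with possible diastolic reversal
  (signal on both sides of the zero line),
* **LVIO** — biphasic pattern combining aortic outflow (systole, one side)
  and mitral inflow (E and A waves, opposite side),
* **OTHER** — a valve-like out-of-domain pattern (narrow tall systolic
  spike) used to exercise the keep/skip confidence stage.

Each study consists of a grayscale spectrogram (velocity vs. time), a
procedural B-mode image with a coloured Doppler cursor overlay, a
:class:`~fetaldoppler.calibration.Calibration`, and a ground-truth record
(per-column envelope velocities, timed and valued physiological events,
cursor pixel mask).  Waveforms are built by concatenating 1–18 cardiac
cycles whose duration and magnitude are jittered by up to ±10% around a
per-view template, mirroring how training spectrograms with a variable
number of beats arise in practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .calibration import Calibration

# --------------------------------------------------------------------------
# view vocabulary
# --------------------------------------------------------------------------

UA = "UA"
MCA = "MCA"
AOI = "AoI"
LVIO = "LVIO"
OTHER = "OTHER"

VIEWS = (UA, MCA, AOI, LVIO)
ALL_VIEWS = VIEWS + (OTHER,)

#: physiological events annotated per view, in canonical channel order
EVENT_VOCAB: dict[str, tuple[str, ...]] = {
    UA: ("onset S", "S peak"),
    MCA: ("onset S", "S peak"),
    AOI: ("onset S", "S peak"),
    LVIO: ("onset S", "S peak", "end S", "onset E", "E peak", "A peak", "end A"),
    OTHER: ("onset S", "S peak"),
}

#: minimum separation between events inside one template (ms); templates
#: violating it are rejected so ground truth stays consistent with the
#: post-processing minimum-distance rule
MIN_EVENT_GAP_MS = 80.0

MAX_CYCLES = 18

# per-view default waveform parameters (cm/s, ms)
_DEFAULT_SHAPE: dict[str, dict[str, float]] = {
    UA: dict(duration=500.0, systolic_peak=60.0, end_diastolic=25.0),
    MCA: dict(duration=450.0, systolic_peak=50.0, end_diastolic=12.0),
    AOI: dict(
        duration=450.0,
        systolic_peak=55.0,
        end_diastolic=8.0,
        reversal_fraction=0.25,
    ),
    LVIO: dict(
        duration=560.0,
        systolic_peak=60.0,
        e_peak=35.0,
        a_peak=45.0,
    ),
    OTHER: dict(duration=420.0, systolic_peak=80.0, end_diastolic=3.0),
}

_DURATION_RANGE = (300.0, 600.0)


# --------------------------------------------------------------------------
# templates
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleTemplate:
    """One cardiac cycle: a signed velocity curve plus its annotated events.

    ``events`` holds ``(name, t_ms, v_cms)`` with times strictly inside
    ``[0, duration)`` and velocities lying on the envelope curve.
    """

    view: str
    duration: float
    events: tuple[tuple[str, float, float], ...]
    _curve: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def velocity_at(self, t_ms) -> np.ndarray:
        """Signed envelope velocity (cm/s) at time(s) ``t_ms`` within the cycle."""
        t = np.asarray(t_ms, dtype=float)
        return np.asarray(self._curve(np.clip(t, 0.0, self.duration)))

    # convenience for tests / plotting
    def sample(self, n: int = 256) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, self.duration, n, endpoint=False)
        return t, self.velocity_at(t)


def _validate_template(tpl: CycleTemplate) -> None:
    names = [e[0] for e in tpl.events]
    if tuple(names) != EVENT_VOCAB[tpl.view]:
        raise ValueError(
            f"{tpl.view} template must carry events {EVENT_VOCAB[tpl.view]}, got {names}"
        )
    times = np.array([e[1] for e in tpl.events])
    if np.any(times < 0) or np.any(times >= tpl.duration):
        raise ValueError("event times must lie strictly inside [0, duration)")
    if len(times) > 1:
        gaps = np.diff(np.sort(times))
        if np.any(gaps < MIN_EVENT_GAP_MS):
            raise ValueError(
                f"events closer than {MIN_EVENT_GAP_MS:g} ms "
                f"(min gap {gaps.min():.1f} ms) are rejected"
            )
    t, v = tpl.sample(512)
    if tpl.view in (UA, MCA, OTHER):
        if not (np.all(v > 0) or np.all(v < 0)):
            raise ValueError(f"{tpl.view} envelope must keep a single sign")
    if tpl.view == LVIO:
        if not (v.max() > 0 and v.min() < 0):
            raise ValueError("LVIO envelope must have opposite-signed lobes")


def _lobe_curve(anchors: Sequence[tuple[float, float]]):
    ts = np.array([a[0] for a in anchors])
    vs = np.array([a[1] for a in anchors])
    return PchipInterpolator(ts, vs)


def generate_cycle_template(
    view: str,
    shape_params: dict | None = None,
    rng: np.random.Generator | None = None,
) -> CycleTemplate:
    """Build a per-view single-cycle waveform template.

    Parameters may be overridden through ``shape_params`` (keys as in the
    per-view defaults: ``duration`` ms in [300, 600], ``systolic_peak`` and
    ``end_diastolic`` cm/s, ``reversal_fraction`` for AoI, ``e_peak`` /
    ``a_peak`` for LVIO, and ``flow_sign`` ±1).  When an ``rng`` is given,
    peak velocities and duration are perturbed by up to ±8% around their
    values so repeated draws yield physiological variety.
    """
    if view not in ALL_VIEWS:
        raise ValueError(f"unknown view {view!r}; expected one of {ALL_VIEWS}")
    p = dict(_DEFAULT_SHAPE[view])
    if shape_params:
        unknown = set(shape_params) - (set(p) | {"flow_sign", "shape_jitter"})
        if unknown:
            raise ValueError(f"unknown shape parameters {sorted(unknown)} for {view}")
        p.update(shape_params)
    sign = float(p.pop("flow_sign", 1.0))
    jitter = float(p.pop("shape_jitter", 0.08))
    lo, hi = _DURATION_RANGE
    if rng is not None and jitter > 0:
        for key in list(p):
            if key in ("duration", "systolic_peak", "end_diastolic", "e_peak", "a_peak"):
                p[key] = p[key] * (1.0 + rng.uniform(-jitter, jitter))
        p["duration"] = float(np.clip(p["duration"], lo, hi))
    D = float(p["duration"])
    if not (lo <= D <= hi):
        raise ValueError(f"cycle duration {D:.0f} ms outside [{lo:.0f}, {hi:.0f}] ms")

    if view in (UA, MCA, AOI, OTHER):
        psv = float(p["systolic_peak"])
        edv = float(p["end_diastolic"])
        if psv <= 0 or edv < 0 or edv >= psv:
            raise ValueError("require systolic_peak > end_diastolic >= 0")
        t_on, t_pk = 0.05 * D, 0.26 * D
        if view == OTHER:
            # narrow valve-like spike with near-zero diastole
            anchors = [
                (0.0, edv),
                (0.03 * D, edv * 1.2 + 0.5),
                (0.25 * D, psv),
                (0.42 * D, 0.12 * psv),
                (0.60 * D, edv * 1.5 + 0.3),
                (D, edv),
            ]
            events = [("onset S", 0.03 * D, None), ("S peak", 0.25 * D, None)]
        elif view == AOI:
            rf = float(p.get("reversal_fraction", 0.0))
            anchors = [
                (0.0, edv),
                (t_on, edv * 0.9),
                (t_pk, psv),
                (0.45 * D, 0.25 * psv),
            ]
            if rf > 0:
                anchors += [
                    (0.56 * D, -rf * psv),
                    (0.72 * D, edv * 0.6),
                ]
            else:
                anchors += [(0.6 * D, edv * 0.7)]
            anchors += [(D, edv)]
            events = [("onset S", t_on, None), ("S peak", t_pk, None)]
        else:  # UA / MCA
            anchors = [
                (0.0, edv),
                (t_on, edv * 0.95),
                (t_pk, psv),
                (0.50 * D, 0.5 * (psv + edv)),
                (0.75 * D, edv * 1.1),
                (D, edv),
            ]
            events = [("onset S", t_on, None), ("S peak", t_pk, None)]
        base = _lobe_curve(anchors)
        curve = (lambda t, b=base, s=sign: s * b(t))
    else:  # LVIO
        psv = float(p["systolic_peak"])
        e_pk = float(p["e_peak"])
        a_pk = float(p["a_peak"])
        if min(psv, e_pk, a_pk) <= 0:
            raise ValueError("LVIO peak velocities must be positive")
        # outflow lobe (systole, positive side)
        t_onS, t_Spk, t_endS = 0.03 * D, 0.19 * D, 0.35 * D
        # inflow lobe (diastole, negative side)
        t_onE, t_Epk, t_Apk, t_endA = 0.51 * D, 0.67 * D, 0.83 * D, 0.99 * D
        out = _lobe_curve(
            [(t_onS, 6.0), (t_Spk, psv), ((t_Spk + t_endS) / 2, 0.45 * psv), (t_endS, 5.0)]
        )
        mid_diast = -0.45 * min(e_pk, a_pk)
        infl = _lobe_curve(
            [
                (t_onE, -5.0),
                (t_Epk, -e_pk),
                ((t_Epk + t_Apk) / 2, mid_diast),
                (t_Apk, -a_pk),
                (t_endA, -5.0),
            ]
        )

        def curve(t, out=out, infl=infl, a=t_onS, b=t_endS, c=t_onE, d=t_endA, s=sign):
            t = np.asarray(t, dtype=float)
            v = np.zeros_like(t)
            m1 = (t >= a) & (t <= b)
            m2 = (t >= c) & (t <= d)
            v[m1] = out(t[m1])
            v[m2] = infl(t[m2])
            return s * v

        events = [
            ("onset S", t_onS, None),
            ("S peak", t_Spk, None),
            ("end S", t_endS, None),
            ("onset E", t_onE, None),
            ("E peak", t_Epk, None),
            ("A peak", t_Apk, None),
            ("end A", t_endA, None),
        ]

    ev = tuple(
        (name, float(t), float(np.asarray(curve(np.array([t])))[0]))
        for name, t, _ in events
    )
    tpl = CycleTemplate(view=view, duration=D, events=ev, _curve=curve)
    _validate_template(tpl)
    return tpl


# --------------------------------------------------------------------------
# cycle concatenation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaledCycle:
    """A template instance with per-cycle duration/velocity jitter applied."""

    template: CycleTemplate
    start: float  # ms, within the track
    duration_scale: float
    velocity_scale: float

    @property
    def duration(self) -> float:
        return self.template.duration * self.duration_scale

    @property
    def end(self) -> float:
        return self.start + self.duration

    def velocity_at(self, t_ms) -> np.ndarray:
        local = (np.asarray(t_ms, dtype=float) - self.start) / self.duration_scale
        return self.velocity_scale * self.template.velocity_at(local)

    def events(self) -> list[tuple[str, float, float]]:
        return [
            (name, self.start + t * self.duration_scale, v * self.velocity_scale)
            for name, t, v in self.template.events
        ]


@dataclass(frozen=True)
class WaveformTrack:
    """1–18 concatenated, jittered cardiac cycles of one view."""

    view: str
    cycles: tuple[ScaledCycle, ...]
    total_duration: float

    def velocity_at(self, t_ms) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        v = np.zeros_like(t)
        for cyc in self.cycles:
            m = (t >= cyc.start) & (t < cyc.end)
            if m.any():
                v[m] = cyc.velocity_at(t[m])
        return v

    def events(self) -> list[tuple[str, float, float]]:
        out: list[tuple[str, float, float]] = []
        for cyc in self.cycles:
            out.extend(cyc.events())
        return out


def concatenate_cycles(
    template: CycleTemplate,
    n_cycles: int,
    jitter_frac: float = 0.1,
    rng: np.random.Generator | None = None,
) -> WaveformTrack:
    """Concatenate ``n_cycles`` copies of ``template`` with ±``jitter_frac``
    random scaling of each cycle's duration and velocity magnitude."""
    if not (1 <= n_cycles <= MAX_CYCLES):
        raise ValueError(f"n_cycles must lie in [1, {MAX_CYCLES}], got {n_cycles}")
    if not (0.0 <= jitter_frac <= 0.1):
        raise ValueError(f"jitter_frac must lie in [0, 0.1], got {jitter_frac}")
    if jitter_frac > 0 and rng is None:
        raise ValueError("rng required when jitter_frac > 0")
    cycles = []
    t0 = 0.0
    for _ in range(n_cycles):
        if jitter_frac > 0:
            ds = 1.0 + rng.uniform(-jitter_frac, jitter_frac)
            vs = 1.0 + rng.uniform(-jitter_frac, jitter_frac)
        else:
            ds = vs = 1.0
        cyc = ScaledCycle(template, start=t0, duration_scale=ds, velocity_scale=vs)
        cycles.append(cyc)
        t0 = cyc.end
    return WaveformTrack(view=template.view, cycles=tuple(cycles), total_duration=t0)


# --------------------------------------------------------------------------
# spectrogram rendering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseParams:
    """Texture model of the rendered spectrogram.

    ``speckle`` is the half-width of the multiplicative uniform noise on the
    fill intensity; the background is |N(0, background_sigma)| clipped at
    ``background_floor``.  Fill intensity ramps from ``fill_hi`` at the zero
    line down to ``fill_lo`` at the envelope edge.  ``aliasing`` wraps
    out-of-range velocities to the opposite edge instead of raising.
    """

    speckle: float = 0.15
    background_sigma: float = 0.02
    background_floor: float = 0.08
    fill_hi: float = 0.95
    fill_lo: float = 0.55
    aliasing: bool = False


NOISELESS = NoiseParams(speckle=0.0, background_sigma=0.0)


def render_spectrogram(
    track: WaveformTrack,
    calibration: Calibration,
    noise_params: NoiseParams = NoiseParams(),
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] = (256, 512),
):
    """Rasterize a waveform track into a grayscale spectrogram.

    Returns ``(image, truth)`` where ``image`` is an ``(H, W)`` float array
    in [0, 1] and ``truth`` records per-column envelope velocity and row,
    events (ms/cm/s and pixel coordinates), the fill mask and the
    calibration.  Column ``c`` corresponds to time ``c * time_per_px``; the
    envelope row is ``zero_line_row - round(v / vel_per_px)``.
    """
    H, W = shape
    cal = calibration
    zrow = int(round(cal.zero_line_row))
    if not (0 <= zrow < H):
        raise ValueError("zero_line_row outside the raster")
    if track.total_duration > W * cal.time_per_px + 1e-9:
        raise ValueError(
            f"track duration {track.total_duration:.1f} ms exceeds raster span "
            f"{W * cal.time_per_px:.1f} ms"
        )
    if rng is None:
        rng = np.random.default_rng(0)

    t_cols = np.arange(W) * cal.time_per_px
    env_v = np.zeros(W)
    active = t_cols < track.total_duration
    env_v[active] = track.velocity_at(t_cols[active])

    offsets = np.round(env_v / cal.vel_per_px).astype(int)
    rows_raw = zrow - offsets
    wrapped = (rows_raw < 0) | (rows_raw >= H)
    if wrapped.any() and not noise_params.aliasing:
        c = int(np.argmax(wrapped))
        raise ValueError(
            f"envelope velocity {env_v[c]:.1f} cm/s at column {c} exceeds the "
            "velocity range and aliasing is disabled"
        )
    env_rows = np.mod(rows_raw, H)

    # background
    if noise_params.background_sigma > 0:
        img = np.abs(rng.normal(0.0, noise_params.background_sigma, size=(H, W)))
        img = np.minimum(img, noise_params.background_floor)
    else:
        img = np.zeros((H, W))

    fill = np.zeros((H, W), dtype=bool)
    for c in range(W):
        off = int(offsets[c])
        if off == 0:
            continue
        # rows between the zero line (exclusive) and the envelope row
        # (inclusive); aliasing folds out-of-range rows to the opposite edge
        n_fill = min(abs(off), H - 1)
        dist = np.arange(1, n_fill + 1)  # px from the zero line
        concept = zrow - np.sign(off) * dist
        span = np.mod(concept, H) if wrapped[c] else concept
        frac = dist / abs(off)
        inten = noise_params.fill_hi - (noise_params.fill_hi - noise_params.fill_lo) * frac
        if noise_params.speckle > 0:
            inten = inten * (1.0 + rng.uniform(-noise_params.speckle, noise_params.speckle, span.size))
        img[span, c] = np.clip(inten, 0.0, 1.0)
        fill[span, c] = True

    events = []
    for name, t, v in track.events():
        col = int(round(t / cal.time_per_px))
        col = min(max(col, 0), W - 1)
        # the event's raster column must lie ON the envelope trace: at lobe
        # boundaries the rounded column can fall one column off the lobe's
        # support, so snap to the neighbouring column on the event's own
        # lobe (same velocity sign) whose value best matches the event's
        if v != 0.0:
            c0, c1 = max(col - 2, 0), min(col + 3, W)
            win = env_v[c0:c1]
            on_lobe = np.sign(win) == np.sign(v)
            if on_lobe.any():
                cost = np.where(
                    on_lobe,
                    np.abs(win - v) + 0.01 * np.abs(np.arange(c0, c1) - col),
                    np.inf,
                )
                col = int(c0 + np.argmin(cost))
        events.append(
            dict(
                name=name,
                t_ms=float(t),
                v_cms=float(env_v[col]),
                col=col,
                row=int(env_rows[col]),
            )
        )

    truth = dict(
        view=track.view,
        calibration=cal.to_dict(),
        envelope_v=env_v.tolist(),
        envelope_row=env_rows.tolist(),
        events=events,
        fill_mask=fill,
        n_cycles=len(track.cycles),
        cycle_starts=[c.start for c in track.cycles],
        total_duration=track.total_duration,
    )
    return np.clip(img, 0.0, 1.0), truth


# --------------------------------------------------------------------------
# B-mode rendering
# --------------------------------------------------------------------------

# per-view texture statistics: (n_blobs, sigma_lo, sigma_hi, base, amp)
_VIEW_TEXTURE = {
    UA: (6, 10.0, 25.0, 0.18, 0.45),
    MCA: (10, 6.0, 16.0, 0.25, 0.40),
    AOI: (8, 12.0, 30.0, 0.22, 0.50),
    LVIO: (5, 18.0, 40.0, 0.15, 0.55),
    OTHER: (12, 4.0, 12.0, 0.30, 0.35),
}

CURSOR_COLOR = np.array([0.95, 0.85, 0.10])
BURNIN_COLOR = np.array([1.00, 0.60, 0.10])


def render_bmode_with_cursor(
    view: str,
    cursor_style: str = "dashed_line",
    rng: np.random.Generator | None = None,
    size: int = 256,
    burn_ins: bool = False,
):
    """Procedural grey B-mode texture with a coloured Doppler cursor overlay.

    Returns ``(rgb, truth)``: an ``(size, size, 3)`` float image and a truth
    dict with the boolean ``cursor_mask`` and any burned-in text boxes.  The
    texture is a view-specific mixture of Gaussian blobs — enough for
    view-consistent statistics, with no pretence of anatomy.
    """
    if cursor_style not in ("dashed_line", "bounding_box"):
        raise ValueError(f"cursor_style must be dashed_line or bounding_box, got {cursor_style!r}")
    if view not in ALL_VIEWS:
        raise ValueError(f"unknown view {view!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    n, s_lo, s_hi, base, amp = _VIEW_TEXTURE[view]
    yy, xx = np.mgrid[0:size, 0:size]
    g = np.full((size, size), base)
    for _ in range(n):
        cy, cx = rng.uniform(0, size, 2)
        sig = rng.uniform(s_lo, s_hi)
        a = rng.uniform(0.3, 1.0) * amp
        g += a * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2)))
    g += rng.normal(0.0, 0.02, size=(size, size))
    g = np.clip(g, 0.0, 1.0)
    rgb = np.repeat(g[:, :, None], 3, axis=2)

    cursor = np.zeros((size, size), dtype=bool)
    cx = int(rng.integers(size // 4, 3 * size // 4))
    cy = int(rng.integers(size // 4, 3 * size // 4))
    if cursor_style == "dashed_line":
        dash, gap, width = 7, 5, 2
        r = 0
        while r < size:
            r1 = min(r + dash, size)
            cursor[r:r1, cx : cx + width] = True
            r = r1 + gap
        # sample-gate ticks
        cursor[cy - 1 : cy + 2, max(cx - 5, 0) : cx] = True
        cursor[cy - 1 : cy + 2, cx + width : cx + width + 5] = True
    else:
        h = int(rng.integers(20, 40))
        w = int(rng.integers(20, 40))
        r0, c0 = max(cy - h // 2, 0), max(cx - w // 2, 0)
        r1, c1 = min(r0 + h, size - 1), min(c0 + w, size - 1)
        t = 2
        cursor[r0 : r0 + t, c0:c1] = True
        cursor[r1 - t : r1, c0:c1] = True
        cursor[r0:r1, c0 : c0 + t] = True
        cursor[r0:r1, c1 - t : c1] = True
    rgb[cursor] = CURSOR_COLOR

    burnin_boxes = []
    if burn_ins:
        for _ in range(int(rng.integers(1, 4))):
            bh, bw = int(rng.integers(6, 12)), int(rng.integers(20, 60))
            r0 = int(rng.integers(0, size - bh))
            c0 = int(rng.integers(0, size - bw))
            rgb[r0 : r0 + bh, c0 : c0 + bw] = BURNIN_COLOR
            cursor[r0 : r0 + bh, c0 : c0 + bw] = False
            burnin_boxes.append((r0, c0, bh, bw))

    truth = dict(cursor_mask=cursor, cursor_style=cursor_style, burnin_boxes=burnin_boxes)
    return rgb, truth


# --------------------------------------------------------------------------
# dataset generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetConfig:
    """Study-condition settings for a generated dataset."""

    views: tuple[str, ...] = VIEWS
    n_per_view: int = 5
    images_per_patient: int = 2
    n_cycles_range: tuple[int, int] = (2, 6)
    jitter_frac: float = 0.1
    shape_jitter: float = 0.08
    noise: NoiseParams = NoiseParams()
    burn_ins: bool = False
    doppler_shape: tuple[int, int] = (256, 512)
    bmode_size: int = 256
    shape_overrides: dict | None = None  # per-view shape_params overrides


@dataclass
class SyntheticStudy:
    """One synthetic screen capture with its ground truth."""

    study_id: str
    view: str
    patient_id: str
    bmode: np.ndarray  # (S, S, 3) float in [0, 1]
    doppler: np.ndarray  # (H, W) float in [0, 1]
    calibration: Calibration
    truth: dict
    seed: int


def _pick_calibration(track: WaveformTrack, shape: tuple[int, int]) -> Calibration:
    """Sweep-speed and velocity-scale choice: fit the track to the raster."""
    H, W = shape
    # keep a few empty columns on the right so events in the last cycle's
    # tail render with their full column band inside the raster
    time_per_px = track.total_duration / (W - 6)
    t = np.arange(W) * time_per_px
    v = track.velocity_at(np.minimum(t, track.total_duration - 1e-9))
    vmax_pos = max(float(v.max()), 0.0)
    vmax_neg = max(float(-v.min()), 0.0)
    if vmax_neg < 1e-9:  # one-sided above: put the zero line low
        zrow = int(round(0.8 * H))
    elif vmax_pos < 1e-9:
        zrow = int(round(0.2 * H))
    else:
        zrow = H // 2
    head = max(zrow, 1)
    foot = max(H - 1 - zrow, 1)
    vel_per_px = max(vmax_pos / (0.85 * head), vmax_neg / (0.85 * foot), 1e-3)
    return Calibration(time_per_px=time_per_px, vel_per_px=vel_per_px, zero_line_row=zrow)


def generate_study(
    view: str,
    seed: int,
    config: DatasetConfig = DatasetConfig(),
    n_cycles: int | None = None,
) -> SyntheticStudy:
    """Generate a single study deterministically from (view, seed, config)."""
    rng = np.random.default_rng(seed)
    overrides = (config.shape_overrides or {}).get(view, {})
    params = dict(overrides)
    params.setdefault("shape_jitter", config.shape_jitter)
    tpl = generate_cycle_template(view, params, rng)
    if n_cycles is None:
        lo, hi = config.n_cycles_range
        n_cycles = int(rng.integers(lo, hi + 1))
    track = concatenate_cycles(tpl, n_cycles, config.jitter_frac, rng)
    cal = _pick_calibration(track, config.doppler_shape)
    doppler, truth = render_spectrogram(track, cal, config.noise, rng, config.doppler_shape)
    style = "dashed_line" if rng.random() < 0.5 else "bounding_box"
    bmode, btruth = render_bmode_with_cursor(
        view, style, rng, config.bmode_size, config.burn_ins
    )
    truth = dict(truth)
    truth.update(btruth)
    return SyntheticStudy(
        study_id=f"{view}_{seed:08d}",
        view=view,
        patient_id="",
        bmode=bmode,
        doppler=doppler,
        calibration=cal,
        truth=truth,
        seed=seed,
    )


def generate_dataset(
    config: DatasetConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[SyntheticStudy], pd.DataFrame]:
    """Generate a labelled dataset of synthetic studies.

    Deterministic given ``(config, seed)``.  Studies carry synthetic patient
    identifiers (``images_per_patient`` consecutive studies of a view share
    one patient) so patient-level splits can be exercised.  When ``out_dir``
    is given, writes 8-bit PNG rasters, JSON truth sidecars and a CSV index
    ``(path, label, patient_id, ...)``.
    """
    total = config.n_per_view * len(config.views)
    if total == 0:
        raise ValueError("dataset must contain at least one study")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(total) % (2**31)]
    studies: list[SyntheticStudy] = []
    rows = []
    k = 0
    for view in config.views:
        for i in range(config.n_per_view):
            st = generate_study(view, child_seeds[k], config)
            pid = f"P{view}{i // config.images_per_patient:03d}"
            st.patient_id = pid
            st.study_id = f"{view}_{i:04d}"
            studies.append(st)
            rows.append(dict(study_id=st.study_id, label=view, patient_id=pid))
            k += 1
    index = pd.DataFrame(rows)
    if out_dir is not None:
        index = write_dataset(studies, index, out_dir)
    return studies, index


# --------------------------------------------------------------------------
# PNG + JSON + CSV persistence
# --------------------------------------------------------------------------


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)


def write_dataset(studies, index: pd.DataFrame, out_dir) -> pd.DataFrame:
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"path": [], "bmode_path": [], "truth_path": []}
    for st in studies:
        dpath = out / f"doppler_{st.study_id}.png"
        bpath = out / f"bmode_{st.study_id}.png"
        tpath = out / f"truth_{st.study_id}.json"
        iio.imwrite(dpath, _to_uint8(st.doppler))
        iio.imwrite(bpath, _to_uint8(st.bmode))
        tr = {k: v for k, v in st.truth.items() if k not in ("fill_mask", "cursor_mask")}
        tr["seed"] = st.seed
        tpath.write_text(json.dumps(tr))
        paths["path"].append(str(dpath))
        paths["bmode_path"].append(str(bpath))
        paths["truth_path"].append(str(tpath))
    index = index.assign(**paths)
    index.to_csv(out / "index.csv", index=False)
    return index


def load_study(doppler_path, bmode_path=None, truth_path=None) -> SyntheticStudy:
    """Read a study back from PNG + JSON files."""
    import imageio.v3 as iio

    doppler = iio.imread(doppler_path).astype(float) / 255.0
    bmode = None
    truth = {}
    cal = None
    view = "?"
    if truth_path is not None:
        truth = json.loads(Path(truth_path).read_text())
        cal = Calibration.from_dict(truth["calibration"])
        view = truth.get("view", "?")
    if bmode_path is not None:
        b = iio.imread(bmode_path).astype(float) / 255.0
        bmode = b if b.ndim == 3 else np.repeat(b[:, :, None], 3, axis=2)
    return SyntheticStudy(
        study_id=Path(doppler_path).stem,
        view=view,
        patient_id=str(truth.get("patient_id", "")),
        bmode=bmode,
        doppler=doppler,
        calibration=cal,
        truth=truth,
        seed=int(truth.get("seed", 0)),
    )
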