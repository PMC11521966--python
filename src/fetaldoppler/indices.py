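"""Deterministic post-processing of delineation masks into Doppler indices.

From the predicted (M+1)-channel mask this module recovers a single-valued
velocity-vs-time envelope, timed and valued physiological events, cardiac
cycles delimited by consecutive onset-S events, and the clinical indices:

* pulsatility index ``PI = (V_max - V_min) / V_mean`` over a cycle, with
  ``V_mean`` the time-average of the envelope magnitude;
* peak velocities and event times;
* LVIO systolic/diastolic durations: ``S = t(end S) - t(onset S)`` (valve
  opening to closure) and ``D = t(end A) - t(onset E)``.

Event channels are cleaned by closing along the time axis, reduced to
connected-component centroids, and forced to a minimum mutual distance of
80 ms (larger components win; earlier wins area ties) to suppress double
detections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import Calibration
from .synthetic import EVENT_VOCAB

MIN_EVENT_SEPARATION_MS = 80.0

#: structuring-element width (columns) for filling gaps along time
GAP_FILL_WIDTH = 9


# --------------------------------------------------------------------------
# data types
# --------------------------------------------------------------------------


@dataclass
class EnvelopeCurve:
    """Single-valued signed velocity (cm/s) per time column.

    Columns with no mask support hold NaN; ``support`` marks valid columns.
    """

    velocity: np.ndarray  # (W,) float, NaN where unsupported
    calibration: Calibration

    @property
    def support(self) -> np.ndarray:
        return ~np.isnan(self.velocity)

    def value_at_col(self, col: int) -> float:
        return float(self.velocity[col])


@dataclass(frozen=True)
class PhysioEvent:
    name: str
    t_ms: float
    v_cms: float


@dataclass
class CardiacCycle:
    start_t: float
    end_t: float
    events: list[PhysioEvent] = field(default_factory=list)

    @property
    def length_ms(self) -> float:
        return self.end_t - self.start_t

    def event(self, name: str) -> PhysioEvent | None:
        for e in self.events:
            if e.name == name:
                return e
        return None


@dataclass
class DopplerIndexReport:
    """Per-cycle index values and their per-image medians."""

    view: str
    per_cycle: list[dict]
    medians: dict
    warnings: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# mask cleanup
# --------------------------------------------------------------------------


def smooth_envelope_mask(mask: np.ndarray) -> np.ndarray:
    """Smooth a binary envelope mask: 7x7 Gaussian blur, re-binarize,
    then binary dilation and closing with a 3x3 structuring element.

    Removes isolated specks (blurred below the 0.5 threshold) and fills
    small holes while moving solid boundaries by at most ~1 pixel.
    """
    m = np.asarray(mask, dtype=float)
    # sigma = (k - 1) / 6 so the 7-tap kernel covers ±3 sigma
    blurred = ndimage.gaussian_filter(m, sigma=1.0, truncate=3.0)
    binar = blurred > 0.5
    st = np.ones((3, 3), dtype=bool)
    padded = np.pad(ndimage.binary_dilation(binar, structure=st), 3)
    out = ndimage.binary_closing(padded, structure=st)[3:-3, 3:-3]
    return out


def select_dominant_side(
    mask: np.ndarray, calibration: Calibration, mode: str = "single"
):
    """Keep the side of the zero line holding the maximum |velocity|.

    ``mode='single'`` returns one mask with the opposite side zeroed;
    ``mode='lvio'`` returns ``(dominant, opposite)`` so outflow and inflow
    lobes are processed separately.
    """
    if mode not in ("single", "lvio"):
        raise ValueError(f"mode must be 'single' or 'lvio', got {mode!r}")
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask: nothing above or below the zero line")
    z = calibration.zero_line_row
    rows = np.where(m.any(axis=1))[0]
    ext_above = float(z - rows.min()) if (rows < z).any() else 0.0
    ext_below = float(rows.max() - z) if (rows > z).any() else 0.0
    above = m.copy()
    above[int(np.ceil(z)) :, :] = False
    below = m.copy()
    below[: int(np.floor(z)) + 1, :] = False
    # ties go to the side above the line
    dominant, opposite = (above, below) if ext_above >= ext_below else (below, above)
    if mode == "single":
        return dominant
    return dominant, opposite


def extract_envelope_curve(
    mask: np.ndarray,
    calibration: Calibration,
    refine_mask: np.ndarray | None = None,
    refine_window: int = 2,
) -> EnvelopeCurve:
    """Per column, the velocity of the filled pixel farthest from the zero
    line (one-sided mask).

    Morphological smoothing can move the mask boundary by about a pixel; if
    the raw (pre-smoothing) channel is passed as ``refine_mask``, the
    extreme row of each column is refined to the raw boundary within
    ``±refine_window`` rows, removing that bias while staying robust to
    distant specks.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask: no envelope to extract")
    H, W = m.shape
    z = calibration.zero_line_row
    vel = np.full(W, np.nan)
    rr = np.arange(H)
    ref = np.asarray(refine_mask, dtype=bool) if refine_mask is not None else None
    for c in np.where(m.any(axis=0))[0]:
        rows = rr[m[:, c]]
        extreme = int(rows[np.argmax(np.abs(rows - z))])
        if ref is not None:
            # raw pixels inside the cleaned column's row span (pm window):
            # excludes distant specks but undoes smoothing-boundary shifts
            lo = max(int(rows.min()) - refine_window, 0)
            hi = min(int(rows.max()) + refine_window + 1, H)
            cand = rr[lo:hi][ref[lo:hi, c]]
            if cand.size:
                extreme = int(cand[np.argmax(np.abs(cand - z))])
        vel[c] = calibration.row_to_velocity(extreme)
    return EnvelopeCurve(velocity=vel, calibration=calibration)


def merge_envelope_curves(a: EnvelopeCurve, b: EnvelopeCurve) -> EnvelopeCurve:
    """Combine two one-sided curves (LVIO outflow + inflow) into one signed
    curve; where both support a column the larger magnitude wins."""
    va, vb = a.velocity, b.velocity
    out = np.where(np.isnan(va), vb, va)
    both = ~np.isnan(va) & ~np.isnan(vb)
    out[both] = np.where(np.abs(va[both]) >= np.abs(vb[both]), va[both], vb[both])
    return EnvelopeCurve(velocity=out, calibration=a.calibration)


# --------------------------------------------------------------------------
# events
# --------------------------------------------------------------------------


def extract_event_times(
    event_channel: np.ndarray,
    calibration: Calibration,
    min_sep_ms: float = MIN_EVENT_SEPARATION_MS,
) -> list[float]:
    """Event time-coordinates (ms) from one binary event channel.

    Gaps along time are closed, connected components reduced to their
    area-weighted time centroids, and candidates closer than ``min_sep_ms``
    resolved by keeping the larger-area component (the earlier one on area
    ties); a gap of exactly ``min_sep_ms`` is allowed.  An empty channel
    yields an empty list.
    """
    ch = np.asarray(event_channel, dtype=bool)
    if not ch.any():
        return []
    st = np.ones((1, GAP_FILL_WIDTH), dtype=bool)
    # zero-pad so the closing sees a plain zero background beyond the raster
    # (scipy's border handling would otherwise distort bands near the edges)
    w = GAP_FILL_WIDTH
    padded = np.pad(ch, ((0, 0), (w, w)))
    closed = ndimage.binary_closing(padded, structure=st)[:, w:-w]
    labels, n = ndimage.label(closed)
    cands = []  # (t_ms, area)
    for lab in range(1, n + 1):
        comp = labels == lab
        cols = np.where(comp)[1]
        t = float(cols.mean() * calibration.time_per_px)
        cands.append((t, int(comp.sum())))
    return enforce_min_separation(cands, min_sep_ms)


def enforce_min_separation(candidates, min_sep_ms: float = MIN_EVENT_SEPARATION_MS):
    """Greedy minimum-distance rule on ``(t_ms, area)`` candidates.

    Candidates are admitted in order of decreasing area (earlier time first
    on ties); a candidate closer than ``min_sep_ms`` to any admitted one is
    dropped.  Returns admitted times sorted ascending.
    """
    order = sorted(candidates, key=lambda ta: (-ta[1], ta[0]))
    kept: list[float] = []
    for t, _ in order:
        if all(abs(t - k) >= min_sep_ms for k in kept):
            kept.append(t)
    return sorted(kept)


def attach_magnitudes(
    times_ms, curve: EnvelopeCurve, name: str = "", col_tolerance: int = 3
) -> list[PhysioEvent]:
    """Velocity magnitude of each event: the envelope value at its column.

    An event in an unsupported gap snaps to the nearest supported column
    within ``col_tolerance``; farther events are dropped with a warning.
    """
    support_cols = np.where(curve.support)[0]
    events = []
    W = curve.velocity.size
    for t in times_ms:
        col = int(round(curve.calibration.time_to_col(t)))
        col = min(max(col, 0), W - 1)
        if not curve.support[col]:
            if support_cols.size == 0:
                warnings.warn(f"event {name!r} at {t:.0f} ms: envelope has no support; dropped")
                continue
            nearest = support_cols[np.argmin(np.abs(support_cols - col))]
            if abs(int(nearest) - col) > col_tolerance:
                warnings.warn(
                    f"event {name!r} at {t:.0f} ms is {abs(int(nearest) - col)} columns "
                    "from envelope support; dropped"
                )
                continue
            col = int(nearest)
        events.append(PhysioEvent(name=name, t_ms=float(t), v_cms=float(curve.velocity[col])))
    return events


def segment_cycles(events: list[PhysioEvent]) -> list[CardiacCycle]:
    """Cardiac cycles delimited by consecutive onset-S events; other events
    fall into the cycle containing their time."""
    onsets = sorted(e.t_ms for e in events if e.name == "onset S")
    if len(onsets) < 2:
        raise ValueError(f"insufficient cycles: need >=2 'onset S' events, got {len(onsets)}")
    cycles = [CardiacCycle(start_t=a, end_t=b) for a, b in zip(onsets[:-1], onsets[1:])]
    for e in events:
        for cyc in cycles:
            if cyc.start_t <= e.t_ms < cyc.end_t or (
                e.name == "onset S" and e.t_ms == cyc.start_t
            ):
                cyc.events.append(e)
                break
    for cyc in cycles:
        cyc.events.sort(key=lambda e: e.t_ms)
    return cycles


# --------------------------------------------------------------------------
# indices
# --------------------------------------------------------------------------


def compute_pi(curve: EnvelopeCurve, cycle: CardiacCycle) -> dict:
    """Pulsatility index over one cycle, on envelope magnitudes.

    ``v_max``/``v_min`` are the extreme |velocities| among supported columns
    in ``[start_t, end_t)``; ``v_mean`` their time-average.  Raises when the
    mean velocity vanishes (PI undefined).
    """
    cal = curve.calibration
    c0 = int(np.ceil(cal.time_to_col(cycle.start_t) - 1e-9))
    c1 = int(np.ceil(cal.time_to_col(cycle.end_t) - 1e-9))
    seg = curve.velocity[c0:c1]
    seg = seg[~np.isnan(seg)]
    if seg.size == 0:
        raise ValueError("envelope has no support over the cycle")
    mag = np.abs(seg)
    v_max, v_min, v_mean = float(mag.max()), float(mag.min()), float(mag.mean())
    if v_mean <= 0:
        raise ValueError("undefined PI: mean velocity over the cycle is zero")
    return dict(v_max=v_max, v_min=v_min, v_mean=v_mean, pi=(v_max - v_min) / v_mean)


def compute_lvio_durations(cycle: CardiacCycle) -> dict:
    """Systolic and diastolic durations (ms) from an LVIO cycle.

    S duration: onset S (valve opening) to end S (closure); D duration:
    onset E to end A.  A missing constituent event omits that metric with a
    warning.
    """
    out: dict = {}
    on_s, end_s = cycle.event("onset S"), cycle.event("end S")
    if on_s is not None and end_s is not None:
        out["s_duration"] = abs(end_s.t_ms - on_s.t_ms)
    else:
        warnings.warn("missing onset S / end S event: S duration omitted")
    on_e, end_a = cycle.event("onset E"), cycle.event("end A")
    if on_e is not None and end_a is not None:
        out["d_duration"] = abs(end_a.t_ms - on_e.t_ms)
    else:
        warnings.warn("missing onset E / end A event: D duration omitted")
    return out


# --------------------------------------------------------------------------
# full mask -> report
# --------------------------------------------------------------------------


def postprocess_masks(mask, calibration: Calibration) -> tuple[EnvelopeCurve, list[PhysioEvent]]:
    """Full post-processing chain of a :class:`DelineationMask`:
    smoothing, dominant-side selection (twice for LVIO), envelope
    extraction, event centroiding with the 80 ms rule, and magnitude
    attachment."""
    view = mask.view
    raw = np.asarray(mask.envelope, dtype=bool)
    cleaned = smooth_envelope_mask(raw)
    if not cleaned.any():
        raise ValueError("empty envelope mask after smoothing")
    if view == "LVIO":
        dom, opp = select_dominant_side(cleaned, calibration, mode="lvio")
        curve_out = extract_envelope_curve(dom, calibration, refine_mask=raw)
        if opp.any():
            curve_in = extract_envelope_curve(opp, calibration, refine_mask=raw)
            curve = merge_envelope_curves(curve_out, curve_in)
        else:
            curve = curve_out
    else:
        dom = select_dominant_side(cleaned, calibration, mode="single")
        curve = extract_envelope_curve(dom, calibration, refine_mask=raw)
    events: list[PhysioEvent] = []
    for name in EVENT_VOCAB[view]:
        times = extract_event_times(mask.event_channel(name), calibration)
        events.extend(attach_magnitudes(times, curve, name=name))
    events.sort(key=lambda e: e.t_ms)
    return curve, events


def compute_report(curve: EnvelopeCurve, events: list[PhysioEvent], view: str) -> DopplerIndexReport:
    """Per-cycle indices and per-image medians for one study."""
    cycles = segment_cycles(events)
    per_cycle = []
    warns: list[str] = []
    for cyc in cycles:
        row: dict = dict(
            start_t=cyc.start_t,
            cycle_length=cyc.length_ms,
            onset_s_t=cyc.start_t,
        )
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            try:
                row.update(compute_pi(curve, cyc))
            except ValueError as exc:
                warns.append(str(exc))
            pk = cyc.event("S peak")
            if pk is not None:
                row["s_peak_t"] = pk.t_ms
                row["s_peak_v"] = abs(pk.v_cms)
            if view == "LVIO":
                row.update(compute_lvio_durations(cyc))
                for name, key in (("E peak", "e_peak_v"), ("A peak", "a_peak_v")):
                    e = cyc.event(name)
                    if e is not None:
                        row[key] = abs(e.v_cms)
            warns.extend(str(w.message) for w in wlist)
        per_cycle.append(row)
    keys = sorted({k for row in per_cycle for k in row})
    medians = {
        k: float(np.median([row[k] for row in per_cycle if k in row]))
        for k in keys
        if any(k in row for row in per_cycle)
    }
    return DopplerIndexReport(view=view, per_cycle=per_cycle, medians=medians, warnings=warns)


# --------------------------------------------------------------------------
# evaluation protocol
# --------------------------------------------------------------------------


def evaluate_indices(pred_reports, truth_reports, keys=None):
    """Per-index MAPE and RMSE between paired per-image reports.

    Each index is first reduced to its per-image median across cycles —
    separately for prediction and truth — then errors are aggregated over
    images: MAPE as mean ± SD of ``100 * |pred - truth| / |truth|``
    (zero-truth images excluded, with the count reported) and RMSE as
    mean ± SD of the per-image absolute errors.
    """
    if len(pred_reports) == 0 or len(pred_reports) != len(truth_reports):
        raise ValueError("need equal, non-zero numbers of paired reports")
    if keys is None:
        keys = sorted(
            {k for r in truth_reports for k in r.medians}
            & {k for r in pred_reports for k in r.medians}
        )
    table = {}
    for key in keys:
        ape, abserr, n_zero = [], [], 0
        for p, t in zip(pred_reports, truth_reports):
            if key not in p.medians or key not in t.medians:
                continue
            pv, tv = p.medians[key], t.medians[key]
            abserr.append(abs(pv - tv))
            if abs(tv) < 1e-12:
                n_zero += 1
            else:
                ape.append(100.0 * abs(pv - tv) / abs(tv))
        if not abserr:
            continue
        table[key] = dict(
            mape_mean=float(np.mean(ape)) if ape else np.nan,
            mape_sd=float(np.std(ape)) if ape else np.nan,
            rmse_mean=float(np.mean(abserr)),
            rmse_sd=float(np.std(abserr)),
            n=len(abserr),
            n_zero_truth_excluded=n_zero,
        )
    if not table:
        raise ValueError("no overlapping index keys between predictions and truth")
    return table
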