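"""Photobleach-chase analysis: classify sheath sections as bright / bleached
/ dim, track their distances from the polymerization origin, normalize
intensities to the cytosolic background, and call the assembly mechanism.

The logic of the assay: a growing sheath is partially photobleached with a
laser line. Material polymerized before the bleach and missed by the laser
stays *bright*; material hit by the laser is *bleached* to the cytosolic
background level; material added afterwards is *dim*, because it is drawn
from the partially bleached soluble pool. The three candidate mechanisms
make distinct predictions for the bleached mark:

* distal addition   — mark fixed in position, intensity and width;
* proximal insertion — mark fixed in intensity/width but moving away from
  the origin at the polymerization speed;
* intercalation     — mark spreading and gaining intensity as dim subunits
  mix in, in proportion to total length growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .dynamics import FrontTrace, estimate_speed, trace_front
from .kymograph import (BackgroundStats, Kymogram, _runs_above,
                        effective_noise_sd, locate_origin)


@dataclass(frozen=True)
class ChaseThresholds:
    """All decision constants of the chase pipeline, in one place.

    The classification rules are quantitative stand-ins for the assay's
    qualitative criteria: a span is *bleached* when at most ``bleached_k``
    background sds above background, *bright* when at least ``bright_floor``
    of the pre-bleach on-polymer level, *dim* in between. The mechanism call
    uses a drift tolerance expressed as a fraction of the measured
    polymerization speed and a relative width-change tolerance.
    """

    k_front: float = 3.0
    bleached_k: float = 2.0
    bright_floor: float = 0.7
    min_span_bins: int = 2
    drift_tol_fraction: float = 0.2
    width_tol: float = 0.3
    intensity_rise_min_pct: float = 5.0
    intensity_recovery_pct: float = 20.0
    bleached_floor_frac: float = 0.15
    classify_window_s: float = 8.0
    edge_trim_bins: int = 3
    profile_halfwidth_frames: int = 2


@dataclass
class TimepointSet:
    """The assay's four measurement times: pre-bleach, first post-bleach
    frame, 20 s before the end of assembly, and the end of assembly."""

    t1_s: float
    t2_s: float
    t3_s: float | None
    t4_s: float
    t3_skipped: bool = False

    @classmethod
    def from_bleach_and_end(cls, t_bleach_s: float, t_end_s: float,
                            frame_interval_s: float,
                            pre_end_offset_s: float = 20.0) -> "TimepointSet":
        t1 = t_bleach_s
        t2 = t_bleach_s + frame_interval_s
        t3: float | None = t_end_s - pre_end_offset_s
        t4 = t_end_s
        skipped = False
        if t3 is not None and t3 <= t2:
            warnings.warn("post-bleach assembly shorter than the pre-end "
                          "offset; skipping t3")
            t3, skipped = None, True
        if not (t1 < t2 <= (t3 if t3 is not None else t4) < t4 or
                (t3 is None and t1 < t2 < t4)):
            raise ValueError("timepoints must satisfy t1 < t2 <= t3 < t4")
        return cls(t1, t2, t3, t4, skipped)

    def post_bleach(self) -> list[tuple[str, float]]:
        out = [("t2", self.t2_s)]
        if self.t3_s is not None:
            out.append(("t3", self.t3_s))
        out.append(("t4", self.t4_s))
        return out

    def all(self) -> list[tuple[str, float]]:
        return [("t1", self.t1_s)] + self.post_bleach()


@dataclass
class SectionLabel:
    klass: str  # bright | bleached | dim
    span_nm: tuple[float, float]
    centroid_nm: dict[str, float] = field(default_factory=dict)
    width_nm: dict[str, float] = field(default_factory=dict)
    mean_intensity_pct: dict[str, float] = field(default_factory=dict)


@dataclass
class MechanismCall:
    label: str  # distal | proximal | intercalation | ambiguous
    bleached_drift_nm_per_s: float
    bleached_width_change_fraction: float
    bleached_intensity_change_pct: float
    thresholds: ChaseThresholds


@dataclass
class Eligibility:
    eligible: bool
    reasons: list[str]
    front_trace: FrontTrace | None = None


# ---------------------------------------------------------------------------
# profile helpers


def _profile_at(kym: Kymogram, t_s: float, halfwidth: int,
                t_min_s: float | None = None,
                t_max_s: float | None = None) -> np.ndarray:
    """Time-averaged intensity profile around ``t_s``; the window never
    crosses ``t_min_s``/``t_max_s`` (e.g. the bleach boundary)."""
    i = kym.frame_index(t_s)
    lo = max(i - halfwidth, 0)
    hi = min(i + halfwidth + 1, kym.n_frames)
    if t_min_s is not None:
        lo = max(lo, kym.frame_index(t_min_s))
    if t_max_s is not None:
        hi = min(hi, kym.frame_index(t_max_s) + 1)
    hi = max(hi, lo + 1)
    return kym.values[:, lo:hi].mean(axis=1)


def _bleached_threshold(bg_t: float, noise_sd: float,
                        amplitude: float, th: ChaseThresholds) -> float:
    """A span counts as bleached below this level: the noise-based rule
    (k sds above background) with an amplitude-fraction floor that keeps
    the classification meaningful at vanishing noise, where PSF spill from
    the flanking sections lifts the bleached span slightly above the exact
    background."""
    return bg_t + max(th.bleached_k * noise_sd,
                      th.bleached_floor_frac * amplitude)


def _front_at(trace: FrontTrace, t_s: float) -> float:
    ok = trace.valid
    if not ok.any():
        raise ValueError("empty front trace")
    idx = np.argmin(np.abs(trace.times_s[ok] - t_s))
    return float(trace.front_nm[ok][idx])


def normalize_intensity(raw, cytosolic_background: float,
                        pre_bleach_polymer_level: float,
                        reference_background: float | None = None):
    """Map raw counts to the assay's percent scale: the cytosolic
    background is 0% and the mean pre-bleach on-polymer level is 100%.
    Exactly invariant under affine rescaling of camera counts.

    ``cytosolic_background`` is the background at the measured timepoint
    (the soluble-pool bleach dims the cytosol mid-movie);
    ``reference_background`` is the background contemporaneous with the
    pre-bleach reference level (defaults to ``cytosolic_background``).
    """
    ref_bg = (cytosolic_background if reference_background is None
              else reference_background)
    if pre_bleach_polymer_level <= ref_bg:
        raise ValueError("reference level must exceed the background")
    return 100.0 * (np.asarray(raw, dtype=float) - cytosolic_background) / (
        pre_bleach_polymer_level - ref_bg)


def measure_pre_bleach_level(kym: Kymogram, t_bleach_s: float,
                             background: BackgroundStats,
                             k: float = 3.0) -> float:
    """Reference on-polymer intensity over the pre-bleach frames.

    Uses the 90th percentile of above-threshold run-interior values: a short
    early sheath loses peak intensity to PSF spill at its two edges, so a
    plain mean would understate the plateau level that wide sections reach
    later in the movie.
    """
    kym = kym.oriented()
    sd = effective_noise_sd(kym, background)
    n_pre = kym.frame_index(t_bleach_s) + 1
    vals: list[np.ndarray] = []
    for t in range(n_pre):
        col = kym.values[:, t]
        thr = background.level(t) + k * sd
        runs = [r for r in _runs_above(col, thr) if r[1] - r[0] >= 2]
        if not runs:
            continue
        lo, hi = min(runs, key=lambda r: r[0])
        if hi - lo >= 6:
            lo, hi = lo + 2, hi - 2
        vals.append(col[lo:hi])
    if not vals:
        raise ValueError("no pre-bleach polymer signal found")
    return float(np.percentile(np.concatenate(vals), 90))


# ---------------------------------------------------------------------------
# eligibility


def eligible_for_chase(kym: Kymogram, t_bleach_s: float,
                       background: BackgroundStats,
                       thresholds: ChaseThresholds = ChaseThresholds(),
                       ) -> Eligibility:
    """Check the three inclusion criteria for a photobleach-chase event:
    polymerizing before the bleach, only partially bleached, and still
    polymerizing along the same line afterwards."""
    th = thresholds
    reasons: list[str] = []
    if kym.origin_bin is None:
        try:
            locate_origin(kym, background, th.k_front)
        except ValueError:
            return Eligibility(False, ["no signal above background"])
    kym = kym.oriented()
    try:
        trace = trace_front(kym, background, k=th.k_front)
    except ValueError:
        return Eligibility(False, ["no trackable front"])
    sp = kym.spacing_nm
    i_b = kym.frame_index(t_bleach_s)
    pre = trace.front_nm[:i_b + 1][trace.valid[:i_b + 1]]
    if len(pre) < 2 or pre[-1] - pre[0] < 2 * sp:
        reasons.append("not polymerizing before the bleach")
    post = trace.front_nm[i_b + 1:][trace.valid[i_b + 1:]]
    if len(post) < 2 or post[-1] - post[0] < 2 * sp:
        reasons.append("not polymerizing after the bleach")
    # partial bleach, two observable signatures:
    #  (a) a below-background span inside the sheath extent (mark interior
    #      to the polymer), or
    #  (b) a regression of the measured front at the bleach instant (mark
    #      clipping the tip: polymerization alone can never shrink)
    t2 = t_bleach_s + kym.frame_interval_s
    prof = _profile_at(kym, t2, th.profile_halfwidth_frames, t_min_s=t2)
    bg2 = background.level(kym.frame_index(t2))
    try:
        pre_level = measure_pre_bleach_level(kym, t_bleach_s, background,
                                             th.k_front)
        amp = pre_level - background.level(kym.frame_index(t_bleach_s))
    except ValueError:
        amp = 0.0
    # polymer extent: fronts measured before the bleach count too (the mark
    # may have erased the tip-side signal)
    k_hi = min(i_b + 4, len(trace.front_nm))
    upto = trace.front_nm[:k_hi][trace.valid[:k_hi]]
    extent = int(min((np.nanmax(upto) if len(upto) else 0.0) / sp,
                     kym.n_bins - 1))
    seg = prof[:extent + 1]
    sd_prof = effective_noise_sd(kym, background,
                                 2 * th.profile_halfwidth_frames + 1)
    dark_thr = _bleached_threshold(bg2, sd_prof, amp, th)
    dark = seg <= dark_thr
    dark_runs = _runs_above(dark.astype(float), 0.5)
    dark_runs = [r for r in dark_runs
                 if r[1] - r[0] >= th.min_span_bins and 0 < r[0]]
    front_drop = (len(pre) > 0 and len(post) > 0
                  and pre[-1] - post[0] >= 3 * sp)
    # partial: unbleached polymer clearly survives somewhere on the line
    lit_thr = dark_thr + 0.25 * max(amp, 0.0)
    lit_runs = [r for r in _runs_above(seg, lit_thr)
                if r[1] - r[0] >= th.min_span_bins]
    if not dark_runs and not front_drop:
        reasons.append("no bleached span")
    elif not lit_runs:
        reasons.append("not partially bleached")
    return Eligibility(len(reasons) == 0, reasons, trace)


# ---------------------------------------------------------------------------
# classification


def classify_sections(kym: Kymogram, t_bleach_s: float, t_end_s: float,
                      background: BackgroundStats,
                      pre_bleach_polymer_level: float,
                      thresholds: ChaseThresholds = ChaseThresholds(),
                      ) -> list[SectionLabel]:
    """Per-distance-bin classification of the early post-bleach kymogram
    into bright / bleached / dim spans.

    For each bin the intensity is averaged over the frames of a short
    post-bleach window in which the front has already passed that bin, then
    thresholded. Adjacent same-class bins are merged; one-sided blur
    artifacts at class boundaries are reassigned; spans shorter than
    ``min_span_bins`` are discarded.
    """
    th = thresholds
    kym = kym.oriented()
    trace = trace_front(kym, background, k=th.k_front)
    sp = kym.spacing_nm
    i2 = kym.frame_index(t_bleach_s + kym.frame_interval_s)
    i_hi = min(kym.frame_index(t_bleach_s + th.classify_window_s),
               kym.frame_index(t_end_s))
    cols = [i for i in range(i2, i_hi + 1) if trace.valid[i]]
    if not cols:
        raise ValueError("no valid post-bleach frames in the "
                         "classification window")
    # polymer extent from the running max of the front (incl. pre-bleach
    # frames: a mark clipping the tip hides the tip-side signal)
    upto = trace.front_nm[:i_hi + 1][trace.valid[:i_hi + 1]]
    extent_bins = int(np.nanmax(upto) / sp) if len(upto) else 1
    extent_bins = max(extent_bins - th.edge_trim_bins, 1)
    mean_int = np.full(extent_bins + 1, np.nan)
    for d in range(extent_bins + 1):
        use = [c for c in cols if trace.front_nm[c] >= d * sp]
        if use:
            mean_int[d] = kym.values[d, use].mean()
    ok = ~np.isnan(mean_int)
    bg_win = float(np.mean([background.level(c) for c in cols]))
    bg_pre = background.level(kym.frame_index(t_bleach_s))
    amp = pre_bleach_polymer_level - bg_pre
    sd_bin = effective_noise_sd(kym, background, max(len(cols) // 2, 1))
    bleach_thr = _bleached_threshold(bg_win, sd_bin, amp, th)
    bright_thr = bg_win + th.bright_floor * amp
    klass = np.full(extent_bins + 1, "", dtype=object)
    klass[ok & (mean_int <= bleach_thr)] = "bleached"
    klass[ok & (mean_int >= bright_thr)] = "bright"
    klass[ok & (mean_int > bleach_thr) & (mean_int < bright_thr)] = "dim"
    if not (klass == "bleached").any():
        # absolute threshold can miss a shallow mark (e.g. early subunit
        # mixing under intercalation): fall back to the half-depth valley
        filled = np.where(ok, mean_int, bg_win)
        dr = _dark_run(filled, extent_bins)
        if dr is not None:
            lo_b = int(np.ceil(dr[0]))
            hi_b = int(np.floor(dr[1])) + 1
            sel = np.zeros_like(ok)
            sel[lo_b:hi_b] = True
            klass[sel & ok & (mean_int < bright_thr)] = "bleached"
    runs = _class_runs(klass)
    runs = _fix_boundary_artifacts(runs)
    runs = [(c, lo, hi) for c, lo, hi in runs if hi - lo >= th.min_span_bins]
    runs = _merge_adjacent(runs)
    if not any(c == "bleached" for c, _, _ in runs):
        raise ValueError("no bleached span found (event should have been "
                         "rejected by the eligibility check)")
    return [SectionLabel(c, (lo * sp, (hi - 1) * sp)) for c, lo, hi in runs]


def _class_runs(klass: np.ndarray) -> list[tuple[str, int, int]]:
    runs: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(klass) + 1):
        if i == len(klass) or klass[i] != klass[start]:
            if klass[start]:
                runs.append((str(klass[start]), start, i))
            start = i
    return runs


def _merge_adjacent(runs):
    out = []
    for r in runs:
        if out and out[-1][0] == r[0] and out[-1][2] >= r[1]:
            out[-1] = (r[0], out[-1][1], r[2])
        else:
            out.append(list(r))
    return [tuple(r) for r in out]


def _fix_boundary_artifacts(runs):
    """PSF blur creates short 'dim' transition runs wherever bright and
    bleached spans meet, and at the origin edge. Split such runs between
    their neighbours (or absorb an origin-edge run into its neighbour)."""
    out = [list(r) for r in runs]
    changed = True
    while changed:
        changed = False
        for i, (c, lo, hi) in enumerate(list(out)):
            if c != "dim":
                continue
            left = out[i - 1][0] if i > 0 else None
            right = out[i + 1][0] if i + 1 < len(out) else None
            if {left, right} == {"bright", "bleached"}:
                mid = (lo + hi) // 2
                out[i - 1][2] = mid
                out[i + 1][1] = mid
                del out[i]
                changed = True
                break
            if lo == 0 and hi - lo <= 3 and right in ("bright", "bleached"):
                out[i + 1][1] = lo
                del out[i]
                changed = True
                break
    return [tuple(r) for r in out]


# ---------------------------------------------------------------------------
# tracking


def _dark_run(prof: np.ndarray, extent_bins: int,
              pred_bins: tuple[float, float] | None = None
              ) -> tuple[float, float] | None:
    """Half-depth edges of the darkest valley within [0, extent_bins].

    Self-calibrating: each edge is where the profile recovers halfway from
    the valley minimum to the shoulder maximum on that side. This keeps the
    bleached span trackable even when intercalating dim subunits lift it
    above the absolute background threshold. Valleys with a shoulder on
    both sides take priority; a valley running into the extent boundary (a
    mark riding just behind the polymerizing front, folded into the front
    decay by PSF blur) is accepted as tip-merged with its span closed at
    the extent. ``pred_bins`` is an optional predicted centroid interval
    (from the previous timepoint and the polymerization speed) used to pick
    between otherwise comparable valleys.
    """
    n = min(extent_bins + 1, len(prof))
    if n < 5:
        return None
    seg = uniform_filter1d(prof[:n], size=3, mode="nearest")
    rng_amp = float(seg.max() - seg.min())
    if rng_amp <= 0:
        return None
    interior = np.arange(1, n - 1)
    is_min = (seg[interior] <= seg[interior - 1]) & \
             (seg[interior] <= seg[interior + 1])
    cand = list(interior[is_min])
    # a tail that decreases monotonically into the extent boundary hides
    # its minimum at the boundary itself
    if n >= 3 and seg[n - 2] <= seg[n - 3] and (n - 2) not in cand:
        cand.append(n - 2)
    cand = np.asarray(cand, dtype=int)
    candidates = cand[np.argsort(seg[cand])] if len(cand) else cand
    margin = 0.08 * rng_amp
    proper = [int(c) for c in candidates
              if seg[:c + 1].max() > seg[c] + margin
              and seg[c:].max() > seg[c] + margin]
    tipped = [int(c) for c in candidates
              if seg[:c + 1].max() > seg[c] + margin and n - 1 - c <= 12]
    pool, tip_merged = (proper, False) if proper else (tipped, True)
    if not pool:
        return None
    if pred_bins is not None:
        lo_p, hi_p = pred_bins
        inside = [c for c in pool if lo_p <= c <= hi_p]
        imin = inside[0] if inside else min(
            pool, key=lambda c: min(abs(c - lo_p), abs(c - hi_p)))
    else:
        imin = pool[0]
    vmin = seg[imin]
    lsh = seg[:imin + 1].max()
    tl = vmin + 0.5 * (lsh - vmin)
    i = imin
    while i > 0 and seg[i - 1] < tl:
        i -= 1
    if i == 0:
        left = 0.0
    elif seg[i - 1] > seg[i]:
        left = (i - 1) + (seg[i - 1] - tl) / (seg[i - 1] - seg[i])
    else:
        left = float(i)
    if tip_merged:
        right = float(n - 1)
    else:
        rsh = seg[imin:].max()
        tr = vmin + 0.5 * (rsh - vmin)
        j = imin
        while j < n - 1 and seg[j + 1] < tr:
            j += 1
        if j == n - 1:
            right = float(n - 1)
        elif seg[j + 1] > seg[j]:
            right = j + (tr - seg[j]) / (seg[j + 1] - seg[j])
        else:
            right = float(j)
    if right <= left:
        return None
    return float(left), float(right)


def _bright_run(prof, extent_bins, bright_thr, prev_centroid_bins, bg_mean,
                min_span):
    n = min(extent_bins + 1, len(prof))
    runs = [r for r in _runs_above(prof[:n], bright_thr)
            if r[1] - r[0] >= min_span]
    if not runs:
        return None
    if prev_centroid_bins is None:
        lo, hi = max(runs, key=lambda r: r[1] - r[0])
    else:
        lo, hi = min(runs, key=lambda r: abs((r[0] + r[1] - 1) / 2
                                             - prev_centroid_bins))
    wgt = np.clip(prof[lo:hi] - bg_mean, 0, None)
    cent = float((np.arange(lo, hi) * wgt).sum() / wgt.sum()) \
        if wgt.sum() > 0 else (lo + hi - 1) / 2.0
    return lo, hi, cent


def track_sections(sections: list[SectionLabel], kym: Kymogram,
                   tps: TimepointSet, background: BackgroundStats,
                   pre_bleach_polymer_level: float,
                   thresholds: ChaseThresholds = ChaseThresholds(),
                   trace: FrontTrace | None = None) -> pd.DataFrame:
    """Measure span centroid distance from the origin, span width and
    normalized mean intensity for each classified section at each assay
    timepoint. Bright and bleached sections are additionally evaluated at
    the pre-bleach timepoint t1 over their t2 footprint."""
    th = thresholds
    kym = kym.oriented()
    if trace is None:
        trace = trace_front(kym, background, k=th.k_front)
    sp = kym.spacing_nm
    bg_pre = background.level(kym.frame_index(tps.t1_s))
    by_class: dict[str, SectionLabel] = {}
    for s in sections:
        # widest span per class is the tracked representative
        if (s.klass not in by_class
                or (s.span_nm[1] - s.span_nm[0])
                > (by_class[s.klass].span_nm[1] - by_class[s.klass].span_nm[0])):
            by_class[s.klass] = s
    rows = []
    prev_bright = None
    prev_dark: tuple[float, float] | None = None  # (centroid bins, t_s)
    last_bleached: tuple[float, float] | None = None
    amp = pre_bleach_polymer_level - bg_pre
    sd_prof = effective_noise_sd(kym, background,
                                 2 * th.profile_halfwidth_frames + 1)
    v_a_bins_per_s = abs(estimate_speed(trace).v_a_nm_per_s) / sp
    for label, t in tps.post_bleach():
        prof = _profile_at(kym, t, th.profile_halfwidth_frames,
                           t_min_s=tps.t2_s)
        bg_t = background.level(kym.frame_index(t))
        bright_thr = bg_t + th.bright_floor * amp
        # the sheath only grows while assembling, so the running max of the
        # measured front bounds the polymer extent even when a dark mark
        # riding at the tip depresses the instantaneous front estimate
        i_t = kym.frame_index(t)
        upto = trace.front_nm[:i_t + 1][trace.valid[:i_t + 1]]
        extent = int((np.nanmax(upto) if len(upto) else
                      _front_at(trace, t)) / sp)
        if "bleached" in by_class:
            pred = None
            if prev_dark is not None:
                pc, pt = prev_dark
                slack = 6.0
                pred = (pc - slack, pc + v_a_bins_per_s * (t - pt) + slack)
            dr = _dark_run(prof, extent, pred)
            if dr is not None:
                left, right = dr
                last_bleached = dr
                cent = 0.5 * (left + right)
                prev_dark = (cent, t)
                sel = slice(int(np.ceil(left)), int(np.floor(right)) + 1)
                inten = float(np.mean(prof[sel])) if sel.stop > sel.start \
                    else float(prof[int(round(cent))])
                rows.append(_row("bleached", label, t, cent * sp,
                                 (right - left) * sp, left * sp, right * sp,
                                 normalize_intensity(
                                     inten, bg_t,
                                     pre_bleach_polymer_level, bg_pre)))
        if "bright" in by_class:
            br = _bright_run(prof, extent, bright_thr, prev_bright,
                             bg_t, th.min_span_bins)
            if br is not None:
                lo, hi, cent = br
                prev_bright = cent
                inten = float(prof[lo:hi].mean())
                rows.append(_row("bright", label, t, cent * sp,
                                 (hi - lo) * sp, lo * sp, (hi - 1) * sp,
                                 normalize_intensity(
                                     inten, bg_t,
                                     pre_bleach_polymer_level, bg_pre)))
        if "dim" in by_class:
            n = min(extent + 1, len(prof))
            bleach_thr = _bleached_threshold(bg_t, sd_prof, amp, th)
            is_dim = (prof[:n] > bleach_thr) & (prof[:n] < bright_thr)
            runs = [r for r in _runs_above(is_dim.astype(float), 0.5)
                    if r[1] - r[0] >= th.min_span_bins]
            if last_bleached is not None:
                runs = [r for r in runs if r[0] >= last_bleached[1] - 1
                        or r[1] <= last_bleached[0] + 1]
            if runs:
                lo, hi = max(runs, key=lambda r: r[1] - r[0])
                cent = (lo + hi - 1) / 2.0
                inten = float(prof[lo:hi].mean())
                rows.append(_row("dim", label, t, cent * sp,
                                 (hi - lo) * sp, lo * sp, (hi - 1) * sp,
                                 normalize_intensity(
                                     inten, bg_t,
                                     pre_bleach_polymer_level, bg_pre)))
    # t1: pre-bleach intensity of the to-be-bleached and bright material,
    # evaluated over the t2 span footprint
    prof1 = _profile_at(kym, tps.t1_s, th.profile_halfwidth_frames,
                        t_max_s=tps.t1_s)
    df = pd.DataFrame(rows)
    for klass in ("bright", "bleached"):
        sub = df[(df["section"] == klass) & (df["timepoint"] == "t2")] \
            if len(df) else df
        if len(sub):
            lo = int(round(sub.iloc[0]["span_lo_nm"] / sp))
            hi = int(round(sub.iloc[0]["span_hi_nm"] / sp)) + 1
            hi = min(hi, len(prof1))
            if hi > lo:
                inten = float(prof1[lo:hi].mean())
                rows.append(_row(klass, "t1", tps.t1_s,
                                 sub.iloc[0]["centroid_nm"],
                                 sub.iloc[0]["width_nm"],
                                 sub.iloc[0]["span_lo_nm"],
                                 sub.iloc[0]["span_hi_nm"],
                                 normalize_intensity(
                                     inten, bg_pre,
                                     pre_bleach_polymer_level, bg_pre)))
    out = pd.DataFrame(rows)
    order = {"t1": 0, "t2": 1, "t3": 2, "t4": 3}
    if len(out):
        out = out.sort_values(
            ["section", "timepoint"],
            key=lambda s: s.map(order) if s.name == "timepoint" else s,
        ).reset_index(drop=True)
    # annotate per-section dictionaries on the SectionLabel objects
    for s in sections:
        sub = out[out["section"] == s.klass] if len(out) else out
        for _, r in sub.iterrows():
            s.centroid_nm[r["timepoint"]] = r["centroid_nm"]
            s.width_nm[r["timepoint"]] = r["width_nm"]
            s.mean_intensity_pct[r["timepoint"]] = r["intensity_pct"]
    return out


def _row(section, timepoint, t_s, centroid, width, lo, hi, inten):
    return {"section": section, "timepoint": timepoint, "t_s": float(t_s),
            "centroid_nm": float(centroid), "width_nm": float(width),
            "span_lo_nm": float(lo), "span_hi_nm": float(hi),
            "intensity_pct": float(inten)}


# ---------------------------------------------------------------------------
# mechanism inference


def infer_mechanism(table: pd.DataFrame, v_a_nm_per_s: float,
                    thresholds: ChaseThresholds = ChaseThresholds(),
                    ) -> MechanismCall:
    """Decide the assembly mechanism from the tracked bleached span.

    Evidence: the drift of the bleached-span centroid (nm/s, OLS over the
    post-bleach timepoints), its relative width change between t2 and t4,
    and its normalized-intensity change. A pure function of the table and
    thresholds.
    """
    th = thresholds
    b = table[(table["section"] == "bleached")
              & (table["timepoint"] != "t1")]
    if len(b) < 3:
        raise ValueError("need at least 3 post-bleach timepoints for the "
                         "bleached section")
    res = stats.linregress(b["t_s"], b["centroid_nm"])
    drift = float(res.slope)
    w2 = float(b[b["timepoint"] == "t2"]["width_nm"].iloc[0])
    w4 = float(b[b["timepoint"] == "t4"]["width_nm"].iloc[0])
    width_change = (w4 - w2) / w2
    i2 = float(b[b["timepoint"] == "t2"]["intensity_pct"].iloc[0])
    i4 = float(b[b["timepoint"] == "t4"]["intensity_pct"].iloc[0])
    d_int = i4 - i2
    drift_tol = th.drift_tol_fraction * abs(v_a_nm_per_s)
    if (width_change >= th.width_tol and d_int >= th.intensity_rise_min_pct) \
            or d_int >= th.intensity_recovery_pct:
        # mark spreads and/or regains intensity as dim subunits mix in;
        # strong intensity recovery alone is diagnostic, because a bleached
        # mark shows no recovery under end addition at either terminus
        label = "intercalation"
    elif abs(drift) < drift_tol and abs(width_change) < th.width_tol:
        # mark stationary with stable footprint
        label = "distal"
    elif drift >= drift_tol and d_int < th.intensity_rise_min_pct:
        # mark moves away from the origin without gaining intensity; its
        # width is not used here because a mark riding at the tip is
        # delimited by the moving front, which inflates apparent width
        label = "proximal"
    else:
        label = "ambiguous"
    return MechanismCall(label, drift, width_change, d_int, th)
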