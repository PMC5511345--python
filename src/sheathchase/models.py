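"""Model objects over the measurement layer.

`SheathKymographModel` fits the polymerization kinetics of a single sheath
from its kymogram (origin, front trace, speed regression, end of assembly);
`BleachChaseModel` fits the full photobleach-chase analysis and calls the
assembly mechanism. Both follow the construct-then-``fit()`` idiom and
return results objects carrying estimates, uncertainties and a ``summary()``
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import chase as _chase
from .chase import (ChaseThresholds, Eligibility, MechanismCall, SectionLabel,
                    TimepointSet, eligible_for_chase, infer_mechanism,
                    measure_pre_bleach_level, track_sections)
from .dynamics import (AssemblyEnd, FrontTrace, SpeedEstimate,
                       detect_assembly_end, estimate_speed, trace_front)
from .kymograph import (BackgroundStats, Kymogram, LineProfile, OriginCall,
                        background_stats, extract_kymogram, locate_origin)
from .optics import ImageStack


@dataclass
class SheathKymographResults:
    origin: OriginCall
    front_trace: FrontTrace
    speed: SpeedEstimate
    assembly_end: AssemblyEnd
    kymogram: Kymogram

    @property
    def v_a_nm_per_s(self) -> float:
        return self.speed.v_a_nm_per_s

    @property
    def rsquared(self) -> float:
        return self.speed.r_squared

    def summary(self) -> str:
        s = self.speed
        lines = [
            "Sheath kymograph fit",
            "====================",
            f"nucleation frame       {self.origin.nucleation_frame}"
            f"  (t = {self.origin.nucleation_time_s:.1f} s)",
            f"polymerization speed   {s.v_a_nm_per_s:8.2f} nm/s"
            f"  (se {s.stderr_nm_per_s:.2f}, n = {s.n_points})",
            f"intercept              {s.intercept_nm:8.1f} nm",
            f"R-squared              {s.r_squared:8.4f}",
            f"end of assembly        {self.assembly_end.t_end_s:8.1f} s"
            + ("  [censored]" if self.assembly_end.censored else ""),
        ]
        return "\n".join(lines)


class SheathKymographModel:
    """Polymerization kinetics of one sheath from its kymogram."""

    def __init__(self, kymogram: Kymogram, background: BackgroundStats,
                 k_front: float = 3.0):
        self.kymogram = kymogram
        self.background = background
        self.k_front = k_front

    @classmethod
    def from_stack(cls, stack: ImageStack, line: LineProfile,
                   cell_mask=None, k_front: float = 3.0):
        kym = extract_kymogram(stack, line)
        bg = background_stats(stack, cell_mask)
        return cls(kym, bg, k_front)

    def fit(self, window_s: tuple[float, float] | None = None
            ) -> SheathKymographResults:
        origin = locate_origin(self.kymogram, self.background, self.k_front)
        kym = self.kymogram.oriented()
        trace = trace_front(kym, self.background, k=self.k_front)
        end = detect_assembly_end(trace)
        if window_s is None:
            # default regression window: from the first frame on which the
            # sheath is longer than a few bins (a sub-resolution blob has
            # no localizable front) to the end of assembly (the terminal
            # plateau carries no speed information)
            grown = trace.valid & (trace.front_nm >= 4 * trace.spacing_nm)
            t_start = (float(trace.times_s[grown][0]) if grown.any()
                       else float(trace.times_s[0]))
            window_s = (t_start, end.t_end_s)
        speed = estimate_speed(trace, window_s)
        return SheathKymographResults(origin, trace, speed, end, kym)


@dataclass
class BleachChaseResults:
    status: str  # "ok" | "rejected" | "insufficient"
    eligibility: Eligibility
    timepoints: TimepointSet | None = None
    sections: list[SectionLabel] | None = None
    table: pd.DataFrame | None = None
    call: MechanismCall | None = None
    speed: SpeedEstimate | None = None
    speed_pre: SpeedEstimate | None = None
    speed_post: SpeedEstimate | None = None
    pre_bleach_level: float | None = None

    @property
    def label(self) -> str | None:
        return self.call.label if self.call is not None else None

    def summary(self) -> str:
        lines = ["Photobleach-chase fit", "====================="]
        if self.status != "ok":
            lines.append(f"status: {self.status}")
            lines.extend(f"  reason: {r}" for r in self.eligibility.reasons)
            return "\n".join(lines)
        c = self.call
        tp = self.timepoints
        lines += [
            f"mechanism call         {c.label}",
            f"bleached drift         {c.bleached_drift_nm_per_s:8.2f} nm/s"
            f"  (tolerance {c.thresholds.drift_tol_fraction:.0%} of v_a)",
            f"bleached width change  {c.bleached_width_change_fraction:8.2%}",
            f"bleached dI            {c.bleached_intensity_change_pct:8.1f} "
            "pct points",
            f"v_a (pre-bleach)       {self.speed_pre.v_a_nm_per_s:8.2f} nm/s"
            f"  R2 {self.speed_pre.r_squared:.4f}",
            f"v_a (post-bleach)      {self.speed_post.v_a_nm_per_s:8.2f} nm/s"
            f"  R2 {self.speed_post.r_squared:.4f}",
            f"timepoints (s)         t1={tp.t1_s:.0f} t2={tp.t2_s:.0f} "
            + (f"t3={tp.t3_s:.0f} " if tp.t3_s is not None else "t3=skipped ")
            + f"t4={tp.t4_s:.0f}",
        ]
        return "\n".join(lines)


class BleachChaseModel:
    """Full photobleach-chase analysis of one sheath.

    Requires the bleach time from acquisition metadata; it is never inferred
    from the images.
    """

    def __init__(self, kymogram: Kymogram, t_bleach_s: float,
                 background: BackgroundStats,
                 thresholds: ChaseThresholds | None = None):
        self.kymogram = kymogram
        self.t_bleach_s = float(t_bleach_s)
        self.background = background
        self.thresholds = thresholds or ChaseThresholds()

    @classmethod
    def from_stack(cls, stack: ImageStack, line: LineProfile,
                   t_bleach_s: float | None = None, cell_mask=None,
                   thresholds: ChaseThresholds | None = None):
        if t_bleach_s is None:
            if "t_bleach_s" not in stack.meta:
                raise ValueError("bleach time missing: pass t_bleach_s or "
                                 "provide it in the stack metadata")
            t_bleach_s = float(stack.meta["t_bleach_s"])
        kym = extract_kymogram(stack, line)
        bg = background_stats(stack, cell_mask)
        return cls(kym, t_bleach_s, bg, thresholds)

    def fit(self) -> BleachChaseResults:
        th = self.thresholds
        elig = eligible_for_chase(self.kymogram, self.t_bleach_s,
                                  self.background, th)
        if not elig.eligible:
            return BleachChaseResults("rejected", elig)
        kym = self.kymogram.oriented()
        trace = elig.front_trace
        end = detect_assembly_end(trace)
        tps = TimepointSet.from_bleach_and_end(self.t_bleach_s, end.t_end_s,
                                               kym.frame_interval_s)
        speed = estimate_speed(trace, (trace.times_s[0], end.t_end_s))
        dt = kym.frame_interval_s
        # skip the first frames after nucleation: a sheath shorter than a
        # couple of PSF widths has no resolvable tip-side plateau yet
        t_first = float(trace.times_s[trace.valid][0])
        speed_pre = estimate_speed(trace, (t_first + 2 * dt,
                                           self.t_bleach_s))
        speed_post = estimate_speed(trace, (self.t_bleach_s + dt,
                                            end.t_end_s))
        pre_level = measure_pre_bleach_level(kym, self.t_bleach_s,
                                             self.background, th.k_front)
        try:
            sections = _chase.classify_sections(kym, self.t_bleach_s,
                                                end.t_end_s, self.background,
                                                pre_level, th)
            table = track_sections(sections, kym, tps, self.background,
                                   pre_level, th, trace=trace)
            call = infer_mechanism(table, speed.v_a_nm_per_s, th)
        except ValueError:
            return BleachChaseResults("insufficient", elig, tps, None,
                                      None, None, speed, speed_pre,
                                      speed_post, pre_level)
        return BleachChaseResults("ok", elig, tps, sections, table, call,
                                  speed, speed_pre, speed_post, pre_level)
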