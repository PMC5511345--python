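"""Forward simulation of T6SS sheath life cycles.

A sheath is a linear polymer of stacked rings nucleated on a membrane-anchored
baseplate. It polymerizes along a straight chord at constant speed ``v_a``,
contracts near-instantaneously to about half its extended length, and is then
disassembled. Three candidate assembly mechanisms are simulated:

* ``distal`` — new rings are appended at the end away from the baseplate;
* ``proximal`` — new rings are inserted at the baseplate, pushing the
  existing polymer outward;
* ``intercalation`` — new rings are inserted at uniformly random positions
  within the existing polymer.

Each ring carries the relative brightness of the soluble subunit pool at the
moment it was incorporated, so a photobleach event (which darkens rings inside
a line footprint and partially bleaches the soluble pool) leaves a readable
record of where subunits were added afterwards.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .geometry import CellGeometry

#: Ring pitch along the polymer axis, in um. Well below the 65 nm pixel
#: size, so its exact value does not affect any rendered observable.
RING_PITCH_UM = 0.01


class Mechanism(str, Enum):
    DISTAL = "distal"
    PROXIMAL = "proximal"
    INTERCALATION = "intercalation"


class Phase(str, Enum):
    ASSEMBLING = "assembling"
    EXTENDED = "extended"
    CONTRACTED = "contracted"
    DISASSEMBLING = "disassembling"
    GONE = "gone"


@dataclass
class FluorophorePool:
    """Soluble subunit pool. Brightness only ever decreases (photobleaching
    is irreversible); ``pool_size`` is an optional finite subunit budget."""

    soluble_brightness: float = 1.0
    pool_size: int | None = None

    def copy(self) -> "FluorophorePool":
        return FluorophorePool(self.soluble_brightness, self.pool_size)


@dataclass
class SheathTruth:
    """Ground-truth state of one sheath polymer."""

    sheath_id: int
    anchor_um: np.ndarray
    direction: np.ndarray
    v_a_nm_per_s: float
    t_nucleation_s: float
    chord_um: float
    mechanism: Mechanism = Mechanism.DISTAL
    ring_positions_um: np.ndarray = field(default_factory=lambda: np.zeros(0))
    ring_brightness: np.ndarray = field(default_factory=lambda: np.zeros(0))
    phase: Phase = Phase.ASSEMBLING
    target_length_um: float | None = None  # stop growing here if < chord
    t_contract_s: float | None = None  # scheduled contraction time
    length_um: float = 0.0  # continuously grown length (n*pitch + residual)
    _residual_um: float = 0.0

    def __post_init__(self) -> None:
        self.anchor_um = np.asarray(self.anchor_um, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be nonzero")
        self.direction = d / n
        self.mechanism = Mechanism(self.mechanism)

    @property
    def n_rings(self) -> int:
        return len(self.ring_positions_um)

    @property
    def max_growth_um(self) -> float:
        if self.target_length_um is None:
            return self.chord_um
        return min(self.chord_um, self.target_length_um)

    def ring_xy_um(self) -> np.ndarray:
        """(n, 2) world coordinates of the rings."""
        return self.anchor_um[None, :] + np.outer(self.ring_positions_um, self.direction)

    def copy(self) -> "SheathTruth":
        c = copy.copy(self)
        c.anchor_um = self.anchor_um.copy()
        c.direction = self.direction.copy()
        c.ring_positions_um = self.ring_positions_um.copy()
        c.ring_brightness = self.ring_brightness.copy()
        return c


def step_assembly(
    sheath: SheathTruth,
    pool: FluorophorePool,
    dt_s: float,
    rng: np.random.Generator | None = None,
) -> None:
    """Advance polymerization by ``dt_s`` seconds, in place.

    New rings carry the pool's current brightness. Growth is capped at the
    available chord (or an explicit target length). Position bookkeeping is
    index-based: rings sit at ``i * RING_PITCH_UM`` from the anchor while
    assembling, so the three mechanisms reduce to where in the brightness
    array new entries are inserted.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if sheath.phase is not Phase.ASSEMBLING:
        raise ValueError(f"cannot grow a sheath in phase {sheath.phase.value}")
    room = sheath.max_growth_um - sheath.length_um
    add = min(sheath.v_a_nm_per_s * dt_s / 1000.0, max(room, 0.0))
    total = add + sheath._residual_um
    n_new = int(total // RING_PITCH_UM)
    sheath._residual_um = total - n_new * RING_PITCH_UM
    sheath.length_um += add
    if n_new == 0:
        return
    if pool.pool_size is not None:
        n_new = min(n_new, pool.pool_size)
        pool.pool_size -= n_new
        if n_new == 0:
            return
    b = pool.soluble_brightness
    old = sheath.ring_brightness
    if sheath.mechanism is Mechanism.DISTAL:
        new = np.concatenate([old, np.full(n_new, b)])
    elif sheath.mechanism is Mechanism.PROXIMAL:
        new = np.concatenate([np.full(n_new, b), old])
    else:
        if rng is None:
            raise ValueError("intercalation growth requires an rng")
        new = old
        for _ in range(n_new):
            j = int(rng.integers(0, len(new) + 1))
            new = np.insert(new, j, b)
    sheath.ring_brightness = new
    sheath.ring_positions_um = np.arange(len(new)) * RING_PITCH_UM


@dataclass
class BleachEvent:
    """Laser line photobleach with a saturating Gaussian stripe profile.

    The laser dose falls off as a Gaussian with perpendicular distance
    ``d`` from the line, but at full output power the bleach saturates:
    rings keep a brightness fraction
    ``1 - (1 - polymer_survival) * min(1, saturation * exp(-d^2/2 sigma^2))``.
    ``footprint_fwhm_um`` is the width of the *fully bleached* stripe (the
    dark zone visible in the images); for ``saturation > 1`` the underlying
    Gaussian sigma is derived so that the dose saturates exactly across
    that stripe, with skirts that sharpen as the saturation grows.
    ``saturation = 1`` recovers a plain Gaussian profile of that FWHM.
    The soluble pool is scaled by ``pool_survival`` (the partially bleached
    cytosolic subunits that later build the dim section).
    """

    t_bleach_s: float
    line_start_um: tuple[float, float]
    line_end_um: tuple[float, float]
    footprint_fwhm_um: float = 0.8
    polymer_survival: float = 0.0
    pool_survival: float = 0.4
    saturation: float = 4.0

    def __post_init__(self) -> None:
        for v in (self.polymer_survival, self.pool_survival):
            if not 0.0 <= v <= 1.0:
                raise ValueError("survival factors must lie in [0, 1]")
        if self.saturation < 1.0:
            raise ValueError("saturation must be >= 1")

    @property
    def profile_sigma_um(self) -> float:
        half = self.footprint_fwhm_um / 2.0
        if self.saturation > 1.0:
            return half / np.sqrt(2.0 * np.log(self.saturation))
        return self.footprint_fwhm_um / 2.354820045


def _point_segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(np.dot(ab, ab))
    if denom == 0:
        raise ValueError("degenerate bleach line (zero length)")
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def apply_photobleach(
    sheaths: list[SheathTruth], pool: FluorophorePool, event: BleachEvent
) -> None:
    """Apply an irreversible line photobleach to polymers and pool, in place."""
    a = np.asarray(event.line_start_um, dtype=float)
    b = np.asarray(event.line_end_um, dtype=float)
    sigma = event.profile_sigma_um
    for s in sheaths:
        if s.n_rings == 0 or s.phase is Phase.GONE:
            continue
        d = _point_segment_distance(s.ring_xy_um(), a, b)
        dose = np.minimum(1.0, event.saturation * np.exp(-(d**2) / (2 * sigma**2)))
        depth = (1.0 - event.polymer_survival) * dose
        s.ring_brightness = s.ring_brightness * (1.0 - depth)
    pool.soluble_brightness *= event.pool_survival


def contract_sheath(sheath: SheathTruth, fraction: float) -> None:
    """Instantaneous contraction toward the static anchor, in place.

    Every ring position is scaled by ``fraction``; per-ring brightness is
    untouched, so the summed fluorescence is conserved.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("contraction fraction must lie in (0, 1)")
    if sheath.phase not in (Phase.EXTENDED, Phase.ASSEMBLING):
        raise ValueError(f"cannot contract a sheath in phase {sheath.phase.value}")
    sheath.ring_positions_um = sheath.ring_positions_um * fraction
    sheath.length_um *= fraction
    sheath.phase = Phase.CONTRACTED


@dataclass
class SeededSheath:
    """Deterministic nucleation used by controlled experiments."""

    t_nucleation_s: float
    anchor_um: tuple[float, float]
    direction: tuple[float, float]
    v_a_nm_per_s: float
    target_length_um: float | None = None
    t_contract_s: float | None = None
    initial_length_um: float = 0.0  # prefilled full-brightness polymer at t0


@dataclass
class SimulationConfig:
    geometry: CellGeometry
    seed: int
    mechanism: Mechanism = Mechanism.DISTAL
    v_a_mean_nm_per_s: float = 38.0
    v_a_sd_nm_per_s: float = 5.0
    contraction_fraction: float = 0.5
    contraction_jitter_sd: float = 0.03
    nucleation_rate_per_min: float = 0.0
    extended_dwell_s: float | None = 10.0  # None = never contract
    disassembly_delay_s: float = 20.0
    disassembly_tau_s: float = 15.0
    frame_interval_s: float = 2.0
    duration_s: float = 120.0
    bleach: BleachEvent | None = None
    seeded_sheaths: list[SeededSheath] = field(default_factory=list)
    pool: FluorophorePool = field(default_factory=FluorophorePool)

    def __post_init__(self) -> None:
        self.mechanism = Mechanism(self.mechanism)
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if not 0.0 < self.contraction_fraction < 1.0:
            raise ValueError("contraction_fraction must lie in (0, 1)")
        if self.nucleation_rate_per_min < 0:
            raise ValueError("rates must be nonnegative")
        if self.geometry.area_um2() <= 0:
            raise ValueError("zero-area geometry")
        if self.bleach is not None and not (
            0.0 <= self.bleach.t_bleach_s <= self.duration_s
        ):
            raise ValueError("bleach time outside the acquisition window")


@dataclass
class FrameState:
    t_s: float
    sheaths: list[SheathTruth]
    pool: FluorophorePool


@dataclass
class SimulationResult:
    config: SimulationConfig
    times_s: np.ndarray
    frames: list[FrameState]  # empty when record_frames=False
    events: list[dict]
    sheaths: list[SheathTruth]  # final states

    def event_log(self) -> pd.DataFrame:
        cols = ["time_s", "sheath_id", "event", "length_um"]
        return pd.DataFrame(self.events, columns=cols)

    def ring_table(self) -> pd.DataFrame:
        """Per-frame ring table (long format)."""
        rows = []
        for fr in self.frames:
            for s in fr.sheaths:
                xy = s.ring_xy_um()
                for i in range(s.n_rings):
                    rows.append(
                        (fr.t_s, s.sheath_id, i, s.ring_positions_um[i],
                         s.ring_brightness[i], xy[i, 0], xy[i, 1])
                    )
        return pd.DataFrame(
            rows,
            columns=["time_s", "sheath_id", "ring", "position_um",
                     "brightness", "x_um", "y_um"],
        )

    def sheath_summary(self) -> pd.DataFrame:
        rows = [
            {
                "sheath_id": s.sheath_id,
                "t_nucleation_s": s.t_nucleation_s,
                "v_a_nm_per_s": s.v_a_nm_per_s,
                "chord_um": s.chord_um,
                "max_length_um": getattr(s, "max_length_seen_um", s.length_um),
                "phase": s.phase.value,
            }
            for s in self.sheaths
        ]
        return pd.DataFrame(rows)


def simulate(config: SimulationConfig, record_frames: bool = True) -> SimulationResult:
    """Run the sheath life-cycle simulation on the frame grid.

    Deterministic given ``config.seed``. Sheaths pass through the phases
    assembling -> extended -> contracted -> disassembling -> gone; the event
    log records nucleation, bleach, contraction and disassembly times.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_s
    n_frames = int(np.floor(config.duration_s / dt + 1e-9)) + 1
    times = np.arange(n_frames) * dt

    pool = config.pool.copy()
    sheaths: list[SheathTruth] = []
    events: list[dict] = []
    frames: list[FrameState] = []
    bleach_done = False
    next_id = 0
    t_phase: dict[int, float] = {}  # sheath_id -> time of last phase change

    def log(t, sid, ev, length):
        events.append({"time_s": float(t), "sheath_id": sid, "event": ev,
                       "length_um": float(length)})

    def nucleate(t, anchor, direction, v_a, target=None, t_contract=None,
                 initial_length=0.0):
        nonlocal next_id
        chord = config.geometry.chord_length(anchor, direction)
        s = SheathTruth(
            sheath_id=next_id, anchor_um=anchor, direction=direction,
            v_a_nm_per_s=v_a, t_nucleation_s=t, chord_um=chord,
            mechanism=config.mechanism, target_length_um=target,
            t_contract_s=t_contract,
        )
        if initial_length > 0:
            n = int(round(min(initial_length, s.max_growth_um) / RING_PITCH_UM))
            s.ring_positions_um = np.arange(n) * RING_PITCH_UM
            s.ring_brightness = np.full(n, pool.soluble_brightness)
            s.length_um = n * RING_PITCH_UM
        next_id += 1
        sheaths.append(s)
        t_phase[s.sheath_id] = t
        log(t, s.sheath_id, "nucleation", s.length_um)
        return s

    # seeded sheaths with pre-window nucleation start already polymerized
    pending = sorted(config.seeded_sheaths, key=lambda x: x.t_nucleation_s)
    for sd in [p for p in pending if p.t_nucleation_s < 0]:
        s = nucleate(sd.t_nucleation_s, np.asarray(sd.anchor_um),
                     np.asarray(sd.direction), sd.v_a_nm_per_s,
                     sd.target_length_um, sd.t_contract_s, sd.initial_length_um)
        if sd.initial_length_um == 0 and sd.t_nucleation_s < 0:
            step_assembly(s, pool, -sd.t_nucleation_s, rng)
    pending = [p for p in pending if p.t_nucleation_s >= 0]

    for k, t in enumerate(times):
        if record_frames:
            frames.append(FrameState(t, [s.copy() for s in sheaths
                                         if s.phase is not Phase.GONE],
                                     pool.copy()))
        if k == n_frames - 1:
            break
        t_next = times[k + 1]
        # photobleach falls inside this interval (frame at t is pre-bleach)
        if (config.bleach is not None and not bleach_done
                and t <= config.bleach.t_bleach_s < t_next):
            apply_photobleach(sheaths, pool, config.bleach)
            bleach_done = True
            for s in sheaths:
                if s.phase is not Phase.GONE:
                    log(config.bleach.t_bleach_s, s.sheath_id, "bleach",
                        s.length_um)
        # nucleation: scheduled first, then Poisson, ordered by index
        while pending and t <= pending[0].t_nucleation_s < t_next:
            sd = pending.pop(0)
            nucleate(sd.t_nucleation_s, np.asarray(sd.anchor_um),
                     np.asarray(sd.direction), sd.v_a_nm_per_s,
                     sd.target_length_um, sd.t_contract_s,
                     sd.initial_length_um)
        n_nuc = rng.poisson(config.nucleation_rate_per_min / 60.0 * dt)
        for _ in range(n_nuc):
            anchor, direction, _ = config.geometry.sample_chord(rng)
            v_a = max(rng.normal(config.v_a_mean_nm_per_s,
                                 config.v_a_sd_nm_per_s), 5.0)
            nucleate(t, anchor, direction, v_a)
        # per-sheath dynamics over [t, t_next)
        for s in sheaths:
            if s.phase is Phase.ASSEMBLING:
                step_assembly(s, pool, dt, rng)
                s.max_length_seen_um = max(
                    getattr(s, "max_length_seen_um", 0.0), s.length_um)
                due = (s.t_contract_s is not None
                       and t <= s.t_contract_s < t_next)
                if due:
                    _contract(s, config, rng, t_next, t_phase, log)
                elif s.length_um >= s.max_growth_um - RING_PITCH_UM / 2:
                    s.phase = Phase.EXTENDED
                    t_phase[s.sheath_id] = t_next
                    log(t_next, s.sheath_id, "extended", s.length_um)
            elif s.phase is Phase.EXTENDED:
                due = (s.t_contract_s is not None
                       and t <= s.t_contract_s < t_next)
                dwell_over = (s.t_contract_s is None
                              and config.extended_dwell_s is not None
                              and t_next - t_phase[s.sheath_id]
                              >= config.extended_dwell_s)
                if due or dwell_over:
                    _contract(s, config, rng, t_next, t_phase, log)
            elif s.phase is Phase.CONTRACTED:
                if t_next - t_phase[s.sheath_id] >= config.disassembly_delay_s:
                    s.phase = Phase.DISASSEMBLING
                    t_phase[s.sheath_id] = t_next
                    log(t_next, s.sheath_id, "disassembly", s.length_um)
            elif s.phase is Phase.DISASSEMBLING:
                s.ring_brightness = s.ring_brightness * np.exp(
                    -dt / config.disassembly_tau_s)
                if s.n_rings == 0 or s.ring_brightness.max() < 0.02:
                    s.phase = Phase.GONE
                    log(t_next, s.sheath_id, "gone", s.length_um)
    return SimulationResult(config, times, frames, events, sheaths)


def _contract(s, config, rng, t_now, t_phase, log):
    frac = float(np.clip(
        rng.normal(config.contraction_fraction, config.contraction_jitter_sd),
        0.05, 0.95))
    contract_sheath(s, frac)
    t_phase[s.sheath_id] = t_now
    log(t_now, s.sheath_id, "contraction", s.length_um)
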