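"""Ready-made synthetic experiments matching the imaging protocols the
analysis is built for.

These presets pin the acquisition conditions — 65 nm pixels, 2 s frames for
2 min with a line photobleach after 30 s for the chase assay, and 500 frames
per second for 5 s for high-speed contraction imaging — and default kinetic
parameters (v_a 55 nm/s for the sparse-sheath chase background, 38 nm/s for
wild-type-like populations, contraction to ~half length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CellGeometry, CellShape
from .kymograph import LineProfile
from .optics import ImageStack, OpticsConfig, render_stack
from .simulate import (BleachEvent, FluorophorePool, Mechanism, SeededSheath,
                       SimulationConfig, SimulationResult, simulate)


@dataclass
class ChaseExperiment:
    stack: ImageStack
    sim: SimulationResult
    line: LineProfile
    t_bleach_s: float
    v_a_nm_per_s: float
    geometry: CellGeometry


def _sub_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


def default_optics(seed: int | None = None, noise: bool = True) -> OpticsConfig:
    return OpticsConfig(shot_noise=noise,
                        read_noise_sd=2.0 if noise else 0.0,
                        seed=seed)


def chase_experiment(
    mechanism: Mechanism | str,
    seed: int,
    v_a_nm_per_s: float = 55.0,
    noise: bool = True,
    diameter_um: float = 5.0,
    duration_s: float = 120.0,
    frame_interval_s: float = 2.0,
    t_bleach_s: float = 30.0,
    t_nucleation_s: float = 0.0,
    pool_survival: float = 0.4,
    bleach_back_um: float = 0.75,
) -> ChaseExperiment:
    """One controlled photobleach-chase event.

    A single sheath nucleates on the membrane of a spheroplast and grows
    along a diameter chord; the bleach line crosses the sheath
    perpendicularly ``bleach_back_um`` behind the front position at the
    bleach time, so the bleached mark sits just inside the growing tip.
    """
    mech = Mechanism(mechanism)
    geom = CellGeometry(CellShape.SPHEROPLAST, diameter_um)
    anchor = np.array([-diameter_um / 2.0, 0.0])
    direction = np.array([1.0, 0.0])
    front_at_bleach = v_a_nm_per_s * (t_bleach_s - t_nucleation_s) / 1000.0
    cross = anchor + direction * max(front_at_bleach - bleach_back_um, 0.1)
    perp = np.array([0.0, 1.0])
    bleach = BleachEvent(
        t_bleach_s=t_bleach_s,
        line_start_um=tuple(cross - 1.2 * perp),
        line_end_um=tuple(cross + 1.2 * perp),
        pool_survival=pool_survival,
    )
    cfg = SimulationConfig(
        geometry=geom, seed=_sub_seed(seed, 1), mechanism=mech,
        v_a_mean_nm_per_s=v_a_nm_per_s, v_a_sd_nm_per_s=0.0,
        nucleation_rate_per_min=0.0, extended_dwell_s=None,
        frame_interval_s=frame_interval_s, duration_s=duration_s,
        bleach=bleach,
        seeded_sheaths=[SeededSheath(t_nucleation_s, tuple(anchor),
                                     tuple(direction), v_a_nm_per_s)],
        pool=FluorophorePool(),
    )
    sim = simulate(cfg)
    optics = default_optics(seed=_sub_seed(seed, 2), noise=noise)
    stack = render_stack(sim, optics)
    stack.meta["t_bleach_s"] = t_bleach_s
    line = LineProfile(tuple(anchor),
                       tuple(anchor + direction * (geom.chord_length(anchor, direction) + 0.3)))
    return ChaseExperiment(stack, sim, line, t_bleach_s, v_a_nm_per_s, geom)


def speed_experiment(v_a_nm_per_s: float, seed: int, noise: bool = True,
                     diameter_um: float = 6.0, duration_s: float = 80.0,
                     frame_interval_s: float = 2.0) -> ChaseExperiment:
    """A single growing sheath with no bleach, for speed-recovery checks."""
    geom = CellGeometry(CellShape.SPHEROPLAST, diameter_um)
    anchor = np.array([-diameter_um / 2.0, 0.0])
    direction = np.array([1.0, 0.0])
    cfg = SimulationConfig(
        geometry=geom, seed=_sub_seed(seed, 3),
        v_a_mean_nm_per_s=v_a_nm_per_s, v_a_sd_nm_per_s=0.0,
        nucleation_rate_per_min=0.0, extended_dwell_s=None,
        frame_interval_s=frame_interval_s, duration_s=duration_s,
        seeded_sheaths=[SeededSheath(4.0, tuple(anchor), tuple(direction),
                                     v_a_nm_per_s)],
    )
    sim = simulate(cfg)
    stack = render_stack(sim, default_optics(_sub_seed(seed, 4), noise))
    line = LineProfile(tuple(anchor),
                       tuple(anchor + direction * (diameter_um + 0.3)))
    return ChaseExperiment(stack, sim, line, np.nan, v_a_nm_per_s, geom)


def contraction_experiment(seed: int, noise: bool = True,
                           diameter_um: float = 2.8,
                           frame_interval_s: float = 2.0,
                           duration_s: float = 80.0) -> ChaseExperiment:
    """One sheath growing across a spheroplast and contracting mid-movie,
    imaged at the standard 2 s frame interval."""
    rng = np.random.default_rng(_sub_seed(seed, 5))
    geom = CellGeometry(CellShape.SPHEROPLAST, diameter_um)
    anchor = np.array([-diameter_um / 2.0, 0.0])
    direction = np.array([1.0, 0.0])
    v_a = 50.0
    t_nuc = 4.0
    t_full = t_nuc + diameter_um * 1000.0 / v_a
    t_contract = t_full + 2 * frame_interval_s + rng.uniform(0, 4)
    cfg = SimulationConfig(
        geometry=geom, seed=_sub_seed(seed, 6),
        nucleation_rate_per_min=0.0, extended_dwell_s=None,
        disassembly_delay_s=1e9,
        frame_interval_s=frame_interval_s, duration_s=duration_s,
        seeded_sheaths=[SeededSheath(t_nuc, tuple(anchor), tuple(direction),
                                     v_a, t_contract_s=t_contract)],
    )
    sim = simulate(cfg)
    stack = render_stack(sim, default_optics(_sub_seed(seed, 7), noise))
    line = LineProfile(tuple(anchor),
                       tuple(anchor + direction * (diameter_um + 0.3)))
    return ChaseExperiment(stack, sim, line, np.nan, v_a, geom)


def highspeed_contraction_stack(seed: int, n_events: int = 5,
                                noise: bool = True,
                                diameter_um: float = 8.0,
                                duration_s: float = 5.0,
                                fps: float = 500.0):
    """High-frame-rate acquisition: ``n_events`` extended sheaths in one
    large spheroplast contract at staggered times within the 5 s window.

    Returns (stack, sim, [LineProfile per sheath]) — lines follow the truth
    chords, as manual line drawing is not emulated.
    """
    geom = CellGeometry(CellShape.SPHEROPLAST, diameter_um)
    r = diameter_um / 2.0
    seeded = []
    lines = []
    t_contracts = np.linspace(0.4, duration_s - 0.6, n_events)
    for i in range(n_events):
        th = 2 * np.pi * i / n_events
        anchor = np.array([r * np.cos(th), r * np.sin(th)])
        direction = -anchor / np.linalg.norm(anchor)
        length = 0.45 * diameter_um
        seeded.append(SeededSheath(
            t_nucleation_s=-1.0, anchor_um=tuple(anchor),
            direction=tuple(direction), v_a_nm_per_s=50.0,
            target_length_um=length, t_contract_s=float(t_contracts[i]),
            initial_length_um=length))
        lines.append(LineProfile(tuple(anchor),
                                 tuple(anchor + direction * (length + 0.4))))
    cfg = SimulationConfig(
        geometry=geom, seed=_sub_seed(seed, 8),
        nucleation_rate_per_min=0.0, extended_dwell_s=None,
        disassembly_delay_s=1e9,
        frame_interval_s=1.0 / fps, duration_s=duration_s,
        seeded_sheaths=seeded,
    )
    sim = simulate(cfg)
    optics = default_optics(_sub_seed(seed, 9), noise)
    stack = render_stack(sim, optics)
    return stack, sim, lines


def spheroplast_population(
    seed: int,
    n_cells: int = 150,
    nucleation_rate_per_min: float = 3.54,  # 7.08 per 2 min
    observation_s: float = 300.0,
    diameter_range_um: tuple[float, float] = (3.0, 9.0),
    v_a_mean_nm_per_s: float = 38.0,
    measurement_noise_um: float = 0.065,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a spheroplast population at truth level (no rendering) and
    return (cell records, pooled event log).

    Each cell's longest sheath over the observation window is chord-limited
    by its diameter; the recorded length carries one pixel of measurement
    noise, emulating manual line measurements.
    """
    rng = np.random.default_rng(_sub_seed(seed, 10))
    records = []
    logs = []
    for i in range(n_cells):
        d = rng.uniform(*diameter_range_um)
        geom = CellGeometry(CellShape.SPHEROPLAST, d)
        cfg = SimulationConfig(
            geometry=geom, seed=_sub_seed(seed, 11 + i),
            nucleation_rate_per_min=nucleation_rate_per_min,
            v_a_mean_nm_per_s=v_a_mean_nm_per_s,
            duration_s=observation_s, frame_interval_s=2.0,
            extended_dwell_s=10.0,
        )
        sim = simulate(cfg, record_frames=False)
        summ = sim.sheath_summary()
        longest = float(summ["max_length_um"].max()) if len(summ) else 0.0
        longest = min(max(longest + rng.normal(0, measurement_noise_um), 0.0),
                      d)
        log = sim.event_log()
        log.insert(0, "cell_id", f"cell{i:04d}")
        logs.append(log)
        records.append({
            "cell_id": f"cell{i:04d}", "morphology": "spheroplast",
            "dynamic_t6ss": len(summ) > 0, "diameter_um": d,
            "surface_area_um2": geom.area_um2(),
            "longest_sheath_um": longest if len(summ) else np.nan,
            "n_sheath_events_2min": int(
                (log["event"] == "nucleation").sum() * 120.0 / observation_s),
        })
    nonempty = [lg for lg in logs if len(lg)]
    events = (pd.concat(nonempty, ignore_index=True) if nonempty
              else pd.DataFrame(columns=["cell_id", "time_s", "sheath_id",
                                         "event", "length_um"]))
    return pd.DataFrame(records), events
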