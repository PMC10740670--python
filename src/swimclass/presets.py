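"""Preset kinematic regimes and ready-made cohort designs.

The preset library encodes a dose-like family of swimming regimes for an
ethanol-style exposure series: a mild speed increase at low doses, marked
hyperactivity at 1.5%, circular swimming emerging at 2.0-2.5%, an unstable
edge-case at 3.0%, and sedation/immobility at the top doses.  The numeric
values are the package's own choices (pixel units in a radius-100 well at
25 fps); they are tuned for qualitative, not biomechanical, realism.
"""

from __future__ import annotations

from .simulate import CohortDesign, RegimeParams, RegimeSchedule
from .trajectory import ArenaGeometry, ClassLabel

__all__ = [
    "DEFAULT_ARENA",
    "ETHANOL_PRESETS",
    "ethanol_label",
    "ethanol_cohort_design",
    "speed_circling_design",
    "sobering_step_schedule",
    "sobering_linear_schedule",
]

DEFAULT_ARENA = ArenaGeometry(center=(120.0, 120.0), radius=100.0)

#: Regime per ethanol concentration (percent v/v); 0.0 is the merged control.
ETHANOL_PRESETS: dict[float, RegimeParams] = {
    0.0: RegimeParams(speed_mean=30, speed_sd=12, turn_concentration=3,
                      pause_prob=0.15, pause_duration_mean=1.0),
    0.5: RegimeParams(speed_mean=38, speed_sd=13, turn_concentration=3,
                      pause_prob=0.12, pause_duration_mean=1.0),
    1.0: RegimeParams(speed_mean=55, speed_sd=14, turn_concentration=5,
                      pause_prob=0.08, pause_duration_mean=0.8),
    1.5: RegimeParams(speed_mean=78, speed_sd=15, turn_concentration=12,
                      pause_prob=0.04, pause_duration_mean=0.6),
    2.0: RegimeParams(speed_mean=70, speed_sd=15, turn_concentration=25,
                      pause_prob=0.04, pause_duration_mean=0.6, circling_bias=1.2),
    2.5: RegimeParams(speed_mean=66, speed_sd=15, turn_concentration=25,
                      pause_prob=0.05, pause_duration_mean=0.7, circling_bias=1.5),
    3.0: RegimeParams(speed_mean=40, speed_sd=18, turn_concentration=2,
                      pause_prob=0.5, pause_duration_mean=3.0, circling_bias=0.8),
    3.5: RegimeParams(speed_mean=5, speed_sd=4, turn_concentration=1,
                      pause_prob=0.8, pause_duration_mean=8.0),
    4.0: RegimeParams(immobile=True),
}


def ethanol_label(concentration: float) -> ClassLabel:
    return ClassLabel.drug("ethanol", concentration)


def ethanol_cohort_design(
    concentrations=tuple(ETHANOL_PRESETS),
    n_fish_per_condition: int = 12,
    duration: float = 90 * 60.0,
    fps: float = 25.0,
    arena: ArenaGeometry = DEFAULT_ARENA,
    seed: int = 0,
) -> CohortDesign:
    """Full dose-series cohort: 12 fish per condition, 90-min recordings."""
    conditions = tuple(
        (ethanol_label(c), RegimeSchedule.constant(ETHANOL_PRESETS[c], duration))
        for c in concentrations
    )
    return CohortDesign(
        conditions=conditions,
        n_fish_per_condition=n_fish_per_condition,
        duration=duration,
        fps=fps,
        arena=arena,
        seed=seed,
    )


def speed_circling_design(
    n_fish_per_condition: int = 6,
    duration: float = 15 * 60.0,
    fps: float = 25.0,
    arena: ArenaGeometry = DEFAULT_ARENA,
    seed: int = 0,
) -> CohortDesign:
    """Cohort contrasting track shape against speed statistics.

    Three kinematic regime groups, each a pair of near-identical conditions
    that a classifier should mutually confuse: a slow pair (the merged
    control and 0.5%), a fast straight-swimming pair (1.5% and 2.0%), and a
    fast circling pair (2.5% and 3.0%).  The straight and circling groups
    share the same step-speed distribution, so speed statistics merge all
    four fast conditions into one cluster (two speed clusters in total),
    while track-shape classification also separates straight from circling
    swimming (three clusters) — the design isolates exactly that contrast.
    """
    slow_a = RegimeParams(speed_mean=30, speed_sd=10, turn_concentration=3,
                          pause_prob=0.15, pause_duration_mean=1.0)
    slow_b = RegimeParams(speed_mean=30, speed_sd=12, turn_concentration=3,
                          pause_prob=0.13, pause_duration_mean=1.0)
    fast_straight_a = RegimeParams(speed_mean=70, speed_sd=15, turn_concentration=30,
                                   pause_prob=0.05, pause_duration_mean=0.5)
    fast_straight_b = RegimeParams(speed_mean=70, speed_sd=18, turn_concentration=30,
                                   pause_prob=0.05, pause_duration_mean=0.5)
    fast_circling_a = RegimeParams(speed_mean=70, speed_sd=15, turn_concentration=60,
                                   pause_prob=0.05, pause_duration_mean=0.5,
                                   circling_bias=2.6)
    fast_circling_b = RegimeParams(speed_mean=70, speed_sd=18, turn_concentration=60,
                                   pause_prob=0.05, pause_duration_mean=0.5,
                                   circling_bias=2.4)
    conditions = tuple(
        (ethanol_label(c), RegimeSchedule.constant(r, duration))
        for c, r in [(0.0, slow_a), (0.5, slow_b), (1.5, fast_straight_a),
                     (2.0, fast_straight_b), (2.5, fast_circling_a),
                     (3.0, fast_circling_b)]
    )
    return CohortDesign(
        conditions=conditions,
        n_fish_per_condition=n_fish_per_condition,
        duration=duration,
        fps=fps,
        arena=arena,
        seed=seed,
    )


def sobering_step_schedule(
    high_concentration: float = 2.0,
    switch_time: float = 30 * 60.0,
    duration: float = 90 * 60.0,
) -> RegimeSchedule:
    """Abrupt return to control kinematics at ``switch_time`` (default 30 min)."""
    return RegimeSchedule(
        start_regime=ETHANOL_PRESETS[high_concentration],
        end_regime=ETHANOL_PRESETS[0.0],
        transition="step",
        transition_time=switch_time,
        duration=duration,
    )


def sobering_linear_schedule(
    high_concentration: float = 2.0,
    duration: float = 90 * 60.0,
) -> RegimeSchedule:
    """Gradual (linear) return to control kinematics over the recording."""
    return RegimeSchedule(
        start_regime=ETHANOL_PRESETS[high_concentration],
        end_regime=ETHANOL_PRESETS[0.0],
        transition="linear",
        duration=duration,
    )
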