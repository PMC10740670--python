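"""Shared synthetic regime designs used across test modules."""

from swimclass.presets import DEFAULT_ARENA
from swimclass.simulate import CohortDesign, RegimeParams, RegimeSchedule
from swimclass.trajectory import ClassLabel
from swimclass.workflow import cohort_segments


def separable_segments(seed=3, n_fish=4, duration=300):
    """Fast straight swimmers vs immobile fish: separable by construction."""
    fast = RegimeParams(speed_mean=70, speed_sd=15, turn_concentration=30,
                        pause_prob=0)
    dead = RegimeParams(immobile=True)
    conds = (
        (ClassLabel.control(), RegimeSchedule.constant(fast, duration)),
        (ClassLabel.drug("ethanol", 4.0), RegimeSchedule.constant(dead, duration)),
    )
    design = CohortDesign(conditions=conds, n_fish_per_condition=n_fish,
                          duration=duration, fps=25, arena=DEFAULT_ARENA, seed=seed)
    return cohort_segments(design, 30)
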