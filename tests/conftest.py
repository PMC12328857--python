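"""Shared fixtures: a desk-scale phantom reused across the suite.

The phantom is ~300 mL (a scaled-down organ); fraction masses are scaled by
liver volume so the tissue loading in mg/mL matches the full-scale study
schedule (five 250 mg fractions into ~2,600 mL).
"""

import numpy as np
import pytest

from holoperf.phantom import (
    FlowCondition,
    FractionSchedule,
    build_liver_phantom,
    grow_arterial_tree,
    simulate_deposition,
)

FULL_SCALE_VOLUME_ML = 2600.0


@pytest.fixture(scope="session")
def labels_small():
    return build_liver_phantom(
        shape=(48, 48, 32), spacing=2.0, target_volume_ml=300.0, seed=1
    )


@pytest.fixture(scope="session")
def trees_small(labels_small):
    return {
        lobe: grow_arterial_tree(
            labels_small.lobe_mask(lobe),
            labels_small.spacing,
            generations=7,
            seed=100 + lobe,
        )
        for lobe in range(1, 6)
    }


def scaled_schedule(labels, masses_mg=(250.0,) * 5) -> FractionSchedule:
    """The study schedule with masses scaled to the phantom's liver volume
    (preserves the administered mg per mL of tissue)."""
    scale = labels.liver_volume_ml() / FULL_SCALE_VOLUME_ML
    return FractionSchedule(masses_mg=tuple(m * scale for m in masses_mg))


@pytest.fixture(scope="session")
def schedule_small(labels_small):
    return scaled_schedule(labels_small)


@pytest.fixture(scope="session")
def perfusion_uneven():
    return np.array([0.4, 0.3, 0.15, 0.1, 0.05])


@pytest.fixture(scope="session")
def truth_medium(labels_small, trees_small, schedule_small, perfusion_uneven):
    return simulate_deposition(
        labels_small,
        trees_small,
        schedule_small,
        FlowCondition.from_name("medium"),
        seed=3,
        lobe_perfusion=perfusion_uneven,
    )
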