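import numpy as np
import pandas as pd
import pytest

from zfsocial import (
    AgentParams,
    ArenaGeometry,
    KnotPathParams,
    StimulusProgram,
    TrajectoryTable,
    simulate_agent,
    simulate_knot_stimulus,
)


@pytest.fixture(scope="session")
def dish() -> ArenaGeometry:
    return ArenaGeometry.circle(20.0)


@pytest.fixture(scope="session")
def tank() -> ArenaGeometry:
    return ArenaGeometry.dyad_tank()


@pytest.fixture(scope="session")
def knot_stimulus(dish):
    """One 300 s epoch of a 4 mm dot on the default knot path, 30 Hz."""
    return simulate_knot_stimulus(
        KnotPathParams(), StimulusProgram.single(4.0, 300.0), fps=30.0, seed=11, arena=dish
    )


@pytest.fixture(scope="session")
def null_session(dish, knot_stimulus) -> TrajectoryTable:
    """An asocial (zero-gain) agent watching the default stimulus."""
    return simulate_agent(AgentParams(), knot_stimulus, dish, fps=30.0, seed=7)


def make_table(x, y, fps=10.0, arena=None, heading=None, stim_x=None, stim_y=None,
               stim_diam=None, epoch_id=None, body_length=5.0, **kwargs) -> TrajectoryTable:
    """Hand-built trajectory table for closed-form test cases."""
    n = len(x)
    if arena is None:
        arena = ArenaGeometry.circle(1000.0)
    frames = pd.DataFrame({
        "t": np.arange(n) / fps,
        "x": np.asarray(x, dtype=float),
        "y": np.asarray(y, dtype=float),
        "heading": np.full(n, np.nan) if heading is None else np.asarray(heading, float),
        "stim_x": np.full(n, np.nan) if stim_x is None else np.asarray(stim_x, float),
        "stim_y": np.full(n, np.nan) if stim_y is None else np.asarray(stim_y, float),
        "stim_diam": np.zeros(n) if stim_diam is None else np.asarray(stim_diam, float),
        "epoch_id": np.full(n, -1) if epoch_id is None else np.asarray(epoch_id, int),
    })
    return TrajectoryTable(frames=frames, fps=fps, arena=arena,
                           body_length=body_length, **kwargs)
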