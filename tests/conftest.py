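import numpy as np
import pandas as pd
import pytest

from teamsync import simulator
from teamsync.tracking_io import MatchDataset, MatchMetadata, TRACKING_COLUMNS


@pytest.fixture(scope="session")
def small_match():
    """A small simulated match with ground truth (300 frames total)."""
    cfg = simulator.SimulationConfig(n_frames_per_half=150, seed=11)
    return simulator.simulate_match(cfg)


@pytest.fixture(scope="session")
def small_ds(small_match):
    return small_match[0]


def build_manual_dataset(frames_spec, metadata=None):
    """Construct a tiny valid dataset from per-frame dicts.

    frames_spec: list of dicts with keys half, frame, ball (x, y),
    ball_status, possession, and optional per-player overrides
    {(team, k): (x, y)}.
    """
    metadata = metadata or MatchMetadata()
    rows = []
    for spec in frames_spec:
        half, frame = spec["half"], spec["frame"]
        status = spec.get("ball_status", "alive")
        poss = spec.get("possession", "home")
        bx, by = spec.get("ball", (0.0, 0.0))
        rows.append(
            dict(half=half, frame=frame, object_type="ball", team="none",
                 player_id="", x_m=bx, y_m=by, ball_status=status, possession=poss)
        )
        overrides = spec.get("players", {})
        for team in ("home", "away"):
            for k in range(11):
                x, y = overrides.get(
                    (team, k),
                    (10.0 + k + (0 if team == "home" else 30), 5.0 + k),
                )
                rows.append(
                    dict(half=half, frame=frame, object_type="player", team=team,
                         player_id=f"{team[0].upper()}{k + 1:02d}", x_m=x, y_m=y,
                         ball_status=status, possession=poss)
                )
    df = pd.DataFrame(rows)[list(TRACKING_COLUMNS)]
    return MatchDataset(metadata=metadata, frames=df)


@pytest.fixture
def manual_ds():
    """10 alive + 5 dead frames with alternating possession."""
    spec = []
    for i in range(15):
        spec.append(
            dict(half=1, frame=i,
                 ball=(float(i), 1.0),
                 ball_status="alive" if i < 10 else "dead",
                 possession="home" if i % 2 == 0 else "away")
        )
    return build_manual_dataset(spec)
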