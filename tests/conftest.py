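import pandas as pd
import pytest

from ssgperf.synthetic import GeneratorConfig, generate_study


def make_events(rows):
    """Build a validated-shape event table from (game, fmt, team, side, player,
    indicator, outcome) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "game_id",
            "format",
            "team",
            "side_team_id",
            "player_id",
            "indicator",
            "outcome",
        ],
    )


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study at the default (reference-design) configuration."""
    return generate_study(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def default_pipeline(default_study):
    import warnings

    from ssgperf.pipeline import run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(
            default_study.events, default_study.roster, default_study.games
        )
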