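"""Packaged reference data.

The package ships the published per-indicator event totals from an
observational study at a professional soccer academy (63 elite youth players
across four age-category teams; 82 six-minute 7-vs-7 small-sided games and
six 11-vs-11 half-games per team).  These pre-aggregated counts are the
canonical input for the representativeness analysis when raw event logs are
unavailable, and they calibrate the synthetic generator's default event
rates.
"""

from __future__ import annotations

import pandas as pd

#: Total observed events per indicator in each format (11-vs-11 halves and
#: small-sided games) from the reference academy study, ordered by the
#: 11-vs-11 frequency.
REFERENCE_EVENT_TOTALS: dict[str, tuple[int, int]] = {
    # indicator: (observed_m11, observed_ssg)
    "pass_forward": (2167, 2526),
    "tackle": (619, 758),
    "take_on": (601, 775),
    "applying_pressure": (439, 524),
    "pass_interception": (418, 414),
    "defensive_aerial_duel": (303, 40),
    "staying_in_front": (195, 389),
    "offensive_aerial_duel": (195, 47),
    "dribble": (165, 247),
    "shot_on_target": (68, 222),
    "chance_created": (43, 118),
}


def load_reference_counts() -> pd.DataFrame:
    """Reference per-indicator event totals as a DataFrame.

    Returns
    -------
    DataFrame indexed by indicator with integer columns ``observed_m11`` and
    ``observed_ssg``.
    """
    df = pd.DataFrame.from_dict(
        REFERENCE_EVENT_TOTALS, orient="index", columns=["observed_m11", "observed_ssg"]
    )
    df.index.name = "indicator"
    return df
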