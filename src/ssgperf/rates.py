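"""Exposure-normalised rate statistics for count-type indicators.

Players differ widely in total playing time, so raw event counts are not
comparable.  Count-type indicators (pass interceptions, applying pressure,
chances created, shots on target) are therefore expressed as events per
six-minute bout — the duration of one small-sided game — computed against
each player's total minutes in the given format:

    rate = 6 * n_events / total_minutes
"""

from __future__ import annotations

import pandas as pd

from ssgperf.data_model import COUNT_INDICATORS

BOUT_MINUTES = 6.0

_EXPOSURE_COL = {"SSG": "minutes_ssg", "M11": "minutes_m11"}


def events_per_bout(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    fmt: str,
    indicators: tuple[str, ...] = COUNT_INDICATORS,
) -> pd.DataFrame:
    """Per-player events-per-bout rates for the count-type indicators.

    Parameters
    ----------
    events
        Validated event table (raw or merged view; count labels are
        unaffected by merging).
    roster
        Retained player roster; exposure is the player's total minutes in
        ``fmt`` across all games, per the roster.
    fmt
        ``"SSG"`` or ``"M11"``.

    Returns
    -------
    Tidy table with columns ``player_id, format, indicator, rate, exposure``;
    one row per retained player per indicator, rate 0 for players without
    events.

    Raises
    ------
    ValueError
        If a rostered player has non-positive exposure in ``fmt`` (such
        players should have been excluded upstream).
    """
    if fmt not in _EXPOSURE_COL:
        raise ValueError(f"format must be one of {sorted(_EXPOSURE_COL)}, got {fmt!r}")
    exposure = roster.set_index("player_id")[_EXPOSURE_COL[fmt]].astype(float)
    if (exposure <= 0).any():
        bad = exposure[exposure <= 0].index.tolist()
        raise ValueError(f"player(s) with zero {fmt} minutes must be excluded upstream: {bad}")

    sub = events[(events["format"] == fmt) & events["indicator"].isin(indicators)]
    counts = (
        sub.groupby(["player_id", "indicator"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=exposure.index, columns=list(indicators), fill_value=0)
        .fillna(0)
    )
    rates = counts.mul(BOUT_MINUTES / exposure, axis=0)

    out = rates.stack().rename("rate").reset_index()
    out.columns = ["player_id", "indicator", "rate"]
    out.insert(1, "format", fmt)
    out["exposure"] = out["player_id"].map(exposure)
    return out
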