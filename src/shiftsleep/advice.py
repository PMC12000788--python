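"""Advice-message catalog and descriptive statistics of advice logs.

The catalog holds the 23 physician-selectable messages grouped into six
categories.  Statistics operate on an advice log with one row per advice
piece (participant, date, selected message IDs, participant response).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date

import pandas as pd

#: message id -> (category, short description)
MESSAGE_CATALOG: dict[int, tuple[str, str]] = {
    1: ("dietary_intake", "Refrain from consuming alcohol before sleep."),
    2: ("dietary_intake", "Stop consuming caffeine 3 hours before lights-out."),
    3: ("dietary_intake", "Refrain from eating midnight snacks."),
    4: ("activity", "Refrain from using a smartphone in the bedroom."),
    5: ("activity", "Take a bath a little earlier than usual."),
    6: ("activity", "Refrain from exercising 3 hours before lights-out."),
    7: ("sleep", "Darken the bedroom when you go to bed."),
    8: ("sleep", "Leave the bedroom when you do not fall asleep within 15 minutes."),
    9: ("sleep", "Set your wake-up time according to each work shift."),
    10: ("sleep", "Do not try too hard to fall asleep quickly."),
    11: ("shift", "Consult with your superior for clockwise shift rotation."),
    12: ("nap", "Take a nap of about 90 minutes before the night shift."),
    13: ("nap", "Take a 15-20 minute nap during rest time at work."),
    14: ("nap", "Take a nap earlier after a late-night shift to refresh."),
    15: ("nap", "Create a quiet, dark environment for daytime naps."),
    16: ("activity", "Make a habit of relaxing before sleep."),
    17: ("activity", "Use the wearable's guided breathing program."),
    18: ("activity", "Do moderate exercise regularly."),
    19: ("mentality", "Be broad-minded and approach things positively."),
    20: ("sleep", "Continue current sleep habits."),
    21: ("sleep", "Try to make enough time for sleep."),
    22: ("sleep", "Get up at the same time, working or on holiday."),
    23: ("nap", "Do not nap for too long."),
}

ALL_MESSAGE_IDS = tuple(sorted(MESSAGE_CATALOG))

CATEGORY_MESSAGES: dict[str, tuple[int, ...]] = {
    "dietary_intake": (1, 2, 3),
    "activity": (4, 5, 6, 16, 17, 18),
    "sleep": (7, 8, 9, 10, 20, 21, 22),
    "shift": (11,),
    "nap": (12, 13, 14, 15, 23),
    "mentality": (19,),
}

RESPONSES = ("none", "eager", "difficult")

#: messages frequent enough to model individually
DEFAULT_MODELED_MESSAGES = (4, 7, 12, 14, 15, 20, 21)


@dataclass(frozen=True)
class AdviceEvent:
    """One physician advice piece."""

    participant: str
    date: Date
    message_ids: frozenset[int] = field(default_factory=frozenset)
    response: str = "none"

    def __post_init__(self) -> None:
        if not 1 <= len(self.message_ids) <= 5:
            raise ValueError(
                f"advice piece must carry 1-5 messages, got {len(self.message_ids)}"
            )
        bad = self.message_ids - set(ALL_MESSAGE_IDS)
        if bad:
            raise ValueError(f"unknown message ids: {sorted(bad)}")
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")


def _message_sets(advice: pd.DataFrame) -> list[set[int]]:
    out = []
    for raw in advice["message_ids"]:
        if isinstance(raw, str):
            ids = {int(tok) for tok in raw.split("|") if tok}
        else:
            ids = set(raw)
        out.append(ids)
    return out


def advice_statistics(advice: pd.DataFrame) -> pd.DataFrame:
    """Per-message selection counts and proportions.

    Parameters
    ----------
    advice:
        Advice log with a ``message_ids`` column (pipe-delimited string or
        iterable of ints), one row per advice piece.

    Returns
    -------
    DataFrame indexed by message id with columns ``count``, ``n_pieces`` and
    ``selection_pct`` (share of advice pieces containing the message, in %).
    """
    sets = _message_sets(advice)
    n_pieces = len(sets)
    rows = []
    for mid in ALL_MESSAGE_IDS:
        count = sum(mid in s for s in sets)
        rows.append(
            {
                "message_id": mid,
                "count": count,
                "n_pieces": n_pieces,
                "selection_pct": 100.0 * count / n_pieces if n_pieces else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("message_id")


def category_statistics(advice: pd.DataFrame) -> pd.DataFrame:
    """Category-level share of the total number of message selections (%)."""
    per_message = advice_statistics(advice)
    total = int(per_message["count"].sum())
    rows = []
    for cat, mids in CATEGORY_MESSAGES.items():
        count = int(per_message.loc[list(mids), "count"].sum())
        rows.append(
            {
                "category": cat,
                "count": count,
                "total_selections": total,
                "share_pct": 100.0 * count / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def response_statistics(advice: pd.DataFrame) -> pd.DataFrame:
    """Per-message response breakdown over advice pieces containing the message.

    Returns counts and percentages of each response kind; ``difficult_pct`` is
    the difficulty rate among pieces that contain the message.
    """
    sets = _message_sets(advice)
    responses = list(advice["response"])
    rows = []
    for mid in ALL_MESSAGE_IDS:
        mask = [mid in s for s in sets]
        n = sum(mask)
        counts = {r: 0 for r in RESPONSES}
        for keep, resp in zip(mask, responses):
            if keep:
                counts[resp] += 1
        row: dict[str, float] = {"message_id": mid, "n_containing": n}
        for r in RESPONSES:
            row[f"{r}_count"] = counts[r]
            row[f"{r}_pct"] = 100.0 * counts[r] / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("message_id")
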