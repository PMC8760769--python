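"""Dominance rank order index from focal retreat records.

Each female is observed until she is involved in 30 retreat interactions per
phase (10 on each of three observation days). Her rank index is the fraction
of those interactions in which the *other* female retreated: 0 is completely
subdominant, 1 completely dominant.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .data import RankIndexRecord
from .errors import ProtocolError

log = logging.getLogger(__name__)

#: Retreats observed per focal female per phase under the protocol.
PROTOCOL_N_RETREATS = 30
#: Retreats per observation day.
PROTOCOL_PER_DAY = 10


def compute_rank_index(
    retreats: pd.DataFrame,
    focal_id: str,
    phase: int,
    strict: bool = True,
) -> RankIndexRecord:
    """Rank index for one focal female in one phase.

    index = (# interactions the focal won, i.e. the opponent retreated) / 30.

    In strict mode (default) the observation protocol is enforced: exactly 30
    records, 10 per day. In lenient mode the index is computed over whatever
    records exist, with a warning reporting the count.
    """
    sel = retreats[(retreats["focal_id"] == focal_id)
                   & (retreats["phase"] == phase)]
    n = len(sel)
    if strict:
        if n != PROTOCOL_N_RETREATS:
            raise ProtocolError(
                f"focal {focal_id!r} phase {phase}: expected "
                f"{PROTOCOL_N_RETREATS} retreat records, found {n}"
            )
        per_day = sel["day_index"].value_counts()
        if sorted(per_day.index) != [1, 2, 3] or (per_day != PROTOCOL_PER_DAY).any():
            raise ProtocolError(
                f"focal {focal_id!r} phase {phase}: expected "
                f"{PROTOCOL_PER_DAY} retreats on each of days 1-3, found "
                f"{per_day.to_dict()}"
            )
        denom = PROTOCOL_N_RETREATS
    else:
        if n == 0:
            raise ProtocolError(
                f"focal {focal_id!r} phase {phase}: no retreat records"
            )
        if n != PROTOCOL_N_RETREATS:
            log.warning(
                "focal %r phase %d: %d retreat records (protocol expects %d); "
                "index computed over available records",
                focal_id, phase, n, PROTOCOL_N_RETREATS,
            )
        denom = n
    wins = int(sel["focal_won"].sum())
    return RankIndexRecord(individual_id=focal_id, phase=phase,
                           index=wins / denom)


def rank_indices_for_group(
    retreats: pd.DataFrame,
    focal_ids: Iterable[str],
    phase: int,
    strict: bool = True,
) -> pd.DataFrame:
    """Rank indices for every female of a housing group in one phase.

    ``focal_ids`` lists the group's members; each must appear as a focal in
    the retreat records. Indices are independent focal-sampling estimates and
    need not sum to any constant.
    """
    focal_ids = list(focal_ids)
    observed = set(retreats.loc[retreats["phase"] == phase, "focal_id"])
    missing = [f for f in focal_ids if f not in observed]
    if missing:
        raise ProtocolError(
            f"phase {phase}: no retreat records for focal(s) {missing}"
        )
    records = [
        compute_rank_index(retreats, focal, phase, strict=strict)
        for focal in focal_ids
    ]
    return pd.DataFrame(
        [(r.individual_id, r.phase, r.index) for r in records],
        columns=["individual_id", "phase", "index"],
    )


def rank_indices_for_study(
    retreats: pd.DataFrame,
    group_of: dict,
    phases: Iterable[int] = (1, 2),
    strict: bool = True,
) -> pd.DataFrame:
    """Rank indices for all individuals and phases of a study."""
    frames = []
    groups: dict = {}
    for ind, grp in group_of.items():
        groups.setdefault(grp, []).append(ind)
    for phase in phases:
        for members in groups.values():
            frames.append(
                rank_indices_for_group(retreats, members, phase, strict=strict)
            )
    return pd.concat(frames, ignore_index=True)
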