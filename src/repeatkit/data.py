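"""Domain types for a repeated-measures dominance/endocrine study.

The study design modelled here: females housed in a small number of groups,
each individual measured in two (or more) phases. Each phase contributes one
stress-response test (body weights, age) with three plasma cortisol samples
(baseline, and responsiveness after 1 h and 2 h in a novel enclosure), one
dominance rank index per female, and optionally the raw dyadic retreat
records the index was computed from.

The canonical in-memory container is :class:`StudyDataset`, a set of pandas
DataFrames with fixed column schemas plus a validator enforcing the study's
structural invariants. The per-row dataclasses document the row schemas and
support record-wise construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError

#: Recognised cortisol sampling times, in within-test order.
SAMPLING_TIMES = ("baseline", "resp_1h", "resp_2h")

#: Valid measurement phases.
PHASES = (1, 2)


@dataclass(frozen=True)
class IndividualRecord:
    """One study animal: a female belonging to exactly one housing group."""

    individual_id: str
    group_id: str


@dataclass(frozen=True)
class CortisolSample:
    """One plasma cortisol measurement within a response test.

    ``concentration`` is in assay units per volume and must be positive.
    """

    individual_id: str
    phase: int
    sampling_time: str
    concentration: float


@dataclass(frozen=True)
class ResponseTestRecord:
    """Per-test covariates: age and body weights at start/end of the test."""

    individual_id: str
    phase: int
    age_days: float
    weight_start: float
    weight_end: float

    @property
    def weight_change_abs(self) -> float:
        return abs(self.weight_start - self.weight_end)


@dataclass(frozen=True)
class RetreatRecord:
    """One dyadic retreat interaction observed via focal sampling.

    ``focal_won`` is true when the opponent retreated from the focal female.
    """

    focal_id: str
    opponent_id: str
    phase: int
    day_index: int
    focal_won: bool


@dataclass(frozen=True)
class RankIndexRecord:
    """Dominance rank order index in [0, 1] for one (individual, phase)."""

    individual_id: str
    phase: int
    index: float


_TESTS_COLS = ["individual_id", "phase", "age_days", "weight_start",
               "weight_end", "weight_change_abs"]
_SAMPLES_COLS = ["individual_id", "phase", "sampling_time", "concentration"]
_RANK_COLS = ["individual_id", "phase", "index"]
_RETREAT_COLS = ["focal_id", "opponent_id", "phase", "day_index", "focal_won"]


@dataclass
class StudyDataset:
    """Validated long-format study records.

    Fields are pandas DataFrames with the column schemas documented by the
    record dataclasses above. ``retreats`` is optional: rank indices may be
    supplied precomputed.
    """

    individuals: pd.DataFrame
    tests: pd.DataFrame
    samples: pd.DataFrame
    rank_indices: pd.DataFrame
    retreats: Optional[pd.DataFrame] = None

    # ------------------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        individuals: Iterable[IndividualRecord],
        tests: Iterable[ResponseTestRecord],
        samples: Iterable[CortisolSample],
        rank_indices: Iterable[RankIndexRecord],
        retreats: Optional[Iterable[RetreatRecord]] = None,
        validate: bool = True,
    ) -> "StudyDataset":
        ind = pd.DataFrame(
            [(r.individual_id, r.group_id) for r in individuals],
            columns=["individual_id", "group_id"],
        )
        tst = pd.DataFrame(
            [(t.individual_id, t.phase, t.age_days, t.weight_start,
              t.weight_end, t.weight_change_abs) for t in tests],
            columns=_TESTS_COLS,
        )
        smp = pd.DataFrame(
            [(s.individual_id, s.phase, s.sampling_time, s.concentration)
             for s in samples],
            columns=_SAMPLES_COLS,
        )
        rnk = pd.DataFrame(
            [(r.individual_id, r.phase, r.index) for r in rank_indices],
            columns=_RANK_COLS,
        )
        ret = None
        if retreats is not None:
            ret = pd.DataFrame(
                [(r.focal_id, r.opponent_id, r.phase, r.day_index,
                  r.focal_won) for r in retreats],
                columns=_RETREAT_COLS,
            )
        ds = cls(ind, tst, smp, rnk, ret)
        if validate:
            ds.validate()
        return ds

    # ------------------------------------------------------------------
    def validate(self) -> "StudyDataset":
        """Check all structural invariants; raise on the first violation."""
        ind = self.individuals
        for frame, cols, name in [
            (ind, ["individual_id", "group_id"], "individuals"),
            (self.tests, _TESTS_COLS, "tests"),
            (self.samples, _SAMPLES_COLS, "samples"),
            (self.rank_indices, _RANK_COLS, "rank_indices"),
        ]:
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise SchemaError(
                    f"{name} table is missing column(s): {', '.join(missing)}"
                )

        if ind["individual_id"].duplicated().any():
            dup = ind.loc[ind["individual_id"].duplicated(), "individual_id"]
            raise IntegrityError(
                f"duplicate individual id(s): {sorted(set(dup))}"
            )
        known = set(ind["individual_id"])

        for frame, idcol, name in [
            (self.tests, "individual_id", "tests"),
            (self.samples, "individual_id", "samples"),
            (self.rank_indices, "individual_id", "rank_indices"),
        ]:
            unknown = set(frame[idcol]) - known
            if unknown:
                raise IntegrityError(
                    f"{name} references unknown individual(s): {sorted(unknown)}"
                )

        for frame, name in [(self.tests, "tests"), (self.samples, "samples"),
                            (self.rank_indices, "rank_indices")]:
            bad = set(frame["phase"]) - set(PHASES)
            if bad:
                raise IntegrityError(f"{name} has invalid phase(s): {sorted(bad)}")

        if self.tests.duplicated(["individual_id", "phase"]).any():
            raise IntegrityError("more than one test per (individual, phase)")
        if self.rank_indices.duplicated(["individual_id", "phase"]).any():
            raise IntegrityError("more than one rank index per (individual, phase)")

        bad_time = set(self.samples["sampling_time"]) - set(SAMPLING_TIMES)
        if bad_time:
            raise IntegrityError(f"unknown sampling_time(s): {sorted(bad_time)}")
        key = ["individual_id", "phase", "sampling_time"]
        if self.samples.duplicated(key).any():
            first = self.samples.loc[self.samples.duplicated(key), key].iloc[0]
            raise IntegrityError(
                "duplicate cortisol sample for "
                f"({first['individual_id']}, phase {first['phase']}, "
                f"{first['sampling_time']})"
            )
        if (self.samples["concentration"] <= 0).any():
            raise ValueError("cortisol concentrations must be strictly positive")

        wc = self.tests["weight_change_abs"].to_numpy(dtype=float)
        expect = np.abs(self.tests["weight_start"].to_numpy(dtype=float)
                        - self.tests["weight_end"].to_numpy(dtype=float))
        if not np.allclose(wc, expect, atol=1e-9):
            raise IntegrityError(
                "weight_change_abs != |weight_start - weight_end|"
            )
        if (wc < 0).any():
            raise IntegrityError("negative absolute weight change")

        idx = self.rank_indices["index"].to_numpy(dtype=float)
        if ((idx < 0) | (idx > 1)).any():
            raise IntegrityError("rank index outside [0, 1]")

        if self.retreats is not None:
            missing = [c for c in _RETREAT_COLS if c not in self.retreats.columns]
            if missing:
                raise SchemaError(
                    f"retreats table is missing column(s): {', '.join(missing)}"
                )
            ret = self.retreats
            if (ret["focal_id"] == ret["opponent_id"]).any():
                raise IntegrityError("retreat record with focal == opponent")
            grp = dict(zip(ind["individual_id"], ind["group_id"]))
            unknown = (set(ret["focal_id"]) | set(ret["opponent_id"])) - known
            if unknown:
                raise IntegrityError(
                    f"retreats reference unknown individual(s): {sorted(unknown)}"
                )
            cross = [
                (f, o) for f, o in zip(ret["focal_id"], ret["opponent_id"])
                if grp[f] != grp[o]
            ]
            if cross:
                raise IntegrityError(
                    f"retreat between different housing groups: {cross[0]}"
                )
        return self

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def group_of(self) -> dict:
        return dict(zip(self.individuals["individual_id"],
                        self.individuals["group_id"]))

    # ------------------------------------------------------------------
    def per_test_table(self) -> pd.DataFrame:
        """One row per (individual, phase): covariates, wide cortisol, rank.

        This is the 24-row analysis table of the standard 12-female, 2-phase
        design: columns ``individual_id, group_id, phase, age_days,
        weight_start, weight_end, weight_change_abs, cortisol_baseline,
        cortisol_resp_1h, cortisol_resp_2h, rank_index``.
        """
        wide = (
            self.samples.pivot_table(
                index=["individual_id", "phase"],
                columns="sampling_time",
                values="concentration",
                aggfunc="first",
            )
            .rename(columns={t: f"cortisol_{t}" for t in SAMPLING_TIMES})
            .reset_index()
        )
        wide.columns.name = None
        out = self.tests.merge(wide, on=["individual_id", "phase"], how="left")
        out = out.merge(
            self.rank_indices.rename(columns={"index": "rank_index"}),
            on=["individual_id", "phase"],
            how="left",
        )
        out = out.merge(self.individuals, on="individual_id", how="left")
        return out.sort_values(["individual_id", "phase"]).reset_index(drop=True)

    def long_cortisol_table(self) -> pd.DataFrame:
        """One row per cortisol sample with per-test covariates attached.

        The 72-row table (12 individuals x 2 phases x 3 sampling times in the
        standard design) used by the rank-cortisol random-slope model.
        """
        out = self.samples.merge(
            self.tests, on=["individual_id", "phase"], how="left"
        )
        out = out.merge(
            self.rank_indices.rename(columns={"index": "rank_index"}),
            on=["individual_id", "phase"],
            how="left",
        )
        out = out.merge(self.individuals, on="individual_id", how="left")
        out["sampling_time"] = pd.Categorical(
            out["sampling_time"], categories=list(SAMPLING_TIMES), ordered=True
        )
        out = out.sort_values(
            ["individual_id", "phase", "sampling_time"]
        ).reset_index(drop=True)
        out["sampling_time"] = out["sampling_time"].astype(str)
        return out
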