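"""End-to-end analysis of a study: repeatability table, fixed-effect
summaries, variance-component comparisons and the rank-cortisol model.

Given a validated :class:`~repeatkit.data.StudyDataset`, the pipeline fits,
in order:

1. Five adjusted-repeatability models, each with a residual-permutation p
   and a parametric-bootstrap SE/CI: log baseline cortisol, log cortisol
   responsiveness after 1 h and 2 h (each adjusted for rank index, body
   weight, measurement and housing group), the rank index itself (adjusted
   for age, body weight, measurement, group) and log absolute weight change
   during the test (adjusted for 2-h responsiveness, age, measurement,
   group).
2. Paired-bootstrap comparisons of the (mean-corrected) within- and
   between-individual variance components among the three cortisol traits.
3. A random-slope mixed model of untransformed cortisol concentration on
   sampling time, rank index, their interaction, body weight, measurement
   and group — individual intercept plus sampling-time slopes with
   unstructured covariance — summarised by its fixed-effect table,
   estimated marginal means per sampling time and all pairwise contrasts.

Continuous covariates are mean-centered within each model's analysis rows;
measurement is coded with the second phase as reference; no multiple-testing
adjustment is applied anywhere. Every stochastic stage is seeded from one
root seed, so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .data import SAMPLING_TIMES, StudyDataset
from .errors import RepeatkitError
from .lmm import (ContrastResult, EMMSet, FittedLMM, ModelSpec,
                  RandomStructure, categorical, continuous, emmeans,
                  fit_reml, fixed_effects_table, pairwise_contrasts)
from .repeatability import (BootstrapSamples, RepeatabilityResult,
                            estimate_repeatability)
from .varcomp import ComponentComparison, compare_all, mean_correct

log = logging.getLogger(__name__)

#: Traits analysed for adjusted repeatability, in report order.
REPEATABILITY_TRAITS = (
    "cortisol_baseline", "cortisol_resp_1h", "cortisol_resp_2h",
    "rank_index", "weight_change_abs",
)

CORTISOL_TRAITS = ("cortisol_baseline", "cortisol_resp_1h", "cortisol_resp_2h")

DEFAULT_TRANSFORMS = {
    "cortisol_baseline": "log",
    "cortisol_resp_1h": "log",
    "cortisol_resp_2h": "log",
    "rank_index": "identity",
    "weight_change_abs": "log",
}


class PipelineStageError(RepeatkitError):
    """A pipeline stage failed; partial outputs are preserved on .partial."""

    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial = partial


@dataclass
class PipelineConfig:
    """Tunable pipeline settings with the analysis defaults."""

    nperm: int = 500
    nboot: int = 1000
    alpha: float = 0.05
    seed: int = 0
    transforms: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    strict_protocol: bool = True
    #: "squared_mean" divides bootstrap variances by the squared model-scale
    #: trait mean before comparison; "none" compares raw components
    mean_correction: str = "squared_mean"
    #: grams added to zero weight changes before the log transform (half the
    #: decigram measurement resolution)
    zero_offset: float = 0.05
    schema: Optional[Dict[str, str]] = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.mean_correction not in ("squared_mean", "none"):
            raise ValueError(
                f"unknown mean_correction {self.mean_correction!r}"
            )


@dataclass
class ReportBundle:
    """All pipeline outputs, convertible to flat TSV-ready tables."""

    repeatability: List[RepeatabilityResult]
    comparisons: List[ComponentComparison]
    rank_fixed_effects: pd.DataFrame
    weight_fixed_effects: pd.DataFrame
    rank_cortisol_fit: FittedLMM
    rank_cortisol_fixed_effects: pd.DataFrame
    rank_cortisol_emmeans: EMMSet
    rank_cortisol_contrasts: List[ContrastResult]
    descriptives: pd.DataFrame
    bootstrap_samples: Dict[str, BootstrapSamples] = field(repr=False,
                                                           default=None)
    config: PipelineConfig = None

    def repeatability_table(self) -> pd.DataFrame:
        rows = [
            (r.trait, r.R, r.se, r.ci[0], r.ci[1], r.p_perm, r.nperm, r.nboot)
            for r in self.repeatability
        ]
        return pd.DataFrame(rows, columns=[
            "trait", "R", "SE", "CI_low", "CI_high", "p", "nperm", "nboot",
        ])

    def comparison_table(self) -> pd.DataFrame:
        rows = [
            (c.trait_a, c.trait_b, c.component, c.mean_diff, c.p_asym,
             c.p_display, c.n_pairs)
            for c in self.comparisons
        ]
        return pd.DataFrame(rows, columns=[
            "trait_a", "trait_b", "component", "mean_diff", "p_asym",
            "p_display", "n_pairs",
        ])

    def contrast_table(self) -> pd.DataFrame:
        rows = [
            (c.name, c.estimate, c.se, c.df, c.t_value, c.p_value)
            for c in self.rank_cortisol_contrasts
        ]
        return pd.DataFrame(rows, columns=[
            "contrast", "estimate", "se", "df", "t_value", "p_value",
        ])

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {
            "repeatability": self.repeatability_table(),
            "fixed_effects_rank_index": self.rank_fixed_effects,
            "fixed_effects_weight_change": self.weight_fixed_effects,
            "rank_cortisol_fixed_effects": self.rank_cortisol_fixed_effects,
            "rank_cortisol_emmeans": self.rank_cortisol_emmeans.to_frame(),
            "rank_cortisol_contrasts": self.contrast_table(),
            "varcomp_comparisons": self.comparison_table(),
            "descriptives": self.descriptives,
        }


# ----------------------------------------------------------------------
# model builders

def _common_factors() -> Tuple:
    return (categorical("measurement", reference="2"),
            categorical("group_id"))


def repeatability_spec(trait: str, transform: str) -> ModelSpec:
    """The adjusted-repeatability model for one trait."""
    if trait in CORTISOL_TRAITS:
        fixed = (continuous("rank_index"), continuous("weight_start"),
                 *_common_factors())
    elif trait == "rank_index":
        fixed = (continuous("age_days"), continuous("weight_start"),
                 *_common_factors())
    elif trait == "weight_change_abs":
        response_cov = "cortisol_resp_2h"
        fixed = (continuous(response_cov), continuous("age_days"),
                 *_common_factors())
    else:
        raise ValueError(f"no repeatability model defined for {trait!r}")
    return ModelSpec(
        response=trait if trait != "weight_change_abs" else "weight_change_pos",
        transform=transform,
        fixed=fixed,
        group="individual_id",
        random=RandomStructure("intercept"),
    )


def rank_cortisol_spec() -> ModelSpec:
    """Untransformed cortisol on sampling time x rank, random slopes."""
    return ModelSpec(
        response="concentration",
        transform="identity",
        fixed=(
            categorical("sampling_time", reference="baseline"),
            continuous("rank_index"),
            continuous("weight_start"),
            categorical("measurement", reference="2"),
            categorical("group_id"),
        ),
        interactions=(("sampling_time", "rank_index"),),
        group="individual_id",
        random=RandomStructure("slope", factor="sampling_time"),
    )


def analysis_frames(dataset: StudyDataset,
                    config: Optional[PipelineConfig] = None):
    """(per_test, long) model-ready frames for a study.

    Adds the ``measurement`` factor (phase as a category) and the
    zero-offset weight-change column the repeatability models consume.
    """
    config = config or PipelineConfig()
    per_test = dataset.per_test_table().copy()
    per_test["measurement"] = per_test["phase"].astype(str)
    wc = per_test["weight_change_abs"].to_numpy(dtype=float)
    per_test["weight_change_pos"] = np.where(
        wc == 0.0, config.zero_offset, wc
    )
    long = dataset.long_cortisol_table().copy()
    long["measurement"] = long["phase"].astype(str)
    return per_test, long


_analysis_frames = analysis_frames


# ----------------------------------------------------------------------
# pipeline stages

def descriptives(dataset: StudyDataset) -> pd.DataFrame:
    """Per-group mean and SD of start weight and weight lost, across tests.

    Groups with a single test report SD as NaN (undefined), never zero.
    """
    per_test = dataset.per_test_table()
    out = (
        per_test.groupby("group_id")
        .agg(
            start_weight_mean=("weight_start", "mean"),
            start_weight_sd=("weight_start", lambda s: s.std(ddof=1)),
            weight_loss_mean=("weight_change_abs", "mean"),
            weight_loss_sd=("weight_change_abs", lambda s: s.std(ddof=1)),
        )
        .reset_index()
    )
    return out


def run_full_analysis(dataset: StudyDataset,
                      config: Optional[PipelineConfig] = None) -> ReportBundle:
    """Run the complete analysis; see the module docstring for the stages."""
    config = config or PipelineConfig()
    partial: dict = {}
    stage = "prepare"
    try:
        per_test, long = _analysis_frames(dataset, config)
        ss = np.random.SeedSequence(config.seed).spawn(
            len(REPEATABILITY_TRAITS) + 1)

        # -- stage 1: adjusted repeatability per trait -------------------
        results: List[RepeatabilityResult] = []
        boot: Dict[str, BootstrapSamples] = {}
        fits: Dict[str, FittedLMM] = {}
        for k, trait in enumerate(REPEATABILITY_TRAITS):
            stage = f"repeatability:{trait}"
            spec = repeatability_spec(trait, config.transforms[trait])
            log.info("stage %s (nperm=%d nboot=%d)", stage,
                     config.nperm, config.nboot)
            res = estimate_repeatability(
                per_test, spec, nperm=config.nperm, nboot=config.nboot,
                seed=ss[k], trait=trait,
            )
            results.append(res)
            boot[trait] = res.samples
            fits[trait] = res.fit
            partial["repeatability"] = results

        # -- stage 2: variance-component comparisons --------------------
        stage = "varcomp_compare"
        log.info("stage %s (%s correction)", stage, config.mean_correction)
        cort_samples = {}
        for trait in CORTISOL_TRAITS:
            s = boot[trait]
            if config.mean_correction == "squared_mean":
                spec = repeatability_spec(trait, config.transforms[trait])
                yvals = per_test[trait].to_numpy(dtype=float)
                m = float(np.mean(np.log(yvals))
                          if spec.transform == "log" else np.mean(yvals))
                s = mean_correct(s, m)
            cort_samples[trait] = s
        comparisons = compare_all(cort_samples)
        partial["comparisons"] = comparisons

        # -- stage 3: fixed-effect tables for the per-test models -------
        stage = "fixed_effects_tables"
        rank_fe = fixed_effects_table(fits["rank_index"])
        weight_fe = fixed_effects_table(fits["weight_change_abs"])
        partial["rank_fixed_effects"] = rank_fe
        partial["weight_fixed_effects"] = weight_fe

        # -- stage 4: rank-cortisol random-slope model -------------------
        stage = "rank_cortisol_model"
        log.info("stage %s", stage)
        rc_fit = fit_reml(long, rank_cortisol_spec(),
                          random_state=int(ss[-1].generate_state(1)[0] % (2**31)))
        rc_fe = fixed_effects_table(rc_fit)
        emms = emmeans(rc_fit, "sampling_time")
        contrasts = pairwise_contrasts(emms)
        partial["rank_cortisol_fit"] = rc_fit

        stage = "descriptives"
        desc = descriptives(dataset)
    except RepeatkitError:
        raise
    except Exception as exc:           # noqa: BLE001 - annotate stage
        raise PipelineStageError(stage, exc, partial) from exc

    return ReportBundle(
        repeatability=results,
        comparisons=comparisons,
        rank_fixed_effects=rank_fe,
        weight_fixed_effects=weight_fe,
        rank_cortisol_fit=rc_fit,
        rank_cortisol_fixed_effects=rc_fe,
        rank_cortisol_emmeans=emms,
        rank_cortisol_contrasts=contrasts,
        descriptives=desc,
        bootstrap_samples=boot,
        config=config,
    )
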