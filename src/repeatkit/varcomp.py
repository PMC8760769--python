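"""Paired-bootstrap comparison of variance components across traits.

Each trait's parametric bootstrap yields replicate (v_between, v_within)
pairs. To ask whether, say, the within-individual variance of one trait
exceeds that of another, replicates are paired by index, the per-replicate
difference is formed, and an asymptotic two-tailed p-value is computed as
twice the smaller tail proportion of differences below/above zero. Exact
zero differences are split half to each tail, so comparing a sample set
with itself gives p = 1.

Traits measured on different scales are made comparable by mean correction:
each replicate variance is divided by the squared trait mean on the model
scale (a CV^2-style scaling), which leaves every p-value invariant when both
traits of a pair are scaled by equal means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List

import numpy as np

from .errors import ConfigurationError
from .repeatability import BootstrapSamples

COMPONENTS = ("within", "between")


@dataclass(frozen=True)
class ComponentComparison:
    """Paired-bootstrap difference of one variance component, a minus b."""

    trait_a: str
    trait_b: str
    component: str               # "within" | "between"
    mean_diff: float
    p_asym: float
    n_pairs: int

    @property
    def p_display(self) -> str:
        """p formatted for reporting; an exact zero is a resolution bound."""
        if self.p_asym == 0.0:
            return f"< {2.0 / self.n_pairs:.4g}"
        return f"{self.p_asym:.4g}"


def mean_correct(samples: BootstrapSamples, trait_mean: float) -> BootstrapSamples:
    """Scale replicate variances by the squared trait mean (model scale).

    R is a variance ratio and is unchanged. ``trait_mean`` must be nonzero.
    """
    if trait_mean == 0:
        raise ConfigurationError("mean correction requires a nonzero trait mean")
    m2 = float(trait_mean) ** 2
    return replace(
        samples,
        v_between=samples.v_between / m2,
        v_within=samples.v_within / m2,
    )


def compare_components(
    a: BootstrapSamples, b: BootstrapSamples, component: str,
    trait_a: str = "a", trait_b: str = "b",
) -> ComponentComparison:
    """Compare one variance component between two traits.

    Replicates are paired by index over the first min(len(a), len(b))
    replicates; p_asym = 2 * min(P(d < 0), P(d > 0)) with zero differences
    split half to each tail, capped at 1.
    """
    xa = np.asarray(a.component(component), dtype=float)
    xb = np.asarray(b.component(component), dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ConfigurationError("empty bootstrap sample set")
    n = min(xa.size, xb.size)
    d = xa[:n] - xb[:n]
    ties = float(np.count_nonzero(d == 0.0))
    below = float(np.count_nonzero(d < 0.0)) + 0.5 * ties
    above = float(np.count_nonzero(d > 0.0)) + 0.5 * ties
    p = min(2.0 * min(below, above) / n, 1.0)
    return ComponentComparison(
        trait_a=trait_a, trait_b=trait_b, component=component,
        mean_diff=float(d.mean()), p_asym=float(p), n_pairs=int(n),
    )


def compare_all(
    trait_samples: Dict[str, BootstrapSamples],
    components: Iterable[str] = COMPONENTS,
) -> List[ComponentComparison]:
    """All unordered trait pairs x requested components.

    Pair order follows the mapping's listed trait order, so the sign of
    mean_diff is reproducible.
    """
    names = list(trait_samples)
    if len(names) < 2:
        raise ConfigurationError("need at least two traits to compare")
    out = []
    for na, nb in itertools.combinations(names, 2):
        for comp in components:
            if comp not in COMPONENTS:
                raise ConfigurationError(f"unknown component {comp!r}")
            out.append(compare_components(
                trait_samples[na], trait_samples[nb], comp,
                trait_a=na, trait_b=nb,
            ))
    return out
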