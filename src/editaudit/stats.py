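"""Poisson null model and multi-proportion significance testing.

The null expectation for unintended mutations is a Poisson accumulation
process: with a per-genome mutation rate mu_g per generation and g cell
divisions, the expected fraction of clones carrying at least one mutation
is 1 - exp(-mu_g * g) (a linear approximation mu_g * g is available for
comparison).  Observed per-protocol proportions are compared with a
k-proportion chi-square test (df = k - 1) followed by the Marascuilo
post-hoc procedure, whose pairwise critical range at family-wise level
alpha is

    CR_ij = sqrt(chi2_{1-alpha, k-1}) * sqrt(p_i(1-p_i)/n_i + p_j(1-p_j)/n_j)

with the pair declared significant when |p_i - p_j| > CR_ij.  The
"adjusted p" reported per pair is the minimal family-wise alpha at which
the pair's flag flips, found by bisection on the (monotone) flag boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .records import CloneRecord, GroupCounts

#: E. coli K-12 point estimate from mutation-accumulation experiments
MU_NT_PER_GENERATION = 2.0e-10
GENOME_LENGTH_MG1655 = 4_641_652


@dataclass(frozen=True)
class NullModel:
    mu_nt: float
    genome_length: int

    @property
    def mu_genome(self) -> float:
        return per_genome_rate(self.mu_nt, self.genome_length)

    def expected_fraction(self, generations: float, model: str = "poisson") -> float:
        return expected_fraction(self.mu_genome, generations, model)


@dataclass(frozen=True)
class PairResult:
    label_i: str
    label_j: str
    abs_difference: float
    critical_range: float
    significant: bool
    min_alpha: float


@dataclass(frozen=True)
class MarascuiloResult:
    chi2: float
    df: int
    p_value: float
    alpha: float
    pairs: tuple[PairResult, ...]

    def pair(self, label_i: str, label_j: str) -> PairResult:
        want = {label_i, label_j}
        for p in self.pairs:
            if {p.label_i, p.label_j} == want:
                return p
        raise KeyError(f"no pair {label_i} vs {label_j}")


def per_genome_rate(mu_nt: float, genome_length: int) -> float:
    """Per-genome per-generation mutation rate mu_g = mu * L."""
    if mu_nt < 0 or genome_length < 0:
        raise ValueError("rate and genome length must be non-negative")
    return mu_nt * genome_length


def round_sig(x: float, digits: int = 2) -> float:
    """Round to significant figures, as rates are reported in summaries."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def expected_fraction(
    mu_genome: float, generations: float, model: str = "poisson"
) -> float:
    """Expected fraction of clones with >=1 unintended mutation."""
    if mu_genome < 0 or generations < 0:
        raise ValueError("arguments must be non-negative")
    lam = mu_genome * generations
    if model == "poisson":
        return 1.0 - math.exp(-lam)
    if model == "linear":
        return min(lam, 1.0)
    raise ValueError(f"unknown null model {model!r}")


def estimate_mu_genome(fraction_mutated: float, generations: float) -> float:
    """Invert the Poisson null: mu_g = -ln(1 - f) / g."""
    if not 0 <= fraction_mutated < 1:
        raise ValueError("fraction must be in [0, 1)")
    if generations <= 0:
        raise ValueError("generations must be positive")
    return -math.log1p(-fraction_mutated) / generations


def group_summary(clones: Sequence[CloneRecord]) -> dict[str, GroupCounts]:
    """Count clones with >=1 unintended mutation per protocol group."""
    if not clones:
        raise ValueError("no clones supplied")
    by_label: dict[str, list[CloneRecord]] = {}
    for c in clones:
        by_label.setdefault(c.group_label, []).append(c)
    return {
        label: GroupCounts(
            label=label,
            n_clones=len(members),
            n_with_mutation=sum(c.has_unintended for c in members),
        )
        for label, members in by_label.items()
    }


def chi_square_proportions(
    groups: Sequence[GroupCounts],
) -> tuple[float, int, float]:
    """k-proportion chi-square against the pooled proportion (df = k-1)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.n_clones for g in groups], dtype=float)
    xs = np.array([g.n_with_mutation for g in groups], dtype=float)
    pooled = xs.sum() / ns.sum()
    df = len(groups) - 1
    if pooled in (0.0, 1.0):
        return 0.0, df, 1.0
    ps = xs / ns
    chi2 = float((ns * (ps - pooled) ** 2).sum() / (pooled * (1 - pooled)))
    return chi2, df, float(sps.chi2.sf(chi2, df))


def _critical_range(
    gi: GroupCounts, gj: GroupCounts, alpha: float, df: int
) -> float:
    var = (
        gi.proportion * (1 - gi.proportion) / gi.n_clones
        + gj.proportion * (1 - gj.proportion) / gj.n_clones
    )
    return math.sqrt(sps.chi2.ppf(1 - alpha, df)) * math.sqrt(var)


def _min_alpha(
    gi: GroupCounts, gj: GroupCounts, df: int, tol: float = 1e-10
) -> float:
    """Smallest family-wise alpha at which the pair is significant, by
    bisection on the monotone significance flag."""
    diff = abs(gi.proportion - gj.proportion)
    lo, hi = 0.0, 1.0

    def significant(alpha: float) -> bool:
        return diff > _critical_range(gi, gj, alpha, df)

    if diff == 0:
        return 1.0
    if not significant(1.0 - tol):
        return 1.0
    if significant(tol):
        return 0.0
    lo, hi = tol, 1.0 - tol  # not significant at lo, significant at hi
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if significant(mid):
            hi = mid
        else:
            lo = mid
    return hi


def marascuilo(
    groups: Sequence[GroupCounts], alpha: float = 0.05
) -> MarascuiloResult:
    """Marascuilo post-hoc pairwise comparison of k proportions."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    chi2, df, p = chi_square_proportions(groups)
    pairs = []
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            diff = abs(gi.proportion - gj.proportion)
            cr = _critical_range(gi, gj, alpha, df)
            pairs.append(
                PairResult(
                    label_i=gi.label,
                    label_j=gj.label,
                    abs_difference=diff,
                    critical_range=cr,
                    significant=diff > cr,
                    min_alpha=_min_alpha(gi, gj, df),
                )
            )
    return MarascuiloResult(
        chi2=chi2, df=df, p_value=p, alpha=alpha, pairs=tuple(pairs)
    )
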