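"""RNAi screen scoring: per-shRNA growth-deficit calls and per-gene ranking.

The proliferation readout is the fold change in absorbance between day 0
and the endpoint (default day 10).  An shRNA is called a deficit when its
replicate fold changes are significantly lower (Welch two-tailed t-test,
p < alpha) than BOTH the empty-vector and non-targeting controls, and the
mean fold change is below both control means.  Genes are ranked by the
number of their shRNAs (out of 5) called as deficits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import ttest_ind

from .core_io import GrowthCurve

__all__ = [
    "ScreenConfig",
    "ShrnaCall",
    "ScreenResult",
    "fold_change",
    "deficit_call",
    "score_screen",
    "rank_genes",
]


@dataclass(frozen=True)
class ScreenConfig:
    endpoint_day: int = 10
    alpha: float = 0.05
    controls: tuple[str, ...] = ("shEV", "shNT")
    require_decrease: bool = True
    require_all_controls: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class ShrnaCall:
    construct: str
    gene: str
    mean_fold_change: float
    pvalues: dict[str, float]
    deficit: bool


@dataclass(frozen=True)
class ScreenResult:
    gene: str
    calls: tuple[ShrnaCall, ...]
    n_deficit: int
    mean_fold_change: float


def fold_change(curve: GrowthCurve, endpoint_day: int = 10) -> float:
    """Endpoint absorbance over day-0 absorbance for one replicate curve."""
    try:
        start = curve.absorbance_at(0)
        end = curve.absorbance_at(endpoint_day)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    return end / start


def deficit_call(
    shrna_fcs: Sequence[float],
    control_fcs: Mapping[str, Sequence[float]],
    config: ScreenConfig = ScreenConfig(),
) -> tuple[bool, dict[str, float]]:
    """Welch t-test of shRNA fold changes against each control group.

    Deficit requires p < alpha and a lower mean against every control
    (``require_all_controls``) or any control when relaxed.
    """
    if len(shrna_fcs) < 2 or any(len(v) < 2 for v in control_fcs.values()):
        raise ValueError("need >= 2 replicates per group for a t-test")
    pvalues: dict[str, float] = {}
    beaten: list[bool] = []
    for label, fcs in control_fcs.items():
        stat = ttest_ind(list(shrna_fcs), list(fcs), equal_var=False)
        pvalues[label] = float(stat.pvalue)
        lower = np.mean(shrna_fcs) < np.mean(fcs) if config.require_decrease else True
        beaten.append(stat.pvalue < config.alpha and lower)
    deficit = all(beaten) if config.require_all_controls else any(beaten)
    return deficit, pvalues


def score_screen(
    curves: Sequence[GrowthCurve], config: ScreenConfig = ScreenConfig()
) -> list[ScreenResult]:
    """Group curves by construct, call deficits, aggregate per gene."""
    fcs_by_construct: dict[str, list[float]] = {}
    gene_of: dict[str, str] = {}
    for c in curves:
        fcs_by_construct.setdefault(c.construct, []).append(
            fold_change(c, config.endpoint_day)
        )
        gene_of[c.construct] = c.gene
    missing = [ctrl for ctrl in config.controls if ctrl not in fcs_by_construct]
    if missing:
        raise ValueError(f"missing control constructs: {missing}")
    control_fcs = {ctrl: fcs_by_construct[ctrl] for ctrl in config.controls}

    calls_by_gene: dict[str, list[ShrnaCall]] = {}
    for construct in sorted(fcs_by_construct):
        if construct in config.controls:
            continue
        fcs = fcs_by_construct[construct]
        deficit, pvalues = deficit_call(fcs, control_fcs, config)
        call = ShrnaCall(
            construct=construct,
            gene=gene_of[construct],
            mean_fold_change=float(np.mean(fcs)),
            pvalues=pvalues,
            deficit=deficit,
        )
        calls_by_gene.setdefault(gene_of[construct], []).append(call)

    results = []
    for gene, calls in calls_by_gene.items():
        results.append(
            ScreenResult(
                gene=gene,
                calls=tuple(calls),
                n_deficit=sum(c.deficit for c in calls),
                mean_fold_change=float(np.mean([c.mean_fold_change for c in calls])),
            )
        )
    return results


def rank_genes(results: Sequence[ScreenResult]) -> list[ScreenResult]:
    """Descending by number of deficit shRNAs; ties by stronger growth
    deficit (lower mean fold change), then gene id."""
    return sorted(
        results, key=lambda r: (-r.n_deficit, r.mean_fold_change, r.gene)
    )
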