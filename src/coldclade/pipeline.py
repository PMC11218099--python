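"""End-to-end orchestration: metrics + tree -> contrasts -> ecotype calls."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .contrasts import ContrastResult, dual_contrast
from .ecotype import EcotypeCall, classify_group
from .phylo import GroupedPhylogeny

__all__ = ["GroupClassification", "classify_polar_groups"]

TEMPERATURE_METRICS = ("t_min", "t_opt", "t_max")


@dataclass
class GroupClassification:
    call: EcotypeCall
    genotype: tuple[ContrastResult, ContrastResult]
    phenotype: dict[str, ContrastResult]
    gc: tuple[ContrastResult, ContrastResult] | None = None
    all_contrasts: list[ContrastResult] = field(default_factory=list)


def classify_polar_groups(
    metrics: pd.DataFrame,
    phylogeny: GroupedPhylogeny,
    focal_groups: list[str] | None = None,
    alpha: float = 0.05,
    phenotype_rule: str = "topt-plus-one",
    genotype_metric: str = "arg_lys_ratio",
    gc_metric: str = "gc_genome",
    neighbour_overrides: dict[str, list[str]] | None = None,
) -> dict[str, GroupClassification]:
    """Run the dual-baseline contrasts and classify every focal group.

    GC contrasts are computed and reported when the column is present but
    never enter the call.  ``neighbour_overrides`` pins hand-enumerated
    clade-neighbour baselines per group.
    """
    if focal_groups is None:
        focal_groups = sorted(
            {g for g in phylogeny.groups.values() if g not in {"nonpolar", "outgroup"}}
        )
    overrides = neighbour_overrides or {}
    out: dict[str, GroupClassification] = {}
    for group in focal_groups:
        kwargs = dict(alpha=alpha, neighbour_override=overrides.get(group))
        genotype = dual_contrast(metrics, phylogeny, group, genotype_metric, **kwargs)
        phenotype = {
            m: dual_contrast(metrics, phylogeny, group, m, **kwargs)[0]
            for m in TEMPERATURE_METRICS
            if m in metrics.columns
        }
        gc = (
            dual_contrast(metrics, phylogeny, group, gc_metric, **kwargs)
            if gc_metric in metrics.columns
            else None
        )
        call = classify_group(genotype, phenotype, alpha=alpha, phenotype_rule=phenotype_rule)
        contrasts = [*genotype, *phenotype.values(), *(gc or ())]
        out[group] = GroupClassification(call, genotype, phenotype, gc, contrasts)
    return out
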