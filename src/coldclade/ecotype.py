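"""Genotype x phenotype ecotype classification and trait prevalence.

A polar group is called *genetically cold-adapted* only when its
genotype proxy (genome-wide Arg/Lys ratio) drops significantly against
BOTH baselines — all non-polar genomes and the group's own clade
neighbours — and its growth-temperature phenotype is also shifted down.
A phenotype shift without the dual genotype signal is *plastic only*:
survival by phenotypic plasticity, not genetic adaptation.  GC contrasts
are reported alongside but deliberately excluded from the call, since GC
is an unvalidated cold proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .contrasts import ContrastResult

__all__ = [
    "EcotypeClass",
    "EcotypeCall",
    "classify_group",
    "classify_from_signals",
    "trait_prevalence",
]


class EcotypeClass(str, Enum):
    GENETIC_COLD_ADAPTED = "GENETIC_COLD_ADAPTED"
    PLASTIC_ONLY = "PLASTIC_ONLY"
    NO_COLD_ADAPTATION = "NO_COLD_ADAPTATION"
    INSUFFICIENT_DATA = "INSUFFICIENT_DATA"


@dataclass
class EcotypeCall:
    group_label: str
    call: EcotypeClass
    evidence: dict = field(default_factory=dict)


def classify_from_signals(
    genotype_vs_all: bool | None,
    genotype_vs_neighbours: bool | None,
    phenotype_vs_all: bool | None,
    group_label: str = "",
) -> EcotypeCall:
    """Pure truth table over the three evidence booleans.

    ``None`` marks an unavailable required contrast and forces
    INSUFFICIENT_DATA.  Otherwise: genotype = both genotype signals;
    genotype and phenotype -> GENETIC_COLD_ADAPTED; phenotype alone ->
    PLASTIC_ONLY; no phenotype -> NO_COLD_ADAPTATION.
    """
    evidence = {
        "genotype_vs_all": genotype_vs_all,
        "genotype_vs_neighbours": genotype_vs_neighbours,
        "phenotype_vs_all": phenotype_vs_all,
    }
    if any(v is None for v in evidence.values()):
        return EcotypeCall(group_label, EcotypeClass.INSUFFICIENT_DATA, evidence)
    genotype = genotype_vs_all and genotype_vs_neighbours
    if not phenotype_vs_all:
        call = EcotypeClass.NO_COLD_ADAPTATION
    elif genotype:
        call = EcotypeClass.GENETIC_COLD_ADAPTED
    else:
        call = EcotypeClass.PLASTIC_ONLY
    return EcotypeCall(group_label, call, evidence)


def _sig(c: ContrastResult | None) -> bool | None:
    if c is None or not c.available:
        return None
    return bool(c.significant and c.direction == "decrease")


def classify_group(
    genotype: tuple[ContrastResult, ContrastResult],
    phenotype: dict[str, ContrastResult],
    alpha: float = 0.05,
    phenotype_rule: str = "topt-plus-one",
) -> EcotypeCall:
    """Combine Arg/Lys and growth-temperature contrasts into one call.

    ``genotype`` is the (vs all non-polar, vs clade neighbours) pair for
    the Arg/Lys ratio; ``phenotype`` maps ``t_min``/``t_opt``/``t_max``
    to their vs-all-non-polar contrasts.  The default phenotype rule
    requires a significant t_opt decrease plus at least one of
    t_min/t_max (``all`` demands all three), a slight relaxation so a
    single noisy temperature cannot flip a call.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if phenotype_rule not in {"topt-plus-one", "all"}:
        raise ValueError(f"unknown phenotype rule {phenotype_rule!r}")
    vs_all, vs_nb = genotype
    g_all, g_nb = _sig(vs_all), _sig(vs_nb)
    temps = {k: _sig(phenotype.get(k)) for k in ("t_min", "t_opt", "t_max")}
    if any(v is None for v in temps.values()):
        phen: bool | None = None
    elif phenotype_rule == "all":
        phen = all(temps.values())
    else:
        phen = temps["t_opt"] and (temps["t_min"] or temps["t_max"])
    group = vs_all.focal_group if vs_all is not None else ""
    call = classify_from_signals(g_all, g_nb, phen, group_label=group)
    call.evidence.update(
        {
            "n_focal": vs_all.n_focal if vs_all is not None else 0,
            "phenotype_rule": phenotype_rule,
            "temperature_signals": temps,
            "alpha": alpha,
        }
    )
    return call


def trait_prevalence(
    traits: pd.DataFrame,
    groups: dict[str, str],
    cycles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-reaction prevalence and per-group positivity flags.

    ``traits`` is a boolean reactions x genomes table.  The output has
    one row per reaction with the fraction of genomes positive and, per
    group, a flag 'all'/'some'/'none'; rows are ordered by cycle label
    then reaction id.
    """
    tr = traits.astype(bool)
    group_members = {}
    for g in sorted(set(groups.values())):
        members = [m for m, lab in groups.items() if lab == g and m in tr.columns]
        if not members:
            raise ValueError(f"group {g!r} has zero genomes in the trait table")
        group_members[g] = members
    rows = []
    for reaction in tr.index:
        present = tr.loc[reaction]
        row = {
            "reaction": reaction,
            "cycle": (cycles or {}).get(reaction, ""),
            "n_positive": int(present.sum()),
            "n_genomes": int(present.size),
            "fraction": float(present.mean()),
        }
        for g, members in group_members.items():
            sub = present[members]
            row[f"{g}_flag"] = "all" if sub.all() else ("some" if sub.any() else "none")
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values(["cycle", "reaction"], kind="stable")
        .reset_index(drop=True)
    )
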