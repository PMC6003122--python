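"""Cohort stratification and stratified network comparisons.

Two rule shapes are supported, mirroring the study's contrasts:

* group rules — merge a set of group labels into one stratum and compare it
  with the remaining subjects (e.g. merged smoker + never-smoker controls
  vs COPD);
* cut rules — dichotomize on a variable at a threshold, the upper stratum
  closed (value >= cut) and the lower strict (value < cut), matching the
  "< 60 or >= 60" convention (DLCO 60% ref, 300 eosinophils/uL,
  45 pack-years).

Subjects missing the cut variable are excluded and counted, never imputed.
All strata keep the full variable roster; pairs unusable within a stratum
are carried as invalid by the correlation engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, CohortValidationError
from .metrics import NetworkComparison, compare_networks, metrics_report
from .network import MultiLevelNetwork, build_network
from .correlation import SpearmanCorrelation
from .subsample import SubsampleConfig, consensus_network, subsample_consensus

__all__ = ["StratificationRule", "StratifiedSplit", "split_cohort",
           "StratifiedAnalysis", "stratified_networks"]


@dataclass(frozen=True)
class StratificationRule:
    """Either a group-label merge or a variable dichotomy.

    Exactly one of ``groups`` (a set of group labels) or
    (``variable``, ``cut``) must be given.  ``side`` names which stratum
    carries the closed bound and is fixed to ``"ge"``: the upper stratum is
    value >= cut.
    """

    name: str
    groups: frozenset = None
    variable: str = None
    cut: float = None
    side: str = "ge"

    def __post_init__(self):
        if not self.name:
            raise CohortValidationError("rule needs a name")
        if self.groups is not None:
            object.__setattr__(self, "groups", frozenset(self.groups))
            if not self.groups:
                raise CohortValidationError(f"rule {self.name!r}: empty group set")
            if self.variable is not None or self.cut is not None:
                raise CohortValidationError(
                    f"rule {self.name!r}: give either groups or a variable cut"
                )
        else:
            if self.variable is None or self.cut is None:
                raise CohortValidationError(
                    f"rule {self.name!r}: needs groups or (variable, cut)"
                )
            if self.side not in ("ge", "lt"):
                raise CohortValidationError(
                    f"rule {self.name!r}: side must be 'ge' or 'lt'"
                )

    @property
    def is_group_rule(self) -> bool:
        return self.groups is not None


@dataclass(frozen=True)
class StratifiedSplit:
    """Partition of retained subjects into labelled strata."""

    rule: StratificationRule
    strata: tuple[tuple[str, CohortTable], ...]
    n_excluded: int

    def __getitem__(self, label: str) -> CohortTable:
        for lab, c in self.strata:
            if lab == label:
                return c
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [lab for lab, _ in self.strata]

    def items(self):
        return list(self.strata)


def split_cohort(cohort: CohortTable, rule: StratificationRule) -> StratifiedSplit:
    """Split a cohort by a stratification rule.

    Group rules yield the merged selected stratum (named after the rule) and
    the complement (named after the remaining group labels).  Cut rules yield
    ``<var>_lt<cut>`` and ``<var>_ge<cut>`` strata; subjects missing the cut
    variable are excluded and counted in ``n_excluded``.  Any empty stratum
    raises, naming the rule.
    """
    if rule.is_group_rule:
        present = set(cohort.groups.unique())
        unknown = rule.groups - present
        if unknown:
            raise CohortValidationError(
                f"rule {rule.name!r}: groups not in cohort: {sorted(unknown)}"
            )
        sel = cohort.groups.isin(rule.groups)
        rest_labels = sorted(present - rule.groups)
        if not rest_labels:
            raise CohortValidationError(
                f"rule {rule.name!r} selects every group; no second stratum"
            )
        rest_name = "_".join(rest_labels)
        parts = [(rule.name, sel.to_numpy()),
                 (rest_name, (~sel).to_numpy())]
        n_excluded = 0
    else:
        if rule.variable not in cohort.variables:
            raise CohortValidationError(
                f"rule {rule.name!r}: unknown variable {rule.variable!r}"
            )
        vals = cohort.data[rule.variable].to_numpy(dtype=float)
        known = np.isfinite(vals)
        n_excluded = int((~known).sum())
        cut = float(rule.cut)
        ge = known & (vals >= cut)
        lt = known & (vals < cut)
        tag = f"{cut:g}"
        parts = [(f"{rule.variable}_lt{tag}", lt),
                 (f"{rule.variable}_ge{tag}", ge)]
    strata = []
    for label, mask in parts:
        if not mask.any():
            raise CohortValidationError(
                f"rule {rule.name!r}: stratum {label!r} is empty"
            )
        strata.append((label, cohort.select_subjects(mask)))
    return StratifiedSplit(rule=rule, strata=tuple(strata),
                           n_excluded=n_excluded)


@dataclass(frozen=True)
class StratifiedAnalysis:
    """Networks and comparisons for a set of stratification rules."""

    pooled: MultiLevelNetwork
    splits: tuple[tuple[str, StratifiedSplit], ...]
    networks: tuple[tuple[str, tuple[tuple[str, MultiLevelNetwork], ...]], ...]
    consensus: tuple[tuple[str, tuple[tuple[str, MultiLevelNetwork], ...]], ...]
    comparisons: tuple[tuple[str, tuple[tuple[str, str, NetworkComparison], ...]], ...]

    def rule_networks(self, rule_name: str) -> dict[str, MultiLevelNetwork]:
        for name, nets in self.networks:
            if name == rule_name:
                return dict(nets)
        raise KeyError(rule_name)

    def rule_comparisons(self, rule_name: str):
        for name, comps in self.comparisons:
            if name == rule_name:
                return list(comps)
        raise KeyError(rule_name)


def stratified_networks(
    cohort: CohortTable,
    rules,
    p_threshold: float = 0.01,
    equalize: SubsampleConfig | None = None,
    min_n: int = 5,
    k: int = 5,
) -> StratifiedAnalysis:
    """Build the pooled network plus per-rule stratum networks and comparisons.

    With no rules, only the pooled all-participants network is produced.
    When ``equalize`` is given, each stratum also gets an equal-n subsampling
    consensus network, and comparisons use the consensus networks (raw
    networks are always available).  Output ordering is deterministic.
    """
    pooled_corr = SpearmanCorrelation(min_n=min_n).fit(cohort)
    pooled = build_network(pooled_corr, cohort.levels, p_threshold)

    splits, networks, consensus, comparisons = [], [], [], []
    for rule in rules:
        try:
            split = split_cohort(cohort, rule)
            per_stratum = []
            per_consensus = []
            for label, sub in split.items():
                corr = SpearmanCorrelation(min_n=min_n).fit(sub)
                per_stratum.append(
                    (label, build_network(corr, sub.levels, p_threshold))
                )
                if equalize is not None:
                    cons = subsample_consensus(
                        sub, equalize, min_n=min_n, p_threshold=p_threshold
                    )
                    per_consensus.append(
                        (label, consensus_network(cons, sub.levels, p_threshold))
                    )
            basis = per_consensus if equalize is not None else per_stratum
            comps = []
            for i in range(len(basis)):
                for j in range(i + 1, len(basis)):
                    la, na = basis[i]
                    lb, nb = basis[j]
                    comps.append((la, lb, compare_networks(na, nb, k=k)))
        except Exception as exc:
            raise type(exc)(f"[rule {rule.name!r}] {exc}") from exc
        splits.append((rule.name, split))
        networks.append((rule.name, tuple(per_stratum)))
        consensus.append((rule.name, tuple(per_consensus)))
        comparisons.append((rule.name, tuple(comps)))
    return StratifiedAnalysis(
        pooled=pooled,
        splits=tuple(splits),
        networks=tuple(networks),
        consensus=tuple(consensus),
        comparisons=tuple(comparisons),
    )
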