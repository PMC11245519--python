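"""Receptor-type classification and cohort roll-ups.

After scanning, each motif-positive protein is classified into a receptor
family from its domain architecture (first matching rule by priority) and
counted per (motif variant, receptor class, taxon).  The default rules
cover the four families in which the purine-binding domain occurs:
chemoreceptors (MCPsignal), diguanylate cyclases/phosphodiesterases
(GGDEF/EAL), sensor histidine kinases (HisKA/HATPase_c/HisKA_3) and
Ser/Thr phosphatases (SpoIIE/PP2C).  Hybrid architectures exist, so rule
priority is explicit and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import AnnotationTable, DuplicateIdentifierError

#: lineage rank order assumed for plain ordered-lineage strings
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ReceptorClassRule:
    class_name: str
    trigger_domains: frozenset[str]
    priority: int

    def __post_init__(self) -> None:
        if not self.trigger_domains:
            raise ValueError(f"rule {self.class_name!r} has an empty trigger set")


DEFAULT_RULES: tuple[ReceptorClassRule, ...] = (
    ReceptorClassRule("chemoreceptor", frozenset({"MCPsignal"}), 1),
    ReceptorClassRule(
        "diguanylate cyclase/phosphodiesterase", frozenset({"GGDEF", "EAL"}), 2
    ),
    ReceptorClassRule(
        "histidine kinase", frozenset({"HisKA", "HATPase_c", "HisKA_3"}), 3
    ),
    ReceptorClassRule("Ser/Thr phosphatase", frozenset({"SpoIIE", "PP2C"}), 4),
)


def classify_receptor(
    architecture: Sequence[str], rules: Iterable[ReceptorClassRule] = DEFAULT_RULES
) -> str:
    """First rule (by priority) whose trigger domains intersect the architecture."""
    rules = sorted(rules, key=lambda r: r.priority)
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("rule priorities must be unique")
    domains = set(architecture)
    for rule in rules:
        if rule.trigger_domains & domains:
            return rule.class_name
    return "other"


@dataclass
class SummaryReport:
    """Counts per (motif variant, receptor class, taxon) with margins."""

    counts: pd.DataFrame  # columns: variant, receptor_class, taxon, count
    rank: str
    n_matched: int

    def total(self) -> int:
        return int(self.counts["count"].sum())

    def margin(self, by: str) -> pd.Series:
        return self.counts.groupby(by)["count"].sum().sort_index()

    def to_mapping(self) -> dict:
        return {
            "rank": self.rank,
            "n_matched": self.n_matched,
            "cells": self.counts.to_dict(orient="records"),
        }


def summarize_cohort(
    variants: pd.DataFrame,
    annotations: AnnotationTable,
    rank: str = "phylum",
    rules: Iterable[ReceptorClassRule] = DEFAULT_RULES,
) -> SummaryReport:
    """Roll up matched proteins by motif variant, receptor class and taxon.

    ``variants`` is the scan output table (protein_id, variant, matched).
    Every matched protein must have an annotation row; proteins whose
    lineage does not reach ``rank`` count under "unassigned".  The report
    is independent of input row order.
    """
    ids = list(variants["protein_id"])
    if len(ids) != len(set(ids)):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateIdentifierError(dups)
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    rank_idx = RANKS.index(rank)

    rows = []
    matched = variants[variants["matched"]]
    for _, row in matched.iterrows():
        pid = row["protein_id"]
        if pid not in annotations:
            raise KeyError(f"matched protein {pid!r} lacks an annotation row")
        lineage = annotations.lineage(pid)
        taxon = lineage[rank_idx] if rank_idx < len(lineage) and lineage[rank_idx] else UNASSIGNED
        cls = classify_receptor(annotations.architecture(pid), rules)
        rows.append({"variant": row["variant"], "receptor_class": cls, "taxon": taxon})
    if not rows:
        empty = pd.DataFrame(columns=["variant", "receptor_class", "taxon", "count"])
        return SummaryReport(empty, rank, 0)
    counts = (
        pd.DataFrame(rows)
        .groupby(["variant", "receptor_class", "taxon"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["variant", "receptor_class", "taxon"], ignore_index=True)
    )
    return SummaryReport(counts, rank, int(len(matched)))
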