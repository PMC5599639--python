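"""Collapsing per-CpG results into differentially methylated gene regions.

A gene region is a (gene symbol, region class) unit where the region class
is one of the Illumina ``UCSC_RefGene_Group`` values (TSS1500, TSS200,
5'UTR, 1stExon, Body, 3'UTR).  A probe can contribute to at most two
distinct genes (the annotation extension allowing a CpG to be assigned to
two neighboring genes); duplicate (gene, region) pairs from one probe are
counted once.  An alternate collapsing mode groups probes by CpG-island
context (Island / Shore / Shelf / OpenSea) instead of gene regions.

A unit is called a DMGR when (default rule) the median q-value of its
member CpGs falls below the cutoff, or (``rule="any"``) when at least one
member CpG is individually significant.  Direction is coded ``+`` (all
significant members hyper-methylated in tumor), ``-`` (all hypo), or
``-+`` (both directions present).
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .io import split_gene_annotation

logger = logging.getLogger(__name__)

ISLAND_MODE_REGION = "island_context"


@dataclasses.dataclass
class ProbeRegionMapping:
    """Probe -> (gene, region) unit assignment."""

    pairs: pd.DataFrame            # columns: probe_id, gene, region
    unmapped: list[str]            # probes with no unit
    mode: str
    n_dropped_genes: int = 0       # (probe, gene) pairs beyond the two-gene cap

    @property
    def n_units(self) -> int:
        return len(self.pairs[["gene", "region"]].drop_duplicates())


def map_probes_to_regions(manifest: pd.DataFrame, mode: str = "gene_region") -> ProbeRegionMapping:
    """Assign probes to collapsing units.

    ``gene_region`` mode splits the parallel gene/group lists, deduplicates
    (gene, region) pairs, and keeps pairs from at most the first two
    distinct genes in annotation order; probes with no gene annotation are
    unmapped and counted.  ``island_context`` mode maps every probe to its
    island-relation value.
    """
    if mode not in ("gene_region", "island_context"):
        raise ValueError("mode must be 'gene_region' or 'island_context'")
    records: list[tuple[str, str, str]] = []
    unmapped: list[str] = []
    n_dropped = 0
    if mode == "island_context":
        for row in manifest.itertuples():
            records.append((row.probe_id, str(row.island_relation), ISLAND_MODE_REGION))
    else:
        for row in manifest.itertuples():
            pairs = split_gene_annotation(row.gene_names, row.gene_groups)
            seen: list[tuple[str, str]] = []
            genes_in_order: list[str] = []
            for gene, group in pairs:
                if gene not in genes_in_order:
                    genes_in_order.append(gene)
                if (gene, group) not in seen:
                    seen.append((gene, group))
            allowed = set(genes_in_order[:2])
            dropped_here = [pr for pr in seen if pr[0] not in allowed]
            if dropped_here:
                n_dropped += len(dropped_here)
                logger.info(
                    "probe %s annotated to %d genes; kept first two, dropped %s",
                    row.probe_id, len(genes_in_order),
                    sorted({g for g, _ in dropped_here}),
                )
            kept = [pr for pr in seen if pr[0] in allowed]
            if not kept:
                unmapped.append(row.probe_id)
            for gene, group in kept:
                records.append((row.probe_id, gene, group))
    pairs_frame = pd.DataFrame(records, columns=["probe_id", "gene", "region"])
    if unmapped:
        logger.info("%d probes had no gene annotation and are unmapped", len(unmapped))
    return ProbeRegionMapping(pairs=pairs_frame, unmapped=unmapped, mode=mode,
                              n_dropped_genes=n_dropped)


def call_dmgrs(
    results: pd.DataFrame,
    mapping: ProbeRegionMapping,
    q_cutoff: float = 0.01,
    rule: str = "median",
    stratum: str = "",
) -> pd.DataFrame:
    """Collapse per-CpG results into gene-region calls.

    ``results`` is a CpG result table with columns ``probe_id``,
    ``beta_tumor`` and ``q``.  Returns one row per (gene, region) unit with
    at least one member result: member probes, counts, the median q over
    members with a valid q, the direction code, and the boolean ``dmgr``
    call under the chosen rule.
    """
    if rule not in ("median", "any"):
        raise ValueError("rule must be 'median' or 'any'")
    if mapping.pairs.empty:
        logger.warning("empty probe-region mapping; no DMGRs can be called")
        return _empty_calls(stratum)
    merged = mapping.pairs.merge(
        results[["probe_id", "beta_tumor", "q"]], on="probe_id", how="inner"
    )
    if merged.empty:
        return _empty_calls(stratum)
    rows = []
    for (gene, region), grp in merged.groupby(["gene", "region"], sort=True):
        valid_q = grp["q"].dropna()
        if valid_q.empty:
            continue  # zero member results
        sig = grp[grp["q"] < q_cutoff]
        median_q = float(valid_q.median())
        n_sig = len(sig)
        has_hyper = (sig["beta_tumor"] > 0).any()
        has_hypo = (sig["beta_tumor"] < 0).any()
        if has_hyper and has_hypo:
            direction = "-+"
        elif has_hyper:
            direction = "+"
        elif has_hypo:
            direction = "-"
        else:
            direction = ""
        is_dmgr = (median_q < q_cutoff) if rule == "median" else (n_sig >= 1)
        rows.append({
            "gene": gene, "region": region,
            "probe_ids": ";".join(grp["probe_id"]),
            "n_probes": len(grp), "n_sig": n_sig,
            "median_q": median_q, "direction": direction,
            "dmgr": bool(is_dmgr), "stratum": stratum,
        })
    calls = pd.DataFrame(rows, columns=_CALL_COLUMNS)
    if calls.empty or not calls["dmgr"].any():
        logger.info("no DMGRs called in stratum %r at q < %g", stratum, q_cutoff)
    return calls


_CALL_COLUMNS = ["gene", "region", "probe_ids", "n_probes", "n_sig",
                 "median_q", "direction", "dmgr", "stratum"]


def _empty_calls(stratum: str) -> pd.DataFrame:
    return pd.DataFrame(columns=_CALL_COLUMNS)


@dataclasses.dataclass
class IntersectionResult:
    """Cross-stratum overlap of DMGR calls.

    ``overlap_classes`` maps each non-empty subset of strata (as a sorted
    tuple) to the number of (gene, region) units significant in exactly
    those strata — the exclusive Venn-class counts.
    """

    strata: list[str]
    shared_calls: set[tuple[str, str]]
    per_stratum_totals: dict[str, int]
    overlap_classes: dict[tuple[str, ...], int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"strata": "|".join(k), "n_strata": len(k), "n_units": v}
            for k, v in sorted(self.overlap_classes.items(),
                               key=lambda kv: (-len(kv[0]), kv[0]))
        ]
        return pd.DataFrame(rows, columns=["strata", "n_strata", "n_units"])

    def shared_frame(self) -> pd.DataFrame:
        rows = sorted(self.shared_calls)
        return pd.DataFrame(rows, columns=["gene", "region"])


def intersect_strata(calls: dict[str, pd.DataFrame | set]) -> IntersectionResult:
    """Intersect DMGR call sets across strata.

    ``calls`` maps stratum label to either a call table from
    :func:`call_dmgrs` (rows with ``dmgr == True`` are used) or a set of
    (gene, region) keys.  Emits the full-intersection shared set and all
    ``2^s - 1`` exclusive overlap-class counts for Venn/UpSet reporting.
    """
    if len(calls) < 2:
        raise ValueError("need at least two strata to intersect")
    sets: dict[str, set[tuple[str, str]]] = {}
    for label, value in calls.items():
        if isinstance(value, pd.DataFrame):
            if value.empty:
                sets[label] = set()
            else:
                hits = value[value["dmgr"]] if "dmgr" in value.columns else value
                sets[label] = set(zip(hits["gene"], hits["region"]))
        else:
            sets[label] = set(value)
    labels = sorted(sets)
    shared = set.intersection(*sets.values())
    universe = set.union(*sets.values())
    classes: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set(combo)
            exact = [
                u for u in universe
                if all(u in sets[s] for s in inside)
                and not any(u in sets[s] for s in labels if s not in inside)
            ]
            classes[combo] = len(exact)
    return IntersectionResult(
        strata=labels,
        shared_calls=shared,
        per_stratum_totals={s: len(sets[s]) for s in labels},
        overlap_classes=classes,
    )
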