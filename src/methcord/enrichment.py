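"""Genomic-context enrichment, disease-locus overlap and gene-set tests.

Region enrichment reports, per genomic feature class (TSS200, TSS1500,
5'UTR, 1st exon, gene body, 3'UTR, intergenic) and per CpG-island class
(island, shores, shelves, open sea), the fraction of array probes in that
class that were called — i.e. ratios proportional to the probe count of
each region, so classes of different sizes are comparable.  A probe
annotated to several feature classes (gene isoforms) counts once in EACH,
so feature-class hits can sum to more than the number of calls.

Locus overlap counts how many externally supplied disease-associated genes
contain at least one called site.  Gene-set over-representation is the
plain hypergeometric tail on gene counts against a restricted gene
universe (no probe-number bias correction; the raw p-values are labelled
as plain hypergeometric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import FEATURE_CLASSES, ISLAND_CLASSES

logger = logging.getLogger("methcord")


@dataclass(frozen=True)
class OverlapReport:
    """Overlap of called sites with a disease-locus gene list."""

    phenotype: str
    n_catalog_loci: int
    n_overlapping_sites: int      # site-locus incidences (a site in 2 loci counts twice)
    n_unique_sites: int
    n_loci_represented: int
    percent_represented: float    # 100 * n_loci_represented / n_catalog_loci

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype,
            "n_catalog_loci": self.n_catalog_loci,
            "n_overlapping_sites": self.n_overlapping_sites,
            "n_unique_sites": self.n_unique_sites,
            "n_loci_represented": self.n_loci_represented,
            "percent_represented": round(self.percent_represented, 1),
        }


def _class_counts(probes: pd.Index, annotation: pd.DataFrame,
                  direction: pd.Series | None) -> pd.DataFrame:
    feat = annotation.loc[probes, "feature_class"]
    isl = annotation.loc[probes, "island_class"]
    rows = []
    for cls in FEATURE_CLASSES:
        mask = feat.map(lambda s: cls in s)
        rows.append(("feature", cls, mask))
    for cls in ISLAND_CLASSES:
        rows.append(("island", cls, isl == cls))
    out = []
    for kind, cls, mask in rows:
        rec = {"kind": kind, "region": cls, "n": int(mask.sum())}
        if direction is not None:
            hits = direction.loc[probes[mask.to_numpy()]]
            n = max(len(hits), 1)
            rec["hypo_fraction"] = float((hits == "hypo").sum() / n)
            rec["hyper_fraction"] = float((hits == "hyper").sum() / n)
        out.append(rec)
    return pd.DataFrame(out)


def region_enrichment(calls: pd.Index, annotation: pd.DataFrame,
                      universe: pd.Index,
                      direction: pd.Series | None = None) -> pd.DataFrame:
    """Per-region called/array probe ratios.

    ``direction`` (optional, per-probe 'hypo'/'hyper' labels) adds the
    hypo/hyper split of the hits per region.
    """
    missing = calls.difference(annotation.index)
    if len(missing):
        raise KeyError(f"called probe(s) missing from annotation: "
                       f"{missing.tolist()[:5]}")
    if len(calls.difference(universe)):
        raise ValueError("calls must be a subset of the universe")
    hits = _class_counts(calls, annotation, direction)
    background = _class_counts(universe, annotation, None)
    table = hits.rename(columns={"n": "n_hits"}).merge(
        background.rename(columns={"n": "n_array"}), on=["kind", "region"])
    denom = table["n_array"].to_numpy()
    table["ratio"] = [h / d if d > 0 else 0.0
                      for h, d in zip(table["n_hits"], denom)]
    table["percent"] = 100.0 * table["ratio"]
    return table


def locus_overlap(calls: pd.Index, annotation: pd.DataFrame,
                  loci: list[str], phenotype: str = "") -> OverlapReport:
    """Count catalog loci represented among the called sites.

    A locus is represented iff >= 1 called site's annotated gene set
    contains it (case-insensitive symbol match); n_overlapping_sites counts
    site-locus incidences.
    """
    if not loci:
        raise ValueError("empty locus list")
    locus_keys = {g.upper() for g in loci}
    n_catalog = len(locus_keys)
    represented: set[str] = set()
    incidences = 0
    unique_sites = 0
    for probe in calls:
        genes = {g.upper() for g in annotation.loc[probe, "genes"]}
        hit = genes & locus_keys
        if hit:
            unique_sites += 1
            incidences += len(hit)
            represented |= hit
    return OverlapReport(
        phenotype=phenotype,
        n_catalog_loci=n_catalog,
        n_overlapping_sites=incidences,
        n_unique_sites=unique_sites,
        n_loci_represented=len(represented),
        percent_represented=100.0 * len(represented) / n_catalog,
    )


def gene_universe(candidates: pd.Index, annotation: pd.DataFrame) -> frozenset[str]:
    """Union of gene symbols annotated to the candidate probes — the
    background for over-representation testing."""
    genes: set[str] = set()
    for probe in candidates:
        genes |= set(annotation.loc[probe, "genes"])
    if not genes:
        logger.warning("gene universe is empty (all candidates intergenic?)")
    return frozenset(genes)


def hypergeom_enrichment(called_genes: frozenset[str] | set[str],
                         universe: frozenset[str] | set[str],
                         sets: dict[str, frozenset[str]]) -> pd.DataFrame:
    """Plain hypergeometric over-representation of each gene set.

    With N = |universe|, K = |set ∩ universe|, n = |called|, k = |set ∩
    called|: p = P(X >= k), X ~ Hypergeometric(N, K, n).  Sets disjoint
    from the universe are skipped.  No probe-number bias correction is
    applied and no multiple-testing correction across sets.
    """
    called = set(called_genes)
    uni = set(universe)
    if not called <= uni:
        raise ValueError("called genes must be a subset of the universe")
    big_n, small_n = len(uni), len(called)
    rows = []
    for name, genes in sets.items():
        in_uni = genes & uni
        big_k = len(in_uni)
        if big_k == 0:
            continue
        k = len(in_uni & called)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, small_n))
        rows.append({"set": name, "n_set_genes": big_k, "n_called_genes": k,
                     "p": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["set", "n_set_genes", "n_called_genes", "p"])
    return table.sort_values("p", kind="stable").reset_index(drop=True)
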