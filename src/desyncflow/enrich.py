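"""Hypergeometric over-representation of regulator targets among affected genes.

Given N background genes on the measurement platform, K of which are targets
of a transcription factor, and n affected genes of which k are targets, the
enrichment p-value is the upper tail of the hypergeometric distribution
including the observed count:

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

equivalent to R's ``phyper(k - 1, K, N - K, n, lower.tail = FALSE)``. The
platform (all genes represented on the array) is the background.

Counting is gene-level by default — a gene is affected if any of its probes
is affected — since target lists are gene-level; probe-level counting is
available for parity with probe-indexed site annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSet
from .screen import benjamini_hochberg


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    n_background: int        # N
    n_targets: int           # K, platform-restricted
    n_affected: int          # n
    n_affected_targets: int  # k
    p_hyper: float
    fold_enrichment: float


def hypergeom_enrichment(affected: set, targets: GeneSet,
                         background: set) -> EnrichmentResult:
    """Upper-tail hypergeometric test of target over-representation.

    ``affected`` must be a subset of ``background``; ``targets`` should
    already be platform-restricted (members outside the background are an
    error, to prevent silently inflated K).
    """
    affected = {str(g).upper() for g in affected}
    background = {str(g).upper() for g in background}
    target_genes = targets.members if isinstance(targets, GeneSet) else set(targets)
    target_genes = {str(g).upper() for g in target_genes}

    if not affected <= background:
        raise ValueError("affected genes must be a subset of the background")
    if not target_genes <= background:
        raise ValueError("target set must be platform-restricted "
                         "(members outside the background)")
    N = len(background)
    K = len(target_genes)
    n = len(affected)
    if n == 0:
        raise ValueError("no affected genes: enrichment undefined")
    k = len(affected & target_genes)

    # P(X >= k), inclusive of the observed k
    p = float(hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N) if K > 0 else np.nan
    return EnrichmentResult(
        set_name=getattr(targets, "name", ""), n_background=N, n_targets=K,
        n_affected=n, n_affected_targets=k, p_hyper=p, fold_enrichment=fold,
    )


def affected_genes(screen_results: pd.DataFrame) -> set:
    """Genes with at least one affected probe (gene-level collapsing)."""
    sel = screen_results.loc[screen_results["affected"], "gene_symbol"]
    return set(sel[sel != ""].unique())


def enrich_all(screen_results: pd.DataFrame, gene_sets, background: set,
               level: str = "gene", bh: bool = False) -> pd.DataFrame:
    """Enrichment of each gene set among affected genes (or probes).

    ``level="gene"`` (default) collapses probes to genes; ``level="probe"``
    counts probes directly, with the probe universe as background and a set
    "member" meaning the probe's gene is in the set.
    """
    rows = []
    for gs in gene_sets:
        if level == "gene":
            aff = affected_genes(screen_results)
            bg = {str(g).upper() for g in background}
            restricted = GeneSet(gs.name, gs.description,
                                 frozenset(gs.members & bg))
            res = hypergeom_enrichment(aff, restricted, bg)
        elif level == "probe":
            bg = set(screen_results["probe_id"])
            member_probes = set(
                screen_results.loc[
                    screen_results["gene_symbol"].isin(gs.members), "probe_id"]
            )
            aff = set(screen_results.loc[screen_results["affected"], "probe_id"])
            res = hypergeom_enrichment(
                aff, GeneSet(gs.name, gs.description, frozenset(member_probes)), bg)
        else:
            raise ValueError(f"unknown counting level {level!r}")
        rows.append(res.__dict__ | {"level": level})
    out = pd.DataFrame(rows)
    if bh:
        out["p_hyper_bh"] = benjamini_hochberg(out["p_hyper"].to_numpy())
    return out


def write_enrichment(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")
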