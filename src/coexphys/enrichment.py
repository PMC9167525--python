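"""Hypergeometric over-representation of annotation terms in gene modules.

Terms (e.g. KEGG orthology terms or GO terms) are tested against the
tissue-expressed gene universe with an upper-tail hypergeometric test and
BH-FDR across the terms tested for one module. Enriched terms can be rolled
up to pathways, reporting the pathway with the most enriched terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """term -> gene set, term -> pathway ids, pathway id -> display name."""

    term_genes: dict[str, set[str]]
    term_pathways: dict[str, set[str]] = field(default_factory=dict)
    pathway_names: dict[str, str] = field(default_factory=dict)


def load_gene_sets(path) -> AnnotationMap:
    """Parse gene sets from a GMT file or a two-column term<TAB>gene TSV.

    GMT lines are ``term<TAB>description<TAB>gene1<TAB>gene2...``; the
    two-column form lists one (term, gene) pair per line. Duplicate genes
    within a term are deduplicated; malformed lines are logged and skipped.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()
             if ln.strip()]
    if not lines:
        raise ValueError(f"annotation file {path} is empty")
    term_genes: dict[str, set[str]] = {}
    is_gmt = path.suffix.lower() == ".gmt"
    for i, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if is_gmt:
            if len(parts) < 3:
                logger.warning("%s line %d: malformed GMT line skipped",
                               path.name, i)
                continue
            term, genes = parts[0], parts[2:]
        else:
            if len(parts) != 2:
                logger.warning("%s line %d: expected 2 columns, skipped",
                               path.name, i)
                continue
            term, genes = parts[0], [parts[1]]
        term_genes.setdefault(term, set()).update(g for g in genes if g)
    if not term_genes:
        raise ValueError(f"no valid gene sets parsed from {path}")
    return AnnotationMap(term_genes=term_genes)


def load_term_pathways(path, annotation: AnnotationMap) -> AnnotationMap:
    """Attach a two-column term<TAB>pathway TSV to an annotation map."""
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0].strip():
            continue
        annotation.term_pathways.setdefault(parts[0], set()).add(parts[1])
        if len(parts) > 2:
            annotation.pathway_names[parts[1]] = parts[2]
    return annotation


def hypergeom_test(module: set[str], term: set[str],
                   universe: set[str]) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), k = |module & term|.

    The term set is restricted to the universe before counting; the module
    must already be a subset of the universe.
    """
    extra = set(module) - set(universe)
    if extra:
        raise ValueError(
            f"module genes outside the universe: {sorted(extra)[:5]}")
    term_in = set(term) & set(universe)
    n_univ, n_term, n_mod = len(universe), len(term_in), len(module)
    k = len(set(module) & term_in)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_univ, n_term, n_mod))


def enrich_module(module: set[str], annotation: AnnotationMap,
                  universe: set[str], fdr: float = 0.05) -> pd.DataFrame:
    """Test every annotation term against one module; BH across terms.

    Terms with no gene in the universe are dropped (logged). Returns one row
    per tested term with overlap k, restricted term size K, module size n,
    universe size N, p and q, sorted by p.
    """
    universe = set(universe)
    module = set(module)
    rows = []
    for term, genes in annotation.term_genes.items():
        term_in = genes & universe
        if not term_in:
            logger.info("term %s has no genes in the universe; dropped", term)
            continue
        k = len(module & term_in)
        p = hypergeom_test(module, term_in, universe)
        rows.append((term, k, len(term_in), len(module), len(universe), p))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out.sort_values(["p", "term"], ignore_index=True)


def top_pathway(enriched: pd.DataFrame, annotation: AnnotationMap
                ) -> tuple[str | None, int, bool]:
    """Pathway with the most enriched terms; (pathway, count, tie flag).

    Ties are flagged and broken deterministically by alphabetical pathway
    id (the underlying choice of the "most informative" pathway is not
    algorithmic, so the tie is surfaced rather than hidden).
    """
    sig_terms = enriched.loc[enriched.get("significant", pd.Series(dtype=bool))
                             .astype(bool), "term"] if len(enriched) else []
    counts: dict[str, int] = {}
    for term in sig_terms:
        for pw in annotation.term_pathways.get(term, ()):
            counts[pw] = counts.get(pw, 0) + 1
    if not counts:
        return None, 0, False
    best = max(counts.values())
    winners = sorted(pw for pw, c in counts.items() if c == best)
    return winners[0], best, len(winners) > 1


def enrich_all_modules(labels: pd.Series, annotation: AnnotationMap,
                       universe: set[str] | None = None,
                       fdr: float = 0.05) -> pd.DataFrame:
    """Per-module enrichment over all modules (label 0 excluded)."""
    if universe is None:
        universe = set(labels.index)
    frames = []
    for m in sorted(set(labels) - {0}):
        module = set(labels.index[labels == m]) & universe
        res = enrich_module(module, annotation, universe, fdr)
        res.insert(0, "module", m)
        frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["module", "term", "k", "K", "n", "N", "p", "q",
                     "significant"])
    return pd.concat(frames, ignore_index=True)
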