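"""Single-marker association scan, significance filtering, hit annotation,
elim-style Fisher GO enrichment and DEG threshold classification.

The scan is ordinary least squares per site with optional covariates (e.g.
leading PCoA axes) partialled out of both phenotype and genotype; missing
genotypes are mean-imputed per site.  The significance filter is the
three-part rule -log10(p) > 2.5 AND p < 0.05 AND Benjamini-Hochberg
FDR < 0.05.  Enrichment is a one-sided Fisher exact (hypergeometric tail)
test per GO term with the elim procedure: terms are processed bottom-up by
longest-path depth, and the annotated study genes of any term significant at
alpha are removed from its ancestors before those are tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .seqio import GeneModel
from .variants import GenotypeMatrix


# ---------------------------------------------------------------------------
# GWAS


def gwas_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray | pd.Series,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-site OLS slope t-test with BH q-values across all tested sites.

    Monomorphic sites (zero genotype variance after mean imputation) are
    skipped; their ids are listed in ``result.attrs["skipped"]``.
    """
    y = np.asarray(phenotype, dtype=float)
    G = genotypes.data.astype(float).copy()
    n = G.shape[1]
    if y.size != n:
        raise ValueError(f"phenotype length {y.size} != accession count {n}")
    # mean-impute missing genotypes per site
    miss = G < 0
    with np.errstate(invalid="ignore"):
        means = np.where(
            (~miss).sum(axis=1) > 0,
            np.nansum(np.where(miss, np.nan, G), axis=1) / np.maximum((~miss).sum(axis=1), 1),
            0.0,
        )
    G[miss] = np.broadcast_to(means[:, None], G.shape)[miss]

    k_cov = 0
    if covariates is not None:
        X = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        k_cov = X.shape[1] - 1
        P = X @ np.linalg.pinv(X)
        y = y - P @ y
        G = G - G @ P.T
    else:
        y = y - y.mean()
        G = G - G.mean(axis=1, keepdims=True)

    gvar = (G**2).sum(axis=1)
    yvar = float((y**2).sum())
    tested = gvar > 1e-12
    ids = [f"{r.contig}:{r.position}" for r in genotypes.sites.itertuples(index=False)]
    skipped = [ids[i] for i in np.flatnonzero(~tested)]

    dof = n - 2 - k_cov
    if dof < 1:
        raise ValueError("not enough accessions for the requested model")
    Gt = G[tested]
    beta = (Gt @ y) / gvar[tested]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Gt @ y) / np.sqrt(gvar[tested] * yvar) if yvar > 0 else np.zeros(Gt.shape[0])
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(dof) / np.sqrt(np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), dof)
    q = multipletests(p, method="fdr_bh")[1] if p.size else np.array([])
    out = pd.DataFrame(
        {
            "site": [ids[i] for i in np.flatnonzero(tested)],
            "contig": genotypes.sites.loc[tested, "contig"].to_numpy(),
            "position": genotypes.sites.loc[tested, "position"].to_numpy(),
            "beta": beta,
            "p": p,
            "q": q,
        }
    )
    out.attrs["skipped"] = skipped
    return out


def significance_filter(
    results: pd.DataFrame,
    neg_log10_p: float = 2.5,
    p_thresh: float = 0.05,
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """The three-part rule: -log10(p) > 2.5 AND p < 0.05 AND FDR q < 0.05.

    The -log10(p) cut-off is a fixed constant, not recomputed from the
    number of tests.  Returns the passing subset; the full table gains a
    ``passes_filter`` column in place.
    """
    with np.errstate(divide="ignore"):
        neglog = -np.log10(results["p"].to_numpy())
    passes = (neglog > neg_log10_p) & (results["p"] < p_thresh) & (results["q"] < q_thresh)
    results["passes_filter"] = passes
    return results[passes].copy()


def annotate_hits(hits: pd.DataFrame, gene_models: list[GeneModel]) -> pd.DataFrame:
    """Mark each hit genic iff it falls within a gene span (1-based
    inclusive), attaching the gene id."""
    rows = []
    by_contig: dict[str, list[GeneModel]] = {}
    for gm in gene_models:
        by_contig.setdefault(gm.contig, []).append(gm)
    for row in hits.itertuples(index=False):
        gene_id = ""
        for gm in by_contig.get(row.contig, []):
            if gm.start <= row.position <= gm.end:
                gene_id = gm.gene_id
                break
        rows.append((row.site, row.contig, int(row.position), bool(gene_id), gene_id))
    return pd.DataFrame(rows, columns=["site", "contig", "position", "genic", "gene"])


# ---------------------------------------------------------------------------
# GO DAG + elim Fisher enrichment


@dataclass
class GoDag:
    """GO-style DAG with gene annotations propagated to ancestors.

    Edges run child -> parent.  After propagation every term's gene set
    contains the union of its children's sets.
    """

    graph: nx.DiGraph
    annotations: dict[str, set[str]] = field(default_factory=dict)  # gene -> terms (direct)
    term_genes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("GO graph contains a cycle")
        self.propagate()

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str]], annotations: dict[str, set[str]]) -> "GoDag":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        for terms in annotations.values():
            g.add_nodes_from(terms)
        return cls(graph=g, annotations={k: set(v) for k, v in annotations.items()})

    def propagate(self) -> None:
        term_genes: dict[str, set[str]] = {t: set() for t in self.graph.nodes}
        for gene, terms in self.annotations.items():
            for t in terms:
                if t not in term_genes:
                    term_genes[t] = set()
                term_genes[t].add(gene)
                for anc in nx.descendants(self.graph, t):  # ancestors along child->parent edges
                    term_genes[anc].add(gene)
        self.term_genes = term_genes

    def depths(self) -> dict[str, int]:
        """Longest-path depth from the root(s); roots have depth 0."""
        depth: dict[str, int] = {}
        for t in nx.topological_sort(self.graph.reverse(copy=False)):
            parents = list(self.graph.successors(t))
            depth[t] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth

    def ancestors(self, term: str) -> set[str]:
        return set(nx.descendants(self.graph, term))


def fisher_exact_p(k: int, n_term: int, n_study: int, n_background: int) -> float:
    """One-sided Fisher exact enrichment p: hypergeometric upper tail
    P(X >= k)."""
    return float(stats.hypergeom.sf(k - 1, n_background, n_term, n_study))


def fisher_elim_enrichment(
    study: set[str],
    background: set[str],
    dag: GoDag,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term Fisher enrichment with the elim decorrelation procedure.

    Terms are tested from the deepest DAG level upward (ties in term-id
    order).  When a term's elim p falls below ``alpha`` its annotated study
    genes are removed from all its ancestors before they are tested.  With
    alpha = 0, or when no term reaches alpha, elim p equals the raw p
    everywhere.
    """
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    M, N = len(background), len(study)
    term_bg = {t: genes & background for t, genes in dag.term_genes.items()}
    raw_p = {
        t: fisher_exact_p(len(genes & study), len(genes), N, M) for t, genes in term_bg.items()
    }
    depths = dag.depths()
    order = sorted(dag.term_genes, key=lambda t: (-depths[t], t))
    removed: dict[str, set[str]] = {t: set() for t in dag.term_genes}
    rows = []
    for t in order:
        genes = term_bg[t]
        study_hits_set = (genes & study) - removed[t]
        k = len(study_hits_set)
        elim_p = fisher_exact_p(k, len(genes), N, M)
        if elim_p < alpha:
            contributed = genes & study
            for anc in dag.ancestors(t):
                removed[anc] |= contributed
        rows.append(
            {
                "term": t,
                "study_hits": k,
                "study_misses": N - k,
                "background_hits": len(genes),
                "background_misses": M - len(genes),
                "raw_p": raw_p[t],
                "elim_p": elim_p,
                "significant": elim_p < alpha,
            }
        )
    return pd.DataFrame(rows).sort_values("elim_p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# DEG classification


def deg_classify(
    table: pd.DataFrame,
    q_thresh: float = 0.05,
    lfc_thresh: float = 2.0,
) -> pd.DataFrame:
    """Call genes up/down/not_de from log2 fold change and q-value.

    up iff q < 0.05 and log2FC > 2; down iff q < 0.05 and log2FC < -2.
    Rows with missing q are not_de and flagged.
    """
    out = table.copy()
    q = pd.to_numeric(out["q"], errors="coerce")
    lfc = pd.to_numeric(out["log2fc"], errors="coerce")
    missing_q = q.isna()
    call = np.full(len(out), "not_de", dtype=object)
    call[(~missing_q) & (q < q_thresh) & (lfc > lfc_thresh)] = "up"
    call[(~missing_q) & (q < q_thresh) & (lfc < -lfc_thresh)] = "down"
    out["call"] = call
    out["missing_q"] = missing_q.to_numpy()
    return out
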