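"""Cluster-vs-rest differential expression and gene-set overrepresentation.

DE uses a per-gene Welch's t-test on normalized log values (the
pre-scaling layer: t-tests on zero-mean scaled data make fold changes
meaningless), with Benjamini-Hochberg correction within each cluster's
gene list.  Markers are the top-N genes by log2 fold change (N=500 by
default; small panels — e.g. a 19-protein CODEX run — simply return every
differential feature).  Enrichment is a one-sided hypergeometric
overrepresentation test of the marker set against GMT gene-set
collections, BH-corrected across terms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import AnnotatedMatrix, Partition, to_dense
from .errors import FormatError, ParameterError

log = logging.getLogger(__name__)


@dataclass
class DEResult:
    gene_id: str
    t_stat: float
    p_value: float
    q_value: float
    log2_fc: float


@dataclass
class EnrichmentRow:
    term_name: str
    overlap_count: int
    term_size: int
    p_value: float
    q_value: float
    overlapping_genes: list


def welch_t(x, y):
    """Welch's unequal-variance t-test.

    Returns ``(t, df, p)`` with sample (ddof=1) variances, the
    Welch-Satterthwaite degrees of freedom, and a two-sided p from the
    Student t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("welch_t needs at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    diff = x.mean() - y.mean()
    if se2 == 0:
        if diff == 0:
            return 0.0, float(nx + ny - 2), 1.0
        return float(np.sign(diff) * np.inf), float(nx + ny - 2), 0.0
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def de_cluster_vs_rest(m: AnnotatedMatrix, partition: Partition,
                       cluster_id: int) -> list[DEResult]:
    """Per-gene Welch t of one cluster against all other cells.

    Runs on the ``"lognorm"`` layer when present (normalized, pre-scaling
    values), else on ``values``.  log2 fold change is computed on expm1
    means with a pseudocount of 1.  Genes whose test is undefined get
    p = NaN and are excluded from ranking downstream.
    """
    if len(partition) != m.n_cells:
        raise ParameterError("partition length does not match matrix")
    in_c = partition.labels == cluster_id
    n1, n2 = int(in_c.sum()), int((~in_c).sum())
    if n1 < 2 or n2 < 2:
        raise ParameterError(
            f"cluster {cluster_id}: needs >= 2 cells in cluster and rest "
            f"(got {n1} and {n2})")
    vals = m.layers.get("lognorm", m.values)
    x = to_dense(vals).astype(float)
    a, b = x[in_c], x[~in_c]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = va / n1 + vb / n2
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((va / n1) ** 2 / (n1 - 1) + (vb / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se2 == 0
    t[zero_se & (diff == 0)] = 0.0
    p[zero_se & (diff == 0)] = 1.0
    p[zero_se & (diff != 0)] = np.nan  # undefined-variance gene: excluded from ranking
    fc = np.log2((np.expm1(a).mean(axis=0) + 1.0) / (np.expm1(b).mean(axis=0) + 1.0))
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return [DEResult(gene_id=g, t_stat=float(t[i]), p_value=float(p[i]),
                     q_value=float(q[i]), log2_fc=float(fc[i]))
            for i, g in enumerate(m.feature_ids)]


def top_markers(results: list[DEResult], n: int = 500,
                absolute_fc: bool = False) -> list[str]:
    """Top-n genes by log2 fold change (descending; NaN-p genes excluded).

    Ties break toward the smaller p, then the gene id.  Fewer than n
    results returns them all.
    """
    if not results:
        raise ParameterError("no DE results to rank")
    usable = [r for r in results if not np.isnan(r.p_value)]
    keyfc = (lambda r: abs(r.log2_fc)) if absolute_fc else (lambda r: r.log2_fc)
    ranked = sorted(usable, key=lambda r: (-keyfc(r), r.p_value, r.gene_id))
    return [r.gene_id for r in ranked[:n]]


def de_table(results: list[DEResult], path=None):
    """DE results as a DataFrame (gene, t, p, q, log2_fc), optionally TSV."""
    import pandas as pd
    df = pd.DataFrame([{"gene_id": r.gene_id, "t_stat": r.t_stat,
                        "p_value": r.p_value, "q_value": r.q_value,
                        "log2_fc": r.log2_fc} for r in results])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set collection: name, description, genes...

    Duplicate genes within a term are deduplicated; empty terms are
    dropped with a warning.
    """
    sets: dict[str, set] = {}
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n_lines += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)")
            name, genes = fields[0], {g for g in fields[2:] if g}
            if not genes:
                warnings.warn(f"{path}:{lineno}: empty term {name!r} dropped")
                continue
            sets[name] = genes
    if n_lines == 0:
        warnings.warn(f"{path}: empty GMT file")
    return sets


def enrich(query_genes, gene_sets: dict[str, set],
           background_size: int) -> list[EnrichmentRow]:
    """One-sided hypergeometric overrepresentation per term, BH across terms.

    p = P[overlap >= observed] drawing ``len(query)`` genes from a
    background of ``background_size`` containing ``term_size`` term genes.
    Rows come back sorted by p ascending.
    """
    query = set(map(str, query_genes))
    rows = []
    for name, term in gene_sets.items():
        if background_size < len(query | term):
            raise ParameterError(
                f"background_size={background_size} smaller than "
                f"|query ∪ {name!r}| = {len(query | term)}")
        overlap = sorted(query & term)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, background_size, len(term), len(query)))
        rows.append(EnrichmentRow(term_name=name, overlap_count=k,
                                  term_size=len(term), p_value=min(1.0, p),
                                  q_value=np.nan, overlapping_genes=overlap))
    if rows:
        q = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        for r, qv in zip(rows, q):
            r.q_value = float(qv)
    rows.sort(key=lambda r: (r.p_value, r.term_name))
    return rows


def enrichment_table(rows: list[EnrichmentRow], path=None):
    import pandas as pd
    df = pd.DataFrame([{"term_name": r.term_name, "overlap_count": r.overlap_count,
                        "term_size": r.term_size, "p_value": r.p_value,
                        "q_value": r.q_value,
                        "overlapping_genes": ",".join(r.overlapping_genes)}
                       for r in rows])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
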