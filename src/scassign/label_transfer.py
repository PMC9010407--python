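"""Reference -> query label transfer with semi-supervised refinement.

The transfer model mirrors the ingest-style recipe: restrict both datasets
to their overlapping genes, scale the query with the *reference's* per-gene
statistics, project it through a PCA fit only on the reference (40
components), and label each query cell by majority vote among its k nearest
reference cells in that latent space.  Clusters whose transferred labels
look reliable (median per-cell vote confidence >= 0.9, or an explicit
cluster list) are frozen, and constrained Leiden on the query's own kNN
graph refines the remaining assignments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core_data import AnnotatedMatrix, Partition, canonicalize, to_dense
from .embed_cluster import (ClusterParams, ReductionParams, build_knn_graph,
                            leiden_semisupervised, reduce_pca)
from .errors import ParameterError

log = logging.getLogger(__name__)


@dataclass
class TransferModel:
    overlapping_genes: list
    reference_means: np.ndarray
    reference_sds: np.ndarray
    projection: PCA
    reference_embedding: np.ndarray
    reference_labels: np.ndarray


@dataclass
class TransferResult:
    labels: np.ndarray      # per query cell
    confidence: np.ndarray  # fraction of voting neighbors agreeing, in [1/k, 1]


def fit_transfer(reference: AnnotatedMatrix, label_key: str,
                 query_features, n_components: int = 40,
                 seed: int = 0) -> TransferModel:
    """Fit the projection on the reference restricted to overlapping genes.

    The gene intersection keeps reference feature order.  Scaling
    statistics (mean, population sd) come from the reference alone — the
    query is later standardized with these same numbers, which is what
    makes self-transfer an exact identity.
    """
    if label_key not in reference.cell_meta.columns:
        raise KeyError(f"label key {label_key!r} missing from reference cell_meta")
    qset = set(map(str, query_features))
    overlap = [g for g in reference.feature_ids if g in qset]
    if len(overlap) < 2:
        raise ParameterError(
            "gene intersection too small; reference features look like "
            f"{list(reference.feature_ids[:5])}, query like "
            f"{list(query_features)[:5]}")
    ridx = [i for i, g in enumerate(reference.feature_ids) if g in qset]
    x = to_dense(reference.values)[:, ridx].astype(float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    sds_safe = np.where(sds > 0, sds, 1.0)
    xs = (x - means) / sds_safe
    n_comp = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
    ref_emb = pca.fit_transform(xs)
    return TransferModel(
        overlapping_genes=overlap, reference_means=means, reference_sds=sds_safe,
        projection=pca, reference_embedding=ref_emb,
        reference_labels=reference.cell_meta[label_key].to_numpy())


def project_query(model: TransferModel, query: AnnotatedMatrix) -> np.ndarray:
    """Embed query cells with the reference-fit scaling and projection."""
    pos = {g: i for i, g in enumerate(query.feature_ids)}
    missing = [g for g in model.overlapping_genes if g not in pos]
    if missing:
        raise ParameterError(f"query lacks overlapping genes (first 5): {missing[:5]}")
    qidx = [pos[g] for g in model.overlapping_genes]
    xq = to_dense(query.values)[:, qidx].astype(float)
    xq = (xq - model.reference_means) / model.reference_sds
    return model.projection.transform(xq)


def transfer_labels(model: TransferModel, query: AnnotatedMatrix,
                    k: int = 15) -> TransferResult:
    """Majority vote among the k nearest reference cells per query cell.

    Ties are broken by summed inverse distance to the tied labels' voters,
    then by the smaller label.  Confidence is the winning vote fraction.
    """
    n_ref = model.reference_embedding.shape[0]
    if k > n_ref:
        raise ParameterError(f"k={k} exceeds {n_ref} reference cells")
    emb = project_query(model, query)
    ref = model.reference_embedding
    labels = np.empty(query.n_cells, dtype=object)
    confidence = np.zeros(query.n_cells)
    sq_ref = np.einsum("ij,ij->i", ref, ref)
    for i in range(query.n_cells):
        d2 = sq_ref - 2.0 * (ref @ emb[i]) + emb[i] @ emb[i]
        nbrs = np.argsort(d2, kind="stable")[:k]
        votes = model.reference_labels[nbrs]
        uniq, counts = np.unique(votes.astype(str), return_counts=True)
        top = counts.max()
        tied = uniq[counts == top]
        if len(tied) > 1:
            inv = {}
            for lab in tied:
                sel = nbrs[votes.astype(str) == lab]
                inv[lab] = np.sum(1.0 / (np.sqrt(np.maximum(d2[sel], 0)) + 1e-12))
            best = max(inv.values())
            tied = sorted(lab for lab, v in inv.items() if v >= best - 1e-12)
        labels[i] = tied[0]
        confidence[i] = top / k
    return TransferResult(labels=labels, confidence=confidence)


def select_frozen_clusters(result: TransferResult, partition: Partition,
                           min_median_confidence: float = 0.9,
                           override_clusters=None) -> Partition:
    """Freeze clusters whose median transfer confidence clears the bar.

    ``override_clusters`` freezes exactly the listed cluster ids instead —
    the path for reproducing a manual, expert choice of reliable clusters.
    """
    if not (0 < min_median_confidence <= 1):
        raise ParameterError("min_median_confidence must be in (0, 1]")
    if len(partition) != len(result.labels):
        raise ParameterError("partition does not align with transfer result")
    frozen = np.zeros(len(partition), dtype=bool)
    if override_clusters is not None:
        wanted = set(int(c) for c in override_clusters)
        frozen = np.isin(partition.labels, list(wanted))
    else:
        for c in np.unique(partition.labels):
            mask = partition.labels == c
            if np.median(result.confidence[mask]) >= min_median_confidence:
                frozen |= mask
    return Partition(partition.labels.copy(), frozen)


def transfer_and_refine(reference: AnnotatedMatrix, query: AnnotatedMatrix,
                        label_key: str, cluster_params: ClusterParams | None = None,
                        n_components: int = 40, k_vote: int = 15,
                        min_median_confidence: float = 0.9,
                        override_clusters=None):
    """Full transfer pipeline; returns (refined, transferred) partitions.

    Transferred labels initialize a constrained Leiden run on the query's
    own PCA/kNN graph, with the confident clusters frozen.
    """
    cp = cluster_params or ClusterParams()
    model = fit_transfer(reference, label_key, query.feature_ids,
                         n_components=n_components, seed=cp.seed)
    result = transfer_labels(model, query, k=k_vote)
    codes, _ = pd.factorize(pd.Series(result.labels).astype(str), sort=True)
    transferred = Partition(codes)

    n_comp = min(n_components, query.n_cells - 1, query.n_features)
    q_emb = reduce_pca(query, ReductionParams(n_components=n_comp, seed=cp.seed))
    graph = build_knn_graph(q_emb.embeddings["reduced"], cp.k_neighbors)
    init = select_frozen_clusters(result, transferred,
                                  min_median_confidence, override_clusters)
    refined = leiden_semisupervised(graph, init, cp)
    log.info("transfer_and_refine: %d/%d cells frozen across %d clusters",
             int(init.frozen.sum()), len(init), transferred.n_clusters)
    return refined, transferred


def copy_labels_by_cell_id(source: AnnotatedMatrix, target: AnnotatedMatrix,
                           label_key: str, unassigned: str = "unassigned") -> AnnotatedMatrix:
    """Copy labels between modalities profiled on the same cells.

    Target cells whose cell_id appears in the source receive its label;
    the rest get ``unassigned``.  Zero matches warns (not an error).
    """
    if label_key not in source.cell_meta.columns:
        raise KeyError(f"label key {label_key!r} missing from source cell_meta")
    src = dict(zip(source.cell_ids, source.cell_meta[label_key]))
    out = target.copy()
    labels = [src.get(cid, unassigned) for cid in target.cell_ids]
    n_matched = sum(cid in src for cid in target.cell_ids)
    if n_matched == 0:
        warnings.warn("no cell ids shared between source and target; "
                      "all target cells unassigned")
    log.info("copy_labels_by_cell_id: %d/%d target cells matched",
             n_matched, target.n_cells)
    out.cell_meta[label_key] = labels
    return out
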