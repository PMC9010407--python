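"""Peak-to-gene activity scoring for scATAC-seq.

A peak-by-cell accessibility matrix is converted into a cell-by-gene
*gene activity* matrix: each gene's annotated span (GENCODE-dialect GTF,
gene records) is extended strand-aware — 5000 bp past the 3' end
(downstream) and 1000 bp past the 5' end (upstream) by default — and the
counts of every peak overlapping the extended range by at least 1 bp are
summed per cell.  A peak overlapping several extended genes contributes to
each; genes with no overlapping peak keep an all-zero column.  The result
is then CPM-normalized, log1p-transformed and scaled like any expression
matrix, ready for PCA and clustering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from intervaltree import IntervalTree

from .core_data import AnnotatedMatrix, GenomicInterval
from .errors import FormatError, ParameterError
from .preprocess import normalize_cpm_log1p, scale_unit_variance

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRange:
    gene_id: str
    gene_name: str
    interval: GenomicInterval

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class ExtensionParams:
    downstream_bp: int = 5000
    upstream_bp: int = 1000
    strand_aware: bool = True

    def __post_init__(self):
        if self.downstream_bp < 0 or self.upstream_bp < 0:
            raise ParameterError("extensions must be >= 0")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gtf_genes(path) -> list[GeneRange]:
    """Read gene records from a GENCODE-dialect GTF.

    1-based inclusive GTF coordinates become 0-based half-open.  Records
    without a strand are skipped with a warning; duplicate gene_ids are an
    error.  Unplaced contigs are retained as-is.
    """
    genes: list[GeneRange] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "gene":
                continue
            if strand not in ("+", "-"):
                log.warning("%s:%d: gene record without strand skipped", path, lineno)
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr:
                raise FormatError(f"{path}:{lineno}: malformed attributes (no gene_id)")
            gid = attr["gene_id"]
            if gid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            genes.append(GeneRange(
                gene_id=gid, gene_name=attr.get("gene_name", gid),
                interval=GenomicInterval(chrom, s - 1, e, strand)))
    return genes


def extend_range(g: GeneRange, p: ExtensionParams) -> GenomicInterval:
    """Strand-aware extension: downstream is past the 3' end.

    + strand: [start - upstream, end + downstream);
    - strand: [start - downstream, end + upstream).  Clipped at 0.
    With ``strand_aware=False`` the + rule applies regardless of strand.
    """
    iv = g.interval
    if p.strand_aware and iv.strand == "-":
        lo, hi = iv.start - p.downstream_bp, iv.end + p.upstream_bp
    else:
        lo, hi = iv.start - p.upstream_bp, iv.end + p.downstream_bp
    return GenomicInterval(iv.chrom, max(0, lo), hi, iv.strand)


_PEAK_RES = (
    re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$"),
    re.compile(r"^(?P<chrom>.+)_(?P<start>\d+)_(?P<end>\d+)$"),
    re.compile(r"^(?P<chrom>.+?)-(?P<start>\d+)-(?P<end>\d+)$"),
)


def parse_peak_ids(feature_ids) -> list[GenomicInterval]:
    """Parse "chrom:start-end" peak ids ("_" and "-" dialects accepted)."""
    out, bad = [], []
    for fid in feature_ids:
        for rex in _PEAK_RES:
            m = rex.match(str(fid))
            if m:
                out.append(GenomicInterval(m["chrom"], int(m["start"]),
                                           int(m["end"]), "."))
                break
        else:
            bad.append(str(fid))
    if bad:
        raise FormatError(f"unparseable peak ids (first 5): {bad[:5]}")
    return out


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def gene_activity_matrix(peaks_by_cells: AnnotatedMatrix, genes: list[GeneRange],
                         p: ExtensionParams | None = None,
                         harmonize_chroms: bool = False) -> AnnotatedMatrix:
    """Sum per-cell counts of peaks overlapping each extended gene range.

    ``peaks_by_cells`` is cells x peaks with coordinate-encoded peak ids.
    Overlap is >= 1 bp on 0-based half-open intervals; multi-gene peaks
    count toward every overlapped gene.  ``harmonize_chroms`` strips a
    "chr" prefix on both sides before matching (never applied silently).
    """
    if not genes:
        raise ParameterError("at least one gene required")
    p = p or ExtensionParams()
    peaks = parse_peak_ids(peaks_by_cells.feature_ids)
    key = _strip_chr if harmonize_chroms else (lambda s: s)

    trees: dict[str, IntervalTree] = {}
    for j, pk in enumerate(peaks):
        trees.setdefault(key(pk.chrom), IntervalTree()).addi(pk.start, pk.end, j)

    counts = peaks_by_cells.layers.get("counts", peaks_by_cells.values)
    counts = counts.tocsc() if sp.issparse(counts) else np.asarray(counts)
    n_cells, n_genes = peaks_by_cells.n_cells, len(genes)
    activity = np.zeros((n_cells, n_genes))
    total_overlaps = 0
    for gi, gene in enumerate(genes):
        ext = extend_range(gene, p)
        tree = trees.get(key(ext.chrom))
        if tree is None:
            continue
        peak_idx = sorted(hit.data for hit in tree.overlap(ext.start, ext.end))
        total_overlaps += len(peak_idx)
        if peak_idx:
            block = counts[:, peak_idx]
            activity[:, gi] = np.asarray(block.sum(axis=1)).ravel()
    if total_overlaps == 0:
        peak_chroms = sorted({pk.chrom for pk in peaks})[:3]
        gene_chroms = sorted({g.interval.chrom for g in genes})[:3]
        raise FormatError(
            f"no peak overlaps any gene range; peak chromosomes look like "
            f"{peak_chroms} and gene chromosomes like {gene_chroms} — "
            "consider harmonize_chroms=True to reconcile 'chr' prefixes")
    out = AnnotatedMatrix(activity, peaks_by_cells.cell_ids,
                          [g.gene_id for g in genes])
    out.feature_meta["gene_name"] = [g.gene_name for g in genes]
    out.set_layer("counts", out.values.copy())
    return out


def atac_pipeline(peaks_by_cells: AnnotatedMatrix, gtf_path,
                  p: ExtensionParams | None = None, target_sum: float = 1e5,
                  harmonize_chroms: bool = False) -> AnnotatedMatrix:
    """Gene activity scoring -> CPM/log1p -> unit-variance scaling."""
    genes = parse_gtf_genes(gtf_path)
    m = gene_activity_matrix(peaks_by_cells, genes, p, harmonize_chroms)
    m = normalize_cpm_log1p(m, target_sum)
    lognorm = m.values.copy()
    m = scale_unit_variance(m)
    m.layers["lognorm"] = lognorm
    return m
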