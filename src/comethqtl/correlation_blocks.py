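"""Co-methylation correlation-block calling.

Four steps per chromosome chunk: (1) pairwise Pearson correlation of beta
values across samples, zeroing values below a threshold; (2) Gaussian
distance weighting with a hard cutoff for pairs further apart than the
absolute distance cutoff; (3) weighted-graph construction; (4) Louvain
community detection. Every CpG — including isolated ones — ends up in
exactly one block.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from comethqtl.io_formats import MethylationMatrix

logger = logging.getLogger(__name__)


@dataclass
class BlockParams:
    cluster_cor_threshold: float = 0.2
    gauss_sd: float = 3000.0
    absolute_distance_cutoff: float = 500_000.0
    max_cpgs_per_chunk: int = 40_000
    clustering_seed: int = 42
    louvain_resolution: float = 1.0
    min_shared_samples: int = 3  # pairwise-complete minimum for a correlation

    def __post_init__(self) -> None:
        if self.gauss_sd <= 0:
            raise ValueError("gauss_sd must be positive")
        if self.absolute_distance_cutoff <= 0:
            raise ValueError("absolute_distance_cutoff must be positive")
        if self.max_cpgs_per_chunk < 2:
            raise ValueError("max_cpgs_per_chunk must be at least 2")


@dataclass
class CorrelationBlock:
    """A clustered set of co-methylated CpGs with its representative tag-CpG."""

    chrom: str
    member_cpg_ids: list[str]
    tag_cpg_id: str | None = None

    def __len__(self) -> int:
        return len(self.member_cpg_ids)


def chunk_cpgs(n: int, max_cpgs_per_chunk: int) -> list[tuple[int, int]]:
    """Split ``n`` positionally sorted CpGs into contiguous chunks.

    Returns (start, stop) index pairs; k = ceil(n / max) chunks whose sizes
    differ by at most one, preserving input order.
    """
    if n == 0:
        return []
    k = math.ceil(n / max_cpgs_per_chunk)
    base, extra = divmod(n, k)
    bounds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def _pairwise_correlation(beta_chunk: np.ndarray, min_shared: int) -> np.ndarray:
    """Pearson correlation between rows, pairwise-complete over samples.

    Pairs with fewer than ``min_shared`` shared non-missing samples, or a
    constant CpG, yield correlation 0.
    """
    if np.isfinite(beta_chunk).all():
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(beta_chunk)
        corr = np.atleast_2d(corr)
        return np.nan_to_num(corr, nan=0.0)
    # missing data: fall back to pandas pairwise-complete machinery
    df = pd.DataFrame(beta_chunk.T)
    corr = df.corr(method="pearson", min_periods=min_shared).to_numpy()
    return np.nan_to_num(corr, nan=0.0)


def pairwise_similarity(
    beta_chunk: np.ndarray,
    positions: np.ndarray,
    params: BlockParams | None = None,
) -> sparse.csr_matrix:
    """Distance-weighted correlation similarity for one chunk.

    s_ij = r_ij * exp(-d_ij^2 / (2 * gauss_sd^2)), set to 0 when
    r_ij < cluster_cor_threshold or d_ij > absolute_distance_cutoff.
    The diagonal is excluded. Returned sparse and symmetric.
    """
    params = params or BlockParams()
    beta_chunk = np.asarray(beta_chunk, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    n = beta_chunk.shape[0]
    if n == 0:
        return sparse.csr_matrix((0, 0))
    corr = _pairwise_correlation(beta_chunk, params.min_shared_samples)
    n_constant = int((np.nanstd(beta_chunk, axis=1) == 0).sum())
    if n_constant:
        logger.info("%d constant CpGs get zero similarity to all partners",
                    n_constant)
    corr[corr < params.cluster_cor_threshold] = 0.0
    dist = np.abs(positions[:, None] - positions[None, :]).astype(float)
    weight = np.exp(-(dist**2) / (2.0 * params.gauss_sd**2))
    sim = corr * weight
    sim[dist > params.absolute_distance_cutoff] = 0.0
    np.fill_diagonal(sim, 0.0)
    return sparse.csr_matrix(sim)


def call_blocks(
    methylation: MethylationMatrix,
    params: BlockParams | None = None,
    assign_tags: bool = True,
) -> list[CorrelationBlock]:
    """Call correlation blocks for every chromosome of a methylation matrix.

    Chunks never span chromosomes; pairs in different chunks are never
    connected. Louvain is run with ``clustering_seed`` for determinism and
    singleton communities become single-CpG blocks.
    """
    params = params or BlockParams()
    blocks: list[CorrelationBlock] = []
    for chrom in pd.unique(methylation.chrom):
        idx = np.flatnonzero(methylation.chrom == chrom)
        for start, stop in chunk_cpgs(len(idx), params.max_cpgs_per_chunk):
            chunk_idx = idx[start:stop]
            sim = pairwise_similarity(
                methylation.beta[chunk_idx], methylation.pos[chunk_idx], params
            )
            graph = nx.from_scipy_sparse_array(sim)
            graph.add_nodes_from(range(len(chunk_idx)))
            communities = nx.community.louvain_communities(
                graph,
                weight="weight",
                resolution=params.louvain_resolution,
                seed=params.clustering_seed,
            )
            for community in communities:
                members = sorted(community)  # chunk is position-sorted already
                blocks.append(
                    CorrelationBlock(
                        chrom=str(chrom),
                        member_cpg_ids=[
                            methylation.cpg_ids[chunk_idx[m]] for m in members
                        ],
                    )
                )
    pos_of = dict(zip(methylation.cpg_ids, methylation.pos))
    blocks.sort(key=lambda b: (b.chrom, int(pos_of[b.member_cpg_ids[0]])))
    if assign_tags:
        from comethqtl.methqtl import select_tag_cpg

        for block in blocks:
            block.tag_cpg_id = select_tag_cpg(block, methylation)
    return blocks


def blocks_to_tables(
    blocks: list[CorrelationBlock], methylation: MethylationMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BED-style block summary (0-based half-open) and a membership table."""
    pos = dict(zip(methylation.cpg_ids, methylation.pos))
    bed_rows, member_rows = [], []
    for k, block in enumerate(blocks):
        block_id = f"block_{k + 1}"
        positions = [pos[c] for c in block.member_cpg_ids]
        bed_rows.append(
            {
                "chrom": block.chrom,
                "start": min(positions) - 1,
                "end": max(positions),
                "block_id": block_id,
                "size": len(block),
                "tag_cpg": block.tag_cpg_id,
            }
        )
        for cpg in block.member_cpg_ids:
            member_rows.append({"block_id": block_id, "cpg_id": cpg})
    return pd.DataFrame(bed_rows), pd.DataFrame(member_rows)
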