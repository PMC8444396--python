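"""Annotation-overlap enrichment with one-sided Fisher exact tests.

Intervals are 1-based inclusive internally; BED input (0-based half-open)
is converted on load. A position equal to an interval endpoint overlaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AnnotationSet:
    """Named set of genomic intervals (chrom, start, end), 1-based inclusive."""

    name: str
    intervals: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required <= set(self.intervals.columns):
            raise ValueError(f"intervals need columns {sorted(required)}")
        if (self.intervals["start"] > self.intervals["end"]).any():
            raise ValueError("interval start exceeds end")

    @classmethod
    def from_bed(cls, path: str, name: str | None = None) -> "AnnotationSet":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
        )
        df["chrom"] = df["chrom"].astype(str).str.replace("^chr", "", regex=True)
        df["start"] = df["start"] + 1  # BED is 0-based half-open
        return cls(name=name or str(path), intervals=df)

    def overlaps(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Boolean vector: does each (chrom, pos) fall in any interval?"""
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.zeros(positions.size, dtype=bool)
        for chrom, sub in self.intervals.groupby("chrom"):
            mask = chroms == str(chrom)
            if not mask.any():
                continue
            # merge to sorted disjoint intervals, then binary-search
            ivs = sub.sort_values("start")[["start", "end"]].to_numpy()
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged])
            ends = np.array([m[1] for m in merged])
            pos = positions[mask]
            j = np.searchsorted(starts, pos, side="right") - 1
            hit = (j >= 0) & (pos <= ends[np.clip(j, 0, None)])
            out[mask] = hit
        return out


def promoter_regions(tss_pos: int, strand: str) -> tuple[int, int]:
    """Promoter interval around a TSS: 1.5 kb upstream, 0.5 kb downstream.

    Plus strand: [tss - 1500, tss + 500]; minus strand mirrored.
    Coordinates below 1 are clipped with a warning.
    """
    if strand == "+":
        start, end = tss_pos - 1500, tss_pos + 500
    elif strand == "-":
        start, end = tss_pos - 500, tss_pos + 1500
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if start < 1:
        logger.warning("promoter start %d clipped to 1", start)
        start = 1
    return start, end


def overlap_enrichment(
    query_positions: pd.DataFrame,
    annotation: AnnotationSet,
    background_positions: pd.DataFrame,
) -> tuple[float, float, tuple[int, int, int, int]]:
    """One-sided Fisher enrichment of query vs background annotation overlap.

    Both position frames need columns ``chrom`` and ``pos``; the query must
    be a subset of the background (matched on chrom:pos). The 2x2 table is
    (in query?, overlaps annotation?) with the non-query cells drawn from
    background minus query. Returns (odds_ratio, one_sided_p, (a, b, c, d));
    the odds ratio uses the 0.5 Haldane correction when any cell is zero.
    """
    if query_positions.empty:
        raise ValueError("empty query")
    key = lambda df: set(zip(df["chrom"].astype(str), df["pos"].astype(int)))
    if not key(query_positions) <= key(background_positions):
        raise ValueError("query positions must be a subset of the background")
    q_keys = key(query_positions)
    bg = background_positions.drop_duplicates(subset=["chrom", "pos"])
    in_query = np.array(
        [(str(c), int(p)) in q_keys for c, p in zip(bg["chrom"], bg["pos"])]
    )
    hits = annotation.overlaps(bg["chrom"].to_numpy(), bg["pos"].to_numpy())
    a = int(np.sum(in_query & hits))
    b = int(np.sum(in_query & ~hits))
    c = int(np.sum(~in_query & hits))
    d = int(np.sum(~in_query & ~hits))
    _, p_one_sided = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if min(a, b, c, d) == 0:
        odds_ratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds_ratio = (a * d) / (b * c)
    return float(odds_ratio), float(p_one_sided), (a, b, c, d)
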