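"""Per-base depth, per-gene breadth/mean depth, and cross-sample normalization.

Breadth of a gene is the fraction of its positions covered by at least one
primary alignment; mean depth is the average per-base depth over the gene
interval (in x, fold coverage).  Gene mean depth divided by the sample's
genome-wide mean depth gives the dimensionless *normalized depth* used for
cross-sample comparison.

CIGAR semantics follow standard depth tools: M/=/X add depth at each
consumed position, D/N consume reference without adding depth, I/S/H touch
no reference position.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from symprof.io import (
    DEPTH_OPS,
    REF_CONSUMING_OPS,
    AlignmentRecord,
    GeneInterval,
    ParameterError,
    read_sam,
)

logger = logging.getLogger("symprof")


class AlignmentOutOfBounds(ParameterError):
    """An alignment consumed reference positions past the reference end."""


def _depth_segments(rec: AlignmentRecord) -> list[tuple[int, int]]:
    """Half-open reference segments of ``rec`` that receive depth."""
    segments = []
    pos = rec.pos0
    for length, op in rec.cigar:
        if op in DEPTH_OPS:
            segments.append((pos, pos + length))
            pos += length
        elif op in REF_CONSUMING_OPS:  # D, N
            pos += length
    return segments


def depth_from_segments(
    starts: np.ndarray, ends: np.ndarray, reference_length: int
) -> np.ndarray:
    """Accumulate half-open [start, end) segments into a per-base depth vector."""
    delta = np.zeros(reference_length + 1, dtype=np.int64)
    np.add.at(delta, starts, 1)
    np.add.at(delta, ends, -1)
    return np.cumsum(delta[:-1])


def per_base_depth(
    alignments: Iterable[AlignmentRecord], reference_length: int
) -> np.ndarray:
    """Per-base depth vector over the reference from primary alignments."""
    if reference_length < 1:
        raise ParameterError("reference_length must be >= 1")
    starts: list[int] = []
    ends: list[int] = []
    for rec in alignments:
        end = rec.pos0 + rec.reference_span
        if end > reference_length:
            raise AlignmentOutOfBounds(
                f"read {rec.read_id!r} consumes positions up to {end}, "
                f"past reference end {reference_length}"
            )
        for s, e in _depth_segments(rec):
            starts.append(s)
            ends.append(e)
    return depth_from_segments(
        np.asarray(starts, dtype=np.intp), np.asarray(ends, dtype=np.intp), reference_length
    )


def gene_coverage(depth: np.ndarray, gene: GeneInterval) -> tuple[float, float]:
    """(breadth, mean_depth) of a gene interval over a depth profile."""
    if gene.end > depth.shape[0]:
        raise ParameterError(f"gene {gene.gene_id!r} extends past the reference end")
    window = depth[gene.start : gene.end]
    breadth = float(np.count_nonzero(window)) / gene.length
    mean_depth = float(window.sum()) / gene.length
    return breadth, mean_depth


def genome_mean_depth(depth: np.ndarray) -> float:
    """Genome-wide mean depth: total aligned bases / reference length."""
    if depth.shape[0] < 1:
        raise ParameterError("zero-length reference")
    return float(depth.sum()) / depth.shape[0]


def normalize_depth(mean_depth: float, genome_mean: float) -> float:
    """Gene mean depth / genome-wide mean depth; NaN when the genome mean is 0.

    A zero genome mean means the sample has no usable alignments; the caller
    flags such samples and normalized depth is reported missing.
    """
    if genome_mean < 0:
        raise ParameterError("genome mean depth cannot be negative")
    if genome_mean == 0:
        return math.nan
    return mean_depth / genome_mean


def coverage_table_from_profiles(
    profiles: Mapping[str, np.ndarray], genes: Sequence[GeneInterval]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(gene, sample) coverage metrics from per-sample depth profiles.

    Returns ``(coverage, sample_depth)``: one coverage row per (sample, gene)
    with breadth, mean depth and normalized depth, and a per-sample side
    table with the genome-wide mean depth and a usability flag.
    """
    cov_rows = []
    sample_rows = []
    for sample_id, depth in profiles.items():
        gmean = genome_mean_depth(depth)
        usable = gmean > 0
        if not usable:
            logger.warning("coverage_table: sample %s has zero mapped depth", sample_id)
        sample_rows.append(
            {"sample_id": sample_id, "genome_mean_depth": gmean, "usable": usable}
        )
        # vectorized per-gene sums via cumulative arrays
        csum = np.concatenate(([0], np.cumsum(depth)))
        cnz = np.concatenate(([0], np.cumsum(depth > 0)))
        for g in genes:
            total = csum[g.end] - csum[g.start]
            covered = cnz[g.end] - cnz[g.start]
            mean_d = total / g.length
            cov_rows.append(
                {
                    "sample_id": sample_id,
                    "gene_id": g.gene_id,
                    "breadth": covered / g.length,
                    "mean_depth": mean_d,
                    "normalized_depth": normalize_depth(mean_d, gmean),
                }
            )
    coverage = pd.DataFrame(
        cov_rows, columns=["sample_id", "gene_id", "breadth", "mean_depth", "normalized_depth"]
    )
    sample_depth = pd.DataFrame(
        sample_rows, columns=["sample_id", "genome_mean_depth", "usable"]
    )
    return coverage, sample_depth


def coverage_table(
    sample_sams: Mapping[str, str],
    genes: Sequence[GeneInterval],
    reference_length: int,
    mapq_min: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coverage metrics for a cohort of per-sample SAM files."""
    if not sample_sams:
        raise ParameterError("coverage_table requires at least one sample")
    profiles = {
        sample_id: per_base_depth(read_sam(path, mapq_min=mapq_min), reference_length)
        for sample_id, path in sample_sams.items()
    }
    return coverage_table_from_profiles(profiles, genes)


def write_coverage_tables(
    coverage: pd.DataFrame, sample_depth: pd.DataFrame, out_dir, float_fmt: str = "%.6f"
) -> None:
    coverage.to_csv(out_dir / "coverage.tsv", sep="\t", index=False, float_format=float_fmt)
    sample_depth.to_csv(
        out_dir / "sample_depth.tsv", sep="\t", index=False, float_format=float_fmt
    )
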