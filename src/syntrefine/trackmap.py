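"""Comparison of positional feature tracks between two species over
syntenic one-to-one orthologs.

For each gene the track is aggregated to a single value: the fraction of
the gene's base pairs covered by track elements (unweighted tracks) or
the length-weighted average signal over the full gene span, with
uncovered bases contributing zero (weighted tracks). Per-species value
vectors are standardised to Z-scores, and per ortholog pair the absolute
Z-score difference ``d_i = |z_A,i - z_B,i|`` measures feature
conservation; the vector mean summarises the whole track pair. Because
both species are standardised, the measure is symmetric — neither genome
is a source or a target — and invariant to positive rescaling of either
track. For two unrelated tracks the d_i behave like |Z1 - Z2| of
independent standard normals, whose expectation is 2/sqrt(pi) ~ 1.1284.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .model import DataWarning, FeatureTrack, Gene

ANALYTIC_NULL_MEAN = 2.0 / np.sqrt(np.pi)


def gene_feature_values(genes: Sequence[Gene], track: FeatureTrack) -> np.ndarray:
    """Aggregate a track to one raw value per gene.

    Unweighted: overlapped bp / gene length in [0, 1] per element, summed
    over elements (overlapping elements stack). Weighted:
    sum(overlap_bp * weight) / gene length.
    """
    trees: dict = {}
    for chrom, start, end, weight in track.elements:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, weight)

    values = np.zeros(len(genes), dtype=float)
    for i, g in enumerate(genes):
        if g.length <= 0:
            raise ValueError(f"gene {g.id!r} has non-positive length")
        tree = trees.get(g.chromosome)
        if tree is None:
            continue
        total = 0.0
        for iv in tree.overlap(g.start, g.end):
            ov = min(iv.end, g.end) - max(iv.begin, g.start)
            total += ov * (iv.data if track.has_weights else 1.0)
        values[i] = total / g.length
    return values


def zscore_normalize(values) -> np.ndarray:
    """Standardise to mean 0, population SD 1.

    A constant vector yields all zeros with a :class:`DataWarning`;
    fewer than two values is an error.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("zscore_normalize requires at least 2 values")
    sd = values.std()  # population SD
    if sd == 0.0:
        warnings.warn("constant value vector: Z-scores set to zero",
                      DataWarning, stacklevel=2)
        return np.zeros_like(values)
    return (values - values.mean()) / sd


@dataclass
class TrackComparison:
    """Per-pair absolute Z-score differences and their mean."""

    d: np.ndarray
    mean_difference: float
    pairs: Optional[tuple] = None
    z_A: Optional[np.ndarray] = None
    z_B: Optional[np.ndarray] = None
    values_A: Optional[np.ndarray] = None
    values_B: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.d)

    def table(self):
        """Per-pair table sorted ascending by difference, so the most
        conserved orthologs come first. Returns a pandas DataFrame."""
        import pandas as pd

        n = len(self.d)
        frame = pd.DataFrame(
            {
                "gene_A": [p.gene_A for p in self.pairs] if self.pairs else [""] * n,
                "gene_B": [p.gene_B for p in self.pairs] if self.pairs else [""] * n,
                "value_A": self.values_A if self.values_A is not None else np.full(n, np.nan),
                "value_B": self.values_B if self.values_B is not None else np.full(n, np.nan),
                "z_A": self.z_A if self.z_A is not None else np.full(n, np.nan),
                "z_B": self.z_B if self.z_B is not None else np.full(n, np.nan),
                "difference": self.d,
            }
        )
        return frame.sort_values(
            ["difference", "gene_A"], kind="mergesort"
        ).reset_index(drop=True)


def difference_scores(z_A, z_B, pairs: Optional[Sequence] = None,
                      values_A=None, values_B=None) -> TrackComparison:
    """Per-pair ``|z_A - z_B|`` over pair-aligned Z-vectors."""
    z_A = np.asarray(z_A, dtype=float)
    z_B = np.asarray(z_B, dtype=float)
    if z_A.shape != z_B.shape:
        raise ValueError(f"length mismatch: {z_A.shape} vs {z_B.shape}")
    d = np.abs(z_A - z_B)
    return TrackComparison(
        d=d,
        mean_difference=float(d.mean()) if d.size else 0.0,
        pairs=tuple(pairs) if pairs is not None else None,
        z_A=z_A,
        z_B=z_B,
        values_A=None if values_A is None else np.asarray(values_A, dtype=float),
        values_B=None if values_B is None else np.asarray(values_B, dtype=float),
    )


def compare_tracks(
    pairs: Sequence,
    genes_by_id: dict,
    track_A: FeatureTrack,
    track_B: FeatureTrack,
) -> TrackComparison:
    """Full pipeline for one track pair over resolved ortholog pairs."""
    genes_A = [genes_by_id[p.gene_A] for p in pairs]
    genes_B = [genes_by_id[p.gene_B] for p in pairs]
    values_A = gene_feature_values(genes_A, track_A)
    values_B = gene_feature_values(genes_B, track_B)
    z_A = zscore_normalize(values_A)
    z_B = zscore_normalize(values_B)
    return difference_scores(z_A, z_B, pairs=pairs,
                             values_A=values_A, values_B=values_B)


def randomize_track(track: FeatureTrack, chrom_sizes: dict, seed=None) -> FeatureTrack:
    """Null model: per chromosome, the same number of elements with the
    same multiset of lengths at uniformly random start positions
    (overlaps permitted). Weights stay attached to their element length."""
    rng = np.random.default_rng(seed)
    out = []
    for chrom, elements in sorted(track.by_chromosome().items()):
        if chrom not in chrom_sizes:
            raise ValueError(f"no chromosome size for {chrom!r}")
        size = chrom_sizes[chrom]
        for _, start, end, weight in elements:
            length = end - start
            if length > size:
                raise ValueError(
                    f"element of length {length} exceeds chromosome {chrom!r} "
                    f"(length {size})"
                )
            new_start = int(rng.integers(0, size - length + 1))
            out.append((chrom, new_start, new_start + length, weight))
    return FeatureTrack(elements=out, has_weights=track.has_weights)


def significance_vs_random(real: TrackComparison, random: TrackComparison) -> float:
    """One-sided rank-sum p-value for "real differences are smaller than
    random" (normal approximation with tie correction and continuity)."""
    if len(real) < 20 or len(random) < 20:
        raise ValueError("significance_vs_random requires >= 20 pairs per sample")
    result = stats.mannwhitneyu(real.d, random.d, alternative="less",
                                method="asymptotic")
    return float(result.pvalue)
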