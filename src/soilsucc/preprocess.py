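"""Depth filtering and normalization of feature tables.

Scaling-with-ranked-subsampling (SRS) is the default normalization for OTU
tables: each sample's counts are scaled to a common depth *cmin*, the integer
parts kept, and the remaining units distributed one each down the ranking of
fractional parts.  Unlike rarefaction it is deterministic and preserves the
rank structure of each sample.  Gene-family tables are rarefied (multivariate
hypergeometric draws) to the observed minimum depth instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import FeatureTable

logger = logging.getLogger("soilsucc")


class DepthError(ValueError):
    """A sample is too shallow for the requested depth, or nothing survives."""


@dataclass
class NormalizationSpec:
    """How to bring samples to a common depth.

    method: 'srs' (deterministic scaling with ranked subsampling), 'rarefy'
    (random subsampling without replacement) or 'relative' (proportions).
    cmin: target depth for srs/rarefy. tie_break: how SRS resolves equal
    fractional parts — 'by_count_then_index' (deterministic, default) or
    'random' (seeded).
    """

    method: str = "srs"
    cmin: int = 3000
    seed: int = 0
    tie_break: str = "by_count_then_index"

    def __post_init__(self) -> None:
        if self.method not in ("srs", "rarefy", "relative"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.tie_break not in ("by_count_then_index", "random"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        if self.method != "relative" and self.cmin <= 0:
            raise ValueError("cmin must be a positive integer")


def filter_low_depth(ft: FeatureTable, min_reads: int) -> FeatureTable:
    """Drop samples whose total read count falls below ``min_reads``.

    Samples with exactly ``min_reads`` are retained (only strictly shallower
    samples are discarded).
    """
    sums = ft.column_sums()
    keep = sums[sums >= min_reads].index
    removed = [s for s in ft.sample_ids if s not in set(keep)]
    if removed:
        logger.info("filter_low_depth: removed %d sample(s): %s",
                    len(removed), removed)
    if len(keep) == 0:
        raise DepthError(f"no sample reaches min_reads={min_reads}")
    return ft.with_values(ft.values[list(keep)])


def _srs_column(col: np.ndarray, cmin: int, tie_break: str,
                rng: np.random.Generator | None) -> np.ndarray:
    total = col.sum()
    scaled = col * (cmin / total)
    floors = np.floor(scaled).astype(np.int64)
    remainder = int(cmin - floors.sum())
    if remainder == 0:
        return floors
    frac = scaled - floors
    if tie_break == "by_count_then_index":
        # descending fractional part, ties → larger original count, then
        # smaller feature index; argsort is ascending so negate sort keys
        order = np.lexsort((np.arange(col.size), -col, -frac))
    else:
        jitter = rng.random(col.size)
        order = np.lexsort((jitter, -frac))
    out = floors.copy()
    out[order[:remainder]] += 1
    return out


def srs_normalize(ft: FeatureTable, spec: NormalizationSpec) -> FeatureTable:
    """Normalize every sample to depth ``spec.cmin`` by SRS.

    Output column sums equal cmin exactly.  Deterministic under the default
    tie-break; the 'random' tie-break uses ``spec.seed``.
    """
    sums = ft.column_sums()
    shallow = sums[sums < spec.cmin]
    if len(shallow):
        raise DepthError(
            f"cmin={spec.cmin} exceeds depth of sample(s) {list(shallow.index)}"
        )
    rng = np.random.default_rng(spec.seed) if spec.tie_break == "random" else None
    arr = ft.values.to_numpy()
    out = np.column_stack(
        [_srs_column(arr[:, j], spec.cmin, spec.tie_break, rng)
         for j in range(arr.shape[1])]
    )
    return ft.with_values(
        pd.DataFrame(out, index=ft.values.index, columns=ft.values.columns)
    )


def rarefy(ft: FeatureTable, cmin: int, seed: int = 0) -> FeatureTable:
    """Subsample every sample to ``cmin`` reads without replacement.

    Each column is a multivariate-hypergeometric draw of cmin reads from the
    observed counts; zero features stay zero.
    """
    sums = ft.column_sums()
    shallow = sums[sums < cmin]
    if len(shallow):
        raise DepthError(
            f"cmin={cmin} exceeds depth of sample(s) {list(shallow.index)}"
        )
    rng = np.random.default_rng(seed)
    arr = ft.values.to_numpy().astype(np.int64)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(arr[:, j], cmin)
    return ft.with_values(
        pd.DataFrame(out, index=ft.values.index, columns=ft.values.columns)
    )


def to_relative(ft: FeatureTable) -> FeatureTable:
    """Convert counts to within-sample relative abundances (columns sum to 1)."""
    sums = ft.column_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise DepthError(f"sample(s) with zero total: {list(zero.index)}")
    return ft.with_values(ft.values / sums)


def normalize(ft: FeatureTable, spec: NormalizationSpec) -> FeatureTable:
    """Dispatch to the method named in ``spec``."""
    if spec.method == "srs":
        return srs_normalize(ft, spec)
    if spec.method == "rarefy":
        return rarefy(ft, spec.cmin, spec.seed)
    return to_relative(ft)


def community_weighted_mean(cover, trait) -> tuple[float, float]:
    """Abundance-weighted mean of a trait over species with trait data.

    Weights are renormalized over the species that have a (non-null) trait
    value.  Returns (cwm, coverage) where coverage is the fraction of total
    cover carried by species with trait data; (nan, 0.0) when no species has
    a trait value.
    """
    cover = np.asarray(cover, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if cover.shape != trait.shape:
        raise ValueError("cover and trait must have matching length")
    if (cover < 0).any():
        raise ValueError("cover must be non-negative")
    have = ~np.isnan(trait)
    total = cover.sum()
    covered = cover[have].sum()
    if covered == 0:
        warnings.warn("community_weighted_mean: no species with trait data",
                      stacklevel=2)
        return float("nan"), 0.0
    w = cover[have] / covered
    coverage = covered / total if total > 0 else 0.0
    return float(np.dot(w, trait[have])), float(coverage)
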