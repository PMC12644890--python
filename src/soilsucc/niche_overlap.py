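"""Levin's niche breadth and overlap of gene families along the gradient.

A gene family's "niche" here is its occupancy profile across the samples of
one land-use stage: genes found evenly across many samples are habitat
generalists (high Levin breadth, high pairwise overlap), genes concentrated
in few samples are specialists.  Families whose abundance signal is too weak
to quantify are removed first by a signal-to-noise limit-of-quantification
rule (mean relative abundance must exceed q standard errors, q = 1.65, the
one-sided 95% normal point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import STAGES, FeatureTable, SampleFrame
from .diversity_stats import bh_adjust

DEFAULT_LOQ = 1.65


@dataclass
class NicheMetrics:
    feature_id: str
    stage: str
    breadth_B: float
    breadth_std: float
    above_loq: bool = True


@dataclass
class TrendFit:
    """Linear vs quadratic fit of overlap against stage rank."""

    model: str          # 'linear' or 'quadratic'
    slope: float        # slope of the linear fit (per stage step)
    quad_coef: float
    p_quad: float       # nested F-test for the quadratic term
    r2_linear: float
    r2_quadratic: float


def loq_filter(gene_table: FeatureTable, q: float = DEFAULT_LOQ
               ) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop gene families below the limit of quantification.

    Works on per-sample relative abundances.  A family is retained when its
    mean abundance across samples is at least ``q`` times the standard error
    of that mean (features observed identically everywhere have SE = 0 and
    are always retained).  Returns the filtered table and a per-feature
    report with the signal-to-noise ratio and the decision.
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    vals = gene_table.values.to_numpy(dtype=float)
    n = vals.shape[1]
    mean = vals.mean(axis=1)
    se = vals.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(se > 0, mean / se, np.inf)
    keep = mean >= q * se
    report = pd.DataFrame(
        {"mean": mean, "se": se, "snr": snr, "retained": keep},
        index=gene_table.values.index,
    ).rename_axis("feature_id")
    filtered = gene_table.with_values(gene_table.values.loc[keep])
    return filtered, report


def levins_breadth(feature_row, stage: str = "", feature_id: str = "",
                   ) -> NicheMetrics | None:
    """Levin's niche breadth of one feature across the samples of a stage.

    B = 1 / sum(p^2) for the feature's normalized occupancy p; standardized
    breadth (B - 1)/(N - 1) is 0 for single-sample occupancy and 1 for
    perfectly even occupancy over all N samples.
    """
    x = np.asarray(feature_row, dtype=float)
    if (x < 0).any():
        raise ValueError("occupancies must be non-negative")
    total = x.sum()
    if total == 0:
        warnings.warn(f"all-zero occupancy for feature {feature_id!r}",
                      stacklevel=2)
        return None
    p = x / total
    b = 1.0 / float((p * p).sum())
    n = x.size
    std = (b - 1.0) / (n - 1.0) if n > 1 else 0.0
    return NicheMetrics(feature_id, stage, b, std)


def levins_overlap(f, g) -> tuple[float, float, float]:
    """Levin's directional niche overlaps and their clipped symmetric mean.

    O_fg = sum(f*g)/sum(g^2) measures how much of g's niche f occupies (and
    can exceed 1); the symmetric summary is the mean of both directions
    clipped to [0, 1].
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape:
        raise ValueError("occupancy vectors must have equal length")
    sf2, sg2 = float(f @ f), float(g @ g)
    if sf2 == 0 or sg2 == 0:
        raise ValueError("zero occupancy vector in overlap")
    cross = float(f @ g)
    o_fg, o_gf = cross / sg2, cross / sf2
    sym = float(np.clip((o_fg + o_gf) / 2.0, 0.0, 1.0))
    return o_fg, o_gf, sym


def _pairwise_symmetric(p: np.ndarray) -> np.ndarray:
    """Upper-triangle symmetric overlaps among the rows of a normalized matrix."""
    s = p @ p.T
    sq = np.diag(s).copy()
    m = (s / sq[None, :] + s / sq[:, None]) / 2.0
    iu = np.triu_indices(p.shape[0], k=1)
    return np.clip(m[iu], 0.0, 1.0)


def stage_overlap_summary(
    gene_table: FeatureTable,
    sf: SampleFrame,
    class_map: dict[str, str] | None = None,
    min_features: int = 2,
    loq_q: float | None = DEFAULT_LOQ,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean pairwise gene-family overlap per stage (and per class).

    Within each stage, every retained family's occupancy is normalized over
    that stage's samples and all pairwise symmetric Levin overlaps are taken
    within each class of ``class_map`` (one pooled class when None).  The
    niche space of a stage is its own sample set, so the limit of
    quantification is applied within each stage as well (``loq_q``; None
    skips it): a family abundant elsewhere but unquantifiable in this stage
    does not enter the stage's overlap.  Returns (summary, tests): the
    per-stage/class mean +- sd of overlaps, and pairwise rank-sum
    comparisons of the overlap distributions between stages within each
    class, BH-adjusted.
    """
    stage = sf.stage.loc[gene_table.sample_ids]
    features = gene_table.feature_ids
    if class_map is None:
        class_map = {f: "all" for f in features}
    classes = sorted(set(class_map.get(f) for f in features) - {None})
    rows, dists = [], {}
    for st in STAGES:
        samples = stage.index[stage == st]
        if len(samples) == 0:
            continue
        sub = gene_table.values[list(samples)].to_numpy(dtype=float)
        totals = sub.sum(axis=1)
        if loq_q is not None and len(samples) > 1:
            m = sub.mean(axis=1)
            se = sub.std(axis=1, ddof=1) / np.sqrt(len(samples))
            quantifiable = m >= loq_q * se
        else:
            quantifiable = np.ones(sub.shape[0], dtype=bool)
        for cls in classes:
            sel = np.array([class_map.get(f) == cls and totals[i] > 0
                            and quantifiable[i]
                            for i, f in enumerate(features)])
            if sel.sum() < min_features:
                warnings.warn(
                    f"stage {st!r} class {cls!r}: <{min_features} retained "
                    "features, overlap undefined", stacklevel=2)
                rows.append({"stage": st, "class": cls, "mean_overlap": np.nan,
                             "sd_overlap": np.nan, "n_pairs": 0})
                continue
            p = sub[sel]
            p = p / p.sum(axis=1, keepdims=True)
            ov = _pairwise_symmetric(p)
            dists[(st, cls)] = ov
            rows.append({"stage": st, "class": cls,
                         "mean_overlap": float(ov.mean()),
                         "sd_overlap": float(ov.std(ddof=1)) if ov.size > 1 else 0.0,
                         "n_pairs": int(ov.size)})
    summary = pd.DataFrame(rows)

    test_rows = []
    present = [s for s in STAGES if any(k[0] == s for k in dists)]
    for cls in classes:
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                if (a, cls) not in dists or (b, cls) not in dists:
                    continue
                xa, xb = dists[(a, cls)], dists[(b, cls)]
                if np.ptp(np.concatenate([xa, xb])) == 0:
                    test_rows.append({"class": cls, "stage_a": a, "stage_b": b,
                                      "statistic": np.nan, "p": np.nan})
                    continue
                u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
                test_rows.append({"class": cls, "stage_a": a, "stage_b": b,
                                  "statistic": float(u), "p": float(p)})
    tests = pd.DataFrame(test_rows)
    if len(tests):
        ok = ~tests["p"].isna()
        tests["p_adj"] = np.nan
        if ok.any():
            tests.loc[ok, "p_adj"] = bh_adjust(tests.loc[ok, "p"].to_numpy())
    return summary, tests


def overlap_trend(stage_values: pd.DataFrame, alpha: float = 0.05) -> TrendFit:
    """Fit mean overlap against stage rank: straight line vs parabola.

    ``stage_values`` needs columns 'stage' and 'overlap' (one or many rows
    per stage).  The quadratic model is preferred only when its squared term
    survives a nested F-test at ``alpha``; otherwise the linear fit (and its
    slope sign) describes the gradient.
    """
    df = stage_values.dropna(subset=["overlap"])
    stages_present = [s for s in STAGES if s in set(df["stage"])]
    if len(stages_present) < 3:
        raise ValueError("need at least 3 stages for a trend fit")
    rank = df["stage"].map({s: i for i, s in enumerate(STAGES)}).to_numpy(float)
    y = df["overlap"].to_numpy(float)
    n = y.size

    def ols(design):
        x = np.column_stack([np.ones(n), *design])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        return beta, float(resid @ resid)

    beta_l, rss_l = ols([rank])
    beta_q, rss_q = ols([rank, rank**2])
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2_l = 1.0 - rss_l / ss_tot if ss_tot > 0 else 1.0
    r2_q = 1.0 - rss_q / ss_tot if ss_tot > 0 else 1.0
    df_err = n - 3
    tiny = max(1e-12 * max(ss_tot, 1.0), 1e-300)
    if df_err <= 0 or rss_l <= tiny:
        # perfect (or saturated) linear fit: nothing for the parabola to add
        p_quad = 1.0
    elif rss_q <= tiny:
        p_quad = 0.0
    else:
        f = (rss_l - rss_q) / (rss_q / df_err)
        p_quad = float(stats.f.sf(f, 1, df_err))
    model = "quadratic" if p_quad < alpha else "linear"
    return TrendFit(model=model, slope=float(beta_l[1]),
                    quad_coef=float(beta_q[2]), p_quad=p_quad,
                    r2_linear=r2_l, r2_quadratic=r2_q)
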