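"""Functional redundancy vs specialization: the D / Q / R decomposition.

For one community with relative abundances p and pairwise functional
distances d scaled into [0, 1]:

    D = sum(p_i^2)                  Simpson dominance
    Q = sum_ij p_i p_j d_ij         Rao's quadratic entropy (functional div.)
    R = (1 - D) - Q                 functional redundancy
    U = Q / (1 - D)                 functional uniqueness / specialization

Because d <= 1 implies Q <= 1 - D, the triple (D, Q, R) closes exactly to 1
and can be placed on a ternary plot whose vertical axis opposes redundancy to
specialization.  Functional distances are Euclidean on min-max scaled
gene-family (pathway) traits, computed within each land-use stage's
metacommunity only (taxa absent from a stage are excluded before the
stage-specific max-rescaling of distances).

The module also carries the decoupling regressions (functional-versus-
taxonomic Shannon diversity per ecosystem, whose significant coupling marks
*low* redundancy) and hierarchical partitioning of covariate contributions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .tables_io import STAGES, FeatureTable, SampleFrame, TraitMatrix
from .diversity_stats import DistanceMatrix, PermanovaResult, permanova


class ScalingError(ValueError):
    """Distances outside [0, 1] reached the ternary decomposition."""


@dataclass
class FunctionalDistanceMatrix:
    values: np.ndarray            # taxa x taxa, in [0, 1], max == 1
    taxa: list[str]
    scaling_context: str = ""     # land-use stage the max-scaling used
    degenerate: bool = False      # all distances zero (single taxon / identical traits)


@dataclass
class TernaryCoordinates:
    sample_id: str
    D: float
    Q: float
    R: float
    U: float | None


@dataclass
class DecouplingResult:
    ecosystem: str
    slope: float
    intercept: float
    p_slope: float
    r_squared: float
    n: int
    slope_difference_F: float = np.nan
    p_difference: float = np.nan
    ags_adjusted: bool = False


def scale_traits(tm: TraitMatrix) -> TraitMatrix:
    """Min-max scale every trait column into [0, 1].

    Constant columns carry no distance information and are set to zero with a
    warning.
    """
    v = tm.values
    if v.empty:
        raise ValueError("empty trait matrix")
    lo, hi = v.min(axis=0), v.max(axis=0)
    span = hi - lo
    constant = span[span == 0].index.tolist()
    if constant:
        warnings.warn(f"constant trait column(s) set to 0: {constant[:5]}"
                      f"{'...' if len(constant) > 5 else ''}", stacklevel=2)
    span = span.replace(0, 1.0)
    scaled = (v - lo) / span
    scaled[constant] = 0.0
    return TraitMatrix(values=scaled, family_class=tm.family_class,
                       substrate_class=tm.substrate_class)


def functional_distances(scaled: TraitMatrix, taxa_subset,
                         scaling_context: str = "") -> FunctionalDistanceMatrix:
    """Euclidean trait distances among the taxa present in one stage.

    Distances are divided by their maximum so the stage's most dissimilar
    pair sits at 1, the bound the ternary closure relies on.
    """
    taxa = [t for t in scaled.taxa if t in set(taxa_subset)]
    if len(taxa) < 2:
        return FunctionalDistanceMatrix(
            values=np.zeros((len(taxa), len(taxa))), taxa=taxa,
            scaling_context=scaling_context, degenerate=True)
    pts = scaled.values.loc[taxa].to_numpy(dtype=float)
    d = squareform(pdist(pts))
    dmax = d.max()
    if dmax == 0:
        return FunctionalDistanceMatrix(values=d, taxa=taxa,
                                        scaling_context=scaling_context,
                                        degenerate=True)
    return FunctionalDistanceMatrix(values=d / dmax, taxa=taxa,
                                    scaling_context=scaling_context)


def rao_q(p, d: np.ndarray) -> float:
    """Rao's quadratic entropy: full double sum p_i p_j d_ij over all i, j."""
    p = np.asarray(p, dtype=float)
    d = np.asarray(d, dtype=float)
    if d.shape != (p.size, p.size):
        raise ValueError("abundance vector and distance matrix are misaligned")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must be relative abundances summing to 1")
    return float(p @ d @ p)


def ternary_decompose(p, d: np.ndarray, sample_id: str = "") -> TernaryCoordinates:
    """Split a community's diversity into dominance D, Rao Q and redundancy R.

    Requires d within [0, 1] (after max-scaling); violations surface as a
    ScalingError instead of being clipped, since they break the closure
    D + Q + R = 1.
    """
    d = np.asarray(d, dtype=float)
    if d.size and (d.max() > 1.0 + 1e-9 or d.min() < -1e-12):
        raise ScalingError("functional distances must lie in [0, 1]")
    p = np.asarray(p, dtype=float)
    dom = float((p * p).sum())
    q = rao_q(p, d)
    r = (1.0 - dom) - q
    if r < -1e-9:
        raise ScalingError("negative redundancy: distance scaling violated")
    r = max(r, 0.0)
    u = q / (1.0 - dom) if (1.0 - dom) > 1e-12 else None
    return TernaryCoordinates(sample_id, dom, q, r, u)


def ternary_table(
    otu: FeatureTable,
    traits: TraitMatrix,
    sf: SampleFrame,
    nutrient: str | None = None,
) -> pd.DataFrame:
    """Per-sample (D, Q, R, U) using stage-specific functional distances.

    ``nutrient`` restricts the trait columns to one cycle (C, N or P).  For
    each stage, the metacommunity is the set of taxa with nonzero total
    abundance across that stage's samples; distances are scaled within it.
    """
    tm = traits
    if nutrient is not None:
        fams = tm.families_of_class(nutrient)
        if not fams:
            raise ValueError(f"no gene families of class {nutrient!r}")
        tm = TraitMatrix(values=tm.values[fams],
                         family_class={f: tm.family_class[f] for f in fams},
                         substrate_class={f: s for f, s in tm.substrate_class.items()
                                          if f in set(fams)})
    scaled = scale_traits(tm)
    stage = sf.stage.loc[otu.sample_ids]
    rel = otu.values / otu.values.sum(axis=0)
    rows = []
    for st in STAGES:
        samples = [s for s in otu.sample_ids if stage[s] == st]
        if not samples:
            continue
        sub = rel[samples]
        present = sub.index[sub.sum(axis=1) > 0]
        present = [t for t in present if t in set(scaled.taxa)]
        fdm = functional_distances(scaled, present, scaling_context=st)
        idx = {t: i for i, t in enumerate(fdm.taxa)}
        for s in samples:
            pvec = sub[s].loc[fdm.taxa].to_numpy(dtype=float)
            pvec = pvec / pvec.sum()
            tc = ternary_decompose(pvec, fdm.values, sample_id=s)
            rows.append({"sample_id": s, "stage": st, "D": tc.D, "Q": tc.Q,
                         "R": tc.R, "U": np.nan if tc.U is None else tc.U})
    return pd.DataFrame(rows).set_index("sample_id")


def ternary_group_test(coords: pd.DataFrame, groups, n_perm: int = 9999,
                       seed: int = 0) -> PermanovaResult:
    """perMANOVA on Bray-Curtis distances between (D, Q, R) triples."""
    triples = coords[["D", "Q", "R"]].to_numpy(dtype=float)
    d = squareform(pdist(triples, metric="braycurtis"))
    dm = DistanceMatrix(values=d, ids=list(coords.index), metric="bray_curtis")
    return permanova(dm, groups, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# decoupling regressions


def _ols(y: np.ndarray, X: np.ndarray):
    """Slope/intercept OLS with classical normal-theory inference."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - k
    if dof <= 0:
        raise ValueError("not enough observations for OLS inference")
    sigma2 = rss / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else np.nan
    return beta, se, pvals, r2, rss, dof


def _nested_f(rss_null: float, rss_full: float, dof_full: int
              ) -> tuple[float, float]:
    """F-test of one extra parameter; degenerate perfect fits give F=0."""
    gain = max(rss_null - rss_full, 0.0)
    if rss_full <= 1e-300:
        return (0.0, 1.0) if gain <= 1e-300 else (np.inf, 0.0)
    f = gain / (rss_full / dof_full)
    return float(f), float(stats.f.sf(f, 1, dof_full))


def decoupling_regression(
    tax_H: pd.Series,
    fun_H: pd.Series,
    sf: SampleFrame,
    ags: pd.Series | None = None,
) -> list[DecouplingResult]:
    """Functional ~ taxonomic Shannon diversity, one OLS fit per ecosystem.

    A significant slope marks *low* functional redundancy (taxon loss drags
    functional diversity with it).  When ``ags`` is given, average genome
    size enters every model as a covariate so gene counts scaling with genome
    size cannot masquerade as coupling.  The grassland/forest slope contrast
    is the F-test of the ecosystem x tax_H interaction in the pooled model.
    """
    common = tax_H.index.intersection(fun_H.index).intersection(sf.data.index)
    if ags is not None:
        common = common.intersection(ags.dropna().index)
    eco = sf.ecosystem.loc[common]
    results = []
    for ecosystem in ("grassland", "forest"):
        ids = common[eco.loc[common] == "forest"] if ecosystem == "forest" \
            else common[eco.loc[common] == "grassland"]
        if len(ids) < 4:
            raise ValueError(f"need >= 4 samples in {ecosystem}, got {len(ids)}")
        x = tax_H.loc[ids].to_numpy(float)
        y = fun_H.loc[ids].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"constant taxonomic diversity in {ecosystem}")
        cols = [np.ones_like(x), x]
        if ags is not None:
            cols.append(ags.loc[ids].to_numpy(float))
        X = np.column_stack(cols)
        beta, se, pvals, r2, *_ = _ols(y, X)
        results.append(DecouplingResult(
            ecosystem=ecosystem, slope=float(beta[1]), intercept=float(beta[0]),
            p_slope=float(pvals[1]), r_squared=float(r2), n=len(ids),
            ags_adjusted=ags is not None))

    # pooled model with interaction: y ~ x * ecosystem (+ ags)
    x = tax_H.loc[common].to_numpy(float)
    y = fun_H.loc[common].to_numpy(float)
    is_forest = (eco.loc[common] == "forest").to_numpy(float)
    cols = [np.ones_like(x), x, is_forest, x * is_forest]
    if ags is not None:
        cols.append(ags.loc[common].to_numpy(float))
    X_full = np.column_stack(cols)
    X_null = np.delete(X_full, 3, axis=1)
    _, _, _, _, rss_full, dof_full = _ols(y, X_full)
    _, _, _, _, rss_null, _ = _ols(y, X_null)
    f_int, p_int = _nested_f(rss_null, rss_full, dof_full)
    for r in results:
        r.slope_difference_F = float(f_int)
        r.p_difference = p_int
    return results


# ---------------------------------------------------------------------------
# hierarchical partitioning


def hierarchical_partitioning(response, predictors: pd.DataFrame
                              ) -> pd.Series:
    """Independent contribution of each predictor to the full-model R^2.

    All-subsets OLS: a predictor's contribution is its marginal R^2 gain
    averaged within each hierarchy level (subset size) and then across
    levels.  Contributions sum exactly to the full-model R^2.  Refuses more
    than 6 predictors (the number of subsets doubles per predictor).
    """
    y = np.asarray(response, dtype=float)
    names = list(predictors.columns)
    k = len(names)
    if k == 0:
        raise ValueError("need at least one predictor")
    if k > 6:
        raise ValueError("more than 6 predictors: subset space explodes; "
                         "pre-select a subset")
    Xall = predictors.to_numpy(dtype=float)
    Xall = (Xall - Xall.mean(axis=0)) / Xall.std(axis=0, ddof=0)
    n = y.size
    if n <= 2**1 or n <= k + 1:
        raise ValueError("too few observations for the design")

    r2: dict[frozenset, float] = {frozenset(): 0.0}
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant response")
    for size in range(1, k + 1):
        for subset in itertools.combinations(range(k), size):
            X = np.column_stack([np.ones(n), Xall[:, list(subset)]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            r2[frozenset(subset)] = 1.0 - float(resid @ resid) / ss_tot

    contrib = {}
    for i in range(k):
        others = [j for j in range(k) if j != i]
        level_means = []
        for h in range(0, k):
            gains = [r2[frozenset(s) | {i}] - r2[frozenset(s)]
                     for s in itertools.combinations(others, h)]
            level_means.append(np.mean(gains))
        contrib[names[i]] = float(np.mean(level_means))
    return pd.Series(contrib, name="independent_contribution")
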