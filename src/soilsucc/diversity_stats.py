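"""Alpha/beta diversity, permutational tests, effect sizes and trend shapes.

Alpha diversity is Shannon's H' (natural log) and the Simpson dominance
index D = sum(p^2).  Beta diversity uses Bray-Curtis distances, ordinated by
classical PCoA and tested by perMANOVA (pseudo-F with a seeded permutation
p-value; permutations can be restricted within strata for the paired
grassland-forest design).  Paired ecosystem contrasts are summarized as
partial omega-squared from a two-way block ANOVA, and per-substrate contrasts
as Hedges' g.  The stage-response classifier assigns one of
flat / linear / unimodal / threshold to a covariate or diversity trajectory
across the four ordered land-use stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .tables_io import STAGES, EffectSize, FeatureTable, SampleFrame


class DegenerateDataError(ValueError):
    """The data carry no variation the requested statistic can use."""


# ---------------------------------------------------------------------------
# alpha diversity


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("relative abundances must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"abundances must sum to 1 (got {p.sum()!r})")
    return p


def shannon(p) -> float:
    """Shannon entropy H' = -sum(p ln p) in nats; 0*ln(0) taken as 0."""
    p = _check_probs(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def simpson_dominance(p) -> float:
    """Simpson dominance D = sum(p^2): probability two draws coincide."""
    p = _check_probs(p)
    return float((p * p).sum())


def richness(p) -> int:
    return int((np.asarray(p) > 0).sum())


def diversity_profile(ft: FeatureTable) -> pd.DataFrame:
    """Per-sample Shannon H', Simpson D and richness from a count table."""
    rows = {}
    for s in ft.sample_ids:
        col = ft.values[s].to_numpy(dtype=float)
        tot = col.sum()
        if tot == 0:
            rows[s] = (np.nan, np.nan, 0)
            continue
        p = col / tot
        rows[s] = (shannon(p), simpson_dominance(p), richness(p))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["shannon_H", "simpson_D", "richness"]
    ).rename_axis("sample_id")


# ---------------------------------------------------------------------------
# distances and ordination


@dataclass
class DistanceMatrix:
    values: np.ndarray
    ids: list[str]
    metric: str = "bray_curtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise DegenerateDataError("Bray-Curtis undefined for two all-zero samples")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(ft: FeatureTable) -> DistanceMatrix:
    """All-pairs Bray-Curtis distances between the samples of a table."""
    mat = ft.values.to_numpy(dtype=float).T
    if (mat.sum(axis=1) == 0).any():
        raise DegenerateDataError("all-zero sample in distance computation")
    d = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(values=d, ids=ft.sample_ids, metric="bray_curtis")


def euclidean_matrix(points: np.ndarray, ids) -> DistanceMatrix:
    d = squareform(pdist(np.asarray(points, dtype=float)))
    return DistanceMatrix(values=d, ids=list(ids), metric="euclidean")


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray    # all n, descending, negatives included


def pcoa(d: DistanceMatrix, k: int = 2) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers -d^2/2 and eigendecomposes; axes are ordered by eigenvalue
    and scaled by sqrt(eigenvalue).  Negative eigenvalues are reported
    unchanged (no Lingoes/Cailliez correction); axes are only produced for
    positive eigenvalues.
    """
    n = d.n
    if n < 3:
        raise ValueError("pcoa needs at least 3 points")
    if k > n - 1:
        raise ValueError(f"k={k} exceeds the maximum of n-1={n - 1} axes")
    a = -0.5 * d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((n, k))
    for ax in range(k):
        if eigval[ax] > 1e-12:
            coords[:, ax] = eigvec[:, ax] * math.sqrt(eigval[ax])
    cols = [f"PCo{i + 1}" for i in range(k)]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=d.ids, columns=cols),
        eigenvalues=eigval,
    )


# ---------------------------------------------------------------------------
# perMANOVA


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    permutations: int
    partial_omega_sq: float
    degenerate: bool = False


def _within_ss(d2: np.ndarray, labels_int: np.ndarray, k: int) -> float:
    ss = 0.0
    for g in range(k):
        z = labels_int == g
        ng = z.sum()
        ss += d2[np.ix_(z, z)].sum() / (2.0 * ng)
    return ss


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 10_000,
    seed: int = 0,
    strata=None,
) -> PermanovaResult:
    """One-way permutational multivariate ANOVA on a distance matrix.

    SS_total = sum of squared distances / N; SS_within pools within-group
    squared distances weighted 1/n_g; pseudo-F = (SS_between/df_b) /
    (SS_within/df_w).  The p-value is (1 + #{F_perm >= F_obs}) / (1 + n_perm)
    under seeded label permutations, optionally restricted within ``strata``
    blocks (e.g. site pairs).  Degenerate partitions (zero within- or
    between-group variation) are flagged rather than tested.
    """
    labels = pd.Series(list(groups))
    if len(labels) != d.n:
        raise ValueError("group labels must match the distance matrix")
    cats = labels.astype("category")
    labels_int = cats.cat.codes.to_numpy()
    k = len(cats.cat.categories)
    if k < 2:
        raise ValueError("permanova needs at least 2 groups")
    counts = np.bincount(labels_int)
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")

    n = d.n
    d2 = d.values**2
    ss_t = d2.sum() / (2.0 * n)
    ss_w = _within_ss(d2, labels_int, k)
    ss_b = ss_t - ss_w
    df_b, df_w = k - 1, n - k
    if ss_t <= 1e-12 or ss_w <= 1e-12:
        return PermanovaResult(np.nan, np.nan, np.nan, n_perm, np.nan,
                               degenerate=True)
    f_obs = (ss_b / df_b) / (ss_w / df_w)
    r2 = ss_b / ss_t
    ms_w = ss_w / df_w
    omega = (ss_b - df_b * ms_w) / (ss_t + ms_w)

    rng = np.random.default_rng(seed)
    perm = np.tile(np.arange(n), (n_perm, 1))
    if strata is not None:
        strata = pd.Series(list(strata))
        if len(strata) != n:
            raise ValueError("strata must match the distance matrix")
        for _, idx in strata.groupby(strata).groups.items():
            idx = np.asarray([strata.index.get_loc(i) for i in idx])
            keys = rng.random((n_perm, idx.size))
            perm[:, idx] = idx[np.argsort(keys, axis=1)]
    else:
        keys = rng.random((n_perm, n))
        perm = np.argsort(keys, axis=1)
    lab_perm = labels_int[perm]  # n_perm x n

    ss_w_perm = np.zeros(n_perm)
    for g in range(k):
        z = (lab_perm == g).astype(float)
        ss_w_perm += np.einsum("bi,bi->b", z @ d2, z) / (2.0 * counts[g])
    ss_b_perm = ss_t - ss_w_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_b_perm / df_b) / (ss_w_perm / df_w)
    p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm,
                           float(omega))


# ---------------------------------------------------------------------------
# effect sizes


def _omega_partial(ss_eff: float, df_eff: int, ms_err: float, n: int) -> float:
    denom = ss_eff + (n - df_eff) * ms_err
    if denom <= 0:
        return np.nan
    return (ss_eff - df_eff * ms_err) / denom


def partial_omega_sq(values, factor, block=None) -> float:
    """Partial omega-squared for ``factor`` from a fixed-effects ANOVA.

    Without ``block`` this is a one-way ANOVA; with ``block`` a two-way
    additive (randomized block) ANOVA, so the factor effect is judged against
    the residual after removing block differences.
    """
    y = np.asarray(values, dtype=float)
    f = pd.Series(list(factor)).astype("category")
    n = y.size
    grand = y.mean()
    ss_tot = ((y - grand) ** 2).sum()

    def group_ss(codes):
        ss = 0.0
        for g in np.unique(codes):
            sel = codes == g
            ss += sel.sum() * (y[sel].mean() - grand) ** 2
        return ss

    fc = f.cat.codes.to_numpy()
    ss_eff = group_ss(fc)
    df_eff = len(f.cat.categories) - 1
    if block is None:
        df_err = n - len(f.cat.categories)
        ss_err = ss_tot - ss_eff
    else:
        b = pd.Series(list(block)).astype("category")
        bc = b.cat.codes.to_numpy()
        ss_block = group_ss(bc)
        df_block = len(b.cat.categories) - 1
        df_err = n - 1 - df_eff - df_block
        ss_err = ss_tot - ss_eff - ss_block
    if df_err <= 0:
        raise DegenerateDataError("no residual degrees of freedom")
    ms_err = ss_err / df_err
    if ss_tot <= 1e-12:
        raise DegenerateDataError("constant response in ANOVA")
    return float(_omega_partial(ss_eff, df_eff, ms_err, n))


def paired_anova_omega(
    values: pd.Series,
    sf: SampleFrame,
    grassland_stage: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> EffectSize:
    """Partial omega^2 for the grassland-forest contrast of one stage.

    Uses the complete pairs whose grassland member is at ``grassland_stage``;
    the ecosystem effect is estimated in a two-way ANOVA blocked on pair.  The
    95% CI comes from a seeded nonparametric bootstrap over pairs.  The
    contrast is oriented grassland minus forest (forests are the successional
    reference), which only matters for accompanying mean differences — omega^2
    itself is sign-free.
    """
    pairs = sf.complete_pairs()
    stage = sf.stage
    pairs = pairs[stage.loc[pairs["grassland"]].to_numpy() == grassland_stage]
    pairs = pairs[
        pairs["grassland"].isin(values.index) & pairs["forest"].isin(values.index)
    ]
    if len(pairs) < 3:
        raise DegenerateDataError(
            f"need >= 3 complete pairs at stage {grassland_stage!r}, "
            f"got {len(pairs)}"
        )
    g = values.loc[pairs["grassland"]].to_numpy(dtype=float)
    f = values.loc[pairs["forest"]].to_numpy(dtype=float)

    def omega_of(gv, fv):
        y = np.concatenate([gv, fv])
        eco = ["grassland"] * len(gv) + ["forest"] * len(fv)
        blk = list(range(len(gv))) * 2
        return partial_omega_sq(y, eco, block=blk)

    if np.ptp(np.concatenate([g, f])) == 0:
        raise DegenerateDataError("constant response across all paired samples")
    est = omega_of(g, f)
    rng = np.random.default_rng(seed)
    idx = np.arange(len(pairs))
    boots = []
    for _ in range(n_boot):
        take = rng.choice(idx, size=idx.size, replace=True)
        try:
            boots.append(omega_of(g[take], f[take]))
        except DegenerateDataError:
            continue
    boots = np.asarray([b for b in boots if np.isfinite(b)])
    if boots.size:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = min(lo, est), max(hi, est)
    else:
        lo = hi = est
    return EffectSize("partial_omega_sq", float(est), float(lo), float(hi),
                      n1=len(g), n2=len(f))


def hedges_g(x, y) -> EffectSize:
    """Bias-corrected standardized mean difference (mean(x)-mean(y))/s_pooled.

    Applies the small-sample correction J = 1 - 3/(4(n1+n2-2)-1); the 95% CI
    uses the standard normal approximation to the sampling variance of g.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("hedges_g needs at least 2 observations per group")
    dof = n1 + n2 - 2
    s_pooled = math.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / dof)
    if s_pooled == 0:
        raise DegenerateDataError("zero pooled standard deviation")
    d = (x.mean() - y.mean()) / s_pooled
    j = 1.0 - 3.0 / (4.0 * dof - 1.0)
    g = j * d
    se = math.sqrt((n1 + n2) / (n1 * n2) + g * g / (2.0 * dof))
    return EffectSize("hedges_g", float(g), float(g - 1.959964 * se),
                      float(g + 1.959964 * se), n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# stage comparisons and multiplicity


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank ties) and its chi-square p-value."""
    if np.ptp(np.concatenate(groups)) == 0:
        raise DegenerateDataError("all values identical: ranks carry no "
                                  "information")
    try:
        h, p = stats.kruskal(*groups)
    except ValueError as exc:
        raise DegenerateDataError(str(exc)) from exc
    if np.isnan(h):
        raise DegenerateDataError("tie correction degenerate")
    return float(h), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def stage_comparisons(values: pd.Series, sf: SampleFrame,
                      test: str = "kruskal_wallis") -> pd.DataFrame:
    """Rank-based comparisons of a per-sample variable across stages.

    'kruskal_wallis' returns a single omnibus row over the stages present;
    'wilcoxon_pairwise' returns one row per stage pair (rank-sum test) with a
    BH-adjusted p column.  All-tied data are flagged degenerate, not errors.
    """
    stage = sf.stage.loc[values.index]
    present = [s for s in STAGES if (stage == s).sum() >= 2]
    if len(present) < 2:
        raise ValueError("need at least two stages with >= 2 samples")
    groups = {s: values[stage == s].to_numpy(dtype=float) for s in present}
    if test == "kruskal_wallis":
        try:
            h, p = kruskal_wallis(list(groups.values()))
            return pd.DataFrame(
                [{"test": "kruskal_wallis", "stages": ",".join(present),
                  "statistic": h, "p": p, "degenerate": False}]
            )
        except DegenerateDataError:
            return pd.DataFrame(
                [{"test": "kruskal_wallis", "stages": ",".join(present),
                  "statistic": np.nan, "p": np.nan, "degenerate": True}]
            )
    if test != "wilcoxon_pairwise":
        raise ValueError(f"unknown test {test!r}")
    rows = []
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            xa, xb = groups[a], groups[b]
            if np.ptp(np.concatenate([xa, xb])) == 0:
                rows.append({"stage_a": a, "stage_b": b, "statistic": np.nan,
                             "p": np.nan, "degenerate": True})
                continue
            u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append({"stage_a": a, "stage_b": b, "statistic": float(u),
                         "p": float(p), "degenerate": False})
    out = pd.DataFrame(rows)
    ok = ~out["p"].isna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# response-shape classification


@dataclass
class ShapeResult:
    shape: str                     # flat | linear | unimodal | threshold
    ambiguous: bool
    p_gate: float                  # stage one-way ANOVA F-test p-value
    aicc: dict = field(default_factory=dict)


def _aicc(rss: float, n: int, n_params: int) -> float:
    k = n_params + 1  # + residual variance
    if n - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + (2 * k * (k + 1)) / (n - k - 1)


def response_shape(values: pd.Series, sf: SampleFrame,
                   alpha: float = 0.05) -> ShapeResult:
    """Classify a variable's trajectory over the four ordered stages.

    A one-way ANOVA of the stage factor gates the classification: if stage
    explains no significant variation (F-test at ``alpha``) the shape is
    'flat', which calibrates the false-positive rate of the classifier to
    ``alpha`` under Gaussian noise.  Otherwise linear (stage rank), quadratic
    (unimodal) and forest-step (threshold) least-squares fits compete by
    AICc; a winning margin under 2 sets the ``ambiguous`` flag.
    """
    stage = sf.stage.loc[values.index]
    if set(STAGES) - set(stage.unique()):
        raise ValueError("all four stages must be present")
    y = values.to_numpy(dtype=float)
    rank = stage.cat.codes.to_numpy().astype(float)
    n = y.size

    # gate: categorical stage vs constant
    groups = [y[rank == r] for r in range(4)]
    grand = y.mean()
    ss_tot = ((y - grand) ** 2).sum()
    ss_b = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_w = ss_tot - ss_b
    df_b, df_w = 3, n - 4
    if ss_w <= 1e-12 and ss_b <= 1e-12:
        return ShapeResult("flat", False, 1.0)
    if ss_w <= 1e-12:
        p_gate = 0.0
    else:
        f_gate = (ss_b / df_b) / (ss_w / df_w)
        p_gate = float(stats.f.sf(f_gate, df_b, df_w))
    if p_gate > alpha:
        return ShapeResult("flat", False, p_gate)

    def fit(design: np.ndarray) -> float:
        x = np.column_stack([np.ones(n)] + [c for c in design.T])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        return float(resid @ resid)

    step = (rank == 3).astype(float)
    rss_lin = fit(rank[:, None])
    rss_quad = fit(np.column_stack([rank, rank**2]))
    rss_step = fit(step[:, None])
    aicc = {
        "linear": _aicc(rss_lin, n, 2),
        "unimodal": _aicc(rss_quad, n, 3),
        "threshold": _aicc(rss_step, n, 2),
    }
    ranked = sorted(aicc, key=aicc.get)
    margin = aicc[ranked[1]] - aicc[ranked[0]]
    return ShapeResult(ranked[0], bool(margin < 2.0), p_gate, aicc)
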