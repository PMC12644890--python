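"""Substrate-induced respiration (SIR) processing and diversity links.

SIR tables carry one row per sample with a basal (water-only) respiration
rate and one rate per substrate of the six-substrate panel (glucose through
chitin, simple to recalcitrant).  Basal respiration is subtracted from every
substrate rate to remove the moisture-pulse (Birch) effect; negative net
rates are kept — flooring them would bias the aggregate — but flagged for QC.
MSIR, the sum of net rates over the panel, serves as the community's
aggregate catabolic capacity and is regressed on taxonomic and functional
diversity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables_io import SIR_SUBSTRATES, GRASSLAND_STAGES, EffectSize, SampleFrame
from .diversity_stats import hedges_g
from .redundancy_framework import DecouplingResult, _nested_f, _ols
from scipy import stats


def _check_columns(profiles: pd.DataFrame) -> None:
    missing = [c for c in ("basal",) + SIR_SUBSTRATES if c not in profiles.columns]
    if missing:
        raise ValueError(f"SIR table missing column(s): {missing}")


def net_sir(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subtract basal respiration from every substrate rate.

    Returns (net, flags): net rates per substrate (basal column retained for
    provenance) and a boolean frame marking negative net rates.
    """
    _check_columns(profiles)
    net = profiles.copy()
    for s in SIR_SUBSTRATES:
        net[s] = profiles[s] - profiles["basal"]
    flags = net[list(SIR_SUBSTRATES)] < 0
    return net, flags


def msir(profiles: pd.DataFrame, already_net: bool = False) -> pd.Series:
    """Multiple substrate-induced respiration: sum of net rates per sample."""
    _check_columns(profiles)
    if already_net:
        net = profiles
    else:
        net, _ = net_sir(profiles)
    return net[list(SIR_SUBSTRATES)].sum(axis=1).rename("msir")


def substrate_effect_sizes(profiles: pd.DataFrame, sf: SampleFrame
                           ) -> pd.DataFrame:
    """Hedges' g per substrate for each grassland stage vs its paired forests.

    Sign convention: positive g means higher net respiration in forests
    (forest minus grassland).  Rates are basal-corrected before comparison.
    Stages with fewer than two complete pairs are an error.
    """
    net, _ = net_sir(profiles)
    pairs = sf.complete_pairs()
    stage = sf.stage
    rows = []
    for st in GRASSLAND_STAGES:
        sel = pairs[stage.loc[pairs["grassland"]].to_numpy() == st]
        sel = sel[sel["grassland"].isin(net.index) & sel["forest"].isin(net.index)]
        if len(sel) < 2:
            raise ValueError(
                f"stage {st!r}: need >= 2 complete pairs with SIR data, "
                f"got {len(sel)}")
        for substrate in SIR_SUBSTRATES:
            f = net.loc[sel["forest"], substrate].to_numpy(float)
            g = net.loc[sel["grassland"], substrate].to_numpy(float)
            es = hedges_g(f, g)
            rows.append({"grassland_stage": st, "substrate": substrate,
                         "hedges_g": es.estimate, "ci_low": es.ci_low,
                         "ci_high": es.ci_high, "n_pairs": len(sel)})
    return pd.DataFrame(rows)


def msir_diversity_regression(
    msir_values: pd.Series,
    diversity: dict[str, pd.Series],
    sf: SampleFrame,
) -> pd.DataFrame:
    """Regress MSIR on each candidate diversity predictor.

    For every named predictor (taxonomic H', C-gene H' per kingdom, ...)
    fits OLS within each ecosystem and pooled over both, reports slope,
    p-value, R^2, Pearson r, and the ecosystem x predictor interaction F
    testing slope homogeneity between grasslands and forests.
    """
    rows = []
    eco = sf.ecosystem
    for name, pred in diversity.items():
        common = msir_values.index.intersection(pred.dropna().index)
        x_all = pred.loc[common].to_numpy(float)
        y_all = msir_values.loc[common].to_numpy(float)
        if np.ptp(x_all) == 0:
            raise ValueError(f"constant predictor {name!r}")
        e = eco.loc[common].to_numpy()
        fits = {}
        for scope in ("pooled", "grassland", "forest"):
            m = np.ones_like(x_all, bool) if scope == "pooled" else e == scope
            x, y = x_all[m], y_all[m]
            if x.size < 4 or np.ptp(x) == 0:
                fits[scope] = None
                continue
            X = np.column_stack([np.ones_like(x), x])
            beta, se, pvals, r2, *_ = _ols(y, X)
            r, _ = stats.pearsonr(x, y)
            fits[scope] = (beta[1], se[1], pvals[1], r2, r, x.size)
        # slope homogeneity: interaction F in the pooled two-slope model
        is_f = (e == "forest").astype(float)
        X_full = np.column_stack([np.ones_like(x_all), x_all, is_f, x_all * is_f])
        X_null = X_full[:, :3]
        _, _, _, _, rss_full, dof_full = _ols(y_all, X_full)
        _, _, _, _, rss_null, _ = _ols(y_all, X_null)
        f_int, p_int = _nested_f(rss_null, rss_full, dof_full)
        for scope, fit in fits.items():
            if fit is None:
                continue
            slope, se1, p1, r2, r, n = fit
            rows.append({"predictor": name, "scope": scope,
                         "slope": float(slope), "slope_se": float(se1),
                         "p_slope": float(p1), "r_squared": float(r2),
                         "pearson_r": float(r), "df": int(n - 2),
                         "interaction_F": float(f_int),
                         "p_interaction": float(p_int)})
    return pd.DataFrame(rows)
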