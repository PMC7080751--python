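"""Descriptive clone-population analytics and analytic identities.

Covers the summary statistics used to characterise neutral clonal drift in a
homeostatic epithelium: the timecourse of mean surviving clone size, labelled
clone density and labelled basal fraction (per animal, mean +/- s.e.m.), the
scaling collapse of late-time clone-size distributions onto the exponential
master curve P(size >= x * mean) = exp(-x), the homeostatic flux identity
Gamma = rho * lambda / (1 - rho), and the sister-cell fate correlation
implied by the symmetric-division probability r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cellcycle import InvalidParameterError


@dataclass
class CloneTimecourse:
    per_animal: pd.DataFrame  # mouse_id, time_days, n_clones, mean_basal, total_basal
    summary: pd.DataFrame  # time_days, mean_size, sem_size, rel_density, rel_labeled_fraction
    trend_p_labeled_fraction: float  # Mann-Kendall p for a time trend


@dataclass
class ScalingCurve:
    x: np.ndarray  # size / mean-size grid
    tails: pd.DataFrame  # one column per time point: P(size >= x * mean)
    reference: np.ndarray  # exp(-x)
    max_abs_deviation: pd.Series  # per time point, vs the reference


def summarize_clone_timecourse(clone_table: pd.DataFrame) -> CloneTimecourse:
    """Per-animal clone statistics averaged into a population timecourse.

    Statistics are computed per animal first and then averaged across animals
    (mean +/- s.e.m.), so animals — not pooled clones — are the unit of
    replication.  Density and labelled fraction are reported relative to the
    first time point's across-animal mean.
    """
    surviving = clone_table[clone_table["n_basal"] >= 1]
    if len(surviving) == 0:
        raise InvalidParameterError("no surviving clones in the table")
    agg = dict(
        n_clones=("n_basal", "size"),
        mean_basal=("n_basal", "mean"),
        total_basal=("n_basal", "sum"),
    )
    # when the induction effort is recorded, density and labelled fraction are
    # per induced cell; otherwise raw per-animal counts are used (appropriate
    # only when sampling effort was constant across time points)
    has_effort = "n_induced" in surviving.columns
    if has_effort:
        agg["n_induced"] = ("n_induced", "first")
    per_animal = surviving.groupby(["time_days", "mouse_id"], as_index=False).agg(**agg)
    if has_effort:
        per_animal["n_clones"] = per_animal["n_clones"] / per_animal["n_induced"]
        per_animal["total_basal"] = per_animal["total_basal"] / per_animal["n_induced"]
    rows = []
    t0 = per_animal["time_days"].min()
    dens0 = per_animal.loc[per_animal["time_days"] == t0, "n_clones"].mean()
    lab0 = per_animal.loc[per_animal["time_days"] == t0, "total_basal"].mean()
    for t, grp in per_animal.groupby("time_days"):
        n = len(grp)
        rows.append(
            {
                "time_days": t,
                "n_animals": n,
                "mean_size": grp["mean_basal"].mean(),
                "sem_size": grp["mean_basal"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "rel_density": grp["n_clones"].mean() / dens0,
                "rel_labeled_fraction": grp["total_basal"].mean() / lab0,
            }
        )
    summary = pd.DataFrame(rows)
    # Mann-Kendall trend on the per-time across-animal means of labelled mass
    if summary["time_days"].nunique() >= 3:
        tau, p = stats.kendalltau(summary["time_days"], summary["rel_labeled_fraction"])
    else:
        p = np.nan
    return CloneTimecourse(per_animal, summary, float(p))


def scaling_collapse(
    size_samples: dict, x_max: float = 4.0, n_x: int = 40
) -> ScalingCurve:
    """Empirical tails P(size >= x * mean) per time point on a common x grid.

    ``size_samples`` maps time (days) -> array of surviving basal clone
    sizes.  Under neutral drift at late times the curves collapse onto
    exp(-x); the per-time maximum absolute deviation from that reference is
    reported.  Times with fewer than 2 surviving clones are excluded.
    """
    x = np.linspace(0.0, x_max, n_x)
    cols = {}
    dev = {}
    for t in sorted(size_samples):
        sizes = np.asarray(size_samples[t], dtype=float)
        sizes = sizes[sizes >= 1]
        if sizes.size < 2:
            continue
        mean = sizes.mean()
        tail = np.array([(sizes >= xi * mean).mean() for xi in x])
        cols[t] = tail
        dev[t] = float(np.max(np.abs(tail - np.exp(-x))))
    if not cols:
        raise InvalidParameterError("no time point has >= 2 surviving clones")
    tails = pd.DataFrame(cols, index=x)
    return ScalingCurve(x, tails, np.exp(-x), pd.Series(dev))


def ks_between_times(curve: ScalingCurve, t_a: float, t_b: float) -> float:
    """Max absolute difference between two scaled tail curves (KS-type)."""
    return float(np.max(np.abs(curve.tails[t_a].to_numpy() - curve.tails[t_b].to_numpy())))


def homeostatic_stratification_rate(rho: float, lambda_week: float) -> float:
    """Gamma = rho * lambda / (1 - rho): the stratification rate (/week) that
    balances progenitor output against basal-layer exit in homeostasis."""
    if not (0.0 < rho < 1.0):
        raise InvalidParameterError("rho must lie in (0, 1)")
    if not lambda_week > 0:
        raise InvalidParameterError("lambda must be positive")
    return rho * lambda_week / (1.0 - rho)


def sister_fate_statistics(p_pp: float, p_pd: float, p_dd: float) -> dict:
    """Fate statistics of a daughter pair given PP/PD/DD outcome probabilities.

    In the balanced case (p_pp == p_dd == r) each daughter divides with
    probability 1/2 and the correlation between sister fates is 4r - 1:
    independent fates give r = 0.25, purely asymmetric divisions (r = 0)
    perfect anti-correlation.  Unbalanced inputs additionally return the
    differentiation skew delta = (p_dd - p_pp) / (p_dd + p_pp).
    """
    probs = np.array([p_pp, p_pd, p_dd], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("probabilities must be non-negative and sum to 1")
    p_divide = p_pp + 0.5 * p_pd
    out = {"per_daughter_division_prob": p_divide}
    if abs(p_pp - p_dd) <= 1e-12:
        r = p_pp
        out["r"] = r
        out["sister_fate_correlation"] = 4.0 * r - 1.0
    else:
        out["r"] = 0.5 * (p_pp + p_dd)
        out["delta"] = (p_dd - p_pp) / (p_dd + p_pp)
        # general phi coefficient of the 2x2 sister-fate table
        q = 1.0 - p_divide
        denom = p_divide * q
        out["sister_fate_correlation"] = (
            (p_pp - p_divide**2) / denom if denom > 0 else float("nan")
        )
    return out


def compare_distributions_ks(sizes_a, sizes_b) -> dict:
    """Two-sample KS comparison of clone-size samples (reporter-control use)."""
    res = stats.ks_2samp(np.asarray(sizes_a), np.asarray(sizes_b), method="asymp")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
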