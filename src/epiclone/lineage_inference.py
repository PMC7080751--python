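"""Maximum-likelihood inference of progenitor fate parameters from clones.

Lineage-tracing experiments record, per clone, the number of basal and
suprabasal cells at a series of times post induction.  With the division
rate lambda and the cycle-time law fixed externally (from H2B-GFP dilution),
the single-progenitor model has two free parameters: the symmetric-division
probability r and the progenitor fraction rho (the stratification rate is
eliminated by the homeostatic identity Gamma = rho*lambda/(1-rho)).

The likelihood of the binned basal clone-size distributions is evaluated on
an (r, rho) grid by simulating a clone ensemble per grid point (common
random numbers across points keep the Monte-Carlo surface smooth), and
profile-likelihood confidence intervals follow from the likelihood-ratio
test at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cellcycle import CycleTimeDistribution, InvalidParameterError
from .simulator import CloneSizeDistribution, SPParams, bin_basal_sizes, simulate_sp_counts
from .units import DAYS_PER_WEEK

#: chi-square thresholds for 95% likelihood-ratio confidence regions
CHI2_1_95 = 3.841
CHI2_2_95 = 5.991


@dataclass
class ObservedCloneDistribution:
    """Binned basal clone sizes observed at one time point."""

    time: float  # days
    k_max: int  # bins 1..k_max-1 and pooled k_max+
    counts: np.ndarray
    per_animal: pd.DataFrame | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise InvalidParameterError("counts must be non-negative")
        if self.counts.shape != (self.k_max,):
            raise InvalidParameterError("counts must have one entry per bin (1..K-1, K+)")

    @property
    def n_clones(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / max(self.n_clones, 1)


def bin_clone_sizes(clone_table: pd.DataFrame, k_max: int = 7) -> list[ObservedCloneDistribution]:
    """Binned distributions per time point from a tidy clone table.

    Clones with no basal cell are excluded (a clone 'survives' while it keeps
    at least one basal cell); sizes >= k_max pool into the top bin.
    """
    if len(clone_table) == 0:
        raise InvalidParameterError("clone table is empty")
    out = []
    for t, grp in clone_table.groupby("time_days"):
        surviving = grp[grp["n_basal"] >= 1]
        counts = bin_basal_sizes(surviving["n_basal"].to_numpy(), k_max)
        per_animal = (
            surviving.groupby("mouse_id")
            .agg(n_clones=("n_basal", "size"), mean_basal=("n_basal", "mean"))
            .reset_index()
        )
        out.append(ObservedCloneDistribution(float(t), k_max, counts, per_animal))
    return out


def clone_size_loglik(
    obs: ObservedCloneDistribution, sim: CloneSizeDistribution, floor: float | None = None
) -> float:
    """Multinomial log-likelihood sum_b n_b log p_b of observed bin counts
    under simulated bin probabilities, floored and renormalized so that
    unsimulated bins stay finitely unlikely rather than impossible."""
    if sim.k_max != obs.k_max or sim.time != obs.time:
        raise InvalidParameterError("bin scheme / time mismatch between observed and simulated")
    p = sim.probabilities.astype(float)
    if floor is None:
        floor = 1.0 / (2.0 * max(sim.n_surviving, 1))
    if np.any((p == 0) & (obs.counts > 0)):
        warnings.warn("observed clones in a bin with zero simulated probability; floored")
    p = np.maximum(p, floor)
    p = p / p.sum()
    return float(np.sum(obs.counts * np.log(p)))


@dataclass
class FitResult:
    lambda_week: float
    cycle: CycleTimeDistribution
    r_grid: np.ndarray
    rho_grid: np.ndarray
    loglik: np.ndarray  # shape (len(r_grid), len(rho_grid)); NaN where invalid
    r_mle: float
    rho_mle: float
    r_ci95: tuple
    rho_ci95: tuple
    gof: pd.DataFrame
    r2_t: float
    s_t: float
    n_sim: int
    seed: int
    boundary_flag: bool = False
    predicted: dict = field(default_factory=dict, repr=False)

    @property
    def gamma_mle(self) -> float:
        """Stratification rate implied by homeostasis at the MLE (/week)."""
        return self.rho_mle * self.lambda_week / (1.0 - self.rho_mle)

    def to_dict(self) -> dict:
        return {
            "lambda_week": self.lambda_week,
            "cycle": self.cycle.to_config(),
            "r_mle": self.r_mle,
            "rho_mle": self.rho_mle,
            "gamma_mle_week": self.gamma_mle,
            "r_ci95": list(self.r_ci95),
            "rho_ci95": list(self.rho_ci95),
            "r2_t": self.r2_t,
            "s_t": self.s_t,
            "gof": self.gof.to_dict(orient="records"),
            "n_sim": self.n_sim,
            "seed": self.seed,
            "boundary_flag": self.boundary_flag,
        }


def _quadratic_refine(grid: np.ndarray, prof: np.ndarray, i: int) -> float:
    """Sub-grid argmax by a local parabola through three profile points."""
    if i == 0 or i == len(grid) - 1:
        return float(grid[i])
    y0, y1, y2 = prof[i - 1], prof[i], prof[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0 or not np.isfinite(denom):
        return float(grid[i])
    off = 0.5 * (y0 - y2) / denom
    off = np.clip(off, -0.5, 0.5)
    return float(grid[i] + off * (grid[i + 1] - grid[i]))


def profile_ci(
    surface: np.ndarray, axis_values: np.ndarray, axis: int, alpha: float = 0.05
) -> tuple:
    """Profile-likelihood interval {theta: 2(l_max - l_prof(theta)) <= chi2_1},
    with endpoints linearly interpolated between grid points."""
    if alpha != 0.05:
        from scipy import stats

        thresh = stats.chi2.ppf(1 - alpha, df=1) / 2.0
    else:
        thresh = CHI2_1_95 / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prof = np.nanmax(surface, axis=1 - axis)
    finite = np.isfinite(prof)
    if not finite.any():
        raise InvalidParameterError("likelihood surface has no finite values")
    lmax = np.nanmax(prof)
    inside = prof >= lmax - thresh
    if inside[finite].all():
        warnings.warn("flat likelihood profile: CI spans the whole grid")
        return (float(axis_values[finite][0]), float(axis_values[finite][-1]))
    idx = np.where(inside & finite)[0]
    lo_i, hi_i = idx[0], idx[-1]

    def _interp(i_in, i_out):
        # crossing of prof with (lmax - thresh) between grid points
        y_in, y_out = prof[i_in], prof[i_out]
        if not np.isfinite(y_out) or y_in == y_out:
            return float(axis_values[i_in])
        f = (y_in - (lmax - thresh)) / (y_in - y_out)
        return float(axis_values[i_in] + f * (axis_values[i_out] - axis_values[i_in]))

    lo = _interp(lo_i, lo_i - 1) if lo_i > 0 else float(axis_values[0])
    hi = _interp(hi_i, hi_i + 1) if hi_i < len(axis_values) - 1 else float(axis_values[-1])
    return (lo, hi)


def goodness_of_fit(
    obs_freqs: dict, pred_freqs: dict
) -> tuple[pd.DataFrame, float, float]:
    """Determination coefficient R^2 and fit standard error S per time point.

    Frequencies are in percent.  R^2 = 1 - RSS/TSS over bins; S is the RMS
    residual in percentage points; R2_T and S_T are unweighted means over
    time points.
    """
    rows = []
    for t in sorted(obs_freqs):
        o = np.asarray(obs_freqs[t], dtype=float)
        p = np.asarray(pred_freqs[t], dtype=float)
        if o.shape != p.shape:
            raise InvalidParameterError("bin mismatch between observed and predicted")
        rss = float(np.sum((o - p) ** 2))
        tss = float(np.sum((o - o.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
        s = float(np.sqrt(rss / o.size))
        rows.append({"time_days": t, "r2": r2, "s": s})
    df = pd.DataFrame(rows)
    return df, float(df["r2"].mean()), float(df["s"].mean())


def ci_coverage(obs_list: list, predicted: dict) -> dict:
    """How many observed clone-size proportions have the model prediction
    inside their 95% CI (p_hat +/- 1.96 * SE of a proportion)."""
    n_cov = 0
    n_tot = 0
    for obs in obs_list:
        if obs.n_clones == 0:
            raise InvalidParameterError(f"no clones at time {obs.time}")
        p_hat = obs.frequencies
        se = np.sqrt(p_hat * (1 - p_hat) / obs.n_clones)
        pred = np.asarray(predicted[obs.time], dtype=float)
        cov = np.abs(pred - p_hat) <= 1.96 * se
        n_cov += int(cov.sum())
        n_tot += cov.size
    return {"n_covered": n_cov, "n_total": n_tot}


def mle_grid_search(
    obs_all: list,
    lambda_week: float,
    cycle: CycleTimeDistribution,
    r_grid=None,
    rho_grid=None,
    n_sim: int = 100_000,
    initial: str = "progenitor",
    rng=None,
) -> FitResult:
    """Grid-search MLE of (r, rho) from binned clone-size distributions.

    For each admissible grid point, Gamma follows from homeostasis, an
    ensemble of ``n_sim`` clones is simulated once (recording every observed
    time) with common random numbers across grid points, and the multinomial
    log-likelihood is summed over time points.  Returns the MLE (with local
    quadratic sub-grid refinement), profile-likelihood 95% CIs, and the
    goodness-of-fit table at the MLE grid point.
    """
    if r_grid is None:
        r_grid = np.arange(0.01, 0.501, 0.01)
    if rho_grid is None:
        rho_grid = np.arange(0.05, 0.951, 0.05)
    r_grid = np.asarray(list(r_grid), dtype=float)
    rho_grid = np.asarray(list(rho_grid), dtype=float)
    if r_grid.size == 0 or rho_grid.size == 0:
        raise InvalidParameterError("parameter grids must be non-empty")
    if not obs_all:
        raise InvalidParameterError("no observed distributions given")
    rng = np.random.default_rng(rng) if not hasattr(rng, "integers") else rng
    seed = int(rng.integers(0, 2**31 - 1))

    times = np.array(sorted(o.time for o in obs_all))
    k_max = obs_all[0].k_max
    obs_by_time = {o.time: o for o in obs_all}

    loglik = np.full((r_grid.size, rho_grid.size), np.nan)
    sim_store: dict = {}
    n_skipped = 0
    for i, r in enumerate(r_grid):
        for j, rho in enumerate(rho_grid):
            if not (0.0 <= r <= 0.5) or not (0.0 < rho < 1.0):
                n_skipped += 1
                continue
            params = SPParams.homeostatic(lambda_week, r, rho, cycle=cycle)
            prog, diff, _ = simulate_sp_counts(params, n_sim, times, seed, initial=initial)
            basal = prog + diff
            ll = 0.0
            sims = []
            for k, t in enumerate(times):
                counts = bin_basal_sizes(basal[:, k], k_max)
                sim = CloneSizeDistribution(
                    time=float(t),
                    k_max=k_max,
                    counts=counts,
                    n_clones_simulated=n_sim,
                    surviving_fraction=float((basal[:, k] >= 1).mean()),
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ll += clone_size_loglik(obs_by_time[float(t)], sim)
                sims.append(sim)
            loglik[i, j] = ll
            sim_store[(i, j)] = sims
    if n_skipped and not np.isfinite(loglik).any():
        raise InvalidParameterError("all grid points violate the parameter constraints")
    if n_skipped:
        warnings.warn(f"{n_skipped} grid points outside the parameter domain were skipped")

    i_mle, j_mle = np.unravel_index(np.nanargmax(loglik), loglik.shape)
    boundary = i_mle in (0, r_grid.size - 1) or j_mle in (0, rho_grid.size - 1)
    if boundary:
        warnings.warn("MLE on the grid boundary; widen the grid")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r_prof = np.nanmax(loglik, axis=1)
        rho_prof = np.nanmax(loglik, axis=0)
    r_mle = _quadratic_refine(r_grid, r_prof, int(i_mle))
    rho_mle = _quadratic_refine(rho_grid, rho_prof, int(j_mle))

    r_ci = profile_ci(loglik, r_grid, axis=0)
    rho_ci = profile_ci(loglik, rho_grid, axis=1)

    sims_mle = sim_store[(int(i_mle), int(j_mle))]
    obs_pct = {o.time: 100.0 * o.frequencies for o in obs_all}
    pred_pct = {s.time: 100.0 * s.probabilities for s in sims_mle}
    gof, r2_t, s_t = goodness_of_fit(obs_pct, pred_pct)

    return FitResult(
        lambda_week=lambda_week,
        cycle=cycle,
        r_grid=r_grid,
        rho_grid=rho_grid,
        loglik=loglik,
        r_mle=r_mle,
        rho_mle=rho_mle,
        r_ci95=r_ci,
        rho_ci95=rho_ci,
        gof=gof,
        r2_t=r2_t,
        s_t=s_t,
        n_sim=n_sim,
        seed=seed,
        boundary_flag=bool(boundary),
        predicted={s.time: s.probabilities for s in sims_mle},
    )
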