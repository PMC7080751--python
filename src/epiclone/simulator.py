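"""Non-Markovian Monte Carlo of epithelial clones and label dilution.

Implements the competing cell-fate models of squamous epithelial maintenance:

* **SP** — single-progenitor: one dividing population with stochastic daughter
  fates PP / PD / DD at probabilities r / 1-2r / r; differentiating basal
  cells stratify at rate Gamma; homeostasis ties Gamma = rho*lambda/(1-rho)
  to the progenitor fraction rho of the basal layer.
* **2xSC** — two independent self-renewing populations dividing at different
  rates (each is an SP process with its own parameters).
* **SC-CP** — slow-cycling stem cells feeding committed progenitors whose
  fates are skewed toward differentiation by delta, balanced by stem output.

All simulations are exact event-driven Monte Carlo with arbitrary cycle-time
laws (see :mod:`epiclone.cellcycle`); the heavy loops are JIT-compiled in
:mod:`epiclone._engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .cellcycle import CycleTimeDistribution, InvalidParameterError, from_rate, sample_initial_phase
from .units import DAYS_PER_WEEK

_HOMEOSTASIS_RTOL = 1e-9


def _seed_from(rng) -> int:
    """A 31-bit kernel seed from a Generator, an int, or None."""
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        return int(rng) % (2**31 - 1)
    return int(rng.integers(0, 2**31 - 1))


@dataclass(frozen=True)
class SPParams:
    """Single-progenitor model parameters.

    Rates are /week; the cycle law's mean must equal ``7/lambda`` days.
    ``mu_week`` (suprabasal shedding) is optional; when 0, suprabasal
    counts accumulate without loss.
    """

    lambda_week: float
    r: float
    rho: float
    gamma_week: float
    cycle: CycleTimeDistribution
    mu_week: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.r <= 0.5):
            raise InvalidParameterError("r must lie in [0, 0.5]")
        if not (0.0 < self.rho < 1.0):
            raise InvalidParameterError("rho must lie in (0, 1)")
        if self.lambda_week <= 0 or self.gamma_week <= 0:
            raise InvalidParameterError("rates must be positive")
        if self.mu_week < 0:
            raise InvalidParameterError("mu_week must be >= 0")
        if abs(self.cycle.mean_cycle - DAYS_PER_WEEK / self.lambda_week) > 1e-9 * self.cycle.mean_cycle:
            raise InvalidParameterError(
                "cycle mean must equal 7/lambda days "
                f"(got {self.cycle.mean_cycle:.4f} d for lambda={self.lambda_week}/week)"
            )

    @property
    def is_homeostatic(self) -> bool:
        return abs(self.rho * self.lambda_week - (1 - self.rho) * self.gamma_week) <= (
            _HOMEOSTASIS_RTOL * self.rho * self.lambda_week
        )

    @classmethod
    def homeostatic(
        cls,
        lambda_week: float,
        r: float,
        rho: float,
        cycle: CycleTimeDistribution | None = None,
        *,
        family: str = "shifted_gamma",
        shape: float = 8.0,
        t_min: float = 0.0,
        mu_week: float = 0.0,
    ) -> "SPParams":
        """Construct with Gamma fixed by the flux balance rho*lambda = (1-rho)*Gamma."""
        if cycle is None:
            cycle = from_rate(lambda_week, family=family, shape=shape, t_min=t_min)
        gamma = rho * lambda_week / (1.0 - rho)
        return cls(lambda_week=lambda_week, r=r, rho=rho, gamma_week=gamma, cycle=cycle, mu_week=mu_week)


@dataclass(frozen=True)
class PopulationSpec:
    """One proliferating population in a hierarchy model."""

    lambda_week: float
    cycle: CycleTimeDistribution
    # probabilities over daughter pairs (SS, SP, SD, PP, PD, DD)
    fate: tuple = (0.0, 0.0, 0.0, 0.0, 1.0, 0.0)

    def __post_init__(self):
        if abs(sum(self.fate) - 1.0) > 1e-9 or min(self.fate) < 0:
            raise InvalidParameterError("fate probabilities must be non-negative and sum to 1")


@dataclass(frozen=True)
class HierarchyParams:
    """Stem / committed-progenitor hierarchy (SC-CP) or generic two-type model.

    ``populations`` maps the dividing types: index 0 = stem, 1 = progenitor.
    ``fractions`` are basal-layer fractions (stem, progenitor, differentiating)
    at labelling; ``gamma_week`` is the stratification rate of differentiating
    basal cells.
    """

    populations: tuple  # (stem: PopulationSpec, progenitor: PopulationSpec)
    fractions: tuple  # (f_stem, f_prog, f_diff)
    gamma_week: float
    delta: float = 0.0  # progenitor fate skew toward differentiation

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9 or min(self.fractions) < 0:
            raise InvalidParameterError("fractions must be non-negative and sum to 1")
        if self.gamma_week <= 0:
            raise InvalidParameterError("gamma_week must be positive")


def make_sccp_params(
    lambda_prog_week: float,
    *,
    stem_rate_ratio: float = 0.25,
    r_stem: float = 0.1,
    r_prog: float = 0.1,
    delta: float = 0.1,
    stem_fraction: float = 0.12,
    prog_fraction: float = 0.48,
    gamma_week: float | None = None,
    family: str = "shifted_gamma",
    shape: float = 8.0,
    t_min: float = 0.0,
) -> HierarchyParams:
    """SC-CP defaults: stem cells divide ``stem_rate_ratio`` times as fast as
    progenitors (default 4x slower); progenitor fates are skewed toward
    differentiation by ``delta`` (PP: r(1-delta), PD: 1-2r, DD: r(1+delta)),
    with the imbalance compensated by the stem -> progenitor channel."""
    lam_s = lambda_prog_week * stem_rate_ratio
    stem = PopulationSpec(
        lambda_week=lam_s,
        cycle=from_rate(lam_s, family=family, shape=shape, t_min=t_min * (1.0 / stem_rate_ratio)),
        fate=(r_stem, 1 - 2 * r_stem, 0.0, r_stem, 0.0, 0.0),
    )
    prog = PopulationSpec(
        lambda_week=lambda_prog_week,
        cycle=from_rate(lambda_prog_week, family=family, shape=shape, t_min=t_min),
        fate=(0.0, 0.0, 0.0, r_prog * (1 - delta), 1 - 2 * r_prog, r_prog * (1 + delta)),
    )
    if gamma_week is None:
        # flux balance: diff production = gamma * f_diff
        f_diff = 1.0 - stem_fraction - prog_fraction
        prod = prog_fraction * lambda_prog_week  # each prog division yields ~1 diff daughter
        gamma_week = prod / max(f_diff, 1e-9)
    return HierarchyParams(
        populations=(stem, prog),
        fractions=(stem_fraction, prog_fraction, 1.0 - stem_fraction - prog_fraction),
        gamma_week=gamma_week,
        delta=delta,
    )


@dataclass
class CloneTrajectory:
    record_times: np.ndarray  # days
    n_progenitor: np.ndarray
    n_diff_basal: np.ndarray
    n_suprabasal: np.ndarray

    @property
    def n_basal(self) -> np.ndarray:
        return self.n_progenitor + self.n_diff_basal


@dataclass
class CloneSizeDistribution:
    """Binned basal clone sizes at one time, conditioned on survival."""

    time: float  # days
    k_max: int  # bins are 1..k_max-1 plus a pooled k_max+ bin
    counts: np.ndarray  # length k_max, surviving clones only
    n_clones_simulated: int
    surviving_fraction: float
    mean_basal_size: float = float("nan")  # mean over surviving clones

    @property
    def probabilities(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / tot

    @property
    def n_surviving(self) -> int:
        return int(self.counts.sum())


def bin_basal_sizes(sizes: np.ndarray, k_max: int) -> np.ndarray:
    """Counts over bins (1, 2, ..., k_max-1, k_max+) for surviving sizes >= 1."""
    sizes = np.asarray(sizes)
    sizes = sizes[sizes >= 1]
    clipped = np.minimum(sizes, k_max)
    return np.bincount(clipped, minlength=k_max + 1)[1:]


def _validate_record_times(record_times):
    rt = np.asarray(record_times, dtype=float)
    if rt.size == 0:
        raise InvalidParameterError("record_times must be non-empty")
    if np.any(rt < 0) or np.any(np.diff(rt) < 0):
        raise InvalidParameterError("record_times must be sorted and >= 0")
    return rt


def _sp_kernel_args(params: SPParams):
    c = params.cycle
    return (
        c.code,
        c.mean_cycle,
        c.shape,
        c.t_min,
        params.r,
        params.gamma_week / DAYS_PER_WEEK,
        params.mu_week / DAYS_PER_WEEK,
        params.rho,
    )


def simulate_clone(
    params: SPParams,
    record_times,
    rng=None,
    initial: str = "progenitor",
) -> CloneTrajectory:
    """Simulate one clone; ``initial`` is 'progenitor' or 'basal_representative'."""
    rt = _validate_record_times(record_times)
    init_mode = {"progenitor": 0, "basal_representative": 1}.get(initial)
    if init_mode is None:
        raise InvalidParameterError(f"unknown initial cell mode {initial!r}")
    prog, diff, supra = _engine.sp_clone_kernel(
        1, rt, *_sp_kernel_args(params), init_mode, _seed_from(rng)
    )
    return CloneTrajectory(rt, prog[0], diff[0], supra[0])


def simulate_sp_counts(
    params: SPParams,
    n_clones: int,
    record_times,
    rng=None,
    initial: str = "progenitor",
):
    """Raw per-clone (progenitor, diff-basal, suprabasal) counts at each time.

    Returns arrays of shape (n_clones, n_times).
    """
    rt = _validate_record_times(record_times)
    if n_clones < 1:
        raise InvalidParameterError("n_clones must be >= 1")
    init_mode = {"progenitor": 0, "basal_representative": 1}[initial]
    return _engine.sp_clone_kernel(
        int(n_clones), rt, *_sp_kernel_args(params), init_mode, _seed_from(rng)
    )


def simulate_hierarchy_counts(
    params: HierarchyParams, n_clones: int, record_times, rng=None
):
    """Raw (stem, progenitor, diff, suprabasal) counts for SC-CP clones."""
    rt = _validate_record_times(record_times)
    stem, prog = params.populations
    fams = np.array([stem.cycle.code, prog.cycle.code], np.int64)
    means = np.array([stem.cycle.mean_cycle, prog.cycle.mean_cycle])
    shapes = np.array([stem.cycle.shape, prog.cycle.shape])
    tmins = np.array([stem.cycle.t_min, prog.cycle.t_min])
    fate_cum = np.cumsum(np.array([stem.fate, prog.fate], dtype=float), axis=1)
    return _engine.hierarchy_clone_kernel(
        int(n_clones),
        rt,
        fams,
        means,
        shapes,
        tmins,
        fate_cum,
        params.gamma_week / DAYS_PER_WEEK,
        np.asarray(params.fractions, dtype=float),
        _seed_from(rng),
    )


def simulate_clone_ensemble(
    model: str,
    params,
    n_clones: int,
    record_times,
    rng=None,
    *,
    initial: str = "progenitor",
    k_max: int = 7,
) -> list[CloneSizeDistribution]:
    """Ensemble of clones -> per-time binned basal-size distributions.

    ``model`` is one of 'SP', 'SCCP', 'TwoSC'.  Distributions are conditioned
    on survival (>= 1 basal cell) with the surviving fraction reported.
    For 'TwoSC', ``params`` is a tuple ``((sp_a, sp_b), (frac_a, frac_b))`` of
    two independent SP parameter sets and their basal fractions at labelling.
    """
    rt = _validate_record_times(record_times)
    if n_clones < 1:
        raise InvalidParameterError("n_clones must be >= 1")
    rng = np.random.default_rng(rng) if not hasattr(rng, "integers") else rng

    if model == "SP":
        prog, diff, _ = simulate_sp_counts(params, n_clones, rt, rng, initial=initial)
        basal = prog + diff
    elif model == "SCCP":
        stem, prog, diff, _ = simulate_hierarchy_counts(params, n_clones, rt, rng)
        basal = stem + prog + diff
    elif model == "TwoSC":
        (sp_a, sp_b), (frac_a, frac_b) = params
        if abs(frac_a + frac_b - 1.0) > 1e-9:
            raise InvalidParameterError("TwoSC fractions must sum to 1")
        n_a = int(rng.binomial(n_clones, frac_a))
        parts = []
        for sp, n in ((sp_a, n_a), (sp_b, n_clones - n_a)):
            if n > 0:
                p, d, _ = simulate_sp_counts(sp, n, rt, rng, initial=initial)
                parts.append(p + d)
        basal = np.vstack(parts)
    else:
        raise InvalidParameterError(f"unknown model {model!r}; choose SP, SCCP or TwoSC")

    out = []
    for j, t in enumerate(rt):
        sizes = basal[:, j]
        surviving = sizes[sizes >= 1]
        out.append(
            CloneSizeDistribution(
                time=float(t),
                k_max=k_max,
                counts=bin_basal_sizes(sizes, k_max),
                n_clones_simulated=n_clones,
                surviving_fraction=surviving.size / n_clones,
                mean_basal_size=float(surviving.mean()) if surviving.size else float("nan"),
            )
        )
    return out


def simulate_dilution(
    params: SPParams,
    chase_times,
    n_initial_cells: int,
    rng=None,
    *,
    init_intensity_mean: float = 1.0,
    init_intensity_cv: float = 0.4,
    measurement_noise_cv: float = 0.0,
) -> pd.DataFrame:
    """H2B-GFP dilution in a homeostatic basal population.

    Starts ``n_initial_cells`` independent basal lineages (progenitors at
    stationary cycle phase w.p. rho, else differentiating cells), with initial
    intensities drawn from a lognormal law of the given mean and CV.  Every
    division halves the parent's label into both daughters; stratification
    removes cells from the observed pool.  Recorded intensities are multiplied
    by lognormal measurement noise of CV ``measurement_noise_cv``.

    Returns a tidy frame with columns (time_days, cell_id, intensity).
    """
    ct = _validate_record_times(chase_times)
    if ct[0] != 0:
        raise InvalidParameterError("chase_times must include 0")
    if n_initial_cells < 1:
        raise InvalidParameterError("n_initial_cells must be >= 1")
    if measurement_noise_cv < 0:
        raise InvalidParameterError("measurement noise CV must be >= 0")
    if init_intensity_cv < 0:
        raise InvalidParameterError("initial intensity CV must be >= 0")
    rng = np.random.default_rng(rng) if not hasattr(rng, "integers") else rng

    init_I = _lognormal(rng, init_intensity_mean, init_intensity_cv, n_initial_cells)
    c = params.cycle
    cap = max(256, 8 * n_initial_cells)
    while True:
        out, counts = _engine.sp_dilution_kernel(
            init_I,
            ct,
            c.code,
            c.mean_cycle,
            c.shape,
            c.t_min,
            params.r,
            params.gamma_week / DAYS_PER_WEEK,
            params.rho,
            _seed_from(rng),
            cap,
        )
        if np.all(counts >= 0):
            break
        cap *= 4  # overflow: re-run with a larger buffer

    frames = []
    for j, t in enumerate(ct):
        vals = out[j, : counts[j]].copy()
        if measurement_noise_cv > 0:
            vals = vals * _lognormal(rng, 1.0, measurement_noise_cv, vals.size)
        frames.append(
            pd.DataFrame(
                {"time_days": t, "cell_id": np.arange(vals.size), "intensity": vals}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _lognormal(rng, mean: float, cv: float, n: int) -> np.ndarray:
    """Lognormal samples with the given arithmetic mean and CV (CV=0 -> constant)."""
    if cv == 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)
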