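"""Synthetic lineage-tracing and H2B-GFP chase experiments.

No raw clone tables or intensity tables are deposited with the study this
package models, so these generators emulate both experimental designs end to
end: sparse clonal labelling of basal cells followed by cross-sectional
harvests (one cohort of animals per time point), and doxycycline-chase
dilution experiments with multiple fields of view per animal, lognormal
between-field illumination offsets, measurement noise, and CD45+ leukocyte
contaminants that retain label.

``PRESETS`` carries the inferred single-progenitor parameter sets for the
five tissues with printed estimates (esophagus x2, paw, ear, back), so every
pipeline stage can be exercised with one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cellcycle import InvalidParameterError
from .simulator import SPParams, simulate_dilution, simulate_sp_counts, _lognormal


@dataclass(frozen=True)
class LineageDesign:
    """Cross-sectional lineage-tracing design: cohorts of animals are induced
    at low efficiency and harvested at fixed times post induction."""

    time_points: tuple = (10.0, 30.0, 84.0, 180.0)
    animals_per_time: tuple = (3, 3, 6, 4)
    target_clones_per_time: tuple = (300, 315, 302, 305)
    labeling_efficiency: float = 1.0 / 301.0
    initial_mode: str = "basal_representative"

    def __post_init__(self):
        k = len(self.time_points)
        if len(self.animals_per_time) != k or len(self.target_clones_per_time) != k:
            raise InvalidParameterError("per-time design tuples must share a length")
        if min(self.animals_per_time) < 1 or min(self.target_clones_per_time) < 1:
            raise InvalidParameterError("counts must be >= 1")
        if not (0.0 < self.labeling_efficiency < 1.0):
            raise InvalidParameterError("labeling efficiency must lie in (0, 1)")


@dataclass(frozen=True)
class ChaseDesign:
    """H2B-GFP dilution chase design (one cohort of animals per chase time)."""

    chase_times: tuple = (0.0, 7.0, 12.0, 18.0)
    animals_per_time: tuple = (3, 3, 3, 2)
    fields_per_animal: int = 5
    cells_per_field: int = 130
    leukocyte_fraction: float = 0.03
    field_cv: float = 0.10  # between-field multiplicative intensity variation
    noise_cv: float = 0.20  # per-cell measurement noise
    init_intensity_mean: float = 1000.0  # arbitrary fluorescence units
    init_intensity_cv: float = 0.40

    def __post_init__(self):
        if len(self.animals_per_time) != len(self.chase_times):
            raise InvalidParameterError("animals_per_time must match chase_times")
        if 0.0 not in self.chase_times:
            raise InvalidParameterError("chase_times must include 0")
        for frac in (self.leukocyte_fraction,):
            if not (0.0 <= frac < 1.0):
                raise InvalidParameterError("fractions must lie in [0, 1)")
        if self.fields_per_animal < 1 or self.cells_per_field < 1:
            raise InvalidParameterError("counts must be >= 1")


@dataclass(frozen=True)
class TissuePreset:
    name: str
    lambda_week: float
    r: float
    rho: float
    t_min_days: float
    shape: float = 8.0  # package default gamma shape (narrow cycle law)

    def params(self, shape: float | None = None, family: str = "shifted_gamma") -> SPParams:
        return SPParams.homeostatic(
            self.lambda_week,
            self.r,
            self.rho,
            family=family,
            shape=self.shape if shape is None else shape,
            t_min=self.t_min_days if family != "exponential" else 0.0,
        )


#: inferred single-progenitor parameter sets per tissue (lineage-tracing MLEs)
PRESETS = {
    "esophagus-lrig1": TissuePreset("esophagus-lrig1", 2.9, 0.10, 0.65, 0.5),
    "esophagus-ahyfp": TissuePreset("esophagus-ahyfp", 2.9, 0.06, 0.56, 0.5),
    "paw": TissuePreset("paw", 2.0, 0.14, 0.53, 1.0),
    "ear": TissuePreset("ear", 1.5, 0.04, 0.54, 1.0),
    "dorsum": TissuePreset("dorsum", 1.2, 0.04, 0.61, 2.0),
}


def get_preset(name: str) -> TissuePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def generate_lineage_experiment(
    truth: SPParams, design: LineageDesign, rng=None
) -> pd.DataFrame:
    """Simulate a clone table (mouse_id, time_days, clone_id, n_basal, n_suprabasal).

    For each time point's cohort, enough clones are initiated that the
    expected number of *surviving* clones (>= 1 basal cell) matches the
    design target; survival probability is estimated from a pilot ensemble,
    so realised counts fluctuate binomially around the target.  Records
    include extinct-at-harvest clones only implicitly (they are not imaged);
    only surviving clones appear, as in the wholemount counts.
    """
    rng = np.random.default_rng(rng) if not hasattr(rng, "integers") else rng
    init_mode = design.initial_mode
    rows = []
    for t, n_mice, target in zip(
        design.time_points, design.animals_per_time, design.target_clones_per_time
    ):
        # pilot estimate of the surviving fraction at this time
        if t == 0:
            p_surv = 1.0
        else:
            prog, diff, _ = simulate_sp_counts(
                truth, 8000, [t], rng, initial=init_mode
            )
            p_surv = max(((prog + diff)[:, 0] >= 1).mean(), 1e-3)
        per_mouse = target / n_mice
        n_init = max(1, int(round(per_mouse / p_surv)))
        for m in range(n_mice):
            mouse = f"t{int(t)}d_m{m + 1}"
            prog, diff, supra = simulate_sp_counts(
                truth, n_init, [t], rng, initial=init_mode
            )
            basal = (prog + diff)[:, 0]
            keep = np.where(basal >= 1)[0]
            for cid, idx in enumerate(keep):
                rows.append(
                    {
                        "mouse_id": mouse,
                        "time_days": float(t),
                        "clone_id": f"{mouse}_c{cid + 1}",
                        "n_basal": int(basal[idx]),
                        "n_suprabasal": int(supra[idx, 0]),
                        # induction effort behind this animal's surviving
                        # clones; lets density (clones per induced cell)
                        # be reconstructed from the cross-sections
                        "n_induced": n_init,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["mouse_id", "time_days", "clone_id", "n_basal", "n_suprabasal", "n_induced"],
    )


def generate_h2bgfp_experiment(
    truth: SPParams, design: ChaseDesign, rng=None
) -> pd.DataFrame:
    """Simulate an intensity table
    (mouse_id, time_days, fov_id, cell_id, intensity, is_leukocyte).

    Keratinocytes dilute by division under the single-progenitor model;
    leukocytes retain their initial label.  Cells are assigned to fields of
    view, each with a lognormal multiplicative offset (CV ``field_cv``), and
    every record carries lognormal measurement noise (CV ``noise_cv``).
    """
    rng = np.random.default_rng(rng) if not hasattr(rng, "integers") else rng
    rows = []
    for t, n_mice in zip(design.chase_times, design.animals_per_time):
        for m in range(n_mice):
            mouse = f"t{int(t)}d_m{m + 1}"
            n_cells = design.fields_per_animal * design.cells_per_field
            tidy = simulate_dilution(
                truth,
                [0.0, float(t)] if t > 0 else [0.0],
                n_cells,
                rng,
                init_intensity_mean=design.init_intensity_mean,
                init_intensity_cv=design.init_intensity_cv,
                measurement_noise_cv=0.0,  # noise added after field offsets
            )
            vals = tidy.loc[tidy["time_days"] == float(t), "intensity"].to_numpy()
            field_of = rng.integers(0, design.fields_per_animal, vals.size)
            offsets = _lognormal(rng, 1.0, design.field_cv, design.fields_per_animal)
            for f in range(design.fields_per_animal):
                fov = f"{mouse}_f{f + 1}"
                ker = vals[field_of == f] * offsets[f]
                n_leuko = rng.binomial(ker.size, design.leukocyte_fraction) if ker.size else 0
                leuko = (
                    _lognormal(rng, design.init_intensity_mean, design.init_intensity_cv, n_leuko)
                    * offsets[f]
                )
                both = np.concatenate([ker, leuko])
                flags = np.r_[np.zeros(ker.size, bool), np.ones(n_leuko, bool)]
                noise = _lognormal(rng, 1.0, design.noise_cv, both.size)
                for cid, (inten, fl) in enumerate(zip(both * noise, flags)):
                    rows.append(
                        {
                            "mouse_id": mouse,
                            "time_days": float(t),
                            "fov_id": fov,
                            "cell_id": f"{fov}_c{cid + 1}",
                            "intensity": float(inten),
                            "is_leukocyte": bool(fl),
                        }
                    )
    return pd.DataFrame(
        rows, columns=["mouse_id", "time_days", "fov_id", "cell_id", "intensity", "is_leukocyte"]
    )
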