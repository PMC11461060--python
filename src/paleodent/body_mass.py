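"""Allometric body-mass estimation from first/second molar dimensions.

Eight published regressions link molar length (and, for one lower-m1
equation, length × width) to body mass in extant ungulates.  Each
equation is defined on one locus (m1, m2, M1 or M2; case encodes the
jaw) and predicts mass in grams or kilograms in its native form; all
predictions are normalised to kilograms here.  "log" denotes base-10,
"ln" natural logarithm, following the allometry literature.

Aggregation to a species-at-locality mass follows a two-stage rule:
per equation, one tooth per individual per locus is drawn at random
(seeded), the per-equation mean over individuals is taken, and the
final mass is the median of all per-equation means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LENGTH_SANITY_MM = (5.0, 120.0)


class MassEstimationError(ValueError):
    pass


@dataclass(frozen=True)
class AllometricEquation:
    """One published molar-dimension → body-mass regression."""

    equation_id: str
    locus: str
    needs_width: bool
    unit: str  # "g" or "kg"
    _predict: Callable[[float, float | None], float]

    def mass_kg(self, length_mm: float, width_mm: float | None = None) -> float:
        """Evaluate the regression, converting the native unit to kg."""
        if length_mm <= 0:
            raise MassEstimationError(f"non-positive length {length_mm}")
        if self.needs_width:
            if width_mm is None:
                raise MassEstimationError(f"{self.equation_id} requires a width")
            if width_mm <= 0:
                raise MassEstimationError(f"non-positive width {width_mm}")
        native = self._predict(length_mm, width_mm)
        return native / 1000.0 if self.unit == "g" else native


EQUATIONS: tuple[AllometricEquation, ...] = (
    AllometricEquation(
        "m1_ln_LxW_g", "m1", True, "g",
        lambda L, W: math.exp(1.5133 * math.log(L * W) + 3.6515)),
    AllometricEquation(
        "m1_log_L_kg", "m1", False, "kg",
        lambda L, W: 10 ** (3.26 * math.log10(L / 10.0) + 1.337)),
    AllometricEquation(
        "m2_log_L_kg", "m2", False, "kg",
        lambda L, W: 10 ** (3.2 * math.log10(L / 10.0) + 1.13)),
    AllometricEquation(
        "m2_log_L_g", "m2", False, "g",
        lambda L, W: 10 ** (3.07 * math.log10(L) + 1.07)),
    AllometricEquation(
        "M1_ln_L_g", "M1", False, "g",
        lambda L, W: math.exp(3.19 * math.log(L) + 2.1)),
    AllometricEquation(
        "M2_log_L_kg", "M2", False, "kg",
        lambda L, W: 10 ** (3.18 * math.log10(L / 10.0) + 1.091)),
    AllometricEquation(
        "M2_log_L_g", "M2", False, "g",
        lambda L, W: 10 ** (3.03 * math.log10(L) + 1.06)),
    AllometricEquation(
        "M2_ln_L_g", "M2", False, "g",
        lambda L, W: math.exp(3.09 * math.log(L) + 2.14)),
)

EQUATIONS_BY_ID: Mapping[str, AllometricEquation] = {e.equation_id: e for e in EQUATIONS}

MASS_LOCI = ("m1", "m2", "M1", "M2")


def equations_for_locus(locus: str) -> tuple[AllometricEquation, ...]:
    return tuple(e for e in EQUATIONS if e.locus == locus)


def estimate_single_tooth(locus: str, length_mm: float,
                          width_mm: float | None = None) -> dict[str, float]:
    """Masses in kg from every equation applicable to this tooth.

    The width-requiring m1 equation is skipped (not errored) when no
    width was measured, matching incomplete museum material.
    """
    if locus not in MASS_LOCI:
        raise MassEstimationError(
            f"locus {locus!r} unsupported for mass estimation (need one of {MASS_LOCI})")
    if length_mm <= 0:
        raise MassEstimationError(f"non-positive length {length_mm}")
    out: dict[str, float] = {}
    for eq in equations_for_locus(locus):
        if eq.needs_width and width_mm is None:
            continue
        out[eq.equation_id] = eq.mass_kg(length_mm, width_mm)
    return out


def aggregate_species_locality(measurements: pd.DataFrame,
                               seed: int = 0,
                               group_by_locus: bool = False) -> pd.DataFrame:
    """Aggregate tooth measurements to species-by-locality body masses.

    Parameters
    ----------
    measurements
        Columns ``specimen_id, species, locality, locus, length_mm`` and
        optionally ``individual_id, width_mm, biozone``.
    seed
        Seeds the one-tooth-per-individual-per-locus random draw so the
        aggregation is reproducible.
    group_by_locus
        If True the median is taken over locus-level sub-medians instead
        of over the pooled per-equation means.

    Returns
    -------
    DataFrame with one row per (species, locality): ``n_individuals``,
    one ``mean_<equation_id>`` column per contributing equation, and
    ``median_mass_kg``.
    """
    df = measurements.copy()
    if "individual_id" not in df.columns:
        df["individual_id"] = df["specimen_id"]
    df["individual_id"] = df["individual_id"].where(
        df["individual_id"].astype(str).str.len() > 0, df["specimen_id"])
    df = df[df["locus"].isin(MASS_LOCI)]
    lo, hi = LENGTH_SANITY_MM
    df = df[(df["length_mm"] > lo) & (df["length_mm"] < hi)]

    rng = np.random.default_rng(seed)
    rows = []
    for (species, locality), grp in df.groupby(["species", "locality"], sort=True):
        # one tooth per individual per locus, chosen with the seeded RNG
        picks = []
        for (_, _locus), sub in grp.groupby(["individual_id", "locus"], sort=True):
            sub = sub.sort_values("specimen_id").reset_index(drop=True)
            picks.append(sub.iloc[int(rng.integers(len(sub)))])
        chosen = pd.DataFrame(picks)

        eq_means: dict[str, list[float]] = {}
        for _, tooth in chosen.iterrows():
            width = tooth.get("width_mm")
            width = None if width is None or pd.isna(width) else float(width)
            for eq_id, mass in estimate_single_tooth(
                    str(tooth["locus"]), float(tooth["length_mm"]), width).items():
                eq_means.setdefault(eq_id, []).append(mass)
        if not eq_means:
            continue
        means = {eq_id: float(np.mean(v)) for eq_id, v in eq_means.items()}
        if group_by_locus:
            per_locus: dict[str, list[float]] = {}
            for eq_id, m in means.items():
                per_locus.setdefault(EQUATIONS_BY_ID[eq_id].locus, []).append(m)
            final = float(np.median([np.median(v) for v in per_locus.values()]))
        else:
            final = float(np.median(list(means.values())))
        row = {"species": species, "locality": locality,
               "n_individuals": int(chosen["individual_id"].nunique()),
               "median_mass_kg": final}
        row.update({f"mean_{k}": v for k, v in means.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def species_masses(summary: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Convenience: {(species, locality): median mass kg} from a summary."""
    return {(r["species"], r["locality"]): r["median_mass_kg"]
            for _, r in summary.iterrows()}
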