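"""Stable-isotope diet and palaeoclimate reconstruction from enamel carbonate.

The chain, per specimen:

1. diet–bioapatite enrichment  ε* = exp(2.42 + 0.032·ln(mass_kg))  [‰]
2. δ13C_diet = δ13C_CO3,enamel − ε* − corr, where corr is the shift of
   atmospheric δ13C_CO2 between the reconstructed past value (−6.1 to
   −5.7‰) and the modern −8‰ (so corr ≈ +1.9‰, subtracted).
3. MAP (mm/yr), two transfer functions:
   * Kohn-style latitude/altitude regression, solved for MAP:
     MAP = 10^[(−δ13C_diet − 10.29 − 0.0124·|lat| + 1.9e−4·alt)/5.61] − 300
   * leaf-discrimination form:
     MAP = 10^(0.092·Δ13C_leaf + 1.148) − 300,
     Δ13C_leaf = (δ13C_atm − δ13C_diet)/(1 + δ13C_diet/1000)
4. δ18O_CO3 V-PDB → V-SMOW: δ = 1.03091·x + 30.91
5. δ18O of precipitation (megaherbivore calibration, composed from the
   phosphate–precipitation and phosphate–carbonate relations):
   δ18O_precip = 1.02·δ18O_CO3,SMOW − 33.3
6. MAT (°C): (δ18O_precip + 14.178)/0.442  or  1.41·δ18O_precip + 23.63.

Negative MAP values can arise in arid settings; locality aggregation
excludes negative per-specimen Kohn values from the mean ("without
negative values" rule) and flags the exclusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from paleodent.datamodel import ValidationError

D13C_ATM_MODERN = -8.0
D13C_ATM_PAST_DEFAULT = -6.1
C3_DIET_THRESHOLD = -22.0          # δ13C_diet below this: C3 feeding
BIOME_THRESHOLD = -25.0            # woodland-mesic vs open-xeric C3 grassland
EMPIRICAL_SHIFT_CUTOFF = -25.6     # observed late-Oligocene shift cut-off

ANALYTICAL_SD_D13C = 0.2           # ±1σ within-run precision, ‰
ANALYTICAL_SD_D18O = 0.3


@dataclass(frozen=True)
class AtmosphereContext:
    """Atmospheric δ13C_CO2 context for the diet correction."""

    d13c_atm_past: float = D13C_ATM_PAST_DEFAULT
    d13c_atm_modern: float = D13C_ATM_MODERN

    @property
    def corr(self) -> float:
        """Past-minus-modern atmospheric shift, subtracted from the diet value."""
        return self.d13c_atm_past - self.d13c_atm_modern


@dataclass(frozen=True)
class SiteContext:
    """Per-locality geographic context for the latitude/altitude MAP form."""

    latitude_deg: float = 45.0
    altitude_m: float = 0.0
    atmosphere: AtmosphereContext = field(default_factory=AtmosphereContext)


# --------------------------------------------------------------------------
# Unit transfer functions
# --------------------------------------------------------------------------

def enrichment_factor(body_mass_kg: float) -> float:
    """Diet–bioapatite carbon enrichment ε* (‰) as a function of body mass."""
    if body_mass_kg <= 0:
        raise ValidationError(f"body mass must be positive, got {body_mass_kg}")
    return math.exp(2.42 + 0.032 * math.log(body_mass_kg))


def carbon_diet(d13c_co3_pdb: float, epsilon_star: float,
                atmosphere: AtmosphereContext | None = None) -> float:
    """δ13C of the diet (‰ V-PDB) from enamel carbonate δ13C."""
    atm = atmosphere or AtmosphereContext()
    return d13c_co3_pdb - epsilon_star - atm.corr


def classify_carbon(d13c_diet: float) -> dict[str, object]:
    """Feeding / biome labels for a δ13C_diet value.

    ``c3``: strict C3 feeding (< −22‰); ``biome``: which side of the
    −25‰ woodland-mesic vs open-xeric threshold; ``below_shift_cutoff``:
    the empirical −25.6‰ shift flag.
    """
    if not math.isfinite(d13c_diet):
        raise ValidationError("non-finite d13C_diet")
    c3 = d13c_diet < C3_DIET_THRESHOLD
    biome = None
    if c3:
        biome = "woodland-mesic" if d13c_diet < BIOME_THRESHOLD else "open-xeric"
    return {"c3": c3, "biome": biome,
            "below_shift_cutoff": d13c_diet < EMPIRICAL_SHIFT_CUTOFF}


def map_kohn(d13c_diet: float, latitude_deg: float = 45.0,
             altitude_m: float = 0.0) -> float:
    """Mean annual precipitation (mm/yr) from the latitude/altitude
    regression, solved for MAP.  May be negative; the caller applies the
    negative-exclusion rule when aggregating."""
    if abs(latitude_deg) > 90:
        raise ValidationError("latitude out of range")
    expo = (-d13c_diet - 10.29 - 0.0124 * abs(latitude_deg)
            + 1.9e-4 * altitude_m) / 5.61
    return 10.0 ** expo - 300.0


def leaf_discrimination(d13c_diet: float, d13c_atm: float = D13C_ATM_PAST_DEFAULT) -> float:
    """Δ13C_leaf, the photosynthetic discrimination of the consumed plants."""
    denom = 1.0 + d13c_diet / 1000.0
    if denom == 0:
        raise ValidationError("d13C_diet = -1000 is a pole of the discrimination")
    return (d13c_atm - d13c_diet) / denom


def map_rey(d13c_diet: float, d13c_atm: float = D13C_ATM_PAST_DEFAULT
            ) -> tuple[float, float]:
    """MAP (mm/yr) from leaf discrimination; returns (MAP, Δ13C_leaf)."""
    delta_leaf = leaf_discrimination(d13c_diet, d13c_atm)
    return 10.0 ** (0.092 * delta_leaf + 1.148) - 300.0, delta_leaf


def pdb_to_smow(d18o_pdb: float) -> float:
    """Carbonate δ18O scale conversion V-PDB → V-SMOW (‰)."""
    return 1.03091 * d18o_pdb + 30.91


def precip_from_carbonate(d18o_co3_smow: float, rounded: bool = True) -> float:
    """δ18O of local precipitation (‰ V-SMOW) from enamel-carbonate δ18O.

    The default uses the rounded composed coefficients (1.02, −33.3);
    ``rounded=False`` composes the two source relations exactly:
    δ18O_PO4 = 0.96·δ18O_CO3 − 8.05 and δ18O_PO4 = 0.94·δ18O_precip + 23.3.
    """
    if rounded:
        return 1.02 * d18o_co3_smow - 33.3
    return (0.96 * d18o_co3_smow - 8.05 - 23.3) / 0.94


def mat_tutken(d18o_precip: float) -> float:
    """Mean annual temperature (°C), inverse-slope calibration."""
    return (d18o_precip + 14.178) / 0.442


def mat_skrzypek(d18o_precip: float) -> float:
    """Mean annual temperature (°C), direct linear calibration."""
    return 1.41 * d18o_precip + 23.63


def specimen_chain(d13c_co3_pdb: float, d18o_co3_pdb: float, body_mass_kg: float,
                   site: SiteContext | None = None) -> dict[str, float]:
    """Full per-specimen chain; the composition of every unit operation."""
    site = site or SiteContext()
    eps = enrichment_factor(body_mass_kg)
    diet = carbon_diet(d13c_co3_pdb, eps, site.atmosphere)
    map_r, delta_leaf = map_rey(diet, site.atmosphere.d13c_atm_past)
    smow = pdb_to_smow(d18o_co3_pdb)
    precip = precip_from_carbonate(smow)
    return {
        "epsilon_star": eps,
        "d13c_diet": diet,
        "delta13c_leaf": delta_leaf,
        "map_kohn": map_kohn(diet, site.latitude_deg, site.altitude_m),
        "map_rey": map_r,
        "d18o_co3_smow": smow,
        "d18o_precip": precip,
        "mat_tutken": mat_tutken(precip),
        "mat_skrzypek": mat_skrzypek(precip),
    }


# --------------------------------------------------------------------------
# Locality aggregation
# --------------------------------------------------------------------------

@dataclass
class ClimateEstimate:
    locality: str
    biozone: str
    n_specimens: int
    d13c_diet: float
    mat_tutken: float
    mat_skrzypek: float
    map_rey: float
    map_kohn: float | None
    n_kohn_excluded: int
    policy: str


def locality_climate(samples: pd.DataFrame,
                     masses: Mapping[str, float],
                     sites: Mapping[str, SiteContext] | None = None,
                     policy: str = "specimen-weighted") -> list[ClimateEstimate]:
    """Aggregate per-specimen chains to locality climate estimates.

    Parameters
    ----------
    samples
        Columns ``specimen_id, species, locality, biozone, sampling,
        d13c_co3_pdb, d18o_co3_pdb``.  Serial sub-samples should be
        reduced to one row per tooth beforehand.
    masses
        Species → body mass (kg); species-at-locality keys
        ``"species@locality"`` take precedence over plain species keys.
    policy
        ``"specimen-weighted"`` (default) averages over specimens;
        ``"species-mean-unweighted"`` first averages within species then
        across species.
    """
    if policy not in ("specimen-weighted", "species-mean-unweighted"):
        raise ValidationError(f"unknown aggregation policy {policy!r}")
    sites = sites or {}
    out: list[ClimateEstimate] = []
    for locality, grp in samples.groupby("locality", sort=True):
        if grp.empty:
            continue
        site = sites.get(str(locality), SiteContext())
        chains = []
        for _, row in grp.iterrows():
            key = f"{row['species']}@{locality}"
            mass = masses.get(key, masses.get(str(row["species"])))
            if mass is None:
                raise ValidationError(
                    f"no body mass for species {row['species']!r} at {locality!r}")
            c = specimen_chain(float(row["d13c_co3_pdb"]), float(row["d18o_co3_pdb"]),
                               float(mass), site)
            c["species"] = row["species"]
            chains.append(c)
        cdf = pd.DataFrame(chains)
        if policy == "species-mean-unweighted":
            cdf = cdf.groupby("species", sort=True).mean(numeric_only=True).reset_index()
        kohn = cdf["map_kohn"].to_numpy(dtype=float)
        kohn_pos = kohn[kohn >= 0]
        out.append(ClimateEstimate(
            locality=str(locality),
            biozone=str(grp["biozone"].iloc[0]) if "biozone" in grp.columns else "",
            n_specimens=len(grp),
            d13c_diet=float(cdf["d13c_diet"].mean()),
            mat_tutken=float(cdf["mat_tutken"].mean()),
            mat_skrzypek=float(cdf["mat_skrzypek"].mean()),
            map_rey=float(cdf["map_rey"].mean()),
            map_kohn=float(kohn_pos.mean()) if len(kohn_pos) else None,
            n_kohn_excluded=int((kohn < 0).sum()),
            policy=policy,
        ))
    return out


def climate_table(estimates: Sequence[ClimateEstimate]) -> pd.DataFrame:
    """Locality × (MAT, MAP) summary frame in reporting shape."""
    return pd.DataFrame([{
        "locality": e.locality, "biozone": e.biozone, "n": e.n_specimens,
        "mat_tutken_c": e.mat_tutken, "mat_skrzypek_c": e.mat_skrzypek,
        "map_kohn_mm": e.map_kohn, "map_rey_mm": e.map_rey,
        "n_kohn_excluded": e.n_kohn_excluded,
    } for e in estimates])


# --------------------------------------------------------------------------
# Uncertainty propagation
# --------------------------------------------------------------------------

def mat_uncertainty(sd_d18o_pdb: float = ANALYTICAL_SD_D18O,
                    calibration: str = "tutken") -> float:
    """Propagate analytical δ18O precision through the MAT chain (±°C).

    The chain is affine, so the bound is |slope| × σ: the PDB→SMOW slope
    (1.03091) times the carbonate→precipitation slope (1.02) times the
    MAT calibration slope.
    """
    slope = 1.03091 * 1.02
    slope *= (1.0 / 0.442) if calibration == "tutken" else 1.41
    return abs(slope) * sd_d18o_pdb


# --------------------------------------------------------------------------
# Serial (intra-tooth) seasonality
# --------------------------------------------------------------------------

@dataclass
class SeasonalityProfile:
    d13c_range: float
    d18o_range: float
    fit: dict[str, dict[str, float]] | None
    spearman_rho: float | None
    spearman_p: float | None


def _fit_sinusoid(pos: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Least-squares a·sin(2π·pos/T + φ) + c over a grid of periods.

    For each candidate period the amplitude/phase/offset sub-problem is
    linear (sin & cos basis), so only the period is grid-searched.
    """
    span = float(pos.max() - pos.min())
    if span <= 0:
        return {"amplitude": 0.0, "period": math.inf, "phase": 0.0,
                "offset": float(np.mean(y)), "rmse": float(np.std(y))}
    def fit_at(T: float):
        w = 2.0 * math.pi / T
        X = np.column_stack([np.sin(w * pos), np.cos(w * pos), np.ones_like(pos)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rmse = float(np.sqrt(np.mean((y - X @ coef) ** 2)))
        return rmse, coef

    periods = np.linspace(span / 3.0, 3.0 * span, 400)
    best = None
    for T in periods:
        rmse, coef = fit_at(T)
        if best is None or rmse < best[0]:
            best = (rmse, T, coef)
    # local refinement around the best grid period
    from scipy import optimize
    lo = max(best[1] - (periods[1] - periods[0]), periods[0])
    hi = min(best[1] + (periods[1] - periods[0]), periods[-1])
    res = optimize.minimize_scalar(lambda T: fit_at(T)[0], bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    if res.fun < best[0]:
        best = (float(res.fun), float(res.x), fit_at(float(res.x))[1])
    rmse, T, (a_sin, a_cos, c) = best
    amplitude = float(math.hypot(a_sin, a_cos))
    phase = float(math.atan2(a_cos, a_sin))
    return {"amplitude": amplitude, "period": float(T), "phase": phase,
            "offset": float(c), "rmse": rmse}


def seasonality_profile(positions_mm: Sequence[float],
                        d13c: Sequence[float],
                        d18o: Sequence[float]) -> SeasonalityProfile:
    """Seasonal profile of one serially sampled tooth.

    Reports intra-tooth ranges for both isotopes, a least-squares
    sinusoid fit per isotope (≥ 4 points required for the fit), and the
    rank correlation between the two series.
    """
    pos = np.asarray(positions_mm, dtype=float)
    c = np.asarray(d13c, dtype=float)
    o = np.asarray(d18o, dtype=float)
    if not (len(pos) == len(c) == len(o)):
        raise ValidationError("serial series must share one position axis")
    profile = SeasonalityProfile(
        d13c_range=float(c.max() - c.min()) if len(c) else float("nan"),
        d18o_range=float(o.max() - o.min()) if len(o) else float("nan"),
        fit=None, spearman_rho=None, spearman_p=None)
    if len(pos) >= 4:
        profile.fit = {"d13c": _fit_sinusoid(pos, c), "d18o": _fit_sinusoid(pos, o)}
        if np.std(c) > 0 and np.std(o) > 0:
            from paleodent import stats as pstats
            res = pstats.spearman(c, o)
            profile.spearman_rho = res.statistic
            profile.spearman_p = res.p_value
    return profile
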