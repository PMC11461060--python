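"""Synthetic specimen-collection generator.

Generates dental-measurement, hypoplasia, mesowear, isotope and surface
data with the statistical structure each pipeline stage assumes, so the
whole package is testable without museum material.  The default
:class:`StudyDesign` mirrors a published Oligocene–Miocene rhinocerotid
collection: 15 Western/Central European localities (biozones MP28–MN3),
10 species, per-proxy sample sizes, species-at-locality body masses,
hypoplasia prevalences, enamel-carbonate isotope means and mesowear
medians.  Every generator is a pure function of (design, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from paleodent import body_mass as bm
from paleodent.datamodel import ValidationError
from paleodent.dmta import SurfaceScan

# --------------------------------------------------------------------------
# Default study design
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesAtLocality:
    """True (design) values for one species at one locality."""

    locality: str
    biozone: str
    species: str
    n_body_mass: int
    n_hypoplasia: int
    n_mesowear: int
    n_isotopes: int
    body_mass_kg: float | None
    hypoplasia_pct: float
    d13c_co3_pdb: float | None
    d18o_co3_pdb: float | None
    mesowear_median: float | None

    @property
    def genus(self) -> str:
        return self.species.split()[0]


@dataclass
class StudyDesign:
    rows: tuple[SpeciesAtLocality, ...]
    seed: int = 0
    measurement_noise_sd: float = 0.05       # lognormal sigma on tooth length
    width_to_length: float = 0.6
    isotope_sd_permil: float = 0.5           # bulk per-specimen scatter
    serial_amp_d13c: float = 0.25            # seasonal amplitudes (‰)
    serial_amp_d18o: float = 0.5
    serial_period_mm: float = 30.0
    serial_points: int = 12
    serial_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        for r in self.rows:
            if not (0.0 <= r.hypoplasia_pct <= 100.0):
                raise ValidationError(f"prevalence out of [0, 100] for {r.species}")
            if min(r.n_body_mass, r.n_hypoplasia, r.n_mesowear, r.n_isotopes) < 0:
                raise ValidationError("negative sample size")


# columns: locality, biozone, species, n_bm, n_hypo, n_meso, n_iso,
#          mass_kg, hypo_pct, d13c, d18o, mesowear_median
_DEFAULT_ROWS = [
    ("Gaimersheim", "MP28", "Mesaceratherium gaimersheimense", 9, 52, 4, 2, 800, 5.77, -10.5, -5.6, 2),
    ("Gaimersheim", "MP28", "Ronzotherium romani", 16, 91, 2, 7, 2370, 13.19, -10.3, -6.1, 1.5),
    ("Rickenbach", "MP29", "Brachydiceratherium lamilloquense", 8, 14, 3, 0, 1600, 42.86, -10.0, -4.4, 2),
    ("Rickenbach", "MP29", "Mesaceratherium gaimersheimense", 4, 13, 2, 7, 1240, 46.15, None, None, 2),
    ("Rickenbach", "MP29", "Ronzotherium romani", 6, 22, 3, 0, 1820, 4.55, -10.9, -8.9, 4),
    ("La Milloque", "MP29", "Brachydiceratherium lamilloquense", 10, 84, 5, 5, 1290, 20.24, -10.5, -3.8, 1),
    ("La Milloque", "MP29", "Mesaceratherium paulhiacense", 11, 38, 6, 3, 940, 10.53, -10.3, -3.5, 2),
    ("Thézels", "MP30", "Brachydiceratherium aff. lemanense", 3, 17, 0, 0, 1650, 0.0, None, None, None),
    ("Thézels", "MP30", "Mesaceratherium gaimersheimense", 34, 154, 8, 5, 850, 7.14, -8.8, -3.4, 2),
    ("Gannat", "MP30-MN1", "Brachydiceratherium lemanense", 22, 132, 5, 13, 1760, 21.21, -8.1, -3.4, 2),
    ("Gannat", "MP30-MN1", "Pleuroceros pleuroceros", 7, 33, 1, 0, 740, 6.06, None, None, 2),
    ("Tomerdingen", "MN1", "Diaceratherium tomerdingense", 7, 36, 1, 0, 1440, 16.67, None, None, 4),
    ("Paulhiac", "MN1", "Brachydiceratherium aginense", 2, 12, 3, 0, 2000, 16.67, None, None, 1),
    ("Paulhiac", "MN1", "Brachydiceratherium lemanense", 9, 80, 2, 0, 1210, 1.25, None, None, 2.5),
    ("Paulhiac", "MN1", "Mesaceratherium paulhiacense", 0, 17, 0, 0, 820, 11.76, None, None, None),
    ("Paulhiac", "MN1", "Pleuroceros pleuroceros", 2, 8, 0, 0, 680, 25.0, None, None, None),
    ("Wischberg", "MN1", "Brachydiceratherium lemanense", 3, 6, 0, 0, 1450, 66.67, None, None, None),
    ("Wischberg", "MN1", "Pleuroceros pleuroceros", 4, 19, 1, 0, 660, 0.0, None, None, 2),
    ("Pappenheim", "MN2", "Brachydiceratherium lemanense", 3, 12, 1, 0, 2000, 50.0, None, None, 2),
    ("Ulm-Westtangente", "MN2", "Mesaceratherium cf. paulhiacense", 27, 149, 12, 5, 1880, 17.45, -10.6, -5.3, 2.5),
    ("Ulm-Westtangente", "MN2", "Protaceratherium minutum", 64, 317, 16, 3, 500, 16.72, -8.1, -5.1, 2),
    ("Engehalde", "MN2", "Brachydiceratherium aginense", 4, 14, 0, 0, 1060, 28.57, None, None, None),
    ("Engehalde", "MN2", "Brachydiceratherium lemanense", 5, 23, 1, 0, 1160, 17.39, None, None, 2),
    ("Laugnac", "MN2", "Brachydiceratherium aginense", 18, 100, 3, 0, 1770, 14.0, None, None, 2),
    ("Valquemado", "MN2", "Protaceratherium minutum", 8, 47, 1, 4, 670, 8.51, -9.0, -3.1, 0),
    ("Loranca del Campo", "MN3", "Brachydiceratherium cf. aurelianense", 0, 16, 0, 0, None, 18.75, None, None, None),
    ("Loranca del Campo", "MN3", "Protaceratherium minutum", 36, 173, 13, 10, 660, 14.45, -9.1, -3.1, 2),
    ("Wintershof-West", "MN3", "Brachydiceratherium aurelianense", 4, 14, 1, 0, 1370, 28.57, None, None, 3),
    ("Wintershof-West", "MN3", "Mesaceratherium paulhiacense", 3, 10, 1, 0, 1000, 10.0, None, None, 1),
    ("Wintershof-West", "MN3", "Protaceratherium minutum", 1, 1, 0, 0, 580, 0.0, None, None, None),
]


def default_design(seed: int = 0) -> StudyDesign:
    rows = tuple(SpeciesAtLocality(*r) for r in _DEFAULT_ROWS)
    return StudyDesign(rows=rows, seed=seed)


#: approximate present-day site coordinates (latitude °N, altitude m)
DEFAULT_SITES = {
    "Gaimersheim": (48.8, 0.0), "Rickenbach": (47.3, 0.0),
    "La Milloque": (44.5, 0.0), "Thézels": (44.4, 0.0),
    "Gannat": (46.1, 0.0), "Tomerdingen": (48.5, 0.0),
    "Paulhiac": (44.4, 0.0), "Wischberg": (47.1, 0.0),
    "Pappenheim": (48.9, 0.0), "Ulm-Westtangente": (48.4, 0.0),
    "Engehalde": (47.0, 0.0), "Laugnac": (44.3, 0.0),
    "Valquemado": (41.0, 0.0), "Loranca del Campo": (40.0, 0.0),
    "Wintershof-West": (48.9, 0.0),
}


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------

def _rng(design: StudyDesign, seed: int | None, salt: int) -> np.random.Generator:
    base = design.seed if seed is None else seed
    return np.random.default_rng((int(base) * 1_000_003 + salt) % (2 ** 31))


def gen_measurements(design: StudyDesign, seed: int | None = None) -> pd.DataFrame:
    """Tooth length/width rows obtained by inverting a randomly chosen
    allometric equation at the species' true mass, with multiplicative
    lognormal noise on the length."""
    rng = _rng(design, seed, 1)
    rows = []
    for ri, r in enumerate(design.rows):
        if r.n_body_mass == 0 or r.body_mass_kg is None:
            continue
        for i in range(r.n_body_mass):
            eq = bm.EQUATIONS[int(rng.integers(len(bm.EQUATIONS)))]
            length = invert_equation(eq, r.body_mass_kg, design.width_to_length)
            noisy = length * math.exp(rng.normal(0.0, design.measurement_noise_sd))
            rows.append({
                "specimen_id": f"{r.locality[:3]}-{ri:02d}-{i:03d}",
                "individual_id": f"{r.locality[:3]}-{ri:02d}-{i:03d}",
                "species": r.species, "locality": r.locality,
                "biozone": r.biozone, "locus": eq.locus,
                "length_mm": noisy,
                "width_mm": noisy * design.width_to_length,
            })
    cols = ["specimen_id", "individual_id", "species", "locality", "biozone",
            "locus", "length_mm", "width_mm"]
    return pd.DataFrame(rows, columns=cols)


def invert_equation(eq: bm.AllometricEquation, mass_kg: float,
                    width_to_length: float) -> float:
    """Tooth length (mm) at which ``eq`` predicts exactly ``mass_kg``."""
    native = mass_kg * 1000.0 if eq.unit == "g" else mass_kg
    eq_id = eq.equation_id
    if eq_id == "m1_ln_LxW_g":
        # ln(m) = 1.5133 ln(L·W) + 3.6515 with W = ratio·L
        lw = math.exp((math.log(native) - 3.6515) / 1.5133)
        return math.sqrt(lw / width_to_length)
    if eq_id == "m1_log_L_kg":
        return 10.0 * 10 ** ((math.log10(native) - 1.337) / 3.26)
    if eq_id == "m2_log_L_kg":
        return 10.0 * 10 ** ((math.log10(native) - 1.13) / 3.2)
    if eq_id == "m2_log_L_g":
        return 10 ** ((math.log10(native) - 1.07) / 3.07)
    if eq_id == "M1_ln_L_g":
        return math.exp((math.log(native) - 2.1) / 3.19)
    if eq_id == "M2_log_L_kg":
        return 10.0 * 10 ** ((math.log10(native) - 1.091) / 3.18)
    if eq_id == "M2_log_L_g":
        return 10 ** ((math.log10(native) - 1.06) / 3.03)
    if eq_id == "M2_ln_L_g":
        return math.exp((math.log(native) - 2.14) / 3.09)
    raise ValidationError(f"unknown equation {eq_id}")


def gen_hypoplasia(design: StudyDesign, seed: int | None = None,
                   exact: bool = False) -> pd.DataFrame:
    """Per-tooth binary hypoplasia outcomes.

    ``exact=True`` realises exactly round(prevalence × n / 100) affected
    teeth per species-locality (deterministic); otherwise each tooth is
    an independent Bernoulli draw at the design prevalence.
    """
    rng = _rng(design, seed, 2)
    rows = []
    for ri, r in enumerate(design.rows):
        if r.n_hypoplasia == 0:
            continue
        if exact:
            k = int(round(r.hypoplasia_pct * r.n_hypoplasia / 100.0))
            flags = np.zeros(r.n_hypoplasia, dtype=bool)
            flags[:k] = True
        else:
            flags = rng.random(r.n_hypoplasia) < r.hypoplasia_pct / 100.0
        for i, affected in enumerate(flags):
            rows.append({
                "specimen_id": f"H-{r.locality[:3]}-{ri:02d}-{i:04d}",
                "species": r.species, "genus": r.genus,
                "locality": r.locality, "biozone": r.biozone,
                "affected": bool(affected),
                "defect_type": "linear" if affected else "",
                "distance_edj_mm": float(rng.uniform(2.0, 30.0)) if affected else "",
                "multiplicity": 1 if affected else "",
            })
    cols = ["specimen_id", "species", "genus", "locality", "biozone",
            "affected", "defect_type", "distance_edj_mm", "multiplicity"]
    return pd.DataFrame(rows, columns=cols)


def gen_mesowear(design: StudyDesign, seed: int | None = None) -> pd.DataFrame:
    """Mesowear observations whose per-group median equals the design
    median (integer medians: constant scores; half-integer medians:
    an even mix of the two flanking integers)."""
    rng = _rng(design, seed, 3)
    rows = []
    for ri, r in enumerate(design.rows):
        if r.n_mesowear == 0 or r.mesowear_median is None:
            continue
        med = float(r.mesowear_median)
        for i in range(r.n_mesowear):
            if med == int(med):
                score = int(med)
            else:
                score = int(math.floor(med)) if i % 2 == 0 else int(math.ceil(med))
            rows.append({
                "specimen_id": f"M-{r.locality[:3]}-{ri:02d}-{i:03d}",
                "species": r.species, "locality": r.locality,
                "biozone": r.biozone, "locus": "M2", "cusp": "paracone",
                "wear_stage": int(rng.integers(4, 8)), "score": score,
            })
    cols = ["specimen_id", "species", "locality", "biozone", "locus", "cusp",
            "wear_stage", "score"]
    return pd.DataFrame(rows, columns=cols)


def gen_isotopes(design: StudyDesign, seed: int | None = None,
                 serial: bool = False) -> pd.DataFrame:
    """Enamel-carbonate isotope samples.

    Bulk samples scatter normally around the design species means.
    With ``serial=True``, each sampled tooth becomes an along-crown
    series following a shared-phase sinusoid per isotope (seasonal
    signal) plus noise.
    """
    rng = _rng(design, seed, 4)
    rows = []
    for ri, r in enumerate(design.rows):
        if r.n_isotopes == 0 or r.d13c_co3_pdb is None or r.d18o_co3_pdb is None:
            continue
        for i in range(r.n_isotopes):
            sid = f"I-{r.locality[:3]}-{ri:02d}-{i:03d}"
            if not serial:
                rows.append({
                    "specimen_id": sid, "species": r.species,
                    "locality": r.locality, "biozone": r.biozone,
                    "sampling": "bulk", "serial_position_mm": "",
                    "d13c_co3_pdb": r.d13c_co3_pdb + rng.normal(0, design.isotope_sd_permil),
                    "d18o_co3_pdb": r.d18o_co3_pdb + rng.normal(0, design.isotope_sd_permil),
                })
            else:
                phase = rng.uniform(0, 2 * math.pi)
                positions = np.linspace(0, design.serial_period_mm,
                                        design.serial_points)
                w = 2 * math.pi / design.serial_period_mm
                for pos in positions:
                    rows.append({
                        "specimen_id": sid, "species": r.species,
                        "locality": r.locality, "biozone": r.biozone,
                        "sampling": "serial", "serial_position_mm": float(pos),
                        "d13c_co3_pdb": (r.d13c_co3_pdb
                                         + design.serial_amp_d13c * math.sin(w * pos + phase)
                                         + rng.normal(0, design.serial_noise_sd)),
                        "d18o_co3_pdb": (r.d18o_co3_pdb
                                         + design.serial_amp_d18o * math.sin(w * pos + phase)
                                         + rng.normal(0, design.serial_noise_sd)),
                    })
    cols = ["specimen_id", "species", "locality", "biozone", "sampling",
            "serial_position_mm", "d13c_co3_pdb", "d18o_co3_pdb"]
    return pd.DataFrame(rows, columns=cols)


def gen_serial_series(amplitude_d13c: float = 0.25, amplitude_d18o: float = 0.5,
                      period_mm: float = 30.0, n_points: int = 12,
                      noise_sd: float = 0.0, phase: float = 0.0,
                      mean_d13c: float = -10.0, mean_d18o: float = -4.0,
                      seed: int = 0) -> pd.DataFrame:
    """One standalone along-crown series with a shared-phase sinusoid."""
    rng = np.random.default_rng(seed)
    pos = np.linspace(0, period_mm, n_points)
    w = 2 * math.pi / period_mm
    return pd.DataFrame({
        "serial_position_mm": pos,
        "d13c_co3_pdb": mean_d13c + amplitude_d13c * np.sin(w * pos + phase)
                        + rng.normal(0, noise_sd, n_points),
        "d18o_co3_pdb": mean_d18o + amplitude_d18o * np.sin(w * pos + phase)
                        + rng.normal(0, noise_sd, n_points),
    })


# --------------------------------------------------------------------------
# Synthetic surfaces
# --------------------------------------------------------------------------

ARCHETYPES = ("flat", "tilted_plane", "sinusoid_grooves", "isotropic_gaussian",
              "spectral_fractal", "rough_quadrant")


def gen_surface(archetype: str, size: int = 256,
                spacing_um: float | None = None, seed: int = 0,
                amplitude_um: float = 0.5,
                groove_wavelength_um: float = 10.0,
                correlation_um: float = 2.0,
                spectral_exponent: float = 2.5,
                facet: str = "grinding") -> SurfaceScan:
    """Deterministic synthetic surface of a named archetype.

    ``spacing_um`` defaults to 200/size so the grid always spans the
    standard 200 × 200 μm field.
    """
    if archetype not in ARCHETYPES:
        raise ValidationError(f"unknown archetype {archetype!r}")
    spacing = spacing_um if spacing_um is not None else 200.0 / size
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    x_um = xx * spacing
    y_um = yy * spacing
    if archetype == "flat":
        z = np.zeros((size, size))
    elif archetype == "tilted_plane":
        z = 1.0 * x_um + 0.5 * y_um
    elif archetype == "sinusoid_grooves":
        z = amplitude_um * np.sin(2 * math.pi * x_um / groove_wavelength_um)
    elif archetype == "isotropic_gaussian":
        from scipy import ndimage
        white = rng.normal(0, 1, (size, size))
        z = ndimage.gaussian_filter(white, sigma=correlation_um / spacing,
                                    mode="wrap")
        z *= amplitude_um / max(z.std(), 1e-12)
    elif archetype == "spectral_fractal":
        fy = np.fft.fftfreq(size)[:, None]
        fx = np.fft.rfftfreq(size)[None, :]
        f = np.sqrt(fy ** 2 + fx ** 2)
        f[0, 0] = np.inf  # zero mean
        amp = f ** (-spectral_exponent / 2.0)
        phases = np.exp(2j * math.pi * rng.random(amp.shape))
        z = np.fft.irfft2(amp * phases, s=(size, size))
        z *= amplitude_um / max(z.std(), 1e-12)
    elif archetype == "rough_quadrant":
        # one strongly rough quadrant on a mildly rough background
        z = 0.1 * amplitude_um * rng.normal(0, 1, (size, size))
        h = size // 2
        z[:h, :h] += amplitude_um * rng.normal(0, 1, (h, h))
    return SurfaceScan(z, spacing, facet=facet, specimen_id=f"{archetype}-{seed}")


# --------------------------------------------------------------------------
# Full synthetic study
# --------------------------------------------------------------------------

def gen_full_study(design: StudyDesign, out_dir: str | Path,
                   seed: int | None = None) -> dict:
    """Write a complete synthetic input set plus a ground-truth ledger.

    Produces ``measurements.csv``, ``hypoplasia.csv``, ``mesowear.csv``,
    ``isotopes.csv`` and ``truth.json`` under ``out_dir``; returns the
    truth ledger.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = {
        "measurements": gen_measurements(design, seed),
        "hypoplasia": gen_hypoplasia(design, seed),
        "mesowear": gen_mesowear(design, seed),
        "isotopes": gen_isotopes(design, seed),
    }
    for name, frame in frames.items():
        frame.to_csv(out_dir / f"{name}.csv", index=False)
    truth = {
        "seed": design.seed if seed is None else seed,
        "rows": [asdict(r) for r in design.rows],
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth
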