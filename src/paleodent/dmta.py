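"""Dental microwear texture analysis (DMTA) on profilometric height maps.

A wear facet is scanned as a rectangular grid of elevations (μm) with a
known lateral spacing.  After a standard pre-treatment (inversion of
the negative replica, filling of non-measured points, outlier-peak
removal, levelling, polynomial form removal, central-window selection)
four families of texture parameters are computed:

* ``Asfc``  — area-scale fractal complexity: 1000 × the steepest
  negative slope of log10(relative area) against log10(scale) at fine
  scales; rough, pitted surfaces (hard-object feeding) score high.
* ``epLsar`` — anisotropy of profile relative lengths across
  orientations (the corrected, equally-weighted normalisation);
  scratch-dominated (grass-like) textures score high.
* ``Str``   — ISO 25178 texture aspect ratio: ratio of the fastest to
  slowest autocorrelation decay length at threshold ``s`` (0.5 here);
  near 1 = isotropic, near 0 = strongly oriented.
* ``HAsfc`` — heterogeneity of complexity: relative median absolute
  deviation of cell-wise Asfc over a 3×3 or 9×9 partition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from paleodent.datamodel import ValidationError

FACETS = ("grinding", "shearing")

#: defaults for the standard 200 × 200 μm field
FIELD_UM = 200.0
NOMINAL_PX = 1551
FINE_SCALE_LIMIT_UM2 = 100.0
EPLSAR_SCALE_UM = 1.8
EPLSAR_ANGLE_STEP_DEG = 5.0
STR_THRESHOLD = 0.5
PEAK_K = 10.0
NMP_LIMIT = 0.01


class SurfaceError(ValueError):
    pass


@dataclass
class SurfaceScan:
    """A masked height grid with lateral spacing in μm.

    ``mask`` is True where the point was measured.  ``heights`` may hold
    NaN at non-measured points before preprocessing.
    """

    heights: np.ndarray
    spacing_um: float
    mask: np.ndarray | None = None
    facet: str = "grinding"
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise SurfaceError("height grid must be 2-D")
        if self.spacing_um <= 0:
            raise SurfaceError("spacing must be positive")
        if self.mask is None:
            self.mask = np.isfinite(self.heights)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.heights.shape:
            raise SurfaceError("mask shape mismatch")
        if self.facet not in FACETS:
            raise SurfaceError(f"facet must be one of {FACETS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def nonmeasured_fraction(self) -> float:
        return 1.0 - float(self.mask.mean())


@dataclass
class TextureResult:
    asfc: float
    eplsar: float
    str_ratio: float
    hasfc_3x3: float
    hasfc_9x9: float
    facet: str = "grinding"
    specimen_id: str = ""
    diagnostics: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# I/O: plain-matrix grid + JSON sidecar
# --------------------------------------------------------------------------

def read_surface(matrix_path: str | Path, sidecar_path: str | Path | None = None
                 ) -> SurfaceScan:
    """Read a surface from a CSV height matrix plus a JSON sidecar.

    The sidecar carries {rows, cols, spacing_um, facet, specimen_id};
    non-measured points are NaN in the matrix.
    """
    matrix_path = Path(matrix_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else matrix_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    z = np.loadtxt(matrix_path, delimiter=",", ndmin=2)
    if "rows" in meta and z.shape != (meta["rows"], meta["cols"]):
        raise SurfaceError(f"grid shape {z.shape} contradicts sidecar "
                           f"({meta['rows']}, {meta['cols']})")
    return SurfaceScan(z, float(meta["spacing_um"]),
                       facet=meta.get("facet", "grinding"),
                       specimen_id=meta.get("specimen_id", ""))


def write_surface(scan: SurfaceScan, matrix_path: str | Path) -> None:
    matrix_path = Path(matrix_path)
    z = scan.heights.copy()
    z[~scan.mask] = np.nan
    np.savetxt(matrix_path, z, delimiter=",", fmt="%.6g")
    meta = {"rows": scan.shape[0], "cols": scan.shape[1],
            "spacing_um": scan.spacing_um, "units": "um",
            "facet": scan.facet, "specimen_id": scan.specimen_id}
    matrix_path.with_suffix(".json").write_text(json.dumps(meta))


# --------------------------------------------------------------------------
# Pre-treatment
# --------------------------------------------------------------------------

def _fill_nonmeasured(z: np.ndarray, mask: np.ndarray,
                      tol: float = 1e-12, max_iter: int = 10_000) -> np.ndarray:
    """Replace unmeasured points by the mean of their 8-neighbours.

    An initial frontier fill is relaxed (Jacobi iterations on the
    unmeasured set only) until convergence, so the interpolant of the
    symmetric mean-of-neighbours stencil is reproduced exactly; linear
    surfaces pass through unchanged.
    """
    if mask.all():
        return z.copy()
    z = z.copy()
    z[~mask] = 0.0
    filled = mask.copy()
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    while not filled.all():
        counts = ndimage.convolve(filled.astype(float), kernel, mode="constant")
        sums = ndimage.convolve(np.where(filled, z, 0.0), kernel, mode="constant")
        frontier = (~filled) & (counts > 0)
        if not frontier.any():
            raise SurfaceError("cannot fill: no measured points at all")
        z[frontier] = sums[frontier] / counts[frontier]
        filled |= frontier
    # relax the filled values against all (measured + filled) neighbours;
    # the linearly extrapolated border pad keeps the stencil exact on
    # affine surfaces, so a tilted plane passes through unchanged
    hole = ~mask
    for _ in range(max_iter):
        new = _neighbor_mean(z)[hole]
        delta = float(np.max(np.abs(new - z[hole])))
        z[hole] = new
        if delta < tol:
            break
    return z


def _neighbor_mean(z: np.ndarray) -> np.ndarray:
    """Mean of the 8 neighbours of every pixel, with a linearly
    extrapolated one-pixel pad so affine surfaces are fixed points."""
    ny, nx = z.shape
    zp = np.empty((ny + 2, nx + 2))
    zp[1:-1, 1:-1] = z
    zp[0, 1:-1] = 2 * z[0] - z[1]
    zp[-1, 1:-1] = 2 * z[-1] - z[-2]
    zp[:, 0] = 2 * zp[:, 1] - zp[:, 2]
    zp[:, -1] = 2 * zp[:, -2] - zp[:, -3]
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    sums = ndimage.convolve(zp, kernel, mode="nearest")[1:-1, 1:-1]
    return sums / 8.0


def _remove_peaks(z: np.ndarray, k: float) -> tuple[np.ndarray, int]:
    """Mask pixels deviating from the 5×5 local median by more than
    k × global RMS roughness and refill them from their neighbours."""
    med = ndimage.median_filter(z, size=5, mode="nearest")
    rms = float(np.sqrt(np.mean((z - z.mean()) ** 2)))
    if rms == 0:
        return z, 0
    outliers = np.abs(z - med) > k * rms
    if not outliers.any():
        return z, 0
    return _fill_nonmeasured(z, ~outliers), int(outliers.sum())


def _remove_form(z: np.ndarray, degree: int) -> np.ndarray:
    """Subtract the least-squares bivariate polynomial of total degree
    ``degree``.

    Chebyshev tensor basis on [-1, 1]² restricted to i + j <= degree;
    the Gram matrix separates into 1-D Grams on a full grid, so the fit
    costs O(grid) regardless of degree and never materialises a dense
    design matrix.
    """
    ny, nx = z.shape
    py = np.polynomial.chebyshev.chebvander(np.linspace(-1, 1, ny), degree)
    px = np.polynomial.chebyshev.chebvander(np.linspace(-1, 1, nx), degree)
    gy = py.T @ py
    gx = px.T @ px
    m = py.T @ z @ px
    terms = [(i, j) for i in range(degree + 1) for j in range(degree + 1 - i)]
    n_terms = len(terms)
    gram = np.empty((n_terms, n_terms))
    rhs = np.empty(n_terms)
    for t, (i, j) in enumerate(terms):
        rhs[t] = m[i, j]
        for u, (k, l) in enumerate(terms):
            gram[t, u] = gy[i, k] * gx[j, l]
    coef = np.linalg.solve(gram, rhs)
    cmat = np.zeros((degree + 1, degree + 1))
    for t, (i, j) in enumerate(terms):
        cmat[i, j] = coef[t]
    return z - py @ cmat @ px.T


def preprocess(raw: SurfaceScan,
               invert: bool = True,
               peak_k: float = PEAK_K,
               form_degree: int = 8,
               window_um: float | None = FIELD_UM,
               nmp_limit: float = NMP_LIMIT) -> SurfaceScan:
    """Standard pre-treatment pipeline, in order: inversion (negative
    replica → positive relief), non-measured-point filling, aberrant
    peak removal, plane levelling, polynomial form removal (total
    degree 8), central-window selection.

    ``window_um=None`` keeps the full grid.  Raises :class:`SurfaceError`
    if the non-measured fraction is at or above ``nmp_limit`` or the
    requested window exceeds the grid.
    """
    nmp = raw.nonmeasured_fraction
    if nmp >= nmp_limit:
        raise SurfaceError(
            f"non-measured fraction {nmp:.2%} exceeds the {nmp_limit:.0%} limit")
    z = raw.heights.copy()
    if invert:
        z = -z
    z = _fill_nonmeasured(z, raw.mask)
    z, n_peaks = _remove_peaks(z, peak_k)
    z = _remove_form(z, 1)            # levelling (plane)
    z = _remove_form(z, form_degree)  # form removal
    if window_um is not None:
        want = int(round(window_um / raw.spacing_um))
        ny, nx = z.shape
        if want > min(ny, nx):
            raise SurfaceError(
                f"window of {want} px exceeds the {ny}x{nx} grid")
        oy, ox = (ny - want) // 2, (nx - want) // 2
        z = z[oy:oy + want, ox:ox + want]
    return SurfaceScan(z, raw.spacing_um, mask=np.ones_like(z, dtype=bool),
                       facet=raw.facet, specimen_id=raw.specimen_id)


# --------------------------------------------------------------------------
# Scale-sensitive fractal analysis
# --------------------------------------------------------------------------

def _triangulated_area(z: np.ndarray, spacing: float, step: int,
                       offset: tuple[int, int] = (0, 0)) -> tuple[float, float]:
    """(3-D area, projected area) of the surface tiled at a coarseness of
    ``step`` pixels, each square cell split into two triangles."""
    sub = z[offset[0]::step, offset[1]::step]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise SurfaceError("grid too small for this scale")
    d = step * spacing
    z00 = sub[:-1, :-1]
    z01 = sub[:-1, 1:]
    z10 = sub[1:, :-1]
    z11 = sub[1:, 1:]

    # each cell split along its diagonal into triangles
    # t1 = (d,0,z01-z00), (d,d,z11-z00); t2 = (0,d,z10-z00), (d,d,z11-z00)
    def tri(u, v):
        # |u × v| / 2 with u=(ux,uy,uz), v=(vx,vy,vz)
        ux, uy, uz = u
        vx, vy, vz = v
        cx = uy * vz - uz * vy
        cy = uz * vx - ux * vz
        cz = ux * vy - uy * vx
        return 0.5 * np.sqrt(cx ** 2 + cy ** 2 + cz ** 2)

    a_t1 = tri((d, 0.0, z01 - z00), (d, d, z11 - z00))
    a_t2 = tri((0.0, d, z10 - z00), (d, d, z11 - z00))
    area3d = float(a_t1.sum() + a_t2.sum())
    nrows, ncols = sub.shape
    projected = (nrows - 1) * (ncols - 1) * d * d
    return area3d, float(projected)


def relative_area_curve(surface: SurfaceScan,
                        steps: Sequence[int] | None = None
                        ) -> list[tuple[float, float]]:
    """(scale μm², relative area) pairs over a range of coarsenesses.

    Scale is the projected area of one triangular facet,
    (step × spacing)² / 2.  Relative area is the triangulated 3-D area
    divided by the projected area; 1 for a flat surface.  At each scale
    the relative area is averaged over mesh origins (up to 4 offsets per
    axis), which de-noises the curve at coarse scales.
    """
    z = surface.heights
    n = min(z.shape)
    if steps is None:
        # geometric ladder of integer steps
        raw = np.unique(np.round(np.geomspace(1, max(n // 6, 2), 24)).astype(int))
        steps = [int(s) for s in raw if n // s >= 3]
    out = []
    for step in steps:
        if step < 1 or n // step < 3:
            continue
        offsets = np.linspace(0, step - 1, min(step, 4)).astype(int)
        ratios = []
        for oy in offsets:
            for ox in offsets:
                if (min(z.shape) - max(oy, ox)) // step < 3:
                    continue
                area3d, proj = _triangulated_area(z, surface.spacing_um, step,
                                                  (int(oy), int(ox)))
                ratios.append(area3d / proj)
        scale = (step * surface.spacing_um) ** 2 / 2.0
        out.append((scale, float(np.mean(ratios))))
    if not out:
        raise SurfaceError("no usable scales for this grid")
    return out


def asfc(curve: Sequence[tuple[float, float]],
         fine_limit_um2: float = FINE_SCALE_LIMIT_UM2,
         window: int = 5) -> float:
    """Area-scale fractal complexity from a relative-area curve.

    Asfc = −1000 × the steepest slope of log10(relative area) against
    log10(scale), estimated over sliding ``window``-point fits on the
    fine-scale end (scales below ``fine_limit_um2``).  A flat curve
    (all relative areas 1) yields 0.
    """
    pts = sorted((s, a) for s, a in curve if s <= fine_limit_um2)
    if len(pts) < window:
        pts = sorted(curve)[:max(window, 5)]
    if len(pts) < 2:
        raise SurfaceError("relative-area curve too short")
    ls = np.log10([p[0] for p in pts])
    la = np.log10(np.maximum([p[1] for p in pts], 1e-300))
    if np.allclose(la, 0.0):
        return 0.0
    w = min(window, len(pts))
    steepest = 0.0
    for i in range(len(pts) - w + 1):
        slope = np.polyfit(ls[i:i + w], la[i:i + w], 1)[0]
        steepest = min(steepest, slope)
    return max(0.0, -1000.0 * float(steepest))


def asfc_of(surface: SurfaceScan, **kwargs) -> float:
    return asfc(relative_area_curve(surface), **kwargs)


# --------------------------------------------------------------------------
# Anisotropy: epLsar and Str
# --------------------------------------------------------------------------

def _profile_relative_length(z: np.ndarray, spacing: float, theta_rad: float,
                             sample_um: float) -> float:
    """Mean relative length of transect profiles along direction theta,
    sampled at ``sample_um`` increments via bilinear interpolation."""
    ny, nx = z.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    half = (min(ny, nx) / 2.0 - 1.0)  # inscribed half-size, px
    step_px = sample_um / spacing
    n_along = int(2 * half / step_px)
    if n_along < 2:
        raise SurfaceError("profile scale too coarse for this grid")
    t = (np.arange(n_along) - (n_along - 1) / 2.0) * step_px
    ux, uy = math.cos(theta_rad), math.sin(theta_rad)
    vx, vy = -uy, ux
    offsets = np.arange(-half, half, max(4.0, step_px))
    rel_lengths = []
    for off in offsets:
        xs = cx + t * ux + off * vx
        ys = cy + t * uy + off * vy
        inside = (xs >= 0) & (xs <= nx - 1) & (ys >= 0) & (ys <= ny - 1)
        if inside.sum() < 2:
            continue
        prof = ndimage.map_coordinates(z, [ys[inside], xs[inside]], order=1)
        dz = np.diff(prof)
        dx = sample_um
        length = np.sum(np.sqrt(dx * dx + dz * dz))
        rel_lengths.append(length / (dx * len(dz)))
    if not rel_lengths:
        raise SurfaceError("no valid transects")
    return float(np.mean(rel_lengths))


def eplsar(surface: SurfaceScan,
           profile_scale_um: float = EPLSAR_SCALE_UM,
           angle_step_deg: float = EPLSAR_ANGLE_STEP_DEG) -> float:
    """Exact-proportion length-scale anisotropy of relief (corrected
    normalisation: all orientations weighted equally).

    Profile relative lengths are computed at ``profile_scale_um`` for
    orientations over [0°, 180°); their normalised shares are combined
    as a mean resultant vector on the doubled-angle circle.  0 for
    isotropic relief, larger for oriented relief.  The relief is
    RMS-normalised first, so the parameter depends on texture shape
    only and is exactly invariant under uniform height rescaling.
    """
    angles = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
    if len(angles) < 4:
        raise SurfaceError("need at least 4 orientations")
    z = surface.heights
    rms = float(np.sqrt(np.mean((z - z.mean()) ** 2)))
    if rms > 0:
        z = z / rms
    lengths = np.array([
        _profile_relative_length(z, surface.spacing_um, a, profile_scale_um)
        for a in angles])
    total = lengths.sum()
    if total == 0:
        return 0.0
    f = lengths / total
    vec = np.sum(f * np.exp(2j * angles))
    return float(np.abs(vec))


def _autocorrelation(z: np.ndarray) -> np.ndarray:
    """Normalised (biased) 2-D autocorrelation via FFT, centred."""
    z = z - z.mean()
    ny, nx = z.shape
    f = np.fft.rfft2(z, s=(2 * ny, 2 * nx))
    # biased (linearly tapered) estimate: guarantees decay towards the
    # field edge, which is what the decay-length search needs
    acf = np.fft.fftshift(np.fft.irfft2(f * np.conj(f), s=(2 * ny, 2 * nx)))
    peak = acf.max()
    if peak <= 0:
        raise SurfaceError("degenerate surface: zero variance")
    return acf / peak


def str_param(surface: SurfaceScan, s: float = STR_THRESHOLD,
              angle_step_deg: float = 1.0) -> tuple[float, dict]:
    """ISO 25178 texture aspect ratio Str = Rmin/Rmax in (0, 1].

    The normalised autocorrelation is sampled along rays at
    ``angle_step_deg`` increments; the decay length to threshold ``s``
    is interpolated linearly.  Directions whose autocorrelation never
    reaches ``s`` inside the field are capped at the maximal sampled
    radius and flagged in the diagnostics.
    """
    if not (0.0 < s < 1.0):
        raise SurfaceError("threshold s must be in (0, 1)")
    acf = _autocorrelation(surface.heights)
    ny, nx = acf.shape
    cy, cx = np.unravel_index(int(np.argmax(acf)), acf.shape)
    rmax_px = min(cy, cx, ny - 1 - cy, nx - 1 - cx) - 1
    radii = np.arange(0.0, rmax_px, 0.5)
    angles = np.deg2rad(np.arange(0.0, 360.0, angle_step_deg))
    decays = np.empty(len(angles))
    capped = 0
    for i, a in enumerate(angles):
        xs = cx + radii * math.cos(a)
        ys = cy + radii * math.sin(a)
        prof = ndimage.map_coordinates(acf, [ys, xs], order=1)
        below = np.nonzero(prof < s)[0]
        if len(below) == 0:
            decays[i] = radii[-1]
            capped += 1
            continue
        j = below[0]
        if j == 0:
            decays[i] = 0.0
            continue
        # linear interpolation of the crossing
        r0, r1 = radii[j - 1], radii[j]
        p0, p1 = prof[j - 1], prof[j]
        decays[i] = r0 + (p0 - s) / (p0 - p1) * (r1 - r0)
    if capped == len(angles):
        raise SurfaceError("autocorrelation never decays to s in any direction")
    rmin, rmaxv = float(decays.min()), float(decays.max())
    ratio = rmin / rmaxv if rmaxv > 0 else 1.0
    return ratio, {"rmin_px": rmin, "rmax_px": rmaxv, "capped_directions": capped}


# --------------------------------------------------------------------------
# Heterogeneity of complexity
# --------------------------------------------------------------------------

def hasfc(surface: SurfaceScan, grid: int = 3,
          variant: str = "rel-mad") -> float:
    """Heterogeneity of complexity over a grid × grid partition.

    Asfc is computed per cell (remainder pixels truncated); the default
    summary is the relative median absolute deviation
    median(|Asfc_i − median|)/median; ``variant="range"`` uses
    (max − min)/median instead.  Cells with a degenerate curve
    contribute Asfc = 0.  The relief is RMS-normalised before cell
    analysis, so the heterogeneity ratio is exactly invariant under
    uniform height rescaling.
    """
    if grid < 2:
        raise SurfaceError("grid must be at least 2")
    z = surface.heights
    rms = float(np.sqrt(np.mean((z - z.mean()) ** 2)))
    if rms > 0:
        z = z / rms
    ny, nx = z.shape
    hy, hx = ny // grid, nx // grid
    if min(hy, hx) < 8:
        raise SurfaceError("cells too small for a relative-area curve")
    values = []
    for i in range(grid):
        for j in range(grid):
            cell = SurfaceScan(z[i * hy:(i + 1) * hy, j * hx:(j + 1) * hx],
                               surface.spacing_um, facet=surface.facet)
            try:
                values.append(asfc_of(cell))
            except SurfaceError:
                values.append(0.0)
    values = np.asarray(values)
    med = float(np.median(values))
    if med == 0:
        return 0.0
    if variant == "range":
        return float((values.max() - values.min()) / med)
    return float(np.median(np.abs(values - med)) / med)


# --------------------------------------------------------------------------
# Full pipeline and interpretation
# --------------------------------------------------------------------------

def analyze(surface: SurfaceScan, preprocessed: bool = False,
            **pre_kwargs) -> TextureResult:
    """Pre-treat (unless already done) and compute all five parameters."""
    surf = surface if preprocessed else preprocess(surface, **pre_kwargs)
    ratio, diag = str_param(surf)
    return TextureResult(
        asfc=asfc_of(surf),
        eplsar=eplsar(surf),
        str_ratio=ratio,
        hasfc_3x3=hasfc(surf, 3),
        hasfc_9x9=hasfc(surf, 9),
        facet=surf.facet,
        specimen_id=surf.specimen_id,
        diagnostics=diag,
    )


#: interpretation thresholds from extant-taxon comparisons
STR_TOUGH_MAX = 0.2     # Str below: tough, abrasive (grass-like/folivory)
STR_LOW_ANISO_MIN = 0.3  # Str above: low anisotropy
ASFC_HARD_MIN = 2.0      # Asfc above: hard-object inclusion


def classify_dmt(result: TextureResult, facet: str | None = None) -> dict[str, object]:
    """Dietary-tendency labels from the printed interpretation thresholds.

    Returns the triggered rules alongside the combined tendency so the
    interpretation is auditable.
    """
    facet = facet or result.facet
    rules = []
    if result.str_ratio < STR_TOUGH_MAX:
        rules.append("tough/abrasive (grass-like or folivory)")
    if result.str_ratio > STR_LOW_ANISO_MIN:
        rules.append("low anisotropy")
    if result.asfc > ASFC_HARD_MIN:
        rules.append("hard-object inclusion")
    if result.str_ratio > STR_LOW_ANISO_MIN and result.asfc > ASFC_HARD_MIN:
        tendency = "browsing with hard objects"
    elif result.str_ratio > STR_LOW_ANISO_MIN:
        tendency = "browser"
    elif result.str_ratio < STR_TOUGH_MAX:
        tendency = "abrasive-feeder"
    else:
        tendency = "mixed/undetermined"
    return {"facet": facet, "tendency": tendency, "rules": rules}
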