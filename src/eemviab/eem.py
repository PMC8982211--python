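"""Excitation–emission matrix (EEM) data structures, scatter-avoidance
geometry, masking, unfolding and difference-spectrum utilities.

An EEM ("fluorescence landscape") records full emission spectra at a series
of excitation wavelengths, giving one intensity matrix per sample.  Rayleigh
and Raman scatter contaminate cells where the emission wavelength is close
to the excitation wavelength; the acquisition geometry used here avoids them
by starting each emission scan a fixed offset above the excitation
wavelength (for excitations at or above a cutoff) or at a fixed emission
floor (below the cutoff).  Cells that are never scanned are *masked* —
explicitly undefined, stored as NaN — and omitted when an EEM is unfolded
into the fixed-order vector consumed by first-order calibration methods.

Canonical unfolding order is ascending excitation wavelength, then ascending
emission wavelength.  The permutation is immaterial to any multivariate
model downstream, so the reproducible order is preferred over instrument
scan chronology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np


class GeometryError(ValueError):
    """Raised for an acquisition geometry that violates its invariants."""


class DataIntegrityError(ValueError):
    """Raised when an intensity is undefined (or present) where it must not be."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Plate-reader scan geometry defining the excitation/emission grids.

    All wavelengths are integers in nm.  The default geometry scans
    excitation 250–500 nm in 10 nm steps (26 wavelengths) with an emission
    grid from 300 to 650 nm in 5 nm steps (71 grid points); emission starts
    at ``lambda_ex + scatter_offset`` for excitations at or above
    ``ex_cutoff`` and at ``em_floor`` otherwise.
    """

    ex_start: int = 250
    ex_stop: int = 500
    ex_step: int = 10
    em_stop: int = 650
    em_step: int = 5
    em_floor: int = 300
    ex_cutoff: int = 290
    scatter_offset: int = 20

    def __post_init__(self) -> None:
        if self.ex_step <= 0 or self.em_step <= 0:
            raise GeometryError("ex_step and em_step must be positive")
        if self.ex_stop < self.ex_start:
            raise GeometryError("ex_stop must be >= ex_start")
        if (self.ex_stop - self.ex_start) % self.ex_step != 0:
            raise GeometryError(
                f"excitation range {self.ex_start}-{self.ex_stop} nm is not "
                f"divisible by ex_step={self.ex_step} nm"
            )
        if (self.em_stop - self.em_floor) % self.em_step != 0:
            raise GeometryError(
                f"emission range {self.em_floor}-{self.em_stop} nm is not "
                f"divisible by em_step={self.em_step} nm"
            )
        for ex in range(self.ex_start, self.ex_stop + 1, self.ex_step):
            lo = self._em_start(ex)
            if (lo - self.em_floor) % self.em_step != 0:
                raise GeometryError(
                    f"emission start {lo} nm for excitation {ex} nm is off "
                    f"the emission grid (floor {self.em_floor}, step {self.em_step})"
                )
            if lo > self.em_stop:
                raise GeometryError(
                    f"empty emission interval at excitation {ex} nm"
                )

    def _em_start(self, lambda_ex: int) -> int:
        if lambda_ex >= self.ex_cutoff:
            return max(self.em_floor, lambda_ex + self.scatter_offset)
        return self.em_floor

    @property
    def ex_wavelengths(self) -> np.ndarray:
        """Excitation grid, ascending (nm)."""
        return np.arange(self.ex_start, self.ex_stop + 1, self.ex_step)

    @property
    def em_wavelengths(self) -> np.ndarray:
        """Emission grid, ascending (nm)."""
        return np.arange(self.em_floor, self.em_stop + 1, self.em_step)

    @property
    def n_ex(self) -> int:
        return (self.ex_stop - self.ex_start) // self.ex_step + 1

    @property
    def n_em(self) -> int:
        return (self.em_stop - self.em_floor) // self.em_step + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_ex, self.n_em)


def valid_emission_range(
    geometry: AcquisitionGeometry, lambda_ex: int
) -> tuple[int, int]:
    """Scanned emission interval ``(em_min, em_max)`` for one excitation.

    ``lambda_ex`` must lie on the excitation grid.  Both endpoints lie on
    the emission grid by construction of a valid geometry.
    """
    exs = geometry.ex_wavelengths
    if lambda_ex not in exs:
        raise GeometryError(
            f"excitation wavelength {lambda_ex} nm is not on the grid "
            f"{geometry.ex_start}-{geometry.ex_stop} nm step {geometry.ex_step} nm"
        )
    return (geometry._em_start(int(lambda_ex)), geometry.em_stop)


@dataclass(frozen=True)
class ValidityMask:
    """Boolean scatter mask plus the canonical valid-cell ordering.

    ``index_map`` lists (ex_index, em_index) pairs for every valid cell in
    canonical order: ascending excitation, then ascending emission.  Its
    length is the dimensionality of the unfolded spectrum (1340 for the
    default geometry).
    """

    geometry: AcquisitionGeometry
    grid: np.ndarray = field(repr=False)
    index_map: np.ndarray = field(repr=False)

    @property
    def n_valid(self) -> int:
        return int(self.index_map.shape[0])


@lru_cache(maxsize=32)
def build_mask(geometry: AcquisitionGeometry) -> ValidityMask:
    """Construct the scatter-avoidance validity mask for a geometry."""
    ems = geometry.em_wavelengths
    grid = np.zeros(geometry.shape, dtype=bool)
    for i, ex in enumerate(geometry.ex_wavelengths):
        lo, hi = valid_emission_range(geometry, int(ex))
        grid[i] = (ems >= lo) & (ems <= hi)
    index_map = np.argwhere(grid)  # argwhere is already lexicographic
    grid.flags.writeable = False
    index_map.flags.writeable = False
    return ValidityMask(geometry=geometry, grid=grid, index_map=index_map)


@dataclass
class ExcitationEmissionMatrix:
    """One sample's λex × λem intensity grid with metadata.

    Masked (never-scanned) cells hold NaN.  Intensities at valid cells are
    finite and non-negative, except for difference spectra
    (``is_difference=True``) where negative changes are meaningful.
    """

    geometry: AcquisitionGeometry
    intensities: np.ndarray
    sample_id: str = ""
    dose_min: float = 0.0
    replicate: int = 0
    is_difference: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.geometry.shape:
            raise DataIntegrityError(
                f"intensity matrix shape {self.intensities.shape} does not "
                f"match geometry shape {self.geometry.shape}"
            )

    def validate(self) -> None:
        """Check finiteness (and non-negativity unless a difference spectrum)."""
        mask = build_mask(self.geometry)
        vals = self.intensities[mask.grid]
        if not np.all(np.isfinite(vals)):
            i, j = _first_offending(self, ~np.isfinite(self.intensities))
            raise DataIntegrityError(
                f"undefined intensity at valid cell λex={i} nm, λem={j} nm "
                f"(sample {self.sample_id!r})"
            )
        if not self.is_difference and np.any(vals < 0):
            i, j = _first_offending(self, self.intensities < 0)
            raise DataIntegrityError(
                f"negative intensity at λex={i} nm, λem={j} nm in a "
                f"non-difference spectrum (sample {self.sample_id!r})"
            )


def _first_offending(eem: ExcitationEmissionMatrix, bad: np.ndarray) -> tuple[int, int]:
    mask = build_mask(eem.geometry)
    where = np.argwhere(bad & mask.grid)
    i, j = where[0]
    return (int(eem.geometry.ex_wavelengths[i]), int(eem.geometry.em_wavelengths[j]))


@dataclass
class UnfoldedSpectrum:
    """A masked EEM flattened to a fixed-order vector (canonical order)."""

    values: np.ndarray
    mask: ValidityMask
    sample_id: str = ""
    dose_min: float = 0.0
    replicate: int = 0
    is_difference: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.shape[0] != self.mask.n_valid:
            raise DataIntegrityError(
                f"unfolded vector length {self.values.shape} does not match "
                f"the mask's {self.mask.n_valid} valid cells"
            )


def unfold(
    eem: ExcitationEmissionMatrix, mask: ValidityMask | None = None
) -> UnfoldedSpectrum:
    """Flatten an EEM to its canonical valid-cell vector, omitting masked cells."""
    if mask is None:
        mask = build_mask(eem.geometry)
    if mask.geometry != eem.geometry:
        raise GeometryError("mask geometry does not match EEM geometry")
    values = eem.intensities[mask.index_map[:, 0], mask.index_map[:, 1]]
    if not np.all(np.isfinite(values)):
        k = int(np.flatnonzero(~np.isfinite(values))[0])
        i, j = mask.index_map[k]
        raise DataIntegrityError(
            f"undefined intensity at valid cell "
            f"λex={int(eem.geometry.ex_wavelengths[i])} nm, "
            f"λem={int(eem.geometry.em_wavelengths[j])} nm "
            f"(sample {eem.sample_id!r})"
        )
    return UnfoldedSpectrum(
        values=values,
        mask=mask,
        sample_id=eem.sample_id,
        dose_min=eem.dose_min,
        replicate=eem.replicate,
        is_difference=eem.is_difference,
    )


def refold(spec: UnfoldedSpectrum) -> ExcitationEmissionMatrix:
    """Inverse of :func:`unfold`: place vector entries back on the grid."""
    geometry = spec.mask.geometry
    grid = np.full(geometry.shape, np.nan)
    grid[spec.mask.index_map[:, 0], spec.mask.index_map[:, 1]] = spec.values
    return ExcitationEmissionMatrix(
        geometry=geometry,
        intensities=grid,
        sample_id=spec.sample_id,
        dose_min=spec.dose_min,
        replicate=spec.replicate,
        is_difference=spec.is_difference,
    )


def difference_eem(
    treated: ExcitationEmissionMatrix, control: ExcitationEmissionMatrix
) -> ExcitationEmissionMatrix:
    """Cell-wise treated − control difference spectrum (negatives allowed)."""
    if treated.geometry != control.geometry:
        raise GeometryError("treated and control EEMs have different geometries")
    return ExcitationEmissionMatrix(
        geometry=treated.geometry,
        intensities=treated.intensities - control.intensities,
        sample_id=f"{treated.sample_id}-minus-{control.sample_id}",
        dose_min=treated.dose_min,
        replicate=treated.replicate,
        is_difference=True,
    )


def subtract_blank(
    eem: ExcitationEmissionMatrix, blank: ExcitationEmissionMatrix
) -> ExcitationEmissionMatrix:
    """Optional blank correction: subtract a medium-only well's EEM.

    The result is clipped at zero and remains an ordinary (non-difference)
    spectrum.  The pipeline default is raw spectra — blank correction is a
    protocol decision, offered as a hook.
    """
    if eem.geometry != blank.geometry:
        raise GeometryError("blank EEM geometry does not match the sample's")
    corrected = np.clip(eem.intensities - blank.intensities, 0.0, None)
    return ExcitationEmissionMatrix(
        geometry=eem.geometry,
        intensities=corrected,
        sample_id=eem.sample_id,
        dose_min=eem.dose_min,
        replicate=eem.replicate,
    )


@dataclass(frozen=True)
class SpectralRegion:
    """A rectangular λex × λem window, bounds inclusive on the grid."""

    label: str
    ex_lo: int
    ex_hi: int
    em_lo: int
    em_hi: int

    def __post_init__(self) -> None:
        if not (self.ex_lo < self.ex_hi and self.em_lo < self.em_hi):
            raise GeometryError(f"degenerate region bounds in {self.label!r}")


#: The three UV-responsive windows of the A375 difference spectra: the
#: aromatic-amino-acid region (fluorescence decreases with dose) and two
#: coenzyme/vitamin regions (fluorescence increases with dose).
DEFAULT_REGIONS: tuple[SpectralRegion, ...] = (
    SpectralRegion("amino-acid decrease", 250, 300, 300, 420),
    SpectralRegion("coenzyme increase A", 300, 340, 360, 460),
    SpectralRegion("coenzyme increase B", 340, 430, 420, 480),
)


def region_summary(
    diff: ExcitationEmissionMatrix,
    regions: Sequence[SpectralRegion] = DEFAULT_REGIONS,
) -> dict[str, float]:
    """Mean intensity change (AU) over the valid cells of each region.

    Linear in the input spectrum; requires ``diff.is_difference``.
    """
    if not diff.is_difference:
        raise DataIntegrityError("region_summary expects a difference spectrum")
    mask = build_mask(diff.geometry)
    exs = diff.geometry.ex_wavelengths
    ems = diff.geometry.em_wavelengths
    out: dict[str, float] = {}
    for region in regions:
        in_ex = (exs >= region.ex_lo) & (exs <= region.ex_hi)
        in_em = (ems >= region.em_lo) & (ems <= region.em_hi)
        cells = mask.grid & np.outer(in_ex, in_em)
        if not cells.any():
            raise GeometryError(
                f"region {region.label!r} intersects no valid cell of the geometry"
            )
        out[region.label] = float(diff.intensities[cells].mean())
    return out
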