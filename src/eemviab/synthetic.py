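"""Synthetic UV-stress datasets with the statistical structure the
viability soft-sensor assumes.

The generator emulates a 96-well experiment in which a melanoma cell culture
is irradiated with UV for increasing durations, viability declines along a
Hill-type dose–response curve, and each well is characterized both by an
excitation–emission matrix and (in separate wells) by an MTT-style
colorimetric assay.  Endogenous-fluorophore signals are modelled as
separable 2-D Gaussian peaks whose amplitudes respond linearly to the loss
of viability; the six default peak centers are the fluorescence maxima of
unstressed cells (aromatic amino acids near 290/340 nm, coenzyme and
vitamin bands at longer wavelengths).

Two replicate-level noise sources are distinguished:

* *well-to-well biology* — each EEM well's spectra are driven by its own
  viability, drawn around the dose-response value with SD ``bio_sd_pct``.
  This is what gives per-dose EEM predictions a spread comparable to the
  MTT replicate spread, as observed in real plate data.
* *instrument noise* — additive and multiplicative Gaussian noise per cell.

An optional ``medium_mode="confound"`` adds a dose-dependent
medium-photodegradation signal in the same three spectral windows that the
cellular response occupies.  It phenomenologically reproduces the pitfall
of UV-exposed culture medium: a model trained on such data correlates with
dose even when the cells' own spectra carry no viability information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eem import AcquisitionGeometry, ExcitationEmissionMatrix, build_mask


@dataclass(frozen=True)
class FluorophorePeak:
    """A separable Gaussian fluorophore band with linear viability response.

    Amplitude at viability ``v`` (percent) is
    ``amplitude_100 * (1 + kappa * (100 - v) / 100)``, floored at zero:
    ``kappa < 0`` encodes a band that fades as cells die, ``kappa > 0`` one
    that brightens, ``kappa = 0`` an uninformative band.
    """

    label: str
    center_ex: float
    center_em: float
    sigma_ex: float = 20.0
    sigma_em: float = 25.0
    amplitude_100: float = 100.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_ex <= 0 or self.sigma_em <= 0:
            raise ValueError(f"peak {self.label!r}: sigmas must be positive")
        if self.amplitude_100 < 0:
            raise ValueError(f"peak {self.label!r}: amplitude_100 must be >= 0")

    def amplitude(self, viability: float) -> float:
        """Band amplitude (AU) at a given viability percentage."""
        return max(
            0.0, self.amplitude_100 * (1.0 + self.kappa * (100.0 - viability) / 100.0)
        )

    def surface(self, geometry: AcquisitionGeometry) -> np.ndarray:
        """Unit-amplitude Gaussian evaluated on the full λex × λem grid."""
        ex = geometry.ex_wavelengths[:, None].astype(float)
        em = geometry.em_wavelengths[None, :].astype(float)
        return np.exp(
            -((ex - self.center_ex) ** 2) / (2.0 * self.sigma_ex**2)
            - ((em - self.center_em) ** 2) / (2.0 * self.sigma_em**2)
        )


#: Control-cell fluorescence maxima with the UV response pattern of the
#: three dose-responsive windows: the amino-acid band decreases, two
#: coenzyme bands increase, three bands are uninformative.
DEFAULT_PEAKS: tuple[FluorophorePeak, ...] = (
    FluorophorePeak("aromatic amino acids", 290, 340, amplitude_100=100.0, kappa=-0.4),
    FluorophorePeak("NAD(P)H band", 360, 440, amplitude_100=100.0, kappa=+0.6),
    FluorophorePeak("flavin band A", 390, 500, amplitude_100=60.0, kappa=0.0),
    FluorophorePeak("porphyrin band A", 390, 590, amplitude_100=40.0, kappa=0.0),
    FluorophorePeak("flavin band B", 430, 520, amplitude_100=80.0, kappa=+0.6),
    FluorophorePeak("porphyrin band B", 430, 590, amplitude_100=40.0, kappa=0.0),
)

#: Medium-photodegradation components for the confound mode: signed
#: amplitudes reached at ``confound_ref_dose_min`` minutes of UV, placed in
#: the same three windows as the cellular response (photobleached medium
#: amino acids/vitamins, two photoproduct bands).
CONFOUND_COMPONENTS: tuple[tuple[FluorophorePeak, float], ...] = (
    (FluorophorePeak("medium photobleach", 280, 350, 25.0, 35.0, 15.0), -1.0),
    (FluorophorePeak("medium photoproduct A", 320, 410, 25.0, 30.0, 25.0), +1.0),
    (FluorophorePeak("medium photoproduct B", 385, 450, 30.0, 30.0, 25.0), +1.0),
)


@dataclass(frozen=True)
class DoseResponseParams:
    """Hill-type UV dose → viability curve, v(0) = 100%.

    ``v(t) = v_min + (100 - v_min) / (1 + (t / t50)^h)``.  Defaults place
    ~50% kill near 20 min and <25% viability at 40 min and beyond.
    """

    v_min: float = 15.0
    t50: float = 20.0
    h: float = 4.0

    def __post_init__(self) -> None:
        if not (0 <= self.v_min < 100):
            raise ValueError("v_min must lie in [0, 100)")
        if self.t50 <= 0 or self.h <= 0:
            raise ValueError("t50 and h must be positive")


def simulate_viability(dose_min: float, params: DoseResponseParams | None = None) -> float:
    """Deterministic true viability (%) after ``dose_min`` minutes of UV."""
    if dose_min < 0:
        raise ValueError(f"negative UV dose: {dose_min} min")
    p = params or DoseResponseParams()
    return p.v_min + (100.0 - p.v_min) / (1.0 + (dose_min / p.t50) ** p.h)


@dataclass(frozen=True)
class NoiseParams:
    """Instrument noise: additive SD (AU) and multiplicative relative SD."""

    sigma_add: float = 0.5  # 0.5% of the strongest default band
    sigma_rel: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma_add < 0 or self.sigma_rel < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one simulated experiment."""

    doses: tuple[float, ...] = (0, 10, 20, 40, 50, 60)
    n_eem_reps: int = 12
    n_mtt_reps: int = 6
    mtt_sd: float = 5.0
    bio_sd: float = 5.0
    seed: int = 0
    peaks: tuple[FluorophorePeak, ...] = DEFAULT_PEAKS
    dose_response: DoseResponseParams = field(default_factory=DoseResponseParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    medium_mode: str = "off"
    confound_ref_dose_min: float = 60.0
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)

    def __post_init__(self) -> None:
        if len(self.doses) == 0 or min(self.doses) < 0:
            raise ValueError("doses must be non-empty and non-negative")
        if self.n_eem_reps < 1:
            raise ValueError("n_eem_reps must be >= 1")
        if not (3 <= self.n_mtt_reps <= 9):
            raise ValueError(
                f"n_mtt_reps={self.n_mtt_reps} outside the plate design range [3, 9]"
            )
        if self.medium_mode not in ("off", "confound"):
            raise ValueError(f"unknown medium_mode {self.medium_mode!r}")
        if self.mtt_sd < 0 or self.bio_sd < 0:
            raise ValueError("replicate SDs must be non-negative")


def medium_surface(config: SyntheticConfig, dose_min: float) -> np.ndarray:
    """Dose-dependent medium contribution on the full grid (AU).

    Zero in ``medium_mode="off"`` (the medium-exchange protocol keeps the
    medium contribution constant and it is dropped); in ``"confound"`` mode
    a photodegradation signal scales linearly with dose.
    """
    grid = np.zeros(config.geometry.shape)
    if config.medium_mode == "confound":
        scale = dose_min / config.confound_ref_dose_min
        for peak, sign in CONFOUND_COMPONENTS:
            grid += sign * scale * peak.amplitude_100 * peak.surface(config.geometry)
    return grid


def simulate_eem(
    viability: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    *,
    dose_min: float = 0.0,
    sample_id: str = "",
    replicate: int = 0,
) -> ExcitationEmissionMatrix:
    """Draw one EEM for a well at the given viability.

    Intensity at each cell is the sum of the fluorophore bands at their
    viability-dependent amplitudes plus the medium term, perturbed by
    multiplicative and additive Gaussian noise and clipped at zero.
    Consumes and advances ``rng``; identical generator states give
    identical spectra.
    """
    if not (0.0 <= viability <= 100.0):
        raise ValueError(f"viability {viability}% outside [0, 100]")
    geometry = config.geometry
    clean = medium_surface(config, dose_min)
    for peak in config.peaks:
        amp = peak.amplitude(viability)
        if amp > 0:
            clean = clean + amp * peak.surface(geometry)
    noisy = clean * (1.0 + config.noise.sigma_rel * rng.standard_normal(geometry.shape))
    noisy = noisy + config.noise.sigma_add * rng.standard_normal(geometry.shape)
    noisy = np.clip(noisy, 0.0, None)
    noisy[~build_mask(geometry).grid] = np.nan
    return ExcitationEmissionMatrix(
        geometry=geometry,
        intensities=noisy,
        sample_id=sample_id,
        dose_min=dose_min,
        replicate=replicate,
    )


def simulate_mtt(
    viability: float, n: int, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """``n`` MTT replicate viabilities: Gaussian around the true value,
    truncated below at 0 (ratios above 100% are possible, as on real plates).

    ``n`` must lie in the plate design range [3, 9].
    """
    if not (3 <= n <= 9):
        raise ValueError(f"n={n} outside the MTT plate design range [3, 9]")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return np.clip(rng.normal(viability, sd, size=n), 0.0, None)


@dataclass
class SyntheticDataset:
    """All artifacts of one simulated experiment."""

    config: SyntheticConfig
    eems: list[ExcitationEmissionMatrix]
    true_viability: dict[float, float]
    mtt_table: pd.DataFrame  # columns: dose_min, replicate, viability_pct

    def mtt_values(self, dose_min: float) -> np.ndarray:
        sel = self.mtt_table["dose_min"] == dose_min
        return self.mtt_table.loc[sel, "viability_pct"].to_numpy()


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dose × replicate design, reproducibly from the seed.

    Per dose: the true viability from the dose–response curve, then
    ``n_eem_reps`` wells with per-well viabilities (SD ``bio_sd``, clipped
    to [0, 100]) and their EEMs, then ``n_mtt_reps`` MTT replicates.
    """
    rng = np.random.default_rng(config.seed)
    eems: list[ExcitationEmissionMatrix] = []
    true_viability: dict[float, float] = {}
    mtt_rows: list[dict] = []
    for dose in config.doses:
        v_true = simulate_viability(dose, config.dose_response)
        true_viability[dose] = v_true
        well_v = np.clip(
            rng.normal(v_true, config.bio_sd, size=config.n_eem_reps), 0.0, 100.0
        )
        for rep in range(config.n_eem_reps):
            eems.append(
                simulate_eem(
                    float(well_v[rep]),
                    config,
                    rng,
                    dose_min=dose,
                    sample_id=f"d{dose:g}-r{rep:02d}",
                    replicate=rep,
                )
            )
        mtt = simulate_mtt(v_true, config.n_mtt_reps, config.mtt_sd, rng)
        mtt_rows.extend(
            {"dose_min": dose, "replicate": r, "viability_pct": float(val)}
            for r, val in enumerate(mtt)
        )
    return SyntheticDataset(
        config=config,
        eems=eems,
        true_viability=true_viability,
        mtt_table=pd.DataFrame(mtt_rows, columns=["dose_min", "replicate", "viability_pct"]),
    )
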