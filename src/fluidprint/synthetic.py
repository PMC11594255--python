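"""Synthetic multi-class biofluid cohorts: concentrations and NMR spectra.

Real patient spectra from the motivating clinical setting are not publicly
deposited, so every downstream stage (bucketing, classification, screening,
enrichment) is exercised on simulated cohorts that reproduce the *structure*
of the data: three-class designs per biofluid, log-normal concentration
variability, Lorentzian peak spectra with additive noise, spot-urine
dilution, and water/EDTA artifact regions.

The simulator is first-class, tested code, not a fixture: its defaults are
the study conditions under which the pipeline's statistical behaviour
(null calibration, signal recovery) is asserted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BIOFLUIDS, CLASS_LABELS, MetaboliteTable, SampleMetadata, Spectrum, check_biofluid

# water hump common to all fluids; EDTA multiplets specific to plasma
WATER_REGION = (4.5, 5.5)
EDTA_REGIONS = ((3.04, 3.31), (3.59, 3.66))

DEFAULT_AXIS = (0.0, 10.0, 9000)
DEFAULT_LOG_SD = 0.25
DEFAULT_DILUTION_RANGE = (0.3, 3.0)


@dataclass
class MetaboliteDefinition:
    """A metabolite's multiplet pattern and typical concentration per fluid.

    ``peaks`` are (center_ppm, relative_intensity, linewidth_fwhm_ppm)
    triples; relative intensities are normalized to sum to 1 so that a
    concentration of c contributes total spectral area c.
    """

    name: str
    peaks: list[tuple[float, float, float]]
    base_concentration: dict[str, float]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"metabolite {self.name!r} has no peaks")
        rel_sum = sum(p[1] for p in self.peaks)
        if rel_sum <= 0:
            raise ValueError(f"metabolite {self.name!r} has non-positive total intensity")
        # normalize multiplet so rel intensities sum to 1
        self.peaks = [(float(c), float(r) / rel_sum, float(w)) for c, r, w in self.peaks]
        for c, r, w in self.peaks:
            if not 0.0 <= c <= 10.0:
                raise ValueError(f"{self.name}: peak center {c} ppm outside [0, 10]")
            if r < 0:
                raise ValueError(f"{self.name}: negative relative intensity")
            if w <= 0:
                raise ValueError(f"{self.name}: linewidth must be positive")
        for fluid, conc in self.base_concentration.items():
            check_biofluid(fluid)
            if conc <= 0:
                raise ValueError(f"{self.name}: base concentration in {fluid} must be > 0")


@dataclass
class CohortDesign:
    """Design of one synthetic cohort for a single biofluid.

    ``effect_sizes`` maps (class_label, metabolite_name) to a multiplicative
    fold-change on the base concentration; unlisted pairs default to 1.0
    (HEALTHY in particular). ``dilution_range`` only applies to urine and
    models spot-urine concentration variability as a global multiplicative
    factor on the whole sample.
    """

    biofluid: str
    n_per_class: dict[str, int]
    effect_sizes: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.05
    log_sd: float = DEFAULT_LOG_SD
    dilution_range: tuple[float, float] = DEFAULT_DILUTION_RANGE
    seed: int = 0
    axis: tuple[float, float, int] = DEFAULT_AXIS

    def __post_init__(self) -> None:
        check_biofluid(self.biofluid)
        for label, n in self.n_per_class.items():
            if label not in CLASS_LABELS:
                raise ValueError(f"unknown class label {label!r}")
            if n < 0:
                raise ValueError("class counts must be >= 0")
        for (label, met), fc in self.effect_sizes.items():
            if fc <= 0:
                raise ValueError(f"fold-change for ({label}, {met}) must be > 0")
        lo, hi = self.dilution_range
        if not (0 < lo <= hi):
            raise ValueError("dilution_range must satisfy 0 < min <= max")
        if self.noise_sd < 0 or self.log_sd < 0:
            raise ValueError("noise_sd and log_sd must be >= 0")


def _lorentzian(ppm: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area Lorentzian absorption lineshape."""
    gamma = fwhm / 2.0
    return (gamma / np.pi) / ((ppm - center) ** 2 + gamma**2)


def simulate_spectrum(
    concentrations: dict[str, float],
    library: list[MetaboliteDefinition],
    axis_spec: tuple[float, float, int] = DEFAULT_AXIS,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    sample_id: str = "sim",
    biofluid: str = "urine",
) -> Spectrum:
    """Render a spectrum from metabolite concentrations.

    Intensity(ppm) = sum_m conc_m * sum_peaks rel * L(ppm; center, fwhm) + eps,
    with L the unit-area Lorentzian and eps ~ N(0, noise_sd^2) i.i.d. per
    point. The axis is returned in the conventional decreasing-ppm display
    order. A peak center outside the axis raises a warning rather than being
    silently truncated.
    """
    by_name = {m.name: m for m in library}
    unknown = sorted(set(concentrations) - set(by_name))
    if unknown:
        raise KeyError(f"unknown metabolite name(s) in concentrations: {unknown}")
    lo, hi, n_points = axis_spec
    if n_points < 2:
        raise ValueError("axis needs at least 2 points")
    ppm = np.linspace(lo, hi, n_points)
    intensity = np.zeros(n_points)
    for name, conc in concentrations.items():
        if conc == 0:
            continue
        for center, rel, fwhm in by_name[name].peaks:
            if not (lo <= center <= hi):
                warnings.warn(
                    f"peak of {name!r} at {center} ppm lies outside the axis "
                    f"[{lo}, {hi}]; its signal is truncated",
                    stacklevel=2,
                )
            intensity += conc * rel * _lorentzian(ppm, center, fwhm)
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        intensity = intensity + gen.normal(0.0, noise_sd, n_points)
    return Spectrum(sample_id, biofluid, ppm[::-1], intensity[::-1])


def _tapered_lorentzian(
    ppm: np.ndarray, center: float, fwhm: float, region: tuple[float, float]
) -> np.ndarray:
    """Lorentzian confined to ``region`` by a raised-cosine window.

    Artifact signals are windowed to their nominal exclusion interval so
    bucket tables built with the standard exclusions are exactly invariant
    to artifact amplitude (no tail leakage into retained bins). A small
    guard band keeps the window clear of the interval endpoints, where bin
    integrals interpolate across the boundary grid points.
    """
    guard = 0.005
    lo, hi = region[0] + guard, region[1] - guard
    shape = _lorentzian(ppm, center, fwhm)
    window = np.zeros_like(ppm)
    inside = (ppm >= lo) & (ppm <= hi)
    window[inside] = 0.5 - 0.5 * np.cos(2 * np.pi * (ppm[inside] - lo) / (hi - lo))
    return shape * window


def inject_artifacts(
    spectrum: Spectrum, biofluid: str, rng: np.random.Generator | int | None = None
) -> Spectrum:
    """Add instrument/sample artifacts: a broad residual-water hump in
    4.5-5.5 ppm (all fluids) and sharp EDTA peaks inside 3.04-3.31 and
    3.59-3.66 ppm (plasma only). Amplitudes are randomized; the input
    spectrum is not modified.
    """
    check_biofluid(biofluid)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    asc = spectrum.ascending
    ppm, intensity = asc.ppm, asc.intensity.copy()
    scale = max(float(np.max(np.abs(intensity))), 1.0)
    water_amp = scale * gen.uniform(0.5, 2.0)
    intensity += water_amp * _tapered_lorentzian(ppm, 4.98, 0.4, WATER_REGION)
    if biofluid == "plasma":
        for (lo, hi), centers in zip(EDTA_REGIONS, ((3.12, 3.22), (3.61, 3.63))):
            amp = scale * gen.uniform(0.2, 1.0)
            for c in centers:
                intensity += amp * _tapered_lorentzian(ppm, c, 0.01, (lo, hi))
    out_ppm, out_int = ppm, intensity
    if spectrum.ppm[0] > spectrum.ppm[-1]:  # restore display order
        out_ppm, out_int = ppm[::-1], intensity[::-1]
    return Spectrum(spectrum.sample_id, spectrum.biofluid, out_ppm, out_int)


def generate_cohort(
    design: CohortDesign,
    library: list[MetaboliteDefinition],
    artifacts: bool = True,
) -> tuple[list[Spectrum], list[SampleMetadata], MetaboliteTable]:
    """Draw one cohort: spectra, metadata and the concentration table.

    Per-sample concentrations are log-normal around base x fold-change
    (sigma on the log scale = ``design.log_sd``). For urine, a global
    dilution factor drawn uniformly from ``dilution_range`` multiplies both
    the spectrum and the raw concentration table (creatinine included), so
    creatinine normalization downstream cancels it. Fully reproducible from
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    fluid = design.biofluid
    names = [m.name for m in library if fluid in m.base_concentration]
    if fluid == "urine" and "creatinine" not in names:
        raise ValueError("urine cohorts need a creatinine entry in the library")
    base = np.array([m.base_concentration[fluid] for m in library if fluid in m.base_concentration])

    spectra: list[Spectrum] = []
    metadata: list[SampleMetadata] = []
    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    counter = 0
    for label in CLASS_LABELS:
        n = design.n_per_class.get(label, 0)
        fold = np.array([design.effect_sizes.get((label, m), 1.0) for m in names])
        for _ in range(n):
            counter += 1
            sid = f"{fluid}_{label}_{counter:03d}"
            conc = base * fold * np.exp(rng.normal(0.0, design.log_sd, len(names)))
            dilution = 1.0
            if fluid == "urine":
                dilution = rng.uniform(*design.dilution_range)
            conc = conc * dilution
            spec = simulate_spectrum(
                dict(zip(names, conc)),
                library,
                axis_spec=design.axis,
                noise_sd=design.noise_sd,
                rng=rng,
                sample_id=sid,
                biofluid=fluid,
            )
            if artifacts:
                spec = inject_artifacts(spec, fluid, rng)
            spectra.append(spec)
            rows.append(conc)
            age = float(np.round(rng.uniform(0.5, 40.0), 2))
            sex = str(rng.choice(["female", "male"]))
            metadata.append(SampleMetadata(sid, label, fluid, age_years=age, sex=sex))
            sample_ids.append(sid)
    table = MetaboliteTable(
        sample_ids=sample_ids,
        metabolite_names=names,
        concentrations=np.vstack(rows) if rows else np.empty((0, len(names))),
        biofluid=fluid,
    )
    return spectra, metadata, table
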