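"""Shared domain containers for biofluid NMR fingerprinting.

A cohort is described by three mutually consistent objects: one
:class:`Spectrum` per sample, one :class:`SampleMetadata` row per sample,
and a :class:`MetaboliteTable` holding quantified concentrations
(samples x metabolites). Class labels follow the ICD-10 severity coding
used in 5q spinal muscular atrophy: ``G12.0`` (type I, severe) and
``G12.1`` (type II/III, mild to moderate), plus ``HEALTHY`` controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIOFLUIDS = ("urine", "plasma", "csf")
CLASS_LABELS = ("HEALTHY", "G12.0", "G12.1")


def check_biofluid(biofluid: str) -> str:
    if biofluid not in BIOFLUIDS:
        raise ValueError(f"unknown biofluid {biofluid!r}; expected one of {BIOFLUIDS}")
    return biofluid


@dataclass
class Spectrum:
    """One sample's 1D proton NMR spectrum.

    The ppm axis must be strictly monotone; the conventional NMR display
    order (decreasing ppm) is accepted alongside ascending axes. Intensity
    is on an arbitrary (urine, pre-scaling) or concentration-calibrated
    (plasma/CSF) scale.
    """

    sample_id: str
    biofluid: str
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        check_biofluid(self.biofluid)
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")

    @property
    def ascending(self) -> "Spectrum":
        """A view of the spectrum with an ascending ppm axis."""
        if self.ppm[0] < self.ppm[-1]:
            return self
        return Spectrum(self.sample_id, self.biofluid, self.ppm[::-1], self.intensity[::-1])

    def ppm_range(self) -> tuple[float, float]:
        return float(self.ppm.min()), float(self.ppm.max())


@dataclass
class SampleMetadata:
    sample_id: str
    class_label: str
    biofluid: str
    age_years: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        check_biofluid(self.biofluid)
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"unknown class label {self.class_label!r}; expected one of {CLASS_LABELS}"
            )
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")


@dataclass
class MetaboliteTable:
    """Quantified metabolite concentrations, samples x metabolites.

    Plasma/CSF values are absolute concentrations (mmol/L); urine values
    are raw (pre-normalization) mmol/L and must include a ``creatinine``
    column so concentrations can later be expressed per mol creatinine.
    """

    sample_ids: list[str]
    metabolite_names: list[str]
    concentrations: np.ndarray
    biofluid: str = "urine"

    def __post_init__(self) -> None:
        check_biofluid(self.biofluid)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        n, m = self.concentrations.shape
        if n != len(self.sample_ids) or m != len(self.metabolite_names):
            raise ValueError("concentration matrix shape does not match id/name lists")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids in metabolite table")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.biofluid == "urine":
            if "creatinine" not in self.metabolite_names:
                raise ValueError("urine metabolite tables must contain a creatinine column")
            crea = self.concentrations[:, self.metabolite_names.index("creatinine")]
            if np.any(crea <= 0):
                raise ValueError("urine creatinine must be positive for every sample")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.concentrations, index=self.sample_ids, columns=self.metabolite_names
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, biofluid: str) -> "MetaboliteTable":
        return cls(
            sample_ids=[str(i) for i in frame.index],
            metabolite_names=[str(c) for c in frame.columns],
            concentrations=frame.to_numpy(dtype=float),
            biofluid=biofluid,
        )


@dataclass
class BucketTable:
    """Samples x retained-spectral-bins feature matrix.

    Rows are samples in input order; columns are bin centers in ascending
    ppm order. ``config`` records the binning dialect that produced it.
    """

    sample_ids: list[str]
    bin_centers_ppm: np.ndarray
    values: np.ndarray
    config: "object" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.bin_centers_ppm = np.asarray(self.bin_centers_ppm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), self.bin_centers_ppm.size):
            raise ValueError("values shape does not match sample_ids x bin_centers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("bucket table contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bin_{c:.3f}" for c in self.bin_centers_ppm]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)
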