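"""Biofluid-specific spectral bucketing: scaling, binning, exclusions.

Each biofluid has its own dialect:

* urine — minimum-baseline scaling over 1.0-4.3 ppm (removes spot-urine
  dilution), 0.01-ppm bins over 0.8-9.0 ppm, water region 4.5-6.5 excluded;
* CSF — concentration scale (identity here), 0.02-ppm bins over
  0.8-4.55 ppm, 4.5-6.5 excluded;
* plasma — concentration scale, 0.01-ppm bins over 0.3-10 ppm, EDTA
  (3.04-3.31, 3.59-3.66) and water (4.5-5.5) excluded.

Bins are consecutive left-closed/right-open intervals on an ascending ppm
grid; a trailing partial interval is dropped. Bin values are trapezoidal
integrals of the intensity over the interval (grid-resolution-robust), and
any bin whose interval has nonzero-length overlap with an exclusion region
is removed. Columns are reported in ascending ppm order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import BucketTable, Spectrum, check_biofluid

_OVERLAP_TOL = 1e-9


@dataclass
class BinningConfig:
    biofluid: str
    bin_width_ppm: float
    range_ppm: tuple[float, float]
    exclusions: list[tuple[float, float]] = field(default_factory=list)
    scaling_mode: str = "absolute_concentration"  # or "min_baseline_region"
    scaling_region_ppm: tuple[float, float] | None = None
    baseline_percentile: float = 5.0

    def __post_init__(self) -> None:
        check_biofluid(self.biofluid)
        if self.bin_width_ppm <= 0:
            raise ValueError("bin_width_ppm must be > 0")
        lo, hi = self.range_ppm
        if not lo < hi:
            raise ValueError("range_ppm must satisfy low < high")
        for a, b in self.exclusions:
            if not a < b:
                raise ValueError(f"exclusion interval ({a}, {b}) is not well-ordered")
        if self.scaling_mode not in ("min_baseline_region", "absolute_concentration"):
            raise ValueError(f"unknown scaling_mode {self.scaling_mode!r}")
        if self.scaling_mode == "min_baseline_region" and self.scaling_region_ppm is None:
            raise ValueError("min_baseline_region scaling requires scaling_region_ppm")


def default_config(biofluid: str) -> BinningConfig:
    """The standard bucketing dialect for a biofluid (see module docstring)."""
    check_biofluid(biofluid)
    if biofluid == "urine":
        return BinningConfig(
            biofluid="urine",
            bin_width_ppm=0.01,
            range_ppm=(0.8, 9.0),
            exclusions=[(4.5, 6.5)],
            scaling_mode="min_baseline_region",
            scaling_region_ppm=(1.0, 4.3),
        )
    if biofluid == "csf":
        return BinningConfig(
            biofluid="csf",
            bin_width_ppm=0.02,
            range_ppm=(0.8, 4.55),
            exclusions=[(4.5, 6.5)],
            scaling_mode="absolute_concentration",
        )
    return BinningConfig(
        biofluid="plasma",
        bin_width_ppm=0.01,
        range_ppm=(0.3, 10.0),
        exclusions=[(3.04, 3.31), (3.59, 3.66), (4.5, 5.5)],
        scaling_mode="absolute_concentration",
    )


def scale_spectrum(spectrum: Spectrum, config: BinningConfig) -> Spectrum:
    """Apply the dialect's intensity scaling.

    ``min_baseline_region``: subtract the baseline floor (the
    ``baseline_percentile``-th percentile of intensity within the scaling
    region) from the whole spectrum, then divide by the integral of the
    floored signal over the scaling region, making that integral 1. Any
    global multiplicative dilution factor cancels exactly.

    ``absolute_concentration``: identity (spectra arrive on a calibrated
    concentration scale).
    """
    if config.scaling_mode == "absolute_concentration":
        return spectrum
    asc = spectrum.ascending
    lo, hi = config.scaling_region_ppm
    if asc.ppm[0] > lo + _OVERLAP_TOL or asc.ppm[-1] < hi - _OVERLAP_TOL:
        raise ValueError(
            f"spectrum {spectrum.sample_id!r} axis [{asc.ppm[0]:.3f}, {asc.ppm[-1]:.3f}] "
            f"does not cover scaling region ({lo}, {hi})"
        )
    mask = (asc.ppm >= lo) & (asc.ppm <= hi)
    floor = np.percentile(asc.intensity[mask], config.baseline_percentile)
    floored = asc.intensity - floor
    integral = float(np.trapezoid(floored[mask], asc.ppm[mask]))
    if integral <= 0:
        raise ValueError(f"degenerate scaling region for sample {spectrum.sample_id!r}")
    return Spectrum(spectrum.sample_id, spectrum.biofluid, spectrum.ppm, (spectrum.intensity - floor) / integral)


def _antiderivative_at(x: np.ndarray, y: np.ndarray, F: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Exact trapezoidal antiderivative (piecewise quadratic) at points q."""
    i = np.clip(np.searchsorted(x, q, side="right") - 1, 0, len(x) - 2)
    dq = q - x[i]
    slope = (y[i + 1] - y[i]) / (x[i + 1] - x[i])
    return F[i] + dq * y[i] + 0.5 * slope * dq * dq


def _bin_edges(config: BinningConfig) -> np.ndarray:
    lo, hi = config.range_ppm
    n_bins = int(np.floor((hi - lo) / config.bin_width_ppm + _OVERLAP_TOL))
    return lo + np.arange(n_bins + 1) * config.bin_width_ppm


def _retained_mask(edges: np.ndarray, exclusions: list[tuple[float, float]]) -> np.ndarray:
    left, right = edges[:-1], edges[1:]
    keep = np.ones(left.size, dtype=bool)
    for a, b in exclusions:
        overlap = np.minimum(right, b) - np.maximum(left, a)
        keep &= overlap <= _OVERLAP_TOL
    return keep


def bin_spectrum(spectrum: Spectrum, config: BinningConfig) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a (scaled) spectrum into the dialect's retained bins.

    Returns ascending bin centers and per-bin trapezoidal integrals. The
    sum of all raw bin values telescopes exactly to the integral over the
    binned range.
    """
    asc = spectrum.ascending
    x, y = asc.ppm, asc.intensity
    lo, hi = config.range_ppm
    gaps = []
    if x[0] > lo + _OVERLAP_TOL:
        gaps.append(f"[{lo:.4f}, {min(x[0], hi):.4f}]")
    if x[-1] < hi - _OVERLAP_TOL:
        gaps.append(f"[{max(x[-1], lo):.4f}, {hi:.4f}]")
    if gaps:
        raise ValueError(
            f"spectrum {spectrum.sample_id!r} axis does not cover the binning range; "
            f"missing {', '.join(gaps)}"
        )
    edges = _bin_edges(config)
    from scipy.integrate import cumulative_trapezoid

    F = np.concatenate([[0.0], cumulative_trapezoid(y, x)])
    Fe = _antiderivative_at(x, y, F, edges)
    values = np.diff(Fe)
    keep = _retained_mask(edges, config.exclusions)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers[keep], values[keep]


def build_bucket_table(spectra: list[Spectrum], config: BinningConfig) -> BucketTable:
    """Scale + bin a list of spectra into a samples x bins bucket table."""
    if not spectra:
        raise ValueError("no spectra given")
    fluids = {s.biofluid for s in spectra}
    if fluids != {config.biofluid}:
        raise ValueError(
            f"mixed or mismatched biofluids {sorted(fluids)} for a {config.biofluid!r} config"
        )
    rows, centers = [], None
    for spec in spectra:
        try:
            c, v = bin_spectrum(scale_spectrum(spec, config), config)
        except ValueError as exc:
            raise ValueError(f"sample {spec.sample_id!r}: {exc}") from exc
        if centers is None:
            centers = c
        rows.append(v)
    return BucketTable(
        sample_ids=[s.sample_id for s in spectra],
        bin_centers_ppm=centers,
        values=np.vstack(rows),
        config=replace(config),
    )
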