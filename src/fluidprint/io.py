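"""File formats: spectrum CSVs, cohort metadata, bucket tables, metabolite
tables, GMT pathway sets, and YAML cohort designs.

The spectrum exchange format is one two-column CSV (ppm, intensity) per
sample plus a cohort-level metadata CSV naming each spectrum file. Floats
are written with 17 significant digits so write -> read round-trips are
exact.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binning import BinningConfig
from .core import BucketTable, MetaboliteTable, SampleMetadata, Spectrum
from .enrichment import PathwayLibrary
from .synthetic import CohortDesign, MetaboliteDefinition

_FLOAT_FMT = "%.17g"


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ppm", "intensity"])
        for p, i in zip(spectrum.ppm, spectrum.intensity):
            w.writerow([_FLOAT_FMT % p, _FLOAT_FMT % i])


def read_spectrum(path: str | Path, sample_id: str, biofluid: str) -> Spectrum:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return Spectrum(sample_id, biofluid, data[:, 0], data[:, 1])


def write_cohort(
    directory: str | Path, spectra: list[Spectrum], metadata: list[SampleMetadata]
) -> Path:
    """Write per-sample spectrum CSVs plus a metadata manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    by_id = {s.sample_id: s for s in spectra}
    if len(by_id) != len(spectra):
        raise ValueError("duplicate sample_ids among spectra")
    for meta in metadata:
        spec = by_id.get(meta.sample_id)
        if spec is None:
            raise ValueError(f"no spectrum for sample {meta.sample_id!r}")
        fname = f"{meta.sample_id}.csv"
        write_spectrum(spec, directory / fname)
        rows.append(
            {
                "sample_id": meta.sample_id,
                "biofluid": meta.biofluid,
                "class_label": meta.class_label,
                "age_years": "" if meta.age_years is None else meta.age_years,
                "sex": meta.sex or "",
                "spectrum_file": fname,
            }
        )
    manifest = directory / "metadata.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_spectra(manifest: str | Path) -> tuple[list[Spectrum], list[SampleMetadata]]:
    """Read a cohort back from its metadata manifest."""
    manifest = Path(manifest)
    if manifest.is_dir():
        manifest = manifest / "metadata.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"metadata manifest not found: {manifest}")
    df = pd.read_csv(manifest, dtype={"sample_id": str})
    required = {"sample_id", "biofluid", "class_label", "spectrum_file"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{manifest}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_ids in manifest: {dupes}")
    spectra, metadata = [], []
    for idx, row in df.iterrows():
        spec_path = manifest.parent / str(row["spectrum_file"])
        if not spec_path.exists():
            raise FileNotFoundError(
                f"{manifest} line {idx + 2}: spectrum file not found: {spec_path}"
            )
        spectra.append(read_spectrum(spec_path, str(row["sample_id"]), str(row["biofluid"])))
        age = row.get("age_years")
        metadata.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                class_label=str(row["class_label"]),
                biofluid=str(row["biofluid"]),
                age_years=None if pd.isna(age) or age == "" else float(age),
                sex=None if pd.isna(row.get("sex")) else str(row.get("sex")) or None,
            )
        )
    return spectra, metadata


def write_bucket_table(table: BucketTable, path: str | Path) -> None:
    """Bucket CSV (first column sample_id, columns named bin_<center>) plus a
    JSON provenance sidecar holding the binning config."""
    path = Path(path)
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, float_format=_FLOAT_FMT)
    if table.config is not None:
        sidecar = path.with_suffix(path.suffix + ".config.json")
        sidecar.write_text(json.dumps(asdict(table.config), indent=2))


def read_bucket_table(path: str | Path) -> BucketTable:
    path = Path(path)
    df = pd.read_csv(path, index_col="sample_id", float_precision="round_trip")
    centers = np.array([float(c.removeprefix("bin_")) for c in df.columns])
    config = None
    sidecar = path.with_suffix(path.suffix + ".config.json")
    if sidecar.exists():
        config = BinningConfig(**{
            k: tuple(v) if isinstance(v, list) and k.endswith("ppm") and k != "bin_width_ppm"
            else ([tuple(e) for e in v] if k == "exclusions" else v)
            for k, v in json.loads(sidecar.read_text()).items()
        })
    return BucketTable([str(i) for i in df.index], centers, df.to_numpy(dtype=float), config)


def write_metabolite_table(table: MetaboliteTable, path: str | Path) -> None:
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_metabolite_table(path: str | Path, biofluid: str) -> MetaboliteTable:
    df = pd.read_csv(path, index_col="sample_id", float_precision="round_trip")
    return MetaboliteTable.from_frame(df, biofluid)


def read_gmt(path: str | Path) -> PathwayLibrary:
    """Parse a GMT file: tab-separated set name, description, then members."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path} line {lineno}: need name, description and >= 1 member")
        name, members = parts[0], [m for m in parts[2:] if m]
        if name in sets:
            raise ValueError(f"{path} line {lineno}: duplicate set name {name!r}")
        if not members:
            raise ValueError(f"{path} line {lineno}: set {name!r} has no members")
        sets[name] = members
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return PathwayLibrary(sets=sets, source_tag=str(path))


def write_gmt(library: PathwayLibrary, path: str | Path, description: str = "-") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in library.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def bundled_pathway_library() -> PathwayLibrary:
    """The packaged synthetic KEGG-style pathway fixture."""
    from importlib.resources import files

    gmt = files("fluidprint.data").joinpath("kegg_synthetic.gmt")
    sets: dict[str, list[str]] = {}
    for line in gmt.read_text().splitlines():
        if line.strip():
            parts = line.split("\t")
            sets[parts[0]] = [m for m in parts[2:] if m]
    return PathwayLibrary(sets=sets, source_tag="bundled kegg_synthetic.gmt")


def library_from_yaml(path: str | Path) -> list[MetaboliteDefinition]:
    """Metabolite library schema: list of {name, peaks: [[ppm, rel, fwhm]...],
    base_concentration: {fluid: mmol/L}}."""
    spec = yaml.safe_load(Path(path).read_text())
    return [
        MetaboliteDefinition(
            name=entry["name"],
            peaks=[tuple(p) for p in entry["peaks"]],
            base_concentration=dict(entry["base_concentration"]),
        )
        for entry in spec
    ]


_DESIGN_KEYS = {
    "biofluid", "n_per_class", "effect_sizes", "noise_sd", "log_sd",
    "dilution_range", "seed", "axis",
}


def design_from_yaml(path: str | Path) -> CohortDesign:
    """Cohort design schema: biofluid, n_per_class (label -> count),
    effect_sizes (label -> {metabolite -> fold}), noise_sd, log_sd,
    dilution_range, seed, axis. Unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    unknown = set(raw) - _DESIGN_KEYS
    if unknown:
        raise ValueError(f"unknown design keys: {sorted(unknown)}")
    effects = {}
    for label, per_met in (raw.get("effect_sizes") or {}).items():
        for met, fold in per_met.items():
            effects[(label, met)] = float(fold)
    kwargs = {k: raw[k] for k in raw if k not in ("effect_sizes",)}
    if "dilution_range" in kwargs:
        kwargs["dilution_range"] = tuple(kwargs["dilution_range"])
    if "axis" in kwargs:
        kwargs["axis"] = tuple(kwargs["axis"])
    return CohortDesign(effect_sizes=effects, **kwargs)
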