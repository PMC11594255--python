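"""Bundled 30-metabolite reference library and a demo cohort design.

Chemical-shift positions are literature-plausible values for common urinary,
plasma and CSF metabolites; they need not be spectroscopically exact for
bucket-level analysis, only mutually distinct and documented. Base
concentrations are order-of-magnitude typical values: urine entries are raw
mmol/L before creatinine normalization, plasma and CSF are mmol/L.

The demo effect sizes shift energy-metabolism and amino-acid metabolites
between the severity classes, mirroring the kind of contrast the pipeline
is meant to detect; their magnitudes are calibration knobs for the
synthetic benchmark, not estimates of a real disease effect.
"""

from __future__ import annotations

from .synthetic import CohortDesign, MetaboliteDefinition

# name, [(center_ppm, rel_intensity, fwhm_ppm)...], {fluid: base mmol/L}
_LIBRARY_SPEC = [
    ("creatinine", [(3.05, 0.6, 0.008), (4.06, 0.4, 0.008)], {"urine": 12.0, "plasma": 0.07, "csf": 0.05}),
    ("creatine", [(3.03, 0.6, 0.008), (3.93, 0.4, 0.008)], {"urine": 0.6, "plasma": 0.04, "csf": 0.03}),
    ("citrate", [(2.54, 0.5, 0.012), (2.66, 0.5, 0.012)], {"urine": 2.5, "plasma": 0.11, "csf": 0.16}),
    ("succinate", [(2.41, 1.0, 0.008)], {"urine": 0.06, "plasma": 0.02, "csf": 0.02}),
    ("fumarate", [(6.52, 1.0, 0.008)], {"urine": 0.005, "plasma": 0.002, "csf": 0.002}),
    ("2-oxoglutarate", [(2.44, 0.6, 0.01), (3.01, 0.4, 0.01)], {"urine": 0.3, "plasma": 0.01, "csf": 0.01}),
    ("malate", [(2.37, 0.4, 0.01), (2.68, 0.3, 0.01), (4.30, 0.3, 0.01)], {"urine": 0.02, "plasma": 0.005, "csf": 0.005}),
    ("lactate", [(1.33, 0.75, 0.008), (4.11, 0.25, 0.008)], {"urine": 0.1, "plasma": 1.5, "csf": 1.7}),
    ("pyruvate", [(2.36, 1.0, 0.008)], {"urine": 0.05, "plasma": 0.06, "csf": 0.1}),
    ("glucose", [(3.24, 0.2, 0.01), (3.40, 0.2, 0.01), (3.53, 0.2, 0.01), (3.72, 0.2, 0.01), (5.23, 0.2, 0.01)], {"urine": 0.3, "plasma": 5.0, "csf": 3.2}),
    ("alanine", [(1.48, 1.0, 0.008)], {"urine": 0.25, "plasma": 0.35, "csf": 0.03}),
    ("glutamine", [(2.14, 0.5, 0.012), (2.45, 0.5, 0.012)], {"urine": 0.4, "plasma": 0.55, "csf": 0.5}),
    ("glutamate", [(2.08, 0.5, 0.012), (2.34, 0.5, 0.012)], {"urine": 0.05, "plasma": 0.06, "csf": 0.01}),
    ("glycine", [(3.56, 1.0, 0.008)], {"urine": 1.0, "plasma": 0.25, "csf": 0.01}),
    ("serine", [(3.84, 0.6, 0.01), (3.96, 0.4, 0.01)], {"urine": 0.3, "plasma": 0.12, "csf": 0.03}),
    ("threonine", [(1.32, 0.5, 0.008), (4.25, 0.5, 0.01)], {"urine": 0.15, "plasma": 0.14, "csf": 0.03}),
    ("valine", [(0.98, 0.5, 0.008), (1.04, 0.5, 0.008)], {"urine": 0.04, "plasma": 0.22, "csf": 0.02}),
    ("leucine", [(0.95, 0.7, 0.008), (1.70, 0.3, 0.01)], {"urine": 0.04, "plasma": 0.12, "csf": 0.015}),
    ("isoleucine", [(0.93, 0.5, 0.008), (1.01, 0.5, 0.008)], {"urine": 0.02, "plasma": 0.06, "csf": 0.006}),
    ("phenylalanine", [(7.32, 0.4, 0.01), (7.37, 0.3, 0.01), (7.42, 0.3, 0.01)], {"urine": 0.08, "plasma": 0.06, "csf": 0.01}),
    ("tyrosine", [(6.89, 0.5, 0.01), (7.19, 0.5, 0.01)], {"urine": 0.12, "plasma": 0.06, "csf": 0.01}),
    ("tryptophan", [(7.28, 0.5, 0.01), (7.54, 0.5, 0.01)], {"urine": 0.05, "plasma": 0.05, "csf": 0.002}),
    ("histidine", [(7.07, 0.5, 0.01), (7.80, 0.5, 0.01)], {"urine": 0.5, "plasma": 0.08, "csf": 0.012}),
    ("taurine", [(3.26, 0.5, 0.01), (3.42, 0.5, 0.01)], {"urine": 0.7, "plasma": 0.05, "csf": 0.006}),
    ("betaine", [(3.27, 0.8, 0.008), (3.90, 0.2, 0.008)], {"urine": 0.3, "plasma": 0.04, "csf": 0.005}),
    ("trimethylamine-N-oxide", [(3.25, 1.0, 0.008)], {"urine": 1.2, "plasma": 0.03, "csf": 0.002}),
    ("hippurate", [(3.97, 0.3, 0.01), (7.55, 0.3, 0.012), (7.64, 0.2, 0.012), (7.83, 0.2, 0.012)], {"urine": 1.5, "plasma": 0.01, "csf": 0.001}),
    ("formate", [(8.46, 1.0, 0.008)], {"urine": 0.05, "plasma": 0.03, "csf": 0.03}),
    ("acetate", [(1.92, 1.0, 0.008)], {"urine": 0.07, "plasma": 0.04, "csf": 0.03}),
    ("3-hydroxybutyrate", [(1.20, 0.6, 0.008), (2.31, 0.2, 0.01), (2.40, 0.2, 0.01)], {"urine": 0.03, "plasma": 0.06, "csf": 0.04}),
]


def default_library() -> list[MetaboliteDefinition]:
    """The bundled 30-metabolite library (fresh copies, safe to mutate)."""
    return [
        MetaboliteDefinition(name, [tuple(p) for p in peaks], dict(base))
        for name, peaks, base in _LIBRARY_SPEC
    ]


# Energy/amino-acid shifts distinguishing the severe (G12.0) and mild
# (G12.1) classes in demo cohorts. Moderate fold-changes: detectable with
# class sizes in the tens, with substantial group overlap.
DEMO_EFFECT_SIZES: dict[tuple[str, str], float] = {
    ("G12.0", "creatine"): 2.2,
    ("G12.0", "citrate"): 0.55,
    ("G12.0", "glucose"): 1.5,
    ("G12.0", "alanine"): 1.6,
    ("G12.0", "glutamine"): 0.65,
    ("G12.0", "lactate"): 1.5,
    ("G12.1", "creatine"): 1.5,
    ("G12.1", "citrate"): 0.75,
    ("G12.1", "glucose"): 1.2,
    ("G12.1", "alanine"): 1.25,
    ("G12.1", "glutamine"): 0.85,
    ("G12.1", "lactate"): 1.2,
}


def demo_design(
    biofluid: str = "urine",
    n_per_class: dict[str, int] | None = None,
    seed: int = 0,
    **overrides,
) -> CohortDesign:
    """A ready-to-run three-class cohort design with the demo effect sizes."""
    return CohortDesign(
        biofluid=biofluid,
        n_per_class=n_per_class or {"HEALTHY": 30, "G12.0": 20, "G12.1": 25},
        effect_sizes=dict(DEMO_EFFECT_SIZES),
        seed=seed,
        **overrides,
    )
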