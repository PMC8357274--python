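"""The bundled default scenario: an inundated salt-flat mat.

The numbers encode the study system the package targets: a five-layer
(orange/green/brown/black/gray) mat about 6 mm thick under a 2.5-mm salt
crust, with two oxygenic photosynthesis zones near 2 and 4 mm depth after
inundation, sulfide supplied from below and consumed photosynthetically in
the 2-4 mm zone, PAR attenuated to 1% of the surface level about 3.5 mm
into the mat, ~1% spectrally flat light loss in the salt crust, a standing
sulfide pool around 0.2 mol m^-3, and sulfate reduction peaking near 7 mm
at the mat-sediment transition.  Pigment bands sit at the diagnostic
wavelengths (Chl-a 674 nm, phycocyanin 624 nm, BChl-c 745 nm, BChl-a
845/902 nm) at the depths where the corresponding phototrophs live.
"""

from __future__ import annotations

import numpy as np

from .profiles import RateDepthProfile
from .synthetic import MatScenario, PigmentBand, ZERO_FLUX

#: molecular diffusivities in m^2 s^-1 (D_Stot = 0.64 x D_O2)
D_O2 = 1.5e-9
D_STOT = 0.64 * D_O2


def default_scenario(seed: int = 0, noise: bool = False) -> MatScenario:
    """The bundled five-layer inundated-mat scenario.

    With ``noise=False`` (default) every generated output is exactly
    reproducible and analytic round trips are clean; ``noise=True``
    switches on realistic sensor/counting noise levels.
    """
    noise_sd = (
        {"O2": 2e-3, "Stot": 1e-3, "irradiance": 1e-4, "tracer": 0.05}
        if noise
        else {}
    )
    return MatScenario(
        # orange, green, brown, black, gray
        layer_boundaries_mm=[0.0, 1.0, 2.0, 3.2, 4.5, 6.0],
        true_rates={
            # mol m^-3 s^-1, production positive
            "O2_light": [-1.55e-4, 3.11e-4, 1.5e-4, -1.5e-4, 0.0],
            "O2_dark": [-1.2e-4, -2.0e-5, 0.0, 0.0, 0.0],
            "Stot_light": [0.0, 0.0, -2.0e-6, -1.0e-6, 2.0e-6],
        },
        diffusivity={"O2": D_O2, "Stot": D_STOT},
        boundary_conditions={
            "O2_light": (0.25, ZERO_FLUX),
            "O2_dark": (0.25, ZERO_FLUX),
            "Stot_light": (0.0, 0.4),
        },
        porosity=0.35,
        pigment_bands=(
            PigmentBand("chlorophyll_a_upper", 674.0, 10.0, 0.6, 1.3, 0.4),
            PigmentBand("chlorophyll_a_lower", 674.0, 10.0, 0.8, 2.3, 0.4),
            PigmentBand("phycocyanin", 624.0, 12.0, 0.5, 2.3, 0.5),
            PigmentBand("bacteriochlorophyll_a_845", 845.0, 15.0, 0.5, 3.5, 0.6),
            PigmentBand("bacteriochlorophyll_a_902", 902.0, 15.0, 0.35, 3.5, 0.6),
            PigmentBand("bacteriochlorophyll_c", 745.0, 12.0, 0.6, 4.5, 0.7),
        ),
        matrix_attenuation_per_mm=[1.05, 1.29, 1.43, 1.24, 1.15],
        salt_thickness_mm=2.5,
        salt_attenuation_per_mm=-float(np.log(0.99)) / 2.5,  # ~1% loss over the crust
        noise_sd=noise_sd,
        seed=seed,
    )


def default_true_srr(peak_rate: float = 5.0e-6) -> RateDepthProfile:
    """Ground-truth sulfate reduction rate profile peaking near 7 mm depth."""
    depth = np.array([0.0, 2.0, 4.5, 7.0, 11.0, 20.0, 30.0])
    rate = peak_rate * np.array([0.02, 0.05, 0.5, 1.0, 0.45, 0.15, 0.05])
    return RateDepthProfile(depth, rate, "SRR")


#: default community ground truth: taxon proportions per layer
DEFAULT_TAXON_PROFILES = {
    "orange": {
        "Nostocales_unclassified": 0.010,
        "Dactylococcopsis": 0.014,
        "Geitlerinema": 0.004,
        "Rhodovibrio": 0.15,
        "Salinibacter": 0.10,
        "Rhodothermaceae_unclassified": 0.23,
        "Desulfovermiculus": 0.005,
        "Ca_Chlorothrix": 0.02,
        "Halobacteriales": 0.20,
        "other": 0.267,
    },
    "green": {
        "Dactylococcopsis": 0.020,
        "Coleofasciculus": 0.011,
        "Rhodovibrio": 0.19,
        "Salinibacter": 0.10,
        "Rhodothermaceae_unclassified": 0.13,
        "Desulfovermiculus": 0.01,
        "Ca_Chlorothrix": 0.06,
        "Halobacteriales": 0.25,
        "other": 0.229,
    },
    "brown": {
        "Nostocales_unclassified": 0.0024,
        "Ca_Chlorothrix": 0.29,
        "Rhodovibrio": 0.10,
        "Desulfovermiculus": 0.04,
        "Marinilabiliaceae": 0.05,
        "Halobacteriales": 0.30,
        "other": 0.2176,
    },
    "black": {
        "Synechocystis": 0.0024,
        "Desulfovermiculus": 0.08,
        "Marinilabiliaceae": 0.13,
        "Halobacteriales": 0.56,
        "Ca_Chlorothrix": 0.01,
        "other": 0.2176,
    },
    "gray": {
        "Desulfovermiculus": 0.10,
        "Marinilabiliaceae": 0.10,
        "Halobacteriales": 0.45,
        "other": 0.35,
    },
}

#: total cell counts per g wet weight: upper three layers several-fold above
#: the lower two (microscopy ranges 1.2-1.6e10 vs 3.5-4.3e9)
DEFAULT_TOTAL_CELLS = {
    "orange": 1.6e10,
    "green": 1.4e10,
    "brown": 1.2e10,
    "black": 4.3e9,
    "gray": 3.5e9,
}

#: guild assignment for the default taxa
DEFAULT_GUILDS = {
    "Nostocales_unclassified": "cyanobacteria",
    "Dactylococcopsis": "cyanobacteria",
    "Geitlerinema": "cyanobacteria",
    "Coleofasciculus": "cyanobacteria",
    "Synechocystis": "cyanobacteria",
    "Desulfovermiculus": "SRB",
    "Ca_Chlorothrix": "SOB",
}
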