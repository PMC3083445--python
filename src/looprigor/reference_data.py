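"""Published screen of SFTI-FCQR residue-14 variants.

In-silico hydrogen-bond statistics (mean ± SEM over three replicate MD
trajectories of each variant in complex with KLK4) and the matching
in-vitro inhibition measurements, bundled so the join, ranking and
rigidity–potency correlation can be reproduced without re-running any
simulation or assay.  All concentrations in nM, KM in µM, rate constants
in s⁻¹ / M⁻¹s⁻¹, half-life in minutes.
"""

from __future__ import annotations

__all__ = [
    "HBOND_SCREEN",
    "MORRISON_KI_KLK4_NM",
    "IC50_KLK4_NM",
    "IC50_KLK14_NM",
    "REFERENCE_VARIANT",
    "COMPETITIVE_KI_ASP14_NM",
    "KM_FVQR_PNA_UM",
    "KOFF_ASN14_PER_S",
    "KON_ASN14_M1S1",
    "HALF_LIFE_LYS14_MIN",
    "ASSAY_ENZYME_NM",
    "ASSAY_SUBSTRATE_UM",
]

# variant -> (internal mean, internal SEM, intermolecular mean, intermolecular SEM)
HBOND_SCREEN: dict[str, tuple[float, float, float, float]] = {
    "SFTI-FCQR Asn14": (4.68, 0.086, 8.46, 0.10),
    "SFTI-FCQR Val14": (4.26, 0.14, 8.17, 0.18),
    "SFTI-FCQR Tyr14": (4.07, 0.24, 8.22, 0.30),
    "SFTI-FCQR Met14": (3.98, 0.12, 8.11, 0.20),
    "SFTI-FCQR Lys14": (3.91, 0.47, 8.11, 0.17),
    "SFTI-FCQR Phe14": (3.89, 0.15, 7.58, 0.08),
    "SFTI-FCQR Ile14": (3.85, 0.43, 7.30, 0.35),
    "SFTI-FCQR Asp14": (3.70, 0.11, 8.28, 0.19),
    "SFTI-FCQR Gly14": (3.67, 0.30, 7.86, 0.17),
    "SFTI-FCQR Pro14": (3.66, 0.43, 6.49, 0.23),
    "SFTI-FCQR Glu14": (3.59, 0.50, 7.83, 0.36),
    "SFTI-FCQR Arg14": (3.51, 0.51, 7.65, 0.04),
    "SFTI-FCQR Gln14": (3.36, 0.25, 7.52, 0.14),
    "SFTI-FCQR Leu14": (3.33, 0.26, 8.11, 0.17),
    "SFTI-FCQR Trp14": (3.12, 0.22, 7.92, 0.36),
    "SFTI-FCQR Thr14": (2.93, 0.093, 7.34, 0.06),
    "SFTI-FCQR Ala14": (2.89, 0.085, 7.25, 0.16),
    "SFTI-FCQR Ser14": (2.56, 0.048, 7.52, 0.10),
    "SFTI-FCQR His14": (2.28, 0.068, 8.07, 0.11),
}

# Morrison tight-binding Ki against KLK4 for the seven assayed variants (nM).
MORRISON_KI_KLK4_NM: dict[str, float] = {
    "SFTI-FCQR Asn14": 0.0386,
    "SFTI-FCQR Tyr14": 2.55,
    "SFTI-FCQR Lys14": 3.56,
    "SFTI-FCQR Asp14": 3.89,
    "SFTI-FCQR Gly14": 10.39,
    "SFTI-FCQR Ala14": 18.31,
    "SFTI-FCQR Ser14": 21.24,
}

IC50_KLK4_NM: dict[str, float] = {
    "SFTI-FCQR Asn14": 0.0635,
    "SFTI-FCQR Tyr14": 3.47,
    "SFTI-FCQR Lys14": 6.07,
    "SFTI-FCQR Asp14": 7.97,
    "SFTI-FCQR Gly14": 14.74,
    "SFTI-FCQR Ala14": 26.23,
    "SFTI-FCQR Ser14": 29.23,
}

IC50_KLK14_NM: dict[str, float] = {
    "SFTI-FCQR Asp14": 1506.0,
    "SFTI-FCQR Asn14": 251.0,
}

REFERENCE_VARIANT = "SFTI-FCQR Asp14"

# Competitive-model Ki of the first-generation inhibitor against KLK4 (nM).
COMPETITIVE_KI_ASP14_NM = 3.62

# Michaelis constant of the FVQR-pNA substrate for KLK4 (µM), held fixed
# in Morrison fits.
KM_FVQR_PNA_UM = 679.9

# Slow-binding kinetics of the optimised Asn14 variant against KLK4.
KOFF_ASN14_PER_S = 0.031
KON_ASN14_M1S1 = 8.03e8

# Degradation half-life of the Lys14 variant in the KLK4 assay (minutes).
HALF_LIFE_LYS14_MIN = 56.3

# Low-enzyme tight-binding assay design for the Asn14 variant.
ASSAY_ENZYME_NM = 0.15
ASSAY_SUBSTRATE_UM = 500.0
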