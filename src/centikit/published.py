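"""Published flutemetamol Centiloid conversion constants, loadable by name.

These are the reported direct SUVR -> CL conversion equations for the three
processing pipelines, and the linear corrections that put PMOD- and
FSL-derived Centiloids onto the standard SPM8-equivalent scale.  They were
derived from the original paired PiB / [18F]flutemetamol scans and cannot be
recomputed without those images; they ship here as reference constants.
"""

from __future__ import annotations

from .core import LinearMap

__all__ = [
    "CONVERSIONS",
    "STANDARDIZATIONS",
    "get_conversion",
    "get_standardization",
]

#: Direct flutemetamol SUVR -> Centiloid equations, per processing pipeline.
CONVERSIONS: dict[str, LinearMap] = {
    "spm8": LinearMap(121.42, -121.16),
    "pmod": LinearMap(115.24, -107.86),
    "fsl": LinearMap(120.32, -112.75),
}

#: Corrections reconciling pipeline CL with the standard SPM8 scale,
#: published as "0.997x + 0.146" (PMOD) and "0.997x + 0.159" (FSL).
STANDARDIZATIONS: dict[str, LinearMap] = {
    "pmod": LinearMap(0.997, 0.146),
    "fsl": LinearMap(0.997, 0.159),
}


def get_conversion(name: str) -> LinearMap:
    """Look up a published SUVR -> CL conversion by pipeline name."""
    key = name.lower()
    if key not in CONVERSIONS:
        raise KeyError(
            f"unknown conversion {name!r}; available: {sorted(CONVERSIONS)}"
        )
    return CONVERSIONS[key]


def get_standardization(name: str) -> LinearMap:
    """Look up a published pipeline -> SPM8-equivalent CL correction."""
    key = name.lower()
    if key not in STANDARDIZATIONS:
        raise KeyError(
            f"unknown standardization {name!r}; "
            f"available: {sorted(STANDARDIZATIONS)}"
        )
    return STANDARDIZATIONS[key]
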