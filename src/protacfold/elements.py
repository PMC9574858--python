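"""Element lookup tables: standard atomic weights and Bondi van der Waals radii.

Only elements that occur in small-molecule degraders (H, C, N, O, S, P,
halogens) are tabulated; unknown elements fall back to carbon-like values
with a logged warning so descriptor calculations stay defined.
"""

from __future__ import annotations

import logging

logger = logging.getLogger(__name__)

#: Standard atomic weights (amu), IUPAC conventional values.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
}

#: Bondi van der Waals radii (Å).
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

_FALLBACK_MASS = 12.011
_FALLBACK_RADIUS = 1.70


def atomic_mass(element: str) -> float:
    """Standard atomic weight of *element* in amu (carbon fallback)."""
    key = element.strip().upper()
    if key not in ATOMIC_MASSES:
        logger.warning("unknown element %r: using carbon-like mass", element)
        return _FALLBACK_MASS
    return ATOMIC_MASSES[key]


def vdw_radius(element: str, overrides: dict[str, float] | None = None) -> float:
    """Bondi van der Waals radius of *element* in Å.

    ``overrides`` maps element symbols (any case) to replacement radii.
    """
    key = element.strip().upper()
    if overrides:
        upper = {k.upper(): v for k, v in overrides.items()}
        if key in upper:
            return upper[key]
    if key not in BONDI_RADII:
        logger.warning("unknown element %r: using carbon-like radius", element)
        return _FALLBACK_RADIUS
    return BONDI_RADII[key]
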