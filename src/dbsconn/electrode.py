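"""Quadripolar DBS lead geometry and stimulation settings.

The lead is modelled as a rigid line of cylindrical contacts along a unit
``direction`` starting at the ``tip``.  Contact ``k`` (named C0..C3 from the
tip upward) is centred at::

    centre_k = tip + (tip_to_first_contact + k * (contact_length + gap)) * direction

Geometries live in a versioned YAML registry shipped with the package; the
only registered model is the Medtronic 3389 (four 1.5 mm contacts separated
by 0.5 mm edge gaps).  The centre of the distal contact is taken to sit half
a contact length (0.75 mm) above the tip, i.e. the contact is flush with the
tip; this is a geometry convention, not a vendor datum.

Stimulation is voltage-controlled monopolar cathodic.  Field models convert
the programmed voltage to an equivalent current source through a configurable
access impedance (default 1000 ohm), ``I = V / Z``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import yaml

__all__ = [
    "LeadModel",
    "LeadPlacement",
    "StimConfig",
    "LeadRegistryError",
    "build_lead",
    "available_leads",
    "contact_centers",
    "active_contact_centers",
    "DEFAULT_IMPEDANCE_OHM",
]

DEFAULT_IMPEDANCE_OHM = 1000.0

_UNIT_TOL = 1e-9


class LeadRegistryError(KeyError):
    """Requested lead model is not in the registry."""


@dataclass(frozen=True)
class LeadModel:
    name: str
    n_contacts: int
    contact_length_mm: float
    intercontact_gap_mm: float
    tip_to_first_contact_mm: float

    def __post_init__(self) -> None:
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")
        if min(self.contact_length_mm, self.intercontact_gap_mm) <= 0:
            raise ValueError("contact lengths and gaps must be positive")

    @property
    def center_spacing_mm(self) -> float:
        """Distance between adjacent contact centres."""
        return self.contact_length_mm + self.intercontact_gap_mm

    def contact_offsets_mm(self) -> np.ndarray:
        """Distance of each contact centre from the tip, C0 first."""
        k = np.arange(self.n_contacts)
        return self.tip_to_first_contact_mm + k * self.center_spacing_mm


@dataclass(frozen=True)
class LeadPlacement:
    """Where a lead sits in world space (tip position and insertion axis)."""

    tip: tuple[float, float, float]
    direction: tuple[float, float, float]
    hemisphere: str = "right"

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > _UNIT_TOL:
            raise ValueError(
                f"direction must be a unit vector (|d| = {np.linalg.norm(d):.12f})"
            )
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")


@dataclass(frozen=True)
class StimConfig:
    """Monopolar cathodic stimulation settings for one lead."""

    active_contacts: tuple[int, ...]
    amplitude_v: float
    frequency_hz: float = 60.0
    pulse_width_us: float = 90.0
    polarity: str = "monopolar_cathodic"

    def __post_init__(self) -> None:
        if self.amplitude_v < 0:
            raise ValueError("amplitude must be >= 0")
        if self.amplitude_v > 0 and len(self.active_contacts) == 0:
            raise ValueError("active_contacts must be nonempty when amplitude > 0")
        if any(c < 0 for c in self.active_contacts):
            raise ValueError("contact indices are 0-based and nonnegative")

    def current_a(self, impedance_ohm: float = DEFAULT_IMPEDANCE_OHM) -> float:
        """Equivalent source current per active contact, I = V / Z."""
        return self.amplitude_v / impedance_ohm


@lru_cache(maxsize=1)
def _registry() -> dict:
    text = (
        importlib.resources.files("dbsconn").joinpath("data/leads.yaml").read_text()
    )
    return yaml.safe_load(text)


def available_leads() -> tuple[str, ...]:
    return tuple(sorted(_registry()["leads"]))


def build_lead(name: str) -> LeadModel:
    """Look up a lead geometry by registry name (e.g. ``"medtronic3389"``)."""
    leads = _registry()["leads"]
    if name not in leads:
        raise LeadRegistryError(
            f"unknown lead {name!r}; registered: {sorted(leads)}"
        )
    entry = leads[name]
    return LeadModel(name=name, **entry)


def contact_centers(model: LeadModel, placement: LeadPlacement) -> np.ndarray:
    """World-mm centres of all contacts, shape (n_contacts, 3), C0 first."""
    tip = np.asarray(placement.tip, dtype=float)
    d = np.asarray(placement.direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > _UNIT_TOL:
        raise ValueError("placement direction is not unit-norm")
    return tip[None, :] + model.contact_offsets_mm()[:, None] * d[None, :]


def active_contact_centers(
    model: LeadModel, placement: LeadPlacement, stim: StimConfig
) -> np.ndarray:
    """Centres of the contacts driven by ``stim``, shape (n_active, 3)."""
    centers = contact_centers(model, placement)
    bad = [c for c in stim.active_contacts if c >= model.n_contacts]
    if bad:
        raise ValueError(f"active contacts {bad} beyond lead with {model.n_contacts}")
    return centers[list(stim.active_contacts)]
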