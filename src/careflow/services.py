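"""Service registry for the modelled mental-health system.

Ten services across care levels 2-5 are modelled:

* level 2 -- general practice (high- and low-intensity contacts),
* level 3 -- IAPT talking-therapy services (assessment, social prescribing,
  therapy),
* level 4 -- community mental-health provider (MHP) services (general,
  specialist, crisis, triage),
* level 5 -- specialist inpatient care.

Level 1 (broad community support) and level 6 services are outside the
modelled system.  ``EXIT`` is the absorbing "leaves the pathway" state used
in transition rows; it is not a service.
"""

from __future__ import annotations

SERVICE_LEVELS: dict[str, int] = {
    "L2_GP_high": 2,
    "L2_GP_low": 2,
    "L3_IAPT_assessment": 3,
    "L3_IAPT_social_prescribing": 3,
    "L3_IAPT_therapy": 3,
    "L4_MHP_general": 4,
    "L4_MHP_specialist": 4,
    "L4_MHP_crisis": 4,
    "L4_MHP_triage": 4,
    "L5_AWP_inpatient": 5,
}

#: Canonical service ordering used throughout the package.
SERVICES: tuple[str, ...] = tuple(SERVICE_LEVELS)

#: Absorbing exit state label used in transition rows and pathway graphs.
EXIT = "exit"

LEVELS: tuple[int, ...] = (2, 3, 4, 5)


def level_of(service_id: str) -> int:
    """Return the care level (2-5) of a service id.

    Raises
    ------
    KeyError
        If ``service_id`` is not one of the ten modelled services.
    """
    try:
        return SERVICE_LEVELS[service_id]
    except KeyError:
        raise KeyError(
            f"unknown service {service_id!r}; expected one of {sorted(SERVICE_LEVELS)}"
        ) from None


def check_service(service_id: str) -> str:
    """Validate a service id, returning it unchanged."""
    level_of(service_id)
    return service_id
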