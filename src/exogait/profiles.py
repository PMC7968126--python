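"""Participant characteristics for treadmill gait simulation.

A :class:`ParticipantProfile` carries the anthropometrics and walking
parameters that drive the synthetic gait generator and the mass
normalization of kinetic outcomes.  ``STUDY_COHORT`` is a seven-person
roster of ambulatory individuals with cerebral palsy (GMFCS I-III)
spanning mild to severe plantarflexor dysfunction, usable as realistic
simulation presets.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ParticipantProfile", "STUDY_COHORT"]

_GMFCS_LEVELS = ("I", "II", "III")


@dataclass(frozen=True)
class ParticipantProfile:
    """Anthropometrics and gait parameters for one participant.

    Parameters
    ----------
    id : str
        Participant label, e.g. ``"P1"``.
    age : float
        Age in years.
    sex : str
        ``"M"`` or ``"F"``.
    height_m : float
        Standing height in meters.
    mass_kg : float
        Body mass in kilograms; divides all kinetic outcomes.
    gmfcs : str
        Gross Motor Function Classification System level, ``I``-``III``
        (ambulatory range).
    walking_speed : float
        Preferred treadmill belt speed in m/s; fixed across conditions.
    gait_type : str
        Free-text description of the gait pattern.
    """

    id: str
    age: float
    sex: str
    height_m: float
    mass_kg: float
    gmfcs: str
    walking_speed: float
    gait_type: str = ""

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError(f"mass_kg must be positive, got {self.mass_kg}")
        if self.walking_speed <= 0:
            raise ValueError(
                f"walking_speed must be positive, got {self.walking_speed}"
            )
        if self.gmfcs not in _GMFCS_LEVELS:
            raise ValueError(
                f"gmfcs must be one of {_GMFCS_LEVELS}, got {self.gmfcs!r}"
            )
        if self.height_m <= 0:
            raise ValueError(f"height_m must be positive, got {self.height_m}")


#: Seven ambulatory participants with cerebral palsy (crouch gait with
#: varying plantarflexor dysfunction), used as simulation presets.
STUDY_COHORT: dict[str, ParticipantProfile] = {
    p.id: p
    for p in (
        ParticipantProfile("P1", 13, "M", 1.51, 43.8, "I", 1.00,
                           "Mild ankle PF dysfunction and bilateral crouch"),
        ParticipantProfile("P2", 31, "M", 1.70, 53.3, "II", 1.05,
                           "Moderate ankle PF dysfunction and bilateral crouch"),
        ParticipantProfile("P3", 9, "M", 1.37, 31.1, "I", 0.75,
                           "Mild ankle PF dysfunction and bilateral crouch"),
        ParticipantProfile("P4", 10, "M", 1.39, 38.5, "I", 0.85,
                           "Mild ankle PF dysfunction and bilateral crouch"),
        ParticipantProfile("P5", 23, "F", 1.47, 43.8, "III", 0.50,
                           "Severe ankle PF dysfunction and bilateral crouch"),
        ParticipantProfile("P6", 6, "M", 1.10, 17.2, "II", 0.65,
                           "Moderate ankle PF dysfunction and bilateral crouch"),
        ParticipantProfile("P7", 6, "M", 1.18, 17.6, "I", 0.85,
                           "Mild ankle PF dysfunction and right leg crouch"),
    )
}
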