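"""Canonical nested model ladder.

Six shipped specs reproduce the standard build-up for this analysis:

* ``null`` — items only (12 params)
* ``m1``   — + gender, alcohol-use main effects (14)
* ``m2``   — + gender x alcohol interaction (15)
* ``m3``   — + four personality scores (19)
* ``m4``   — m3 + gender x personality interactions (23)
* ``m5``   — m3 + alcohol x personality interactions (23)

Each model is compared against the most recent earlier model nested in it,
so m4 and m5 are both tested against m3 (m3 is nested in both; m4 and m5
are not nested in each other).
"""

from __future__ import annotations

from .eirm import ModelSpec
from .items import PERSONALITY_COVARIATES

NULL = ModelSpec("null")
M1 = ModelSpec("m1", person_terms=("gender_female", "alcohol_no"))
M2 = ModelSpec(
    "m2",
    person_terms=("gender_female", "alcohol_no"),
    person_interactions=(("gender_female", "alcohol_no"),),
)
M3 = ModelSpec(
    "m3",
    person_terms=("gender_female", "alcohol_no") + PERSONALITY_COVARIATES,
    person_interactions=(("gender_female", "alcohol_no"),),
)
M4 = ModelSpec(
    "m4",
    person_terms=M3.person_terms,
    person_interactions=M3.person_interactions
    + tuple(("gender_female", p) for p in PERSONALITY_COVARIATES),
)
M5 = ModelSpec(
    "m5",
    person_terms=M3.person_terms,
    person_interactions=M3.person_interactions
    + tuple(("alcohol_no", p) for p in PERSONALITY_COVARIATES),
)

LADDER: tuple[ModelSpec, ...] = (NULL, M1, M2, M3, M4, M5)

BY_NAME = {s.name: s for s in LADDER}


def get_spec(name: str) -> ModelSpec:
    try:
        return BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown spec {name!r}; shipped specs: {sorted(BY_NAME)}") from None
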