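"""Published accounting tables of the INTEROCC brain-tumor study.

The package cannot ship the individual-level INTEROCC data (not publicly
deposited), but the study's published *accounting* numbers — the exclusion
cascade and the sociodemographic margins of the included participants —
are reproducible arithmetic and serve as reference fixtures: a cohort
built to these counts must flow through the exclusion and summary
machinery to exactly the published totals and percentages.
"""

#: Participants with collected information, per status group.
EXCLUSION_INITIAL = {"glioma": 2054, "meningioma": 1924, "control": 5601}

#: Exclusions per ordered criterion (source info / education / chronology /
#: nonstandard-only / unknown occupation), per status group.
EXCLUSION_COUNTS = {
    "glioma": (137, 14, 47, 12, 25),
    "meningioma": (115, 7, 15, 20, 9),
    "control": (260, 11, 29, 32, 42),
}

#: Included participants after the cascade.
FINAL_COUNTS = {"glioma": 1819, "meningioma": 1758, "control": 5227}

#: Share of each group removed by the first criterion, as printed (percent).
SOURCE_EXCLUSION_PCT = {"glioma": 6.7, "meningioma": 6.0, "control": 4.6}

_AGE = ("<35", "35-39", "40-44", "45-49", "50-54", "55-59",
        "60-64", "65-69", "70+")
_COUNTRY = ("Australia", "Canada", "France", "Germany", "Israel",
            "NewZealand", "UK")
_EDU = ("high_school_or_less", "medium_technical", "university")


def _margins(age, sex, country, edu):
    return {
        "age_group": dict(zip(_AGE, age)),
        "sex": {"female": sex[0], "male": sex[1]},
        "region": dict(zip(_COUNTRY, country)),
        "education": dict(zip(_EDU, edu)),
    }


#: Sociodemographic margins of the included participants, per status group.
TABLE1_MARGINS = {
    "glioma": _margins(
        age=(200, 169, 204, 224, 324, 286, 180, 127, 105),
        sex=(715, 1104),
        country=(257, 154, 89, 346, 377, 60, 536),
        edu=(954, 351, 514),
    ),
    "meningioma": _margins(
        age=(76, 96, 163, 261, 354, 303, 174, 156, 175),
        sex=(1287, 471),
        country=(239, 90, 138, 364, 647, 48, 232),
        edu=(1040, 344, 374),
    ),
    "control": _margins(
        age=(401, 443, 604, 713, 930, 972, 488, 416, 260),
        sex=(2917, 2310),
        country=(633, 613, 456, 1478, 898, 136, 1013),
        edu=(2818, 978, 1431),
    ),
}
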