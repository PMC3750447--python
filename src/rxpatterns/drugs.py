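"""Drug-class taxonomy used throughout the pipeline.

Claims are coded at drug-class granularity (the level at which switch and
intensification targets are reported); the two index drugs keep their own
labels because the study design is drug-specific.
"""

EXENATIDE = "exenatide"
GLARGINE = "glargine"

INDEX_DRUGS = (EXENATIDE, GLARGINE)

#: Oral / non-insulin glucose-lowering classes.
ORAL_CLASSES = (
    "biguanide",
    "sulfonylurea",
    "thiazolidinedione",
    "meglitinide",
    "alpha_glucosidase_inhibitor",
    "fixed_dose_combination",
    "sitagliptin",
)

#: Insulin classes other than glargine.
OTHER_INSULIN_CLASSES = (
    "insulin_basal_other",
    "insulin_bolus",
    "insulin_premixed",
    "insulin_other",
)

#: All insulins, glargine included (pre-index use of any excludes a patient).
INSULIN_CLASSES = (GLARGINE,) + OTHER_INSULIN_CLASSES

OTHER_INJECTABLE_CLASSES = ("pramlintide",)

#: Every class counted as glucose-lowering by the modification rules.
GLUCOSE_LOWERING_CLASSES = frozenset(
    INDEX_DRUGS + ORAL_CLASSES + OTHER_INSULIN_CLASSES + OTHER_INJECTABLE_CLASSES
)

#: Pre-index fills of any of these exclude a patient (new-user washout).
WASHOUT_CLASSES = frozenset(("pramlintide", "sitagliptin", EXENATIDE) + INSULIN_CLASSES)

#: Non-glucose-lowering classes emitted by the simulator (baseline covariates
#: only; invisible to the modification rules).
BACKGROUND_CLASSES = (
    "antihyperlipidemic",
    "antihypertensive",
    "antidepressant",
    "glucocorticoid",
)

GLUCOCORTICOID = "glucocorticoid"


def is_glucose_lowering(drug_class: str) -> bool:
    return drug_class in GLUCOSE_LOWERING_CLASSES
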