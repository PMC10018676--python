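"""The six-class label vocabulary shared across the package.

Classes 1-3 are anatomy (LV/RV blood pools and myocardium); 4 and 5 are the
pathology classes (edema and infarction).  Native MyoPS label values are
remapped to this coding on ingest.
"""

BACKGROUND = 0
LV = 1
RV = 2
MYO = 3
EDEMA = 4
INFARCT = 5

NUM_CLASSES = 6

CLASS_NAMES = {
    BACKGROUND: "background",
    LV: "LV blood pool",
    RV: "RV blood pool",
    MYO: "myocardium",
    EDEMA: "edema",
    INFARCT: "infarction",
}

# native MyoPS-style label values -> package coding
MYOPS_REMAP = {0: BACKGROUND, 500: LV, 600: RV, 200: MYO, 1220: EDEMA, 2221: INFARCT}

# evaluation groupings: pathology alone, pathology union, and anatomy
EVAL_GROUPS = {
    "MI": (INFARCT,),
    "MI+ME": (EDEMA, INFARCT),
    "Myo": (MYO,),
    "LV": (LV,),
    "RV": (RV,),
}
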