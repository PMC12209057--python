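"""Charlson comorbidity index from ICD-10 codes.

Implements the Quan (2005) ICD-10 coding algorithm for the 17 Charlson
categories with the original category weights (1/2/3/6).  Severity
hierarchies are honoured: diabetes with chronic complication supersedes
uncomplicated diabetes, moderate/severe liver disease supersedes mild liver
disease, and metastatic solid tumour supersedes non-metastatic malignancy,
so a patient never scores a condition twice at two severities.

Codes are matched by prefix on normalised ICD-10 strings (upper case, dots
stripped), longest prefix first.
"""

from __future__ import annotations

from typing import Iterable

__all__ = ["CHARLSON_WEIGHTS", "assign_categories", "charlson_index"]


def _expand(letter: str, lo: int, hi: int) -> list[str]:
    return [f"{letter}{i:02d}" for i in range(lo, hi + 1)]


#: Quan-2005 ICD-10 prefixes per Charlson category.
QUAN_ICD10: dict[str, list[str]] = {
    "myocardial_infarction": ["I21", "I22", "I252"],
    "congestive_heart_failure": [
        "I099", "I110", "I130", "I132", "I255", "I420", "I425", "I426", "I427",
        "I428", "I429", "I43", "I50", "P290",
    ],
    "peripheral_vascular": [
        "I70", "I71", "I731", "I738", "I739", "I771", "I790", "I792", "K551",
        "K558", "K559", "Z958", "Z959",
    ],
    "cerebrovascular": ["G45", "G46", "H340"] + _expand("I", 60, 69),
    "dementia": ["F00", "F01", "F02", "F03", "F051", "G30", "G311"],
    "chronic_pulmonary": [
        "I278", "I279", "J684", "J701", "J703",
    ] + _expand("J", 40, 47) + _expand("J", 60, 67),
    "rheumatic": ["M05", "M06", "M315", "M32", "M33", "M34", "M351", "M353", "M360"],
    "peptic_ulcer": ["K25", "K26", "K27", "K28"],
    "mild_liver": [
        "B18", "K700", "K701", "K702", "K703", "K709", "K713", "K714", "K715",
        "K717", "K73", "K74", "K760", "K762", "K763", "K764", "K768", "K769", "Z944",
    ],
    # bare three-character parent codes (e.g. plain E11) score as uncomplicated;
    # the longest-prefix match lets fourth-digit complication codes override
    "diabetes_uncomplicated": ["E10", "E11", "E12", "E13", "E14"] + [
        f"E{b}{t}" for b in ("10", "11", "12", "13", "14") for t in ("0", "1", "6", "8", "9")
    ],
    "diabetes_complicated": [
        f"E{b}{t}" for b in ("10", "11", "12", "13", "14") for t in ("2", "3", "4", "5", "7")
    ],
    "hemiplegia": [
        "G041", "G114", "G801", "G802", "G81", "G82", "G830", "G831", "G832",
        "G833", "G834", "G839",
    ],
    "renal": [
        "I120", "I131", "N032", "N033", "N034", "N035", "N036", "N037", "N052",
        "N053", "N054", "N055", "N056", "N057", "N18", "N19", "N250", "Z490",
        "Z491", "Z492", "Z940", "Z992",
    ],
    "malignancy": (
        _expand("C", 0, 26) + _expand("C", 30, 34) + _expand("C", 37, 41) + ["C43"]
        + _expand("C", 45, 58) + _expand("C", 60, 76) + _expand("C", 81, 85)
        + ["C88", "C90", "C91", "C92", "C93", "C94", "C95", "C96", "C97"]
    ),
    "moderate_severe_liver": [
        "I850", "I859", "I864", "I982", "K704", "K711", "K721", "K729", "K765",
        "K766", "K767",
    ],
    "metastatic_tumour": ["C77", "C78", "C79", "C80"],
    "aids": ["B20", "B21", "B22", "B24"],
}

#: Original Charlson weights.
CHARLSON_WEIGHTS: dict[str, int] = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular": 1,
    "cerebrovascular": 1,
    "dementia": 1,
    "chronic_pulmonary": 1,
    "rheumatic": 1,
    "peptic_ulcer": 1,
    "mild_liver": 1,
    "diabetes_uncomplicated": 1,
    "diabetes_complicated": 2,
    "hemiplegia": 2,
    "renal": 2,
    "malignancy": 2,
    "moderate_severe_liver": 3,
    "metastatic_tumour": 6,
    "aids": 6,
}

#: (dominant, superseded) severity pairs — only the dominant one scores.
HIERARCHY: tuple[tuple[str, str], ...] = (
    ("diabetes_complicated", "diabetes_uncomplicated"),
    ("moderate_severe_liver", "mild_liver"),
    ("metastatic_tumour", "malignancy"),
)

# prefix → category lookup, keyed by prefix length for longest-match-first
_PREFIX_MAP: dict[str, str] = {}
for _cat, _prefixes in QUAN_ICD10.items():
    for _p in _prefixes:
        _PREFIX_MAP[_p] = _cat
_PREFIX_LENGTHS = sorted({len(p) for p in _PREFIX_MAP}, reverse=True)


def category_of(code: str) -> str | None:
    """Charlson category of a normalised ICD-10 code, or None."""
    for ln in _PREFIX_LENGTHS:
        cat = _PREFIX_MAP.get(code[:ln])
        if cat is not None:
            return cat
    return None


def assign_categories(codes: Iterable[str]) -> set[str]:
    """Distinct Charlson categories present among the codes, after hierarchy."""
    cats = {c for c in (category_of(code) for code in codes) if c is not None}
    for dominant, superseded in HIERARCHY:
        if dominant in cats:
            cats.discard(superseded)
    return cats


def charlson_index(codes: Iterable[str]) -> int:
    """Charlson comorbidity index score for one patient's ICD-10 codes."""
    return sum(CHARLSON_WEIGHTS[c] for c in assign_categories(codes))
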