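"""Published group-level cardiac structure/function summaries (mean, SD, n).

These printed group summaries serve two roles: as worked-example inputs for
the functional-index identities (SV = EDV - ESV, EF = SV/EDV, CO = SV x HR)
and as the default parameterization of the synthetic cohort generator.

Groups are a 2x2 factorial of surgery (sham vs. abdominal aortic banding,
"aab") and diet (standard chow vs. Western diet, "wd"), studied at 4, 9 and
14 weeks post-surgery.
"""

from __future__ import annotations

__all__ = [
    "GROUPS",
    "WEEKS",
    "GROUP_SUMMARIES",
    "GROUP_NS",
    "SELF_CONSISTENT_ROWS",
]

GROUPS: tuple[tuple[str, str], ...] = (
    ("sham", "chow"),
    ("sham", "wd"),
    ("aab", "chow"),
    ("aab", "wd"),
)

WEEKS: tuple[int, ...] = (4, 9, 14)

# Animals per group at each timepoint.
GROUP_NS: dict[int, dict[tuple[str, str], int]] = {
    4: {("sham", "chow"): 11, ("sham", "wd"): 8, ("aab", "chow"): 10, ("aab", "wd"): 8},
    9: {("sham", "chow"): 11, ("sham", "wd"): 9, ("aab", "chow"): 10, ("aab", "wd"): 8},
    14: {("sham", "chow"): 9, ("sham", "wd"): 6, ("aab", "chow"): 8, ("aab", "wd"): 6},
}

# measure -> (mean, sd) per week per (surgery, diet).
# Units: body_weight_g g; edv_ul/esv_ul/sv_ul uL; ef_pct %; hr_bpm beats/min;
# co_ml_min mL/min.
GROUP_SUMMARIES: dict[int, dict[tuple[str, str], dict[str, tuple[float, float]]]] = {
    4: {
        ("sham", "chow"): {
            "body_weight_g": (340, 20), "edv_ul": (550, 50), "esv_ul": (120, 20),
            "ef_pct": (78, 4), "sv_ul": (430, 50), "hr_bpm": (350, 20), "co_ml_min": (150, 20),
        },
        ("sham", "wd"): {
            "body_weight_g": (350, 20), "edv_ul": (570, 80), "esv_ul": (100, 30),
            "ef_pct": (83, 5), "sv_ul": (470, 50), "hr_bpm": (360, 40), "co_ml_min": (170, 20),
        },
        ("aab", "chow"): {
            "body_weight_g": (340, 20), "edv_ul": (620, 70), "esv_ul": (160, 40),
            "ef_pct": (74, 5), "sv_ul": (450, 60), "hr_bpm": (360, 30), "co_ml_min": (160, 20),
        },
        ("aab", "wd"): {
            "body_weight_g": (340, 20), "edv_ul": (610, 50), "esv_ul": (140, 20),
            "ef_pct": (77, 3), "sv_ul": (470, 50), "hr_bpm": (360, 30), "co_ml_min": (170, 20),
        },
    },
    9: {
        ("sham", "chow"): {
            "body_weight_g": (400, 30), "edv_ul": (640, 50), "esv_ul": (150, 20),
            "ef_pct": (76, 4), "sv_ul": (490, 60), "hr_bpm": (350, 40), "co_ml_min": (170, 30),
        },
        ("sham", "wd"): {
            "body_weight_g": (420, 30), "edv_ul": (660, 60), "esv_ul": (130, 30),
            "ef_pct": (81, 3), "sv_ul": (530, 40), "hr_bpm": (380, 30), "co_ml_min": (190, 30),
        },
        ("aab", "chow"): {
            "body_weight_g": (420, 20), "edv_ul": (660, 80), "esv_ul": (160, 30),
            "ef_pct": (75, 5), "sv_ul": (500, 80), "hr_bpm": (360, 30), "co_ml_min": (180, 30),
        },
        ("aab", "wd"): {
            "body_weight_g": (400, 40), "edv_ul": (710, 60), "esv_ul": (170, 30),
            "ef_pct": (77, 4), "sv_ul": (550, 60), "hr_bpm": (350, 40), "co_ml_min": (190, 30),
        },
    },
    14: {
        ("sham", "chow"): {
            "body_weight_g": (440, 30), "edv_ul": (640, 100), "esv_ul": (140, 30),
            "ef_pct": (78, 2), "sv_ul": (500, 70), "hr_bpm": (350, 30), "co_ml_min": (180, 20),
        },
        ("sham", "wd"): {
            "body_weight_g": (490, 40), "edv_ul": (760, 90), "esv_ul": (160, 40),
            "ef_pct": (79, 4), "sv_ul": (600, 70), "hr_bpm": (350, 30), "co_ml_min": (210, 20),
        },
        ("aab", "chow"): {
            "body_weight_g": (450, 30), "edv_ul": (740, 120), "esv_ul": (180, 50),
            "ef_pct": (75, 5), "sv_ul": (560, 110), "hr_bpm": (360, 40), "co_ml_min": (200, 30),
        },
        ("aab", "wd"): {
            "body_weight_g": (480, 40), "edv_ul": (730, 70), "esv_ul": (170, 20),
            "ef_pct": (77, 4), "sv_ul": (560, 70), "hr_bpm": (380, 30), "co_ml_min": (210, 30),
        },
    },
}

# Rows whose printed SV/EF/CO cells are exactly reproduced by recomputing from
# the printed group-mean EDV/ESV/HR (the remaining rows differ by one
# reporting unit because per-animal values were averaged before rounding).
SELF_CONSISTENT_ROWS: tuple[tuple[int, str, str], ...] = (
    (4, "sham", "chow"),
    (4, "aab", "wd"),
    (14, "sham", "chow"),
    (14, "sham", "wd"),
    (14, "aab", "wd"),
)
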