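"""Published reference measurements bundled as a worked dataset.

Morphometric readings from a time-lapse microscopy study of
*Phanerochaete chrysosporium* germinating and growing for 52 h on five
agar media: an agar-only control (A), non-fractionated *Miscanthus x
giganteus* (B), its hot-water-soluble fraction (C), the unwashed solid
fraction (D) and the washed solid fraction (E).  Values are as printed in
the study's summary tables (duplicate-culture averages): mean object
areas and object counts over the countable period, germination
percentages and rates, fitted growth rates, and final occupied areas.

These tables are the canonical input for the reproduction analyses in
:mod:`mycometry.growthstats` (reconstructing per-frame total occupied
area as mean object area x object count, refitting the exponential
rates, recomputing coalescence percentages and the fraction-additivity
sums) and for the worked example in the README.
"""

from __future__ import annotations

CULTURES = ("A", "B", "C", "D", "E")

#: Observation times of the full series (hours).
FRAME_TIMES_H = (0.0, 23.0, 26.0, 29.0, 46.5, 49.5, 52.0)

#: Times at which individual objects were still countable (hours).
COUNT_TIMES_H = (0.0, 23.0, 26.0, 29.0)

#: Mean area of counted objects (um^2) at 0/23/26/29 h.
MEAN_OBJECT_AREA_UM2 = {
    "A": (5.64e2, 1.76e3, 3.23e3, 6.35e3),
    "B": (5.20e2, 4.39e3, 1.24e4, 7.48e4),
    "C": (6.64e2, 3.65e3, 1.26e4, 1.27e5),
    "D": (5.83e2, 3.10e3, 8.12e3, 2.04e4),
    "E": (6.48e2, 1.53e3, 4.42e3, 8.11e3),
}

#: Number of counted objects at 0/23/26/29 h.
OBJECT_COUNTS = {
    "A": (715, 680, 645, 605),
    "B": (687, 627, 485, 209),
    "C": (648, 588, 472, 120),
    "D": (660, 598, 533, 424),
    "E": (645, 628, 601, 524),
}

#: Mean area of all time-0 objects (resting spores), um^2.
SPORE_AREA_UM2 = 560.0

#: Germination percentage at 23/26/29 h.
GERMINATION_PCT = {
    "A": (17, 64, 89),
    "B": (78, 90, 94),
    "C": (66, 90, 96),
    "D": (64, 93, 97),
    "E": (14, 72, 81),
}

#: Printed germination rates (spores/h) for the intervals
#: 0-23, 23-26 and 26-29 h.
GERMINATION_RATE_SPORES_PER_H = {
    "A": (5, 110, 60),
    "B": (23, 28, 11),
    "C": (19, 51, 13),
    "D": (18, 65, 7),
    "E": (4, 126, 18),
}

#: Printed percentage of objects remaining at 29 h (coalescence).
PCT_OBJECTS_REMAINING_29H = {"A": 85, "B": 30, "C": 18, "D": 60, "E": 80}

#: Fitted occupied-area growth rates: mu1 over 23-29 h and mu2 over
#: 29-52 h (1/h), with the R^2 of each log-linear regression.
MU1_PER_H = {"A": 0.195, "B": 0.290, "C": 0.326, "D": 0.257, "E": 0.248}
MU1_R2 = {"A": 0.999, "B": 0.997, "C": 0.999, "D": 0.997, "E": 0.957}
MU2_PER_H = {"A": 0.101, "B": 0.134, "C": 0.124, "D": 0.121, "E": 0.133}
MU2_R2 = {"A": 0.999, "B": 0.995, "C": 0.996, "D": 0.998, "E": 0.989}

#: Radial expansion speed v (um/h) over 29-52 h and its R^2.
V_UM_PER_H = {"A": 64, "B": 585, "C": 502, "D": 398, "E": 312}
V_R2 = {"A": 0.7, "B": 0.98, "C": 0.99, "D": 0.93, "E": 0.96}

#: Final occupied area at 52 h (um^2) for the two reference cultures.
FINAL_AREA_UM2 = {"A": 3.9e7, "B": 3.2e8}

#: Duplicate-average occupied area at 52 h for culture B, with the
#: single-standard-deviation spread.
FINAL_AREA_B_MEAN_SD_UM2 = (3.0e8, 0.2e8)

#: Control-subtracted occupied areas at 52 h (um^2), as printed, and the
#: pairwise sums testing substrate-fraction additivity.
ADDITIVITY_MINUS_CONTROL_UM2 = {"B": 2.6e8, "C": 1.8e8, "D": 1.0e8, "E": 0.4e8}
ADDITIVITY_SUMS_UM2 = {"(C-A)+(D-A)": 2.8e8, "(C-A)+(E-A)": 2.3e8}


def reconstructed_total_area_um2(culture: str) -> list[float]:
    """Per-frame total occupied area reconstructed as mean object area
    times object count, for the countable times 0/23/26/29 h."""
    return [
        a * n
        for a, n in zip(MEAN_OBJECT_AREA_UM2[culture], OBJECT_COUNTS[culture])
    ]
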