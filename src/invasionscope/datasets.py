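"""Bundled reference data.

Small published summary tables used as worked-example inputs; all other test
and example data are generated by :mod:`invasionscope.synthetic_data`.
"""

from __future__ import annotations

import numpy as np

from .genetic_distances import GroupDistanceMatrix

__all__ = ["carpophilus_coi_pdistance_table"]

_GROUPS = [
    "C. davidsoni",
    "C. dimidiatus",
    "C. truncatus",
    "C. hemipterus",
    "C. mutilatus",
    "C. nepos",
    "C. pilosellus",
    "C. zeaphilus",
]

# Lower-triangle mean between-group distances (percent) and the within-group
# diagonal (percent; NaN = not calculable, singleton group), as published for
# the COI barcode portion of eight Carpophilus species. Rows follow _GROUPS.
_BETWEEN = [
    [],
    [18.49],
    [17.36, 12.86],
    [15.13, 17.46, 15.61],
    [13.52, 16.19, 15.72, 16.43],
    [14.55, 16.01, 14.52, 13.99, 12.55],
    [15.28, 15.44, 13.36, 14.04, 14.90, 14.88],
    [10.33, 17.37, 15.00, 14.82, 12.85, 11.50, 14.72],
]
_BETWEEN_SE = [
    [],
    [0.014],
    [0.012, 0.013],
    [0.012, 0.014, 0.012],
    [0.013, 0.013, 0.013, 0.013],
    [0.014, 0.013, 0.014, 0.014, 0.014],
    [0.015, 0.013, 0.014, 0.014, 0.014, 0.012],
    [0.012, 0.014, 0.014, 0.014, 0.015, 0.015, 0.016],
]
_WITHIN = [0.75, 3.52, 0.62, 1.30, 1.02, 1.94, np.nan, 0.62]
_WITHIN_SE = [0.004, 0.006, 0.002, 0.002, 0.0003, 0.004, np.nan, 0.002]


def carpophilus_coi_pdistance_table() -> GroupDistanceMatrix:
    """Published uncorrected p-distance matrix for eight *Carpophilus* species.

    COI-barcode means in percent: 28 between-group entries (lower triangle)
    and 7 computable within-group diagonal entries (*C. pilosellus* is a
    singleton, hence not calculable).  SEs are reproduced exactly as printed
    in the source table; note they appear to be on the proportion scale while
    the distances are percentages — they are carried through verbatim, not
    rescaled.
    """
    k = len(_GROUPS)
    between = np.full((k, k), np.nan)
    between_se = np.full((k, k), np.nan)
    for i in range(k):
        for j, (v, se) in enumerate(zip(_BETWEEN[i], _BETWEEN_SE[i])):
            between[i, j] = between[j, i] = v
            between_se[i, j] = between_se[j, i] = se
    return GroupDistanceMatrix(
        group_names=list(_GROUPS),
        between=between,
        between_se=between_se,
        within=np.array(_WITHIN),
        within_se=np.array(_WITHIN_SE),
    )
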