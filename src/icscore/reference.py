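"""Published clinicopathological contingency tables for a 79-patient
resected-PDAC cohort, cross-tabulated against the whole-section immune
cell score groups (low 0–1 / moderate 2 / high 3–4).

These printed counts are the only part of the original cohort that is
reconstructible from the publication; they serve as a fixed input for
validating the chi-square association test against the published
p-values.  Rows are the covariate levels, columns the three ICS groups.
"""

from __future__ import annotations

import numpy as np

__all__ = ["COHORT_ASSOCIATION_TABLES", "PUBLISHED_P_VALUES"]

COHORT_ASSOCIATION_TABLES: dict[str, list[list[int]]] = {
    "sex": [[18, 10, 13],            # male
            [21, 12, 5]],            # female
    "tumour_t": [[2, 1, 2],          # T1b   (T1a row is all-zero and omitted)
                 [4, 8, 2],          # T1c
                 [21, 10, 12],       # T2
                 [12, 3, 2]],        # T3
    "node": [[20, 11, 5],            # N0
             [12, 9, 8],             # N1
             [7, 2, 5]],             # N2
    "stage": [[2, 4, 2],             # IA
              [10, 5, 2],            # IB
              [8, 2, 1],             # IIA
              [12, 9, 8],            # IIB
              [7, 2, 5]],            # III
    "perineural_invasion": [[22, 10, 10],   # negative
                            [17, 12, 8]],   # positive
    "resection": [[22, 15, 13],      # R0
                  [17, 7, 5]],       # R1
}

#: the p-values printed alongside the tables above, to 3 decimal places.
PUBLISHED_P_VALUES: dict[str, float] = {
    "sex": 0.145,
    "tumour_t": 0.096,
    "node": 0.361,
    "stage": 0.356,
    "perineural_invasion": 0.694,
    "resection": 0.441,
}


def association_table(variable: str) -> np.ndarray:
    return np.asarray(COHORT_ASSOCIATION_TABLES[variable], dtype=int)
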