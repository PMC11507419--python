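"""Published reference quantities from a four-year Shanghai cohort (2014-2017).

These are the estimates reported for 9091 older adults with chronic diseases
assessed annually by the Shanghai elderly-care unified needs assessment.  They
serve two purposes here: as the default ground truth of the synthetic cohort
generator, and as inputs for internal-consistency checks (the one-year
transition probability matrix must equal expm(Q) of the intensity matrix).
"""

from __future__ import annotations

import numpy as np

#: Off-diagonal transition intensities per year, keyed (from_state, to_state).
INTENSITIES: dict[tuple[int, int], float] = {
    (1, 2): 0.2764,
    (1, 3): 0.0003,
    (2, 1): 0.4731,
    (2, 3): 0.2226,
    (3, 1): 0.0068,
    (3, 2): 0.1204,
}

#: Reported one-year transition probability matrix (rows: from-state 1..3).
ONE_YEAR_PROBABILITY = np.array(
    [
        [0.8022, 0.1758, 0.0220],
        [0.3014, 0.5452, 0.1534],
        [0.0258, 0.0836, 0.8905],
    ]
)

#: Observed transition frequencies over consecutive annual assessment pairs.
TRANSITION_FREQUENCIES = np.array(
    [
        [6647, 1556, 176],
        [1484, 2538, 810],
        [118, 366, 3487],
    ]
)

#: Baseline distribution over states (no / mild / severe ADL disability).
BASELINE_STATE_PROBS = (0.512, 0.268, 0.220)

N_SUBJECTS = 9091

#: Baseline covariate marginals of the cohort.
AGE_MEAN = 77.87
AGE_SD = 9.22
AGE_MIN = 60.0
P_MALE = 0.416
P_HOME_BASED = 0.601
P_WITH_PENSIONS = 8627 / 9091
P_COMORBIDITY = 0.516
#: Education levels 1..5: illiteracy, primary, middle, high school, college+.
EDUCATION_COUNTS = (859, 2487, 2575, 2257, 913)
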