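"""Main-text model inputs: printed transition matrices, prices and utilities.

These are the published point inputs of the Belgian nabiximols add-on
cost-utility model: the on-treatment severity transition matrices for trial
cycles 1-5 (cycle 6 onward reuses cycle 5 in the base case), the
discontinuation schedule embedded in their row sums, the state utilities
mapped from trial quality-of-life questionnaires, and the drug's list price
and dose schedule.  Matrices are stored exactly as printed, i.e. with the
discontinuation probability multiplied in; use
:func:`sativex_severity_chain` for the conditional (row-stochastic) form.
"""

from __future__ import annotations

import numpy as np

from .markov import load_published_matrix
from .trial_data import UtilitySet

__all__ = [
    "PRINTED_SATIVEX_MATRICES",
    "DISCONTINUATION_BY_CYCLE",
    "STATE_UTILITIES",
    "PACK_PRICE_EUR",
    "VIALS_PER_PACK",
    "SPRAYS_PER_VIAL",
    "sativex_severity_chain",
    "discontinuation_for_cycle",
]

#: printed on-treatment matrices (rows mild/moderate/severe); rows sum to
#: 1 - discontinuation of the cycle
PRINTED_SATIVEX_MATRICES: dict[int, np.ndarray] = {
    1: np.array(
        [
            [0.219, 0.719, 0.062],
            [0.094, 0.734, 0.172],
            [0.100, 0.100, 0.800],
        ]
    ),
    2: np.array(
        [
            [0.769, 0.096, 0.096],
            [0.100, 0.731, 0.130],
            [0.048, 0.433, 0.481],
        ]
    ),
    3: np.array(
        [
            [0.962, 0.000, 0.000],
            [0.329, 0.633, 0.000],
            [0.000, 0.240, 0.721],
        ]
    ),
    4: np.array(
        [
            [0.962, 0.000, 0.000],
            [0.111, 0.851, 0.000],
            [0.000, 0.000, 0.962],
        ]
    ),
    5: np.array(
        [
            [0.844, 0.121, 0.000],
            [0.241, 0.724, 0.000],
            [0.000, 0.000, 0.965],
        ]
    ),
}

#: treatment discontinuation probability per trial cycle (cycle 5 value
#: persists for all later cycles)
DISCONTINUATION_BY_CYCLE: dict[int, float] = {1: 0.0, 2: 0.038, 3: 0.038, 4: 0.038, 5: 0.035}

#: mean utilities per severity state, mapped from trial SF-36 responses
STATE_UTILITIES = UtilitySet(u_mild=0.594, u_moderate=0.509, u_severe=0.499)

PACK_PRICE_EUR = 466.40
VIALS_PER_PACK = 3
SPRAYS_PER_VIAL = 90


def discontinuation_for_cycle(cycle: int) -> float:
    if cycle < 1:
        raise ValueError("cycle must be >= 1")
    return DISCONTINUATION_BY_CYCLE[min(cycle, 5)]


def sativex_severity_chain(cycle: int) -> np.ndarray:
    """Conditional on-treatment severity matrix for a cycle (6+ -> cycle 5)."""
    c = min(cycle, 5)
    return load_published_matrix(
        PRINTED_SATIVEX_MATRICES[c], discontinuation_for_cycle(c)
    )
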