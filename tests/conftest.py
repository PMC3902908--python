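"""Shared fixtures: synthetic stand-in candidate sets and oracle helpers.

The experimental candidate tables (probed UTR transcripts with in-line
probing fold labels) are not shipped; the fixtures below are *synthetic
stand-ins* built to the published operating characteristics of the cG/cC
thresholds, so they exercise the evaluation machinery at realistic operating
points without claiming to be the experimental data.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from g4context import EvalCandidate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def calibration_set() -> list[EvalCandidate]:
    """Synthetic stand-in calibration set: 12 candidates (6 folding, 6 not)
    whose cG/cC scores separate perfectly at 2.05 except for one non-folding
    candidate at the intermediate score 2.4 (100% sensitivity, 5/6 = 83.3%
    specificity at the sensitive threshold)."""
    folding = [2.9, 3.4, 3.9, 4.2, 5.1, 6.8]
    nonfolding = [0.6, 0.8, 1.2, 1.5, 1.9, 2.4]
    return [
        *(EvalCandidate(f"fold{i}", s, True) for i, s in enumerate(folding)),
        *(EvalCandidate(f"nonfold{i}", s, False) for i, s in enumerate(nonfolding)),
    ]


@pytest.fixture
def challenge_set() -> list[EvalCandidate]:
    """Synthetic stand-in challenge set: 14 candidates (6 folding, 8 not)
    arranged so the sensitive threshold (2.05) yields exactly 3 false
    positives and no false negatives, and the specific threshold (3.05)
    yields exactly 1 false positive and 1 false negative."""
    folding = [2.8, 4.5, 5.2, 7.3, 8.1, 3.2]
    nonfolding = [0.5, 0.9, 1.2, 1.6, 1.9, 2.4, 2.6, 3.6]
    return [
        *(EvalCandidate(f"fold{i}", s, True) for i, s in enumerate(folding)),
        *(EvalCandidate(f"nonfold{i}", s, False) for i, s in enumerate(nonfolding)),
    ]


#: Synthetic stand-in candidate with an intermediate cG/cC ratio of exactly
#: 2.40: a 4-track PG4 (tracks 5,5,4,4) whose flanks carry C-runs of lengths
#: 5,3,2,1 (cC = 500) and one distal G-track (cG = 1100 + 100 = 1200).
INTERMEDIATE_CANDIDATE = (
    "AUACCCCCAUAUCCCAUA"  # 5' flank: C5 + C3
    "GGGGGAGGGGGAUGGGGAGGGG"  # PG4 core: G5-A-G5-AU-G4-A-G4
    "AUAUCCAUAUAUAGGGAUCAU"  # 3' flank: C2, distal G3 (13 nt away), C1
)


@pytest.fixture
def intermediate_candidate() -> str:
    return INTERMEDIATE_CANDIDATE
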