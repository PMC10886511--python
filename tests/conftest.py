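"""Shared expensive fixtures: reduced-scale embodiment studies.

Three simulated culture days at 220 s per session (the protocol's 5 min
sessions, shortened to keep the suite fast).  Built once per test session
and shared by the acceptance checks and the loop-level property tests.
"""

import pytest

from biohybrid.classify import ClassifierConfig
from biohybrid.coherence import CoherenceConfig
from biohybrid.events import CWTConfig
from biohybrid.workflows import child_seeds, run_embodiment_day

N_DIV = 3
DURATION = 220.0
CWT = CWTConfig(n_freqs=16)
COH = CoherenceConfig()
BASE_SEED = 20240127


def _study(mode):
    seeds = child_seeds(BASE_SEED, N_DIV * 5)
    days = []
    for div in range(N_DIV):
        offset = 1 if mode == "CL" else 3
        days.append(run_embodiment_day(
            mode, div, seeds[div * 5],
            (seeds[div * 5 + offset], seeds[div * 5 + offset + 1]),
            duration=DURATION, cwt=CWT, coh=COH,
            clf=ClassifierConfig(seed=seeds[div * 5], n_runs=5),
        ))
    return days


@pytest.fixture(scope="session")
def cl_days():
    return _study("CL")


@pytest.fixture(scope="session")
def ad_days():
    return _study("AD")
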