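"""Independent oracles for the simulator tests.

The enumeration here deliberately avoids the binomial shortcut the
implementation uses: it walks every joint persist/detect outcome of every
deposited bird and accumulates the exact probability mass of each possible
collected count.
"""
from __future__ import annotations

import itertools
from collections import defaultdict


def exact_collection_pmf(deposits_by_lag, params) -> dict[int, float]:
    """Exact distribution of the collected count by brute-force enumeration.

    Feasible only for a handful of birds (4^birds joint outcomes).
    """
    bird_persistence = []
    for lag, n_birds in enumerate(deposits_by_lag):
        bird_persistence.extend([params.persistence[lag]] * n_birds)
    eff = params.searcher_efficiency
    pmf: dict[int, float] = defaultdict(float)
    outcomes = [(1, 1), (1, 0), (0, 1), (0, 0)]
    for joint in itertools.product(outcomes, repeat=len(bird_persistence)):
        prob = 1.0
        count = 0
        for (persists, detected), p in zip(joint, bird_persistence):
            prob *= (p if persists else 1.0 - p) * (eff if detected else 1.0 - eff)
            count += persists and detected
        pmf[count] += prob
    return dict(pmf)
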