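"""Independent brute-force oracles used to cross-check the implementation.

These stay deliberately naive — direct enumeration over every candidate —
so that they share no code path with the functions they verify.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def enumerate_alleles(counts: dict[int, int], fraction: float) -> int:
    """Allele count by literal enumeration against the modal count."""
    modal = max(counts.values())
    n = 0
    for c in counts.values():
        if c >= fraction * modal:
            n += 1
    return n


def miscalls_at_cutoff(scores, cutoff: float) -> int:
    """Mis-calls of the rule "MSI iff score >= cutoff" on labelled scores."""
    fn = sum(1 for s, lab in scores if lab == "MSI" and s < cutoff)
    fp = sum(1 for s, lab in scores if lab == "MSS" and s >= cutoff)
    return fn + fp


def exhaustive_min_miscalls(scores) -> int:
    """Minimum mis-calls over every distinguishable cutoff (2n+1 candidates)."""
    values = sorted({s for s, _ in scores})
    candidates = [values[0] - 1.0]
    candidates.extend(values)
    for a, b in zip(values, values[1:]):
        candidates.append((a + b) / 2.0)
    candidates.append(values[-1] + 1.0)
    return min(miscalls_at_cutoff(scores, c) for c in candidates)


def pair_counting_auc(scores) -> float:
    """AUC as the literal mean over all (MSI, MSS) pairs."""
    msi = [s for s, lab in scores if lab == "MSI"]
    mss = [s for s, lab in scores if lab == "MSS"]
    total = 0.0
    for a in msi:
        for b in mss:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(msi) * len(mss))


def exhaustive_best_panel(evaluate, locus_ids, k):
    """Best (objective, subset) over every size-k subset, via the supplied
    panel-evaluation function.  Verifies the search, not the evaluator."""
    best = None
    for combo in combinations(sorted(locus_ids), k):
        obj = evaluate(list(combo))
        key = (obj, combo)
        if best is None or key < best:
            best = key
    return best[0], best[1]


def random_score_instance(rng: np.random.Generator, n_max: int = 50):
    """A random labelled-score instance with both classes present."""
    n = int(rng.integers(2, n_max + 1))
    labels = ["MSI", "MSS"] + [
        "MSI" if rng.random() < 0.4 else "MSS" for _ in range(n - 2)
    ]
    # mix of continuous and tied, lattice-like scores
    if rng.random() < 0.5:
        scores = np.round(rng.random(n), 1)
    else:
        scores = rng.random(n)
    return list(zip(scores.tolist(), labels))
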