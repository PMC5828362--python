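"""Independent brute-force reference implementations used to check the
pipeline's vectorized/structured code paths.  Deliberately written with
the standard library only, enumerating everything explicitly."""

from __future__ import annotations

import itertools
import math
import statistics


def brute_force_neighbourhood(
    bg: dict[tuple[int, int], float], window: int
) -> dict[tuple[int, int], float]:
    """Median over the explicit window x window patch for every grid
    position of one block, truncated at edges, self-inclusive."""
    half = window // 2
    out = {}
    for (r, c) in bg:
        patch = []
        for dr in range(-half, half + 1):
            for dc in range(-half, half + 1):
                key = (r + dr, c + dc)
                if key in bg:
                    patch.append(bg[key])
        out[(r, c)] = statistics.median(patch)
    return out


def oracle_cv(values) -> float:
    mean = statistics.fmean(values)
    if mean <= 0:
        return math.inf
    if len(values) < 2:
        return 0.0
    return 100.0 * statistics.stdev(values) / mean


def brute_force_replicate_summary(
    values, cv_threshold: float, min_replicates: int = 2
):
    """Enumerate every admissible replica subset and apply the selection
    rule by exhaustion.

    Admissible subsets keep all unflagged values or drop exactly one.
    Returns (status, mean_or_None, excluded_unflagged_values) where
    status is one of "OK", "NOISY", "HIGH_CV".
    """
    clean = [v for v, flags in values if not set(flags)]
    if len(clean) < min_replicates:
        return "NOISY", None, []
    candidates = []
    for size in (len(clean), len(clean) - 1):
        if size < min_replicates:
            continue
        for combo in itertools.combinations(range(len(clean)), size):
            subset = [clean[i] for i in combo]
            cv = oracle_cv(subset)
            if cv <= cv_threshold:
                removed = [clean[i] for i in range(len(clean)) if i not in combo]
                candidates.append((len(removed), cv, -statistics.fmean(subset), subset, removed))
        if candidates:
            break  # prefer keeping everything over removing one
    if not candidates:
        return "HIGH_CV", None, []
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    _, _, _, subset, removed = candidates[0]
    return "OK", statistics.fmean(subset), removed
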