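"""Independent brute-force reference for the tiered specificity classifier.

Enumerates every candidate tissue and every allowed group exhaustively and
applies the documented precedence and tie-break rules, with no shortcuts.
Kept deliberately separate from the package implementation.
"""

import itertools
import math


def brute_force_classify(values, params):
    """Return (category, target_tissues_tuple, fold_score) for one gene."""
    tissues = list(values)
    n = len(tissues)
    fc, ac = params.fold_cutoff, params.abundance_cutoff
    v = {t: float(values[t]) for t in tissues}

    def fold(num, den):
        if den == 0:
            return math.inf if num > 0 else 0.0
        return num / den

    # tissue_enriched: every tissue tested against the max of the others
    enriched = []
    for t in tissues:
        others = [v[s] for s in tissues if s != t]
        if v[t] > 0 and v[t] >= ac and v[t] >= fc * max(others):
            enriched.append((-v[t], t))
    if enriched:
        _, t = min(enriched)
        others_max = max(v[s] for s in tissues if s != t)
        return "tissue_enriched", (t,), fold(v[t], others_max)

    # group_enriched: all groups of every allowed size; smallest size first,
    # then highest mean, then lexicographically smallest sorted label tuple
    best = None
    for k in range(params.group_min, params.group_max + 1):
        for combo in itertools.combinations(sorted(tissues), k):
            gmean = sum(v[t] for t in combo) / k
            out_max = max(v[s] for s in tissues if s not in combo)
            if gmean > 0 and gmean >= ac and gmean >= fc * out_max:
                key = (k, -gmean, tuple(sorted(combo)))
                if best is None or key < best[0]:
                    best = (key, tuple(sorted(combo)), fold(gmean, out_max))
        if best is not None:
            break
    if best is not None:
        return "group_enriched", best[1], best[2]

    # tissue_enhanced: every tissue against the mean of the others
    enhanced = []
    for t in tissues:
        others_mean = sum(v[s] for s in tissues if s != t) / (n - 1)
        if v[t] > 0 and v[t] >= ac and v[t] >= fc * others_mean:
            enhanced.append((-v[t], t, fold(v[t], others_mean)))
    if enhanced:
        _, t, f = min(enhanced)
        return "tissue_enhanced", (t,), f

    if max(v.values()) < ac:
        return "low_signal", (), 0.0
    return "not_specific", (), 0.0


def random_abundance_vector(rng, n_tissues):
    """A boundary-rich random per-tissue abundance map.

    Mixes log-normal values with planted zeros, exact ties and values pinned
    near the default cutoffs, so rule boundaries are exercised.
    """
    v = rng.lognormal(mean=2.5, sigma=1.2, size=n_tissues)
    zero_mask = rng.random(n_tissues) < 0.15
    v[zero_mask] = 0.0
    if rng.random() < 0.3:  # force exact ties
        i, j = rng.choice(n_tissues, size=2, replace=False)
        v[j] = v[i]
    if rng.random() < 0.3:  # pin a value at the abundance cutoff
        v[rng.integers(n_tissues)] = 10.0
    if rng.random() < 0.3:  # exact fold-of-two pair
        i, j = rng.choice(n_tissues, size=2, replace=False)
        v[j] = 2.0 * v[i]
    return {f"t{i:02d}": float(x) for i, x in enumerate(v)}
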