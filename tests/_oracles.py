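"""Independent oracles used by the tests.

These deliberately avoid the package's estimation code paths: the
haplotype-frequency MLE is found by direct search over the frequency
simplex, evaluating the observed-data multinomial likelihood by brute
enumeration of phase resolutions.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def _class_loglik(freqs: dict, counts: dict) -> float:
    """Multinomial log-likelihood of genotype-class counts.

    ``freqs`` maps haplotype tuples to frequencies; ``counts`` maps
    genotype classes (tuples of unordered allele pairs) to counts.  The
    class probability sums f_a*f_b over all ordered phase resolutions.
    """
    ll = 0.0
    for cls, n in counts.items():
        per_locus = []
        for a, b in cls:
            per_locus.append([(a, b)] if a == b else [(a, b), (b, a)])
        p = 0.0
        for combo in product(*per_locus):
            h1 = tuple(x[0] for x in combo)
            h2 = tuple(x[1] for x in combo)
            p += freqs.get(h1, 0.0) * freqs.get(h2, 0.0)
        if p <= 0:
            return -np.inf
        ll += n * np.log(p)
    return ll


def grid_mle_haplotype_freqs(
    haplotypes: list, counts: dict, coarse: float = 0.02, fine: float = 1e-3
) -> dict:
    """Haplotype-frequency MLE by coarse simplex grid + greedy refinement.

    Stage 1 scans every composition of the simplex at step *coarse*;
    stage 2 hill-climbs by moving probability mass between haplotype pairs,
    halving the step from *coarse* down to *fine*.  Deterministic and
    independent of any EM machinery.
    """
    k = len(haplotypes)
    steps = int(round(1.0 / coarse))

    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    best, best_ll = None, -np.inf
    for comp in compositions(steps, k):
        f = {h: c / steps for h, c in zip(haplotypes, comp)}
        ll = _class_loglik(f, counts)
        if ll > best_ll:
            best, best_ll = f, ll

    step = coarse
    f = dict(best)
    while step > fine / 2:
        improved = True
        while improved:
            improved = False
            for i in haplotypes:
                for j in haplotypes:
                    if i == j or f[j] < step:
                        continue
                    trial = dict(f)
                    trial[i] += step
                    trial[j] -= step
                    ll = _class_loglik(trial, counts)
                    if ll > best_ll + 1e-12:
                        f, best_ll = trial, ll
                        improved = True
        step /= 2.0
    return f
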