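"""Independent brute-force oracles used to validate the fast implementations."""

import numpy as np


def ehh_brute_force(H: np.ndarray, core: int, direction: str):
    """All-pairs EHH: for every extension site, count haplotype pairs whose
    strings are identical over all sites from the core through that site.

    Returns (site_indices, ehh_values); the convention value at distance 0
    (EHH = 1) is not included.
    """
    n, m = H.shape
    step = 1 if direction == "right" else -1
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    denom = len(pairs)
    sites, values = [], []
    j = core + step
    while 0 <= j < m:
        lo, hi = (core, j) if step == 1 else (j, core)
        ident = sum(
            1 for a, b in pairs if np.array_equal(H[a, lo : hi + 1], H[b, lo : hi + 1])
        )
        sites.append(j)
        values.append(ident / denom)
        j += step
    return sites, values
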