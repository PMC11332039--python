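"""Independent scalar transcription of the Weir & Cockerham (1984)
two-population variance components, used as the FST oracle.

Written directly from the published component definitions as plain
Python floats, one site at a time — deliberately separate from the
vectorized implementation it checks.
"""

from __future__ import annotations


def wc_components_oracle(genos1: list[int], genos2: list[int]):
    """(a, b, c) components from two lists of diploid dosages (0/1/2).

    Returns (a, b, c); theta_hat = a / (a + b + c).
    """
    r = 2
    n1, n2 = len(genos1), len(genos2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 diploids per population")
    p1 = sum(genos1) / (2 * n1)
    p2 = sum(genos2) / (2 * n2)
    h1 = sum(1 for g in genos1 if g == 1) / n1
    h2 = sum(1 for g in genos2 if g == 1) / n2

    nbar = (n1 + n2) / r
    # n_c: variance-corrected average sample size
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_theta_oracle(genos1: list[int], genos2: list[int]) -> float:
    a, b, c = wc_components_oracle(genos1, genos2)
    denom = a + b + c
    if denom == 0:
        raise ZeroDivisionError("undefined theta (a+b+c = 0)")
    return a / denom
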