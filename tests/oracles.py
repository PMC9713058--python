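"""Independent reference implementations used to check the package.

These are deliberately written as direct transcriptions of definitions
(hypergeometric enumeration; the published evidence-combination table as
one boolean expression per tier) and share no code with the implementation
they verify.
"""

from __future__ import annotations

from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p by enumerating all tables with fixed margins and
    summing point probabilities not exceeding the observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def point_prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = point_prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = point_prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def acmg_tier_oracle(codes: set[str]) -> str:
    """Five-tier call from one boolean expression per tier of the published
    combining table; evidence counts taken at default strengths."""
    pvs = int("PVS1" in codes)
    ps = sum(1 for c in codes if c.startswith("PS"))
    pm = sum(1 for c in codes if c.startswith("PM"))
    pp = sum(1 for c in codes if c.startswith("PP"))
    ba = int("BA1" in codes)
    bs = sum(1 for c in codes if c.startswith("BS"))
    bp = sum(1 for c in codes if c.startswith("BP"))

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and pm >= 1)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    pathogenic_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if pathogenic_side and benign_side:
        return "VUS"
    if pathogenic:
        return "pathogenic"
    if likely_pathogenic:
        return "likely_pathogenic"
    if benign:
        return "benign"
    if likely_benign:
        return "likely_benign"
    return "VUS"
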