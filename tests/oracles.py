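"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (exhaustive
enumeration, exact rational arithmetic) without touching the package's
own code paths.
"""

from fractions import Fraction
from math import comb

from endotrio.cohort import CHILD, FATHER, HET, HOM_ALT, HOM_REF, MISSING, MOTHER, variant_ids


def brute_force_ravs(cohort, maf_max=0.01, dscore_min=2):
    """Exhaustive per-gene scan for CH pairs and homozygotes.

    Returns {(trio_id, gene, kind), ...} by enumerating every pair of
    qualifying het sites per gene per proband and resolving each side's
    parental origin with plain if/else genotype logic.
    """
    vids = list(variant_ids(cohort.variants))
    found = set()
    autosomes = {str(c) for c in range(1, 23)}
    for ti in range(cohort.n_trios):
        trio_id = cohort.trios["trio_id"].iloc[ti]
        per_gene = {}
        for si in range(cohort.n_sites):
            v = cohort.variants.iloc[si]
            if str(v["chrom"]) not in autosomes or v["maf"] >= maf_max:
                continue
            qualifying = v["func_class"] == "LoF" or (
                v["func_class"] == "missense" and v["dscore"] >= dscore_min
            )
            if not qualifying:
                continue
            fa, mo, ch = cohort.gt[si, ti]
            if MISSING in (fa, mo, ch):
                continue
            fa_alt = fa in (HET, HOM_ALT)
            mo_alt = mo in (HET, HOM_ALT)
            if ch == HOM_ALT and fa_alt and mo_alt:
                found.add((trio_id, v["gene"], "homozygote"))
            elif ch == HET:
                if fa_alt and not mo_alt:
                    per_gene.setdefault(v["gene"], set()).add(("pat", si))
                elif mo_alt and not fa_alt:
                    per_gene.setdefault(v["gene"], set()).add(("mat", si))
        for gene, sites in per_gene.items():
            for o1, s1 in sites:
                for o2, s2 in sites:
                    if s1 < s2 and {o1, o2} == {"pat", "mat"}:
                        found.add((trio_id, gene, "CH"))
    return found


def fisher_two_sided_exact(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric tables with
    probability <= the observed table's, in exact rational arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    observed = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= observed:
            total += prob(x)
    return float(total)


def binomial_two_sided_exact(t, u):
    """Doubled-smaller-tail exact binomial p against 1/2, as a fraction."""
    n = t + u
    k_lo, k_hi = min(t, u), max(t, u)
    denom = Fraction(1, 2**n)
    lower = sum(comb(n, i) for i in range(0, k_lo + 1)) * denom
    upper = sum(comb(n, i) for i in range(k_hi, n + 1)) * denom
    return float(min(Fraction(1), 2 * min(lower, upper)))
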