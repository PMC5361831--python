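"""Group-wise transmission/disequilibrium test for rare variants.

Across all qualifying sites in a gene group (autosomal, MAF < 0.01,
LoF or missense with DScore >= 4 for the functional analysis), each
heterozygous parent contributes one informative transmission event:
T if the child received that parent's minor allele, U otherwise.
Pooled counts are tested against the 50:50 Mendelian expectation with
an exact two-sided binomial test (doubled smaller tail, capped at 1).
Synonymous variants run through the identical machinery as a negative
control; homozygous-alt parents are uninformative and skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CHILD, FATHER, HET, HOM_ALT, HOM_REF, MISSING, MOTHER, TrioCohort


class UntestableError(ValueError):
    """No informative transmissions were observed."""


@dataclass(frozen=True)
class TransmissionCounts:
    """Pooled transmitted / untransmitted minor-allele counts."""

    transmitted: int
    untransmitted: int
    group_name: str = ""
    variant_class: str = "functional"

    @property
    def total(self) -> int:
        return self.transmitted + self.untransmitted


def _class_mask(cohort: TrioCohort, variant_class: str, dscore_min: int) -> np.ndarray:
    v = cohort.variants
    if variant_class == "functional":
        return (
            (v["func_class"] == "LoF")
            | ((v["func_class"] == "missense") & (v["dscore"] >= dscore_min))
        ).to_numpy()
    if variant_class == "synonymous":
        return (v["func_class"] == "synonymous").to_numpy()
    raise ValueError(f"unknown variant class {variant_class!r}")


def count_transmissions(
    cohort: TrioCohort,
    genes: Sequence[str],
    maf_max: float = 0.01,
    dscore_min: int = 4,
    variant_class: str = "functional",
    group_name: str = "",
) -> TransmissionCounts:
    """Pool transmission events over all qualifying sites in a gene group.

    Per trio per site (any missing member skips the trio at that site):
    a het parent opposite a hom-ref parent transmits (T) iff the child
    carries the alt allele; with both parents het, the child genotype
    resolves the two events jointly (hom-ref child: U+2, het: T+1 U+1,
    hom-alt: T+2).  A het parent opposite a hom-alt parent transmits
    iff the child is hom-alt.  Mendelian-impossible configurations are
    skipped.  Each site counts once per group even if its gene carries
    several group annotations.
    """
    v = cohort.variants
    keep = (
        v["gene"].isin(set(genes)).to_numpy()
        & (v["maf"] < maf_max).to_numpy()
        & cohort.is_autosomal()
        & _class_mask(cohort, variant_class, dscore_min)
    )
    gt = cohort.gt[keep]
    fa, mo, ch = gt[:, :, FATHER], gt[:, :, MOTHER], gt[:, :, CHILD]
    ok = (fa != MISSING) & (mo != MISSING) & (ch != MISSING)

    t = np.zeros(fa.shape, dtype=np.int64)
    u = np.zeros(fa.shape, dtype=np.int64)

    # exactly one parent het, other hom-ref: child het => transmitted
    one_het = ((fa == HET) & (mo == HOM_REF)) | ((mo == HET) & (fa == HOM_REF))
    t += np.where(ok & one_het & (ch == HET), 1, 0)
    u += np.where(ok & one_het & (ch == HOM_REF), 1, 0)
    # (child hom-alt here is Mendelian-impossible: skipped)

    # one parent het, other hom-alt: hom-alt parent forced to transmit,
    # the het parent's event resolved by whether the child is hom-alt
    het_vs_hom = ((fa == HET) & (mo == HOM_ALT)) | ((mo == HET) & (fa == HOM_ALT))
    t += np.where(ok & het_vs_hom & (ch == HOM_ALT), 1, 0)
    u += np.where(ok & het_vs_hom & (ch == HET), 1, 0)

    # both parents het: two events resolved jointly by child genotype
    both_het = (fa == HET) & (mo == HET)
    t += np.where(ok & both_het & (ch == HOM_ALT), 2, 0)
    u += np.where(ok & both_het & (ch == HOM_REF), 2, 0)
    t += np.where(ok & both_het & (ch == HET), 1, 0)
    u += np.where(ok & both_het & (ch == HET), 1, 0)

    return TransmissionCounts(
        transmitted=int(t.sum()),
        untransmitted=int(u.sum()),
        group_name=group_name,
        variant_class=variant_class,
    )


def binomial_tdt(counts: TransmissionCounts | tuple[int, int]) -> float:
    """Exact two-sided binomial test of T:U against 0.5.

    p = min(1, 2 * min(P(X <= min(T,U)), P(X >= max(T,U)))) with
    X ~ Binomial(T+U, 1/2): the doubled smaller tail, capped at one.
    For the symmetric null this equals the minimum-likelihood two-sided
    p; e.g. T:U = 1:9 gives 22/1024 ≈ 0.021.
    """
    if isinstance(counts, tuple):
        counts = TransmissionCounts(*counts)
    n = counts.total
    if n == 0:
        raise UntestableError("no informative transmissions")
    k_lo = min(counts.transmitted, counts.untransmitted)
    k_hi = max(counts.transmitted, counts.untransmitted)
    lower = stats.binom.cdf(k_lo, n, 0.5)
    upper = stats.binom.sf(k_hi - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def gtdt(
    cohort: TrioCohort,
    genes: Sequence[str],
    maf_max: float = 0.01,
    dscore_min: int = 4,
    group_name: str = "",
) -> pd.DataFrame:
    """Functional and synonymous gTDT for one gene group, side by side.

    Returns a two-row frame (variant_class, transmitted, untransmitted,
    p); the synonymous row is the built-in negative control.  An
    untestable class reports NaN.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene group")
    rows = []
    for variant_class in ("functional", "synonymous"):
        counts = count_transmissions(
            cohort, genes, maf_max, dscore_min, variant_class, group_name
        )
        try:
            p = binomial_tdt(counts)
        except UntestableError:
            p = float("nan")
        rows.append(
            {
                "group": group_name,
                "variant_class": variant_class,
                "transmitted": counts.transmitted,
                "untransmitted": counts.untransmitted,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def read_gene_groups(path) -> dict[str, list[str]]:
    """Read a 2-column TSV (gene, group) into group -> member lists."""
    tbl = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in tbl.columns]
    tbl.columns = cols
    if "gene" not in cols or "group" not in cols:
        raise ValueError("gene-group file needs 'gene' and 'group' columns")
    return {g: sorted(sub["gene"].astype(str)) for g, sub in tbl.groupby("group")}
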