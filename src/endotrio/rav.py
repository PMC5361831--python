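"""Recessively acting variants: trio phasing, CH/homozygote calls, burden.

A recessively acting variant (RAV) genotype is either a compound
heterozygote — two rare functional heterozygotes in trans within one
gene, assigned to opposite parents by transmission phasing — or a rare
functional homozygote.  The X chromosome is excluded (compound-het
logic is inapplicable in hemizygous males).  Qualifying variants are
autosomal, MAF < 0.01, and LoF or missense with DScore >= 2 ("Mis-D2").

Per-gene association between carrier status and the High-/Normal-5HT
groups uses Fisher's exact test on proband-level carrier counts; genes
with odds ratio > 1 are the candidate risk set, OR < 1 the control set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CHILD, FATHER, HET, HOM_ALT, HOM_REF, MISSING, MOTHER, TrioCohort, variant_ids

logger = logging.getLogger(__name__)

# parental-origin codes from phase-by-transmission
NONE_, PATERNAL, MATERNAL, BOTH, AMBIGUOUS, INCONSISTENT = 0, 1, 2, 3, 4, 5
ORIGIN_NAMES = {
    NONE_: "none",
    PATERNAL: "paternal",
    MATERNAL: "maternal",
    BOTH: "both",
    AMBIGUOUS: "ambiguous",
    INCONSISTENT: "inconsistent",
}


def phase_by_transmission(cohort: TrioCohort) -> np.ndarray:
    """Assign each child alt allele a parental origin from trio genotypes.

    Returns an ``(n_sites, n_trios)`` integer array of origin codes.  A
    het child is phased when exactly one parent carries the alt allele;
    a hom-alt child received one allele from each parent (``both``)
    provided both carry it.  Both-parents-carrier het children, and any
    configuration with a missing member, are ``ambiguous``.  Mendelian
    impossibilities (e.g. hom-alt child with a hom-ref parent) are
    flagged ``inconsistent`` and excluded from CH support.
    """
    fa = cohort.gt[:, :, FATHER]
    mo = cohort.gt[:, :, MOTHER]
    ch = cohort.gt[:, :, CHILD]
    fa_alt = (fa == HET) | (fa == HOM_ALT)
    mo_alt = (mo == HET) | (mo == HOM_ALT)
    any_missing = (fa == MISSING) | (mo == MISSING) | (ch == MISSING)

    origin = np.full(fa.shape, NONE_, dtype=np.int8)
    het = ch == HET
    origin[het & fa_alt & ~mo_alt] = PATERNAL
    origin[het & mo_alt & ~fa_alt] = MATERNAL
    origin[het & fa_alt & mo_alt] = AMBIGUOUS
    origin[het & ~fa_alt & ~mo_alt] = INCONSISTENT  # de novo, not transmission

    hom = ch == HOM_ALT
    origin[hom & fa_alt & mo_alt] = BOTH
    origin[hom & ~(fa_alt & mo_alt)] = INCONSISTENT
    origin[any_missing] = AMBIGUOUS
    return origin


@dataclass(frozen=True)
class RavCall:
    """A compound-het or homozygote RAV genotype in one proband."""

    proband_id: str
    trio_id: str
    gene: str
    kind: str  # "CH" | "homozygote"
    variant_ids: tuple[str, ...]
    origins: tuple[str, ...]


def qualifying_mask(
    cohort: TrioCohort,
    maf_max: float = 0.01,
    dscore_min: int = 2,
    classes: str = "functional",
) -> np.ndarray:
    """Site mask for RAV-qualifying variants.

    ``classes="functional"`` keeps LoF plus missense with
    DScore >= ``dscore_min``; ``classes="synonymous"`` applies the same
    MAF/autosome rules to synonymous variants (the baseline used for
    burden normalization).
    """
    v = cohort.variants
    rare = (v["maf"] < maf_max).to_numpy()
    auto = cohort.is_autosomal()
    if classes == "functional":
        cls = (
            (v["func_class"] == "LoF")
            | ((v["func_class"] == "missense") & (v["dscore"] >= dscore_min))
        ).to_numpy()
    elif classes == "synonymous":
        cls = (v["func_class"] == "synonymous").to_numpy()
    else:
        raise ValueError(f"unknown class filter {classes!r}")
    return rare & auto & cls


def detect_ravs(
    cohort: TrioCohort,
    maf_max: float = 0.01,
    dscore_min: int = 2,
    classes: str = "functional",
) -> list[RavCall]:
    """Call compound heterozygotes and rare homozygotes per proband.

    A gene emits one CH per proband when it carries at least one
    paternal-origin and one maternal-origin qualifying heterozygote
    (ambiguous-origin sites never support a CH; the reported pair is the
    genomically first qualifying variant of each origin).  A gene emits
    a homozygote call when the child is consistently hom-alt at a
    qualifying site.  At most one CH per gene per proband is counted.
    """
    keep = qualifying_mask(cohort, maf_max, dscore_min, classes)
    sub = cohort.subset_sites(keep)
    if sub.n_sites == 0:
        return []
    origin = phase_by_transmission(sub)
    vids = variant_ids(sub.variants)
    genes = sub.variants["gene"].to_numpy()

    calls: list[RavCall] = []
    for ti, tr in enumerate(cohort.trios.itertuples()):
        col = origin[:, ti]
        active = np.nonzero(col != NONE_)[0]
        per_gene: dict[str, dict[str, list[int]]] = {}
        for si in active:
            per_gene.setdefault(genes[si], {"pat": [], "mat": [], "hom": []})
            code = col[si]
            if code == PATERNAL:
                per_gene[genes[si]]["pat"].append(si)
            elif code == MATERNAL:
                per_gene[genes[si]]["mat"].append(si)
            elif code == BOTH:
                per_gene[genes[si]]["hom"].append(si)
        for gene in sorted(per_gene):
            d = per_gene[gene]
            if d["pat"] and d["mat"]:
                i, j = min(d["pat"]), min(d["mat"])
                calls.append(
                    RavCall(
                        proband_id=tr.child_id,
                        trio_id=tr.trio_id,
                        gene=gene,
                        kind="CH",
                        variant_ids=(vids[i], vids[j]),
                        origins=("paternal", "maternal"),
                    )
                )
            for si in d["hom"]:
                calls.append(
                    RavCall(
                        proband_id=tr.child_id,
                        trio_id=tr.trio_id,
                        gene=gene,
                        kind="homozygote",
                        variant_ids=(vids[si],),
                        origins=("both",),
                    )
                )
    calls.sort(key=lambda c: (c.trio_id, c.gene, c.kind))
    return calls


def rav_table(calls: list[RavCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "proband_id": c.proband_id,
                "trio_id": c.trio_id,
                "gene": c.gene,
                "kind": c.kind,
                "variants": ",".join(c.variant_ids),
                "origins": ",".join(c.origins),
            }
            for c in calls
        ],
        columns=["proband_id", "trio_id", "gene", "kind", "variants", "origins"],
    )


# ---------------------------------------------------------------------------
# burden, normalized by the synonymous baseline
# ---------------------------------------------------------------------------


def rav_variant_counts(
    cohort: TrioCohort, member: int, maf_max: float = 0.01, dscore_min: int = 2
) -> pd.DataFrame:
    """Per-individual rare-variant genotype counts, functional and synonymous.

    Counts qualifying variant genotypes (one per het, two per
    homozygote) for one trio member across all autosomal rare sites.
    Phase is unknowable for parents (no grandparental genotypes), so the
    same unphased counting rule is applied to every role and the
    functional:synonymous ratio stays like-for-like across roles.
    """
    out = {}
    for label, classes in (("functional", "functional"), ("synonymous", "synonymous")):
        keep = qualifying_mask(cohort, maf_max, dscore_min, classes)
        g = cohort.gt[keep][:, :, member]
        out[label] = ((g == HET).sum(axis=0) + 2 * (g == HOM_ALT).sum(axis=0)).astype(int)
    ids = {FATHER: "father_id", MOTHER: "mother_id", CHILD: "child_id"}[member]
    return pd.DataFrame(
        {
            "subject_id": cohort.trios[ids],
            "role": {FATHER: "father", MOTHER: "mother", CHILD: "proband"}[member],
            "functional": out["functional"],
            "synonymous": out["synonymous"],
        }
    )


def burden_normalized(
    cohort: TrioCohort, maf_max: float = 0.01, dscore_min: int = 2
) -> tuple[pd.DataFrame, float, float]:
    """Functional burden normalized by the synonymous baseline.

    Returns a per-individual table with the pseudo-counted ratio
    ``(functional + 1) / (synonymous + 1)`` and a rank-based two-group
    comparison (Mann–Whitney U, two-sided) of probands against parents:
    ``(table, U, p)``.
    """
    parts = [
        rav_variant_counts(cohort, m, maf_max, dscore_min) for m in (FATHER, MOTHER, CHILD)
    ]
    table = pd.concat(parts, ignore_index=True)
    table["ratio"] = (table["functional"] + 1) / (table["synonymous"] + 1)
    proband = table.loc[table["role"] == "proband", "ratio"]
    parent = table.loc[table["role"] != "proband", "ratio"]
    if proband.nunique() <= 1 and parent.nunique() <= 1 and set(proband) == set(parent):
        return table, np.nan, 1.0  # degenerate: identical constant ratios
    u, p = stats.mannwhitneyu(proband, parent, alternative="two-sided")
    return table, float(u), float(p)


# ---------------------------------------------------------------------------
# group-stratified per-gene association
# ---------------------------------------------------------------------------


def per_gene_fisher(k: int, n_high: int, m: int, n_normal: int) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for one gene's carriers.

    The 2x2 table is carriers/non-carriers by High-/Normal-5HT group at
    proband level.  The odds ratio is the cross-product ratio with a
    0.5 (Haldane–Anscombe) continuity addition to every cell when any
    cell is zero.
    """
    if n_high <= 0 or n_normal <= 0:
        raise ValueError("both group sizes must be positive")
    a, b, c, d = k, n_high - k, m, n_normal - m
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c), float(p)


def gene_carrier_counts(calls: list[RavCall], groups: pd.DataFrame) -> pd.DataFrame:
    """Proband-level carrier counts per gene, split by 5-HT group.

    ``groups`` maps ``proband_id`` to ``group`` (High/Normal; other
    groups are ignored).  A proband counts once per gene regardless of
    how many RAV events it carries there.
    """
    grp = groups.set_index("proband_id")["group"]
    n_high = int((grp == "High").sum())
    n_normal = int((grp == "Normal").sum())
    carriers: dict[str, set[tuple[str, str]]] = {}
    for c in calls:
        g = grp.get(c.proband_id)
        if g in ("High", "Normal"):
            carriers.setdefault(c.gene, set()).add((c.proband_id, g))
    rows = []
    for gene in sorted(carriers):
        k = sum(1 for _, g in carriers[gene] if g == "High")
        m = sum(1 for _, g in carriers[gene] if g == "Normal")
        odds, p = per_gene_fisher(k, n_high, m, n_normal)
        rows.append({"gene": gene, "high_carriers": k, "normal_carriers": m,
                     "n_high": n_high, "n_normal": n_normal, "odds_ratio": odds, "p": p})
    return pd.DataFrame(
        rows,
        columns=["gene", "high_carriers", "normal_carriers", "n_high", "n_normal",
                 "odds_ratio", "p"],
    )


def split_by_or(per_gene: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Partition genes into candidates (OR > 1) and controls (OR < 1).

    Genes with OR exactly 1 belong to neither set.
    """
    cand = per_gene.loc[per_gene["odds_ratio"] > 1, "gene"].tolist()
    ctrl = per_gene.loc[per_gene["odds_ratio"] < 1, "gene"].tolist()
    return cand, ctrl
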