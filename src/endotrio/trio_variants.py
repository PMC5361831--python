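"""Trio VCF ingestion, exome-style QC filters, and de novo detection.

The read path joins a multi-sample trio VCF against a pedigree and a
per-variant annotation table (gene symbol, consequence, DScore 0–9,
population MAF).  Site-level QC keeps biallelic SNVs with a PASS filter
tag and site mean depth above 10; genotype-level QC masks any trio
member below 6 reads.  De novo variants are then Mendelian violations:
a child alt call with both parents confidently homozygous reference
(on the male X outside the pseudoautosomal regions, a hemizygous alt
with a hom-ref mother).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    CHILD,
    FATHER,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    MOTHER,
    PAR_REGIONS,
    TrioCohort,
    VARIANT_COLUMNS,
    variant_ids,
)

logger = logging.getLogger(__name__)


class PedigreeError(ValueError):
    """The PED file and VCF sample columns do not form complete trios."""


#: default consequence-string vocabulary (ANNOVAR and VEP dialects);
#: editable via the ``vocabulary`` argument of :func:`classify_functional`
CONSEQUENCE_VOCABULARY: dict[str, str] = {
    # loss of function: splice site, nonsense, frameshift
    "stopgain": "LoF",
    "stop_gained": "LoF",
    "splicing": "LoF",
    "splice_acceptor_variant": "LoF",
    "splice_donor_variant": "LoF",
    "frameshift insertion": "LoF",
    "frameshift deletion": "LoF",
    "frameshift_variant": "LoF",
    # missense
    "nonsynonymous SNV": "missense",
    "missense_variant": "missense",
    # synonymous
    "synonymous SNV": "synonymous",
    "synonymous_variant": "synonymous",
}

_warned_consequences: set[str] = set()


def classify_functional(consequence: str, vocabulary: dict[str, str] | None = None) -> str:
    """Map a consequence string to LoF / missense / synonymous / other."""
    vocab = CONSEQUENCE_VOCABULARY if vocabulary is None else vocabulary
    cls = vocab.get(str(consequence).strip())
    if cls is None:
        if consequence not in _warned_consequences:
            logger.warning("unknown consequence %r classified as 'other'", consequence)
            _warned_consequences.add(str(consequence))
        return "other"
    return cls


def dscore_class(func_class: str, dscore: int, threshold: int) -> bool:
    """True iff the variant is missense with DScore >= ``threshold``.

    LoF variants always return False: they are kept by class, not by
    deleteriousness score.
    """
    if not 0 <= threshold <= 9:
        raise ValueError("DScore threshold must be within 0..9")
    return func_class == "missense" and int(dscore) >= threshold


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_ped(path) -> pd.DataFrame:
    """Parse a 6-column PED into a trio table (one row per child)."""
    ped = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family", "individual", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    children = ped[(ped["father"] != "0") & (ped["mother"] != "0")]
    if children.empty:
        raise PedigreeError("PED contains no complete trios")
    members = set(ped["individual"])
    rows = []
    for _, c in children.iterrows():
        if c["father"] not in members or c["mother"] not in members:
            raise PedigreeError(f"trio {c['family']}: parent rows missing from PED")
        rows.append(
            {
                "trio_id": c["family"],
                "father_id": c["father"],
                "mother_id": c["mother"],
                "child_id": c["individual"],
                "child_sex": "male" if str(c["sex"]) == "1" else "female",
            }
        )
    return pd.DataFrame(rows)


def read_annotation(path) -> pd.DataFrame:
    anno = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    anno["func_class"] = [classify_functional(c) for c in anno["consequence"]]
    return anno


_GT_CODE = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}  # cyvcf2 gt_types


def read_trio_cohort(vcf_path, ped_path, annotation_path) -> TrioCohort:
    """Read VCF + PED + annotation into a :class:`TrioCohort`.

    Multi-allelic records are rejected (the analysis is restricted to
    biallelic SNVs); records without a matching annotation row are
    dropped with a warning.
    """
    from cyvcf2 import VCF

    trios = read_ped(ped_path)
    anno = read_annotation(annotation_path)
    anno_key = {
        (str(r.chrom), int(r.pos), r.ref, r.alt): i
        for i, r in enumerate(anno.itertuples())
    }

    vcf = VCF(str(vcf_path))
    sample_col = {s: i for i, s in enumerate(vcf.samples)}
    for col in ("father_id", "mother_id", "child_id"):
        missing = set(trios[col]) - sample_col.keys()
        if missing:
            raise PedigreeError(f"PED {col} not in VCF samples: {sorted(missing)[:5]}")
    member_idx = np.array(
        [
            [sample_col[t] for t in (tr.father_id, tr.mother_id, tr.child_id)]
            for tr in trios.itertuples()
        ]
    )  # (n_trios, 3)

    rows, gts, dps = [], [], []
    n_multi = n_unannotated = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        key = (str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0])
        ai = anno_key.get(key)
        if ai is None:
            n_unannotated += 1
            continue
        a = anno.iloc[ai]
        code = np.array([_GT_CODE[t] for t in rec.gt_types], dtype=np.int8)
        depth = np.asarray(rec.format("DP")).reshape(-1).astype(np.int32)
        gts.append(code[member_idx])
        dps.append(depth[member_idx])
        rows.append(
            {
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "gene": a["gene"],
                "consequence": a["consequence"],
                "func_class": a["func_class"],
                "dscore": int(a["dscore"]),
                "maf": float(a["maf"]),
                "filter_tag": rec.FILTER or "PASS",
                "mean_depth": float(depth.mean()),
            }
        )
    if n_multi:
        logger.warning("dropped %d multi-allelic records", n_multi)
    if n_unannotated:
        logger.warning("dropped %d records with no annotation row", n_unannotated)

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    shape = (len(rows), len(trios), 3)
    return TrioCohort(
        variants=variants,
        trios=trios,
        gt=np.array(gts, dtype=np.int8).reshape(shape),
        dp=np.array(dps, dtype=np.int32).reshape(shape),
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def apply_site_filters(
    cohort: TrioCohort, min_mean_depth: float = 10.0, require_pass: bool = True
) -> TrioCohort:
    """Keep biallelic SNVs with PASS filter and mean depth strictly > 10."""
    v = cohort.variants
    snv = (v["ref"].str.len() == 1) & (v["alt"].str.len() == 1)
    keep = snv & (v["mean_depth"] > min_mean_depth)
    if require_pass:
        keep &= v["filter_tag"] == "PASS"
    return cohort.subset_sites(keep.to_numpy())


def mask_low_depth(cohort: TrioCohort, min_depth: int = 6) -> TrioCohort:
    """Mask any member genotype with depth strictly below ``min_depth``."""
    out = cohort.copy()
    out.gt[out.dp < min_depth] = MISSING
    return out


def expression_filter(
    genes, expression: pd.DataFrame, rpkm_threshold: float = 1.0
) -> list[str]:
    """Keep genes expressed above ``rpkm_threshold`` (strict >).

    ``expression`` needs ``gene`` and ``rpkm`` columns; genes absent from
    the table are dropped with a warning (unknown expression is treated
    as not brain-expressed).
    """
    table = expression.set_index("gene")["rpkm"]
    kept, absent = [], []
    for g in genes:
        if g not in table.index:
            absent.append(g)
        elif float(table.loc[g]) > rpkm_threshold:
            kept.append(g)
    if absent:
        logger.warning("%d genes absent from the expression table were dropped", len(absent))
    return kept


# ---------------------------------------------------------------------------
# de novo detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DnvCall:
    """A de novo variant call in one trio."""

    trio_id: str
    variant_id: str
    gene: str
    func_class: str
    dscore: int
    child_genotype: int
    hemizygous: bool = False


def detect_dnv(cohort: TrioCohort, par_regions=PAR_REGIONS) -> list[DnvCall]:
    """Call de novo variants as Mendelian violations.

    Autosomes and the female X (plus male X inside the pseudoautosomal
    regions): the child carries the alt allele while both parents are
    confidently hom-ref.  Male X outside the PARs: the child is
    hemizygous, so any alt call with a hom-ref mother is de novo and the
    father's genotype is ignored.  A missing required member suppresses
    the call.  Genotypes are assumed already depth-masked and
    site-filtered.
    """
    gt = cohort.gt
    fa, mo, ch = gt[:, :, FATHER], gt[:, :, MOTHER], gt[:, :, CHILD]
    child_alt = (ch == HET) | (ch == HOM_ALT)

    male = (cohort.trios["child_sex"] == "male").to_numpy()[None, :]
    x = cohort.is_x()[:, None]
    par = cohort.in_par(par_regions)[:, None]
    hemi_zone = x & ~par & male

    autosomal_rule = (fa == HOM_REF) & (mo == HOM_REF) & child_alt
    hemi_rule = (mo == HOM_REF) & child_alt & (ch != MISSING)
    is_dnv = np.where(hemi_zone, hemi_rule, autosomal_rule)

    vids = variant_ids(cohort.variants)
    calls = []
    for si, ti in zip(*np.nonzero(is_dnv)):
        v = cohort.variants.iloc[si]
        calls.append(
            DnvCall(
                trio_id=cohort.trios["trio_id"].iloc[ti],
                variant_id=vids[si],
                gene=v["gene"],
                func_class=v["func_class"],
                dscore=int(v["dscore"]),
                child_genotype=int(ch[si, ti]),
                hemizygous=bool(hemi_zone[si, ti]),
            )
        )
    calls.sort(key=lambda c: (c.trio_id, c.variant_id))
    return calls


def dnv_table(calls: list[DnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trio_id": c.trio_id,
                "variant_id": c.variant_id,
                "gene": c.gene,
                "func_class": c.func_class,
                "dscore": c.dscore,
                "hemizygous": c.hemizygous,
            }
            for c in calls
        ],
        columns=["trio_id", "variant_id", "gene", "func_class", "dscore", "hemizygous"],
    )
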