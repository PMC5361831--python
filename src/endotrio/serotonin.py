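"""Whole-blood serotonin (WB5HT) normalization and group assignment.

Hyperserotonemia — elevated whole-blood serotonin — is among the most
replicated biomarkers in autism.  Raw WB5HT depends strongly on pubertal
status and ancestry, so values are standardized against a reference
table of (ancestry, pubertal stage) means and SDs before probands are
stratified: z > 1.75 defines the High-5HT group, z < 1 the Normal-5HT
group, and the band between is held out to sharpen the contrast.

For subjects reporting more than one ancestry, the arithmetic means of
the per-ancestry reference means and SDs are used.  Subjects on
serotonin-altering medication are excluded before normalization.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

HIGH_CUT = 1.75
NORMAL_CUT = 1.0

#: months of age at/above which a subject with missing Tanner stage is
#: considered post-pubertal
PUBERTY_AGE_MONTHS = 144


class UnclassifiableError(ValueError):
    """Neither Tanner stage nor age is available for a subject."""


class MissingReferenceError(KeyError):
    """An ancestry/puberty cell is absent from the reference norms."""


def _is_missing(x) -> bool:
    if x is None:
        return True
    try:
        return bool(np.isnan(x))
    except TypeError:
        return False


def classify_puberty(tanner, age_months) -> str:
    """Classify a subject as ``"pre"`` or ``"post"`` pubertal.

    Tanner stage, when present, takes precedence: stages I–II are
    pre-pubertal and III–V post-pubertal.  With Tanner missing, the
    age rule applies: under 144 months pre-pubertal, 144 months or
    older post-pubertal.
    """
    if not _is_missing(tanner):
        return "pre" if int(tanner) <= 2 else "post"
    if not _is_missing(age_months):
        return "pre" if float(age_months) < PUBERTY_AGE_MONTHS else "post"
    raise UnclassifiableError("both Tanner stage and age are missing")


def lookup_norms(
    ancestries: Iterable[str], puberty: str, norms: pd.DataFrame
) -> tuple[float, float]:
    """Averaged reference (mean, SD) for one or more ancestry labels.

    Labels are matched case-insensitively against the norms table; for
    multi-ancestry subjects the arithmetic mean of the per-ancestry
    means and of the per-ancestry SDs is returned.
    """
    key = norms.assign(
        _anc=norms["ancestry"].str.strip().str.lower(), _pub=norms["puberty"].str.lower()
    ).set_index(["_anc", "_pub"])
    means, sds = [], []
    for a in ancestries:
        a = str(a).strip().lower()
        try:
            row = key.loc[(a, puberty.lower())]
        except KeyError:
            raise MissingReferenceError(
                f"no reference norms for ancestry {a!r}, puberty {puberty!r}"
            ) from None
        means.append(float(row["mean"]))
        sds.append(float(row["sd"]))
    return float(np.mean(means)), float(np.mean(sds))


def wb5ht_zscore(
    raw: float, ancestries: Iterable[str], puberty: str, norms: pd.DataFrame
) -> float:
    """Standardize a raw WB5HT value: z = (raw − m̄) / s̄."""
    m, s = lookup_norms(ancestries, puberty, norms)
    if s <= 0:
        raise ValueError("reference SD must be positive")
    return (float(raw) - m) / s


def assign_group(z) -> str:
    """Map a WB5HT z-score to High / Normal / Intermediate / Excluded.

    z > 1.75 is High, z < 1 is Normal; values in [1, 1.75] (both
    boundaries included — the defining inequalities are strict) fall in
    the Intermediate band excluded from group contrasts.  An undefined
    z yields Excluded.
    """
    if _is_missing(z):
        return "Excluded"
    z = float(z)
    if z > HIGH_CUT:
        return "High"
    if z < NORMAL_CUT:
        return "Normal"
    return "Intermediate"


def normalize_serotonin(pheno: pd.DataFrame, norms: pd.DataFrame) -> pd.DataFrame:
    """Per-subject normalization table: puberty, z and group columns.

    ``pheno`` needs columns ``subject_id, wb5ht_raw, ancestries``
    (``;``-separated labels), ``tanner, age_months`` and optionally
    ``on_excluding_medication``.  Medicated subjects and subjects with
    no measurement keep ``z = NaN`` and group ``Excluded``.
    """
    out = pheno.copy()
    zs, pubs, groups = [], [], []
    meds = out.get("on_excluding_medication", pd.Series(False, index=out.index))
    for (_, s), med in zip(out.iterrows(), meds):
        puberty = classify_puberty(s.get("tanner"), s.get("age_months"))
        pubs.append(puberty)
        if bool(med) or _is_missing(s.get("wb5ht_raw")):
            zs.append(np.nan)
            groups.append("Excluded")
            continue
        z = wb5ht_zscore(s["wb5ht_raw"], str(s["ancestries"]).split(";"), puberty, norms)
        zs.append(z)
        groups.append(assign_group(z))
    out["puberty"] = pubs
    out["z"] = zs
    out["group"] = groups
    return out
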