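"""In-memory containers for trio cohorts.

A :class:`TrioCohort` holds a multi-sample trio call set as dense arrays:
one row per biallelic site, one (father, mother, child) genotype/depth
triple per trio.  Genotypes are coded ``0`` hom-ref, ``1`` het, ``2``
hom-alt, ``-1`` missing.  The variant table carries the per-site
annotation (gene, functional class, DScore, population MAF) that the
downstream filters and tests consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

FATHER, MOTHER, CHILD = 0, 1, 2

#: GRCh37 X-chromosome pseudoautosomal intervals (1-based, inclusive).
PAR_REGIONS = (("X", 60_001, 2_699_520), ("X", 154_931_044, 155_260_560))

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "func_class",
    "dscore",
    "maf",
    "filter_tag",
    "mean_depth",
]


def variant_ids(variants: pd.DataFrame) -> pd.Index:
    """Canonical ``chrom:pos:ref:alt`` identifiers for a variant table."""
    return pd.Index(
        variants["chrom"].astype(str)
        + ":"
        + variants["pos"].astype(str)
        + ":"
        + variants["ref"]
        + ":"
        + variants["alt"],
        name="variant_id",
    )


@dataclass
class TrioCohort:
    """A joint genotype matrix over trios plus per-site annotation.

    Parameters
    ----------
    variants
        One row per site with the columns in :data:`VARIANT_COLUMNS`.
    trios
        One row per trio: ``trio_id, father_id, mother_id, child_id,
        child_sex`` (``child_sex`` in ``{"male", "female"}``).
    gt
        ``int8`` array of shape ``(n_sites, n_trios, 3)``; member axis is
        (father, mother, child).
    dp
        Read depths, same shape as ``gt``.
    """

    variants: pd.DataFrame
    trios: pd.DataFrame
    gt: np.ndarray
    dp: np.ndarray

    def __post_init__(self) -> None:
        n_sites, n_trios = len(self.variants), len(self.trios)
        if self.gt.shape != (n_sites, n_trios, 3):
            raise ValueError(
                f"genotype array shape {self.gt.shape} does not match "
                f"{n_sites} sites x {n_trios} trios"
            )
        if self.dp.shape != self.gt.shape:
            raise ValueError("depth array shape does not match genotype array")

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    @property
    def n_trios(self) -> int:
        return len(self.trios)

    def subset_sites(self, mask: np.ndarray) -> "TrioCohort":
        """Restrict to the sites selected by a boolean or index mask."""
        return TrioCohort(
            variants=self.variants.loc[np.asarray(mask)].reset_index(drop=True)
            if np.asarray(mask).dtype == bool
            else self.variants.iloc[np.asarray(mask)].reset_index(drop=True),
            trios=self.trios,
            gt=self.gt[mask],
            dp=self.dp[mask],
        )

    def copy(self) -> "TrioCohort":
        return TrioCohort(
            variants=self.variants.copy(),
            trios=self.trios.copy(),
            gt=self.gt.copy(),
            dp=self.dp.copy(),
        )

    def is_autosomal(self) -> np.ndarray:
        chrom = self.variants["chrom"].astype(str).str.removeprefix("chr")
        return chrom.isin([str(c) for c in range(1, 23)]).to_numpy()

    def is_x(self) -> np.ndarray:
        chrom = self.variants["chrom"].astype(str).str.removeprefix("chr")
        return (chrom == "X").to_numpy()

    def in_par(self, par_regions=PAR_REGIONS) -> np.ndarray:
        """Mark sites inside a pseudoautosomal interval."""
        chrom = self.variants["chrom"].astype(str).str.removeprefix("chr").to_numpy()
        pos = self.variants["pos"].to_numpy()
        mask = np.zeros(self.n_sites, dtype=bool)
        for c, start, end in par_regions:
            mask |= (chrom == str(c).removeprefix("chr")) & (pos >= start) & (pos <= end)
        return mask


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth emitted alongside a synthetic cohort.

    ``dnv_list`` holds ``(trio_id, variant_id)`` pairs, ``ch_list``
    ``(trio_id, gene, (variant_id, variant_id))`` triples, ``hom_list``
    ``(trio_id, gene, variant_id)`` triples; ``distorted_genes`` names the
    genes whose rare functional alleles transmit with a biased probability.
    """

    dnv_list: tuple = ()
    ch_list: tuple = ()
    hom_list: tuple = ()
    distorted_genes: tuple = ()
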