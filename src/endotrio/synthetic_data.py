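"""Synthetic inputs for the endophenotype-stratified trio pipeline.

Every file the pipeline consumes — multi-sample trio VCF, pedigree,
per-variant annotation, gene model with CDS lengths and expression,
gene sets, an interaction network, serotonin phenotypes and reference
norms — can be generated here with the statistical structure the
analysis assumes: Hardy–Weinberg parents, Mendelian children with
planted de novo variants, planted compound heterozygotes with opposite
parental origins, genes under transmission distortion, a heavy-tailed
CDS-length law, a network with a module wired next to a seed list, and
a two-component whole-blood-serotonin distribution with an elevated
proband tail.

Generators are bit-reproducible under a fixed seed and return in-memory
objects; the ``write_*`` functions serialise them to the standard
plain-text formats (VCF 4.2, 6-column PED, TSV, GMT, edge list).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import (
    CHILD,
    FATHER,
    HET,
    HOM_ALT,
    HOM_REF,
    MOTHER,
    PlantedTruth,
    TrioCohort,
    VARIANT_COLUMNS,
    variant_ids,
)
from .serotonin import classify_puberty, lookup_norms

AUTOSOMES = [str(c) for c in range(1, 23)]

# ANNOVAR-dialect consequence strings by functional class
_LOF_CONSEQUENCES = ("stopgain", "splicing", "frameshift deletion")
_MIS_CONSEQUENCE = "nonsynonymous SNV"
_SYN_CONSEQUENCE = "synonymous SNV"

_BASES = np.array(list("ACGT"))


class InvalidSpecError(ValueError):
    """A generator was asked for a statistically impossible configuration."""


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic trio cohort.

    Defaults emulate a 116-trio exome cohort sequenced at ~60x: roughly
    one functional de novo variant per proband, ~1.2 compound-het genes
    and ~0.36 rare homozygote genes per proband, rare-variant MAFs on
    [5e-4, 0.01], and 28% of probands drawn from the elevated
    whole-blood-serotonin component.
    """

    n_trios: int = 116
    n_genes: int = 500
    dnv_rate: float = 1.0
    ch_rate: float = 1.2
    hom_rate: float = 0.36
    transmission_prob: float = 0.5
    maf_range: tuple[float, float] = (5e-4, 0.01)
    high5ht_fraction: float = 0.28
    seed: int = 0
    # plumbing knobs beyond the headline rates
    background_sites_per_gene: float = 2.0
    distorted_genes: tuple[str, ...] = ()
    distorted_sites_per_gene: int = 4
    low_depth_fraction: float = 0.0
    mean_depth: float = 60.0
    male_fraction: float = 0.845  # 5.44:1 male:female

    def __post_init__(self) -> None:
        if self.n_trios < 1:
            raise InvalidSpecError("n_trios must be positive")
        for name in ("dnv_rate", "ch_rate", "hom_rate", "background_sites_per_gene"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        if not 0.0 < self.transmission_prob < 1.0:
            raise InvalidSpecError("transmission_prob must be in (0, 1)")
        if not 0.0 <= self.high5ht_fraction <= 1.0:
            raise InvalidSpecError("high5ht_fraction must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise InvalidSpecError("maf_range must lie within (0, 0.5)")
        if not 0.0 <= self.low_depth_fraction < 1.0:
            raise InvalidSpecError("low_depth_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# gene universe
# ---------------------------------------------------------------------------


def generate_gene_universe(
    n_genes: int,
    length_law: tuple[float, float] = (1500.0, 0.8),
    seed: int = 0,
    expressed_fraction: float = 0.85,
) -> pd.DataFrame:
    """Gene model table with log-normal CDS lengths and an RPKM column.

    ``length_law`` is ``(median_bp, sigma_log)`` of the CDS-length law;
    lengths are floored at 150 bp (a minimal coding exon).  RPKM is
    log-normal, scaled so that about ``expressed_fraction`` of genes
    exceed 1 (the brain-expression threshold used downstream).

    Returns a frame with columns ``gene, chrom, start, cds_length, rpkm``.
    """
    if n_genes < 10:
        raise InvalidSpecError("need at least 10 genes for a usable universe")
    rng = np.random.default_rng(seed)
    median, sigma = length_law
    lengths = np.maximum(
        np.round(median * np.exp(rng.normal(0.0, sigma, size=n_genes))), 150
    ).astype(int)
    # P(RPKM > 1) = Phi(mu/sigma_r); mu chosen for the requested fraction
    from scipy.stats import norm

    sigma_r = 1.5
    mu_r = sigma_r * norm.ppf(expressed_fraction)
    rpkm = np.exp(rng.normal(mu_r, sigma_r, size=n_genes))
    chrom = np.array(AUTOSOMES)[rng.integers(0, len(AUTOSOMES), size=n_genes)]
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    # lay genes out on 2-Mb grid per chromosome so positions never collide
    order = np.argsort(chrom, kind="stable")
    start = np.empty(n_genes, dtype=np.int64)
    offset = {}
    for idx in order:
        k = offset.get(chrom[idx], 0)
        start[idx] = 1_000_000 + k * 2_000_000
        offset[chrom[idx]] = k + 1
    return pd.DataFrame(
        {"gene": genes, "chrom": chrom, "start": start, "cds_length": lengths, "rpkm": rpkm}
    )


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------


def generate_network(
    n_nodes: int,
    attachment: int = 2,
    planted_module: Sequence[str] = (),
    seed: int = 0,
    genes: Sequence[str] | None = None,
    anchor_genes: Sequence[str] = (),
    shuffle: bool = True,
) -> nx.Graph:
    """Scale-free interaction network with an optionally planted module.

    A Barabási–Albert backbone (``attachment`` edges per incoming node)
    is relabelled with gene symbols; ``planted_module`` genes are
    interconnected as a clique (internal density >= 5x background for any
    realistic size) and each module gene is wired to two ``anchor_genes``
    so the module sits adjacent to a seed list in network distance.
    """
    labels = list(genes)[:n_nodes] if genes is not None else [
        f"G{i:05d}" for i in range(n_nodes)
    ]
    if len(labels) < n_nodes:
        raise InvalidSpecError("fewer gene labels than requested nodes")
    if len(planted_module) > n_nodes:
        raise InvalidSpecError("planted module larger than the network")
    missing = set(planted_module) - set(labels)
    if missing:
        raise InvalidSpecError(f"planted module genes not among node labels: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_nodes, attachment, seed=int(rng.integers(2**31)))
    order = np.arange(n_nodes)
    if shuffle:
        rng.shuffle(order)  # decouple hub status from label order
    g = nx.relabel_nodes(g, {i: labels[order[i]] for i in range(n_nodes)})

    module = list(planted_module)
    for i, a in enumerate(module):
        for b in module[i + 1 :]:
            g.add_edge(a, b)
    anchors = [a for a in anchor_genes if a in g]
    if anchors:
        for m in module:
            for a in rng.choice(anchors, size=min(2, len(anchors)), replace=False):
                if a != m:
                    g.add_edge(m, str(a))
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


# ---------------------------------------------------------------------------
# trio cohort
# ---------------------------------------------------------------------------


def _draw_class(rng, n, p_lof, p_mis, p_syn):
    u = rng.random(n)
    cls = np.where(u < p_lof, "LoF", np.where(u < p_lof + p_mis, "missense", "synonymous"))
    return cls


def _consequence_for(cls: np.ndarray, rng) -> np.ndarray:
    out = np.empty(len(cls), dtype=object)
    lof = cls == "LoF"
    out[lof] = rng.choice(_LOF_CONSEQUENCES, size=int(lof.sum()))
    out[cls == "missense"] = _MIS_CONSEQUENCE
    out[cls == "synonymous"] = _SYN_CONSEQUENCE
    return out


def generate_trio_cohort(
    spec: CohortSpec,
    gene_universe: pd.DataFrame,
    dnv_gene_pools: Mapping[int, Sequence[str]] | None = None,
) -> tuple[TrioCohort, PlantedTruth]:
    """Simulate a trio cohort with planted de novo and recessive events.

    Background sites draw parental genotypes in Hardy–Weinberg at their
    stated MAF and transmit alleles Mendelianly, except that qualifying
    functional alleles in ``spec.distorted_genes`` are transmitted with
    probability ``spec.transmission_prob`` (synonymous alleles in those
    genes stay at 0.5 as a negative control).  Planted events are added
    as extra sites: de novo hets with hom-ref parents, compound-het
    pairs with one paternal- and one maternal-origin rare functional
    heterozygote, and rare functional homozygotes.

    ``dnv_gene_pools`` optionally maps a trio index to the gene pool its
    planted DNVs are drawn from (used to give one phenotype group DNVs
    near a network module).

    Returns the cohort and the :class:`~endotrio.cohort.PlantedTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_genes > len(gene_universe):
        raise InvalidSpecError("cohort asks for more genes than the universe holds")
    genes = gene_universe.iloc[: spec.n_genes].reset_index(drop=True)
    gene_row = {g: i for i, g in enumerate(genes["gene"])}
    for g in spec.distorted_genes:
        if g not in gene_row:
            raise InvalidSpecError(f"distorted gene {g!r} not in the selected gene set")

    n_trios = spec.n_trios
    fam = [f"fam{i + 1:04d}" for i in range(n_trios)]
    trios = pd.DataFrame(
        {
            "trio_id": fam,
            "father_id": [f + ".fa" for f in fam],
            "mother_id": [f + ".mo" for f in fam],
            "child_id": [f + ".p1" for f in fam],
            "child_sex": np.where(rng.random(n_trios) < spec.male_fraction, "male", "female"),
        }
    )

    lo, hi = spec.maf_range
    rows: list[dict] = []
    gt_blocks: list[np.ndarray] = []
    offsets = np.zeros(len(genes), dtype=int)  # per-gene position counter

    def new_site(gene_idx: int, cls: str, dscore: int, maf: float) -> dict:
        offsets[gene_idx] += 1
        g = genes.iloc[gene_idx]
        ref, alt = rng.choice(4, size=2, replace=False)
        return {
            "chrom": g["chrom"],
            "pos": int(g["start"]) + int(offsets[gene_idx]) * 37,
            "ref": _BASES[ref],
            "alt": _BASES[alt],
            "gene": g["gene"],
            "func_class": cls,
            "dscore": dscore,
            "maf": maf,
            "filter_tag": "PASS",
        }

    # ---- background segregating sites -----------------------------------
    n_bg = int(round(spec.background_sites_per_gene * spec.n_genes))
    bg_gene_idx = rng.integers(0, len(genes), size=n_bg)
    bg_cls = _draw_class(rng, n_bg, 0.05, 0.45, 0.50)
    bg_dscore = np.where(
        bg_cls == "missense", rng.integers(0, 10, size=n_bg), np.where(bg_cls == "LoF", 9, 0)
    )
    bg_maf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_bg))

    # extra informative sites in distorted genes, MAF at the top of the
    # rare range so transmission events actually occur at cohort scale
    d_gene_idx, d_cls, d_dscore, d_maf = [], [], [], []
    for g in spec.distorted_genes:
        for k in range(spec.distorted_sites_per_gene):
            d_gene_idx.append(gene_row[g])
            if k % 2 == 0:
                if rng.random() < 0.3:
                    d_cls.append("LoF")
                    d_dscore.append(9)
                else:
                    d_cls.append("missense")
                    d_dscore.append(int(rng.integers(4, 10)))
            else:
                d_cls.append("synonymous")
                d_dscore.append(0)
            d_maf.append(float(rng.uniform(0.6 * hi, hi)))

    seg_gene_idx = np.concatenate([bg_gene_idx, np.array(d_gene_idx, dtype=int)]) if d_gene_idx else bg_gene_idx
    seg_cls = np.concatenate([bg_cls, np.array(d_cls, dtype=object)]) if d_cls else bg_cls
    seg_dscore = np.concatenate([bg_dscore, np.array(d_dscore)]) if d_dscore else bg_dscore
    seg_maf = np.concatenate([bg_maf, np.array(d_maf)]) if d_maf else bg_maf
    n_seg = len(seg_gene_idx)

    for i in range(n_seg):
        rows.append(
            new_site(int(seg_gene_idx[i]), str(seg_cls[i]), int(seg_dscore[i]), float(seg_maf[i]))
        )

    if n_seg:
        maf_col = seg_maf[:, None, None]
        parents = rng.binomial(
            2, np.broadcast_to(maf_col, (n_seg, n_trios, 2)), size=(n_seg, n_trios, 2)
        )
        pat, mat = parents[:, :, 0], parents[:, :, 1]
        # transmitted-allele probability per site: biased only for
        # functional alleles of distorted genes
        distorted_idx = {gene_row[g] for g in spec.distorted_genes}
        functional = (seg_cls == "LoF") | (seg_cls == "missense")
        biased = np.array(
            [functional[i] and int(seg_gene_idx[i]) in distorted_idx for i in range(n_seg)]
        )
        tprob = np.where(biased, spec.transmission_prob, 0.5)[:, None]

        def transmit(par):
            # parent genotype 0/1/2 -> transmitted alt-allele count 0/1
            draw = (rng.random((n_seg, n_trios)) < tprob).astype(np.int8)
            return np.where(par == 2, 1, np.where(par == 1, draw, 0)).astype(np.int8)

        child = transmit(pat) + transmit(mat)
        seg_gt = np.stack([pat, mat, child], axis=2).astype(np.int8)
        gt_blocks.append(seg_gt)

    # ---- planted de novo variants ---------------------------------------
    truth_dnv, truth_ch, truth_hom = [], [], []
    pools = dnv_gene_pools or {}
    all_gene_names = genes["gene"].to_numpy()

    def planted_block() -> np.ndarray:
        return np.zeros((1, n_trios, 3), dtype=np.int8)

    n_dnv = rng.poisson(spec.dnv_rate, size=n_trios)
    for t in range(n_trios):
        pool = np.asarray(pools.get(t, all_gene_names))
        k = min(int(n_dnv[t]), len(pool))
        for g in rng.choice(pool, size=k, replace=False):
            if rng.random() < 0.16:
                cls, ds = "LoF", 9
            else:
                cls, ds = "missense", int(rng.integers(2, 10))
            rows.append(new_site(gene_row[str(g)], cls, ds, lo))
            block = planted_block()
            block[0, t, CHILD] = HET
            gt_blocks.append(block)
            truth_dnv.append((trios["trio_id"][t], len(rows) - 1))

    # ---- planted compound heterozygotes ----------------------------------
    n_ch = rng.poisson(spec.ch_rate, size=n_trios)
    n_hom = rng.poisson(spec.hom_rate, size=n_trios)
    for t in range(n_trios):
        k = int(n_ch[t]) + int(n_hom[t])
        if k == 0:
            continue
        chosen = rng.choice(all_gene_names, size=min(k, len(all_gene_names)), replace=False)
        ch_genes, hom_genes = chosen[: int(n_ch[t])], chosen[int(n_ch[t]) :]
        for g in ch_genes:
            pair = []
            for origin in (FATHER, MOTHER):
                if rng.random() < 0.2:
                    cls, ds = "LoF", 9
                else:
                    cls, ds = "missense", int(rng.integers(2, 10))
                rows.append(new_site(gene_row[str(g)], cls, ds, lo))
                block = planted_block()
                block[0, t, origin] = HET
                block[0, t, CHILD] = HET
                gt_blocks.append(block)
                pair.append(len(rows) - 1)
            truth_ch.append((trios["trio_id"][t], str(g), tuple(pair)))
        for g in hom_genes:
            if rng.random() < 0.2:
                cls, ds = "LoF", 9
            else:
                cls, ds = "missense", int(rng.integers(2, 10))
            rows.append(new_site(gene_row[str(g)], cls, ds, lo))
            block = planted_block()
            block[0, t, FATHER] = HET
            block[0, t, MOTHER] = HET
            block[0, t, CHILD] = HOM_ALT
            gt_blocks.append(block)
            truth_hom.append((trios["trio_id"][t], str(g), len(rows) - 1))

    variants = pd.DataFrame(rows)
    variants["consequence"] = _consequence_for(variants["func_class"].to_numpy(), rng)
    gt = (
        np.concatenate(gt_blocks, axis=0)
        if gt_blocks
        else np.zeros((0, n_trios, 3), dtype=np.int8)
    )

    # depths ~ Poisson(mean_depth); an optional fraction is forced < 6 to
    # exercise downstream masking
    dp = rng.poisson(spec.mean_depth, size=gt.shape).astype(np.int32)
    if spec.low_depth_fraction > 0:
        low = rng.random(gt.shape) < spec.low_depth_fraction
        dp[low] = rng.integers(0, 6, size=int(low.sum()))
    variants["mean_depth"] = dp.reshape(len(variants), -1).mean(axis=1)

    # sort sites genomically, remapping truth row indices to variant ids
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    gt, dp = gt[order], dp[order]
    vids = variant_ids(variants)
    pos_of = np.empty(len(order), dtype=int)
    pos_of[order] = np.arange(len(order))

    truth = PlantedTruth(
        dnv_list=tuple((t, vids[pos_of[i]]) for t, i in truth_dnv),
        ch_list=tuple(
            (t, g, (vids[pos_of[i]], vids[pos_of[j]])) for t, g, (i, j) in truth_ch
        ),
        hom_list=tuple((t, g, vids[pos_of[i]]) for t, g, i in truth_hom),
        distorted_genes=tuple(spec.distorted_genes),
    )
    cohort = TrioCohort(
        variants=variants[VARIANT_COLUMNS], trios=trios, gt=gt, dp=dp
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# serotonin phenotypes
# ---------------------------------------------------------------------------


def default_norms() -> pd.DataFrame:
    """Synthetic reference normalization table (ancestry x puberty).

    Whole-blood serotonin declines across puberty; means/SDs are
    plausible ng/mL magnitudes, not published reference values.
    """
    rows = []
    for ancestry, scale in [("european", 1.0), ("african", 1.08), ("asian", 0.95)]:
        rows.append((ancestry, "pre", 180.0 * scale, 52.0 * scale))
        rows.append((ancestry, "post", 125.0 * scale, 40.0 * scale))
    return pd.DataFrame(rows, columns=["ancestry", "puberty", "mean", "sd"])


def make_subjects(trios: pd.DataFrame, norms: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Subject table (probands + parents) with ancestry, age and Tanner stage."""
    rng = np.random.default_rng(seed)
    ancestries = sorted(norms["ancestry"].unique())
    rows = []
    for _, tr in trios.iterrows():
        anc = str(rng.choice(ancestries))
        if rng.random() < 0.1 and len(ancestries) > 1:
            other = str(rng.choice([a for a in ancestries if a != anc]))
            anc = f"{anc};{other}"
        age = int(rng.integers(60, 217))
        tanner = int(np.clip(1 + (age - 60) // 36 + rng.integers(-1, 2), 1, 5))
        if rng.random() < 0.3:
            tanner = np.nan  # missing Tanner -> age rule applies
        rows.append((tr["child_id"], tr["trio_id"], "proband", anc, age, tanner))
        for role, sid in (("father", tr["father_id"]), ("mother", tr["mother_id"])):
            rows.append((sid, tr["trio_id"], role, anc, int(rng.integers(300, 700)), 5))
    return pd.DataFrame(
        rows, columns=["subject_id", "trio_id", "role", "ancestries", "age_months", "tanner"]
    )


def generate_serotonin(
    subjects: pd.DataFrame,
    norms: pd.DataFrame,
    high5ht_fraction: float,
    seed: int = 0,
    high_mean_z: float = 2.8,
    high_sd_z: float = 0.8,
    medication_fraction: float = 0.0,
) -> pd.DataFrame:
    """Raw whole-blood serotonin values for a subject table.

    Parents are drawn from the reference law for their ancestry/puberty
    cell.  Probands come from a two-component mixture: with probability
    ``high5ht_fraction`` from an elevated component centred ``high_mean_z``
    reference-SDs above the reference mean (so ~90% of that component
    exceeds z = 1.75 after normalization), otherwise from the reference
    law itself.
    """
    rng = np.random.default_rng(seed)
    out = subjects.copy()
    raws, meds = [], []
    for _, s in out.iterrows():
        puberty = classify_puberty(s.get("tanner"), s.get("age_months"))
        m, sd = lookup_norms(str(s["ancestries"]).split(";"), puberty, norms)
        if s["role"] == "proband" and rng.random() < high5ht_fraction:
            raw = m + (high_mean_z + high_sd_z * rng.standard_normal()) * sd
        else:
            raw = rng.normal(m, sd)
        raws.append(max(raw, 1.0))
        meds.append(bool(rng.random() < medication_fraction))
    out["wb5ht_raw"] = raws
    out["on_excluding_medication"] = meds
    return out


# ---------------------------------------------------------------------------
# writers (plain-text standard formats)
# ---------------------------------------------------------------------------

_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", -1: "./."}


def write_vcf(cohort: TrioCohort, path: str | Path) -> None:
    """Write the cohort as a multi-sample VCF 4.2 with GT:DP genotypes."""
    path = Path(path)
    samples: list[str] = []
    for _, tr in cohort.trios.iterrows():
        samples += [tr["father_id"], tr["mother_id"], tr["child_id"]]
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        chroms = list(dict.fromkeys(cohort.variants["chrom"].astype(str)))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        gt = cohort.gt.reshape(cohort.n_sites, -1)
        dp = cohort.dp.reshape(cohort.n_sites, -1)
        for i, (_, v) in enumerate(cohort.variants.iterrows()):
            fields = "\t".join(
                f"{_GT_STR[int(g)]}:{int(d)}" for g, d in zip(gt[i], dp[i])
            )
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t.\t{v['ref']}\t{v['alt']}\t.\t"
                f"{v['filter_tag']}\t.\tGT:DP\t{fields}\n"
            )


def write_ped(cohort: TrioCohort, path: str | Path) -> None:
    """6-column PED (family, individual, father, mother, sex, phenotype)."""
    with Path(path).open("w") as fh:
        for _, tr in cohort.trios.iterrows():
            fam = tr["trio_id"]
            fh.write(f"{fam}\t{tr['father_id']}\t0\t0\t1\t0\n")
            fh.write(f"{fam}\t{tr['mother_id']}\t0\t0\t2\t0\n")
            sex = 1 if tr["child_sex"] == "male" else 2
            fh.write(f"{fam}\t{tr['child_id']}\t{tr['father_id']}\t{tr['mother_id']}\t{sex}\t2\n")


def write_annotation(cohort: TrioCohort, path: str | Path) -> None:
    cols = ["chrom", "pos", "ref", "alt", "gene", "consequence", "dscore", "maf"]
    cohort.variants[cols].to_csv(path, sep="\t", index=False)


def write_gene_model(universe: pd.DataFrame, path: str | Path) -> None:
    universe.to_csv(path, sep="\t", index=False)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def write_norms(norms: pd.DataFrame, path: str | Path) -> None:
    norms.to_csv(path, sep="\t", index=False)


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    """GMT: set name, description, then tab-separated members."""
    with Path(path).open("w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + [str(m) for m in members]) + "\n")


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a}\t{b}\n")


def write_cohort(
    cohort: TrioCohort, outdir: str | Path, truth: PlantedTruth | None = None
) -> dict[str, Path]:
    """Serialise a cohort (VCF + PED + annotation, plus truth as TSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "ped": outdir / "cohort.ped",
        "annotation": outdir / "annotation.tsv",
    }
    write_vcf(cohort, paths["vcf"])
    write_ped(cohort, paths["ped"])
    write_annotation(cohort, paths["annotation"])
    if truth is not None:
        p = outdir / "planted_truth.tsv"
        with p.open("w") as fh:
            fh.write("kind\ttrio_id\tgene\tvariants\n")
            for t, v in truth.dnv_list:
                fh.write(f"dnv\t{t}\t.\t{v}\n")
            for t, g, (v1, v2) in truth.ch_list:
                fh.write(f"ch\t{t}\t{g}\t{v1},{v2}\n")
            for t, g, v in truth.hom_list:
                fh.write(f"hom\t{t}\t{g}\t{v}\n")
        paths["truth"] = p
    return paths
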