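"""End-to-end study flow: inputs -> groups -> variants -> enrichment -> report.

The full analysis mirrors the study design: normalize whole-blood
serotonin and split probands into High-/Normal-5HT groups; call de novo
variants and recessively acting variants; build class-stratified gene
lists (LoF, Mis-D2, combined functional) per group, restricted to genes
expressed in early brain development (RPKM > 1); test each list against
gene sets with the length-matched resampling null and against seed sets
with network propagation; and run the group-wise TDT on pathway gene
groups.  Every stage is a pure function of (inputs, config, seed) and
intermediate tables are written before the enrichment stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .gtdt import gtdt as run_gtdt, read_gene_groups
from . import network_propagation as netprop
from . import rav as rav_mod
from . import serotonin as ser
from . import set_enrichment as enr
from . import trio_variants as tv
from .cohort import TrioCohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    vcf: str
    ped: str
    annotation: str
    phenotypes: str
    norms: str
    gene_model: str
    gene_sets: str | None = None  # GMT
    seed_sets: str | None = None  # GMT of network seed sets
    network: str | None = None  # edge-list TSV
    gene_groups: str | None = None  # gene/group TSV for the gTDT
    out_dir: str = "endotrio_out"
    # thresholds
    min_mean_depth: float = 10.0
    min_member_depth: int = 6
    maf_max: float = 0.01
    dscore_dnv: int = 2
    dscore_gtdt: int = 4
    rpkm_threshold: float = 1.0
    high_cut: float = ser.HIGH_CUT
    normal_cut: float = ser.NORMAL_CUT
    interval: int = 100
    n_null: int = 1000
    alpha: float = 0.3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class AnalysisReport:
    """Tables produced by a full run; every p carries n_null and seed."""

    groups: pd.DataFrame
    dnvs: pd.DataFrame
    ravs: pd.DataFrame
    gene_lists: dict[str, list[str]]
    gsea: pd.DataFrame
    ngsea: pd.DataFrame
    rav_per_gene: pd.DataFrame
    gtdt: pd.DataFrame
    manifest: dict


def _stage(name):
    logger.info("stage: %s", name)


def dnv_gene_lists(
    dnv_frame: pd.DataFrame,
    group_of: Mapping[str, str],
    dscore_min: int = 2,
) -> dict[str, list[str]]:
    """Class-stratified DNV gene lists per 5-HT group (and overall).

    Lists are ``<group>_<class>`` with class in ``lof``, ``mis`` (missense
    with DScore >= ``dscore_min``) and ``func`` (union of the two).
    """
    if dnv_frame.empty:
        return {}
    frame = dnv_frame.copy()
    frame["group"] = [group_of.get(t, "Ungrouped") for t in frame["trio_id"]]
    out: dict[str, list[str]] = {}
    for scope, sub in [("all", frame)] + [
        (g, frame[frame["group"] == g]) for g in ("High", "Normal")
    ]:
        lof = sub.loc[sub["func_class"] == "LoF", "gene"]
        mis = sub.loc[
            (sub["func_class"] == "missense") & (sub["dscore"] >= dscore_min), "gene"
        ]
        out[f"{scope}_lof"] = sorted(set(lof))
        out[f"{scope}_mis"] = sorted(set(mis))
        out[f"{scope}_func"] = sorted(set(lof) | set(mis))
    return out


def analyze_cohort(
    cohort: TrioCohort,
    phenotypes: pd.DataFrame,
    norms: pd.DataFrame,
    gene_model: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]] | None = None,
    seed_sets: Mapping[str, Sequence[str]] | None = None,
    network=None,
    gene_groups: Mapping[str, Sequence[str]] | None = None,
    config: RunConfig | None = None,
) -> AnalysisReport:
    """Run the full analysis on in-memory inputs."""
    cfg = config or RunConfig(vcf="", ped="", annotation="", phenotypes="", norms="", gene_model="")
    rng = np.random.default_rng(cfg.seed)

    _stage("serotonin normalization and grouping")
    pheno = ser.normalize_serotonin(phenotypes, norms)
    probands = pheno[pheno["role"] == "proband"] if "role" in pheno else pheno
    group_of = dict(zip(probands.get("trio_id", probands["subject_id"]), probands["group"]))

    _stage("site and genotype QC")
    filtered = tv.mask_low_depth(
        tv.apply_site_filters(cohort, cfg.min_mean_depth), cfg.min_member_depth
    )

    _stage("de novo detection")
    dnvs = tv.dnv_table(tv.detect_dnv(filtered))
    lists = dnv_gene_lists(dnvs, group_of, cfg.dscore_dnv)

    if "rpkm" in gene_model.columns:
        _stage("expression filter")
        expr = gene_model[["gene", "rpkm"]]
        lists = {k: tv.expression_filter(v, expr, cfg.rpkm_threshold) for k, v in lists.items()}

    _stage("recessively acting variants")
    rav_calls = rav_mod.detect_ravs(filtered, cfg.maf_max, cfg.dscore_dnv)
    ravs = rav_mod.rav_table(rav_calls)
    group_frame = pd.DataFrame(
        {
            "proband_id": cohort.trios["child_id"],
            "group": [group_of.get(t, "Excluded") for t in cohort.trios["trio_id"]],
        }
    )
    have_both = {"High", "Normal"} <= set(group_frame["group"])
    rav_per_gene = (
        rav_mod.gene_carrier_counts(rav_calls, group_frame)
        if rav_calls and have_both
        else pd.DataFrame()
    )

    index = enr.GeneLengthIndex(gene_model)
    gsea_rows, ngsea_rows = [], []
    if gene_sets:
        _stage("length-matched gene-set enrichment")
        for list_name, cand in lists.items():
            if not cand:
                continue
            for set_name, members in gene_sets.items():
                res = enr.gsea(
                    cand, members, index, cfg.n_null, cfg.interval, rng, set_name
                )
                gsea_rows.append({"gene_list": list_name, **res.as_dict()})
    if seed_sets and network is not None:
        _stage("network-propagation enrichment")
        for list_name, cand in lists.items():
            if not cand:
                continue
            for set_name, seeds in seed_sets.items():
                res = netprop.ngsea(
                    cand, seeds, network, index, cfg.n_null, cfg.interval,
                    cfg.alpha, rng, set_name,
                )
                ngsea_rows.append({"gene_list": list_name, **res.as_dict()})

    gtdt_rows = []
    if gene_groups:
        _stage("group-wise TDT")
        for name, members in gene_groups.items():
            gtdt_rows.append(
                run_gtdt(filtered, members, cfg.maf_max, cfg.dscore_gtdt, name)
            )
        # combined analysis over all groups pooled
        pooled = sorted({g for members in gene_groups.values() for g in members})
        gtdt_rows.append(
            run_gtdt(filtered, pooled, cfg.maf_max, cfg.dscore_gtdt, "combined")
        )

    n_tests = len(gsea_rows) + len(ngsea_rows)
    manifest = {
        "seed": cfg.seed,
        "n_null": cfg.n_null,
        "interval": cfg.interval,
        "alpha": cfg.alpha,
        "thresholds": {
            "min_mean_depth": cfg.min_mean_depth,
            "min_member_depth": cfg.min_member_depth,
            "maf_max": cfg.maf_max,
            "dscore_dnv": cfg.dscore_dnv,
            "dscore_gtdt": cfg.dscore_gtdt,
            "rpkm_threshold": cfg.rpkm_threshold,
            "z_cuts": [cfg.normal_cut, cfg.high_cut],
        },
        "n_enrichment_tests": n_tests,
        "multiple_testing": "none (nominal p values)",
    }
    return AnalysisReport(
        groups=pheno,
        dnvs=dnvs,
        ravs=ravs,
        gene_lists=lists,
        gsea=pd.DataFrame(gsea_rows),
        ngsea=pd.DataFrame(ngsea_rows),
        rav_per_gene=rav_per_gene,
        gtdt=pd.concat(gtdt_rows, ignore_index=True) if gtdt_rows else pd.DataFrame(),
        manifest=manifest,
    )


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Read all configured inputs, run the analysis, write the report."""
    _stage("reading inputs")
    cohort = tv.read_trio_cohort(config.vcf, config.ped, config.annotation)
    pheno = pd.read_csv(config.phenotypes, sep="\t")
    if "trio_id" not in pheno.columns:
        raise ValueError("phenotype table needs a trio_id column")
    norms = pd.read_csv(config.norms, sep="\t")
    gene_model = pd.read_csv(config.gene_model, sep="\t")
    gene_sets = enr.read_gmt(config.gene_sets) if config.gene_sets else None
    seed_sets = enr.read_gmt(config.seed_sets) if config.seed_sets else None
    network = netprop.read_edge_list(config.network) if config.network else None
    groups = read_gene_groups(config.gene_groups) if config.gene_groups else None

    report = analyze_cohort(
        cohort, pheno, norms, gene_model, gene_sets, seed_sets, network, groups, config
    )
    write_report(report, config.out_dir)
    return report


def write_report(report: AnalysisReport, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.groups.to_csv(out / "serotonin_groups.tsv", sep="\t", index=False)
    report.dnvs.to_csv(out / "dnvs.tsv", sep="\t", index=False)
    report.ravs.to_csv(out / "ravs.tsv", sep="\t", index=False)
    with (out / "gene_lists.json").open("w") as fh:
        json.dump(report.gene_lists, fh, indent=1, sort_keys=True)
    for name in ("gsea", "ngsea", "rav_per_gene", "gtdt"):
        frame = getattr(report, name)
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    with (out / "run_manifest.json").open("w") as fh:
        json.dump(report.manifest, fh, indent=1, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# planted-contrast simulation (used by the validation suite and examples)
# ---------------------------------------------------------------------------


def simulate_planted_contrast(
    seed: int,
    n_trios: int = 100,
    n_genes: int = 1200,
    module_size: int = 15,
    n_seed_genes: int = 25,
    n_null: int = 200,
    dnv_rate: float = 1.5,
    planted: bool = True,
) -> dict:
    """One end-to-end run where High-5HT probands carry module-adjacent DNVs.

    Builds a gene universe and a network with a module wired next to a
    seed gene set, assigns High/Normal groups from a simulated serotonin
    mixture, plants the High probands' de novo variants inside the
    module (Normal probands draw theirs uniformly elsewhere), and runs
    the network enrichment for each group's DNV gene list against the
    seed set.  With ``planted=False`` the High probands draw uniformly
    too (global null).  Returns the two empirical p-values.
    """
    from . import synthetic_data as syn

    rng = np.random.default_rng(seed)
    universe = syn.generate_gene_universe(n_genes, seed=int(rng.integers(2**31)))
    gene_names = universe["gene"].tolist()
    seeds = gene_names[:n_seed_genes]
    module = gene_names[n_seed_genes : n_seed_genes + module_size]
    network = syn.generate_network(
        n_genes,
        attachment=2,
        planted_module=module,
        seed=int(rng.integers(2**31)),
        genes=gene_names,
        anchor_genes=seeds,
    )

    spec = syn.CohortSpec(
        n_trios=n_trios,
        n_genes=n_genes,
        dnv_rate=dnv_rate,
        ch_rate=0.0,
        hom_rate=0.0,
        background_sites_per_gene=0.2,
        high5ht_fraction=0.28,
        seed=int(rng.integers(2**31)),
    )
    # decide groups first so the DNV gene pools can depend on them
    trios = pd.DataFrame(
        {"trio_id": [f"fam{i + 1:04d}" for i in range(n_trios)],
         "father_id": [f"fam{i + 1:04d}.fa" for i in range(n_trios)],
         "mother_id": [f"fam{i + 1:04d}.mo" for i in range(n_trios)],
         "child_id": [f"fam{i + 1:04d}.p1" for i in range(n_trios)],
         "child_sex": "male"}
    )
    norms = syn.default_norms()
    subjects = syn.make_subjects(trios, norms, seed=int(rng.integers(2**31)))
    pheno = syn.generate_serotonin(
        subjects, norms, spec.high5ht_fraction, seed=int(rng.integers(2**31))
    )
    pheno = ser.normalize_serotonin(pheno, norms)
    probands = pheno[pheno["role"] == "proband"]
    group_of = dict(zip(probands["trio_id"], probands["group"]))

    non_module = np.array([g for g in gene_names if g not in set(module) | set(seeds)])
    pools = {}
    for t in range(n_trios):
        if planted and group_of.get(trios["trio_id"][t]) == "High":
            pools[t] = module
        else:
            pools[t] = non_module
    cohort, _ = syn.generate_trio_cohort(spec, universe, dnv_gene_pools=pools)

    dnvs = tv.dnv_table(tv.detect_dnv(tv.mask_low_depth(tv.apply_site_filters(cohort))))
    lists = dnv_gene_lists(dnvs, group_of)
    index = enr.GeneLengthIndex(universe)
    out = {}
    for grp in ("High", "Normal"):
        cand = lists.get(f"{grp}_func", [])
        if not cand:
            out[f"{grp.lower()}_p"] = float("nan")
            continue
        res = netprop.ngsea(
            cand, seeds, network, index, n_null=n_null,
            seed=np.random.default_rng(int(rng.integers(2**31))),
        )
        out[f"{grp.lower()}_p"] = res.empirical_p
    return out
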