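"""End-to-end workflow: simulate or load a dataset, then run the full
community-response analysis and write a reproducible report bundle.

Stages, in order: (1) Pearson-similarity clustering with bootstrap supports
and permutation-tested percent dissimilarity for the total community and
each requested taxon subset with more than ``min_otus`` OTUs; (2)
rarefaction curves and rarefied diversity indices per group; (3) the
diversity-reduction summary at the configured depth; (4) the taxonomy
sweep with the enriched/diminished responder reports; (5) optionally a
compressed responder phylogeny from an aligned FASTA.  Every number in the
bundle is reproducible from the config plus seed; the run log records the
seed and library versions (and no timestamps, so identical runs produce
byte-identical output).

With three replicates per group the exhaustive two-group permutation test
within one soil has only C(6,3)/2 = 10 distinct partitions, so the smallest
attainable p is 0.1; the report states this next to each such test, and a
soil-stratified test pooling both soils (treatment labels permuted within
soil) is run alongside, where 200 partitions make p <= 0.05 attainable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .otu_report import (
    OtuTable,
    SampleGroups,
    read_metadata,
    read_otu_report,
    write_metadata,
    write_otu_report,
)
from .compare import bootstrap_support, dissimilarity_d, pearson_similarity, permutation_test_d
from .diversity import diversity_reduction, group_rarefied_table, rarefaction_curve, AbundanceVector
from .synthetic import CommunitySpec, simulate_dataset
from .taxa import diminished_otus, enriched_taxa, sweep_taxonomy
from .phylo import bootstrap_tree, compress_branches, read_alignment


@dataclass
class PipelineConfig:
    """Settings of one pipeline run (JSON-serializable)."""

    out_dir: str = "soilshift_out"
    seed: int = 0
    # simulation mode (used when otu_report is None)
    simulate: bool = True
    study_emulation: bool = True
    spec_overrides: dict = field(default_factory=dict)
    # input mode
    otu_report: str | None = None
    metadata: str | None = None
    dgge: str | None = None
    alignment: str | None = None
    # analysis settings
    taxon_subsets: list[str] = field(default_factory=list)  # e.g. "class=Class01"
    min_otus: int = 50
    n_boot: int = 500
    n_perm: int = 9999
    rarefaction_depth: int = 400
    alpha: float = 0.05
    compress_threshold: float = 0.03
    tree_model: str = "JC69"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _structure_block(
    profiles, label: str, groups: SampleGroups, cfg: PipelineConfig, out: Path, log: dict
) -> None:
    """Similarity, bootstrap UPGMA and permutation-tested d for one profile set."""
    sim = pearson_similarity(profiles)
    sim.to_frame().round(4).to_csv(out / f"similarity_{label}.csv")
    dend = bootstrap_support(profiles, n_boot=cfg.n_boot, seed=cfg.seed)
    dend.write_newick(out / f"dendrogram_{label}.nwk")
    rows = []
    for soil in groups.soils:
        control = groups.samples_for(soil, SampleGroups.CONTROL)
        spiked = groups.samples_for(soil, SampleGroups.SPIKED)
        control = [s for s in control if s in sim.sample_ids]
        spiked = [s for s in spiked if s in sim.sample_ids]
        if len(control) < 2 or len(spiked) < 2:
            continue
        res = permutation_test_d(
            profiles, spiked, control, n_perm=cfg.n_perm, seed=cfg.seed
        )
        rows.append(
            {
                "comparison": f"{soil}: spiked vs control",
                "d": res.observed_d,
                "p": res.p_value,
                "n_partitions": res.n_partitions,
                "mode": res.mode,
                "min_attainable_p": res.min_attainable_p,
                "note": (
                    f"min attainable p = {res.min_attainable_p:.3g}; "
                    "not significant at 0.05 by design"
                    if res.min_attainable_p > cfg.alpha
                    else ""
                ),
            }
        )
    # pooled treatment test, permuting treatment labels within soils
    spiked_all = [
        s
        for soil in groups.soils
        for s in groups.samples_for(soil, SampleGroups.SPIKED)
        if s in sim.sample_ids
    ]
    control_all = [
        s
        for soil in groups.soils
        for s in groups.samples_for(soil, SampleGroups.CONTROL)
        if s in sim.sample_ids
    ]
    if len(spiked_all) >= 2 and len(control_all) >= 2:
        strata = {
            s: str(groups.frame.loc[s, "soil"]) for s in spiked_all + control_all
        }
        res = permutation_test_d(
            profiles,
            spiked_all,
            control_all,
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            strata=strata,
        )
        rows.append(
            {
                "comparison": "both soils: spiked vs control (within-soil permutations)",
                "d": res.observed_d,
                "p": res.p_value,
                "n_partitions": res.n_partitions,
                "mode": res.mode,
                "min_attainable_p": res.min_attainable_p,
                "note": "",
            }
        )
    pd.DataFrame(rows).to_csv(out / f"d_tests_{label}.tsv", sep="\t", index=False)
    log.setdefault("structure", []).append(label)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full workflow; returns the run log (also written to
    ``run_log.json`` in the output directory)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "versions": _versions(),
    }

    dgge = None
    if cfg.otu_report is None:
        if not cfg.simulate:
            raise ValueError("stage input: no otu_report given and simulate=False")
        overrides = dict(cfg.spec_overrides)
        if "enriched" in overrides or "diminished" in overrides:
            raise ValueError("plant effects via study_emulation, not raw overrides")
        spec = (
            CommunitySpec.study_emulation(**overrides)
            if cfg.study_emulation
            else CommunitySpec(**overrides)
        )
        ds = simulate_dataset(spec, cfg.seed)
        table, groups, dgge = ds.table, ds.groups, ds.dgge
        write_otu_report(table, out / "otu_report.tsv")
        write_metadata(groups, out / "metadata.tsv")
        dgge.round(6).to_csv(out / "dgge.csv")
        ds.truth.to_json(out / "ground_truth.json")
        log["mode"] = "simulation"
    else:
        if cfg.metadata is None:
            raise ValueError("stage input: metadata required with otu_report")
        table = read_otu_report(cfg.otu_report)
        groups = read_metadata(cfg.metadata)
        if cfg.dgge:
            dgge = pd.read_csv(cfg.dgge, index_col=0)
        log["mode"] = "input"
    groups.check_samples(table.sample_ids)

    # (1) community structure: total, requested subsets, gel profiles
    _structure_block(table, "total", groups, cfg, out, log)
    for spec_str in cfg.taxon_subsets:
        rank, _, name = spec_str.partition("=")
        sub = table.subset_by_taxon(rank.strip(), name.strip())
        if sub.n_otus <= cfg.min_otus:
            log.setdefault("skipped_subsets", []).append(
                f"{spec_str} ({sub.n_otus} OTUs <= min_otus={cfg.min_otus})"
            )
            continue
        _structure_block(sub, f"{rank}_{name}", groups, cfg, out, log)
    if dgge is not None:
        _structure_block(dgge, "dgge", groups, cfg, out, log)

    # (2) rarefaction curves + rarefied indices
    curves = []
    for s in table.sample_ids:
        vec = AbundanceVector(table.counts[s].to_numpy())
        rc = rarefaction_curve(vec)
        curves.append(
            pd.DataFrame(
                {"sample_id": s, "depth": rc.depths, "expected_richness": rc.expected}
            )
        )
    pd.concat(curves).to_csv(out / "rarefaction_curves.tsv", sep="\t", index=False)
    idx_table = group_rarefied_table(
        table, groups, depth=cfg.rarefaction_depth, seed=cfg.seed
    )
    idx_table.to_csv(out / "rarefied_indices.tsv", sep="\t", index=False)

    # (3) diversity reduction per soil
    red_rows = []
    for soil in groups.soils:
        control = table.counts[groups.samples_for(soil, SampleGroups.CONTROL)]
        spiked = table.counts[groups.samples_for(soil, SampleGroups.SPIKED)]
        try:
            pct = diversity_reduction(control, spiked, depth=cfg.rarefaction_depth)
        except ValueError as exc:
            log.setdefault("warnings", []).append(f"diversity_reduction {soil}: {exc}")
            continue
        red_rows.append(
            {"soil": soil, "depth": cfg.rarefaction_depth, "reduction_pct": pct}
        )
    pd.DataFrame(red_rows).to_csv(out / "diversity_reduction.tsv", sep="\t", index=False)

    # (4) taxonomy sweep + responder reports
    sweep = sweep_taxonomy(table, groups)
    sweep.round(6).to_csv(out / "sweep.tsv", sep="\t", index=False)
    enr = enriched_taxa(sweep, groups, alpha=cfg.alpha)
    for soil, frame in enr.enriched.items():
        frame.round(6).to_csv(out / f"enriched_{soil}.tsv", sep="\t", index=False)
    enr.common_enriched.to_csv(out / "enriched_common.tsv", sep="\t", index=False)
    dim = diminished_otus(table, groups, alpha=cfg.alpha)
    for soil, frame in dim.diminished.items():
        frame.round(6).to_csv(out / f"diminished_{soil}.tsv", sep="\t", index=False)
    log["n_enriched"] = {s: int(len(f)) for s, f in enr.enriched.items()}
    log["n_common_enriched"] = int(len(enr.common_enriched))
    log["n_diminished"] = {s: int(len(f)) for s, f in dim.diminished.items()}

    # (5) optional responder phylogeny
    if cfg.alignment:
        aln = read_alignment(cfg.alignment)
        tree = bootstrap_tree(aln, n_boot=cfg.n_boot, seed=cfg.seed, model=cfg.tree_model)
        compressed = compress_branches(tree, cfg.compress_threshold)
        compressed.write(str(out / "responder_tree.nwk"), format="newick")
        log["tree_leaves"] = sum(1 for _ in compressed.tips()) or 1

    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return log


def _versions() -> dict:
    import scipy
    import skbio
    import statsmodels

    return {
        "soilshift": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-bio": skbio.__version__,
    }
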