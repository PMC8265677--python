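"""Stage orchestration: simulate -> ingest -> classify -> dynamics ->
profiles / nucleosome / qpcr -> report.

Configuration is a flat YAML mapping validated against the known keys; a
full echo of the effective configuration goes into the run log so every
threshold is auditable. All outputs are plain TSV/JSON twins of the
figures they correspond to, and reruns with the same config and inputs
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import classify, dynamics, gene_profiles, modcalls, nucleosome, qpcr
from .genome_io import read_fasta, read_gff3_genes, write_fasta, write_gff3_genes
from .synthetic import SimConfig, simulate_callsets, simulate_ct, simulate_expression, simulate_genome, simulate_mnase

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ingest", "classify", "dynamics", "profiles", "nucleosome", "qpcr", "report")

_DEPENDS = {
    "simulate": (),
    "ingest": (),
    "classify": ("ingest",),
    "dynamics": ("classify",),
    "profiles": ("classify",),
    "nucleosome": ("classify",),
    "qpcr": (),
    "report": ("classify",),
}

DEFAULTS: dict = {
    "outdir": "sixma_out",
    "genome_fasta": None,
    "genes_gff3": None,
    "calls_gff_veg": None,
    "calls_gff_s24": None,
    "mnase_bed": None,
    "expression_tsv": None,
    "ct_csv": None,
    "exclude_chromosomes": [],
    "seed": 0,
    "min_qv": 30.0,
    "min_cov": 25.0,
    "target_cov": 100.0,
    "level_window": 1000,
    "tss_window": [-1000, 2000],
    "metagene_min_len": 1000,
    "metagene_bin": 0.05,
    "deg_padj": 0.05,
    "deg_lfc": 2.0,
    "induced_gates": [300, 1500],
    "top_frac": 0.10,
    "frag_min_len": 120,
    "frag_max_len": 180,
    "nucleosome.window": [-500, 1500],
    "nucleosome.smooth": 31,
    "nucleosome.spacing_guess": 200,
    "nucleosome.peak_window": 250,
    "nucleosome.k_max": 5,
    "retain_threshold": 1.0,
}


class PipelineConfig(dict):
    """Validated flat configuration; unknown keys are rejected."""

    def __init__(self, overrides: dict | None = None):
        super().__init__(DEFAULTS)
        for key, value in (overrides or {}).items():
            if key not in DEFAULTS:
                raise KeyError(f"unknown configuration key {key!r}")
            self[key] = value

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a flat key: value mapping")
        return cls(data)


def run(config: PipelineConfig, stages: list[str]) -> dict:
    """Run the requested stages in dependency order; returns the report."""
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    requested = set(stages)
    for stage in requested:
        for dep in _DEPENDS[stage]:
            if dep not in requested:
                raise ValueError(f"stage {stage!r} requires stage {dep!r} to run first")
    ordered = [s for s in STAGES if s in requested]

    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("sixma")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("effective config: %s", json.dumps(dict(config), sort_keys=True))

    state: dict = {}
    report: dict = {"stages": ordered}
    try:
        for stage in ordered:
            logger.info("stage %s", stage)
            _RUNNERS[stage](config, outdir, state, report)
    finally:
        root.removeHandler(handler)
        handler.close()
    return report


def _stage_simulate(config, outdir, state, report) -> None:
    sim = SimConfig(seed=int(config["seed"]))
    genome, genes = simulate_genome(sim)
    fragments, dyad_truth = simulate_mnase(sim, genome, genes)
    cs_a, cs_b, truth = simulate_callsets(sim, genome, dyad_truth)

    write_fasta(genome, outdir / "genome.fa")
    write_gff3_genes(genes, outdir / "genes.gff3")
    modcalls.write_modifications_gff(cs_a, outdir / "calls_veg.gff")
    modcalls.write_modifications_gff(cs_b, outdir / "calls_s24.gff")
    fragments.to_csv(outdir / "mnase_fragments.bed", sep="\t", header=False, index=False)
    truth.duplexes.to_csv(outdir / "truth_duplexes.tsv", sep="\t", index=False)
    truth.nonapt.to_csv(outdir / "truth_nonapt.tsv", sep="\t", index=False)
    dyad_truth.to_csv(outdir / "truth_dyads.tsv", sep="\t", index=False)

    ca = classify.classify_sites(cs_a, genome)
    cb = classify.classify_sites(cs_b, genome)
    window = (0, int(config["level_window"]))
    amt_a = gene_profiles.amounts_for_genes(ca, genes, window)
    amt_b = gene_profiles.amounts_for_genes(cb, genes, window)
    expression = simulate_expression(sim, amt_b - amt_a)
    expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)

    transitions = dynamics.match_conditions(ca, cb)
    conv = dynamics.select_conversion_gatc_sites(transitions, genome, "conversion")
    ret = dynamics.select_conversion_gatc_sites(transitions, genome, "retain")
    conv_ids = [f"{c}:{p + 1}" for c, p in conv[:4]] or ["C1"]
    ret_ids = [f"{c}:{p + 1}" for c, p in ret[:1]] or ["R1"]
    simulate_ct(sim, conv_ids, ret_ids).to_csv(outdir / "ct.csv", index=False)

    config["genome_fasta"] = str(outdir / "genome.fa")
    config["genes_gff3"] = str(outdir / "genes.gff3")
    config["calls_gff_veg"] = str(outdir / "calls_veg.gff")
    config["calls_gff_s24"] = str(outdir / "calls_s24.gff")
    config["mnase_bed"] = str(outdir / "mnase_fragments.bed")
    config["expression_tsv"] = str(outdir / "expression.tsv")
    config["ct_csv"] = str(outdir / "ct.csv")
    report["simulate"] = {"n_genes": len(genes), "n_calls_veg": len(cs_a), "n_calls_s24": len(cs_b)}


def _require(config, key, stage) -> str:
    if not config.get(key):
        raise ValueError(f"stage {stage!r} needs config {key!r}; run 'simulate' or point it at an input")
    return config[key]


def _stage_ingest(config, outdir, state, report) -> None:
    genome = read_fasta(_require(config, "genome_fasta", "ingest"))
    if config["exclude_chromosomes"]:
        genome = genome.drop(config["exclude_chromosomes"])
    state["genome"] = genome
    state["genes"] = read_gff3_genes(_require(config, "genes_gff3", "ingest"), genome)
    for cond, key in (("veg", "calls_gff_veg"), ("s24", "calls_gff_s24")):
        cs = modcalls.read_modifications_gff(_require(config, key, "ingest"), genome,
                                             label=cond.upper())
        cs = modcalls.normalize_coverage(cs, float(config["target_cov"]))
        cs = modcalls.filter_calls(cs, float(config["min_qv"]), float(config["min_cov"]))
        modcalls.write_calls(cs, outdir / f"calls_{cond}.filtered.tsv")
        state[f"calls_{cond}"] = cs
    report["ingest"] = {
        "n_filtered_veg": len(state["calls_veg"]), "n_filtered_s24": len(state["calls_s24"])
    }


def _stage_classify(config, outdir, state, report) -> None:
    report["composition"] = {}
    for cond in ("veg", "s24"):
        cl = classify.classify_sites(state[f"calls_{cond}"], state["genome"])
        state[f"classified_{cond}"] = cl
        summary = classify.summarize_composition(cl, state["genome"])
        summary.to_frame().to_csv(outdir / f"composition_{cond}.tsv", sep="\t", index=False)
        apt, non_apt = classify.apt_fraction(summary)
        report["composition"][cond] = {
            "total": summary.total,
            "class_pct": summary.class_pct,
            "level_pct": summary.level_pct,
            "density": summary.density,
            "apt_pct": apt,
            "non_apt_pct": non_apt,
        }
        dens = classify.chromosome_density(cl, state["genome"])
        dens.to_csv(outdir / f"density_{cond}.tsv", sep="\t", index=False)
        classify.motif_matrix(cl, state["genome"]).to_csv(outdir / f"motif_{cond}.tsv", sep="\t")


def _stage_dynamics(config, outdir, state, report) -> None:
    transitions = dynamics.match_conditions(state["classified_veg"], state["classified_s24"])
    state["transitions"] = transitions
    matrix = dynamics.transition_matrix(transitions)
    matrix.to_csv(outdir / "transition_matrix.tsv", sep="\t")
    change = dynamics.gene_l5_asym_change(
        state["classified_veg"], state["classified_s24"], state["genes"],
        int(config["level_window"]))
    state["l5_change"] = change
    for name in ("gain", "loss"):
        (Path(outdir) / f"genes_{name}_l5_asym.txt").write_text(
            "".join(f"{g}\n" for g in sorted(change[name])))
    conv = dynamics.select_conversion_gatc_sites(transitions, state["genome"], "conversion")
    with open(outdir / "conversion_sites.bed", "w") as fh:
        for chrom, p in conv:
            fh.write(f"{chrom}\t{p}\t{p + 2}\tconversion\n")
    report["dynamics"] = {
        "transition_matrix": {a: {b: int(matrix.loc[a, b]) for b in matrix.columns}
                              for a in matrix.index},
        "n_gain": len(change["gain"]), "n_loss": len(change["loss"]),
        "n_conversion_gatc": len(conv),
    }


def _stage_profiles(config, outdir, state, report) -> None:
    genes = state["genes"]
    report["profiles"] = {}
    for cond in ("veg", "s24"):
        meta = gene_profiles.metagene_profile(
            state[f"classified_{cond}"], genes,
            int(config["metagene_min_len"]), float(config["metagene_bin"]))
        meta.to_frame().to_csv(outdir / f"metagene_{cond}.tsv", sep="\t", index=False)
        tss = gene_profiles.tss_profile(state[f"classified_{cond}"], genes,
                                        tuple(config["tss_window"]))
        tss.to_frame().to_csv(outdir / f"tss_profile_{cond}.tsv", sep="\t", index=False)

    expression = gene_profiles.read_expression_table(_require(config, "expression_tsv", "profiles"))
    window = (0, int(config["level_window"]))
    expression = expression.set_index("gene_id")
    expression["amount_veg"] = gene_profiles.amounts_for_genes(state["classified_veg"], genes, window)
    expression["amount_s24"] = gene_profiles.amounts_for_genes(state["classified_s24"], genes, window)
    expression = expression.dropna(subset=["amount_veg", "amount_s24"]).reset_index()
    state["expression"] = expression

    sets = gene_profiles.classify_gene_sets(
        expression, float(config["deg_padj"]), float(config["deg_lfc"]),
        tuple(config["induced_gates"]), float(config["top_frac"]))
    state["gene_sets"] = sets
    corr_sets = {"all": None,
                 "highly_regulated": sets["highly_regulated"],
                 "starvation_responding": sets["induced"] | sets["repressed"]}
    out = {}
    for name, gs in corr_sets.items():
        try:
            r, p, n = gene_profiles.amount_expression_correlation(expression, gs)
            out[name] = {"r": r, "p": p, "n": n}
        except ValueError as exc:
            out[name] = {"error": str(exc)}
    (Path(outdir) / "correlation.json").write_text(json.dumps(out, indent=2))
    report["profiles"]["correlation"] = out
    report["profiles"]["gene_sets"] = {k: len(v) for k, v in sets.items()}


def _stage_nucleosome(config, outdir, state, report) -> None:
    fragments = nucleosome.read_bed_fragments(_require(config, "mnase_bed", "nucleosome"))
    dyads = nucleosome.fragments_to_dyads(fragments, int(config["frag_min_len"]),
                                          int(config["frag_max_len"]))
    genes = state["genes"]
    window = tuple(config["nucleosome.window"])
    smooth = int(config["nucleosome.smooth"])
    profile = nucleosome.composite_dyad_profile(dyads, genes, window, smooth)
    profile.to_frame().to_csv(outdir / "dyad_profile.tsv", sep="\t", index=False)
    rep = nucleosome.positioning_degree(
        profile, int(config["nucleosome.k_max"]),
        int(config["nucleosome.spacing_guess"]), int(config["nucleosome.peak_window"]))
    try:
        rep.periodicity = nucleosome.estimate_periodicity(profile)
    except ValueError as exc:
        rep.warnings.append(str(exc))
    (Path(outdir) / "positioning.json").write_text(json.dumps(rep.to_dict(), indent=2))
    report["nucleosome"] = rep.to_dict()

    rel = nucleosome.dyad_relative_6ma(state["classified_s24"], dyads)
    rel.to_csv(outdir / "dyad_relative_6ma.tsv", sep="\t", index=False)

    if "l5_change" in state:
        comp = nucleosome.compare_positioning(
            {"gain": state["l5_change"]["gain"], "loss": state["l5_change"]["loss"]},
            dyads, genes, int(config["nucleosome.k_max"]),
            window=window, smooth=smooth)
        payload = {name: r.to_dict() for name, r in comp["reports"].items()}
        payload.update({k: v for k, v in comp.items() if k != "reports"})
        (Path(outdir) / "positioning_by_set.json").write_text(json.dumps(payload, indent=2))
        report["nucleosome_by_set"] = payload


def _stage_qpcr(config, outdir, state, report) -> None:
    records = qpcr.read_ct_csv(_require(config, "ct_csv", "qpcr"))
    table = qpcr.qpcr_report(records, float(config["retain_threshold"]))
    table.to_csv(outdir / "qpcr_report.tsv", sep="\t", index=False)
    report["qpcr"] = table.to_dict(orient="records")


def _stage_report(config, outdir, state, report) -> None:
    (Path(outdir) / "report.json").write_text(json.dumps(report, indent=2, default=str))


_RUNNERS = {
    "simulate": _stage_simulate,
    "ingest": _stage_ingest,
    "classify": _stage_classify,
    "dynamics": _stage_dynamics,
    "profiles": _stage_profiles,
    "nucleosome": _stage_nucleosome,
    "qpcr": _stage_qpcr,
    "report": _stage_report,
}


def run_all(config: PipelineConfig) -> dict:
    return run(config, list(STAGES))
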