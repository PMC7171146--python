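"""Stage orchestration.

``run_pipeline`` executes the requested analysis stages in dependency
order, reading the inputs named in a manifest and writing one TSV (or a
small set of TSVs) per stage into an output directory.  All stages are
pure functions of (inputs, config, seed), so repeated runs produce
byte-identical outputs; a filter ledger records rows in/out of every
filtering step.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import cn, io
from .classify import knn_classify, spearman_profile
from .clonotypes import diversity_per_sample
from .config import PipelineConfig
from .drivers import rank_drivers
from .enrichment import enrich_arm_events
from .genome import grch37_genome
from .ledger import FilterLedger
from .neoantigen import count_per_sample, filter_candidates
from .signatures import build_96_vector, filter_for_signatures, fit_signatures, strand_bias_table
from .simulate import (
    CohortSpec,
    simulate_clonotypes,
    simulate_cn_expression,
    simulate_mutation_catalog,
    synthetic_signature_set,
)

__all__ = ["PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("uvmtk")

STAGES = [
    "simulate",
    "cn_events",
    "enrich",
    "rank_drivers",
    "signatures",
    "classify",
    "neoantigen_filter",
    "til_diversity",
]


class PipelineError(RuntimeError):
    pass


def _need(manifest: dict, stage: str, key: str, produced: dict) -> Path:
    """Resolve an input path: explicit manifest entry, else the output of
    an earlier stage in this run; error naming the missing dependency."""
    entry = manifest.get(stage, {})
    if key in entry:
        return Path(entry[key])
    if key in produced:
        return produced[key]
    raise PipelineError(
        f"stage {stage!r}: missing input {key!r} "
        f"(supply a path or run the producing stage first)"
    )


def run_pipeline(
    config: PipelineConfig,
    manifest: dict[str, dict],
    outdir: str | Path,
) -> dict[str, Path]:
    """Run the stages named in ``manifest`` (mapping stage -> inputs).

    Returns a mapping of logical output names to written paths.  The
    filter ledger is written as ``filter_ledger.tsv``.
    """
    unknown = set(manifest) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ledger = FilterLedger()
    produced: dict[str, Path] = {}
    genome = grch37_genome()

    def emit(name: str, writer) -> Path:
        path = outdir / f"{name}.tsv"
        writer(path)
        produced[name] = path
        log.info("wrote %s", path)
        return path

    if "simulate" in manifest:
        params = dict(manifest["simulate"])
        seed = int(params.pop("seed", config.random_seed))
        spec = CohortSpec(**params)
        cohort = simulate_cn_expression(spec, seed)
        log.info("simulate: n_a=%d n_b=%d seed=%d", spec.n_a, spec.n_b, seed)
        emit("segments_a", lambda p: io.write_segments(cohort.profiles_a, p))
        emit("segments_b", lambda p: io.write_segments(cohort.profiles_b, p))
        emit("counts_a", lambda p: io.write_count_matrix(cohort.counts_a, p))
        emit("counts_b", lambda p: io.write_count_matrix(cohort.counts_b, p))
        emit("gene_models", lambda p: io.write_gene_models(cohort.gene_models, p))
        emit("purity_a", lambda p: cohort.purity_a.rename_axis("sample")
             .reset_index().to_csv(p, sep="\t", index=False))
        emit("purity_b", lambda p: cohort.purity_b.rename_axis("sample")
             .reset_index().to_csv(p, sep="\t", index=False))
        emit("survival_b", lambda p: cohort.survival_b.reset_index()
             .to_csv(p, sep="\t", index=False))
        emit("ppi_degree", lambda p: cohort.ppi_degree.rename_axis("gene")
             .reset_index().to_csv(p, sep="\t", index=False))
        emit("regions", lambda p: cohort.regions.to_csv(p, sep="\t", index=False))
        emit("truth_events", lambda p: cohort.truth_events.to_csv(p, sep="\t", index=False))
        emit("truth_drivers", lambda p: cohort.truth_drivers.to_csv(p, sep="\t", index=False))
        # companion single-sample inputs for the remaining stages
        sigs = synthetic_signature_set(seed=seed)
        emit("signature_matrix", lambda p: io.write_signature_matrix(sigs, p))
        catalog = simulate_mutation_catalog(
            [0.6, 0.3, 0.1], 10_000, sigs.iloc[:, :3], seed=seed
        )
        emit("mutations", lambda p: io.write_maf_lite(catalog, p))
        clono = simulate_clonotypes(
            concentration=1.0, n_clonotypes=50, n_cells=1000, seed=seed
        )
        emit("clonotypes", lambda p: io.write_clonotypes(clono, p))

    if "cn_events" in manifest:
        seg_a = _need(manifest, "cn_events", "segments_a", produced)
        seg_b = _need(manifest, "cn_events", "segments_b", produced)
        genes_path = _need(manifest, "cn_events", "gene_models", produced)
        genes = io.read_gene_models(genes_path)
        profiles_a = io.read_segments(seg_a)
        profiles_b = io.read_segments(seg_b)
        if not profiles_a or not profiles_b:
            raise PipelineError("no samples in segment input")
        for name, profiles in (("a", profiles_a), ("b", profiles_b)):
            mat = cn.gene_copy_matrix(profiles, genes)
            emit(f"gene_cn_{name}", lambda p, m=mat: m.rename_axis("gene").to_csv(p, sep="\t"))
            events = cn.call_arm_events(profiles, genome, config, ledger=ledger)
            emit(f"arm_events_{name}", lambda p, e=events: io.write_arm_events(e, p))

    if "enrich" in manifest:
        ev_a = io.read_arm_events(_need(manifest, "enrich", "arm_events_a", produced))
        ev_b = io.read_arm_events(_need(manifest, "enrich", "arm_events_b", produced))
        result = enrich_arm_events(ev_a, ev_b, config)
        emit("enrichment", lambda p: result.to_csv(p, sep="\t", index=False))
        log.info("enrich: %d events tested, %d enriched",
                 len(result), int(result["enriched"].sum()))

    if "rank_drivers" in manifest:
        counts_a = io.read_count_matrix(_need(manifest, "rank_drivers", "counts_a", produced))
        counts_b = io.read_count_matrix(_need(manifest, "rank_drivers", "counts_b", produced))
        cn_a = pd.read_csv(_need(manifest, "rank_drivers", "gene_cn_a", produced),
                           sep="\t", index_col=0)
        cn_b = pd.read_csv(_need(manifest, "rank_drivers", "gene_cn_b", produced),
                           sep="\t", index_col=0)
        purity_a = io.read_purity(_need(manifest, "rank_drivers", "purity_a", produced))
        purity_b = io.read_purity(_need(manifest, "rank_drivers", "purity_b", produced))
        survival_b = io.read_survival(_need(manifest, "rank_drivers", "survival_b", produced))
        ppi = io.read_ppi_degree(_need(manifest, "rank_drivers", "ppi_degree", produced))
        regions = io.read_regions(_need(manifest, "rank_drivers", "regions", produced))
        genes = io.read_gene_models(_need(manifest, "rank_drivers", "gene_models", produced))
        ranked = rank_drivers(
            counts_a, cn_a, purity_a, counts_b, cn_b, purity_b,
            regions, genes, ppi, survival_b, config, ledger=ledger,
        )
        emit("drivers", lambda p: ranked.to_csv(p, sep="\t", index=False))

    if "signatures" in manifest:
        variants = io.read_maf_lite(_need(manifest, "signatures", "mutations", produced))
        sigs = io.read_signature_matrix(
            _need(manifest, "signatures", "signature_matrix", produced)
        )
        rows = []
        for sample, grp in variants.groupby("sample"):
            kept = filter_for_signatures(grp, config, ledger=ledger)
            if kept.empty:
                continue
            fit = fit_signatures(build_96_vector(kept), sigs)
            for sig in fit.relative.index:
                rows.append({"sample": sample, "signature": sig,
                             "absolute": fit.absolute[sig],
                             "relative": fit.relative[sig],
                             "residual": fit.residual})
        contrib = pd.DataFrame(rows)
        emit("signature_contributions", lambda p: contrib.to_csv(p, sep="\t", index=False))
        bias = strand_bias_table(filter_for_signatures(variants, config))
        emit("strand_bias", lambda p: bias.to_csv(p, sep="\t", index=False))

    if "classify" in manifest:
        panel = io.read_count_matrix(_need(manifest, "classify", "panel", produced))
        labels = pd.read_csv(
            _need(manifest, "classify", "labels", produced), sep="\t"
        ).set_index("sample")["label"]
        query = io.read_count_matrix(
            _need(manifest, "classify", "query", produced)
        ).iloc[:, 0]
        result = knn_classify(query, panel, labels, k=config.knn_k)
        rho = spearman_profile(query, panel)
        out = pd.DataFrame({"rho": rho, "label": labels})
        out["predicted"] = result["label"]
        emit("classification", lambda p: out.rename_axis("sample").to_csv(p, sep="\t"))
        log.info("classify: predicted %s", result["label"])

    if "neoantigen_filter" in manifest:
        cand = pd.read_csv(
            _need(manifest, "neoantigen_filter", "candidates", produced), sep="\t"
        )
        kept = filter_candidates(cand, config, ledger=ledger)
        emit("neoantigens", lambda p: kept.to_csv(p, sep="\t", index=False))
        counts = count_per_sample(kept) if "sample" in kept.columns else pd.Series(dtype=int)
        emit("neoantigen_counts", lambda p: counts.rename_axis("sample")
             .reset_index().to_csv(p, sep="\t", index=False))

    if "til_diversity" in manifest:
        table = io.read_clonotypes(
            _need(manifest, "til_diversity", "clonotypes", produced)
        ).set_index("cell")
        label_filter = manifest["til_diversity"].get("label_filter", "CD8")
        div = diversity_per_sample(table, label_filter=label_filter)
        emit("til_diversity", lambda p: div.to_csv(p, sep="\t", index=False))

    ledger.write(outdir / "filter_ledger.tsv")
    produced["filter_ledger"] = outdir / "filter_ledger.tsv"
    return produced
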