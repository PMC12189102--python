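"""End-to-end orchestration: simulate -> qc -> annotate -> hotspots ->
enrich -> repeats -> fst -> ld, with a machine-readable run manifest.

A single YAML/dict config drives the run; every stage reads the files the
previous stage wrote (so the format readers are exercised), and the
manifest records a SHA-256 checksum of every output so silent changes in
intermediates are detectable.  Stages run in dependency order; a failure
halts the run with a partial manifest.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from pathlib import Path

import pandas as pd

from . import (
    genomic_annotation,
    hotspot_scan,
    ld_tagging,
    popgen_fst,
    region_enrichment,
    repeat_content,
    synthetic_data,
    variant_qc,
)
from .io_formats import (
    read_bed,
    read_genome_tsv,
    read_gff_genes,
    read_repeatmasker_out,
    read_vcf,
    write_bed,
    write_vcf,
)

log = logging.getLogger("svscape.pipeline")

DECISIONS_METADATA = {
    "breakpoint_convention": "DEL=2 junctions, INS=1 anchor",
    "top_rank_ties": "included at the threshold value",
    "fst_estimators": {"small_medium": "weir_cockerham_1984 (windowed ratio-of-sums)",
                       "large": "hudson_bhatia_frequency"},
    "ld_statistic": "composite r2 (squared Pearson correlation of dosages)",
    "randomization": "per-element uniform re-placement on the original chromosome, "
                     "length preserved",
    "te_coverage": "union (merged-interval) semantics, longest-element driver",
}

DEFAULT_CONFIG = {
    "seed": 17,
    "out_dir": "svscape_run",
    "simulate": {},           # SimConfig overrides; omit key to use existing inputs
    "inputs": {},             # vcf/pops/qtl/gff/... paths when not simulating
    "n_perm": 100,
    "top_frac": 0.01,
    "bin_size": 100_000,
    "fst_window": 50_000,
    "fst_step": 20_000,
    "ld_window": 1_000_000,
    "pairs": None,            # list of [pop_a, pop_b]; None = all pairs
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_pop_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["pop"]))


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"config": {k: v for k, v in cfg.items()},
                      "seed": seed, "decisions": DECISIONS_METADATA, "stages": []}

    def record(stage: str, outputs: dict[str, Path], meta: dict | None = None):
        manifest["stages"].append({
            "stage": stage,
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                        for k, p in outputs.items()},
            **({"meta": meta} if meta else {})})
        log.info("stage %s done (%d outputs)", stage, len(outputs))

    try:
        # ---- stage: simulate (or locate inputs) -------------------------
        if cfg.get("simulate") is not None:
            sim_cfg = synthetic_data.SimConfig(seed=seed, **cfg["simulate"])
            sim_dir = out / "inputs"
            cohort = synthetic_data.simulate_cohort(sim_cfg, out_dir=sim_dir)
            inputs = cohort.paths
            record("simulate", {k: Path(v) for k, v in inputs.items()})
        else:
            inputs = dict(cfg["inputs"])

        layout = read_genome_tsv(inputs["genome"])
        pop_map = read_pop_map(inputs["pops"])

        # ---- stage: qc --------------------------------------------------
        table = read_vcf(inputs["vcf"], layout=layout)
        missing = set(table.samples) - set(pop_map)
        if missing:
            raise ValueError(f"samples without population assignment: {sorted(missing)}")
        table, qc_report = variant_qc.qc_pipeline(table, pop_map=pop_map)
        filtered_vcf = out / "filtered.vcf"
        write_vcf(table, filtered_vcf, layout)
        qc_path = out / "qc_report.json"
        qc_path.write_text(json.dumps(qc_report, indent=1, sort_keys=True))
        record("qc", {"filtered_vcf": filtered_vcf, "report": qc_path},
               meta=qc_report)

        # ---- stage: annotate -------------------------------------------
        models = read_gff_genes(inputs["gff"])
        region_calls = genomic_annotation.classify_variants(table, models)
        regions_path = out / "regions.tsv"
        region_calls.to_csv(regions_path, sep="\t", index=False)
        summary = genomic_annotation.region_summary(
            region_calls[region_calls["vtype"] != "SNP"])
        summary_path = out / "region_summary.tsv"
        summary.to_csv(summary_path, sep="\t", index=False, float_format="%.4f")
        record("annotate", {"regions": regions_path, "summary": summary_path})

        # ---- stage: hotspots -------------------------------------------
        qtl = read_bed(inputs["qtl"], name="qtl")
        bins = hotspot_scan.count_breakpoints(table, layout,
                                              bin_size=int(cfg["bin_size"]))
        hotspots = hotspot_scan.call_hotspots(bins, top_frac=float(cfg["top_frac"]))
        hs_bed = out / "hotspots.bed"
        write_bed(hotspots.track(), hs_bed)
        hs_qtl = hotspot_scan.hotspot_qtl_overlap(hotspots, qtl)
        hs_qtl_path = out / "hotspot_qtl.tsv"
        hs_qtl.to_csv(hs_qtl_path, sep="\t", index=False)
        record("hotspots", {"bed": hs_bed, "qtl_overlap": hs_qtl_path},
               meta={"threshold_count": hotspots.threshold_count,
                     "n_hotspots": len(hotspots),
                     "total_breakpoints": bins.total_breakpoints})

        # ---- stage: enrich ----------------------------------------------
        enrich = region_enrichment.enrichment_by_group(
            table, qtl, layout, n_perm=int(cfg["n_perm"]), seed=seed)
        enrich_path = out / "enrichment_qtl.tsv"
        enrich.to_csv(enrich_path, sep="\t", index=False, float_format="%.6g")
        record("enrich", {"qtl": enrich_path})

        # ---- stage: repeats ---------------------------------------------
        ref_reps = read_repeatmasker_out(inputs["ref_rmout"])
        alt_reps = (read_repeatmasker_out(inputs["alt_rmout"])
                    if inputs.get("alt_rmout") else None)
        calls, tally = repeat_content.annotate_repeats(table, ref_reps, alt_reps)
        rep_df = repeat_content.calls_frame(calls, table)
        rep_path = out / "repeats.tsv"
        rep_df.to_csv(rep_path, sep="\t", index=False, float_format="%.6g")
        spectrum, unparsed = repeat_content.simple_repeat_spectrum(calls, table)
        spec_path = out / "simple_repeat_spectrum.tsv"
        spectrum.to_csv(spec_path, sep="\t", index=False)
        record("repeats", {"calls": rep_path, "spectrum": spec_path},
               meta={"skipped": tally, "unparsed_units": unparsed})

        # ---- stage: fst -------------------------------------------------
        pops = sorted(set(pop_map.values()))
        pairs = (list(map(tuple, cfg["pairs"])) if cfg.get("pairs")
                 else list(itertools.combinations(pops, 2)))
        per_pair_genes: dict[tuple[str, str], list[str]] = {}
        fst_outputs: dict[str, Path] = {}
        fst_meta = {}
        for pair in pairs:
            scan = popgen_fst.fst_scan(
                table, pop_map, pair, layout, window=int(cfg["fst_window"]),
                step=int(cfg["fst_step"]), top_frac=float(cfg["top_frac"]),
                genes=models)
            tag = f"{pair[0]}_vs_{pair[1]}"
            pieces = []
            gene_union: set[str] = set()
            for key in ("top_small", "top_medium", "top_large"):
                if key in scan:
                    piece = scan[key].copy()
                    piece.insert(0, "stratum", key.removeprefix("top_"))
                    pieces.append(piece)
                gkey = key.replace("top", "genes")
                if gkey in scan:
                    gene_union.update(scan[gkey])
            per_pair_genes[pair] = sorted(gene_union)
            top_path = out / f"fst_top_{tag}.tsv"
            pd.concat(pieces, ignore_index=True).to_csv(
                top_path, sep="\t", index=False, float_format="%.6g")
            fst_outputs[tag] = top_path
            means = {}
            for key in ("sites_small", "sites_medium", "sites_large"):
                if key in scan:
                    means[key] = float(scan[key]["fst"].mean(skipna=True))
            fst_meta[tag] = means
        shared = popgen_fst.shared_genes(per_pair_genes)
        shared_path = out / "fst_shared_genes.tsv"
        shared.to_csv(shared_path, sep="\t", index=False)
        fst_outputs["shared_genes"] = shared_path
        record("fst", fst_outputs, meta=fst_meta)

        # ---- stage: ld --------------------------------------------------
        eqtl_track = read_bed(inputs["eqtl_snps"], name="eqtl_snps",
                              label_col=3, sublabel_col=4)
        snps = table.where(vtype="SNP")
        indels = table.where(vtype=("INS", "DEL"))
        tag_calls, skipped = ld_tagging.tag_variants(
            indels, snps, eqtl_track, window=int(cfg["ld_window"]))
        ld_df = ld_tagging.tag_frame(tag_calls, indels)
        ld_path = out / "ld_tags.tsv"
        ld_df.to_csv(ld_path, sep="\t", index=False, float_format="%.6g")
        tissue = ld_tagging.tissue_summary(tag_calls, indels)
        tissue_path = out / "ld_tissue_summary.tsv"
        tissue.to_csv(tissue_path, sep="\t", index=False, float_format="%.6g")
        record("ld", {"tags": ld_path, "tissue_summary": tissue_path},
               meta={"untagged": skipped})
    finally:
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
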