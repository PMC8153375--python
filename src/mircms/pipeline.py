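"""End-to-end synthetic run: simulate -> preprocess -> annotate -> novel ->
degradome -> DE -> enrichment -> network -> report.

`run_pipeline` chains every stage from one `SimConfig`, writes all stage
outputs as plain-text tables/FASTA/GraphML under ``out_dir`` and returns
the in-memory results.  All randomness derives from the config seed, and
output writers iterate in sorted order, so two runs with the same seed
produce byte-identical files.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
import pandas as pd

from . import degradome_targets as dt
from . import differential_expression as de
from . import enrichment_network as en
from . import hairpin_filter as hf
from . import mirna_annotation as ann
from . import srna_preprocess as pre
from . import synthetic_data as sim

log = logging.getLogger("mircms")

__all__ = ["run_pipeline", "setup_logging"]


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def run_pipeline(config: sim.SimConfig, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("simulating inputs (seed=%d)", config.seed)
    bundle = sim.write_all(config, out / "inputs")
    catalog, genome, truth = bundle["catalog"], bundle["genome"], bundle["truth"]
    libs = [lib for lib, _ in config.libraries]

    log.info("preprocessing %d sRNA libraries", len(libs))
    ncrna_refs = [seq for recs in sim.make_ncrna_refs(config).values()
                  for _, seq in recs]
    unique, stats = pre.preprocess_libraries(
        bundle["reads_by_lib"], adapter=config.adapter, ncrna_refs=ncrna_refs)
    stats.to_frame().to_csv(out / "preprocess_stats.tsv", sep="\t")
    pre.write_collapsed_fasta(out / "unique_reads.fasta", unique)
    length_tab = pre.length_distribution(unique)
    length_tab.to_csv(out / "length_distribution.tsv", sep="\t")

    log.info("annotating %d unique reads", len(unique))
    annotations, unmapped = ann.annotate_reads(unique, catalog, genome)
    ann_frame = ann.annotations_frame(annotations, libs)
    ann_frame.to_csv(out / "annotations.tsv", sep="\t", index=False)

    log.info("novel prediction on %d unmapped reads", len(unmapped))
    # only reads that occur on the genome are foldable candidates
    candidates = [(f"u{idx + 1:06d}", ur.sequence) for idx, ur in enumerate(unmapped)]
    predictions = hf.predict_novel(candidates, genome, flank=config.flank)
    pred_rows = [{
        "read": p.read_id, "sequence": p.sequence, "contig": p.contig,
        "position": p.position, "passed": p.passed,
        "failing": ";".join(p.report.failing()) if p.report else "no-hairpin",
    } for p in predictions]
    pd.DataFrame(pred_rows, columns=["read", "sequence", "contig", "position",
                                     "passed", "failing"]
                 ).to_csv(out / "novel_predictions.tsv", sep="\t", index=False)
    novel_pass = {p.sequence for p in predictions if p.passed}
    for ur in unmapped:
        if ur.sequence in novel_pass:
            annotations.append(ann.MiRNAAnnotation(
                ur.sequence, f"novel-{ur.sequence[:8]}", "novel", "5p",
                "gp4", "", "non-conserved", dict(ur.counts)))

    log.info("degradome target calling")
    transcripts = bundle["transcripts"]
    mirna_seqs = bundle["mirna_seqs"]
    interactions: dict[str, list[dt.TargetInteraction]] = {}
    category_counts: dict[str, dict[int, int]] = {}
    for lib in libs[:2]:
        tags = dt.preprocess_degradome(bundle["degradome"][lib], config.adapter)
        tplots, rate = dt.map_tags(tags, transcripts)
        found = dt.find_cleavage_targets(mirna_seqs, tplots, transcripts)
        interactions[lib] = found
        cc: dict[int, int] = {}
        for it in found:
            cc[it.category] = cc.get(it.category, 0) + 1
        category_counts[lib] = cc
        log.info("library %s: %d tags mapped (rate %.3f), %d interactions",
                 lib, len(tags), rate, len(found))
        pd.DataFrame([{
            "mirna": it.mirna, "gene": it.gene, "site_start": it.site[0],
            "site_end": it.site[1], "score": it.alignment_score,
            "cleavage_pos": it.cleavage_pos, "category": it.category,
            "tags": it.tag_count} for it in found]
            ).to_csv(out / f"interactions_{lib}.tsv", sep="\t", index=False)
    if len(libs) >= 2:
        venn = dt.compare_sets(interactions[libs[0]], interactions[libs[1]])
    else:
        venn = dt.compare_sets(interactions[libs[0]], [])
    pd.DataFrame([
        ("unique_" + libs[0], venn["n_unique_a"], ";".join(venn["unique_a"])),
        ("unique_" + (libs[1] if len(libs) > 1 else "B"),
         venn["n_unique_b"], ";".join(venn["unique_b"])),
        ("common", venn["n_common"], ";".join(venn["common"])),
    ], columns=["partition", "n", "genes"]).to_csv(
        out / "venn.tsv", sep="\t", index=False)

    log.info("differential expression")
    mirna_counts = pd.DataFrame(
        [{**{"mirna": a.mirna_name},
          **{lib: a.counts.get(lib, 0) for lib in libs}} for a in annotations]
    ).groupby("mirna").sum()
    mirna_norm = de.normalize(mirna_counts)
    mirna_tab = de.mirna_de(mirna_norm[[libs[0]]], mirna_norm[[libs[1]]]) \
        if len(libs) >= 2 else None
    if mirna_tab is not None:
        mirna_tab.to_csv(out / "mirna_de.tsv", sep="\t")
    counts = bundle["counts"]
    cols_a = [c for c in counts.columns if c.startswith("A_")]
    cols_b = [c for c in counts.columns if c.startswith("B_")]
    gene_tab = de.gene_de(counts, cols_a, cols_b)
    gene_tab.to_csv(out / "gene_de.tsv", sep="\t")
    corr = de.sample_correlation(de.normalize(counts))
    corr.to_csv(out / "sample_correlation.tsv", sep="\t")

    log.info("enrichment and network")
    annot_map = en.AnnotationMap.from_frame(bundle["annotation"],
                                            universe=transcripts.keys())
    target_genes = sorted({it.gene for found in interactions.values()
                           for it in found})
    enriched = en.hypergeom_enrich(target_genes, annot_map)
    enriched.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    de_flags = gene_tab["flag"].to_dict()
    all_interactions = [it for lib in sorted(interactions)
                        for it in interactions[lib]]
    network = en.build_network(enriched, annot_map, all_interactions, de_flags)
    en.export_network(network, out / "network.graphml", "GraphML")
    en.export_network(network, out / "network.sif", "SIF")

    group_counts: dict[str, int] = {}
    for a in annotations:
        group_counts[a.group] = group_counts.get(a.group, 0) + 1
    de_counts = {
        "genes_up": int((gene_tab["flag"] == "up").sum()),
        "genes_down": int((gene_tab["flag"] == "down").sum()),
        "genes_exclusive": int(gene_tab["exclusive"].sum()),
    }
    if mirna_tab is not None:
        de_counts["mirnas_flagged"] = int((mirna_tab["flag"] != "ns").sum())
    summary = en.summarize_run(
        length_table=length_tab,
        group_counts=group_counts,
        family_table=ann.family_summary(annotations),
        category_counts=category_counts,
        venn=venn,
        de_counts=de_counts,
        top_terms=enriched.loc[enriched["enriched"]].nsmallest(10, "p_adjusted"),
    )
    (out / "report.md").write_text(en.to_markdown_report(summary))
    headline = {
        "unique_reads": len(unique),
        "annotated": len(annotations),
        "groups": dict(sorted(group_counts.items())),
        "novel_passed": len(novel_pass),
        "interactions": {lib: len(v) for lib, v in sorted(interactions.items())},
        "venn": {k: venn[k] for k in ("n_unique_a", "n_unique_b", "n_common")},
        "de": de_counts,
        "enriched_terms": int(enriched["enriched"].sum()),
        "network": {"nodes": network.number_of_nodes(),
                    "edges": network.number_of_edges()},
    }
    (out / "summary.json").write_text(json.dumps(headline, indent=2, sort_keys=True))
    return {
        "bundle": bundle, "unique": unique, "stats": stats,
        "annotations": annotations, "predictions": predictions,
        "interactions": interactions, "venn": venn,
        "mirna_de": mirna_tab, "gene_de": gene_tab, "enriched": enriched,
        "network": network, "summary": summary, "headline": headline,
    }
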