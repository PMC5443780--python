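"""End-to-end workflow driver: the staged pipeline behind the CLI.

Stages run in order — ORF calling, two-round search, quantification,
consensus/fraction bookkeeping, classification, summaries — with every
output table written as TSV carrying a reproducibility header (tool
version + configuration hash) and a machine-readable manifest listing
all products.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import classify_all, parse_annotations, parse_lineage_table, summarize
from .config import RunConfig
from .consensus import (
    cluster_heatmap_matrix,
    consensus_filter,
    replicate_histogram,
    venn_summary,
)
from .matcher import write_psm_table
from .orf_caller import build_library
from .pipeline import run_two_round
from .quant import abundance_matrix, quantify
from .seq_io import read_fasta, read_mgf, write_protein_fasta

log = logging.getLogger(__name__)


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# metasecretome {__version__} config={cfg.digest_hash()}\n"
    manifest: dict = {"version": __version__, "config_hash": cfg.digest_hash(),
                      "stages": [], "outputs": {}}

    def stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    contigs = list(read_fasta(cfg.contigs))
    runs = [
        (ri.meta, list(read_mgf(ri.mgf, default_charge=2))) for ri in cfg.runs
    ]

    stage("orfs")
    full_library = build_library(
        contigs, min_nt=cfg.min_orf_nt, longest_per_stop=cfg.longest_per_stop
    )
    orf_fasta = out / "orfs_full.faa"
    write_protein_fasta(
        (
            (o.orf_id,
             f"contig={o.contig_id} start={o.start} end={o.end} "
             f"strand={o.strand} frame={o.frame}",
             o.aa_seq)
            for o in full_library.orfs
        ),
        orf_fasta,
    )
    manifest["outputs"]["orfs_full"] = str(orf_fasta)

    stage("search")
    r1, library, idents = run_two_round(
        runs, contigs, cfg.matcher,
        min_orf_nt=cfg.min_orf_nt,
        longest_per_stop=cfg.longest_per_stop,
        min_peptides=cfg.min_peptides,
    )
    psm_path = out / "round1_psms.tsv"
    write_psm_table(r1.supporting_psms, psm_path)
    manifest["outputs"]["round1_psms"] = str(psm_path)
    manifest["outputs"]["matched_contigs"] = sorted(r1.matched_contig_ids)
    ident_df = pd.DataFrame(
        [
            {"orf_id": i.orf_id, "members": ";".join(sorted(i.members)),
             "sample": i.sample, "fraction": i.fraction,
             "replicate": i.replicate, "n_observed": i.n_observed,
             "shared_only": int(i.shared_only),
             "peptides": ";".join(sorted(i.peptides))}
            for i in idents
        ]
    )
    ident_path = out / "protein_identifications.tsv"
    _write_tsv(ident_df, ident_path, header)
    manifest["outputs"]["identifications"] = str(ident_path)

    stage("quant")
    quant_df = quantify(
        idents, library.as_dict(), window=cfg.window,
        max_missed=cfg.matcher.max_missed,
    )
    quant_path = out / "quant.tsv"
    _write_tsv(quant_df, quant_path, header)
    manifest["outputs"]["quant"] = str(quant_path)

    stage("consensus")
    n_reps = max((ri.meta.replicate for ri in cfg.runs), default=1)
    cons = consensus_filter(idents, n_replicates=n_reps)
    hist = replicate_histogram(cons, n_replicates=n_reps)
    _write_tsv(hist, out / "replicate_histogram.tsv", header)
    venn = venn_summary(cons)
    venn_df = pd.DataFrame([{
        "n_total_consensus": venn.n_total_consensus, "n_bf": venn.n_bf,
        "n_snt": venn.n_snt, "n_shared": venn.n_shared,
        "pct_shared": round(venn.pct_shared, 1),
    }])
    _write_tsv(venn_df, out / "venn_summary.tsv", header)
    manifest["outputs"]["replicate_histogram"] = str(out / "replicate_histogram.tsv")
    manifest["outputs"]["venn_summary"] = str(out / "venn_summary.tsv")

    consensus_ids = {c.orf_id for c in cons if c.consensus}
    cons_quant = quant_df[quant_df.orf_id.isin(consensus_ids)]
    if not cons_quant.empty and cons_quant.groupby(
        ["sample", "fraction", "replicate"]
    ).ngroups >= 2:
        mat = abundance_matrix(cons_quant)
        display, _link, leaf_order, newick = cluster_heatmap_matrix(mat)
        _write_tsv(display.reset_index(), out / "heatmap_matrix.tsv", header)
        (out / "sample_dendrogram.nwk").write_text(newick + "\n")
        manifest["outputs"]["heatmap_matrix"] = str(out / "heatmap_matrix.tsv")
        manifest["outputs"]["sample_dendrogram"] = str(out / "sample_dendrogram.nwk")
        manifest["outputs"]["sample_leaf_order"] = leaf_order

    stage("classify")
    ann = cfg.annotations
    records = parse_annotations(
        sorted({i.orf_id for i in idents}),
        blast_tsv=ann.get("blast"),
        dbcan_domtbl=ann.get("dbcan"),
        signalp_tsv=ann.get("signalp"),
        tmhmm_tsv=ann.get("tmhmm"),
        cog_tsv=ann.get("cog"),
    )
    lineage = (
        parse_lineage_table(ann["lineage"]) if "lineage" in ann else None
    )
    classified = classify_all(records, lineage)
    class_df = pd.DataFrame(
        [
            {"orf_id": c.orf_id, "compartment": c.compartment,
             "is_cazyme": int(c.is_cazyme),
             "cazy_families": ";".join(
                 sorted({d.family for d in c.annotation.cazy_domains})
             ) if c.annotation else "",
             "phylum": c.taxon_rollup.get("phylum", ""),
             "genus": c.taxon_rollup.get("genus", "")}
            for c in classified.values()
        ]
    )
    _write_tsv(class_df, out / "classified_proteins.tsv", header)
    manifest["outputs"]["classified"] = str(out / "classified_proteins.tsv")

    stage("summarize")
    cons_classified = {
        oid: c for oid, c in classified.items() if oid in consensus_ids
    }
    tables = summarize(cons_classified, quant_df=cons_quant)
    for name, df in tables.items():
        p = out / f"summary_{name}.tsv"
        _write_tsv(df, p, header)
        manifest["outputs"][f"summary_{name}"] = str(p)

    stage("manifest")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
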