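"""Parsing of external annotation outputs and rule-based classification.

The pipeline never runs BLAST, hmmscan, SignalP or TMHMM itself; it
consumes their standard output files and applies fixed thresholds:

* BLASTP tabular (outfmt 6): best hit per protein, kept only at
  E-value <= 1e-20;
* dbCAN (hmmscan --domtblout against CAZy family HMMs): a domain hit is
  kept iff alignment length > 80 aa and E < 1e-5, or length <= 80 aa and
  E < 1e-3;
* SignalP 4.x short format: the D-score decision column;
* TMHMM short format: the PredHel count.

Compartment rule: secreted iff a signal peptide is predicted and there
is no transmembrane helix; membrane iff >= 1 predicted helix; otherwise
unassigned (intracellular contamination or unknown).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .seq_io import ParseError

BLAST_EVALUE_MAX = 1e-20
DBCAN_LONG_LEN = 80     # alignment length strictly greater -> strict branch
DBCAN_LONG_EVALUE = 1e-5
DBCAN_SHORT_EVALUE = 1e-3

TRANSPORTER_KEYWORDS = (
    "TonB-dependent", "ABC transporter", "ABC-type", "transporter",
    "porin", "outer membrane receptor",
)


@dataclass
class BlastHit:
    subject_id: str
    taxon: str
    evalue: float
    bitscore: float
    description: str = ""


@dataclass
class CazyDomain:
    family: str
    evalue: float
    alignment_length: int


@dataclass
class AnnotationRecord:
    orf_id: str
    blast_best: BlastHit | None = None
    cazy_domains: list[CazyDomain] = field(default_factory=list)
    signal_peptide: bool = False
    tm_helix_count: int = 0
    cog_category: str | None = None


@dataclass
class ClassifiedProtein:
    orf_id: str
    compartment: str  # 'secreted' | 'membrane' | 'unassigned'
    is_cazyme: bool
    taxon_rollup: dict[str, str] = field(default_factory=dict)
    annotation: AnnotationRecord | None = None


def parse_blast_tab(
    path: str | Path, evalue_max: float = BLAST_EVALUE_MAX
) -> dict[str, BlastHit]:
    """Best BLAST hit per query from an outfmt-6 table.

    Rows above the E-value threshold are discarded. A 13th column, when
    present, is taken as the subject title (description); the taxon
    string is the bracketed organism name in the title when present,
    else the whole title.
    """
    best: dict[str, BlastHit] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"{path}:{lineno}: expected >=12 BLAST columns")
            try:
                qid, sid = parts[0], parts[1]
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if evalue > evalue_max:
                continue
            title = parts[12] if len(parts) > 12 else sid
            m = re.search(r"\[([^\]]+)\]\s*$", title)
            taxon = m.group(1) if m else title
            hit = BlastHit(sid, taxon, evalue, bitscore, description=title)
            prev = best.get(qid)
            if prev is None or (evalue, -bitscore) < (prev.evalue, -prev.bitscore):
                best[qid] = hit
    return best


def parse_dbcan_domtbl(path: str | Path) -> dict[str, list[CazyDomain]]:
    """Raw CAZy domain hits from an hmmscan --domtblout file.

    The target name is the family HMM (.hmm suffix stripped); alignment
    length is the ali coordinate span; the domain (i-)E-value is used.
    The dbCAN acceptance rule is applied separately by
    :func:`apply_dbcan_rule`.
    """
    hits: dict[str, list[CazyDomain]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 22:
                raise ParseError(f"{path}:{lineno}: truncated domtblout row")
            try:
                family = parts[0].removesuffix(".hmm")
                query = parts[3]
                i_evalue = float(parts[12])
                ali_from, ali_to = int(parts[17]), int(parts[18])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            hits.setdefault(query, []).append(
                CazyDomain(family, i_evalue, ali_to - ali_from + 1)
            )
    return hits


def apply_dbcan_rule(domains: Iterable[CazyDomain]) -> list[CazyDomain]:
    """Keep a hit iff (len > 80 and E < 1e-5) or (len <= 80 and E < 1e-3)."""
    kept = []
    for d in domains:
        if d.alignment_length > DBCAN_LONG_LEN:
            if d.evalue < DBCAN_LONG_EVALUE:
                kept.append(d)
        elif d.evalue < DBCAN_SHORT_EVALUE:
            kept.append(d)
    return kept


def parse_signalp_short(path: str | Path) -> dict[str, bool]:
    """SignalP 4.x short format: one row per protein; the '?' column holds
    the Y/N D-score decision."""
    out: dict[str, bool] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 10:
                raise ParseError(f"{path}:{lineno}: truncated SignalP row")
            name, decision = parts[0], parts[9]
            if decision not in ("Y", "N"):
                raise ParseError(
                    f"{path}:{lineno}: decision column is {decision!r}, not Y/N"
                )
            # any positive decision across provided organism models wins
            out[name] = out.get(name, False) or decision == "Y"
    return out


_PREDHEL_RE = re.compile(r"PredHel=(\d+)")


def parse_tmhmm_short(path: str | Path) -> dict[str, int]:
    """TMHMM short format: extract the PredHel helix count per protein."""
    out: dict[str, int] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            m = _PREDHEL_RE.search(line)
            if m is None:
                raise ParseError(f"{path}:{lineno}: no PredHel field")
            out[line.split()[0]] = int(m.group(1))
    return out


def parse_cog_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV orf_id -> single-letter COG category."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            out[parts[0].strip()] = parts[1].strip()
    return out


def parse_lineage_table(path: str | Path) -> dict[str, dict[str, str]]:
    """TSV taxon -> kingdom/phylum/order/genus (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    key = df.columns[0]
    ranks = [c for c in df.columns[1:]]
    return {
        row[key]: {r: row[r] for r in ranks if row[r]}
        for _, row in df.iterrows()
    }


def parse_annotations(
    orf_ids: Iterable[str],
    blast_tsv: str | Path | None = None,
    dbcan_domtbl: str | Path | None = None,
    signalp_tsv: str | Path | None = None,
    tmhmm_tsv: str | Path | None = None,
    cog_tsv: str | Path | None = None,
) -> dict[str, AnnotationRecord]:
    """One AnnotationRecord per orf_id; proteins missing from a file get
    the neutral default (no hit / 0 helices / no signal peptide)."""
    blast = parse_blast_tab(blast_tsv) if blast_tsv else {}
    dbcan = parse_dbcan_domtbl(dbcan_domtbl) if dbcan_domtbl else {}
    signalp = parse_signalp_short(signalp_tsv) if signalp_tsv else {}
    tmhmm = parse_tmhmm_short(tmhmm_tsv) if tmhmm_tsv else {}
    cogs = parse_cog_table(cog_tsv) if cog_tsv else {}
    records = {}
    for orf_id in orf_ids:
        records[orf_id] = AnnotationRecord(
            orf_id=orf_id,
            blast_best=blast.get(orf_id),
            cazy_domains=apply_dbcan_rule(dbcan.get(orf_id, [])),
            signal_peptide=signalp.get(orf_id, False),
            tm_helix_count=tmhmm.get(orf_id, 0),
            cog_category=cogs.get(orf_id),
        )
    return records


def classify_compartment(
    rec: AnnotationRecord,
    lineage: Mapping[str, Mapping[str, str]] | None = None,
) -> ClassifiedProtein:
    """Apply the signal-peptide / transmembrane rule and attach taxonomy."""
    if rec.tm_helix_count >= 1:
        compartment = "membrane"
    elif rec.signal_peptide:
        compartment = "secreted"
    else:
        compartment = "unassigned"
    rollup: dict[str, str] = {}
    if rec.blast_best is not None and lineage:
        rollup = dict(lineage.get(rec.blast_best.taxon, {}))
    return ClassifiedProtein(
        orf_id=rec.orf_id,
        compartment=compartment,
        is_cazyme=bool(rec.cazy_domains),
        taxon_rollup=rollup,
        annotation=rec,
    )


def classify_all(
    records: Mapping[str, AnnotationRecord],
    lineage: Mapping[str, Mapping[str, str]] | None = None,
) -> dict[str, ClassifiedProtein]:
    return {
        orf_id: classify_compartment(rec, lineage)
        for orf_id, rec in records.items()
    }


def summarize(
    classified: Mapping[str, ClassifiedProtein],
    quant_df: pd.DataFrame | None = None,
    transporter_keywords: tuple[str, ...] = TRANSPORTER_KEYWORDS,
) -> dict[str, pd.DataFrame]:
    """Report tables over a set of (consensus) classified proteins.

    Returns a dict of DataFrames: ``cazy_families`` (% of identified
    CAZymes per family), ``cazy_share`` (CAZymes as % of proteins),
    ``compartments``, ``cog``, ``taxonomy_<rank>`` rollups,
    ``transporters`` (keyword matches on BLAST descriptions) and, when a
    quant table is given, ``class_abundance`` (per-run molar_pct by
    compartment) and ``cazy_abundance``.
    """
    from .quant import aggregate_class_abundance

    proteins = list(classified.values())
    n = len(proteins)
    out: dict[str, pd.DataFrame] = {}

    fam_counts: dict[str, int] = {}
    for p in proteins:
        if p.annotation is None:
            continue
        for fam in {d.family for d in p.annotation.cazy_domains}:
            fam_counts[fam] = fam_counts.get(fam, 0) + 1
    n_cazy = sum(1 for p in proteins if p.is_cazyme)
    out["cazy_families"] = pd.DataFrame(
        sorted(
            (
                {"family": f, "count": c,
                 "pct_of_cazymes": 100.0 * c / n_cazy if n_cazy else 0.0}
                for f, c in fam_counts.items()
            ),
            key=lambda r: (-r["count"], r["family"]),
        ),
        columns=["family", "count", "pct_of_cazymes"],
    )
    out["cazy_share"] = pd.DataFrame(
        [{"n_cazymes": n_cazy, "n_proteins": n,
          "pct": 100.0 * n_cazy / n if n else 0.0}]
    )

    comp = pd.Series([p.compartment for p in proteins], dtype=str)
    out["compartments"] = (
        comp.value_counts().rename_axis("compartment").reset_index(name="count")
    )

    cog = pd.Series(
        [p.annotation.cog_category for p in proteins
         if p.annotation and p.annotation.cog_category],
        dtype=str,
    )
    out["cog"] = (
        cog.value_counts().rename_axis("cog_category").reset_index(name="count")
    )

    for rank in ("kingdom", "phylum", "order", "genus"):
        vals = [p.taxon_rollup.get(rank) for p in proteins if p.taxon_rollup.get(rank)]
        s = pd.Series(vals, dtype=str).value_counts()
        df = s.rename_axis(rank).reset_index(name="count")
        df["pct_of_assigned"] = 100.0 * df["count"] / len(vals) if vals else 0.0
        out[f"taxonomy_{rank}"] = df

    transporter_rows = []
    for p in proteins:
        hit = p.annotation.blast_best if p.annotation else None
        if hit is None:
            continue
        if any(kw.lower() in hit.description.lower() for kw in transporter_keywords):
            transporter_rows.append({"orf_id": p.orf_id, "description": hit.description})
    out["transporters"] = pd.DataFrame(
        transporter_rows, columns=["orf_id", "description"]
    )

    if quant_df is not None and not quant_df.empty:
        comp_map = {p.orf_id: p.compartment for p in proteins}
        out["class_abundance"] = aggregate_class_abundance(quant_df, comp_map)
        cazy_map = {
            p.orf_id: ("CAZyme" if p.is_cazyme else "non-CAZyme") for p in proteins
        }
        out["cazy_abundance"] = aggregate_class_abundance(quant_df, cazy_map)
    return out
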