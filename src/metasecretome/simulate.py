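"""Synthetic composting-community fixture generator.

Produces a miniature dataset with complete ground truth so that every
pipeline stage can be exercised end to end without any external data:
an assembly of contigs carrying reverse-translated planted proteins
(a configurable fraction carrying a second, unexpressed qualifying ORF —
the multi-ORF decoy scenario the two-round strategy must reject),
synthetic tandem spectra per (fraction, replicate) run sampled from the
planted proteins proportional to abundance weights, and annotation files
(BLAST tabular, dbCAN domtblout, SignalP/TMHMM short format, COG and
lineage tables) with planted values.

The study design emulated is 2 fractions (biotin-labelled BF vs
supernatant SNT) x 3 biological replicates, with mostly disjoint
fraction pools and a small shared set. Defaults are small enough for
seconds-scale tests: 30 planted proteins, 30 spectra per expressed
protein per run, lognormal abundance weights with sigma 0.7 (a modest
dynamic range the fixture's sampling depth can resolve), fragment m/z
jitter one tenth of the 0.1 Da matching tolerance, 10% dropped peaks
and 10% pure-noise spectra. UTR flanks and inter-ORF spacers are built
from stop codons of both strands, and every generated contig is verified
against the ORF caller (and resampled on mismatch), so the ground-truth
ORF table is exact by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .digestion import ObservabilityWindow, Peptide, digest
from .matcher import theoretical_by_ions
from .orf_caller import find_orfs
from .seq_io import Contig, Spectrum, write_fasta, write_mgf

# aa -> synonymous codons (standard code)
_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(_aa, []).append(_codon)
_STOPS_BOTH_STRANDS = ["TAA", "TAG", "TGA", "TTA", "CTA", "TCA"]

# residue alphabet for random proteins, K/R-weighted so tryptic peptides
# come out at MS-typical lengths
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_WEIGHTS = np.array(
    [7.9, 1.9, 5.9, 6.1, 4.0, 7.3, 2.3, 5.3, 7.2, 9.1,
     2.3, 4.3, 4.6, 3.9, 7.2, 6.6, 5.6, 6.9, 1.3, 3.3]
)
_AA_WEIGHTS = _AA_WEIGHTS / _AA_WEIGHTS.sum()

_TAXA = {
    "Cellvibrio japonicus": {
        "kingdom": "Bacteria", "phylum": "Proteobacteria",
        "order": "Cellvibrionales", "genus": "Cellvibrio"},
    "Xanthomonas campestris": {
        "kingdom": "Bacteria", "phylum": "Proteobacteria",
        "order": "Xanthomonadales", "genus": "Xanthomonas"},
    "Flavobacterium johnsoniae": {
        "kingdom": "Bacteria", "phylum": "Bacteroidetes",
        "order": "Flavobacteriales", "genus": "Flavobacterium"},
    "Cytophaga hutchinsonii": {
        "kingdom": "Bacteria", "phylum": "Bacteroidetes",
        "order": "Cytophagales", "genus": "Cytophaga"},
    "Cellulomonas fimi": {
        "kingdom": "Bacteria", "phylum": "Actinobacteria",
        "order": "Micrococcales", "genus": "Cellulomonas"},
}
_CAZY_FAMILIES = ["GH5", "GH6", "GH10", "GH11", "CBM44", "CE1"]
_COG_LETTERS = "GJPEMOT"


@dataclass
class PlantedProtein:
    name: str
    aa_seq: str
    compartment: str          # 'secreted' | 'membrane' | 'unassigned'
    cazy_family: str | None
    taxon: str
    weight: float
    fractions: frozenset[str]  # subset of {'BF', 'SNT'}
    description: str = ""


@dataclass
class CommunitySpec:
    planted_proteins: list[PlantedProtein]
    seed: int
    multi_orf_fraction: float = 0.3
    n_unexpressed_contigs: int = 5
    n_replicates: int = 3
    fractions: tuple[str, ...] = ("BF", "SNT")
    depth_per_protein: int = 30
    noise_spectra_fraction: float = 0.1
    frag_jitter_da: float = 0.01
    peak_drop_rate: float = 0.1
    precursor_jitter_ppm: float = 2.0
    sample: str = "SYN"

    def __post_init__(self) -> None:
        if not 0.0 <= self.multi_orf_fraction <= 1.0:
            raise ValueError("multi_orf_fraction outside [0, 1]")
        if any(p.weight <= 0 for p in self.planted_proteins):
            raise ValueError("abundance weights must be positive")

    @classmethod
    def default(
        cls,
        seed: int,
        n_bf_only: int = 16,
        n_snt_only: int = 11,
        n_shared: int = 3,
        min_len: int = 180,
        max_len: int = 400,
        weight_sigma: float = 0.7,
        **overrides,
    ) -> "CommunitySpec":
        """The standard miniature community: 30 proteins split 16/11/3
        between BF-only, SNT-only and shared pools."""
        # distinct stream from generate_assembly's, which shares spec.seed
        rng = np.random.default_rng([seed, 11])
        pools = (
            [frozenset({"BF"})] * n_bf_only
            + [frozenset({"SNT"})] * n_snt_only
            + [frozenset({"BF", "SNT"})] * n_shared
        )
        taxa = list(_TAXA)
        proteins = []
        for i, pool in enumerate(pools):
            length = int(rng.integers(min_len, max_len + 1))
            aa = random_protein(rng, length)
            compartment = ("secreted", "membrane", "unassigned")[i % 3]
            cazy = _CAZY_FAMILIES[i % len(_CAZY_FAMILIES)] if i % 6 == 0 else None
            taxon = taxa[i % len(taxa)]
            if cazy:
                desc = f"endoglucanase {cazy} [{taxon}]"
            elif compartment == "membrane" and i % 2 == 0:
                desc = f"TonB-dependent receptor [{taxon}]"
            else:
                desc = f"hypothetical protein [{taxon}]"
            proteins.append(
                PlantedProtein(
                    name=f"prot{i:03d}",
                    aa_seq=aa,
                    compartment=compartment,
                    cazy_family=cazy,
                    taxon=taxon,
                    weight=float(rng.lognormal(0.0, weight_sigma)),
                    fractions=pool,
                    description=desc,
                )
            )
        return cls(planted_proteins=proteins, seed=seed, **overrides)


def random_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein starting with M with at least one observable tryptic
    peptide (resampled until so)."""
    window = ObservabilityWindow()
    for _ in range(100):
        body = rng.choice(list(_AA_ALPHABET), size=length - 1, p=_AA_WEIGHTS)
        aa = "M" + "".join(body)
        if observable_peptides(aa):
            return aa
    raise RuntimeError("could not generate an observable protein")


def observable_peptides(aa: str, max_missed: int = 1) -> list[Peptide]:
    window = ObservabilityWindow()
    seen: set[str] = set()
    out = []
    for p in digest(aa, max_missed=max_missed):
        if p.seq not in seen and window.admits(p):
            seen.add(p.seq)
            out.append(p)
    return out


def reverse_translate(aa: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice."""
    return "".join(
        _BACK_TABLE[a][rng.integers(0, len(_BACK_TABLE[a]))] for a in aa
    )


def _stop_rich_flank(rng: np.random.Generator, n_codons: int) -> str:
    """Codon-aligned flank built from stop codons of both strands, so any
    reading frame hits a stop quickly near the planted coding region."""
    picks = rng.integers(0, len(_STOPS_BOTH_STRANDS), size=n_codons)
    return "".join(_STOPS_BOTH_STRANDS[i] for i in picks)


@dataclass
class SyntheticCommunity:
    spec: CommunitySpec
    contigs: list[Contig]
    orf_truth: pd.DataFrame  # contig_id, orf_id, protein_name, aa_seq, expressed
    proteins_by_orf: dict[str, PlantedProtein] = field(default_factory=dict)

    @property
    def expressed_orf_ids(self) -> set[str]:
        return set(self.orf_truth.loc[self.orf_truth.expressed, "orf_id"])

    @property
    def decoy_orf_ids(self) -> set[str]:
        return set(self.orf_truth.loc[~self.orf_truth.expressed, "orf_id"])


def _build_contig(
    cid: str,
    rng: np.random.Generator,
    proteins: list[str],
) -> Contig:
    """flank + (coding+stop [+ spacer + coding+stop]) + flank, codon-aligned."""
    parts = [_stop_rich_flank(rng, int(rng.integers(8, 16)))]
    stops = ["TAA", "TAG", "TGA"]
    for k, aa in enumerate(proteins):
        if k > 0:
            parts.append(_stop_rich_flank(rng, int(rng.integers(4, 8))))
        parts.append(reverse_translate(aa, rng))
        parts.append(stops[rng.integers(0, 3)])
    parts.append(_stop_rich_flank(rng, int(rng.integers(8, 16))))
    return Contig(id=cid, seq="".join(parts))


def generate_assembly(spec: CommunitySpec) -> SyntheticCommunity:
    """Contigs plus an exact ground-truth ORF table.

    Each contig is checked against the ORF caller: its qualifying ORF set
    must be exactly the planted proteins (expressed first, then the
    unexpressed decoy when present); contigs failing the check — e.g.
    because a chance reverse-strand ORF appeared — are resampled.
    """
    rng = np.random.default_rng([spec.seed, 23])
    n_multi = int(round(spec.multi_orf_fraction * len(spec.planted_proteins)))
    multi_idx = set(
        rng.choice(len(spec.planted_proteins), size=n_multi, replace=False)
        if n_multi else []
    )
    contigs: list[Contig] = []
    rows = []
    proteins_by_orf: dict[str, PlantedProtein] = {}

    def plant(cid: str, planted: list[str], flags: list[bool], names: list[str]):
        for _attempt in range(60):
            contig = _build_contig(cid, rng, planted)
            orfs = find_orfs(contig)
            if [o.aa_seq for o in orfs] == planted:
                contigs.append(contig)
                for orf, expressed, name in zip(orfs, flags, names):
                    rows.append(
                        {"contig_id": cid, "orf_id": orf.orf_id,
                         "protein_name": name, "aa_seq": orf.aa_seq,
                         "expressed": expressed}
                    )
                return orfs
        raise RuntimeError(f"could not plant ORFs on {cid}")

    for i, prot in enumerate(spec.planted_proteins):
        cid = f"ctg{i:04d}"
        planted = [prot.aa_seq]
        flags = [True]
        names = [prot.name]
        if i in multi_idx:
            decoy_len = int(rng.integers(101, 150))
            planted.append(random_protein(rng, decoy_len))
            flags.append(False)
            names.append(f"{prot.name}_decoy")
        orfs = plant(cid, planted, flags, names)
        proteins_by_orf[orfs[0].orf_id] = prot

    for j in range(spec.n_unexpressed_contigs):
        cid = f"ctgU{j:03d}"
        aa = random_protein(rng, int(rng.integers(101, 160)))
        plant(cid, [aa], [False], [f"unexpressed{j:03d}"])

    truth = pd.DataFrame(
        rows, columns=["contig_id", "orf_id", "protein_name", "aa_seq", "expressed"]
    )
    return SyntheticCommunity(
        spec=spec, contigs=contigs, orf_truth=truth, proteins_by_orf=proteins_by_orf
    )


def generate_spectra(
    community: SyntheticCommunity,
    fraction: str,
    replicate: int,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Synthetic MS/MS spectra for one (fraction, replicate) run.

    Peptides are sampled from the expressed proteins of the fraction's
    pool proportional to abundance weights; each spectrum carries the
    peptide's b/y ions with Gaussian m/z jitter and random peak dropout,
    plus a configured proportion of pure-noise spectra. Returns the
    spectra and the ground-truth PSM table.
    """
    spec = community.spec
    # run-specific but seed-derived stream (stable across processes)
    frac_key = int.from_bytes(fraction.encode(), "little") % (2**31)
    rng = np.random.default_rng([spec.seed, frac_key, replicate])
    pool = [
        (orf_id, prot)
        for orf_id, prot in sorted(community.proteins_by_orf.items())
        if fraction in prot.fractions
    ]
    if not pool:
        raise ValueError(f"no expressed proteins in fraction {fraction!r}")
    peptide_cache = {orf_id: observable_peptides(p.aa_seq) for orf_id, p in pool}
    # spectral flux scales with molar abundance times the number of
    # observable peptides, which is what emPAI's denominator corrects for
    weights = np.array(
        [p.weight * len(peptide_cache[o]) for o, p in pool], dtype=float
    )
    weights = weights / weights.sum()

    n_signal = spec.depth_per_protein * len(pool)
    n_noise = int(round(spec.noise_spectra_fraction * n_signal))
    window = ObservabilityWindow()

    spectra: list[Spectrum] = []
    truth_rows = []
    counter = itertools.count(1)
    choices = rng.choice(len(pool), size=n_signal, p=weights)
    for pick in choices:
        orf_id, _prot = pool[pick]
        peps = peptide_cache[orf_id]
        pep = peps[rng.integers(0, len(peps))]
        valid_z = [z for z in sorted(window.charges)
                   if window.mz_min <= pep.mz(z) <= window.mz_max]
        z = int(valid_z[rng.integers(0, len(valid_z))])
        mz = pep.mz(z) * (1.0 + rng.normal(0.0, spec.precursor_jitter_ppm * 1e-6))
        theo = theoretical_by_ions(pep)
        keep = rng.random(theo.size) >= spec.peak_drop_rate
        if not keep.any():
            keep[rng.integers(0, theo.size)] = True
        peaks = theo[keep] + rng.normal(0.0, spec.frag_jitter_da, size=keep.sum())
        intens = rng.lognormal(8.0, 1.0, size=peaks.size)
        sid = f"{fraction}{replicate}_scan{next(counter):05d}"
        spectra.append(
            Spectrum(id=sid, precursor_mz=mz, charge=z, mz=peaks, intensity=intens)
        )
        truth_rows.append(
            {"spectrum_id": sid, "orf_id": orf_id, "peptide": pep.seq,
             "charge": z, "is_noise": False}
        )
    for _ in range(n_noise):
        z = 2
        mz = float(rng.uniform(400.0, 1200.0))
        peaks = np.sort(rng.uniform(150.0, 1800.0, size=40))
        intens = rng.lognormal(7.0, 1.0, size=peaks.size)
        sid = f"{fraction}{replicate}_scan{next(counter):05d}"
        spectra.append(
            Spectrum(id=sid, precursor_mz=mz, charge=z, mz=peaks, intensity=intens)
        )
        truth_rows.append(
            {"spectrum_id": sid, "orf_id": "", "peptide": "", "charge": z,
             "is_noise": True}
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["spectrum_id", "orf_id", "peptide", "charge", "is_noise"],
    )
    return spectra, truth


def generate_annotation_files(
    community: SyntheticCommunity, outdir: str | Path
) -> dict[str, Path]:
    """Write BLAST/dbCAN/SignalP/TMHMM/COG/lineage files with planted
    values for the expressed ORFs; returns the path of each file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([community.spec.seed, 97])
    paths = {
        "blast": outdir / "blast.tsv",
        "dbcan": outdir / "dbcan.domtbl",
        "signalp": outdir / "signalp.short.tsv",
        "tmhmm": outdir / "tmhmm.short.tsv",
        "cog": outdir / "cog.tsv",
        "lineage": outdir / "lineage.tsv",
    }
    items = sorted(community.proteins_by_orf.items())
    with open(paths["blast"], "w") as fh:
        for orf_id, prot in items:
            evalue = 10.0 ** -float(rng.uniform(25, 80))
            bits = float(rng.uniform(120, 600))
            fh.write(
                "\t".join(
                    [orf_id, f"ref|{prot.name}|", "95.0",
                     str(len(prot.aa_seq)), "3", "0", "1",
                     str(len(prot.aa_seq)), "1", str(len(prot.aa_seq)),
                     f"{evalue:.2e}", f"{bits:.1f}", prot.description]
                ) + "\n"
            )
    with open(paths["dbcan"], "w") as fh:
        fh.write("# hmmscan :: domtblout\n")
        for orf_id, prot in items:
            if not prot.cazy_family:
                continue
            qlen = len(prot.aa_seq)
            ali_from, ali_to = 10, 10 + 120  # length 121 > 80: strict branch
            ev = 1e-12
            fh.write(
                f"{prot.cazy_family}.hmm - 150 {orf_id} - {qlen} "
                f"{ev:.1e} 250.0 0.1 1 1 {ev:.1e} {ev:.1e} 240.0 0.1 "
                f"1 121 {ali_from} {ali_to} {ali_from} {ali_to} 0.98 "
                f"{prot.cazy_family} family domain\n"
            )
    with open(paths["signalp"], "w") as fh:
        fh.write("# SignalP-4.1 gram- predictions\n")
        for orf_id, prot in items:
            has_sp = prot.compartment == "secreted"
            d = 0.78 if has_sp else 0.12
            fh.write(
                f"{orf_id} 0.5 22 0.5 22 0.6 15 0.45 {d:.3f} "
                f"{'Y' if has_sp else 'N'} 0.450 SignalP-noTM\n"
            )
    with open(paths["tmhmm"], "w") as fh:
        for orf_id, prot in items:
            nhel = int(rng.integers(1, 7)) if prot.compartment == "membrane" else 0
            fh.write(
                f"{orf_id}\tlen={len(prot.aa_seq)}\tExpAA={nhel * 20.0:.2f}\t"
                f"First60=0.00\tPredHel={nhel}\tTopology=o\n"
            )
    with open(paths["cog"], "w") as fh:
        for i, (orf_id, _prot) in enumerate(items):
            fh.write(f"{orf_id}\t{_COG_LETTERS[i % len(_COG_LETTERS)]}\n")
    with open(paths["lineage"], "w") as fh:
        fh.write("taxon\tkingdom\tphylum\torder\tgenus\n")
        for taxon, ranks in _TAXA.items():
            fh.write(
                f"{taxon}\t{ranks['kingdom']}\t{ranks['phylum']}\t"
                f"{ranks['order']}\t{ranks['genus']}\n"
            )
    return paths


def generate_all(spec: CommunitySpec, outdir: str | Path) -> dict:
    """Write the complete fixture dataset (FASTA, per-run MGFs, annotation
    files, ground-truth tables) and return a manifest of paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    community = generate_assembly(spec)
    fasta = outdir / "assembly.fasta"
    write_fasta(community.contigs, fasta)
    community.orf_truth.to_csv(outdir / "orf_truth.tsv", sep="\t", index=False)

    runs = []
    psm_truths = []
    for fraction in spec.fractions:
        for rep in range(1, spec.n_replicates + 1):
            spectra, truth = generate_spectra(community, fraction, rep)
            mgf_path = outdir / f"run_{fraction}_{rep}.mgf"
            write_mgf(spectra, mgf_path)
            truth["fraction"] = fraction
            truth["replicate"] = rep
            psm_truths.append(truth)
            runs.append(
                {"sample": spec.sample, "fraction": fraction,
                 "replicate": rep, "mgf": str(mgf_path)}
            )
    pd.concat(psm_truths, ignore_index=True).to_csv(
        outdir / "psm_truth.tsv", sep="\t", index=False
    )
    weights = pd.DataFrame(
        [
            {"orf_id": orf_id, "protein_name": p.name, "weight": p.weight,
             "compartment": p.compartment, "cazy_family": p.cazy_family or "",
             "taxon": p.taxon, "fractions": ";".join(sorted(p.fractions))}
            for orf_id, p in sorted(community.proteins_by_orf.items())
        ]
    )
    weights.to_csv(outdir / "protein_truth.tsv", sep="\t", index=False)
    ann_paths = generate_annotation_files(community, outdir)
    return {
        "assembly": str(fasta),
        "runs": runs,
        "annotations": {k: str(v) for k, v in ann_paths.items()},
        "truth": {
            "orfs": str(outdir / "orf_truth.tsv"),
            "psms": str(outdir / "psm_truth.tsv"),
            "proteins": str(outdir / "protein_truth.tsv"),
        },
    }
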