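"""The two-round identification strategy.

Round 1 searches the spectra against a permissive six-frame stop-to-stop
translation of every contig, and keeps only contigs that attract at least
one accepted PSM. Round 2 builds a strict ORF library from those matched
contigs alone and re-searches the *original* spectra against it, so a
protein is only reported when it is seen at the protein level — an ORF
with accepted peptide evidence. Identifications that existed only at the
contig level (a spectral match on a contig whose qualifying ORFs gather
no accepted peptides) are dropped, which is the guard against false
positives arising from matches to multi-ORF contigs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .matcher import MatchConfig, PeptideDb, Psm, search_run
from .orf_caller import OrfLibrary, build_library, six_frame_fragments
from .seq_io import Contig, Spectrum

log = logging.getLogger(__name__)

ROUND1_MIN_AA = 7  # permissive floor for the round-1 fragment space


@dataclass
class RunMeta:
    """Metadata of one LC-MS/MS run in the factorial design."""

    sample: str      # e.g. 'WS' / 'RS' analog
    fraction: str    # 'BF' (biotin-labelled) or 'SNT' (supernatant)
    replicate: int   # 1-based biological replicate index

    @property
    def run_id(self) -> str:
        return f"{self.sample}:{self.fraction}:{self.replicate}"


@dataclass
class RoundOneResult:
    matched_contig_ids: set[str]
    supporting_psms: list[Psm] = field(default_factory=list)


@dataclass
class ProteinIdentification:
    """Per-run protein-level identification (a protein group representative)."""

    orf_id: str
    sample: str
    fraction: str
    replicate: int
    peptides: frozenset[str]
    members: frozenset[str] = frozenset()     # ORFs with identical peptide sets
    shared_with: frozenset[str] = frozenset() # other groups sharing >=1 peptide
    shared_only: bool = False                 # no peptide unique to this group

    @property
    def n_observed(self) -> int:
        return len(self.peptides)


def _fragment_contig(fragment_id: str) -> str:
    return fragment_id.rsplit("|", 1)[0]


def round_one(
    spectra: list[Spectrum], contigs: list[Contig], cfg: MatchConfig
) -> RoundOneResult:
    """Contig attribution: six-frame permissive search over all contigs."""
    if not contigs:
        raise ValueError("round_one requires a non-empty assembly")
    space = {
        frag_id: aa
        for c in contigs
        for frag_id, aa in six_frame_fragments(c, min_aa=ROUND1_MIN_AA)
    }
    db = PeptideDb(space, cfg)
    psms = search_run(spectra, db, cfg)
    accepted = [p for p in psms if p.accepted]
    matched = {_fragment_contig(fid) for p in accepted for fid in p.parent_ids}
    if not accepted:
        warnings.warn("round 1 produced no accepted PSMs")
    log.info("round 1: %d accepted PSMs on %d contigs", len(accepted), len(matched))
    return RoundOneResult(matched_contig_ids=matched, supporting_psms=accepted)


def infer_proteins(
    psms: list[Psm], meta: RunMeta, min_peptides: int = 1
) -> list[ProteinIdentification]:
    """Protein grouping from accepted PSMs of one run.

    Shared peptides are credited to every parent; ORFs with identical
    peptide sets collapse to one group represented by the
    lexicographically smallest orf_id. Groups whose peptides are all
    shared with other groups are retained but flagged ``shared_only``.
    """
    pep_by_orf: dict[str, set[str]] = {}
    for p in psms:
        if not p.accepted:
            continue
        for orf in p.parent_ids:
            pep_by_orf.setdefault(orf, set()).add(p.peptide.seq)

    # collapse identical peptide sets
    groups: dict[frozenset[str], list[str]] = {}
    for orf, peps in pep_by_orf.items():
        groups.setdefault(frozenset(peps), []).append(orf)

    reps = {min(members): (peps, frozenset(members)) for peps, members in groups.items()}
    pep_owner: dict[str, set[str]] = {}
    for rep, (peps, _members) in reps.items():
        for pep in peps:
            pep_owner.setdefault(pep, set()).add(rep)

    out: list[ProteinIdentification] = []
    for rep in sorted(reps):
        peps, members = reps[rep]
        if len(peps) < min_peptides:
            continue
        shared_with = frozenset(
            other for pep in peps for other in pep_owner[pep] if other != rep
        )
        shared_only = all(len(pep_owner[pep]) > 1 for pep in peps)
        out.append(
            ProteinIdentification(
                orf_id=rep,
                sample=meta.sample,
                fraction=meta.fraction,
                replicate=meta.replicate,
                peptides=peps,
                members=members,
                shared_with=shared_with,
                shared_only=shared_only,
            )
        )
    return out


def round_two(
    runs: list[tuple[RunMeta, list[Spectrum]]],
    round1: RoundOneResult,
    contigs: list[Contig],
    cfg: MatchConfig,
    min_orf_nt: int = 301,
    longest_per_stop: bool = True,
    min_peptides: int = 1,
) -> tuple[OrfLibrary, list[ProteinIdentification]]:
    """Protein-level search of the original spectra against the
    matched-contig ORF library; returns the library and per-run
    identifications."""
    library = build_library(
        contigs,
        restrict_to=set(round1.matched_contig_ids),
        min_nt=min_orf_nt,
        longest_per_stop=longest_per_stop,
    )
    if len(library) == 0:
        return library, []
    db = PeptideDb(library.as_dict(), cfg)
    identifications: list[ProteinIdentification] = []
    for meta, spectra in runs:
        psms = search_run(spectra, db, cfg)
        accepted = [p for p in psms if p.accepted]
        log.info("round 2 %s: %d accepted PSMs", meta.run_id, len(accepted))
        identifications.extend(infer_proteins(accepted, meta, min_peptides))
    return library, identifications


def run_two_round(
    runs: list[tuple[RunMeta, list[Spectrum]]],
    contigs: list[Contig],
    cfg: MatchConfig,
    min_orf_nt: int = 301,
    longest_per_stop: bool = True,
    min_peptides: int = 1,
) -> tuple[RoundOneResult, OrfLibrary, list[ProteinIdentification]]:
    """Full strategy over one sample: round 1 on the pooled spectra of all
    runs, round 2 per run against the matched-contig ORF library."""
    pooled = [s for _meta, spectra in runs for s in spectra]
    r1 = round_one(pooled, contigs, cfg)
    library, idents = round_two(
        runs, r1, contigs, cfg,
        min_orf_nt=min_orf_nt,
        longest_per_stop=longest_per_stop,
        min_peptides=min_peptides,
    )
    return r1, library, idents
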