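"""Peptide-spectrum matching with target-decoy expect calibration.

This is a deliberately simple, fully documented search engine: candidate
peptides are selected by precursor mass within a ppm tolerance, scored by
the number of theoretical singly charged b- and y-ions matched by an
observed peak within the fragment tolerance, and calibrated against a
pseudo-reversed decoy database. The ``expect`` of a PSM is the empirical
fraction of decoy best hits (same precursor charge) scoring at least as
high, with a +1 pseudocount; rank-1 target PSMs with expect at or below
the cutoff (default 0.05) are accepted. Externally produced PSM tables in
the same schema can be imported instead of running this engine.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import PROTON_MASS, WATER_MONO
from .digestion import (
    Mod,
    NonCanonicalResidue,
    Peptide,
    digest,
    variable_mod_forms,
)
from .constants import CARBAMIDOMETHYL, MONO_RESIDUE_MASS
from .seq_io import Spectrum

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchConfig:
    """Search-engine settings; defaults mirror a 10 ppm / 0.1 Da QTOF search."""

    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.1
    expect_cutoff: float = 0.05
    max_missed: int = 1
    max_var_mods: int = 3
    decoy_mode: str = "reverse"
    min_decoys_for_empirical: int = 50

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class Psm:
    """One peptide-to-spectrum assignment."""

    spectrum_id: str
    peptide: Peptide
    parent_ids: frozenset[str]
    score: float
    ppm_error: float
    is_decoy: bool
    charge: int
    rank: int = 1
    expect: float = math.inf
    accepted: bool = False


def pseudo_reverse(seq: str) -> str:
    """Reverse a tryptic peptide keeping its C-terminal residue in place,
    so decoys keep tryptic termini and a target-like mass distribution."""
    if len(seq) <= 2:
        return seq
    return seq[-2::-1] + seq[-1]


class PeptideDb:
    """Mass-indexed target+decoy peptide database built from a protein map."""

    def __init__(
        self,
        proteins: dict[str, str],
        cfg: MatchConfig,
        with_decoys: bool = True,
    ) -> None:
        entries: dict[tuple[str, tuple[Mod, ...], bool], set[str]] = {}
        for pid, aa in proteins.items():
            for pep in digest(aa, max_missed=cfg.max_missed):
                for is_decoy, seq in self._forms(pep.seq, with_decoys):
                    for mods in variable_mod_forms(seq, cfg.max_var_mods):
                        entries.setdefault((seq, mods, is_decoy), set()).add(pid)
        rows = []
        for (seq, mods, is_decoy), parents in entries.items():
            try:
                pep = Peptide(seq=seq, mods=mods)
            except NonCanonicalResidue:
                continue
            rows.append((pep.mono_mass, pep, frozenset(parents), is_decoy))
        rows.sort(key=lambda r: (r[0], r[1].seq, r[1].mods, r[3]))
        self._masses = np.array([r[0] for r in rows])
        self._rows = rows

    @staticmethod
    def _forms(seq: str, with_decoys: bool):
        yield (False, seq)
        if with_decoys:
            rev = pseudo_reverse(seq)
            if rev != seq:
                yield (True, rev)

    def __len__(self) -> int:
        return len(self._rows)

    @property
    def n_decoys(self) -> int:
        return sum(1 for r in self._rows if r[3])

    def candidates(
        self, spectrum: Spectrum, cfg: MatchConfig
    ) -> list[tuple[Peptide, frozenset[str], bool, float]]:
        """Peptides within the precursor ppm tolerance of the spectrum's
        neutral mass, as (peptide, parents, is_decoy, ppm_error)."""
        if spectrum.charge is None:
            raise ValueError(f"spectrum {spectrum.id!r}: unknown charge")
        z = spectrum.charge
        observed = spectrum.precursor_mz * z - z * PROTON_MASS
        tol = observed * cfg.precursor_tol_ppm * 1e-6
        lo = np.searchsorted(self._masses, observed - tol, side="left")
        hi = np.searchsorted(self._masses, observed + tol, side="right")
        out = []
        for mass, pep, parents, is_decoy in self._rows[lo:hi]:
            ppm = 1e6 * (observed - mass) / mass
            if abs(ppm) <= cfg.precursor_tol_ppm:
                out.append((pep, parents, is_decoy, ppm))
        return out


def theoretical_by_ions(peptide: Peptide) -> np.ndarray:
    """Sorted m/z of all singly charged b- and y-ions, modifications applied."""
    seq = peptide.seq
    n = len(seq)
    res = np.array([MONO_RESIDUE_MASS[a] + (CARBAMIDOMETHYL if a == "C" else 0.0)
                    for a in seq])
    for pos, _name, delta in peptide.mods:
        res[pos] += delta
    prefix = np.cumsum(res)
    total = prefix[-1]
    b = prefix[: n - 1] + PROTON_MASS
    y = (total - prefix[: n - 1]) + WATER_MONO + PROTON_MASS
    return np.sort(np.concatenate([b, y]))


def score_psm(spectrum: Spectrum, peptide: Peptide, cfg: MatchConfig) -> float:
    """Shared-peak count: theoretical b/y ions matched by any observed peak
    within the fragment tolerance, each theoretical ion at most once."""
    if spectrum.n_peaks == 0:
        return 0.0
    theo = theoretical_by_ions(peptide)
    lo = np.searchsorted(spectrum.mz, theo - cfg.fragment_tol_da, side="left")
    hi = np.searchsorted(spectrum.mz, theo + cfg.fragment_tol_da, side="right")
    return float(np.count_nonzero(hi > lo))


def _best_hits(
    spectrum: Spectrum, db: PeptideDb, cfg: MatchConfig
) -> tuple[Psm | None, float | None]:
    """(overall rank-1 PSM, best decoy score) for one spectrum.

    The best decoy score is kept even when a target wins rank 1: the
    per-spectrum decoy optimum is the null observation used for expect
    calibration.
    """
    cands = db.candidates(spectrum, cfg)
    if not cands:
        return None, None
    scored = []
    for pep, parents, is_decoy, ppm in cands:
        s = score_psm(spectrum, pep, cfg)
        # total tie-break: score desc, |ppm| asc, sequence, smallest parent
        scored.append(
            (-s, abs(ppm), pep.seq, min(parents), s, pep, parents, is_decoy, ppm)
        )
    scored.sort(key=lambda t: t[:4])
    _, _, _, _, s, pep, parents, is_decoy, ppm = scored[0]
    decoy_scores = [t[4] for t in scored if t[7]]
    best_decoy = max(decoy_scores) if decoy_scores else None
    psm = Psm(
        spectrum_id=spectrum.id,
        peptide=pep,
        parent_ids=parents,
        score=s,
        ppm_error=ppm,
        is_decoy=is_decoy,
        charge=spectrum.charge,
        rank=1,
    )
    return psm, best_decoy


def _poisson_sf(k: int, lam: float) -> float:
    return float(
        1.0 - sum(math.exp(-lam) * lam**i / math.factorial(i) for i in range(k))
    )


def assign_expect(
    psms: list[Psm],
    cfg: MatchConfig,
    null_scores: dict[int, list[float]] | None = None,
) -> list[Psm]:
    """Fill in expect values from the decoy score distribution.

    The null per precursor-charge stratum is the per-spectrum best decoy
    score; expect(s) = (1 + #{null >= s}) / (1 + N_null). Strata with
    fewer nulls than ``cfg.min_decoys_for_empirical`` pool across
    charges; if the pooled null is still too small the analytic fallback
    models the decoy score as Poisson with the mean null score (1.0 when
    no decoys at all) and a logged notice. Rank-1 target PSMs with
    expect <= cutoff are marked accepted.
    """
    if null_scores is None:
        null_scores = {}
        for p in psms:
            if p.is_decoy:
                null_scores.setdefault(p.charge, []).append(p.score)
    pooled = np.sort(np.concatenate([np.asarray(v) for v in null_scores.values()])
                     if null_scores else np.empty(0))
    out: list[Psm] = []
    by_charge: dict[int, list[Psm]] = {}
    for p in psms:
        by_charge.setdefault(p.charge, []).append(p)
    for charge, group in by_charge.items():
        nulls = np.sort(np.asarray(null_scores.get(charge, [])))
        if nulls.size < cfg.min_decoys_for_empirical:
            nulls = pooled
        if nulls.size >= cfg.min_decoys_for_empirical:
            nd = nulls.size
            for p in group:
                n_ge = nd - int(np.searchsorted(nulls, p.score, side="left"))
                expect = (1.0 + n_ge) / (1.0 + nd)
                accepted = (
                    (not p.is_decoy) and p.rank == 1
                    and expect <= cfg.expect_cutoff
                )
                out.append(replace(p, expect=expect, accepted=accepted))
        else:
            lam = float(nulls.mean()) if nulls.size else 1.0
            lam = max(lam, 0.25)  # degenerate all-zero null
            log.warning(
                "charge %d: only %d decoy scores, Poisson(%.2f) expect fallback",
                charge, nulls.size, lam,
            )
            for p in group:
                expect = max(_poisson_sf(int(math.ceil(p.score)), lam), 1e-12)
                accepted = (
                    (not p.is_decoy) and p.rank == 1
                    and expect <= cfg.expect_cutoff
                )
                out.append(replace(p, expect=expect, accepted=accepted))
    out.sort(key=lambda p: p.spectrum_id)
    return out


def search_run(
    spectra: Iterable[Spectrum], db: PeptideDb, cfg: MatchConfig
) -> list[Psm]:
    """Rank-1 search of one run: candidates, scoring, expect calibration.

    Spectra with unknown charge or empty peak lists are skipped with a
    warning. Output order is deterministic (sorted by spectrum id), so
    repeated runs on identical input are byte-identical.
    """
    rank1: list[Psm] = []
    null_scores: dict[int, list[float]] = {}
    for s in spectra:
        if s.charge is None:
            log.warning("spectrum %s: unknown charge, skipped", s.id)
            continue
        if s.n_peaks == 0:
            log.warning("spectrum %s: empty peak list, skipped", s.id)
            continue
        p, best_decoy = _best_hits(s, db, cfg)
        if p is not None:
            rank1.append(p)
        if best_decoy is not None:
            null_scores.setdefault(s.charge, []).append(best_decoy)
    return assign_expect(rank1, cfg, null_scores)


PSM_COLUMNS = [
    "spectrum_id", "peptide", "mods", "parents", "score",
    "expect", "ppm_error", "charge", "is_decoy", "accepted",
]


def write_psm_table(psms: Sequence[Psm], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PSM_COLUMNS)
        for p in psms:
            mods = ";".join(f"{pos}:{name}" for pos, name, _ in p.peptide.mods)
            w.writerow([
                p.spectrum_id, p.peptide.seq, mods,
                ";".join(sorted(p.parent_ids)),
                f"{p.score:g}", f"{p.expect:.6g}", f"{p.ppm_error:.4f}",
                p.charge, int(p.is_decoy), int(p.accepted),
            ])


def read_psm_table(path: str | Path, expect_cutoff: float = 0.05) -> list[Psm]:
    """Import an externally produced PSM table (same schema, score optional)."""
    psms: list[Psm] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            expect = float(row["expect"])
            is_decoy = bool(int(row.get("is_decoy", 0) or 0))
            psms.append(
                Psm(
                    spectrum_id=row["spectrum_id"],
                    peptide=Peptide(seq=row["peptide"]),
                    parent_ids=frozenset(row["parents"].split(";")),
                    score=float(row.get("score", 0) or 0),
                    ppm_error=float(row.get("ppm_error", 0) or 0),
                    is_decoy=is_decoy,
                    charge=int(row.get("charge", 2) or 2),
                    expect=expect,
                    accepted=(not is_decoy) and expect <= expect_cutoff,
                )
            )
    return psms
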