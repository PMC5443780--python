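"""Sequence and spectrum I/O.

FASTA reading/writing goes through Biopython; MGF through pyteomics.
Both are wrapped to enforce the pipeline's contracts: uppercase-normalised
IUPAC nucleotide contigs with unique ids, and spectra with a positive
precursor, a known (or defaulted) charge and m/z-sorted peaks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .constants import IUPAC_NT


class ParseError(ValueError):
    """Malformed input file; message carries file and, where known, line."""


class ValidationError(ValueError):
    """Input parsed but violates a pipeline invariant."""


@dataclass
class Contig:
    """One assembled nucleotide sequence (the round-1 search universe)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("contig id must be non-empty")
        self.seq = self.seq.upper().replace("U", "T")
        if not self.seq:
            raise ValidationError(f"contig {self.id!r}: empty sequence")
        bad = set(self.seq) - IUPAC_NT
        if bad:
            raise ValidationError(
                f"contig {self.id!r}: non-IUPAC letters {sorted(bad)}"
            )


@dataclass
class Spectrum:
    """One tandem mass spectrum.

    ``charge`` may be None when the file omitted it and no default was
    configured; such spectra are skipped by the matcher with a warning.
    """

    id: str
    precursor_mz: float
    charge: int | None
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValidationError(f"spectrum {self.id!r}: precursor_mz <= 0")
        if self.charge is not None and self.charge <= 0:
            raise ValidationError(f"spectrum {self.id!r}: non-positive charge")
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError(f"spectrum {self.id!r}: peak array mismatch")
        if np.any(self.intensity < 0):
            raise ValidationError(f"spectrum {self.id!r}: negative intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


def read_fasta(path: str | Path) -> Iterator[Contig]:
    """Stream contigs from a FASTA file.

    Ids are the header truncated at the first whitespace; the full header
    is kept as ``description``. Duplicate ids and text before the first
    header are rejected.
    """
    path = Path(path)
    with open(path) as handle:
        # Biopython silently skips leading junk; enforce the contract here.
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        yield Contig(id=rec.id, seq=str(rec.seq), description=rec.description)


def write_fasta(records: Iterable[Contig], path: str | Path, width: int = 60) -> int:
    """Write contigs (or any id/seq records) as wrapped FASTA; returns count."""
    seq_records = (
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    )
    n = SeqIO.write(seq_records, str(path), "fasta")
    return n


def write_protein_fasta(entries: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write (id, description, aa_seq) triples as amino-acid FASTA."""
    recs = (SeqRecord(Seq(aa), id=pid, description=desc) for pid, desc, aa in entries)
    return SeqIO.write(recs, str(path), "fasta")


def _parse_charge(raw, spectrum_id: str) -> int | None:
    if raw is None:
        return None
    # pyteomics yields a ChargeList; MGF dialects write "2+" or "2".
    if isinstance(raw, (list, tuple)):
        if not raw:
            return None
        raw = raw[0]
    z = int(raw)
    if z <= 0:
        raise ParseError(f"spectrum {spectrum_id!r}: negative or zero charge {z}")
    return z


def read_mgf(path: str | Path, default_charge: int | None = None) -> Iterator[Spectrum]:
    """Stream spectra from an MGF file.

    Blocks missing a CHARGE header get ``default_charge`` (possibly None).
    Peak lists may be empty; such spectra are flagged unusable downstream
    rather than rejected here.
    """
    path = Path(path)
    counter = itertools.count(1)
    try:
        with _mgf.MGF(str(path)) as reader:
            for entry in reader:
                params = entry["params"]
                sid = str(params.get("title", f"scan{next(counter)}"))
                pepmass = params.get("pepmass")
                if pepmass is None:
                    raise ParseError(f"{path}: block {sid!r} missing PEPMASS")
                mz0 = pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass
                charge = _parse_charge(params.get("charge"), sid)
                if charge is None:
                    charge = default_charge
                yield Spectrum(
                    id=sid,
                    precursor_mz=float(mz0),
                    charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
    except ParseError:
        raise
    except Exception as exc:  # pyteomics raises assorted errors on bad blocks
        raise ParseError(f"{path}: malformed MGF ({exc})") from exc


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with TITLE/PEPMASS/CHARGE headers."""
    entries = []
    for s in spectra:
        params = {"title": s.id, "pepmass": s.precursor_mz}
        if s.charge is not None:
            params["charge"] = s.charge
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(entries, str(path), file_mode="w")
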