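"""In-silico tryptic digestion, peptide masses and emPAI observability.

Trypsin cleaves after K or R except when the next residue is P. Fixed
carbamidomethylation of Cys is always applied; oxidised Met and
deamidated Asn/Gln are the variable modifications, capped at three
variable mods per peptide to bound the combinatorics.

The emPAI denominator (``count_observable``) counts distinct fully
tryptic peptide sequences whose m/z falls inside the instrument
acquisition window at some allowed charge — an acquisition-window proxy
for the retention-time-based observability of the original emPAI
formulation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .constants import (
    CANONICAL_RESIDUES,
    CARBAMIDOMETHYL,
    MONO_RESIDUE_MASS,
    PROTON_MASS,
    VARIABLE_MODS,
    WATER_MONO,
)

Mod = tuple[int, str, float]  # (0-based position, name, delta Da)


class NonCanonicalResidue(ValueError):
    """Peptide contains X/B/Z etc.; treat as unobservable, not a crash."""


@dataclass(frozen=True)
class Peptide:
    """One tryptic peptide, optionally carrying variable modifications."""

    seq: str
    missed_cleavages: int = 0
    mods: tuple[Mod, ...] = ()
    mono_mass: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if self.mono_mass == 0.0:
            object.__setattr__(self, "mono_mass", peptide_mass(self.seq, self.mods))

    def mz(self, charge: int) -> float:
        return (self.mono_mass + charge * PROTON_MASS) / charge


def peptide_mass(seq: str, mods: tuple[Mod, ...] = ()) -> float:
    """Neutral monoisotopic mass: residues + water + fixed C mod + mods."""
    mass = WATER_MONO
    for aa in seq:
        try:
            mass += MONO_RESIDUE_MASS[aa]
        except KeyError:
            raise NonCanonicalResidue(f"residue {aa!r} in {seq!r}") from None
        if aa == "C":
            mass += CARBAMIDOMETHYL
    for pos, _name, delta in mods:
        if not 0 <= pos < len(seq):
            raise ValueError(f"mod position {pos} outside {seq!r}")
        mass += delta
    return mass


def cleavage_sites(protein: str) -> list[int]:
    """Positions after which trypsin cuts (0-based, cut between i and i+1),
    plus the two sequence boundaries, ascending."""
    sites = [0]
    for i in range(len(protein) - 1):
        if protein[i] in "KR" and protein[i + 1] != "P":
            sites.append(i + 1)
    sites.append(len(protein))
    return sites


def digest(protein: str, max_missed: int = 1) -> list[Peptide]:
    """All fully tryptic peptides with 0..max_missed internal missed
    cleavages, ordered N-to-C within each missed-cleavage count."""
    if not protein:
        raise ValueError("empty protein")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    sites = cleavage_sites(protein)
    peptides: list[Peptide] = []
    for mc in range(max_missed + 1):
        for i in range(len(sites) - 1 - mc):
            seq = protein[sites[i] : sites[i + 1 + mc]]
            try:
                peptides.append(Peptide(seq=seq, missed_cleavages=mc))
            except NonCanonicalResidue:
                # keep the peptide for bookkeeping with mass 0? No: peptides
                # with X cannot be searched or weighed; skip them entirely.
                continue
    return peptides


def variable_mod_forms(seq: str, max_var_mods: int = 3) -> list[tuple[Mod, ...]]:
    """Every combination of variable modifications up to the cap,
    including the unmodified form (empty tuple first)."""
    sites: list[Mod] = [
        (i, VARIABLE_MODS[aa][0], VARIABLE_MODS[aa][1])
        for i, aa in enumerate(seq)
        if aa in VARIABLE_MODS
    ]
    forms: list[tuple[Mod, ...]] = [()]
    for k in range(1, min(max_var_mods, len(sites)) + 1):
        forms.extend(itertools.combinations(sites, k))
    return forms


@dataclass(frozen=True)
class ObservabilityWindow:
    """Peptide length and acquisition-window bounds defining N_observable.

    Defaults mirror a QTOF acquisition of m/z 150-2000 with preferred
    charge states 2-4 and singly charged ions excluded.
    """

    min_len: int = 6
    max_len: int = 40
    mz_min: float = 150.0
    mz_max: float = 2000.0
    charges: frozenset[int] = frozenset({2, 3, 4})

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.mz_min >= self.mz_max:
            raise ValueError("invalid observability window")

    def admits(self, peptide: Peptide) -> bool:
        if not self.min_len <= len(peptide.seq) <= self.max_len:
            return False
        return any(
            self.mz_min <= peptide.mz(z) <= self.mz_max for z in self.charges
        )


def count_observable(
    protein: str,
    window: ObservabilityWindow = ObservabilityWindow(),
    max_missed: int = 1,
) -> int:
    """Number of distinct observable fully tryptic peptide sequences.

    Distinctness is at the sequence level (modified forms of one sequence
    count once); peptides with non-canonical residues are excluded.
    """
    seen: set[str] = set()
    for p in digest(protein, max_missed=max_missed):
        if p.seq in seen:
            continue
        if window.admits(p):
            seen.add(p.seq)
    return len(seen)
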