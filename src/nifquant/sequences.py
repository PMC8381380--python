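"""Protein sequence handling: tryptic digestion, mass/m-z arithmetic, motif scan.

Masses are monoisotopic throughout, the convention of targeted (SRM)
proteomics.  Heavy peptides carry a [13C6,15N2] label on every lysine and
arginine residue, adding 8.0142 Da per K/R; the shift is configurable for
users whose standards use a different arginine label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import HEAVY_SHIFT_KR, PROTON_MASS, WATER_MASS

#: Monoisotopic residue (amino-acid minus water) masses, Da.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

CANONICAL_RESIDUES = frozenset(RESIDUE_MASSES)

LabelState = Literal["light", "heavy"]


def _check_canonical(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    for i, aa in enumerate(sequence):
        if aa not in CANONICAL_RESIDUES:
            raise ValueError(
                f"non-canonical residue {aa!r} at position {i + 1} in {sequence!r}"
            )


@dataclass(frozen=True)
class ProteinEntry:
    """A protein sequence with a stable identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        _check_canonical(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue_counts(self) -> dict[str, int]:
        return {aa: self.sequence.count(aa) for aa in CANONICAL_RESIDUES}


@dataclass(frozen=True)
class Peptide:
    """A tryptic fragment located within a parent protein.

    ``start``/``end`` are 1-based inclusive residue coordinates in the
    parent sequence.
    """

    sequence: str
    parent_id: str = ""
    start: int = 1
    end: int = 0
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        _check_canonical(self.sequence)
        end = self.end if self.end else self.start + len(self.sequence) - 1
        object.__setattr__(self, "end", end)
        if self.end < self.start:
            raise ValueError("end < start")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1.

    Trypsin cleaves C-terminal to K or R unless the following residue is
    proline.
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest_trypsin(
    sequence: str, missed_cleavages: int = 0, parent_id: str = ""
) -> list[Peptide]:
    """In-silico tryptic digest.

    Returns all fully tryptic fragments spanning at most ``missed_cleavages``
    internal retained cut sites, ordered by start position then length.  With
    ``missed_cleavages=0`` the fragments concatenate to the input.
    """
    _check_canonical(sequence)
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    cuts = cleavage_sites(sequence)
    # fragment boundaries: [start, end] 0-based inclusive
    starts = [0] + [c + 1 for c in cuts]
    ends = cuts + [len(sequence) - 1]
    peptides: list[Peptide] = []
    for i, s in enumerate(starts):
        for m in range(missed_cleavages + 1):
            j = i + m
            if j >= len(ends):
                break
            e = ends[j]
            peptides.append(
                Peptide(
                    sequence=sequence[s : e + 1],
                    parent_id=parent_id,
                    start=s + 1,
                    end=e + 1,
                    missed_cleavages=m,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def peptide_mass(
    sequence: str,
    label_state: LabelState = "light",
    heavy_shift: float = HEAVY_SHIFT_KR,
    modification_mass: float = 0.0,
) -> float:
    """Monoisotopic neutral mass of a peptide (Da).

    ``heavy`` adds ``heavy_shift`` per K and per R; ``modification_mass``
    covers covalent adducts such as uridylylation (+306.0253 Da).
    """
    _check_canonical(sequence)
    mass = sum(RESIDUE_MASSES[aa] for aa in sequence) + WATER_MASS
    if label_state == "heavy":
        mass += heavy_shift * sum(sequence.count(aa) for aa in "KR")
    elif label_state != "light":
        raise ValueError(f"unknown label state {label_state!r}")
    return mass + modification_mass


def ion_mz(
    sequence: str,
    charge: int,
    ion: str = "precursor",
    label_state: LabelState = "light",
    heavy_shift: float = HEAVY_SHIFT_KR,
    modification_mass: float = 0.0,
) -> float:
    """m/z of the precursor or a y-series fragment ion.

    ``ion`` is ``"precursor"`` or ``"y<n>"`` where n counts residues from
    the C terminus (so ``y_len`` is the full peptide).  The modification
    mass, if any, is attributed to the full peptide only (precursor and
    full-length y-ion); site-resolved fragment bookkeeping is out of scope.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if ion == "precursor":
        neutral = peptide_mass(sequence, label_state, heavy_shift, modification_mass)
    elif ion.startswith("y"):
        n = int(ion[1:])
        if not 1 <= n <= len(sequence):
            raise ValueError(f"y-ion index {n} out of range for {sequence!r}")
        frag = sequence[len(sequence) - n :]
        mod = modification_mass if n == len(sequence) else 0.0
        neutral = peptide_mass(frag, label_state, heavy_shift, mod)
    else:
        raise ValueError(f"unknown ion type {ion!r}")
    return (neutral + charge * PROTON_MASS) / charge


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def scan_sigma54(
    dna: str, include_reverse_complement: bool = False
) -> list[int]:
    """Scan for the sigma-54 promoter consensus TGGC-N7-TTGC.

    Returns 0-based start positions of every 15-mer window matching the
    consensus on the given strand (plus, optionally, windows whose reverse
    complement matches, reported by their position on the input strand).
    Windows containing non-ACGT bases are skipped with a warning.
    """
    dna = dna.upper()
    hits: list[int] = []
    strands = [dna]
    if include_reverse_complement:
        strands.append(dna.translate(_COMPLEMENT)[::-1])
    n = len(dna)
    for strand_i, seq in enumerate(strands):
        for i in range(n - 14):
            window = seq[i : i + 15]
            if any(b not in "ACGT" for b in window):
                warnings.warn(
                    f"ambiguous base in window at {i}; skipped", stacklevel=2
                )
                continue
            if window[:4] == "TGGC" and window[11:] == "TTGC":
                hits.append(i if strand_i == 0 else n - 15 - i)
    return sorted(set(hits))


# ---------------------------------------------------------------------------
# FASTA / TSV I/O

def read_fasta(path: str | Path) -> list[ProteinEntry]:
    return [
        ProteinEntry(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.id, description="") for e in entries
    ]
    SeqIO.write(records, str(path), "fasta")


def write_digest_tsv(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Digest table: protein_id, peptide, start, end (1-based inclusive), m."""
    with open(path, "w") as fh:
        fh.write("protein_id\tpeptide\tstart\tend\tmissed_cleavages\n")
        for p in peptides:
            fh.write(
                f"{p.parent_id}\t{p.sequence}\t{p.start}\t{p.end}\t{p.missed_cleavages}\n"
            )
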