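"""Protein-product annotation: amino-acid length and average molecular
mass of transcript protein products.

Masses use the average (isotope-abundance-weighted) residue scale, which
is the scale gel-electrophoresis band positions are read on, with one
water added per chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.SeqUtils import molecular_weight

__all__ = ["ProteinRecord", "protein_length", "protein_mass", "annotate_records"]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ProteinRecord:
    transcript_id: str
    sequence: str
    length_aa: int
    mass_kda: float  # rounded to 0.1 kDa


def _check_sequence(sequence: str) -> str:
    seq = sequence.strip().upper().rstrip("*")
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"invalid amino-acid codes: {sorted(bad)}")
    return seq


def protein_length(sequence: str) -> int:
    """Residue count of a protein sequence (standard 20-letter alphabet)."""
    return len(_check_sequence(sequence))


def protein_mass(sequence: str) -> float:
    """Average molecular mass in kDa (unrounded).

    Sum of average residue masses plus one water; e.g. a single glycine
    weighs 57.05 + 18.02 = 75.07 Da.
    """
    seq = _check_sequence(sequence)
    return molecular_weight(seq, seq_type="protein", monoisotopic=False) / 1000.0


def annotate_records(records: dict[str, str]) -> pd.DataFrame:
    """Length/mass table for an id -> sequence mapping (e.g. from FASTA).

    Masses are reported rounded to 0.1 kDa, the precision at which
    protein band positions are read.
    """
    rows = [
        ProteinRecord(tid, _check_sequence(seq), protein_length(seq), round(protein_mass(seq), 1))
        for tid, seq in records.items()
    ]
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in rows],
            "length_aa": [r.length_aa for r in rows],
            "mass_kda": [r.mass_kda for r in rows],
        }
    )
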