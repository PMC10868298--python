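"""Genetic-code tables and the codon state-index convention.

Sense codons (non-stop codons) define the state space of codon substitution
models.  The state-index convention used throughout the package is
lexicographic codon order over the nucleotide ordering (T, C, A, G), i.e.
TTT, TTC, TTA, TTG, TCT, ... — the ordering classical codon-model software
uses.  Code tables come from the NCBI translation tables shipped with
Biopython.
"""

from __future__ import annotations

import itertools

from Bio.Data import CodonTable

from .exceptions import UnsupportedCodeError

#: Nucleotide ordering used for codon enumeration.
CODON_NUCLEOTIDE_ORDER = "TCAG"

#: Supported genetic codes, mapped to NCBI translation-table ids.
GENETIC_CODE_IDS = {
    "universal": 1,
    "standard": 1,
    "vertebrate-mitochondrial": 2,
    "vertebrate_mitochondrial": 2,
}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def _table(code: str) -> CodonTable.CodonTable:
    key = code.strip().lower().replace(" ", "-")
    try:
        ncbi_id = GENETIC_CODE_IDS[key]
    except KeyError:
        raise UnsupportedCodeError(
            f"unknown genetic code {code!r}; supported: {sorted(set(GENETIC_CODE_IDS))}"
        ) from None
    return CodonTable.unambiguous_dna_by_id[ncbi_id]


def all_codons() -> list[str]:
    """All 64 codons in (T, C, A, G)-lexicographic order."""
    return ["".join(c) for c in itertools.product(CODON_NUCLEOTIDE_ORDER, repeat=3)]


def stop_codons(code: str = "universal") -> frozenset[str]:
    return frozenset(_table(code).stop_codons)


def sense_codons(code: str = "universal") -> list[str]:
    """Sense codons of ``code`` in the package's state-index order.

    The universal code has 61 sense codons; the vertebrate mitochondrial
    code has 60 (AGA/AGG are additional stops, ATA/TGA are sense).  The
    state count of a codon model is always derived from this list, never
    hard-coded.
    """
    stops = stop_codons(code)
    return [c for c in all_codons() if c not in stops]


def genetic_code_table(code: str = "universal") -> dict[str, str]:
    """Codon -> one-letter amino acid; stop codons map to ``"*"``."""
    tab = _table(code)
    out = dict(tab.forward_table)
    for c in tab.stop_codons:
        out[c] = "*"
    return out


def is_transition(a: str, b: str) -> bool:
    """True when nucleotides a, b differ by a transition (purine<->purine
    or pyrimidine<->pyrimidine)."""
    return a != b and (
        (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)
    )


def single_nucleotide_difference(c1: str, c2: str) -> int | None:
    """Position (0..2) at which two codons differ, or None unless they
    differ at exactly one position."""
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    if len(diffs) == 1:
        return diffs[0]
    return None
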