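"""Alignment I/O, site-pattern compression, codon translation, tip encoding.

Alignments are sequences of per-taxon symbol lists: one-character symbols
for nucleotides, three-character codon strings after translation.  Columns
with identical tip symbols are collapsed to unique site patterns with
integer weights (first-occurrence order), so the likelihood engine touches
each distinct column once.

Tip states are encoded per the indicator rule: an observed state s yields a
0/1 vector with a single 1 at s; IUPAC ambiguity codes (and, for codons,
codons containing ambiguous nucleotides) yield 1 at every compatible state;
gaps and unknowns yield the all-ones vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Union

import numpy as np
from Bio import SeqIO

from . import codes
from .exceptions import AlignmentError, EncodingError, ParseError

StateCode = Union[int, frozenset]
StateMap = Union[Mapping[str, StateCode], Callable[[str], StateCode]]

__all__ = [
    "Alignment",
    "PatternAlignment",
    "TipEncoding",
    "read_fasta",
    "write_fasta",
    "compress_patterns",
    "translate_codons",
    "encode_tips",
    "nucleotide_state_map",
    "codon_state_encoder",
    "markov_modulated_state_encoder",
    "generic_state_map",
    "IUPAC_NUCLEOTIDE",
]

NUC_ORDER = "ACGT"

#: IUPAC nucleotide codes -> compatible state-index sets over (A, C, G, T).
IUPAC_NUCLEOTIDE: dict[str, frozenset] = {
    "A": frozenset({0}),
    "C": frozenset({1}),
    "G": frozenset({2}),
    "T": frozenset({3}),
    "U": frozenset({3}),
    "R": frozenset({0, 2}),
    "Y": frozenset({1, 3}),
    "S": frozenset({1, 2}),
    "W": frozenset({0, 3}),
    "K": frozenset({2, 3}),
    "M": frozenset({0, 1}),
    "B": frozenset({1, 2, 3}),
    "D": frozenset({0, 2, 3}),
    "H": frozenset({0, 1, 3}),
    "V": frozenset({0, 1, 2}),
    "N": frozenset({0, 1, 2, 3}),
    "-": frozenset({0, 1, 2, 3}),
    "?": frozenset({0, 1, 2, 3}),
    ".": frozenset({0, 1, 2, 3}),
}


@dataclass
class Alignment:
    """Rectangular multiple sequence alignment over an arbitrary symbol set."""

    taxon_names: list[str]
    rows: list[list[str]]

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise AlignmentError("alignment needs at least two sequences")
        if len(set(self.taxon_names)) != self.n_taxa:
            raise ParseError("duplicate sequence names")
        L = self.length
        for name, row in zip(self.taxon_names, self.rows):
            if len(row) != L:
                raise AlignmentError(
                    f"sequence {name!r} has length {len(row)}, expected {L}"
                )


@dataclass
class PatternAlignment:
    """Unique site patterns with multiplicities.

    ``tip_states[n][c]`` is either an integer state index or a frozenset of
    compatible state indices for taxon n at pattern c.  Patterns appear in
    first-occurrence order.
    """

    taxon_names: list[str]
    tip_states: list[list[StateCode]]
    weights: np.ndarray
    state_count: int

    @property
    def pattern_count(self) -> int:
        return len(self.weights)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    def validate(self) -> None:
        if np.any(self.weights <= 0):
            raise AlignmentError("pattern weights must be positive")
        seen = set()
        for c in range(self.pattern_count):
            col = tuple(self.tip_states[n][c] for n in range(self.n_taxa))
            if col in seen:
                raise AlignmentError("duplicate site pattern after compression")
            seen.add(col)
            for n, st in enumerate(col):
                if isinstance(st, frozenset) and not st:
                    raise EncodingError("empty compatibility set", taxon=n, column=c)


@dataclass
class TipEncoding:
    """Engine-ready tip states.

    ``indicators``: (N, C, S) 0/1 array (dense partial-likelihood form).
    ``compact``: (N, C) int array with the state index where unambiguous
    and -1 where a compatibility set is needed.
    """

    indicators: np.ndarray
    compact: np.ndarray


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file; characters are upper-cased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ParseError(f"duplicate FASTA header(s): {dup}")
    rows = [list(str(r.seq).upper()) for r in records]
    aln = Alignment(taxon_names=names, rows=rows)
    aln.validate()
    return aln


def write_fasta(aln: Alignment, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.taxon_names, aln.rows):
            fh.write(f">{name}\n")
            seq = "".join(row)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def nucleotide_state_map() -> dict[str, StateCode]:
    """Symbol map over (A, C, G, T) with full IUPAC ambiguity support;
    unambiguous symbols map to plain integers."""
    out: dict[str, StateCode] = {}
    for sym, st in IUPAC_NUCLEOTIDE.items():
        out[sym] = next(iter(st)) if len(st) == 1 else st
    return out


def generic_state_map(state_labels) -> dict[str, StateCode]:
    """Identity map label -> index for arbitrary state alphabets."""
    return {lab: i for i, lab in enumerate(state_labels)}


def codon_state_encoder(genetic_code: str = "universal") -> Callable[[str], StateCode]:
    """Encoder from codon symbols (possibly with ambiguous nucleotides) to
    sense-codon state indices under ``genetic_code``.

    A codon containing ambiguity or gap characters maps to the set of all
    compatible sense codons; stop codons have no state and raise.
    """
    senses = codes.sense_codons(genetic_code)
    index = {c: i for i, c in enumerate(senses)}
    all_states = frozenset(range(len(senses)))

    def encode(symbol: str) -> StateCode:
        sym = symbol.upper().replace("U", "T")
        if len(sym) != 3:
            raise EncodingError(f"codon symbol {symbol!r} is not a triplet")
        if sym in index:
            return index[sym]
        if all(ch in "ACGT" for ch in sym):
            raise EncodingError(f"stop codon {symbol!r} has no state in {genetic_code!r}")
        try:
            sets = [IUPAC_NUCLEOTIDE[ch] for ch in sym]
        except KeyError as exc:
            raise EncodingError(f"unmappable character in codon {symbol!r}") from exc
        compat = frozenset(
            i
            for c, i in index.items()
            if all(NUC_ORDER.index(c[k]) in sets[k] for k in range(3))
        )
        if not compat:
            raise EncodingError(f"codon {symbol!r} matches no sense codon")
        return compat if len(compat) > 1 else next(iter(compat))

    return encode


def markov_modulated_state_encoder(
    genetic_code: str = "universal", n_components: int = 2
) -> Callable[[str], StateCode]:
    """Encoder for Markov-modulated codon states: the observed codon is
    compatible with the same codon in every (hidden) component."""
    base = codon_state_encoder(genetic_code)
    S0 = len(codes.sense_codons(genetic_code))

    def encode(symbol: str) -> StateCode:
        st = base(symbol)
        members = {st} if isinstance(st, int) else set(st)
        return frozenset(s + k * S0 for s in members for k in range(n_components))

    return encode


def _lookup(state_map: StateMap, symbol: str, taxon: int, column: int) -> StateCode:
    try:
        if callable(state_map):
            return state_map(symbol)
        return state_map[symbol.upper()]
    except EncodingError as exc:
        raise EncodingError(
            f"{exc} (taxon {taxon}, column {column})", taxon=taxon, column=column
        ) from exc
    except KeyError:
        raise EncodingError(
            f"unmappable symbol {symbol!r} at taxon {taxon}, column {column}",
            taxon=taxon,
            column=column,
        ) from None


def compress_patterns(
    aln: Alignment, state_map: StateMap, state_count: int | None = None
) -> PatternAlignment:
    """Collapse identical columns into unique site patterns with weights.

    Pattern order is first occurrence, so downstream per-pattern outputs are
    reproducible.  The weights always sum to the original column count.
    """
    aln.validate()
    N, L = aln.n_taxa, aln.length
    if state_count is None:
        if callable(state_map):
            raise InvalidStateCountError()
        state_count = 1 + max(
            (s for v in state_map.values() for s in ([v] if isinstance(v, int) else v)),
        )
    encoded_cols: dict[tuple, int] = {}
    weights: list[int] = []
    patterns: list[tuple] = []
    for c in range(L):
        col = tuple(_lookup(state_map, aln.rows[n][c], n, c) for n in range(N))
        pos = encoded_cols.get(col)
        if pos is None:
            encoded_cols[col] = len(patterns)
            patterns.append(col)
            weights.append(1)
        else:
            weights[pos] += 1
    tip_states = [[patterns[c][n] for c in range(len(patterns))] for n in range(N)]
    pa = PatternAlignment(
        taxon_names=list(aln.taxon_names),
        tip_states=tip_states,
        weights=np.asarray(weights, dtype=np.int64),
        state_count=state_count,
    )
    pa.validate()
    return pa


class InvalidStateCountError(AlignmentError):
    def __init__(self):
        super().__init__("state_count is required when state_map is a callable")


def translate_codons(
    aln: Alignment, genetic_code: str = "universal", frame: int = 0, strict: bool = True
) -> Alignment:
    """Group a nucleotide alignment into codon columns.

    Codons containing ambiguous nucleotides or gaps are kept as triplet
    symbols and expand to compatibility sets at encoding time.  Unambiguous
    stop codons raise in strict mode and become the fully ambiguous codon
    ``NNN`` otherwise.
    """
    aln.validate()
    if frame not in (0, 1, 2):
        raise AlignmentError("frame must be 0, 1 or 2")
    L = aln.length - frame
    if L <= 0 or L % 3 != 0:
        raise AlignmentError(
            f"alignment length {aln.length} minus frame {frame} is not divisible by 3"
        )
    stops = codes.stop_codons(genetic_code)
    out_rows: list[list[str]] = []
    for n, row in enumerate(aln.rows):
        seq = "".join(row[frame:]).upper().replace("U", "T")
        cods = []
        for k in range(0, L, 3):
            cod = seq[k : k + 3]
            if cod in stops:
                if strict:
                    raise EncodingError(
                        f"stop codon {cod} in sequence {aln.taxon_names[n]!r} "
                        f"at codon position {k // 3}",
                        taxon=n,
                        column=k // 3,
                    )
                cod = "NNN"
            cods.append(cod)
        out_rows.append(cods)
    return Alignment(taxon_names=list(aln.taxon_names), rows=out_rows)


def encode_tips(pa: PatternAlignment) -> TipEncoding:
    """Dense 0/1 indicator encoding of tip states (with compact codes)."""
    N, C, S = pa.n_taxa, pa.pattern_count, pa.state_count
    ind = np.zeros((N, C, S))
    compact = np.full((N, C), -1, dtype=np.int64)
    for n in range(N):
        for c in range(C):
            st = pa.tip_states[n][c]
            if isinstance(st, (int, np.integer)):
                ind[n, c, st] = 1.0
                compact[n, c] = st
            else:
                ind[n, c, list(st)] = 1.0
    return TipEncoding(indicators=ind, compact=compact)
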