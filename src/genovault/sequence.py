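"""Nucleotide and protein string primitives.

Sequences are plain upper-case Python strings over the DNA alphabet plus
the IUPAC ambiguity codes (R, Y, S, W, K, M, B, D, H, V, N) and the gap
character ``-``.  Ambiguity codes matter here because heterozygous
substitutions are encoded as the minimal IUPAC code covering the observed
alleles (reference plus alternates), so a single personalized sequence can
carry both haplotypes' information at a locus.

Translation uses the standard nuclear genetic code.  An ambiguous codon is
translated by the *all-expansions-agree* rule: every concrete expansion of
the codon is translated, and the codon yields that amino acid only when all
expansions agree; otherwise it yields ``X``.  A codon whose expansions are
all stops yields ``*``.
"""

from __future__ import annotations

import itertools

from .errors import AlphabetError

# IUPAC nucleotide ambiguity codes -> the set of concrete bases they denote.
AMBIGUITY: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# Inverse map: concrete base set -> minimal IUPAC code.
_CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in AMBIGUITY.items()}

NUCLEOTIDE_ALPHABET = frozenset(AMBIGUITY) | {"-"}

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

# Standard genetic code, stops as '*'.
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
GENETIC_CODE: dict[str, str] = {
    b1 + b2 + b3: _AMINO[i * 16 + j * 4 + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}


def normalize(seq: str, context: str = "") -> str:
    """Upper-case *seq*, convert RNA U to T, and validate the alphabet.

    Raises :class:`AlphabetError` naming the first offending character.
    """
    s = seq.upper().replace("U", "T")
    for i, c in enumerate(s):
        if c not in NUCLEOTIDE_ALPHABET:
            raise AlphabetError(c, i, context)
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    s = normalize(seq)
    return "".join(COMPLEMENT[c] for c in reversed(s))


def expand_ambiguity(code: str) -> frozenset[str]:
    """Concrete bases denoted by a single IUPAC *code* (A expands to {A})."""
    c = code.upper().replace("U", "T")
    if len(c) != 1 or c not in AMBIGUITY:
        raise AlphabetError(code, 0, "ambiguity code")
    return AMBIGUITY[c]


def iupac_code(bases) -> str:
    """Minimal IUPAC code covering a set of concrete bases.

    The inverse of :func:`expand_ambiguity` for concrete-base sets; used to
    encode heterozygous substitution loci in one character.
    """
    key = frozenset(b.upper().replace("U", "T") for b in bases)
    for b in key:
        if b not in "ACGT":
            raise AlphabetError(b, 0, "iupac_code input")
    if not key:
        raise AlphabetError("", 0, "iupac_code: empty base set")
    return _CODE_FOR_SET[key]


def _translate_codon(codon: str) -> str:
    """Translate one 3-letter codon, applying the expansions-agree rule."""
    if codon in GENETIC_CODE:  # fast path: concrete codon
        return GENETIC_CODE[codon]
    expansions = itertools.product(*(AMBIGUITY[c] for c in codon))
    outputs = {GENETIC_CODE["".join(e)] for e in expansions}
    if len(outputs) == 1:
        return outputs.pop()
    return "X"


def translate(cds: str, stop_policy: str = "truncate_at_stop") -> str:
    """Translate an in-frame CDS into a protein string.

    A trailing incomplete codon (1-2 nt) is ignored.  Under
    ``truncate_at_stop`` (default) translation ends before the first stop
    codon; under ``mark_stops`` stops emit ``*`` and translation continues.
    Gap characters are not translatable and raise :class:`AlphabetError`.
    """
    if stop_policy not in ("truncate_at_stop", "mark_stops"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    s = normalize(cds, "cds")
    if "-" in s:
        raise AlphabetError("-", s.index("-"), "cds")
    out = []
    for i in range(0, len(s) - len(s) % 3, 3):
        aa = _translate_codon(s[i : i + 3])
        if aa == "*" and stop_policy == "truncate_at_stop":
            break
        out.append(aa)
    return "".join(out)
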