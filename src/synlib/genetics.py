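"""Alphabets, the standard genetic code, and translation with stop-codon policies.

Translation wraps the NCBI standard table (via Biopython) but is exposed as a
codon-by-codon walk so that amber suppression (TAG read as Gln, as in supE
strains such as E. coli TG1) can be modelled explicitly.
"""

from __future__ import annotations

from Bio.Data import CodonTable, IUPACData

AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET: str = "ACGT"
STOP_CODONS: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})
AMBER: str = "TAG"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> single-letter amino acid; stops map to '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> sorted list of sense codons
SENSE_CODONS_BY_AA: dict[str, list[str]] = {aa: [] for aa in AA_ALPHABET}
for _codon, _aa in _STANDARD.forward_table.items():
    SENSE_CODONS_BY_AA[_aa].append(_codon)
for _aa in SENSE_CODONS_BY_AA:
    SENSE_CODONS_BY_AA[_aa].sort()

#: IUPAC nucleotide code -> concrete bases (e.g. K -> GT)
IUPAC_NT: dict[str, str] = {k.upper(): v.upper() for k, v in IUPACData.ambiguous_dna_values.items()}


def validate_sequence(seq: str, alphabet: str) -> None:
    """Raise AlphabetError naming the first offending position (1-based)."""
    from .errors import AlphabetError

    allowed = set(alphabet)
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise AlphabetError(
                f"illegal character {ch!r} at position {i + 1} for alphabet {alphabet!r}",
                position=i + 1,
            )


def translate(nt: str, amber_as_gln: bool = False, allow_partial: bool = False) -> str:
    """Translate a coding sequence codon by codon; stops render as '*'.

    With ``amber_as_gln`` the amber codon TAG is read through as Gln (supE
    suppression). A trailing partial codon raises ValueError unless
    ``allow_partial``, in which case it is dropped.
    """
    nt = nt.upper()
    if len(nt) % 3 and not allow_partial:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    out = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        if amber_as_gln and codon == AMBER:
            out.append("Q")
        else:
            out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def is_stop_free(nt: str, amber_as_gln: bool = False) -> bool:
    """True iff every complete codon of ``nt`` (frame 0) is a sense codon under the policy."""
    nt = nt.upper()
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS and not (amber_as_gln and codon == AMBER):
            return False
    return True


def expand_iupac_codon(pattern: str) -> list[str]:
    """All concrete codons matching a three-letter IUPAC pattern (e.g. NNK -> 32 codons)."""
    if len(pattern) != 3:
        raise ValueError(f"codon pattern must have 3 letters, got {pattern!r}")
    bases = []
    for ch in pattern.upper():
        if ch not in IUPAC_NT:
            raise ValueError(f"invalid IUPAC nucleotide code {ch!r}")
        bases.append(IUPAC_NT[ch])
    return [a + b + c for a in bases[0] for b in bases[1] for c in bases[2]]
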