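"""Host codon-usage tables for dual-host codon optimization.

Values are approximate relative synonymous-codon fractions (each amino acid's
codons sum to ~1) for E. coli K-12 and for human coding sequences, of the kind
tabulated in the standard codon-usage compilations. Only the ranking within a
synonymous family matters to the optimizer, so modest inaccuracies in the
fractions are inconsequential; both tables cover all 61 sense codons.
"""

from __future__ import annotations

from .errors import CodonTableError
from .genetics import SENSE_CODONS_BY_AA

ECOLI_USAGE: dict[str, float] = {
    # Ala
    "GCA": 0.21, "GCC": 0.27, "GCG": 0.36, "GCT": 0.16,
    # Arg
    "AGA": 0.04, "AGG": 0.02, "CGA": 0.06, "CGC": 0.40, "CGG": 0.10, "CGT": 0.38,
    # Asn
    "AAC": 0.55, "AAT": 0.45,
    # Asp
    "GAC": 0.37, "GAT": 0.63,
    # Cys
    "TGC": 0.56, "TGT": 0.44,
    # Gln
    "CAA": 0.35, "CAG": 0.65,
    # Glu
    "GAA": 0.69, "GAG": 0.31,
    # Gly
    "GGA": 0.11, "GGC": 0.41, "GGG": 0.15, "GGT": 0.34,
    # His
    "CAC": 0.43, "CAT": 0.57,
    # Ile
    "ATA": 0.07, "ATC": 0.42, "ATT": 0.51,
    # Leu
    "CTA": 0.04, "CTC": 0.10, "CTG": 0.50, "CTT": 0.10, "TTA": 0.13, "TTG": 0.13,
    # Lys
    "AAA": 0.77, "AAG": 0.23,
    # Met
    "ATG": 1.00,
    # Phe
    "TTC": 0.43, "TTT": 0.57,
    # Pro
    "CCA": 0.19, "CCC": 0.12, "CCG": 0.53, "CCT": 0.16,
    # Ser
    "AGC": 0.28, "AGT": 0.15, "TCA": 0.12, "TCC": 0.15, "TCG": 0.15, "TCT": 0.15,
    # Thr
    "ACA": 0.13, "ACC": 0.44, "ACG": 0.27, "ACT": 0.17,
    # Trp
    "TGG": 1.00,
    # Tyr
    "TAC": 0.43, "TAT": 0.57,
    # Val
    "GTA": 0.15, "GTC": 0.22, "GTG": 0.37, "GTT": 0.26,
}

HUMAN_USAGE: dict[str, float] = {
    # Ala
    "GCA": 0.23, "GCC": 0.40, "GCG": 0.11, "GCT": 0.27,
    # Arg
    "AGA": 0.21, "AGG": 0.21, "CGA": 0.11, "CGC": 0.18, "CGG": 0.20, "CGT": 0.08,
    # Asn
    "AAC": 0.53, "AAT": 0.47,
    # Asp
    "GAC": 0.54, "GAT": 0.46,
    # Cys
    "TGC": 0.54, "TGT": 0.46,
    # Gln
    "CAA": 0.27, "CAG": 0.73,
    # Glu
    "GAA": 0.42, "GAG": 0.58,
    # Gly
    "GGA": 0.25, "GGC": 0.34, "GGG": 0.25, "GGT": 0.16,
    # His
    "CAC": 0.58, "CAT": 0.42,
    # Ile
    "ATA": 0.17, "ATC": 0.47, "ATT": 0.36,
    # Leu
    "CTA": 0.07, "CTC": 0.20, "CTG": 0.40, "CTT": 0.13, "TTA": 0.08, "TTG": 0.13,
    # Lys
    "AAA": 0.43, "AAG": 0.57,
    # Met
    "ATG": 1.00,
    # Phe
    "TTC": 0.54, "TTT": 0.46,
    # Pro
    "CCA": 0.28, "CCC": 0.32, "CCG": 0.11, "CCT": 0.29,
    # Ser
    "AGC": 0.24, "AGT": 0.15, "TCA": 0.15, "TCC": 0.22, "TCG": 0.05, "TCT": 0.19,
    # Thr
    "ACA": 0.28, "ACC": 0.36, "ACG": 0.11, "ACT": 0.25,
    # Trp
    "TGG": 1.00,
    # Tyr
    "TAC": 0.56, "TAT": 0.44,
    # Val
    "GTA": 0.12, "GTC": 0.24, "GTG": 0.46, "GTT": 0.18,
}


def validate_usage_table(usage: dict[str, float]) -> None:
    """Require coverage of all 61 sense codons with positive weights."""
    for aa, codons in SENSE_CODONS_BY_AA.items():
        for codon in codons:
            if codon not in usage:
                raise CodonTableError(f"usage table missing sense codon {codon} ({aa})")
            if usage[codon] <= 0:
                raise CodonTableError(f"usage table weight for {codon} must be positive")


for _tbl in (ECOLI_USAGE, HUMAN_USAGE):
    validate_usage_table(_tbl)
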