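"""CDR cassette design: residue frequency tables, diversity math, TRIM mixtures.

A cassette design assigns each diversified position a frequency table over an
allowed residue support (by default all residues except Cys, the standard
exclusion in synthetic CDR design). Designs are realized physically by TRIM
(trinucleotide mutagenesis) mixtures — one pre-synthesized sense codon per
supported residue, dosed at exactly the design frequency — so arbitrary
per-position compositions are reachable without stop codons or frameshifts.
Degenerate-codon schemes (NNK/NNS) are modelled for comparison: they cover
all 20 amino acids but with fixed, unadjustable ratios and one stop codon.

Design diversity is the number of distinct amino-acid sequences a cassette
can encode: the product over positions of the support size, computed in exact
integer arithmetic. A whole-library figure combines cassettes as
Σ over CDR-H3 lengths of the six-cassette product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction

import numpy as np
import pandas as pd

from .codon_usage import ECOLI_USAGE, HUMAN_USAGE, validate_usage_table
from .errors import CodonTableError, DesignError
from .genetics import (
    AA_ALPHABET,
    CODON_TO_AA,
    SENSE_CODONS_BY_AA,
    STOP_CODONS,
    expand_iupac_codon,
    validate_sequence,
)
from .profiling import CompositionProfile, LengthDistribution

_TOL = 1e-9

DEFAULT_EXCLUDE: frozenset[str] = frozenset("C")


# ---------------------------------------------------------------------------
# designs


@dataclass
class CdrDesign:
    """Per-position residue frequencies over an allowed support for one cassette."""

    cdr_id: str
    length: int
    matrix: np.ndarray
    position_labels: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.length, len(AA_ALPHABET)):
            raise ValueError(f"design matrix shape {self.matrix.shape} invalid")
        if (self.matrix < 0).any():
            raise ValueError("design frequencies must be nonnegative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=_TOL):
            raise ValueError("design frequencies must sum to 1 at every position")
        if (self.matrix.max(axis=1) <= 0).any():
            raise ValueError("every position needs a nonempty residue support")
        if not self.position_labels:
            self.position_labels = [str(i + 1) for i in range(self.length)]

    def support(self, position: int) -> list[str]:
        """Residues with nonzero design frequency at 0-based ``position``."""
        return [AA_ALPHABET[j] for j in np.nonzero(self.matrix[position] > 0)[0]]

    def frequency(self, position: int, residue: str) -> float:
        return float(self.matrix[position, AA_ALPHABET.index(residue)])


def build_design(
    profile: CompositionProfile,
    exclude: frozenset[str] | set[str] = DEFAULT_EXCLUDE,
    floor: float = 0.0,
) -> CdrDesign:
    """Turn an observed composition profile into a cassette design.

    Residues in ``exclude`` or with frequency strictly below ``floor`` are
    zeroed and the remaining mass renormalized per position, mimicking the
    practice of tailoring designs to natural composition while dropping rare
    or chemically undesirable residues.
    """
    if not 0.0 <= floor <= 0.05:
        raise ValueError(f"floor must be in [0, 0.05], got {floor}")
    exclude = frozenset(r.upper() for r in exclude)
    unknown = exclude - set(AA_ALPHABET)
    if unknown:
        raise ValueError(f"unknown residues in exclusion set: {sorted(unknown)}")
    matrix = profile.matrix.copy()
    for res in exclude:
        matrix[:, AA_ALPHABET.index(res)] = 0.0
    matrix[matrix < floor] = 0.0
    sums = matrix.sum(axis=1)
    for p in np.nonzero(sums <= 0)[0]:
        label = profile.position_labels[p]
        raise DesignError(
            f"{profile.cdr_id} position {label}: all residue mass excluded; "
            f"no realizable design"
        )
    matrix /= sums[:, None]
    return CdrDesign(
        cdr_id=profile.cdr_id,
        length=profile.length,
        matrix=matrix,
        position_labels=list(profile.position_labels),
        provenance={
            "source": f"profile:{profile.cdr_id}/{profile.length}",
            "exclude": sorted(exclude),
            "floor": floor,
        },
    )


def uniform_cdr_design(
    cdr_id: str,
    length: int,
    exclude: frozenset[str] | set[str] = DEFAULT_EXCLUDE,
    position_labels: list[str] | None = None,
) -> CdrDesign:
    """Uniform design over all non-excluded residues (19 per position by default)."""
    allowed = [res for res in AA_ALPHABET if res not in exclude]
    if not allowed:
        raise DesignError("exclusion set leaves no allowed residues")
    matrix = np.zeros((length, len(AA_ALPHABET)))
    for res in allowed:
        matrix[:, AA_ALPHABET.index(res)] = 1.0 / len(allowed)
    return CdrDesign(
        cdr_id=cdr_id,
        length=length,
        matrix=matrix,
        position_labels=list(position_labels) if position_labels else [],
        provenance={"source": "uniform", "exclude": sorted(exclude)},
    )


@dataclass
class LibraryDesign:
    """Designs for the five fixed CDRs plus one CDR-H3 design per length."""

    fixed: dict[str, CdrDesign]
    h3: dict[int, CdrDesign]
    h3_weights: LengthDistribution

    def __post_init__(self) -> None:
        required = {"H1", "H2", "L1", "L2", "L3"}
        if set(self.fixed) != required:
            raise ValueError(f"fixed designs must cover {sorted(required)}")
        lengths = sorted(self.h3)
        if not lengths:
            raise ValueError("need at least one CDR-H3 design")
        if lengths != list(range(lengths[0], lengths[-1] + 1)):
            raise ValueError("CDR-H3 lengths must be contiguous")
        for L, d in self.h3.items():
            if d.length != L:
                raise ValueError(f"H3 design keyed {L} has length {d.length}")
        if set(self.h3_weights.support) - set(lengths):
            raise ValueError("H3 length weights assign mass outside designed lengths")

    @property
    def h3_lengths(self) -> list[int]:
        return sorted(self.h3)


def default_h3_length_weights(lo: int = 3, hi: int = 18) -> LengthDistribution:
    """A natural-repertoire-like CDR-H3 length distribution (mode ~11–12 aa).

    A discretized normal with mean 11.5 and SD 2.8 over the designed range —
    the typical human Kabat CDR-H3 length profile that a 3–18 window covers.
    """
    weights = {L: math.exp(-0.5 * ((L - 11.5) / 2.8) ** 2) for L in range(lo, hi + 1)}
    total = sum(weights.values())
    return LengthDistribution({L: w / total for L, w in weights.items()})


def uniform_library_design(
    template,
    exclude: frozenset[str] | set[str] = DEFAULT_EXCLUDE,
    h3_weights: LengthDistribution | None = None,
) -> LibraryDesign:
    """Uniform-support library design on a scaffold template's CDR windows."""
    fixed = {
        cdr: uniform_cdr_design(
            cdr,
            length,
            exclude,
            position_labels=[p.label for p in template.diversified_positions[cdr]],
        )
        for cdr, length in template.cdr_lengths.items()
    }
    lo, hi = template.h3_length_range
    h3 = {
        L: uniform_cdr_design(
            "H3", L, exclude, position_labels=[p.label for p in template.h3_positions(L)]
        )
        for L in range(lo, hi + 1)
    }
    return LibraryDesign(
        fixed=fixed,
        h3=h3,
        h3_weights=h3_weights or default_h3_length_weights(lo, hi),
    )


# ---------------------------------------------------------------------------
# diversity


def scientific_3sig(n: int) -> str:
    """Render an exact integer as 3-significant-figure scientific notation."""
    if n <= 0:
        raise ValueError("diversity must be positive")
    mant, exp = f"{Decimal(int(n)):.2E}".split("E")
    return f"{mant} x 10^{int(exp)}"


@dataclass
class DiversityReport:
    """Exact per-cassette design diversities and their whole-library combination."""

    per_cassette: dict[str, int]
    combined: int

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"cassette": name, "design_diversity": d, "rendered": scientific_3sig(d)}
            for name, d in self.per_cassette.items()
        ]
        rows.append(
            {
                "cassette": "combined (model quantity)",
                "design_diversity": self.combined,
                "rendered": scientific_3sig(self.combined),
            }
        )
        return pd.DataFrame(rows)


def design_diversity(design: CdrDesign | LibraryDesign) -> int | DiversityReport:
    """Number of distinct sequences a design can encode, in exact integers.

    For a single cassette: product over positions of the support size. For a
    whole library: per-cassette values plus the combined model quantity
    Σ_L [ H3(L) × Π(five fixed cassettes) ].
    """
    if isinstance(design, CdrDesign):
        d = 1
        for p in range(design.length):
            d *= len(design.support(p))
        return d
    per: dict[str, int] = {cdr: design_diversity(design.fixed[cdr]) for cdr in ("H1", "H2")}
    for cdr in ("L1", "L2", "L3"):
        per[cdr] = design_diversity(design.fixed[cdr])
    fixed_product = 1
    for cdr in ("H1", "H2", "L1", "L2", "L3"):
        fixed_product *= per[cdr]
    combined = 0
    for L in design.h3_lengths:
        per[f"H3({L})"] = design_diversity(design.h3[L])
        combined += per[f"H3({L})"] * fixed_product
    return DiversityReport(per_cassette=per, combined=combined)


def expected_unique(diversity: int, clones: int) -> float:
    """Expected number of distinct variants among ``clones`` uniform draws.

    E = D·(1 − (1 − 1/D)^N), evaluated stably for D ≫ N via log1p/expm1 and,
    for astronomically large D, the collision expansion N − N(N−1)/(2D).
    """
    D, N = int(diversity), int(clones)
    if D < 1:
        raise ValueError("diversity must be >= 1")
    if N < 0:
        raise ValueError("clone count must be >= 0")
    if N == 0:
        return 0.0
    if D == 1:
        return 1.0
    if D <= 10**17:
        return float(D) * -math.expm1(N * math.log1p(-1.0 / D))
    return float(N) - float(Fraction(N * (N - 1), 2 * D))


# ---------------------------------------------------------------------------
# TRIM mixtures


@dataclass
class TrimMixture:
    """Per-position trinucleotide (TRIM) codon proportions realizing a design."""

    cdr_id: str
    positions: list[list[tuple[str, float]]]

    def __post_init__(self) -> None:
        for p, entries in enumerate(self.positions):
            if not entries:
                raise ValueError(f"position {p}: empty codon mixture")
            total = 0.0
            seen_aa: set[str] = set()
            for codon, prop in entries:
                if codon in STOP_CODONS or codon not in CODON_TO_AA:
                    raise ValueError(f"position {p}: {codon} is not a sense codon")
                if prop < 0:
                    raise ValueError(f"position {p}: negative proportion for {codon}")
                aa = CODON_TO_AA[codon]
                if aa in seen_aa:
                    raise ValueError(f"position {p}: more than one codon for residue {aa}")
                seen_aa.add(aa)
                total += prop
            if abs(total - 1.0) > _TOL:
                raise ValueError(f"position {p}: proportions sum to {total}, not 1")

    @property
    def length(self) -> int:
        return len(self.positions)

    def expected_composition(self) -> np.ndarray:
        """Amino-acid frequency matrix implied by the codon proportions."""
        matrix = np.zeros((self.length, len(AA_ALPHABET)))
        for p, entries in enumerate(self.positions):
            for codon, prop in entries:
                matrix[p, AA_ALPHABET.index(CODON_TO_AA[codon])] += prop
        return matrix

    def to_table(self) -> pd.DataFrame:
        rows = []
        for p, entries in enumerate(self.positions):
            for codon, prop in entries:
                rows.append(
                    {"cdr": self.cdr_id, "position": p + 1, "codon": codon, "proportion": prop}
                )
        return pd.DataFrame(rows)


def preferred_codon_table(
    usage_a: dict[str, float] | None = None, usage_b: dict[str, float] | None = None
) -> dict[str, str]:
    """One sense codon per residue maximizing the two hosts' geometric-mean usage.

    Ties break alphabetically. Defaults to the bundled E. coli / human tables.
    """
    usage_a = usage_a if usage_a is not None else ECOLI_USAGE
    usage_b = usage_b if usage_b is not None else HUMAN_USAGE
    validate_usage_table(usage_a)
    validate_usage_table(usage_b)
    table: dict[str, str] = {}
    for aa, codons in SENSE_CODONS_BY_AA.items():
        best, best_score = None, -1.0
        for codon in codons:  # sorted => alphabetical tie-break via strict >
            score = math.sqrt(usage_a[codon] * usage_b[codon])
            if score > best_score:
                best, best_score = codon, score
        table[aa] = best  # type: ignore[assignment]
    return table


def codon_optimize(
    aa_seq: str,
    usage_a: dict[str, float] | None = None,
    usage_b: dict[str, float] | None = None,
) -> str:
    """Deterministic dual-host codon optimization of an amino-acid sequence."""
    aa_seq = aa_seq.upper()
    validate_sequence(aa_seq, AA_ALPHABET)
    table = preferred_codon_table(usage_a, usage_b)
    return "".join(table[aa] for aa in aa_seq)


def trim_mixture(design: CdrDesign, codon_choice: dict[str, str] | None = None) -> TrimMixture:
    """Emit the TRIM codon mixture realizing a cassette design exactly.

    Each supported residue gets one codon (default: the dual-host optimizer's
    choice) dosed at the design frequency, so the mixture's expected
    amino-acid composition equals the design by construction.
    """
    table = codon_choice if codon_choice is not None else preferred_codon_table()
    positions: list[list[tuple[str, float]]] = []
    for p in range(design.length):
        entries: list[tuple[str, float]] = []
        for res in design.support(p):
            if res not in table:
                raise CodonTableError(f"no codon assigned for residue {res}")
            codon = table[res]
            if CODON_TO_AA.get(codon) != res:
                raise CodonTableError(f"codon {codon} does not encode {res}")
            entries.append((codon, design.frequency(p, res)))
        positions.append(entries)
    return TrimMixture(cdr_id=design.cdr_id, positions=positions)


# ---------------------------------------------------------------------------
# degenerate codons


@dataclass
class DegenerateProfile:
    """Amino-acid (and stop) probabilities of a degenerate codon pattern."""

    pattern: str
    probabilities: dict[str, float]
    codon_count: int

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")

    @property
    def stop_probability(self) -> float:
        return self.probabilities.get("*", 0.0)


def degenerate_profile(pattern: str) -> DegenerateProfile:
    """Enumerate a degenerate codon (e.g. NNK) into residue/stop probabilities.

    All concrete codons matching the IUPAC pattern are assumed equiprobable —
    the fixed, unadjustable ratios that distinguish degenerate schemes from
    TRIM mixtures.
    """
    try:
        codons = expand_iupac_codon(pattern)
    except ValueError as exc:
        raise ValueError(str(exc)) from exc
    probs: dict[str, float] = {}
    for codon in codons:
        aa = CODON_TO_AA[codon]
        probs[aa] = probs.get(aa, 0.0) + 1.0 / len(codons)
    return DegenerateProfile(pattern=pattern.upper(), probabilities=probs, codon_count=len(codons))


# ---------------------------------------------------------------------------
# serialization

_H3_WEIGHT_MARKER = "H3_LENGTH_WEIGHTS"


def library_design_to_table(design: LibraryDesign) -> pd.DataFrame:
    """Flatten a LibraryDesign to the tidy design-spec table format."""
    frames = []
    for cdr, d in design.fixed.items():
        frames.append(_design_rows(d))
    for L, d in design.h3.items():
        frames.append(_design_rows(d))
    weight_rows = pd.DataFrame(
        {
            "cdr": _H3_WEIGHT_MARKER,
            "length": list(design.h3_weights.probabilities),
            "position_label": "",
            "residue": "",
            "frequency": list(design.h3_weights.probabilities.values()),
        }
    )
    frames.append(weight_rows)
    return pd.concat(frames, ignore_index=True)


def _design_rows(d: CdrDesign) -> pd.DataFrame:
    rows = []
    for p in range(d.length):
        for res in d.support(p):
            rows.append(
                {
                    "cdr": d.cdr_id,
                    "length": d.length,
                    "position_label": d.position_labels[p],
                    "residue": res,
                    "frequency": d.frequency(p, res),
                }
            )
    return pd.DataFrame(rows)


def library_design_from_table(df: pd.DataFrame) -> LibraryDesign:
    """Rebuild a LibraryDesign from its design-spec table."""
    weights_df = df[df["cdr"] == _H3_WEIGHT_MARKER]
    body = df[df["cdr"] != _H3_WEIGHT_MARKER]
    fixed: dict[str, CdrDesign] = {}
    h3: dict[int, CdrDesign] = {}
    for (cdr, length), grp in body.groupby(["cdr", "length"], sort=True):
        length = int(length)
        labels = list(dict.fromkeys(grp["position_label"].astype(str)))
        matrix = np.zeros((length, len(AA_ALPHABET)))
        label_idx = {lbl: i for i, lbl in enumerate(labels)}
        for _, row in grp.iterrows():
            matrix[label_idx[str(row["position_label"])], AA_ALPHABET.index(row["residue"])] = row[
                "frequency"
            ]
        d = CdrDesign(cdr_id=str(cdr), length=length, matrix=matrix, position_labels=labels)
        if cdr == "H3":
            h3[length] = d
        else:
            fixed[str(cdr)] = d
    weights = LengthDistribution(
        {int(r["length"]): float(r["frequency"]) for _, r in weights_df.iterrows()}
    )
    return LibraryDesign(fixed=fixed, h3=h3, h3_weights=weights)
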