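"""In-silico scFv assembly, synthesis-error injection, and β-lactamase selection.

Overlap-extension PCR joins cassettes and scaffold fragments through shared
flanks; with a fixed scaffold and exact flank identity this reduces to
concatenation, which is how assembly is modelled (no polymerase error model —
the synthesis ErrorModel carries the whole indel/substitution burden).

In-frame selection mimics the biological proofreading filter: the insert is
fused between a β-lactamase signal sequence and the bla N-terminus, and a
clone survives carbenicillin only if the whole fusion reads through in frame
with no stop codon. Under the ``amber_suppressed`` policy TAG is read as Gln
(supE hosts such as E. coli TG1); the default ``standard`` policy treats all
three stops as lethal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design import LibraryDesign, codon_optimize, preferred_codon_table
from .errors import AssemblyError, FusionConfigError, StateError
from .genetics import AA_ALPHABET, NT_ALPHABET, is_stop_free, translate
from .profiling import LengthDistribution
from .scaffold import CdrSet, ScaffoldTemplate

STATUSES = ("in_frame", "frameshift", "internal_stop", "unreadable", "unclassified")


@dataclass(frozen=True)
class Lesion:
    """One synthesis error: position (0-based, in the error-free insert), kind, bases."""

    position: int
    kind: str  # 'sub' | 'ins' | 'del'
    bases: str


@dataclass
class CloneRecord:
    """One assembled scFv clone, optionally bla-fused and/or error-bearing."""

    id: str
    insert_nt: str
    insert_aa: str | None = None
    cdr_choices: CdrSet | None = None
    fused_nt: str | None = None
    status: str = "unclassified"
    lesions: list[Lesion] = field(default_factory=list)
    passed_selection: bool | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")

    @property
    def net_indel(self) -> int:
        """Net length change (insertions − deletions) over the insert."""
        return sum(1 for l in self.lesions if l.kind == "ins") - sum(
            1 for l in self.lesions if l.kind == "del"
        )


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base synthesis error rates (capped at 5%)."""

    deletion_rate: float = 0.0
    insertion_rate: float = 0.0
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deletion_rate", "insertion_rate", "substitution_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.05:
                raise ValueError(f"{name} must be in [0, 0.05], got {rate}")


# ---------------------------------------------------------------------------
# assembly


def assemble_scfv(
    template: ScaffoldTemplate,
    cdrs: CdrSet,
    codon_table: dict[str, str] | None = None,
    clone_id: str = "clone",
) -> CloneRecord:
    """Assemble an error-free scFv insert from a template and six CDRs.

    CDR amino acids are encoded with the (dual-host-optimal by default) TRIM
    codon table, so the insert is stop-free by construction.
    """
    table = codon_table if codon_table is not None else preferred_codon_table()
    lo, hi = template.h3_length_range
    if not lo <= len(cdrs["H3"]) <= hi:
        raise AssemblyError(
            f"CDR-H3 length {len(cdrs['H3'])} outside designed range [{lo}, {hi}]"
        )
    for cdr, length in template.cdr_lengths.items():
        if len(cdrs[cdr]) != length:
            raise AssemblyError(
                f"CDR-{cdr} length {len(cdrs[cdr])} does not match template length {length}"
            )
    pieces: list[str] = []
    for kind, name in template.parts:
        if kind == "const":
            pieces.append(template.segment(name).nt)
        else:
            for res in cdrs[name]:
                if res not in AA_ALPHABET or res not in table:
                    raise AssemblyError(f"CDR-{name} residue {res!r} outside design alphabet")
                pieces.append(table[res])
    insert_nt = "".join(pieces)
    return CloneRecord(
        id=clone_id,
        insert_nt=insert_nt,
        insert_aa=translate(insert_nt),
        cdr_choices=cdrs,
        status="in_frame",
    )


def sample_library(
    design: LibraryDesign,
    template: ScaffoldTemplate,
    n: int,
    seed: int,
    codon_table: dict[str, str] | None = None,
) -> list[CloneRecord]:
    """Draw ``n`` clones from a library design, reproducibly under ``seed``.

    CDR-H3 length is drawn from the design's length weights; every residue is
    drawn independently per position from the design frequencies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA_ALPHABET))
    # fixed-length CDRs: one n×L character block per CDR
    fixed_blocks: dict[str, np.ndarray] = {}
    for cdr, d in design.fixed.items():
        cols = [rng.choice(aa, size=n, p=d.matrix[p]) for p in range(d.length)]
        fixed_blocks[cdr] = np.stack(cols, axis=1)
    weights = design.h3_weights
    lengths_support = list(weights.probabilities)
    probs = np.array([weights.probabilities[L] for L in lengths_support])
    h3_lengths = rng.choice(np.array(lengths_support), size=n, p=probs / probs.sum())
    h3_strings: list[str] = [""] * n
    for L in sorted(set(int(x) for x in h3_lengths)):
        idx = np.nonzero(h3_lengths == L)[0]
        d = design.h3[L]
        cols = [rng.choice(aa, size=len(idx), p=d.matrix[p]) for p in range(L)]
        block = np.stack(cols, axis=1)
        for row, i in enumerate(idx):
            h3_strings[i] = "".join(block[row])
    clones = []
    for i in range(n):
        cdrs = CdrSet(
            cdrs={
                "H1": "".join(fixed_blocks["H1"][i]),
                "H2": "".join(fixed_blocks["H2"][i]),
                "H3": h3_strings[i],
                "L1": "".join(fixed_blocks["L1"][i]),
                "L2": "".join(fixed_blocks["L2"][i]),
                "L3": "".join(fixed_blocks["L3"][i]),
            }
        )
        clones.append(assemble_scfv(template, cdrs, codon_table, clone_id=f"clone{i:06d}"))
    return clones


# ---------------------------------------------------------------------------
# synthesis errors


def apply_synthesis_errors(
    clone: CloneRecord, model: ErrorModel, rng: np.random.Generator | None = None
) -> CloneRecord:
    """Mutate each base independently per the error model; lesions are recorded.

    A fresh CloneRecord is returned (status ``unclassified``); positions in the
    lesion list refer to the error-free insert.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    nt = clone.insert_nt
    n = len(nt)
    u = rng.random(n)
    d, i_rate, s = model.deletion_rate, model.insertion_rate, model.substitution_rate
    out: list[str] = []
    lesions: list[Lesion] = []
    base_idx = {b: k for k, b in enumerate(NT_ALPHABET)}
    ins_draws = rng.integers(0, 4, size=n)
    sub_draws = rng.integers(0, 3, size=n)
    for pos, base in enumerate(nt):
        x = u[pos]
        if x < d:
            lesions.append(Lesion(pos, "del", base))
            continue
        if x < d + i_rate:
            new = NT_ALPHABET[ins_draws[pos]]
            out.append(base)
            out.append(new)
            lesions.append(Lesion(pos, "ins", new))
            continue
        if x < d + i_rate + s:
            alternatives = [b for b in NT_ALPHABET if b != base]
            new = alternatives[sub_draws[pos]]
            out.append(new)
            lesions.append(Lesion(pos, "sub", new))
            continue
        out.append(base)
    return replace(
        clone,
        insert_nt="".join(out),
        insert_aa=None,
        status="unclassified",
        lesions=list(clone.lesions) + lesions,
        fused_nt=None,
        passed_selection=None,
    )


# ---------------------------------------------------------------------------
# bla fusion and in-frame selection

# SYNTHETIC SURROGATES for the selection vector's fusion partners: a TEM-1-like
# β-lactamase signal peptide and a bla N-terminal fragment (the real vector
# sequences are not public). Only their reading frame matters to the model.
SURROGATE_SIGNAL_AA = "MSIQHFRVALIPFFAAFCLPVFA"
SURROGATE_BLA_AA = "HPETLVKVKDAEDQLGARVGYIELDLNSGKILESFRPEERFPMMSTFKVLLCGAVLSRVD"
SURROGATE_SIGNAL_NT = codon_optimize(SURROGATE_SIGNAL_AA)
SURROGATE_BLA_NT = codon_optimize(SURROGATE_BLA_AA)


def bla_fuse(
    clone: CloneRecord, signal_nt: str | None = None, bla_nt: str | None = None
) -> CloneRecord:
    """Fuse signal·insert·bla into the single ORF that selection translates."""
    signal_nt = (signal_nt or SURROGATE_SIGNAL_NT).upper()
    bla_nt = (bla_nt or SURROGATE_BLA_NT).upper()
    for name, seq in (("signal", signal_nt), ("bla", bla_nt)):
        if len(seq) % 3:
            raise FusionConfigError(f"{name} sequence length {len(seq)} is not a multiple of 3")
        if not is_stop_free(seq):
            raise FusionConfigError(f"{name} sequence contains an in-frame stop codon")
    clone.fused_nt = signal_nt + clone.insert_nt + bla_nt
    return clone


def orf_intact(fused_nt: str, stop_policy: str = "standard") -> bool:
    """True iff the fusion reads start→final bla codon in frame with no stop."""
    if stop_policy not in ("standard", "amber_suppressed"):
        raise ValueError(f"unknown stop policy {stop_policy!r}")
    if len(fused_nt) % 3:
        return False
    return is_stop_free(fused_nt, amber_as_gln=(stop_policy == "amber_suppressed"))


def inframe_select(clones: list[CloneRecord], stop_policy: str = "standard") -> list[CloneRecord]:
    """Carbenicillin in-frame selection: keep clones whose fused ORF is intact.

    Every clone's survival decision is recorded on ``passed_selection``.
    """
    survivors = []
    for clone in clones:
        if clone.fused_nt is None:
            raise StateError(f"clone {clone.id} is not bla-fused; cannot select")
        clone.passed_selection = orf_intact(clone.fused_nt, stop_policy)
        if clone.passed_selection:
            survivors.append(clone)
    return survivors
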