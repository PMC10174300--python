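"""Synthetic-data generators: mock repertoires, QC read sets, pilot and screen fixtures.

These stand in for data that is not publicly available — the proprietary
repertoire database behind the composition profiles, the Sanger reads of the
constructed library, and the raw panning screen tables. Every generator is
deterministic under its seed and emits a machine-readable truth record so
downstream stages can be checked exactly (classification) or within stated
statistical tolerance (frequencies).

Named presets reproduce the headline study conditions: a 300-read QC set with
42 unreadable reads and 6 CDR-H3 frameshifts; a 100-clone in-frame-selection
pilot with 9 frameshifted clones; and five panning campaigns (TIM-3, TGF-β,
B7H3, a CCR5 peptide, and a bacterial protein BA) with their
screened/positive/unique counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import CloneRecord, Lesion, bla_fuse, sample_library
from .design import (
    LibraryDesign,
    default_h3_length_weights,
    uniform_library_design,
)
from .errors import FixtureSpecError
from .genetics import AA_ALPHABET
from .profiling import LengthDistribution
from .qc import ScreenRecord
from .scaffold import ScaffoldTemplate

GENERATOR_VERSION = "1.0"


@dataclass(frozen=True)
class FixtureSpec:
    """Counts and seed defining one synthetic fixture."""

    name: str
    seed: int
    n_total: int = 0
    n_unreadable: int = 0
    n_frameshift_h3: int = 0
    screened: int = 0
    positives: int = 0
    n_unique: int = 0
    generator_version: str = GENERATOR_VERSION

    def __post_init__(self) -> None:
        for f in ("n_total", "n_unreadable", "n_frameshift_h3", "screened", "positives", "n_unique"):
            if getattr(self, f) < 0:
                raise FixtureSpecError(f"{f} must be >= 0")
        if self.n_unreadable + self.n_frameshift_h3 > self.n_total:
            raise FixtureSpecError(
                "unreadable + frameshift reads exceed total "
                f"({self.n_unreadable}+{self.n_frameshift_h3} > {self.n_total})"
            )
        if not self.positives <= self.screened:
            raise FixtureSpecError("positives cannot exceed screened")
        if not self.n_unique <= max(self.positives, 0) and self.positives:
            raise FixtureSpecError("unique clones cannot exceed positives")
        if self.n_unique > self.positives:
            raise FixtureSpecError("unique clones cannot exceed positives")


# ---------------------------------------------------------------------------
# presets reproducing the headline study conditions

QC_PRESET = FixtureSpec("qc_300", seed=11, n_total=300, n_unreadable=42, n_frameshift_h3=6)
PILOT_PRESET = FixtureSpec("pilot_100", seed=7, n_total=100, n_frameshift_h3=9)
SCREEN_PRESETS: dict[str, FixtureSpec] = {
    "tim3": FixtureSpec("TIM3", seed=3, screened=1632, positives=772, n_unique=204),
    "tgfb": FixtureSpec("TGFb", seed=3, screened=96, positives=91, n_unique=29),
    "b7h3": FixtureSpec("B7H3", seed=3, screened=192, positives=134, n_unique=23),
    "ccr5_peptide": FixtureSpec("CCR5-peptide", seed=3, screened=1056, positives=237, n_unique=45),
    "ba": FixtureSpec("BA", seed=3, screened=192, positives=166, n_unique=26),
}


# ---------------------------------------------------------------------------
# mock repertoire


@dataclass
class MockRepertoire:
    """Sampled CDR sequences plus the generating frequencies (the recovery truth)."""

    cdr_sequences: dict[str, list[str]]
    frequencies: dict[str, np.ndarray]  # fixed-length CDRs
    h3_frequencies: dict[int, np.ndarray]  # per H3 length
    length_dist: LengthDistribution
    seed: int


_DEFAULT_CDR_LENGTHS = {"H1": 6, "H2": 9, "L1": 7, "L2": 4, "L3": 8}


def make_mock_repertoire(
    n: int,
    length_dist: LengthDistribution | None = None,
    concentration: float = 1.0,
    seed: int = 0,
    cdr_lengths: dict[str, int] | None = None,
) -> MockRepertoire:
    """Emulate a natural repertoire's CDR windows with Dirichlet positional skew.

    Per-position residue frequencies are drawn once from a symmetric
    Dirichlet(concentration) over the 20 residues — small concentrations give
    the skewed, position-specific compositions of real repertoires; the
    concentration → ∞ limit is uniform. ``n`` CDR sets are then sampled
    i.i.d.; CDR-H3 lengths follow ``length_dist`` (default: the bundled
    natural-like 3–18 distribution).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    lengths = dict(cdr_lengths or _DEFAULT_CDR_LENGTHS)
    length_dist = length_dist or default_h3_length_weights()
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA_ALPHABET))
    alpha = np.full(len(AA_ALPHABET), concentration)

    sequences: dict[str, list[str]] = {}
    frequencies: dict[str, np.ndarray] = {}
    for cdr, L in lengths.items():
        freqs = rng.dirichlet(alpha, size=L)
        cols = [rng.choice(aa, size=n, p=freqs[p]) for p in range(L)]
        block = np.stack(cols, axis=1)
        sequences[cdr] = ["".join(row) for row in block]
        frequencies[cdr] = freqs

    support = list(length_dist.probabilities)
    probs = np.array([length_dist.probabilities[L] for L in support])
    draws = rng.choice(np.array(support), size=n, p=probs / probs.sum())
    h3_frequencies: dict[int, np.ndarray] = {}
    h3_seqs: list[str] = [""] * n
    for L in sorted(set(int(x) for x in draws)):
        idx = np.nonzero(draws == L)[0]
        freqs = rng.dirichlet(alpha, size=L)
        h3_frequencies[L] = freqs
        cols = [rng.choice(aa, size=len(idx), p=freqs[p]) for p in range(L)]
        block = np.stack(cols, axis=1)
        for row, i in enumerate(idx):
            h3_seqs[i] = "".join(block[row])
    sequences["H3"] = h3_seqs
    return MockRepertoire(
        cdr_sequences=sequences,
        frequencies=frequencies,
        h3_frequencies=h3_frequencies,
        length_dist=length_dist,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# QC read fixture


@dataclass
class QcFixture:
    """Clone reads plus the per-read ground-truth classification."""

    reads: list[tuple[str, str]]
    truth: list[dict]
    spec: FixtureSpec


def _h3_nt_bounds(template: ScaffoldTemplate, insert_nt: str) -> tuple[int, int]:
    """0-based nt [start, end) of the CDR-H3 gap in an error-free insert."""
    runs, gaps = template.constant_nt_runs()
    pos = 0
    cursor = 0
    for run, gap in zip(runs, gaps + [None]):
        pos = insert_nt.find(run, cursor)
        cursor = pos + len(run)
        if gap == "H3":
            start = cursor
            end = insert_nt.find(runs[gaps.index("H3") + 1], cursor)
            return start, end
    raise RuntimeError("H3 gap not located")  # pragma: no cover


def make_qc_fixture(
    spec: FixtureSpec,
    template: ScaffoldTemplate,
    design: LibraryDesign | None = None,
) -> QcFixture:
    """Generate a sequencing QC read set with known per-read ground truth.

    ``n_unreadable`` reads are truncated upstream of the VL-side anchors,
    ``n_frameshift_h3`` readable reads carry exactly one 1-nt deletion inside
    CDR-H3, and the remainder are clean.
    """
    design = design or uniform_library_design(template)
    rng = np.random.default_rng(spec.seed)
    clones = sample_library(design, template, spec.n_total, seed=int(rng.integers(2**31)))
    runs, gaps = template.constant_nt_runs()
    reads: list[tuple[str, str]] = []
    truth: list[dict] = []
    for i, clone in enumerate(clones):
        nt = clone.insert_nt
        if i < spec.n_unreadable:
            # cut inside VH, upstream of the FR-H4/linker/FR-L1 run
            limit = nt.find(runs[3])
            cut = int(rng.integers(len(runs[0]) // 2, limit))
            reads.append((f"read{i:04d}", nt[:cut]))
            truth.append({"id": f"read{i:04d}", "status": "unreadable", "region": None})
        elif i < spec.n_unreadable + spec.n_frameshift_h3:
            start, end = _h3_nt_bounds(template, nt)
            hit = int(rng.integers(start, end))
            reads.append((f"read{i:04d}", nt[:hit] + nt[hit + 1 :]))
            truth.append({"id": f"read{i:04d}", "status": "frameshift", "region": "H3"})
        else:
            reads.append((f"read{i:04d}", nt))
            truth.append({"id": f"read{i:04d}", "status": "in_frame", "region": None})
    order = rng.permutation(len(reads))
    reads = [reads[j] for j in order]
    truth = [truth[j] for j in order]
    return QcFixture(reads=reads, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# in-frame-selection pilot fixture


@dataclass
class PilotFixture:
    """Fused clones plus per-clone intactness truth for the selection pilot."""

    clones: list[CloneRecord]
    truth: list[bool]  # True = designed intact (should survive selection)
    spec: FixtureSpec


def make_pilot_fixture(
    n: int,
    n_frameshift: int,
    seed: int,
    template: ScaffoldTemplate,
    design: LibraryDesign | None = None,
) -> PilotFixture:
    """Generate a selection pilot: fused clones, ``n_frameshift`` with one 1-nt indel.

    The indel sits inside the diversified cassette (CDR-H3), so the fused ORF
    of a frameshifted clone translates out of frame through bla.
    """
    if n_frameshift > n:
        raise FixtureSpecError(f"n_frameshift {n_frameshift} exceeds n {n}")
    design = design or uniform_library_design(template)
    rng = np.random.default_rng(seed)
    clones = sample_library(design, template, n, seed=int(rng.integers(2**31)))
    truth: list[bool] = []
    out: list[CloneRecord] = []
    for i, clone in enumerate(clones):
        if i < n_frameshift:
            start, end = _h3_nt_bounds(template, clone.insert_nt)
            hit = int(rng.integers(start, end))
            if rng.random() < 0.5:
                lost = clone.insert_nt[hit]
                clone.insert_nt = clone.insert_nt[:hit] + clone.insert_nt[hit + 1 :]
                clone.lesions.append(Lesion(hit, "del", lost))
            else:
                base = "ACGT"[int(rng.integers(4))]
                clone.insert_nt = clone.insert_nt[:hit] + base + clone.insert_nt[hit:]
                clone.lesions.append(Lesion(hit, "ins", base))
            clone.insert_aa = None
            clone.status = "unclassified"
            truth.append(False)
        else:
            truth.append(True)
        out.append(bla_fuse(clone))
    order = rng.permutation(n)
    spec = FixtureSpec("pilot", seed=seed, n_total=n, n_frameshift_h3=n_frameshift)
    return PilotFixture(
        clones=[out[j] for j in order], truth=[truth[j] for j in order], spec=spec
    )


# ---------------------------------------------------------------------------
# screening fixture


def make_screen_fixture(
    antigen: str,
    screened: int,
    positives: int,
    n_unique: int,
    seed: int,
    template: ScaffoldTemplate,
    design: LibraryDesign | None = None,
    background: float = 0.05,
    rounds: tuple[int, ...] = (3, 4),
) -> list[ScreenRecord]:
    """Generate one panning campaign's screen table with explicit positive flags.

    Positive wells carry sequences drawn with replacement from ``n_unique``
    distinct sampled clones (each distinct clone appears at least once, so
    deduplication recovers exactly ``n_unique``). Negative wells get
    background-level OD; positives get 3–10× background. Flags are explicit,
    so downstream summaries never depend on the OD threshold rule.
    """
    spec = FixtureSpec(antigen, seed=seed, screened=screened, positives=positives, n_unique=n_unique)
    design = design or uniform_library_design(template)
    rng = np.random.default_rng(seed)
    uniques: list[CloneRecord] = []
    if n_unique:
        seen: set[str] = set()
        batch = n_unique
        while len(uniques) < n_unique:
            for clone in sample_library(design, template, batch, seed=int(rng.integers(2**31))):
                key = clone.cdr_choices.key
                if key not in seen:
                    seen.add(key)
                    uniques.append(clone)
                    if len(uniques) == n_unique:
                        break
            batch = max(4, n_unique - len(uniques))
    assignment = list(range(n_unique)) + [
        int(rng.integers(n_unique)) for _ in range(positives - n_unique)
    ]
    rng.shuffle(assignment)
    flags = [True] * positives + [False] * (screened - positives)
    order = rng.permutation(screened)
    records: list[ScreenRecord] = []
    pos_cursor = 0
    for out_idx, j in enumerate(order):
        is_pos = flags[j]
        od650 = float(rng.uniform(0.0, 0.02))
        if is_pos:
            signal = float(rng.uniform(3 * background, 10 * background))
            seq = uniques[assignment[pos_cursor]].insert_nt if n_unique else None
            pos_cursor += 1
        else:
            signal = float(rng.uniform(0.0, background))
            seq = None
        records.append(
            ScreenRecord(
                antigen=antigen,
                round=int(rounds[int(rng.integers(len(rounds)))]),
                well=f"W{out_idx:04d}",
                od450=signal + od650,
                od650=od650,
                positive=is_pos,
                sequence=seq,
            )
        )
    return records


def make_screen_preset(
    name: str, template: ScaffoldTemplate, seed: int | None = None
) -> list[ScreenRecord]:
    """Generate a named panning campaign preset (see ``SCREEN_PRESETS``)."""
    spec = SCREEN_PRESETS[name]
    return make_screen_fixture(
        antigen=spec.name,
        screened=spec.screened,
        positives=spec.positives,
        n_unique=spec.n_unique,
        seed=spec.seed if seed is None else seed,
        template=template,
    )
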