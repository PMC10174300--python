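"""Sequenced-clone classification, library QC reports, and panning analytics.

Clone reads are classified against the fixed scaffold: a read is *readable*
when both scaffold ends can be located; a *frameshift* is a CDR gap whose
nucleotide length is not a multiple of 3 (attributed to the CDR containing
the first frame break); an *internal stop* is a stop codon inside an
otherwise frame-intact ORF. Headline rates are rounded to the nearest
integer percent (full precision is retained in machine-readable fields).

Panning analytics: ELISA positivity from background-subtracted absorbance
(OD450 − OD650), hit rate = positives/screened, and unique-binder counting
keyed on the concatenated amino-acid string of the six extracted CDRs (the
paratope), so framework-silent nucleotide changes collapse to one binder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ExtractionError
from .genetics import NT_ALPHABET, is_stop_free, translate, validate_sequence
from .scaffold import CDR_ORDER, ScaffoldTemplate, extract_cdrs


def round_half_up_percent(fraction: float) -> int:
    """Round 100·fraction to the nearest integer percent, halves up."""
    return int(math.floor(100.0 * fraction + 0.5))


# ---------------------------------------------------------------------------
# clone classification


@dataclass
class Classification:
    """Outcome of classifying one sequenced clone read."""

    status: str  # in_frame | frameshift | internal_stop | unreadable
    region: str | None = None  # CDR carrying the first frame break
    h3_length: int | None = None
    h3_in_range: bool | None = None


def classify_clone(
    read_nt: str, template: ScaffoldTemplate, policy: str = "standard"
) -> Classification:
    """Classify a putative scFv insert read against the scaffold.

    The seven constant nucleotide runs of the template are located in order by
    exact matching; the six gaps between them are the CDR cassettes. A read is
    unreadable when the runs cannot all be located (the anchor-findability
    surrogate for sequencing readability), a frameshift when some gap length
    is not a multiple of 3, an internal stop when the in-frame translation
    hits a stop, and in-frame otherwise.
    """
    if policy not in ("standard", "amber_suppressed"):
        raise ValueError(f"unknown stop policy {policy!r}")
    read_nt = read_nt.upper()
    if not read_nt:
        return Classification(status="unreadable")
    validate_sequence(read_nt, NT_ALPHABET)
    runs, gaps = template.constant_nt_runs()
    positions: list[int] = []
    cursor = 0
    for run in runs:
        pos = read_nt.find(run, cursor)
        if pos < 0:
            return Classification(status="unreadable")
        positions.append(pos)
        cursor = pos + len(run)
    gap_lengths: list[int] = []
    for k in range(len(gaps)):
        gap = positions[k + 1] - (positions[k] + len(runs[k]))
        gap_lengths.append(gap)
    h3_gap = gap_lengths[gaps.index("H3")]
    h3_length = h3_gap // 3 if h3_gap % 3 == 0 else None
    lo, hi = template.h3_length_range
    h3_in_range = (lo <= h3_length <= hi) if h3_length is not None else None
    for cdr, gap in zip(gaps, gap_lengths):
        if gap % 3:
            return Classification(
                status="frameshift", region=cdr, h3_length=h3_length, h3_in_range=h3_in_range
            )
    orf = read_nt[positions[0] : positions[-1] + len(runs[-1])]
    if not is_stop_free(orf, amber_as_gln=(policy == "amber_suppressed")):
        return Classification(
            status="internal_stop", h3_length=h3_length, h3_in_range=h3_in_range
        )
    return Classification(status="in_frame", h3_length=h3_length, h3_in_range=h3_in_range)


@dataclass
class QcReport:
    """Aggregate QC statistics over a set of sequenced clone reads."""

    total: int
    readable: int
    in_frame: int
    internal_stop: int
    frameshift_by_region: dict[str, int]
    classifications: list[Classification] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.readable > self.total:
            raise ValueError("readable cannot exceed total")
        if self.in_frame + self.internal_stop + self.frameshift_total != self.readable:
            raise ValueError("readable counts do not partition")

    @property
    def frameshift_total(self) -> int:
        return sum(self.frameshift_by_region.values())

    @property
    def unreadable(self) -> int:
        return self.total - self.readable

    @property
    def h3_frameshift_count(self) -> int:
        return self.frameshift_by_region.get("H3", 0)

    @property
    def h3_frameshift_rate_exact(self) -> float:
        return self.h3_frameshift_count / self.readable if self.readable else 0.0

    @property
    def h3_frameshift_rate_pct(self) -> int:
        """Headline CDR-H3 frameshift rate, nearest integer percent of readable reads."""
        return round_half_up_percent(self.h3_frameshift_rate_exact)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "readable": self.readable,
            "unreadable": self.unreadable,
            "in_frame": self.in_frame,
            "internal_stop": self.internal_stop,
            "frameshift_by_region": dict(self.frameshift_by_region),
            "frameshift_total": self.frameshift_total,
            "h3_frameshift_rate_pct": self.h3_frameshift_rate_pct,
            "h3_frameshift_rate_exact": self.h3_frameshift_rate_exact,
        }


def qc_report(
    reads: list[tuple[str, str]] | list[str],
    template: ScaffoldTemplate,
    policy: str = "standard",
) -> QcReport:
    """Classify every read and aggregate the library QC statistics."""
    if not reads:
        raise ValueError("empty input: no reads to classify")
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    classifications = [classify_clone(s, template, policy) for s in seqs]
    frameshift_by_region: dict[str, int] = {}
    in_frame = internal_stop = unreadable = 0
    for c in classifications:
        if c.status == "unreadable":
            unreadable += 1
        elif c.status == "in_frame":
            in_frame += 1
        elif c.status == "internal_stop":
            internal_stop += 1
        else:
            frameshift_by_region[c.region] = frameshift_by_region.get(c.region, 0) + 1
    return QcReport(
        total=len(seqs),
        readable=len(seqs) - unreadable,
        in_frame=in_frame,
        internal_stop=internal_stop,
        frameshift_by_region=frameshift_by_region,
        classifications=classifications,
    )


# ---------------------------------------------------------------------------
# screening analytics


@dataclass
class ScreenRecord:
    """One well of a phage-ELISA screen."""

    antigen: str
    round: int
    well: str
    od450: float | None = None
    od650: float | None = None
    positive: bool | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        for name in ("od450", "od650"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0")


def call_positive(rec: ScreenRecord, background: float, fold: float = 3.0) -> bool:
    """ELISA positivity: background-subtracted signal ≥ fold × background.

    The corrected signal is OD450 − OD650; a negative corrected signal is
    clamped to 0 (and can never score positive).
    """
    if rec.od450 is None or rec.od650 is None:
        raise ValueError(f"well {rec.well}: absorbances missing")
    if background <= 0:
        raise ValueError("background must be positive")
    signal = max(rec.od450 - rec.od650, 0.0)
    return signal >= fold * background


@dataclass
class HitRate:
    """Hit rate as both headline integer percent and exact fraction."""

    percent: int
    fraction: float
    positives: int
    screened: int


def hit_rate(positives: int, screened: int) -> HitRate:
    """positives/screened as nearest-integer percent (exact ratio retained)."""
    if screened <= 0:
        raise ValueError("screened must be positive")
    if not 0 <= positives <= screened:
        raise ValueError("need 0 <= positives <= screened")
    fraction = positives / screened
    return HitRate(
        percent=round_half_up_percent(fraction),
        fraction=fraction,
        positives=positives,
        screened=screened,
    )


@dataclass
class UniqueBinders:
    """Deduplicated binder count with one representative per class."""

    count: int
    representatives: dict[str, ScreenRecord]
    excluded: int


def unique_binders(
    records: list[ScreenRecord], template: ScaffoldTemplate, key: str = "cdr_aa"
) -> UniqueBinders:
    """Count unique binders among sequenced screen records.

    ``key`` selects the identity notion: ``cdr_aa`` (default; concatenated
    six-CDR amino acids — paratope identity), ``full_aa``, or ``full_nt``.
    Records whose sequence cannot be translated/extracted are excluded and
    counted separately; the result is order-invariant.
    """
    if key not in ("cdr_aa", "full_aa", "full_nt"):
        raise ValueError(f"unknown uniqueness key {key!r}")
    reps: dict[str, ScreenRecord] = {}
    excluded = 0
    for rec in records:
        if not rec.sequence:
            excluded += 1
            continue
        seq = rec.sequence.upper()
        try:
            if set(seq) <= set(NT_ALPHABET):
                if key == "full_nt":
                    k = seq
                else:
                    aa = translate(seq)
                    k = aa if key == "full_aa" else extract_cdrs(aa, template).key
            else:
                if key == "full_nt":
                    raise ValueError("nt key requested but sequence is amino acids")
                k = seq if key == "full_aa" else extract_cdrs(seq, template).key
        except (ExtractionError, ValueError):
            excluded += 1
            continue
        if k not in reps or rec.well < reps[k].well:  # deterministic representative
            reps[k] = rec
    return UniqueBinders(count=len(reps), representatives=reps, excluded=excluded)


@dataclass
class PanningSummary:
    """Screened/positive/unique counts for one panning campaign."""

    antigen: str
    screened: int
    positives: int
    hit_rate_pct: int
    unique_clones: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.positives <= self.screened:
            raise ValueError("need 0 <= positives <= screened")
        if self.unique_clones is not None and self.unique_clones > self.positives:
            raise ValueError("unique clones cannot exceed positives")


def summarize_screen(
    records: list[ScreenRecord],
    template: ScaffoldTemplate | None = None,
    background: float | None = None,
    fold: float = 3.0,
) -> PanningSummary:
    """Summarize one campaign's screen table into a PanningSummary.

    Explicit ``positive`` flags take precedence; otherwise positivity is
    called from absorbances against ``background``. Unique binders are
    counted when a template is supplied and positives carry sequences.
    """
    if not records:
        raise ValueError("empty screen table")
    antigens = {r.antigen for r in records}
    if len(antigens) != 1:
        raise ValueError(f"screen table mixes antigens: {sorted(antigens)}")
    positives = []
    for rec in records:
        flag = rec.positive
        if flag is None:
            if background is None:
                raise ValueError("no positive flags and no background to call from")
            flag = call_positive(rec, background, fold)
        if flag:
            positives.append(rec)
    rate = hit_rate(len(positives), len(records))
    unique = None
    if template is not None and any(r.sequence for r in positives):
        unique = unique_binders(positives, template).count
    return PanningSummary(
        antigen=antigens.pop(),
        screened=len(records),
        positives=len(positives),
        hit_rate_pct=rate.percent,
        unique_clones=unique,
    )


def read_screen_table(path) -> list[ScreenRecord]:
    """Load a delimited screen table (antigen, round, well, od450, od650, positive, sequence)."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            ScreenRecord(
                antigen=str(row["antigen"]),
                round=int(row["round"]),
                well=str(row["well"]),
                od450=float(row["od450"]) if pd.notna(row.get("od450")) else None,
                od650=float(row["od650"]) if pd.notna(row.get("od650")) else None,
                positive=bool(row["positive"]) if pd.notna(row.get("positive")) else None,
                sequence=str(row["sequence"])
                if pd.notna(row.get("sequence")) and str(row.get("sequence"))
                else None,
            )
        )
    return records


def write_screen_table(records: list[ScreenRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "antigen": r.antigen,
                "round": r.round,
                "well": r.well,
                "od450": r.od450,
                "od650": r.od650,
                "positive": r.positive,
                "sequence": r.sequence,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reporter assay


@dataclass
class ReporterMeasurement:
    """One reporter-assay reading: antibody-dilution RLU vs no-antibody control RLU."""

    rlu_ab: float
    rlu_control: float

    def __post_init__(self) -> None:
        if self.rlu_ab < 0:
            raise ValueError("rlu_ab must be >= 0")
        if self.rlu_control <= 0:
            raise ValueError("rlu_control must be positive")


def inhibition_ratio(m: ReporterMeasurement) -> float:
    """Reporter inhibition percent: 100 − (RLU_ab / RLU_control) × 100.

    May be negative (signal enhancement); callers should treat negative
    values as flagged enhancement rather than inhibition.
    """
    return 100.0 - 100.0 * (m.rlu_ab / m.rlu_control)
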