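"""The fixed scFv scaffold: framework segments, CDR slots, extraction, sequence I/O.

The library lives on a single VH–(Gly4Ser)3–VL template whose frameworks are
derived from the high-stability IGHV3-23 (VH) and IGKV1-39 (VL) germlines.
Six CDR windows are diversified: H30–35, H50–58 and H95–102 on the heavy
chain, L28–34, L50–53 and L89–96 on the light chain (Kabat numbering).
CDR-H3 is variable in length (default 3–18 residues); the other five windows
are fixed-length. Because every clone shares the same frameworks, CDRs are
recovered by exact anchor matching rather than general antibody numbering.

Internally all indices are 0-based half-open; Kabat labels appear only in
user-facing tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import (
    AlphabetError,
    ExtractionError,
    FastaParseError,
    ScaffoldConfigError,
    ScaffoldIntegrityError,
)
from .genetics import AA_ALPHABET, NT_ALPHABET, translate, validate_sequence
from .kabat import KabatPosition, h3_positions, parse_positions

LINKER_AA = "GGGGS" * 3
CDR_ORDER: tuple[str, ...] = ("H1", "H2", "H3", "L1", "L2", "L3")
ANCHOR_LEN = 8

# ---------------------------------------------------------------------------
# sequence I/O


def read_sequences(path: str | Path, alphabet: str = "aa") -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercased sequence) pairs, order preserved.

    ``alphabet`` is ``"aa"`` (20-letter) or ``"nt"`` (ACGT). Malformed FASTA
    raises FastaParseError; an out-of-alphabet character raises AlphabetError
    naming the record and 1-based position.
    """
    if alphabet not in ("aa", "nt"):
        raise ValueError(f"alphabet must be 'aa' or 'nt', got {alphabet!r}")
    letters = AA_ALPHABET if alphabet == "aa" else NT_ALPHABET
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[tuple[str, str]] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            try:
                validate_sequence(seq, letters)
            except AlphabetError as exc:
                raise AlphabetError(
                    f"record {rec.id!r}: {exc}", record=rec.id, position=exc.position
                ) from exc
            records.append((rec.id, seq))
    except ValueError as exc:  # Biopython signals malformed FASTA with ValueError
        raise FastaParseError(f"malformed FASTA in {path}: {exc}") from exc
    return records


def write_sequences(path: str | Path, records: list[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# template


@dataclass(frozen=True)
class Segment:
    """A fixed scaffold segment as amino acids plus its nucleotide encoding."""

    aa: str
    nt: str


@dataclass
class CdrSet:
    """The six CDR amino-acid strings of one clone."""

    cdrs: dict[str, str]
    h3_in_range: bool = True

    def __post_init__(self) -> None:
        missing = set(CDR_ORDER) - set(self.cdrs)
        if missing:
            raise ValueError(f"CdrSet missing CDRs: {sorted(missing)}")
        for cdr_id, seq in self.cdrs.items():
            validate_sequence(seq, AA_ALPHABET)

    def __getitem__(self, cdr_id: str) -> str:
        return self.cdrs[cdr_id]

    @property
    def key(self) -> str:
        """Concatenated CDR string (H1..L3) — the paratope identity key."""
        return "".join(self.cdrs[c] for c in CDR_ORDER)


@dataclass
class ScaffoldTemplate:
    """Fixed scFv scaffold: 4+4 framework segments, linker, diversified windows."""

    name: str
    vh_frameworks: tuple[Segment, Segment, Segment, Segment]
    vl_frameworks: tuple[Segment, Segment, Segment, Segment]
    linker: Segment
    diversified_positions: dict[str, tuple[KabatPosition, ...]]
    h3_length_range: tuple[int, int] = (3, 18)
    anchors: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()
        if not self.anchors:
            self.anchors = self._derive_anchors()

    # -- layout ------------------------------------------------------------

    @property
    def parts(self) -> list[tuple[str, str]]:
        """Insert layout VH→linker→VL as ('const', name) / ('cdr', cdr_id) items."""
        return [
            ("const", "FR-H1"), ("cdr", "H1"),
            ("const", "FR-H2"), ("cdr", "H2"),
            ("const", "FR-H3"), ("cdr", "H3"),
            ("const", "FR-H4"), ("const", "LINKER"),
            ("const", "FR-L1"), ("cdr", "L1"),
            ("const", "FR-L2"), ("cdr", "L2"),
            ("const", "FR-L3"), ("cdr", "L3"),
            ("const", "FR-L4"),
        ]

    def segment(self, name: str) -> Segment:
        if name == "LINKER":
            return self.linker
        chain, idx = name.split("-")[1][0], int(name.split("-")[1][1])
        fw = self.vh_frameworks if chain == "H" else self.vl_frameworks
        return fw[idx - 1]

    @property
    def cdr_lengths(self) -> dict[str, int]:
        """Designed lengths of the five fixed-length CDR windows."""
        return {
            cdr: len(self.diversified_positions[cdr])
            for cdr in ("H1", "H2", "L1", "L2", "L3")
        }

    def h3_positions(self, length: int) -> tuple[KabatPosition, ...]:
        return h3_positions(length, max_length=self.h3_length_range[1])

    @property
    def constant_aa_length(self) -> int:
        return sum(len(self.segment(n).aa) for kind, n in self.parts if kind == "const")

    def insert_aa_length(self, h3_length: int) -> int:
        return self.constant_aa_length + sum(self.cdr_lengths.values()) + h3_length

    def constant_nt_runs(self) -> tuple[list[str], list[str]]:
        """Maximal constant nt runs and the CDR gap names between them.

        Returns seven runs (FR-H4 + linker + FR-L1 merge into one) and the six
        gap names H1, H2, H3, L1, L2, L3 in insert order.
        """
        runs: list[str] = []
        current = ""
        gaps: list[str] = []
        for kind, name in self.parts:
            if kind == "const":
                current += self.segment(name).nt
            else:
                runs.append(current)
                current = ""
                gaps.append(name)
        runs.append(current)
        return runs, gaps

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        for kind, name in self.parts:
            if kind != "const":
                continue
            seg = self.segment(name)
            validate_sequence(seg.nt, NT_ALPHABET)
            if len(seg.nt) != 3 * len(seg.aa) or translate(seg.nt) != seg.aa:
                raise ScaffoldIntegrityError(
                    f"segment {name}: nucleotide sequence does not translate to "
                    f"its amino-acid sequence"
                )
        if self.linker.aa != LINKER_AA:
            raise ScaffoldIntegrityError(
                f"linker must be (G4S)x3 = {LINKER_AA!r}, got {self.linker.aa!r}"
            )
        lo, hi = self.h3_length_range
        if not (1 <= lo <= hi):
            raise ScaffoldIntegrityError(f"bad H3 length range {self.h3_length_range}")
        for cdr in ("H1", "H2", "L1", "L2", "L3"):
            if cdr not in self.diversified_positions or not self.diversified_positions[cdr]:
                raise ScaffoldIntegrityError(f"missing diversified positions for {cdr}")
        all_positions: list[KabatPosition] = []
        for cdr in ("H1", "H2", "L1", "L2", "L3"):
            all_positions.extend(self.diversified_positions[cdr])
        all_positions.extend(h3_positions(hi, max_length=hi))
        if len(set(all_positions)) != len(all_positions):
            raise ScaffoldIntegrityError("diversified position sets overlap")

    def _derive_anchors(self) -> dict[str, tuple[str, str]]:
        anchors: dict[str, tuple[str, str]] = {}
        parts = self.parts
        for i, (kind, name) in enumerate(parts):
            if kind != "cdr":
                continue
            prev_aa = self.segment(parts[i - 1][1]).aa
            next_aa = self.segment(parts[i + 1][1]).aa
            anchors[name] = (prev_aa[-ANCHOR_LEN:], next_aa[:ANCHOR_LEN])
        return anchors


# ---------------------------------------------------------------------------
# CDR extraction


def extract_cdrs(aa_seq: str, template: ScaffoldTemplate) -> CdrSet:
    """Slice the six CDRs out of a full scFv amino-acid sequence.

    The scaffold is fixed, so every offset is known once the CDR-H3 length is
    inferred from the total length; each framework flank is then verified
    exactly. A flank mismatch raises ExtractionError naming the adjacent CDR.
    An out-of-range H3 length only flags the returned CdrSet.
    """
    aa_seq = aa_seq.upper()
    validate_sequence(aa_seq, AA_ALPHABET)
    base = template.constant_aa_length + sum(template.cdr_lengths.values())
    h3_len = len(aa_seq) - base
    if h3_len < 0:
        raise ExtractionError(
            f"sequence length {len(aa_seq)} shorter than scaffold minimum {base}", cdr="H3"
        )
    cdrs: dict[str, str] = {}
    parts = template.parts
    offset = 0
    for i, (kind, name) in enumerate(parts):
        if kind == "const":
            seg = template.segment(name).aa
            if aa_seq[offset : offset + len(seg)] != seg:
                prev = parts[i - 1] if i > 0 else (None, None)
                nxt = parts[i + 1] if i + 1 < len(parts) else (None, None)
                blame = prev[1] if prev[0] == "cdr" else (nxt[1] if nxt[0] == "cdr" else name)
                raise ExtractionError(
                    f"framework segment {name} (anchor for CDR-{blame}) not found "
                    f"at expected position {offset}",
                    cdr=blame,
                )
            offset += len(seg)
        else:
            length = h3_len if name == "H3" else template.cdr_lengths[name]
            cdrs[name] = aa_seq[offset : offset + length]
            offset += length
    lo, hi = template.h3_length_range
    return CdrSet(cdrs=cdrs, h3_in_range=lo <= h3_len <= hi)


# ---------------------------------------------------------------------------
# configuration files

_REQUIRED_KEYS = ("name", "frameworks", "linker", "diversified_positions")


def load_scaffold(path: str | Path) -> ScaffoldTemplate:
    """Load and validate a scaffold template from a YAML config file."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ScaffoldConfigError(f"{path}: scaffold config must be a mapping")
    for key in _REQUIRED_KEYS:
        if key not in cfg:
            raise ScaffoldConfigError(f"{path}: missing required key {key!r}")
    try:
        vh = tuple(Segment(s["aa"].upper(), s["nt"].upper()) for s in cfg["frameworks"]["vh"])
        vl = tuple(Segment(s["aa"].upper(), s["nt"].upper()) for s in cfg["frameworks"]["vl"])
    except (KeyError, TypeError, AttributeError) as exc:
        raise ScaffoldConfigError(f"{path}: malformed frameworks section: {exc}") from exc
    if len(vh) != 4 or len(vl) != 4:
        raise ScaffoldConfigError(f"{path}: need exactly 4 VH and 4 VL framework segments")
    linker = Segment(cfg["linker"]["aa"].upper(), cfg["linker"]["nt"].upper())
    div: dict[str, tuple[KabatPosition, ...]] = {}
    for cdr, labels in cfg["diversified_positions"].items():
        div[cdr.upper()] = parse_positions(list(labels))
    anchors = {
        cdr.upper(): (a["prefix"].upper(), a["suffix"].upper())
        for cdr, a in cfg.get("anchors", {}).items()
    }
    h3_range = tuple(cfg.get("h3_length_range", (3, 18)))
    try:
        return ScaffoldTemplate(
            name=str(cfg["name"]),
            vh_frameworks=vh,
            vl_frameworks=vl,
            linker=linker,
            diversified_positions=div,
            h3_length_range=h3_range,  # type: ignore[arg-type]
            anchors=anchors,
        )
    except ValueError as exc:
        raise ScaffoldConfigError(f"{path}: {exc}") from exc


def save_scaffold(template: ScaffoldTemplate, path: str | Path) -> None:
    cfg = {
        "name": template.name,
        "h3_length_range": list(template.h3_length_range),
        "frameworks": {
            "vh": [{"aa": s.aa, "nt": s.nt} for s in template.vh_frameworks],
            "vl": [{"aa": s.aa, "nt": s.nt} for s in template.vl_frameworks],
        },
        "linker": {"aa": template.linker.aa, "nt": template.linker.nt},
        "diversified_positions": {
            cdr: [p.label for p in positions]
            for cdr, positions in template.diversified_positions.items()
            if cdr != "H3"
        },
        "anchors": {
            cdr: {"prefix": pre, "suffix": suf} for cdr, (pre, suf) in template.anchors.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# bundled surrogate template

# Framework amino-acid segments in the style of the IGHV3-23 / IGKV1-39
# germlines (4D5-like). SYNTHETIC SURROGATE: the real library's scaffold
# nucleotide sequences are proprietary; these stand in for them and are
# internally consistent with every template invariant.
_SURROGATE_AA = {
    "FR-H1": "EVQLLESGGGLVQPGGSLRLSCAASGFTF",   # Kabat H1–H29
    "FR-H2": "WVRQAPGKGLEWVS",                  # H36–H49
    "FR-H3": "YYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAK",  # H59–H94
    "FR-H4": "WGQGTLVTVSS",                     # H103–H113
    "FR-L1": "DIQMTQSPSSLSASVGDRVTITCRASQ",     # L1–L27
    "FR-L2": "WYQQKPGKAPKLLIY",                 # L35–L49
    "FR-L3": "LQSGVPSRFSGSGSGTDFTLTISSLQPEDFATYYC",  # L54–L88
    "FR-L4": "TFGQGTKVEIK",                     # L97–L107
}

_SURROGATE_POSITIONS = {
    "H1": [f"H{i}" for i in range(30, 36)],
    "H2": [f"H{i}" for i in range(50, 59)],
    "L1": [f"L{i}" for i in range(28, 35)],
    "L2": [f"L{i}" for i in range(50, 54)],
    "L3": [f"L{i}" for i in range(89, 97)],
}


def surrogate_scaffold() -> ScaffoldTemplate:
    """Build the bundled surrogate template programmatically.

    Nucleotide encodings come from the package's dual-host codon optimizer so
    that the scaffold is, by construction, expression-optimized for both
    E. coli and human codon preferences.
    """
    from .design import codon_optimize  # local import: design does not import scaffold

    def seg(name: str) -> Segment:
        aa = _SURROGATE_AA[name]
        return Segment(aa, codon_optimize(aa))

    return ScaffoldTemplate(
        name="vh3-vk1-surrogate",
        vh_frameworks=(seg("FR-H1"), seg("FR-H2"), seg("FR-H3"), seg("FR-H4")),
        vl_frameworks=(seg("FR-L1"), seg("FR-L2"), seg("FR-L3"), seg("FR-L4")),
        linker=Segment(LINKER_AA, codon_optimize(LINKER_AA)),
        diversified_positions={
            cdr: parse_positions(labels) for cdr, labels in _SURROGATE_POSITIONS.items()
        },
        h3_length_range=(3, 18),
    )


def default_scaffold() -> ScaffoldTemplate:
    """The bundled surrogate scaffold (loads the shipped YAML fixture)."""
    from importlib.resources import files

    return load_scaffold(str(files("synlib.data") / "vh3_vk1_surrogate.yaml"))
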