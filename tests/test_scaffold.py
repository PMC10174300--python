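"""Scaffold template, Kabat bookkeeping, FASTA I/O and CDR extraction."""

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from synlib.errors import (
    AlphabetError,
    AssemblyError,
    ExtractionError,
    FastaParseError,
    ScaffoldConfigError,
    ScaffoldIntegrityError,
)
from synlib.assembly import assemble_scfv
from synlib.genetics import AA_ALPHABET, translate
from synlib.kabat import KabatPosition, h3_positions
from synlib.scaffold import (
    CdrSet,
    extract_cdrs,
    load_scaffold,
    read_sequences,
    save_scaffold,
    surrogate_scaffold,
    write_sequences,
)

ids = st.from_regex(r"[A-Za-z0-9_.-]{1,12}", fullmatch=True)
aa_seqs = st.text(alphabet=AA_ALPHABET, min_size=1, max_size=60)


# ---------------------------------------------------------------------------
# FASTA I/O


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(ids, aa_seqs), min_size=0, max_size=8))
def test_fasta_write_read_identity(tmp_path_factory, records):
    path = tmp_path_factory.mktemp("fasta") / "x.fasta"
    write_sequences(path, records)
    assert read_sequences(path, "aa") == records


def test_read_sequences_empty_file(tmp_path):
    path = tmp_path / "empty.fasta"
    path.write_text("")
    assert read_sequences(path, "aa") == []


def test_read_sequences_rejects_out_of_alphabet(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">r1\nACDJ\n")
    with pytest.raises(AlphabetError) as exc:
        read_sequences(path, "aa")
    assert exc.value.record == "r1"
    assert exc.value.position == 4


def test_read_sequences_malformed_fasta(tmp_path):
    path = tmp_path / "mal.fasta"
    path.write_text("garbage before header\n>r1\nACDE\n")
    with pytest.raises(FastaParseError):
        read_sequences(path, "aa")


def test_read_sequences_nt_alphabet(tmp_path):
    path = tmp_path / "nt.fasta"
    path.write_text(">r1\nacgt\n")
    assert read_sequences(path, "nt") == [("r1", "ACGT")]
    path.write_text(">r1\nACGN\n")
    with pytest.raises(AlphabetError):
        read_sequences(path, "nt")


# ---------------------------------------------------------------------------
# Kabat positions


def test_kabat_insertion_ordering():
    h100 = KabatPosition("H", 100)
    h100a = KabatPosition("H", 100, "A")
    h100b = KabatPosition("H", 100, "B")
    h101 = KabatPosition("H", 101)
    assert h100 < h100a < h100b < h101
    assert KabatPosition.parse("H100A") == h100a


@pytest.mark.parametrize(
    "length,first,last,n_insertions",
    [(3, "H95", "H102", 0), (8, "H95", "H102", 0), (12, "H95", "H102", 4), (18, "H95", "H102", 10)],
)
def test_h3_positions_layout(length, first, last, n_insertions):
    pos = h3_positions(length)
    assert len(pos) == length
    assert pos[0].label == first and pos[-1].label == last
    assert sum(1 for p in pos if p.insertion) == n_insertions
    assert list(pos) == sorted(pos)


def test_h3_positions_rejects_over_range():
    with pytest.raises(ValueError):
        h3_positions(19)


# ---------------------------------------------------------------------------
# template loading and invariants


def test_bundled_template_matches_programmatic_surrogate(template):
    prog = surrogate_scaffold()
    assert template.vh_frameworks == prog.vh_frameworks
    assert template.vl_frameworks == prog.vl_frameworks
    assert template.linker == prog.linker
    assert translate(template.linker.nt) == "GGGGS" * 3


def _tampered_config(template, tmp_path, mutate):
    path = tmp_path / "scaffold.yaml"
    save_scaffold(template, path)
    cfg = yaml.safe_load(path.read_text())
    mutate(cfg)
    path.write_text(yaml.safe_dump(cfg))
    return path


def test_load_scaffold_rejects_short_linker(template, tmp_path):
    path = _tampered_config(
        template, tmp_path, lambda c: c.update(linker={"aa": "GGGGS" * 2, "nt": "GGTGGTGGCGGTTCT" * 2})
    )
    with pytest.raises(ScaffoldIntegrityError):
        load_scaffold(path)


def test_load_scaffold_rejects_translation_mismatch(template, tmp_path):
    def mutate(cfg):
        nt = cfg["frameworks"]["vh"][0]["nt"]
        cfg["frameworks"]["vh"][0]["nt"] = "TTT" + nt[3:]  # FR-H1 now starts Phe, aa says Glu

    path = _tampered_config(template, tmp_path, mutate)
    with pytest.raises(ScaffoldIntegrityError):
        load_scaffold(path)


def test_load_scaffold_rejects_missing_key(template, tmp_path):
    path = _tampered_config(template, tmp_path, lambda c: c.pop("diversified_positions"))
    with pytest.raises(ScaffoldConfigError):
        load_scaffold(path)


# ---------------------------------------------------------------------------
# extraction


def _random_cdrset(template, rng):
    lengths = dict(template.cdr_lengths)
    lo, hi = template.h3_length_range
    lengths["H3"] = int(rng.integers(lo, hi + 1))
    residues = np.array(list(AA_ALPHABET))
    return CdrSet(
        cdrs={cdr: "".join(rng.choice(residues, size=n)) for cdr, n in lengths.items()}
    )


def test_extract_is_inverse_of_assemble(template):
    rng = np.random.default_rng(42)
    for _ in range(100):
        cdrs = _random_cdrset(template, rng)
        clone = assemble_scfv(template, cdrs)
        assert extract_cdrs(clone.insert_aa, template).cdrs == cdrs.cdrs


def test_extract_empty_h3_flags_range(template):
    pieces = []
    cdrs = {"H1": "A" * 6, "H2": "A" * 9, "H3": "", "L1": "A" * 7, "L2": "A" * 4, "L3": "A" * 8}
    for kind, name in template.parts:
        pieces.append(template.segment(name).aa if kind == "const" else cdrs[name])
    result = extract_cdrs("".join(pieces), template)
    assert result["H3"] == ""
    assert not result.h3_in_range


def test_extract_missing_suffix_anchor_names_h3(template):
    cdrs = CdrSet(
        cdrs={"H1": "A" * 6, "H2": "A" * 9, "H3": "A" * 10, "L1": "A" * 7, "L2": "A" * 4, "L3": "A" * 8}
    )
    clone = assemble_scfv(template, cdrs)
    aa = clone.insert_aa
    # corrupt the FR-H4 anchor immediately after CDR-H3
    idx = aa.index("WGQGT")
    broken = aa[:idx] + "AAAAA" + aa[idx + 5 :]
    with pytest.raises(ExtractionError) as exc:
        extract_cdrs(broken, template)
    assert exc.value.cdr == "H3"


def test_assemble_rejects_h3_below_min_length(template):
    cdrs = {"H1": "A" * 6, "H2": "A" * 9, "H3": "", "L1": "A" * 7, "L2": "A" * 4, "L3": "A" * 8}
    with pytest.raises(AssemblyError):
        assemble_scfv(template, CdrSet(cdrs=cdrs))
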