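"""Clone-read classification, QC reports, and panning/screening analytics."""

import numpy as np
import pytest

from synlib.assembly import bla_fuse, sample_library
from synlib.genetics import SENSE_CODONS_BY_AA
from synlib.qc import (
    ReporterMeasurement,
    ScreenRecord,
    call_positive,
    classify_clone,
    hit_rate,
    inhibition_ratio,
    qc_report,
    summarize_screen,
    unique_binders,
)


def _clone(library, template, seed=0):
    return sample_library(library, template, 1, seed=seed)[0]


# ---------------------------------------------------------------------------
# classification


def test_classify_clean_clone_in_frame(library, template):
    c = classify_clone(_clone(library, template).insert_nt, template)
    assert c.status == "in_frame"
    assert c.h3_in_range


def test_classify_h3_deletion_frameshift(library, template):
    clone = _clone(library, template, seed=1)
    runs, _ = template.constant_nt_runs()
    h3_start = clone.insert_nt.find(runs[3])
    hit = h3_start - 2  # inside the CDR-H3 gap
    read = clone.insert_nt[:hit] + clone.insert_nt[hit + 1 :]
    c = classify_clone(read, template)
    assert c.status == "frameshift"
    assert c.region == "H3"


def test_classify_truncated_read_unreadable(library, template):
    clone = _clone(library, template, seed=2)
    read = clone.insert_nt[: len(clone.insert_nt) // 3]
    assert classify_clone(read, template).status == "unreadable"
    assert classify_clone("", template).status == "unreadable"


def test_classify_internal_stop_and_amber_policy(library, template):
    clone = _clone(library, template, seed=3)
    runs, _ = template.constant_nt_runs()
    h1_start = len(runs[0])
    read = clone.insert_nt[:h1_start] + "TAG" + clone.insert_nt[h1_start + 3 :]
    assert classify_clone(read, template).status == "internal_stop"
    assert classify_clone(read, template, policy="amber_suppressed").status == "in_frame"
    ochre = clone.insert_nt[:h1_start] + "TAA" + clone.insert_nt[h1_start + 3 :]
    assert classify_clone(ochre, template, policy="amber_suppressed").status == "internal_stop"


def test_qc_report_partitions_and_is_permutation_invariant(library, template):
    clones = sample_library(library, template, 30, seed=9)
    reads = [c.insert_nt for c in clones]
    runs, _ = template.constant_nt_runs()
    # 3 truncated, 2 with H3 deletion
    for i in range(3):
        reads[i] = reads[i][:100]
    for i in range(3, 5):
        h3_start = reads[i].find(runs[3]) - 2
        reads[i] = reads[i][:h3_start] + reads[i][h3_start + 1 :]
    rep = qc_report(reads, template)
    assert rep.total == 30
    assert rep.unreadable == 3
    assert rep.frameshift_by_region == {"H3": 2}
    assert rep.unreadable + rep.in_frame + rep.frameshift_total + rep.internal_stop == rep.total
    rng = np.random.default_rng(0)
    shuffled = [reads[j] for j in rng.permutation(30)]
    rep2 = qc_report(shuffled, template)
    assert rep2.to_dict() == {**rep.to_dict()}


def test_qc_report_all_clean(library, template):
    reads = [c.insert_nt for c in sample_library(library, template, 10, seed=10)]
    rep = qc_report(reads, template)
    assert rep.readable == rep.in_frame == 10
    assert rep.h3_frameshift_rate_pct == 0


# ---------------------------------------------------------------------------
# ELISA positivity and hit rate


def test_call_positive_cases():
    rec = ScreenRecord("X", 3, "A1", od450=1.2, od650=0.1)
    assert call_positive(rec, background=0.1, fold=3)
    boundary = ScreenRecord("X", 3, "A2", od450=0.4, od650=0.1)
    assert call_positive(boundary, background=0.1, fold=3)  # signal == threshold
    flat = ScreenRecord("X", 3, "A3", od450=0.2, od650=0.2)
    assert not call_positive(flat, background=0.1, fold=3)


def test_hit_rate_rounding():
    assert hit_rate(772, 1632).percent == 47
    assert hit_rate(91, 96).percent == 95
    assert hit_rate(0, 96).percent == 0
    assert hit_rate(772, 1632).fraction == pytest.approx(772 / 1632)
    with pytest.raises(ValueError):
        hit_rate(1, 0)
    with pytest.raises(ValueError):
        hit_rate(5, 4)


def test_hit_rate_monotone_in_positives():
    pcts = [hit_rate(k, 200).percent for k in range(0, 201, 10)]
    assert pcts == sorted(pcts)
    assert all(0 <= p <= 100 for p in pcts)


# ---------------------------------------------------------------------------
# unique binders


def test_unique_binders_collapses_copies_and_silent_changes(library, template):
    clone = _clone(library, template, seed=20)
    nt = clone.insert_nt
    # synonymous change in the first framework codon (Glu: GAA <-> GAG)
    first = nt[:3]
    syn = [c for c in SENSE_CODONS_BY_AA["E"] if c != first][0]
    silent = syn + nt[3:]
    records = [ScreenRecord("X", 3, f"W{i}", positive=True, sequence=nt) for i in range(5)]
    records.append(ScreenRecord("X", 3, "W9", positive=True, sequence=silent))
    result = unique_binders(records, template)
    assert result.count == 1
    assert result.excluded == 0


def test_unique_binders_order_invariant_and_excludes_unextractable(library, template):
    clones = sample_library(library, template, 4, seed=21)
    records = [
        ScreenRecord("X", 3, f"W{i}", positive=True, sequence=c.insert_nt)
        for i, c in enumerate(clones)
    ]
    records.append(ScreenRecord("X", 3, "W8", positive=True, sequence="ATGATG"))
    a = unique_binders(records, template)
    b = unique_binders(records[::-1], template)
    assert a.count == b.count == 4
    assert a.excluded == 1


def test_summarize_screen_rejects_mixed_antigens():
    recs = [
        ScreenRecord("X", 3, "A1", positive=True),
        ScreenRecord("Y", 3, "A2", positive=False),
    ]
    with pytest.raises(ValueError):
        summarize_screen(recs)


# ---------------------------------------------------------------------------
# reporter inhibition


def test_inhibition_ratio_values():
    assert inhibition_ratio(ReporterMeasurement(100, 100)) == pytest.approx(0.0)
    assert inhibition_ratio(ReporterMeasurement(0, 100)) == pytest.approx(100.0)
    assert inhibition_ratio(ReporterMeasurement(20, 100)) == pytest.approx(80.0)
    assert inhibition_ratio(ReporterMeasurement(120, 100)) == pytest.approx(-20.0)  # enhancement
    with pytest.raises(ValueError):
        ReporterMeasurement(10, 0)
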