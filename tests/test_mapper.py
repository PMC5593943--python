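import random

import numpy as np
import pytest

from oracles import exhaustive_align

from rrnadip.catalog import Catalog, RrnaRecord
from rrnadip.mapper import (
    AlignmentParams,
    CleanRead,
    MapperError,
    align_read,
    assign_all,
    build_index,
    map_sequences,
    reverse_complement,
)


def _mutate(rng, seq, n_err):
    pos = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = random.Random(int(p)).choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def test_index_counts_all_kmer_positions(toy3_catalog):
    rec = RrnaRecord.build("X1", "18S ribosomal RNA gene", "ACGTACGT")
    idx = build_index(Catalog([rec]), k=4)
    assert idx.n_kmers == len("ACGTACGT") - 4 + 1
    assert idx.lookup("ACGT") == [("X1", 0), ("X1", 4)]


def test_index_returns_occurrences_in_every_reference():
    shared = "ACGTACGTACG"
    r1 = RrnaRecord.build("A1", "18S ribosomal RNA gene", shared + "GGGG")
    r2 = RrnaRecord.build("A2", "28S ribosomal RNA gene", "TTTT" + shared)
    idx = build_index(Catalog([r1, r2]), k=11)
    assert set(idx.lookup(shared)) == {("A1", 0), ("A2", 4)}


def test_index_matches_bruteforce_substring_scan(toy3_catalog):
    idx = build_index(toy3_catalog, k=11)
    rng = np.random.default_rng(5)
    refs = {r.accession: r.sequence for r in toy3_catalog}
    for _ in range(50):
        acc = toy3_catalog.records[rng.integers(0, 3)].accession
        start = int(rng.integers(0, len(refs[acc]) - 11))
        probe = refs[acc][start : start + 11]
        expected = sorted(
            (a, i)
            for a, s in refs.items()
            for i in range(len(s) - 10)
            if s[i : i + 11] == probe
        )
        assert sorted(idx.lookup(probe)) == expected


def test_index_rejects_too_short_reference():
    rec = RrnaRecord.build("X1", "18S ribosomal RNA gene", "ACGTACG")
    with pytest.raises(MapperError, match="X1"):
        build_index(Catalog([rec]), k=11)


def test_exact_substring_maps_with_full_identity(toy3_catalog):
    idx = build_index(toy3_catalog, k=11)
    rec = toy3_catalog.records[0]
    hit = align_read(rec.sequence[30:90], idx)
    assert hit is not None
    assert (hit.accession, hit.identity, hit.aligned_length, hit.strand) == (
        rec.accession,
        1.0,
        60,
        "+",
    )


def test_reverse_complement_maps_to_same_accession(toy3_catalog):
    idx = build_index(toy3_catalog, k=11)
    rec = toy3_catalog.records[1]
    fwd = align_read(rec.sequence[10:110], idx)
    rev = align_read(reverse_complement(rec.sequence[10:110]), idx)
    assert fwd is not None and rev is not None
    assert rev.accession == fwd.accession
    assert rev.score == fwd.score
    assert (fwd.strand, rev.strand) == ("+", "-")


def test_n_bases_never_seed_but_extend_as_mismatch(toy3_catalog):
    idx = build_index(toy3_catalog, k=11)
    rec = toy3_catalog.records[0]
    read = list(rec.sequence[20:120])
    read[50] = "N"
    hit = align_read("".join(read), idx)
    assert hit is not None
    assert hit.accession == rec.accession
    assert hit.aligned_length == 100
    assert hit.identity == pytest.approx(99 / 100)


def test_same_category_tie_takes_lexicographically_smallest():
    seq = "".join(np.random.default_rng(1).choice(list("ACGT"), 200))
    r1 = RrnaRecord.build("B2", "28S ribosomal RNA gene", seq)
    r2 = RrnaRecord.build("B1", "28S ribosomal RNA gene", seq)
    idx = build_index(Catalog([r1, r2]), k=11)
    hit = align_read(seq[50:150], idx)
    assert hit is not None and hit.accession == "B1"


def test_cross_category_tie_is_discarded_as_ambiguous():
    seq = "".join(np.random.default_rng(2).choice(list("ACGT"), 200))
    r1 = RrnaRecord.build("A1", "18S ribosomal RNA gene", seq)
    r2 = RrnaRecord.build("B1", "28S ribosomal RNA gene", seq)
    catalog = Catalog([r1, r2])
    idx = build_index(catalog, k=11)
    assert align_read(seq[50:150], idx) is None
    reads = [CleanRead("r0", seq[50:150], "normal", "hMeDIP")]
    table, report = assign_all(reads, catalog=catalog)
    assert report["ambiguous"] == 1 and report["assigned"] == 0
    assert table.cells == {}


def test_assignment_conservation_and_counts(toy3_catalog):
    rec = toy3_catalog.records[0]
    reads = [
        CleanRead(f"r{i}", rec.sequence[i : i + 80], "normal", "hMeDIP")
        for i in range(10)
    ]
    table, report = assign_all(reads, catalog=toy3_catalog)
    assert table.get(rec.accession, "normal", "hMeDIP") == 10.0
    assert (
        report["assigned"] + report["unassigned"] + report["ambiguous"]
        == report["total"]
        == 10
    )


def test_empty_read_stream_warns_and_returns_empty_table(toy3_catalog):
    with pytest.warns(UserWarning, match="empty read stream"):
        table, report = assign_all([], catalog=toy3_catalog)
    assert report["total"] == 0 and table.cells == {}


def test_assignments_independent_of_read_order(toy3_catalog):
    rng = np.random.default_rng(7)
    refs = [r.sequence for r in toy3_catalog]
    reads = []
    for i in range(120):
        src = refs[int(rng.integers(0, 3))]
        start = int(rng.integers(0, len(src) - 100))
        seq = _mutate(rng, src[start : start + 100], int(rng.integers(0, 3)))
        reads.append(CleanRead(f"r{i}", seq, "normal", "hMeDIP"))
    t1, _ = assign_all(reads, catalog=toy3_catalog)
    shuffled = reads[::-1]
    t2, _ = assign_all(shuffled, catalog=toy3_catalog)
    assert t1.cells == t2.cells


def test_reads_shorter_than_seed_are_unassigned(toy3_catalog):
    idx = build_index(toy3_catalog, k=11)
    assert align_read("ACGTACG", idx) is None


def test_mapper_agrees_with_exhaustive_offset_oracle(toy3_catalog):
    """Seed-and-extend equals per-offset exhaustive local alignment on a toy set."""
    params = AlignmentParams()
    idx = build_index(toy3_catalog, k=params.k)
    refs = {r.accession: r.sequence for r in toy3_catalog}
    cats = {r.accession: r.category for r in toy3_catalog}
    rng = np.random.default_rng(42)
    reads = []
    for i in range(150):  # planted reads, 0-3 substitution errors
        rec = toy3_catalog.records[int(rng.integers(0, 3))]
        start = int(rng.integers(0, rec.length - 125))
        seq = _mutate(rng, rec.sequence[start : start + 125], int(rng.integers(0, 4)))
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(seq)
    for i in range(50):  # random reads, should fail the filters
        reads.append("".join(rng.choice(list("ACGT"), 125)))

    results = map_sequences(reads, idx, params)
    for seq, (status, payload) in zip(reads, results):
        o_status, o_acc, o_score = exhaustive_align(seq, refs, cats, params)
        assert status == o_status
        if status == "assigned":
            assert payload[0] == o_acc
            assert payload[1] == o_score
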