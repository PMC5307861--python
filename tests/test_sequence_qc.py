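"""Six-frame ORF finder and lncRNA candidate screening rules."""

from itertools import combinations

import numpy as np
import pytest

from lncpop import (TranscriptRecord, classify_candidates,
                    characterize_classes, gc_content, longest_orf)
from lncpop.sequence_qc import reverse_complement
from lncpop.errors import InputError, InsufficientDataError

STOPS = ("TAA", "TAG", "TGA")


def orf_oracle(seq):
    """Brute force: every (strand, start, stop) triple, O(L^2)."""
    best = 0
    for s in (seq, reverse_complement(seq)):
        n = len(s)
        for i in range(n - 2):
            if s[i:i + 3] != "ATG":
                continue
            for j in range(i + 3, n - 2, 3):
                codon = s[j:j + 3]
                if "N" in codon:
                    continue
                if codon in STOPS:
                    best = max(best, j + 3 - i)
                    break
    return best


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("ATGTAA", 6),                      # minimal start+stop
        ("CCCCCC", 0),                      # no start codon
        ("ATGAAACCC", 0),                   # start, never closed
        ("ATGNAATAA", 9),                   # N never matches a stop codon
        ("ATGTNA", 0),                      # N-containing codon is no stop
        ("TTACAT", 6),                      # ORF only on the reverse strand
        ("ATGATGAAATAA", 12),               # nested start, outer ORF wins
    ],
)
def test_longest_orf_examples(seq, expected):
    assert longest_orf(seq) == expected
    assert longest_orf(seq) == orf_oracle(seq)


def test_longest_orf_rejects_illegal_character():
    with pytest.raises(InputError, match="position 2"):
        longest_orf("ATXGGG")


def test_longest_orf_matches_bruteforce_on_random_sequences():
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    for _ in range(300):
        n = int(rng.integers(30, 601))
        seq = "".join(bases[rng.integers(0, 4, n)])
        assert longest_orf(seq) == orf_oracle(seq)


def test_longest_orf_with_ambiguity_codes_matches_bruteforce():
    rng = np.random.default_rng(8)
    bases = np.array(list("ACGTN"))
    for _ in range(150):
        n = int(rng.integers(30, 301))
        seq = "".join(bases[rng.integers(0, 5, n)])
        assert longest_orf(seq) == orf_oracle(seq)


def test_longest_orf_is_strand_symmetric():
    rng = np.random.default_rng(9)
    bases = np.array(list("ACGT"))
    for _ in range(100):
        seq = "".join(bases[rng.integers(0, 4, int(rng.integers(30, 400)))])
        assert longest_orf(seq) == longest_orf(reverse_complement(seq))


def test_gc_content_excludes_ambiguous_bases():
    assert gc_content("GGCC") == 1.0
    assert gc_content("ATGCNN") == pytest.approx(0.5)
    assert np.isnan(gc_content("NNN"))


def _record(id, length, orf):
    """A synthetic record with prescribed length and ORF length."""
    seq = "C" * length  # content irrelevant; metrics are set directly
    return TranscriptRecord(id=id, sequence=seq, length=length,
                            gc_content=0.5, longest_orf_bp=orf)


def test_classify_candidates_rules_and_partition():
    records = [
        _record("short", 150, 0),      # fails length rule first
        _record("coding", 400, 180),   # 180 bp ORF >= 150 -> coding
        _record("lnc", 400, 90),       # passes both rules
        _record("edge_len", 200, 0),   # 'over 200 bp' is strict
        _record("edge_orf", 400, 150), # 'smaller than 150' is strict
    ]
    out = classify_candidates(records).set_index("feature_id")
    assert out.loc["short", "decision"] == "rejected_short"
    assert out.loc["coding", "decision"] == "rejected_coding"
    assert out.loc["lnc", "decision"] == "candidate_lncRNA"
    assert out.loc["edge_len", "decision"] == "rejected_short"
    assert out.loc["edge_orf", "decision"] == "rejected_coding"
    # every record lands in exactly one partition
    assert len(out) == len(records)
    # a short transcript's reason reports the first failed rule
    assert "length" in out.loc["short", "reason"]


def test_classify_candidates_requires_records():
    with pytest.raises(InsufficientDataError):
        classify_candidates([])


def wilcoxon_exact_oracle(a, b):
    """Two-sided rank-sum p by enumerating all rank assignments."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in a)
    n = len(pooled)
    rank_values = list(range(1, n + 1))
    sums = [sum(c) for c in combinations(rank_values, len(a))]
    mean = np.mean(sums)
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-9 for s in sums)
    return extreme / len(sums)


def test_characterize_classes_medians_and_exact_wilcoxon():
    lnc = [_record(f"l{i}", L, 0) for i, L in enumerate([200, 300, 400])]
    mrna = [_record(f"m{i}", L, 300) for i, L in enumerate([1400, 1500, 1600])]
    out = characterize_classes(lnc, mrna)
    assert out["summary"]["lncRNA"]["median_length"] == 300
    assert out["summary"]["mRNA"]["median_length"] == 1500
    expected_p = wilcoxon_exact_oracle([200, 300, 400], [1400, 1500, 1600])
    assert expected_p == pytest.approx(2 / 20)  # complete separation of ranks
    assert out["tests"]["length"]["wilcoxon_p"] == pytest.approx(expected_p)


def test_characterize_classes_null_case():
    a = [_record(f"a{i}", L, 0) for i, L in enumerate([300, 400, 500])]
    b = [_record(f"b{i}", L, 0) for i, L in enumerate([300, 400, 500])]
    out = characterize_classes(a, b)
    assert out["tests"]["length"]["wilcoxon_p"] == pytest.approx(1.0)
    assert (out["summary"]["lncRNA"]["mean_length"]
            == out["summary"]["mRNA"]["mean_length"])


def test_characterize_classes_needs_two_records_per_class():
    with pytest.raises(InsufficientDataError):
        characterize_classes([_record("a", 300, 0)],
                             [_record("b", 300, 0), _record("c", 400, 0)])
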