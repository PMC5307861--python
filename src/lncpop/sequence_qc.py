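"""Sequence-rule screening of assembled transcripts into lncRNA candidates.

A transcript is a candidate long non-coding RNA when it is longer than
``min_length_bp`` (default 200) and its longest open reading frame over
all six reading frames is shorter than ``max_orf_bp`` (default 150).
An ORF is ATG .. in-frame stop with no internal in-frame stop, its
length counted in nucleotides including the stop codon; a start codon
with no downstream in-frame stop does not count (the assembled
transcript is treated as complete).  Codons containing N never match a
start or a stop, and N bases are excluded from GC content entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, InsufficientDataError

__all__ = [
    "TranscriptRecord",
    "longest_orf",
    "gc_content",
    "reverse_complement",
    "classify_candidates",
    "characterize_classes",
]

_VALID = set("ACGTN")
_STOPS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGTN", "TGCAN")


def _validate(sequence: str) -> str:
    if not sequence:
        raise InputError("empty sequence")
    seq = sequence.upper()
    for pos, ch in enumerate(seq):
        if ch not in _VALID:
            raise InputError(f"illegal character {ch!r} at position {pos}")
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMP)[::-1]


def _longest_orf_one_strand(seq: str) -> int:
    best = 0
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                # ambiguity breaks codon matching: an open ORF cannot be
                # closed by, nor started at, an N-containing codon
                continue
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def longest_orf(sequence: str, both_strands: bool = True) -> int:
    """Length in nt (incl. stop codon) of the longest ORF; 0 if none.

    Scans all six reading frames by default; ``both_strands=False``
    restricts to the three forward frames.
    """
    seq = _validate(sequence)
    best = _longest_orf_one_strand(seq)
    if both_strands:
        best = max(best, _longest_orf_one_strand(reverse_complement(seq)))
    return best


def gc_content(sequence: str) -> float:
    """G+C fraction with N excluded from numerator and denominator."""
    seq = _validate(sequence)
    informative = len(seq) - seq.count("N")
    if informative == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / informative


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript with its screening-relevant sequence metrics."""

    id: str
    sequence: str
    length: int
    gc_content: float
    longest_orf_bp: int

    @classmethod
    def from_sequence(cls, id: str, sequence: str) -> "TranscriptRecord":
        seq = _validate(sequence)
        return cls(
            id=id,
            sequence=seq,
            length=len(seq),
            gc_content=gc_content(seq),
            longest_orf_bp=longest_orf(seq),
        )


def classify_candidates(
    records: list[TranscriptRecord],
    min_length_bp: int = 200,
    max_orf_bp: int = 150,
) -> pd.DataFrame:
    """Partition transcripts into lncRNA candidates and rejects.

    A record is a candidate iff ``length > min_length_bp`` (strict) and
    ``longest_orf_bp < max_orf_bp`` (strict).  The length rule is tested
    first, so a short transcript is ``rejected_short`` regardless of its
    ORF content.  Returns a DataFrame with one row per record and
    columns ``feature_id``, ``length_bp``, ``gc``, ``longest_orf_bp``,
    ``decision`` (``candidate_lncRNA`` / ``rejected_short`` /
    ``rejected_coding``) and ``reason``.
    """
    if not records:
        raise InsufficientDataError("classify_candidates needs >= 1 record")
    rows = []
    for rec in records:
        if rec.length <= min_length_bp:
            decision = "rejected_short"
            reason = f"length {rec.length} <= {min_length_bp} bp"
        elif rec.longest_orf_bp >= max_orf_bp:
            decision = "rejected_coding"
            reason = f"longest ORF {rec.longest_orf_bp} >= {max_orf_bp} bp"
        else:
            decision = "candidate_lncRNA"
            reason = ""
        rows.append(
            {
                "feature_id": rec.id,
                "length_bp": rec.length,
                "gc": rec.gc_content,
                "longest_orf_bp": rec.longest_orf_bp,
                "decision": decision,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def characterize_classes(
    lnc: list[TranscriptRecord], mrna: list[TranscriptRecord]
) -> dict:
    """Length/GC summaries per class plus two-sample t and Wilcoxon tests.

    Mirrors the standard characterisation contrast: lncRNAs tend to be
    shorter and lower-GC than mRNAs.  Returns a dict with per-class
    summaries and, for each of ``length`` and ``gc``, the t-test and
    Wilcoxon rank-sum (Mann-Whitney) p-values.
    """
    for name, coll in (("lnc", lnc), ("mrna", mrna)):
        if len(coll) < 2:
            raise InsufficientDataError(
                f"collection {name!r} has {len(coll)} record(s); need >= 2"
            )
    out: dict = {"summary": {}, "tests": {}}
    data = {
        "lncRNA": {
            "length": np.array([r.length for r in lnc], dtype=float),
            "gc": np.array([r.gc_content for r in lnc], dtype=float),
        },
        "mRNA": {
            "length": np.array([r.length for r in mrna], dtype=float),
            "gc": np.array([r.gc_content for r in mrna], dtype=float),
        },
    }
    for cls, d in data.items():
        out["summary"][cls] = {
            "n": int(d["length"].size),
            "mean_length": float(d["length"].mean()),
            "median_length": float(np.median(d["length"])),
            "median_gc": float(np.median(d["gc"])),
        }
    for metric in ("length", "gc"):
        a, b = data["lncRNA"][metric], data["mRNA"][metric]
        t_stat, t_p = sps.ttest_ind(a, b, equal_var=False)
        try:
            w_stat, w_p = sps.mannwhitneyu(a, b, alternative="two-sided")
        except ValueError:  # all values identical
            w_stat, w_p = float("nan"), 1.0
        out["tests"][metric] = {
            "t_stat": float(t_stat),
            "t_p": float(t_p),
            "wilcoxon_stat": float(w_stat),
            "wilcoxon_p": float(w_p),
        }
    return out
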