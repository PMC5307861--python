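"""Screen simulated transcripts into lncRNA candidates.

Applies the sequence rules — length > 200 bp, longest six-frame ORF
< 150 bp — to the simulated transcript FASTA and characterises the
length/GC contrast between the candidate and coding classes.
"""

from common import SCRATCH, write_result
from lncpop import TranscriptRecord, characterize_classes, classify_candidates
from lncpop import io as lio


def main():
    fasta = SCRATCH / "data" / "transcripts.fasta"
    if not fasta.exists():
        raise SystemExit("run 01_simulate_population.py first")
    records = [TranscriptRecord.from_sequence(n, s)
               for n, s in lio.read_fasta(fasta)]
    screen = classify_candidates(records)
    counts = screen["decision"].value_counts().to_dict()
    cand_ids = set(screen.loc[screen["decision"] == "candidate_lncRNA",
                              "feature_id"])
    cand = [r for r in records if r.id in cand_ids]
    coding = [r for r in records if r.id.startswith("cd")]
    chars = characterize_classes(cand, coding)
    summary = {"decisions": counts, "characterization": chars}
    write_result("02_sequence_screen.json", summary)
    print(f"screened {len(records)} transcripts: {counts}")
    print(f"candidate median GC "
          f"{chars['summary']['lncRNA']['median_gc']:.3f} vs coding "
          f"{chars['summary']['mRNA']['median_gc']:.3f} "
          f"(Wilcoxon p = {chars['tests']['gc']['wilcoxon_p']:.2e})")


if __name__ == "__main__":
    main()
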