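"""Simulate the two-environment population FPKM dataset.

Generates the default study conditions — 40 individuals per environment,
600 lncRNAs + 900 mRNAs with planted fold changes, diversity inflation,
co-expression modules and a trait — and writes the full dataset to
scratch/ (large) plus a compact summary to results/.
"""

from common import SCRATCH, get_dataset, write_result
from lncpop import io as lio
from lncpop.simulate import config_to_dict, simulate_sequences


def main():
    matrix, truth, trait, cfg = get_dataset()
    out = SCRATCH / "data"
    lio.write_expression(matrix, out)
    lio.write_trait(trait, out / "trait.tsv")
    seqs = simulate_sequences(n_noncoding=300, n_coding=300,
                              length_range=(150, 2000), seed=cfg.seed)
    lio.write_fasta(seqs, out / "transcripts.fasta")
    lio.write_json(truth.to_json_dict(), out / "truth.json")
    summary = {
        "config": config_to_dict(cfg),
        "n_features": matrix.n_features,
        "n_individuals": matrix.n_individuals,
        "n_planted_de": len(truth.de_features),
        "n_module_features": len(truth.module_assignments),
        "n_trait_genes": len(truth.trait_genes),
        "data_dir": str(out),
    }
    write_result("01_simulation_summary.json", summary)
    print(f"simulated {matrix.n_features} features x "
          f"{matrix.n_individuals} individuals -> {out}")
    print(f"planted: {len(truth.de_features)} DE features, "
          f"{len(truth.module_assignments)} module members, "
          f"{len(truth.trait_genes)} trait genes")


if __name__ == "__main__":
    main()
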