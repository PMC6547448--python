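#!/usr/bin/env python
"""Generate the study-scale synthetic dataset: 850 metabolic genes, 21 TFs,
four chemostat-like conditions.

The planted truth has six activating TFs (most behind a binding threshold,
one saturating), a strongly collinear TF pair, a multiplicative pair and
Gaussian expression noise calibrated so the generating model explains a
realistic minority share of expression variance.  Writes binding matrices,
FPKM tables, pseudo-counts, the TSS table and the truth record under
results/study_data/.
"""

from pathlib import Path

from tfscribe import chip, synthetic

OUT = Path("results/study_data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = synthetic.default_truth(seed=20240901)
    bundle = synthetic.generate_bundle(truth)

    (OUT / "truth.json").write_text(truth.to_json())
    chip.write_tss_table(bundle.tss, OUT / "tss.tsv")
    bundle.counts.to_csv(OUT / "counts.tsv", sep="\t", index_label="gene_id")
    bundle.expression.to_csv(OUT / "fpkm.tsv", sep="\t", index_label="gene_id")
    for cond, mat in bundle.binding.items():
        mat.to_tsv(OUT / f"binding_{cond}.tsv")

    print(f"truth: {len(truth.active_tfs)} active TFs of {truth.n_tfs}; "
          f"collinear pair {truth.collinear_pairs}; interaction {truth.interaction_pair}")
    print(f"wrote {truth.n_genes} genes x {truth.n_tfs} TFs x "
          f"{len(truth.conditions)} conditions under {OUT}")


if __name__ == "__main__":
    main()
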