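"""Lineage-specific phasic programs and the scrambled-lineage null.

The interaction caller tests, per lineage, whether a gene's G1-vs-G2/M
difference departs from the reference lineage, on pseudobulk matched by
(phase, lineage).  The empirical negative control rebuilds pseudobulk from
same-phase cells of mixed lineages with matched sample counts: a genuine
lineage-specific program survives matching and vanishes under scrambling.
"""
from phasic.containers import PipelineConfig
from phasic.io import write_results
from phasic.sc import (filter_genes_sc, interaction_phasic_test,
                       qc_filter_cells)
from phasic.simulate import preset_params, simulate_sc

OUT = "results/05_interaction_calls.tsv"


def main() -> None:
    cfg = PipelineConfig()
    counts, ann, truth = simulate_sc(preset_params("sc-interaction", 1))
    counts, ann = qc_filter_cells(counts, ann, cfg)
    counts = filter_genes_sc(counts, cfg)
    planted = set(truth.loc[truth["is_phasic"], "gene_id"])

    matched = interaction_phasic_test(counts, ann, cfg, "A", seed=1)
    scrambled = interaction_phasic_test(counts, ann, cfg, "A", seed=1,
                                        scrambled=True)
    write_results(matched[matched["phasic_call"]], OUT)
    rec = len(set(matched.loc[matched["phasic_call"], "gene_id"]) & planted)
    print(f"matched-lineage pseudobulk: {int(matched['phasic_call'].sum())} "
          f"interaction calls; {rec}/{len(planted)} planted lineage-B genes "
          f"recovered")
    print(f"scrambled-lineage pseudobulk: "
          f"{int(scrambled['phasic_call'].sum())} calls "
          f"(lineage signal is abolished by mixing)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
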