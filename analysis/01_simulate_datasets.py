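"""Generate the standard synthetic datasets and summarize what was planted.

Every downstream analysis regenerates its data from a named preset, so
this driver only records the study conditions: dataset sizes, planted
effect counts, and how many cells the QC filters remove.
"""
import pandas as pd

from phasic.containers import PipelineConfig
from phasic.sc import filter_genes_sc, qc_filter_cells
from phasic.simulate import preset_params, simulate_bulk_exon_intron, simulate_sc

OUT = "results/01_dataset_summary.tsv"


def main() -> None:
    cfg = PipelineConfig()
    rows = []
    for preset in ("sc-null", "sc-phasic", "sc-interaction"):
        params = preset_params(preset, seed=1)
        counts, ann, truth = simulate_sc(params)
        kept, _ = qc_filter_cells(counts, ann, cfg)
        genes = filter_genes_sc(kept, cfg)
        rows.append({
            "preset": preset,
            "n_genes": counts.n_genes,
            "n_cells": counts.n_units,
            "n_planted_phasic": int(truth["is_phasic"].sum()),
            "cells_after_qc": kept.n_units,
            "genes_after_filter": genes.n_genes,
        })
    pair = preset_params("genotype-pair", seed=1)
    for name, params in pair.items():
        counts, ann, truth = simulate_sc(params)
        rows.append({
            "preset": f"genotype-pair/{name}",
            "n_genes": counts.n_genes,
            "n_cells": counts.n_units,
            "n_planted_phasic": int(truth["is_phasic"].sum()),
            "cells_after_qc": "",
            "genes_after_filter": "",
        })
    ds, truth = simulate_bulk_exon_intron(**preset_params("bulk-decomp", 1))
    rows.append({
        "preset": "bulk-decomp",
        "n_genes": ds.exon.n_genes,
        "n_cells": ds.exon.n_units,
        "n_planted_phasic": int(truth["is_phasic"].sum()),
        "cells_after_qc": "",
        "genes_after_filter": "",
    })
    table = pd.DataFrame(rows)
    table.to_csv(OUT, sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
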