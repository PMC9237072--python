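"""Exon/intron decomposition: is phasic expression transcription- or
stability-driven?

Introns turn over fast, so intronic abundance tracks transcription.  Among
expression-phasic genes, phasic introns mean phasic transcription; phasic
exon/intron ratios with flat introns mean phasic stability.  On the bulk
preset (50/50/20 planted TRANSCRIPTION/STABILITY/BOTH drivers) the
classifier recovers the planted classes with ~95% accuracy among resolved
genes.
"""
import pandas as pd

from phasic.bulk import decompose_transcription_stability
from phasic.simulate import preset_params, simulate_bulk_exon_intron

OUT = "results/03_decomposition.tsv"


def main() -> None:
    ds, truth = simulate_bulk_exon_intron(**preset_params("bulk-decomp", 1))
    table = decompose_transcription_stability(ds, alpha=0.1)
    table[table["class"] != "NOT_PHASIC"].to_csv(OUT, sep="\t", index=False,
                                                 na_rep="NA")
    merged = table.set_index("gene_id").join(
        truth.set_index("gene_id")[["driver_class"]])
    print("class counts:", merged["class"].value_counts().to_dict())
    resolved = merged["class"].isin(["TRANSCRIPTION", "STABILITY", "BOTH"])
    acc = (merged.loc[resolved, "class"]
           == merged.loc[resolved, "driver_class"]).mean()
    print(f"class recovery among {int(resolved.sum())} resolved calls: {acc:.3f}")
    confusion = merged.loc[resolved].groupby(
        ["driver_class", "class"]).size().unstack(fill_value=0)
    print(confusion.to_string())
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
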