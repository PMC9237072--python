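"""Phase preference of per-cell activity scores (KS test).

Regulon-style activity scores are compared between G1 and G2/M cells with
a two-sided two-sample Kolmogorov-Smirnov test; an activity is called
phase-specific below the stringent P < 1e-12 cut-off.  A 1-sigma shift at
n = 1000 cells per phase clears the threshold; no shift never does.
"""
import pandas as pd

from phasic.simulate import simulate_activity_scores
from phasic.stats import ks_phase_preference

OUT = "results/08_phase_preference.tsv"


def main() -> None:
    rows = []
    for shift in (0.0, 0.25, 0.5, 1.0):
        scores, phases = simulate_activity_scores(1000, shift, seed=1)
        d, p, specific = ks_phase_preference(scores, phases)
        rows.append({"shift": shift, "ks_D": round(d, 4), "p_value": p,
                     "phase_specific": specific})
    table = pd.DataFrame(rows)
    table.to_csv(OUT, sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
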