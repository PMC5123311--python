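#!/usr/bin/env python
"""Baseline-vs-effect AUEC analysis of the simulated cohort.

Computes, per blood parameter, the trapezoidal AUEC over the baseline
(-36..0 h) and post-dose (0..72 h) windows, the baseline-normalised A/B
change ratio, the paired-t significance of A/72 vs B/36, pooled RSD%
variability, and the post-dose dynamic extrema. Writes
results/effect_table.csv and prints the significant parameters.
"""

from pathlib import Path

from dipyrone_pd import make_effect_table, read_dataset
from dipyrone_pd.effects import effect_table_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort_csv = ROOT / "results" / "cohort.csv"
    if not cohort_csv.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    dataset = read_dataset(cohort_csv)
    rows = make_effect_table(dataset)
    frame = effect_table_frame(rows)
    frame.to_csv(ROOT / "results" / "effect_table.csv", index=False)
    print(frame.round(4).to_string(index=False))
    significant = [r.parameter for r in rows if not r.degenerate and r.p_value < 0.05]
    print(f"\nsignificant at p < 0.05: {', '.join(significant)}")


if __name__ == "__main__":
    main()
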