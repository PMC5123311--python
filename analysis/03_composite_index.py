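#!/usr/bin/env python
"""Composite hemorheological indices vs metabolite concentration.

Evaluates PT + (Hb + Hct)/RBC^APTT_ratio and MCV + PT on cohort-mean values
at each post-dose time, writes the series to results/, and reports the
squared Pearson correlation of each index with the 4MAA and 4AA plasma
profiles.
"""

from pathlib import Path

from dipyrone_pd import index_series, pearson_r2, read_dataset
from dipyrone_pd.indices import index_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    dataset = read_dataset(ROOT / "results" / "cohort.csv")
    for name in ("composite", "mcv_pt"):
        points = index_series(dataset, index=name, time_window=(0.0, 72.0))
        index_frame(points).to_csv(ROOT / "results" / f"index_{name}.csv", index=False)
        times = [p.time_h for p in points]
        y = [p.value for p in points]
        for analyte in ("4MAA", "4AA"):
            conc = dict(dataset.get_metabolite(analyte).samples)
            x = [conc[t] for t in times]
            res = pearson_r2(x, y)
            print(f"{name:10s} vs {analyte}: r2 = {res.r_squared:.4f} "
                  f"(p = {res.p_value:.4g}, n = {res.n})")


if __name__ == "__main__":
    main()
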