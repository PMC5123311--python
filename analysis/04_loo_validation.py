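#!/usr/bin/env python
"""Leave-one-out validation of the metabolite <-> composite-index models.

Fits index = b0 + b1 * concentration for each analyte, runs the LOO
procedure (PRESS, Q2, Q2_asym) and applies the four-criterion acceptance
gate: 0 < Q2_asym - Q2 < 1, Q2 >= 0.65, R2 >= 0.85, Q2 - R2 < 0. Writes one
flat key=value report per analyte under results/.
"""

from pathlib import Path

from dipyrone_pd import index_series, read_dataset, validate_relationship

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    dataset = read_dataset(ROOT / "results" / "cohort.csv")
    points = index_series(dataset, index="composite", time_window=(0.0, 72.0))
    times = [p.time_h for p in points]
    y = [p.value for p in points]
    for analyte in ("4MAA", "4AA"):
        conc = dict(dataset.get_metabolite(analyte).samples)
        x = [conc[t] for t in times]
        report = validate_relationship(x, y)
        out = ROOT / "results" / f"validation_{analyte}.txt"
        out.write_text(
            "".join(f"{k}={v}\n" for k, v in sorted(report.as_dict().items()))
        )
        print(f"{analyte}: Q2={report.q2:.4f} R2={report.r2:.4f} "
              f"Q2asym-Q2={report.q2asym_minus_q2:.4f} PRESS={report.press:.2f} "
              f"SS={report.ss:.2f} -> passed={report.passed}")


if __name__ == "__main__":
    main()
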