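#!/usr/bin/env python
"""RND/RNDmin scan of a synthetic genome with planted introgression.

Builds a 2-Mb three-species genome with planted donor tracts of 10/30/50 kb,
scans it at the three window lengths, calibrates the RNDmin threshold to a
10% false discovery rate against the planted truth, and reports power by
tract length.  Findings: power rises steeply with tract length at every
window size (short tracts rarely dominate a window's divergence signal), and
the calibrated threshold sits well below the native RND background.

Writes results/rnd_calibration.tsv and results/rnd_windows.tsv.
"""

from pathlib import Path

import pandas as pd

from invintro import rnd, synth

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def build_genome():
    L = 2_000_000
    tract_plan = []
    for i, s in enumerate(range(0, 500_000, 50_000)):
        tract_plan.append(synth.TractPlan("chr1", s, s + 10_000,
                                          0.05 if i % 2 else 0.10))
    for i, s in enumerate(range(600_000, 1_100_000, 50_000)):
        tract_plan.append(synth.TractPlan("chr1", s, s + 30_000,
                                          0.05 if i % 2 else 0.10))
    for i, s in enumerate(range(1_200_000, 1_900_000, 70_000)):
        tract_plan.append(synth.TractPlan("chr1", s, s + 50_000,
                                          0.05 if i % 2 else 0.10))
    return synth.simulate_haplotypes(
        synth.SynthPlan(chromosomes={"chr1": L}, seed=99, tract_plan=tract_plan))


def main() -> None:
    data = build_genome()
    f, d, o = data.focal["chr1"], data.donor["chr1"], data.outgroup["chr1"]
    cal_rows, win_rows = [], []
    for win in (10_000, 20_000, 50_000):
        prof = rnd.rnd_profile(f, d, o, win, min_informative=50)
        cal = rnd.calibrate_threshold(prof, data.truth, target_fdr=0.10,
                                      max_truth_freq=0.65)
        cal_rows.append({"window_kb": win // 1000, "threshold": round(cal.threshold, 4),
                         "fdr": round(cal.fdr, 3), "power": round(cal.power, 3),
                         **{f"power_{int(k/1000)}kb": round(v, 3)
                            for k, v in cal.power_by_length.items()}})
        for w in prof:
            win_rows.append({"window_kb": win // 1000, "start": w.start,
                             "end": w.end, "n_informative": w.n_informative,
                             "rnd_min": round(w.rnd_min, 4)})
        print(f"{win // 1000} kb windows: tau={cal.threshold:.3f} "
              f"FDR={cal.fdr:.2f} power={cal.power:.2f} "
              f"by length={ {int(k): round(v, 2) for k, v in cal.power_by_length.items()} }")
    pd.DataFrame(cal_rows).to_csv(OUT / "rnd_calibration.tsv", sep="\t", index=False)
    pd.DataFrame(win_rows).to_csv(OUT / "rnd_windows.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'rnd_calibration.tsv'}")


if __name__ == "__main__":
    main()
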