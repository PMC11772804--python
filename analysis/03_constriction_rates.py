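#!/usr/bin/env python
"""Estimate ring constriction rates from simulated diameter traces.

Two cohorts of 50 traces mimic a control (0.6 um/min) and a slowed
(0.35 um/min) genotype at 2% measurement noise.  Each trace is onset-aligned,
normalized, and fitted on four consecutive in-band timepoints (R^2 > 0.95);
cohorts are compared with a two-sided Mann-Whitney test and the aligned
mean +/- SD curves are exported for plotting.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cytoquant import (
    TraceSpec,
    detect_onset,
    fit_constant_phase,
    generate_constriction_trace,
    mann_whitney_u,
    mean_trace_with_sd,
    normalize_trace,
    render_report,
)

OUT = Path("results")
COHORTS = {"control": (0.6, 0), "slowed": (0.35, 50_000)}
N_TRACES = 50
NOISE_SD_UM = 0.02 * 8.0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fit_rows, rates = [], {}
    for name, (rate, seed_base) in COHORTS.items():
        norms, t0s, kept = [], [], []
        for i in range(N_TRACES):
            spec = TraceSpec(
                rate_um_per_min=rate, noise_sd_um=NOISE_SD_UM,
                n_frames=30, seed=seed_base + i,
            )
            tr = generate_constriction_trace(spec, sample_id=f"{name}_{i:02d}")
            try:
                t0 = detect_onset(tr)
                fit = fit_constant_phase(tr, t0)
            except ValueError:
                continue
            kept.append(fit.rate_um_per_min)
            norms.append(normalize_trace(tr, t0))
            t0s.append(t0)
            fit_rows.append(
                {
                    "sample_id": tr.sample_id, "t0_index": t0,
                    "d_t0_um": fit.d_t0_um, "window_start": fit.window[0],
                    "alpha_um": fit.alpha_um, "beta_um_per_min": fit.beta_um_per_min,
                    "rate_um_per_min": fit.rate_um_per_min, "r2": fit.r2,
                    "group": name,
                }
            )
        rates[name] = kept
        mean_sd = mean_trace_with_sd(norms, t0s, dt_min=1.0)
        mean_sd.to_csv(OUT / f"constriction_mean_trace_{name}.csv", index=False)
        print(f"{name}: {len(kept)}/{N_TRACES} traces fitted, "
              f"rate {np.mean(kept):.3f} +/- {np.std(kept, ddof=1):.3f} um/min "
              f"(true {rate})")

    cmp = mann_whitney_u(
        rates["control"], rates["slowed"], group_a="control", group_b="slowed"
    )
    print(f"control vs slowed: U = {cmp.U:.0f}, two-sided p = {cmp.p_two_sided:.2e} "
          f"({cmp.method})")
    render_report(OUT, constriction_fits=pd.DataFrame(fit_rows), comparisons=[cmp])
    print(f"wrote constriction fits and comparisons under {OUT}/")


if __name__ == "__main__":
    main()
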