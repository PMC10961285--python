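"""Parametric survival modelling: the Weibull MPR treatment model, its PH
special case, the stepwise multi-factor solution, and case-mix adjustment.

Writes coefficient tables (mle, s.e., z) for the treatment-only and stepwise
fits, and the adjusted vs unadjusted treatment tracks at 12 months.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mprsurv.cohort import read_cohort
from mprsurv.mpr import adjusted_tracks, mpr_aic_compare, mpr_fit, mpr_stepwise
from mprsurv.tables import SURVIVAL_CANDIDATE_FACTORS


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort_full.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    frame = read_cohort(args.cohort)

    fit_t = mpr_fit(frame, ("treatment",), ("treatment",))
    fit_ph = mpr_fit(frame, ("treatment",), ())
    diff = mpr_aic_compare(fit_ph, fit_t)
    fit_t.z_table().to_csv(args.out_dir / "mpr_treatment_fit.csv", index=False)
    print(f"treatment-only MPR: loglik={fit_t.loglik:.1f}, AIC={fit_t.aic:.1f}")
    print(f"AIC(PH Weibull) − AIC(non-PH MPR) = {diff:.1f} "
          f"({'non-PH favoured' if diff > 0 else 'PH favoured'})")

    trace: list = []
    fit_s = mpr_stepwise(frame, SURVIVAL_CANDIDATE_FACTORS, trace=trace)
    fit_s.z_table().to_csv(args.out_dir / "mpr_stepwise_fit.csv", index=False)
    fit_s.save_json(args.out_dir / "mpr_stepwise_fit.json")
    print("stepwise solution:")
    print(f"  scale factors: {list(fit_s.scale_spec.factors)}")
    print(f"  shape factors: {list(fit_s.shape_spec.factors)}")
    print(f"  selection path: {trace}")

    months = np.array([12.0])
    adj = adjusted_tracks(fit_s, "treatment", months)
    crude = adjusted_tracks(fit_t, "treatment", months)
    rows = [
        {"treatment": lvl,
         "unadjusted_12mo": float(crude[lvl][0]),
         "adjusted_12mo": float(adj[lvl][0])}
        for lvl in crude
    ]
    tracks = pd.DataFrame(rows)
    tracks.to_csv(args.out_dir / "treatment_tracks_12mo.csv", index=False)
    print(tracks.to_string(index=False))
    sep_c = crude["surgery"][0] - crude["palliative"][0]
    sep_a = adj["surgery"][0] - adj["palliative"][0]
    direction = "shrinks" if sep_a < sep_c else "moves"
    print(f"finding: case-mix adjustment {direction} the surgery-vs-palliative "
          f"1-year separation from {sep_c:.3f} to {sep_a:.3f} in this replicate")


if __name__ == "__main__":
    main()
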