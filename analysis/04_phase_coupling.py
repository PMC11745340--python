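#!/usr/bin/env python
"""SO-phase coupling by sleep stage and along the sleep-depth continuum.

From the stage-interaction model: preferred phase and coupling magnitude
per stage with CIs.  Then refits the night with the SOP×phase model and
traces the preferred phase as a continuous function of normalized SO
power, the depth-continuum view of coupling.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np

from spindlepp.interpret import phase_tuning, preferred_phase_vs_depth
from spindlepp.io import model_from_json, read_bundle
from spindlepp.model import fit_spec


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--model",
        default="results/models/model_stage_phase_interaction_history15.json",
    )
    ap.add_argument("--bundle", default="results/night01")
    ap.add_argument("--out", default="results/phase")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    model = model_from_json(args.model)
    print("preferred SO phase by stage (0 = up-state peak):")
    for stage in ("N1", "N2", "N3"):
        pc = phase_tuning(model, stage)
        note = " (no statistically relevant preferred phase)" \
            if pc.no_preferred_phase else ""
        print(f"  {stage}: phi_pref = {pc.phi_pref:+.3f} rad, "
              f"M = {pc.magnitude:.3f}{note}")
    bundle = read_bundle(args.bundle)
    cov = bundle.covariates(0.1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sop_model = fit_spec(cov, "sop+phase+sopphase+history15")
    depth = preferred_phase_vs_depth(sop_model, np.linspace(0, 1, 21))
    depth.as_frame().to_csv(out / "phase_vs_depth.csv", index=False)
    print(f"\npreferred phase vs sleep depth written to {out}/phase_vs_depth.csv")
    print(f"  phi_pref at SOP=0: {depth.phi_pref[0]:+.3f} rad")
    print(f"  phi_pref at SOP=1: {depth.phi_pref[-1]:+.3f} rad")


if __name__ == "__main__":
    main()
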