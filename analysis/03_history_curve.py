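#!/usr/bin/env python
"""Extract the history modulation curve and its summary features.

Reads the fitted integrated model, computes the multiplicative history
modulation with 95% CI, extracts refractory/excitatory/peak features, and
saves the curve CSV plus a PNG figure.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from spindlepp.interpret import (
    extract_history_features,
    history_modulation_curve,
    plot_history_curve,
)
from spindlepp.io import model_from_json


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--model",
        default="results/models/model_stage_phase_interaction_history15.json",
    )
    ap.add_argument("--out", default="results/history")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    model = model_from_json(args.model)
    curve = history_modulation_curve(model)
    curve.as_frame().to_csv(out / "history_curve.csv", index=False)
    feats = extract_history_features(curve)
    print("history features of the reference night:")
    for k, v in feats.as_dict().items():
        print(f"  {k}: {v:.3f}" if v == v else f"  {k}: undefined")
    ax = plot_history_curve(curve)
    ax.set_title("History modulation (multiplicative effect on spindle rate)")
    ax.figure.savefig(out / "history_curve.png", dpi=120)
    print(f"curve and figure written under {out}/")


if __name__ == "__main__":
    main()
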