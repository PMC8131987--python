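#!/usr/bin/env python
"""Train the 20–50 °C input-range network under the fixed holdout split.

1512/378/378 training/validation/test records; Levenberg–Marquardt with
validation early stopping.  Saves the model JSON, the per-epoch training
log and the per-condition evaluation report under results/holdout/.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from fluorstab import network as nn
from fluorstab.pipeline import INPUT_RANGES, run_tm_recovery
from fluorstab.synthetic import GeneratorSpec

OUT = Path(__file__).resolve().parent.parent / "results" / "holdout"


def main():
    warnings.filterwarnings("ignore")
    OUT.mkdir(parents=True, exist_ok=True)
    opts = nn.TrainOptions(seed=1)
    result = run_tm_recovery(GeneratorSpec(seed=1), INPUT_RANGES["20-50"],
                             opts=opts)
    hist, rep = result.history, result.report

    (OUT / "model_20-50.json").write_text(
        nn.model_to_json(result.net, hist, opts))
    pd.DataFrame({
        "epoch": np.arange(hist.n_epochs), "train_mse": hist.train_mse,
        "val_mse": hist.val_mse, "test_mse": hist.test_mse, "mu": hist.mu,
    }).to_csv(OUT / "training_log.csv", index=False)
    rows = [{
        "concentration_mg_ml": c.concentration, "pH": c.pH,
        "ionic_strength_mM": c.ionic_strength, "rmse_percent": pct,
        "Tm_experimental_C": rep.tm_experimental[c],
        "Tm_predicted_C": rep.tm_predicted[c],
        "Tm_true_C": rep.tm_true[c],
    } for c, pct in rep.rmse_percent.items()]
    pd.DataFrame(rows).to_csv(OUT / "report_20-50.csv", index=False)

    print(f"stopped ({hist.stop_reason}) after {hist.n_epochs} epochs, "
          f"best epoch {hist.best_epoch}")
    print(f"MSE at stop: train {hist.train_mse[-1]:.0f}, "
          f"validation {hist.val_mse[-1]:.0f}, test {hist.test_mse[-1]:.0f}")
    p = rep.parity["all"]
    print(f"Tm parity over 54 conditions: RMSE {p.rmse:.2f} C, "
          f"slope {p.slope:.2f} +/- {p.slope_se:.2f}, R^2 {p.r_squared:.2f}")
    print(f"median per-condition RMSE%: {rep.median_rmse_percent:.2f}")


if __name__ == "__main__":
    main()
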