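"""Jointly fit the seven-parameter observer model to the simulated data.

Reads results/trials.csv (from 01_simulate_observer.py), fits the model to
the raw binomial counts of all ten psychometric functions simultaneously,
compares the fitted noise and prior parameters with the generating values,
and writes the fit and per-cell model-vs-data proportions to results/.
"""

import json
from pathlib import Path

import pandas as pd

from pursuitbayes import (
    FitConfig,
    ObserverParams,
    fit_observer,
    negative_log_likelihood,
    predicted_probabilities,
    trials_to_cells,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 7


def main() -> None:
    trials = pd.read_csv(RESULTS / "trials.csv")
    truth = ObserverParams.from_json(RESULTS / "true_params.json")

    config = FitConfig(n_starts=10, seed=SEED)
    result = fit_observer(trials, config)

    nll_truth = negative_log_likelihood(trials, truth, n_nodes=config.n_nodes)
    print(f"fitted nll = {result.nll:.2f} (generating params: {nll_truth:.2f})")
    print("parameter      truth   fitted")
    fitted = result.params.to_dict()
    for k, v in truth.to_dict().items():
        print(f"  {k:<10} {v:7.3f} {fitted[k]:8.3f}")

    with open(RESULTS / "fit.json", "w") as fh:
        json.dump({**result.to_dict(), "nll_at_truth": nll_truth, "seed": SEED},
                  fh, indent=2)

    cells = trials_to_cells(trials)
    cells["p_model"] = predicted_probabilities(cells, result.params)
    cells["p_data"] = cells["k"] / cells["n"]
    cells.to_csv(RESULTS / "model_vs_data.csv", index=False)
    print(f"wrote {RESULTS / 'fit.json'} and model_vs_data.csv")


if __name__ == "__main__":
    main()
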