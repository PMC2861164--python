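"""Predict the pursuit-illusion family from the reference observer.

For a grid of speeds, computes the Aubert-Fleischl match ratio, the Filehne
velocity, the trajectory direction error and the gain ratio under the
two-estimator model, alongside the null predictions of the summed-likelihood
alternative (which can produce no Filehne illusion and no direction error
for any parameters).  Writes results/illusion_predictions.csv.
"""

from pathlib import Path

import pandas as pd

from pursuitbayes import (
    fixture_observer,
    gain_ratio,
    predict_aubert_fleischl,
    predict_filehne,
    predict_trajectory,
    summed_model_predictions,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SPEEDS = [1.0, 2.0, 4.0, 8.0, 16.0]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    obs = fixture_observer()
    rows = []
    for v in SPEEDS:
        af = predict_aubert_fleischl(v, obs)
        fi = predict_filehne(v, obs)
        tr = predict_trajectory(v, v / 2.0, obs)
        rows.append({
            "speed": v,
            "af_match_speed": af.predicted,
            "af_ratio": af.gain_ratio,
            "filehne_velocity": fi.predicted,
            "trajectory_deviation_deg": tr.predicted,
            "gain_ratio": gain_ratio(v, obs),
            "summed_filehne": summed_model_predictions(
                "filehne", obs, pursuit_speed=v).predicted,
            "summed_trajectory_deg": summed_model_predictions(
                "trajectory", obs, pursuit_speed=v,
                object_vertical_speed=v / 2.0).predicted,
        })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "illusion_predictions.csv", index=False)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print("\nTwo-estimator model: pursued stimuli look slower (af_ratio < 1), "
          "stationary backgrounds drift against pursuit (filehne < 0), "
          "trajectories tilt (deviation > 0). The summed-likelihood columns "
          "are identically zero: one head-centered likelihood cannot "
          "produce these illusions.")


if __name__ == "__main__":
    main()
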