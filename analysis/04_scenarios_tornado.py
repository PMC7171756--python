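"""Scenario analyses and one-way (tornado) sensitivity.

Runs the published scenario set (4-cycle therapy cap, progression rebate,
four utility variants) and a one-way analysis varying each major input over
its range (costs and utilities +/-25%, discount rate 0-5%). Writes
results/scenario_icers.csv and results/tornado.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from hcc_cea import basecase, sensitivity
from hcc_cea.config import DEFAULT_SCENARIOS

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    dists = basecase.calibrated_distributions()
    scenario_frames, tornado_frames = [], []
    for country in ("germany", "us"):
        model = basecase.build_country_model(country, distributions=dists)
        table = sensitivity.run_scenarios(
            DEFAULT_SCENARIOS, lambda spec: basecase.evaluate(model, scenario=spec)
        )
        scenario_frames.append(table)
        print(f"\n{country} scenario ICERs ($/QALY):")
        for _, row in table.iterrows():
            print(f"  {row['scenario']:<32} {row['icer_per_qaly']:>12,.0f}")

        tornado = sensitivity.one_way(
            basecase.default_one_way_params(model),
            basecase.make_model_closure(model),
        )
        tornado.insert(0, "country", country)
        tornado_frames.append(tornado)
        top = tornado.head(2)["param"].tolist()
        print(f"  widest tornado bars: {top[0]}, {top[1]}")

    pd.concat(scenario_frames, ignore_index=True).to_csv(
        ROOT / "results" / "scenario_icers.csv", index=False
    )
    pd.concat(tornado_frames, ignore_index=True).to_csv(
        ROOT / "results" / "tornado.csv", index=False
    )


if __name__ == "__main__":
    main()
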