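#!/usr/bin/env python
"""Adjudicate COPD exacerbations (all follow-up variants) and pneumonia.

Writes per-patient outcome tables under results/outcomes_<variant>.csv and
prints crude event rates by arm and event type.
"""

from pathlib import Path

import pandas as pd

from copdce.adjudicate import adjudicate_cohort
from copdce.cohort import FollowUpSpec
from copdce.data_model import read_claims

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    db = read_claims(ROOT / "data")
    cohort = pd.read_csv(ROOT / "cohort.csv")
    for variant in ("fixed_12mo", "censor_at_switch", "all_available", "severe_only"):
        spec = FollowUpSpec(variant, study_end=2200)
        events, out = adjudicate_cohort(db, cohort, spec)
        out.to_csv(ROOT / f"outcomes_{variant}.csv", index=False)
        if variant == "fixed_12mo":
            events.to_csv(ROOT / "events.csv", index=False)
        rate = out["n_events"].sum() / out["person_years"].sum()
        print(f"{variant:>17}: {out['n_events'].sum():5d} events, "
              f"{rate:.3f}/person-year")
    out = pd.read_csv(ROOT / "outcomes_fixed_12mo.csv")
    by_arm = out.groupby("arm").agg(rate=("n_events", "mean"),
                                    pneumonia=("pneumonia_any", "mean"),
                                    pdc=("pdc", "mean"))
    print("\ncrude per-arm summaries (12-month follow-up):")
    print(by_arm.round(3).to_string())


if __name__ == "__main__":
    main()
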