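#!/usr/bin/env python
"""Apply the new-user inclusion/exclusion rules to the simulated claims.

Reads results/data/, writes the analyzable cohort and the attrition
waterfall under results/, and prints the attrition table.
"""

from pathlib import Path

from copdce.cohort import build_cohort
from copdce.data_model import read_claims

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    db = read_claims(ROOT / "data")
    res = build_cohort(db, (400, 1130))
    res.cohort.to_csv(ROOT / "cohort.csv", index=False)
    res.attrition.to_csv(ROOT / "attrition.csv", index=False)
    print(res.attrition.to_string(index=False))
    arms = res.cohort["index_drug"].value_counts()
    print(f"\ncohort: {len(res.cohort)} patients "
          f"(BFC {arms.get('BFC', 0)}, FSC {arms.get('FSC', 0)}) -> {ROOT}/cohort.csv")


if __name__ == "__main__":
    main()
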