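#!/usr/bin/env python
"""Generate the default synthetic claims study population.

Writes the four claims tables plus the ground-truth files under
results/data/ and prints the headline marginals of what was generated.
"""

from pathlib import Path

from copdce.data_model import write_claims
from copdce.simulate import SimulationConfig, expected_marginals, generate, write_ground_truth

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main():
    cfg = SimulationConfig(n_patients=12000, seed=1)
    db, truth = generate(cfg)
    write_claims(db, OUT)
    write_ground_truth(truth, OUT)
    elig = truth.patients[truth.patients["eligible"]]
    m = expected_marginals(cfg)
    print(f"wrote {len(db.patients)} patients ({len(elig)} eligible), "
          f"{len(db.medical)} medical and {len(db.pharmacy)} pharmacy claims -> {OUT}")
    print(f"intended exacerbation rate {elig['n_events'].mean():.3f}/person-year "
          f"(target {m['exacerbation_rate']:.2f}); "
          f"BFC share {elig['arm'].eq('BFC').mean():.3f} (target {cfg.bfc_share})")


if __name__ == "__main__":
    main()
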